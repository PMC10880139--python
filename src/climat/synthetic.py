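"""Synthetic longitudinal multimodal cohorts.

Generates the kind of data the forecasting model assumes: a baseline image
whose geometry encodes the current ordinal severity grade, scalar clinical
covariates one of which modulates the progression rate, and a non-decreasing
ordinal severity trajectory over T follow-up horizons with optional
missingness in both targets and covariates.

The imaging phenotype mimics joint-space narrowing on a radiograph: two
bright horizontal bands whose inter-band gap shrinks strictly with severity,
plus small bright blobs ("osteophytes") appearing at higher grades.  3D
volumes extrude the same pattern along the depth axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "is_missing",
    "TrajectoryConfig",
    "PatientRecord",
    "generate_cohort",
    "sample_trajectory",
    "render_image",
    "apply_missingness",
    "measure_gap",
    "save_cohort",
    "load_cohort",
]


class _MissingType:
    """Sentinel for an unobserved covariate or target."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"


MISSING = _MissingType()


def is_missing(value) -> bool:
    return value is MISSING


CONTINUOUS_RANGES = {"age": (45.0, 79.0), "bmi": (18.0, 36.0)}
CATEGORICAL_LEVELS = {"sex": 2, "injury": 2}
COVARIATE_NAMES = ("sex", "injury", "age", "bmi")


@dataclass(frozen=True)
class TrajectoryConfig:
    """Study-design parameters of a synthetic cohort.

    ``n_classes_per_task`` lists the number of severity classes of each of the
    T+1 prediction targets.  ``progression_rate_range`` bounds the per-step
    probability of advancing one severity grade; the body-mass covariate
    shifts each subject's rate by ``covariate_effect * (bmi_std - 0.5)`` so
    that one clinical variable is genuinely informative about progression.
    """

    n_subjects: int = 600
    T: int = 4
    n_classes_per_task: tuple = (5, 5, 5, 5, 5)
    image_size: tuple = (64, 64)
    progression_rate_range: tuple = (0.05, 0.5)
    missing_target_rate: float = 0.3
    missing_covariate_rate: float = 0.1
    noise_sd: float = 0.05
    progressive: bool = True
    seed: int = 0
    baseline_prior: tuple | None = None
    covariate_effect: float = 0.3

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if len(self.n_classes_per_task) != self.T + 1:
            raise ValueError(
                f"n_classes_per_task must have T+1={self.T + 1} entries, "
                f"got {len(self.n_classes_per_task)}"
            )
        if any(nc < 2 for nc in self.n_classes_per_task):
            raise ValueError("every task needs at least 2 classes")
        if len(self.image_size) not in (2, 3) or any(d < 8 for d in self.image_size):
            raise ValueError("image_size must be (H, W) or (D, H, W) with dims >= 8")
        lo, hi = self.progression_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("progression_rate_range must be an interval within [0, 1]")
        for name in ("missing_target_rate", "missing_covariate_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.baseline_prior is not None:
            p = np.asarray(self.baseline_prior, dtype=float)
            if len(p) != self.n_classes_per_task[0]:
                raise ValueError("baseline_prior length must equal the baseline class count")
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("baseline_prior must be a probability vector")


@dataclass
class PatientRecord:
    """One subject: baseline image, clinical covariates, severity trajectory.

    ``target_mask[t]`` is False exactly when ``targets[t]`` is MISSING.  The
    baseline target (t=0) is always observed, matching a training regime in
    which the current diagnosis is always supervised.
    """

    subject_id: str
    image: np.ndarray
    covariates: dict
    targets: list
    target_mask: list
    morphology_seed: int = 0

    def __post_init__(self):
        if len(self.targets) != len(self.target_mask):
            raise ValueError("targets and target_mask must have equal length")
        for t, (y, m) in enumerate(zip(self.targets, self.target_mask)):
            if m == is_missing(y):
                raise ValueError(f"target_mask[{t}] inconsistent with targets[{t}]")


def sample_trajectory(
    baseline_class: int,
    rate: float,
    T: int,
    n_classes: Sequence[int],
    progressive: bool,
    rng: np.random.Generator,
) -> list:
    """Markov ordinal trajectory: advance one grade per step w.p. ``rate``.

    The latent state is clipped at the top grade of the final task; the
    emitted label at horizon t is clipped to that task's class range.  When
    ``progressive`` is False the state may additionally regress one grade
    with probability 0.2 * rate.
    """
    if not 0 <= baseline_class < n_classes[0]:
        raise ValueError(
            f"baseline_class {baseline_class} out of range for {n_classes[0]} classes"
        )
    top = max(n_classes) - 1
    latent = baseline_class
    out = [min(latent, n_classes[0] - 1)]
    for t in range(1, T + 1):
        if rng.random() < rate:
            latent = min(latent + 1, top)
        elif not progressive and rng.random() < 0.2 * rate:
            latent = max(latent - 1, 0)
        out.append(min(latent, n_classes[t] - 1))
    return out


def _band_geometry(H: int, n_levels: int):
    g0 = H // 3
    step = max(1, (g0 - 1) // max(1, n_levels - 1))
    if g0 - (n_levels - 1) * step < 1:
        raise ValueError(
            f"image height {H} too small to encode {n_levels} distinct severity levels"
        )
    return g0, step


def render_image(
    severity: int,
    morphology_seed: int,
    noise_sd: float,
    size: Sequence[int],
    n_levels: int = 5,
) -> np.ndarray:
    """Render a severity-coded image; deterministic given its arguments.

    The gap between the two bright bands decreases strictly with
    ``severity``; grades >= 2 additionally receive ``severity`` bright blobs
    in the outer column thirds (the central third stays clean so the gap
    remains measurable there).
    """
    if not 0 <= severity < n_levels:
        raise ValueError(f"severity {severity} out of range for {n_levels} levels")
    size = tuple(int(d) for d in size)
    is_3d = len(size) == 3
    H, W = size[-2], size[-1]
    g0, step = _band_geometry(H, n_levels)
    gap = g0 - severity * step
    th = max(1, H // 10)
    rng = np.random.default_rng(morphology_seed)
    jitter_span = max(1, H // 16)
    center = H // 2 + int(rng.integers(-jitter_span, jitter_span + 1))

    plane = np.full((H, W), 0.1)
    top_hi = center - gap // 2
    top_lo = max(0, top_hi - th)
    bot_lo = center + (gap + 1) // 2
    bot_hi = min(H, bot_lo + th)
    plane[top_lo:top_hi, :] = 0.9
    plane[bot_lo:bot_hi, :] = 0.9
    if severity >= 2:
        r = max(1, H // 20)
        for _ in range(severity):
            side = rng.integers(2)
            col_lo, col_hi = (0, W // 3) if side == 0 else (2 * W // 3, W - 1)
            cx = int(rng.integers(col_lo, max(col_lo + 1, col_hi)))
            cy = int(rng.integers(max(0, top_lo - r), min(H, bot_hi + r)))
            yy, xx = np.ogrid[:H, :W]
            plane[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 0.8

    if is_3d:
        img = np.broadcast_to(plane, size).copy()
    else:
        img = plane
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def measure_gap(image: np.ndarray) -> int:
    """Count dark rows between the two bright bands in the central columns."""
    if image.ndim == 3:
        image = image[image.shape[0] // 2]
    H, W = image.shape
    profile = image[:, W // 3 : 2 * W // 3].mean(axis=1)
    bright = np.flatnonzero(profile > 0.5)
    if bright.size < 2:
        raise ValueError("no two bands found")
    splits = np.flatnonzero(np.diff(bright) > 1)
    if splits.size == 0:
        return 0
    first_end = bright[splits[0]]
    second_start = bright[splits[0] + 1]
    return int(second_start - first_end - 1)


def apply_missingness(
    records: Sequence[PatientRecord],
    target_rate: float,
    covariate_rate: float,
    rng: np.random.Generator,
) -> list:
    """Mask follow-up targets and covariates independently at the given rates.

    The baseline target (t=0) is never masked.
    """
    for name, rate in (("target_rate", target_rate), ("covariate_rate", covariate_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    out = []
    for rec in records:
        targets = list(rec.targets)
        mask = list(rec.target_mask)
        for t in range(1, len(targets)):
            if rng.random() < target_rate:
                targets[t] = MISSING
                mask[t] = False
        covariates = {
            k: (MISSING if rng.random() < covariate_rate else v)
            for k, v in rec.covariates.items()
        }
        out.append(
            replace(rec, targets=targets, target_mask=mask, covariates=covariates)
        )
    return out


def generate_cohort(config: TrajectoryConfig) -> list:
    """Generate ``config.n_subjects`` records; bit-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    nc0 = config.n_classes_per_task[0]
    prior = (
        np.asarray(config.baseline_prior, dtype=float)
        if config.baseline_prior is not None
        else np.full(nc0, 1.0 / nc0)
    )
    lo, hi = config.progression_rate_range
    age_lo, age_hi = CONTINUOUS_RANGES["age"]
    bmi_lo, bmi_hi = CONTINUOUS_RANGES["bmi"]
    records = []
    for i in range(config.n_subjects):
        baseline = int(rng.choice(nc0, p=prior))
        covariates = {
            "sex": int(rng.integers(CATEGORICAL_LEVELS["sex"])),
            "injury": int(rng.integers(CATEGORICAL_LEVELS["injury"])),
            "age": float(rng.uniform(age_lo, age_hi)),
            "bmi": float(rng.uniform(bmi_lo, bmi_hi)),
        }
        bmi_std = (covariates["bmi"] - bmi_lo) / (bmi_hi - bmi_lo)
        rate = float(
            np.clip(
                rng.uniform(lo, hi) + config.covariate_effect * (bmi_std - 0.5),
                0.0,
                1.0,
            )
        )
        targets = sample_trajectory(
            baseline, rate, config.T, config.n_classes_per_task, config.progressive, rng
        )
        morphology_seed = int(rng.integers(2**31))
        image = render_image(
            targets[0], morphology_seed, config.noise_sd, config.image_size, n_levels=nc0
        )
        records.append(
            PatientRecord(
                subject_id=f"subj_{i:05d}",
                image=image,
                covariates=covariates,
                targets=targets,
                target_mask=[True] * (config.T + 1),
                morphology_seed=morphology_seed,
            )
        )
    return apply_missingness(
        records, config.missing_target_rate, config.missing_covariate_rate, rng
    )


# ----------------------------------------------------------------- serialization
def save_cohort(records: Sequence[PatientRecord], config: TrajectoryConfig, outdir) -> None:
    """Write images (PNG for 2D, NIfTI for 3D), one CSV row per subject, and YAML config.

    CSV schema: subject_id, image (relative path), morphology_seed, one column
    per covariate (empty cell = missing), target_{t} (empty = missing) and
    mask_{t} for t = 0..T.
    """
    from PIL import Image

    import nibabel as nib

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        if rec.image.ndim == 2:
            rel = f"images/{rec.subject_id}.png"
            arr = np.round(rec.image * 65535).astype(np.uint16)
            Image.fromarray(arr).save(outdir / rel)
        else:
            rel = f"images/{rec.subject_id}.nii.gz"
            nib.save(
                nib.Nifti1Image(rec.image.astype(np.float32), affine=np.eye(4)),
                outdir / rel,
            )
        row = {
            "subject_id": rec.subject_id,
            "image": rel,
            "morphology_seed": rec.morphology_seed,
        }
        for k, v in rec.covariates.items():
            row[k] = "" if is_missing(v) else v
        for t, (y, m) in enumerate(zip(rec.targets, rec.target_mask)):
            row[f"target_{t}"] = "" if is_missing(y) else int(y)
            row[f"mask_{t}"] = int(m)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)


def load_cohort(indir) -> tuple:
    """Inverse of :func:`save_cohort`; returns (records, config)."""
    from PIL import Image

    import nibabel as nib

    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    for key in ("n_classes_per_task", "image_size", "progression_rate_range",
                "baseline_prior"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    config = TrajectoryConfig(**raw)
    df = pd.read_csv(indir / "cohort.csv")
    T = config.T
    records = []
    for _, row in df.iterrows():
        path = indir / row["image"]
        if str(path).endswith(".png"):
            image = np.asarray(Image.open(path), dtype=np.float64) / 65535.0
        else:
            image = np.asarray(nib.load(path).get_fdata(), dtype=np.float64)
        covariates = {}
        for name in COVARIATE_NAMES:
            v = row[name]
            if pd.isna(v) or v == "":
                covariates[name] = MISSING
            elif name in CATEGORICAL_LEVELS:
                covariates[name] = int(v)
            else:
                covariates[name] = float(v)
        targets, mask = [], []
        for t in range(T + 1):
            m = bool(int(row[f"mask_{t}"]))
            mask.append(m)
            targets.append(int(row[f"target_{t}"]) if m else MISSING)
        records.append(
            PatientRecord(
                subject_id=row["subject_id"],
                image=image,
                covariates=covariates,
                targets=targets,
                target_mask=mask,
                morphology_seed=int(row["morphology_seed"]),
            )
        )
    return records, config
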