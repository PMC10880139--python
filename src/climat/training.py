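"""Training, cross-validation splitting, evaluation, and the estimator surface.

:class:`ClimatForecaster` is the primary interface: a scikit-learn style
estimator that fits the three-block transformer on a list of
:class:`~climat.synthetic.PatientRecord` objects and predicts the ordinal
severity trajectory.  The module-level :func:`train` / :func:`evaluate` /
:func:`split_cohort` functions are thin wrappers suitable for scripting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import GroupKFold

from . import losses, nn
from .features import CovariateSchema
from .metrics import (
    MetricsReport,
    balanced_accuracy,
    expected_calibration_error,
    multiclass_auroc_ovo,
)
from .model import ClimatConfig, ClimatModel
from .synthetic import MISSING, PatientRecord, is_missing

__all__ = [
    "RunConfig",
    "ClimatForecaster",
    "split_cohort",
    "train",
    "evaluate",
    "permuted_baseline_ba",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one training run."""

    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 30
    lambda_cons: float = 0.5
    loss: str = "club"
    epsilon: float = 1e-6
    sigma_init: float = 1.0
    detach_tau: bool = False
    cx: int = 32
    cm: int = 16
    heads: int = 4
    depth_r: int = 2
    depth_c: int = 2
    depth_p: int = 4
    n_cls: object = "auto"
    head_mode: str = "common"
    fusion: str = "channel"
    pool: str = "average"
    mlp_ratio: float = 4.0
    dropout: float = 0.0
    backbone_width: int = 16
    backbone_stages: int = 3
    quantize_bins: int = 4
    k_folds: int = 5
    seeds: tuple = (0,)
    exclude_top_baseline: bool = False
    n_classes_per_task: tuple | None = None

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.seeds:
            raise ValueError("seeds must be nonempty")

    def estimator_kwargs(self) -> dict:
        d = asdict(self)
        d.pop("k_folds")
        d.pop("seeds")
        return d


def split_cohort(records, k: int, seed: int = 0) -> list:
    """k-fold train/validation index splits grouped by subject ID.

    Every entry of a subject (e.g. augmented follow-up entries) lands in the
    same fold; with equally represented subjects, fold sizes are balanced
    within one subject.
    """
    subjects = np.array([r.subject_id for r in records])
    n_subjects = len(set(subjects))
    if k > n_subjects:
        raise ValueError(f"k={k} exceeds the {n_subjects} distinct subjects")
    splitter = GroupKFold(n_splits=k, shuffle=True, random_state=seed)
    X = np.zeros((len(records), 1))
    return [(tr, va) for tr, va in splitter.split(X, groups=subjects)]


class ClimatForecaster(BaseEstimator):
    """Ordinal disease-trajectory forecaster (radiologist/context/practitioner).

    Parameters mirror :class:`~climat.model.ClimatConfig` plus loss and
    optimizer settings.  ``loss="club"`` trains with the calibrated
    upper-bound loss and learnable per-task temperatures; ``loss="ce"``
    fixes every tau at 1 (plain cross-entropy).

    Fitted attributes: ``model_``, ``temperature_``, ``schema_``, ``T_``,
    ``classes_per_task_``, ``log_`` (per-epoch losses and tau trajectory).
    """

    def __init__(
        self,
        lr=1e-4,
        batch_size=32,
        epochs=30,
        lambda_cons=0.5,
        loss="club",
        epsilon=1e-6,
        sigma_init=1.0,
        detach_tau=False,
        cx=32,
        cm=16,
        heads=4,
        depth_r=2,
        depth_c=2,
        depth_p=4,
        n_cls="auto",
        head_mode="common",
        fusion="channel",
        pool="average",
        mlp_ratio=4.0,
        dropout=0.0,
        backbone_width=16,
        backbone_stages=3,
        quantize_bins=4,
        exclude_top_baseline=False,
        n_classes_per_task=None,
        seed=0,
    ):
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.lambda_cons = lambda_cons
        self.loss = loss
        self.epsilon = epsilon
        self.sigma_init = sigma_init
        self.detach_tau = detach_tau
        self.cx = cx
        self.cm = cm
        self.heads = heads
        self.depth_r = depth_r
        self.depth_c = depth_c
        self.depth_p = depth_p
        self.n_cls = n_cls
        self.head_mode = head_mode
        self.fusion = fusion
        self.pool = pool
        self.mlp_ratio = mlp_ratio
        self.dropout = dropout
        self.backbone_width = backbone_width
        self.backbone_stages = backbone_stages
        self.quantize_bins = quantize_bins
        self.exclude_top_baseline = exclude_top_baseline
        self.n_classes_per_task = n_classes_per_task
        self.seed = seed

    # ------------------------------------------------------------------ build
    def _model_config(self) -> ClimatConfig:
        return ClimatConfig(
            cx=self.cx,
            cm=self.cm,
            heads=self.heads,
            depth_r=self.depth_r,
            depth_c=self.depth_c,
            depth_p=self.depth_p,
            n_cls=self.n_cls,
            head_mode=self.head_mode,
            fusion=self.fusion,
            pool=self.pool,
            mlp_ratio=self.mlp_ratio,
            dropout=self.dropout,
            backbone_width=self.backbone_width,
            backbone_stages=self.backbone_stages,
            quantize_bins=self.quantize_bins,
        )

    def _build(self, T, classes_per_task, schema, image_shape, rng):
        if self.loss not in ("club", "ce"):
            raise ValueError(f"loss must be 'club' or 'ce', got {self.loss}")
        self.T_ = T
        self.classes_per_task_ = list(classes_per_task)
        self.schema_ = schema
        self.model_ = ClimatModel(
            self._model_config(), T, classes_per_task, schema, image_shape, rng
        )
        self.temperature_ = losses.TemperatureState(
            T + 1, eps=self.epsilon, sigma_init=self.sigma_init, detach_tau=self.detach_tau
        )

    @staticmethod
    def _validate_records(records):
        records = list(records)
        if not records:
            raise ValueError("empty cohort")
        T = len(records[0].targets) - 1
        for r in records:
            if not isinstance(r, PatientRecord):
                raise TypeError("records must be PatientRecord instances")
            if len(r.targets) != T + 1:
                raise ValueError("all records must share the same horizon count")
        return records, T

    def _target_arrays(self, records):
        n = len(records)
        labels = np.zeros((n, self.T_ + 1), dtype=int)
        mask = np.zeros((n, self.T_ + 1), dtype=bool)
        for i, r in enumerate(records):
            for t, (y, m) in enumerate(zip(r.targets, r.target_mask)):
                mask[i, t] = m
                labels[i, t] = int(y) if m else 0
        return labels, mask

    def _current_tau(self) -> nn.Tensor:
        if self.loss == "ce":
            return nn.Tensor(np.ones(self.T_ + 1))
        return self.temperature_.tau()

    # -------------------------------------------------------------------- fit
    def fit(self, records, y=None):
        """Train on a list of PatientRecord; ``y`` is ignored (targets live in the records)."""
        records, T = self._validate_records(records)
        if self.n_classes_per_task is not None:
            if len(self.n_classes_per_task) != T + 1:
                raise ValueError("n_classes_per_task must have T+1 entries")
            classes_per_task = [int(nc) for nc in self.n_classes_per_task]
        else:  # infer from observed labels
            classes_per_task = [
                max(
                    (int(r.targets[t]) for r in records if r.target_mask[t]),
                    default=1,
                )
                + 1
                for t in range(T + 1)
            ]
        ss = np.random.SeedSequence(self.seed)
        init_rng, shuffle_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
        schema = CovariateSchema(bins=self.quantize_bins).fit(records)
        self._build(T, classes_per_task, schema, records[0].image.shape, init_rng)

        images = np.stack([r.image for r in records])
        cov_arrays = self.schema_.encode_records(records)
        labels, mask = self._target_arrays(records)
        if mask.sum() == 0:
            raise ValueError("cohort contains no observed targets")

        params = self.model_.parameters()
        if self.loss == "club":
            params = params + self.temperature_.parameters()
        opt = nn.Adam(params, lr=self.lr)
        self.log_ = []
        n = len(records)
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            epoch_losses, epoch_prog, epoch_cons = [], [], []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if not mask[idx].any():
                    continue  # batch with no observed targets contributes nothing
                out = self.model_.forward_arrays(
                    images[idx], [c[idx] for c in cov_arrays]
                )
                tau = self._current_tau()
                prog = losses.prognosis_loss(out["f"], labels[idx], mask[idx], tau)
                cons = losses.consistency_loss(out["f0R"], out["f"][0])
                total = losses.total_loss(prog, cons, self.lambda_cons)
                if not np.isfinite(float(total)):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch} "
                        f"(prognosis={float(prog):.4g}, consistency={float(cons):.4g})"
                    )
                opt.zero_grad()
                total.backward()
                opt.step()
                epoch_losses.append(float(total))
                epoch_prog.append(float(prog))
                epoch_cons.append(float(cons))
            with nn.no_grad():
                tau_now = self._current_tau().data.tolist()
            self.log_.append(
                {
                    "epoch": epoch,
                    "loss": float(np.mean(epoch_losses)),
                    "prognosis": float(np.mean(epoch_prog)),
                    "consistency": float(np.mean(epoch_cons)),
                    "tau": tau_now,
                }
            )
        self.loss_curve_ = [entry["loss"] for entry in self.log_]
        return self

    # -------------------------------------------------------------- inference
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("forecaster is not fitted; call fit() first")

    def predict_proba(self, records) -> list:
        """One (n, Nct) softmax probability array per horizon t."""
        self._check_fitted()
        records, T = self._validate_records(records)
        if T != self.T_:
            raise ValueError(f"records have T={T}, model was fitted with T={self.T_}")
        self.model_.eval()
        probs = [[] for _ in range(self.T_ + 1)]
        with nn.no_grad():
            for start in range(0, len(records), self.batch_size):
                chunk = records[start : start + self.batch_size]
                images, covs = self.model_._encode_records(chunk)
                out = self.model_.forward_arrays(images, covs)
                for t, ft in enumerate(out["f"]):
                    probs[t].append(nn.softmax(ft, axis=-1).data)
        self.model_.train()
        return [np.concatenate(chunks) for chunks in probs]

    def predict(self, records) -> np.ndarray:
        """(n, T+1) array of predicted severity classes."""
        return np.stack([p.argmax(axis=1) for p in self.predict_proba(records)], axis=1)

    def evaluate(self, records, n_bins: int = 10) -> MetricsReport:
        """Per-horizon BA / ECE / one-vs-one AUROC on observed targets only."""
        self._check_fitted()
        records = list(records)
        if self.exclude_top_baseline:
            top = self.classes_per_task_[0] - 1
            records = [r for r in records if int(r.targets[0]) != top]
        probs = self.predict_proba(records)
        labels, mask = self._target_arrays(records)
        report = MetricsReport()
        for t in range(self.T_ + 1):
            sel = mask[:, t]
            report.n_observed.append(int(sel.sum()))
            if not sel.any():
                report.ba.append(None)
                report.ece.append(None)
                report.mauroc.append(None)
                continue
            y = labels[sel, t]
            p = probs[t][sel]
            report.ba.append(balanced_accuracy(y, p.argmax(axis=1)))
            report.ece.append(expected_calibration_error(p, y, n_bins=n_bins))
            try:
                report.mauroc.append(multiclass_auroc_ovo(p, y))
            except ValueError:
                report.mauroc.append(None)
        return report

    def score(self, records, y=None) -> float:
        """Mean balanced accuracy over horizons with observed targets."""
        return self.evaluate(records).horizon_average("ba")

    def attention(self, record: PatientRecord, t: int):
        """(imaging attention grid, clinical-variable weights) at horizon t."""
        self._check_fitted()
        return self.model_.extract_attention(record, t)


def train(config: RunConfig, cohort, seed: int | None = None):
    """Fit a forecaster under ``config``; returns (forecaster, training log)."""
    forecaster = ClimatForecaster(
        seed=config.seeds[0] if seed is None else seed, **config.estimator_kwargs()
    )
    forecaster.fit(cohort)
    return forecaster, forecaster.log_


def evaluate(forecaster: ClimatForecaster, records, n_bins: int = 10) -> MetricsReport:
    return forecaster.evaluate(records, n_bins=n_bins)


def permuted_baseline_ba(forecaster: ClimatForecaster, records, seed: int = 0) -> list:
    """Chance-level control: BA of the model's predictions against permuted labels."""
    rng = np.random.default_rng(seed)
    preds = forecaster.predict(records)
    labels, mask = forecaster._target_arrays(records)
    out = []
    for t in range(forecaster.T_ + 1):
        sel = mask[:, t]
        if not sel.any():
            out.append(None)
            continue
        y = labels[sel, t]
        out.append(balanced_accuracy(rng.permutation(y), preds[sel, t]))
    return out


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(forecaster: ClimatForecaster, path) -> None:
    """Single-file archive: parameters + estimator/schema config + log."""
    forecaster._check_fitted()
    meta = {
        "params": forecaster.get_params(),
        "T": forecaster.T_,
        "classes_per_task": forecaster.classes_per_task_,
        "image_shape": list(forecaster.model_.image_shape),
        "schema": {
            "bins": forecaster.schema_.bins,
            "categorical_levels": forecaster.schema_.categorical_levels,
            "continuous_ranges": {
                k: list(v) for k, v in forecaster.schema_.continuous_ranges.items()
            },
        },
        "log": getattr(forecaster, "log_", []),
    }
    arrays = {f"model.{k}": v for k, v in forecaster.model_.state_dict().items()}
    arrays["temperature.sigma"] = forecaster.temperature_.sigma.data
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ClimatForecaster:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    forecaster = ClimatForecaster(**meta["params"])
    schema = CovariateSchema(
        bins=meta["schema"]["bins"],
        categorical_levels=dict(meta["schema"]["categorical_levels"]),
        continuous_ranges={
            k: tuple(v) for k, v in meta["schema"]["continuous_ranges"].items()
        },
    )
    rng = np.random.default_rng(forecaster.seed)
    forecaster._build(
        meta["T"], meta["classes_per_task"], schema, tuple(meta["image_shape"]), rng
    )
    forecaster.model_.load_state_dict(
        {k[len("model."):]: v for k, v in arrays.items() if k.startswith("model.")}
    )
    forecaster.temperature_.sigma.data = arrays["temperature.sigma"].copy()
    forecaster.log_ = meta["log"]
    return forecaster
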