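"""The multi-agent forecasting network.

Three transformer blocks cooperate the way a radiology consult does:

* **R** (radiologist) encodes the imaging tokens and predicts the current
  severity grade from an average-pooled representation of its output.
* **C** (context) encodes the clinical-variable tokens and exposes the
  output state of its [CLS] token as a single context vector.
* **P** (general practitioner) fuses the radiologist's full output sequence
  with the context vector — by default channel-wise, concatenating a copy of
  the context vector onto every imaging state — and forecasts the severity
  grade at every horizon t = 0..T through K [CLS] tokens and a prediction
  head (one shared head, or one per horizon).

Attention matrices of the last layers of C and P provide clinical-variable
weights and per-horizon imaging saliency maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .features import CovariateSchema, ImageEncoder, ScalarEncoder, TokenSequence, fold_grid
from .synthetic import PatientRecord
from .transformer import EncoderState, TransformerConfig, TransformerEncoder

__all__ = ["ClimatConfig", "PrognosisOutput", "ClimatModel"]


@dataclass(frozen=True)
class ClimatConfig:
    """Architecture hyperparameters.

    ``n_cls`` is K, the number of [CLS] tokens of block P: "auto" resolves to
    T+1 (one output token per horizon); 1 routes a single token to all
    horizon heads.  ``fusion`` is "channel" (context vector concatenated
    feature-wise onto each imaging state) or "sequence" (context vector
    projected to CX and appended as one extra token).  ``pool`` selects how
    block R summarizes its output for the diagnosis head.
    """

    cx: int = 32
    cm: int = 16
    heads: int = 4
    depth_r: int = 2
    depth_c: int = 2
    depth_p: int = 4
    n_cls: object = "auto"  # K: "auto" (=T+1) or an int in {1, T+1}
    head_mode: str = "common"
    fusion: str = "channel"
    pool: str = "average"
    mlp_ratio: float = 4.0
    dropout: float = 0.0
    backbone_width: int = 16
    backbone_stages: int = 3
    quantize_bins: int = 4

    def __post_init__(self):
        if self.head_mode not in ("common", "separate"):
            raise ValueError(f"head_mode must be 'common' or 'separate', got {self.head_mode}")
        if self.fusion not in ("channel", "sequence"):
            raise ValueError(f"fusion must be 'channel' or 'sequence', got {self.fusion}")
        if self.pool not in ("average", "cls"):
            raise ValueError(f"pool must be 'average' or 'cls', got {self.pool}")
        for name in ("depth_r", "depth_c", "depth_p"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class PrognosisOutput:
    """Diagnosis logits from block R, per-horizon logits from block P, attention."""

    f0R: np.ndarray
    f: list
    imaging_attention: list = field(default_factory=list)  # one grid array per horizon
    clinical_attention: np.ndarray | None = None  # (M,) weights over variables
    variable_names: list = field(default_factory=list)


class _PredictionHead(nn.Module):
    """LayerNorm -> linear -> GELU -> linear, producing class logits."""

    def __init__(self, width: int, n_classes: int, rng):
        super().__init__()
        self.norm = nn.LayerNorm(width)
        self.fc1 = nn.Linear(width, width, rng)
        self.fc2 = nn.Linear(width, n_classes, rng)

    def __call__(self, x):
        return self.fc2(nn.gelu(self.fc1(self.norm(x))))


class _DiagnosisHead(nn.Module):
    """Block R head: FFN trunk (linear -> GELU -> LayerNorm) + linear classifier.

    The trunk keeps the block's feed-forward structure at width CX; the final
    linear map produces unconstrained class logits.  Ending the head at the
    layer norm instead would pin the logits to zero mean and fixed norm
    (a two-point set for binary tasks), which degenerates the L1 consistency
    target.
    """

    def __init__(self, width: int, n_classes: int, rng):
        super().__init__()
        self.fc = nn.Linear(width, width, rng)
        self.norm = nn.LayerNorm(width)
        self.out = nn.Linear(width, n_classes, rng)

    def __call__(self, x):
        return self.out(self.norm(nn.gelu(self.fc(x))))


class ClimatModel(nn.Module):
    """Full R/C/P assembly for one cohort geometry."""

    def __init__(
        self,
        config: ClimatConfig,
        T: int,
        n_classes_per_task,
        schema: CovariateSchema,
        image_shape,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.config = config
        self.T = T
        self.n_classes_per_task = list(n_classes_per_task)
        self.schema = schema
        self.image_shape = tuple(image_shape)
        ndim = len(self.image_shape)

        K = T + 1 if config.n_cls == "auto" else int(config.n_cls)
        if K not in (1, T + 1):
            raise ValueError(f"K must be 1 or T+1={T + 1}, got {K}")
        self.K = K
        if config.head_mode == "common" and len(set(self.n_classes_per_task)) > 1:
            raise ValueError(
                "head_mode='common' requires equal class counts at every horizon; "
                "use head_mode='separate'"
            )

        self.image_encoder = ImageEncoder(
            config.cx,
            rng,
            ndim=ndim,
            width=config.backbone_width,
            stages=config.backbone_stages,
        )
        self.grid = self.image_encoder.grid_shape(self.image_shape)
        self.N = int(np.prod(self.grid))
        self.M = len(schema.names)
        self.scalar_encoders = [
            ScalarEncoder(schema.input_dim(name), config.cm, rng) for name in schema.names
        ]

        self.encoder_r = TransformerEncoder(
            TransformerConfig(config.depth_r, config.heads, config.cx,
                              config.mlp_ratio, 1, config.dropout),
            n_tokens=self.N,
            rng=rng,
        )
        self.head_r = _DiagnosisHead(config.cx, self.n_classes_per_task[0], rng)
        self.encoder_c = TransformerEncoder(
            TransformerConfig(config.depth_c, config.heads, config.cm,
                              config.mlp_ratio, 1, config.dropout),
            n_tokens=self.M,
            rng=rng,
        )

        if config.fusion == "channel":
            self.width_p = config.cx + config.cm
            n_tokens_p = self.N + 1
            self.ctx_proj = None
        else:
            self.width_p = config.cx
            n_tokens_p = self.N + 2
            self.ctx_proj = nn.Linear(config.cm, config.cx, rng)
        self.encoder_p = TransformerEncoder(
            TransformerConfig(config.depth_p, config.heads, self.width_p,
                              config.mlp_ratio, K, config.dropout),
            n_tokens=n_tokens_p,
            rng=rng,
        )
        if config.head_mode == "common":
            self.heads_p = [_PredictionHead(self.width_p, self.n_classes_per_task[0], rng)]
        else:
            self.heads_p = [
                _PredictionHead(self.width_p, nc, rng) for nc in self.n_classes_per_task
            ]

    # ----------------------------------------------------------------- blocks
    def radiologist_forward(self, imaging_tokens: TokenSequence):
        """Encode imaging tokens; returns (encoder state, diagnosis logits)."""
        state = self.encoder_r.encode(imaging_tokens.tokens)
        if self.config.pool == "average":
            pooled = state.hidden.mean(axis=1)
        else:
            pooled = state.hidden[:, 0]
        return state, self.head_r(pooled)

    def context_forward(self, clinical_tokens: TokenSequence):
        """Encode clinical tokens; returns (encoder state, context vector h̄C0)."""
        state = self.encoder_c.encode(clinical_tokens.tokens)
        return state, state.hidden[:, 0]

    def practitioner_forward(self, h_r: nn.Tensor, h_c0: nn.Tensor):
        """Fuse radiologist states with the context vector and forecast all horizons."""
        B, n_r, _ = h_r.shape
        if self.config.fusion == "channel":
            ctx = h_c0.reshape(B, 1, self.config.cm).broadcast_to(
                (B, n_r, self.config.cm)
            )
            fused = nn.concat([h_r, ctx], axis=2)
        else:
            ctx = self.ctx_proj(h_c0).reshape(B, 1, self.config.cx)
            fused = nn.concat([h_r, ctx], axis=1)
        state = self.encoder_p.encode(fused)
        logits = []
        for t in range(self.T + 1):
            vec = state.hidden[:, t] if self.K == self.T + 1 else state.hidden[:, 0]
            head = self.heads_p[0] if self.config.head_mode == "common" else self.heads_p[t]
            logits.append(head(vec))
        return state, logits

    # ------------------------------------------------------------------ passes
    def forward_arrays(self, images: np.ndarray, cov_arrays: list):
        """Differentiable batched pass from raw arrays.

        ``images``: (B, H, W) or (B, D, H, W); ``cov_arrays``: one (B, d)
        one-hot array per clinical variable.  Returns a dict with logits and
        the three encoder states.
        """
        img_tokens = self.image_encoder(images)
        state_r, f0R = self.radiologist_forward(img_tokens)
        clin = nn.concat(
            [enc(arr).reshape(arr.shape[0], 1, self.config.cm)
             for enc, arr in zip(self.scalar_encoders, cov_arrays)],
            axis=1,
        )
        state_c, h_c0 = self.context_forward(
            TokenSequence(tokens=clin, modality_tag="non-imaging")
        )
        state_p, f = self.practitioner_forward(state_r.hidden, h_c0)
        return {
            "f0R": f0R,
            "f": f,
            "state_r": state_r,
            "state_c": state_c,
            "state_p": state_p,
            "grid": img_tokens.grid_shape,
        }

    def _encode_records(self, records):
        records = [records] if isinstance(records, PatientRecord) else list(records)
        for rec in records:
            if rec.image is None or not isinstance(rec.image, np.ndarray):
                raise ValueError(f"record {rec.subject_id} has no image; images are mandatory")
        images = np.stack([rec.image for rec in records])
        cov_arrays = self.schema.encode_records(records)
        return images, cov_arrays

    def forward(self, record: PatientRecord) -> PrognosisOutput:
        """Full single-record pass with attention extraction (evaluation mode)."""
        was_training = self.training
        self.eval()
        try:
            images, cov_arrays = self._encode_records(record)
            with nn.no_grad():
                out = self.forward_arrays(images, cov_arrays)
                imaging, clinical = self._attention_from_states(
                    out["state_c"], out["state_p"], out["grid"]
                )
            return PrognosisOutput(
                f0R=out["f0R"].data[0],
                f=[ft.data[0] for ft in out["f"]],
                imaging_attention=[m[0] for m in imaging],
                clinical_attention=clinical[0],
                variable_names=list(self.schema.names),
            )
        finally:
            self.train(was_training)

    # --------------------------------------------------------------- attention
    def _attention_from_states(self, state_c: EncoderState, state_p: EncoderState, grid):
        """Head-averaged, renormalized attention maps from the last layers of C and P."""
        attn_c = state_c.attention[-1].data.mean(axis=1)  # (B, S, S)
        clin = attn_c[:, 0, 1 : 1 + self.M]
        clin = clin / clin.sum(axis=-1, keepdims=True)
        attn_p = state_p.attention[-1].data.mean(axis=1)
        # imaging spatial positions: after K CLS tokens and the R-block CLS state
        start = self.K + 1
        maps = []
        for t in range(self.T + 1):
            row = attn_p[:, t if self.K == self.T + 1 else 0, start : start + self.N]
            row = row / row.sum(axis=-1, keepdims=True)
            maps.append(row.reshape(row.shape[0], *grid))
        return maps, clin

    def extract_attention(self, record: PatientRecord, t: int):
        """(imaging map on the feature grid, clinical-variable weights) at horizon t."""
        if not 0 <= t <= self.T:
            raise IndexError(f"horizon {t} out of range 0..{self.T}")
        out = self.forward(record)
        return out.imaging_attention[t], out.clinical_attention
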