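"""Calibrated multi-task losses for trajectory forecasting.

For task t with logits f and true class c, write g = exp(f).  The
temperature-scaled cross-entropy (TCE) at inverse temperature tau in (0, 1]
is

    L_TCE = -log( g_c^tau / sum_c' g_c'^tau ),

i.e. plain cross-entropy evaluated on tau-scaled logits; tau = 1 recovers
vanilla CE.  For tau in (0, 1] the reverse Hoelder inequality bounds the
tau-norm of g by its 1-norm, which yields the CLUB upper bound

    L_CLUB = tau * L_CE + (1 - tau) * log Nc,

a convex combination of the CE loss and the log class count, with equality
iff tau = 1.  Its gradients are  d L_CLUB / d logits = tau * d L_CE / d logits
and  d L_CLUB / d tau = L_CE - log Nc, so each tau acts as a learnable
per-task weight that trades accuracy against calibration.

Per-task inverse temperatures are derived from unconstrained noise
parameters sigma_t by  rho_t = 1 / (sigma_t^2 + eps),  rho~ = softmax(rho),
tau_t = rho~_t / max(rho~),  which keeps every tau in (0, 1] with
max(tau) = 1 and prevents the all-tau-equal-1 collapse while remaining
differentiable in sigma.

The prognosis loss averages the per-task CLUB terms over observed targets
only (indicator mask); the consistency loss is the L1 distance between the
diagnosis logits of blocks R and P and applies to every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "TemperatureState",
    "LossReport",
    "cross_entropy",
    "temperature_scaled_ce",
    "club",
    "constrain_temperatures",
    "prognosis_loss",
    "consistency_loss",
    "total_loss",
]


def _as_batch(logits) -> tuple:
    """Normalize logits to (B, Nc) Tensor; remember if input was a single vector."""
    t = nn.astensor(logits)
    if t.ndim == 1:
        return t.reshape(1, t.shape[0]), True
    if t.ndim == 2:
        return t, False
    raise ValueError(f"logits must be 1D or 2D, got shape {t.shape}")


def _labels_array(label, n_classes: int, batch: int) -> np.ndarray:
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    if labels.shape[0] != batch:
        raise ValueError(f"expected {batch} labels, got {labels.shape[0]}")
    if np.any((labels < 0) | (labels >= n_classes)):
        raise ValueError(f"label out of range [0, {n_classes})")
    return labels


def cross_entropy(logits, label) -> nn.Tensor:
    """-log softmax probability of the true class, computed log-sum-exp stably.

    Accepts a single logit vector with an integer label (returns a scalar
    tensor) or a (B, Nc) batch with B labels (returns a (B,) tensor).
    """
    x, single = _as_batch(logits)
    B, Nc = x.shape
    labels = _labels_array(label, Nc, B)
    picked = x[np.arange(B), labels]
    out = nn.logsumexp(x, axis=-1) - picked
    return out[0] if single else out


def temperature_scaled_ce(logits, label, tau) -> nn.Tensor:
    """Cross-entropy on tau-scaled logits; requires tau in (0, 1]."""
    tau_val = float(tau)
    if not 0.0 < tau_val <= 1.0:
        raise ValueError(f"tau must be in (0, 1], got {tau_val}")
    x, single = _as_batch(logits)
    out = cross_entropy(nn.astensor(tau) * x, np.atleast_1d(np.asarray(label, dtype=int)))
    return out[0] if single else out


def club(logits, label, tau, n_classes: int | None = None) -> nn.Tensor:
    """CLUB loss  tau * CE + (1 - tau) * log Nc  for tau in [0, 1].

    ``tau`` may be a scalar or a differentiable tensor (the learnable
    temperature path).
    """
    tau_val = float(tau)
    if not 0.0 <= tau_val <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau_val}")
    x, single = _as_batch(logits)
    nc = x.shape[1] if n_classes is None else int(n_classes)
    ce = cross_entropy(x, np.atleast_1d(np.asarray(label, dtype=int)))
    tau_t = nn.astensor(tau)
    out = tau_t * ce + (1.0 - tau_t) * float(np.log(nc))
    return out[0] if single else out


def constrain_temperatures(sigma, eps: float = 1e-6) -> nn.Tensor:
    """Map unconstrained noise parameters to inverse temperatures.

    rho_t = 1 / (sigma_t^2 + eps); rho~ = softmax(rho); tau_t = rho~_t / max(rho~).
    Differentiable end to end (the max uses a subgradient at ties); output
    satisfies max(tau) = 1 and tau in (0, 1].
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    s = nn.astensor(sigma)
    rho = 1.0 / (s * s + eps)
    rho_tilde = nn.softmax(rho, axis=-1)
    argmax = int(np.argmax(rho_tilde.data))
    return rho_tilde / rho_tilde[argmax]


class TemperatureState(nn.Module):
    """Learnable per-task noise parameters sigma_t and derived taus.

    ``sigma`` is unconstrained; :meth:`tau` applies the constraint mapping.
    ``detach_tau=True`` cuts the gradient path from the loss into sigma
    (freezing calibration learning); kept as a diagnostic switch.
    """

    def __init__(self, n_tasks: int, eps: float = 1e-6, sigma_init: float = 1.0,
                 detach_tau: bool = False):
        super().__init__()
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.sigma = nn.Parameter(np.full(n_tasks, float(sigma_init)))
        self.eps = eps
        self.detach_tau = detach_tau

    def tau(self) -> nn.Tensor:
        t = constrain_temperatures(self.sigma, self.eps)
        return t.detach() if self.detach_tau else t


@dataclass
class LossReport:
    """Per-task and combined loss values of one batch (floats, for logging)."""

    per_task_ce: list
    per_task_club: list
    prognosis: float
    consistency: float
    total: float
    tau: list


def prognosis_loss(logits_list, labels, mask, tau) -> nn.Tensor:
    """Masked multi-task CLUB loss, (1 / sum_t I_t) * sum_t I_t * L_CLUB(t).

    ``logits_list``: T+1 tensors of shape (B, Nct); ``labels``: (B, T+1)
    integer array (masked entries arbitrary); ``mask``: (B, T+1) booleans;
    ``tau``: length-(T+1) tensor or sequence.  Per-sample averages over the
    observed tasks, then a mean over samples with at least one observed
    target.  A batch with no observed targets at all is an error.
    """
    labels = np.asarray(labels, dtype=object)
    mask = np.asarray(mask, dtype=bool)
    n_tasks = len(logits_list)
    if mask.ndim == 1:
        mask = mask[None, :]
        labels = labels[None, :]
    B = mask.shape[0]
    if mask.shape[1] != n_tasks:
        raise ValueError(f"mask has {mask.shape[1]} tasks, expected {n_tasks}")
    counts = mask.sum(axis=1)
    if counts.sum() == 0:
        raise ValueError("batch contains no observed targets")
    tau_t = nn.astensor(tau)
    per_sample = None
    for t in range(n_tasks):
        x, _ = _as_batch(logits_list[t])
        nc = x.shape[1]
        safe_labels = np.array(
            [int(y) if m else 0 for y, m in zip(labels[:, t], mask[:, t])]
        )
        club_t = club(x, safe_labels, tau_t[t], nc)  # (B,)
        term = club_t * mask[:, t].astype(float)
        per_sample = term if per_sample is None else per_sample + term
    weights = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    n_active = int((counts > 0).sum())
    return (per_sample * weights).sum() * (1.0 / n_active)


def consistency_loss(f0R, f0) -> nn.Tensor:
    """L1 distance between the two diagnosis logit vectors, batch-averaged."""
    a, single_a = _as_batch(f0R)
    b, single_b = _as_batch(f0)
    if a.shape != b.shape:
        raise ValueError(f"logit shapes differ: {a.shape} vs {b.shape}")
    return (a - b).abs().sum(axis=-1).mean()


def total_loss(prognosis, consistency, lam: float = 0.5) -> nn.Tensor:
    """L = L_prog + lambda * L_cons with lambda >= 0."""
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    return nn.astensor(prognosis) + lam * nn.astensor(consistency)
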