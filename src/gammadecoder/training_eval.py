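"""Loss, metrics, and the ADAM training loop with per-step checkpoint tracking.

Training minimizes the sum of squared errors between the predicted and the
low-pass-filtered EMG envelope over all training trials, excluding a 1 s
burn-in at the start of every trial so the optimizer cannot exploit the
convolution stack's startup transient.  Each EMG channel is fit
independently.  ADAM runs full-batch (sessions are small) at learning rate
0.1 for 1000 steps with no L1/L2 regularization; over-fitting is handled by
early-stop checkpoint selection instead: after every step, R² and Pearson
correlation are recorded on the Training set and on held-out sets A and B,
and the parameter states maximizing R² on A and on B are retained as the
A_max and B_max checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gammadecoder.network import DecoderModel, backward, forward_cached
from gammadecoder.signal_prep import TrialTensor

__all__ = [
    "TrainingConfig",
    "AttemptRecord",
    "sse_loss",
    "r_squared",
    "correlation",
    "train",
    "adam_step",
]

SessionData = dict[str, tuple[TrialTensor, TrialTensor]]


@dataclass
class TrainingConfig:
    learning_rate: float = 0.1
    steps: int = 1000
    adam_b1: float = 0.9
    adam_b2: float = 0.999
    adam_eps: float = 1e-8
    burn_in_s: float = 1.0
    restarts: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.burn_in_s < 0:
            raise ValueError("burn_in_s must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class AttemptRecord:
    """Per-restart training trajectory with retained early-stop checkpoints.

    ``r2`` and ``corr`` map set name ("train", "a", "b") to the per-step
    metric trajectory (entry s = model after s+1 ADAM steps).  ``a_max_step``
    / ``b_max_step`` index the steps whose parameter states (``a_max_state``,
    ``b_max_state``) maximized R² on the corresponding held-out set.
    """

    attempt_index: int
    loss: np.ndarray = field(default_factory=lambda: np.empty(0))
    r2: dict[str, np.ndarray] = field(default_factory=dict)
    corr: dict[str, np.ndarray] = field(default_factory=dict)
    a_max_step: int | None = None
    b_max_step: int | None = None
    a_max_state: dict[str, np.ndarray] | None = None
    b_max_state: dict[str, np.ndarray] | None = None
    converged: bool = True


def _flatten(pred: np.ndarray, target: np.ndarray, burn_in_bins: int):
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.ndim == 3 and pred.shape[2] == 1:
        pred = pred[:, :, 0]
    if target.ndim == 3 and target.shape[2] == 1:
        target = target[:, :, 0]
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if burn_in_bins >= pred.shape[1]:
        raise ValueError(
            f"burn-in of {burn_in_bins} bins leaves no data in {pred.shape[1]}-bin trials"
        )
    return pred[:, burn_in_bins:], target[:, burn_in_bins:]


def sse_loss(pred: np.ndarray, target: np.ndarray, burn_in_bins: int = 0) -> float:
    """Sum of squared errors over all trials and bins past the burn-in."""
    p, t = _flatten(pred, target, burn_in_bins)
    return float(np.sum((p - t) ** 2))


def r_squared(pred: np.ndarray, target: np.ndarray, burn_in_bins: int = 0) -> float:
    """Coefficient of determination, pooled over all included (trial, bin) points.

    ``1 - SS_res / SS_tot`` with the total sum of squares taken about the
    pooled target mean; at most 1, negative when the fit is worse than the
    mean.
    """
    p, t = _flatten(pred, target, burn_in_bins)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("target variance is zero over the included bins; R² undefined")
    return 1.0 - float(np.sum((p - t) ** 2)) / ss_tot


def correlation(pred: np.ndarray, target: np.ndarray, burn_in_bins: int = 0) -> float:
    """Pearson correlation over the same pooled (trial, bin) points as R²."""
    p, t = _flatten(pred, target, burn_in_bins)
    t = t.ravel()
    if np.std(t) == 0.0:
        raise ValueError("target variance is zero over the included bins")
    return float(np.corrcoef(p.ravel(), t)[0, 1])


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: dict,
    cfg: TrainingConfig,
) -> None:
    """One ADAM update in place; ``state`` holds first/second moments and step count."""
    state["t"] += 1
    t = state["t"]
    b1, b2 = cfg.adam_b1, cfg.adam_b2
    for key, g in grads.items():
        m = state["m"][key] = b1 * state["m"][key] + (1 - b1) * g
        v = state["v"][key] = b2 * state["v"][key] + (1 - b2) * g * g
        m_hat = m / (1 - b1**t)
        v_hat = v / (1 - b2**t)
        params[key] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)


def _subset(data: SessionData, indices: dict[str, np.ndarray], emg_channel: int):
    """Per-set session inputs and single-channel targets, skipping empty sets."""
    xs: dict[str, np.ndarray] = {}
    ys: dict[str, np.ndarray] = {}
    for sid, (neural, emg) in data.items():
        idx = np.asarray(indices[sid], dtype=int)
        if idx.size == 0:
            continue
        xs[sid] = neural.data[idx]
        ys[sid] = emg.data[idx][:, :, emg_channel]
    return xs, ys


def _pooled_metrics(preds: dict[str, np.ndarray], ys: dict[str, np.ndarray], burn_in: int):
    p = np.concatenate([preds[sid][:, :, 0] for sid in ys], axis=0)
    t = np.concatenate([ys[sid] for sid in ys], axis=0)
    return r_squared(p, t, burn_in), correlation(p, t, burn_in)


def resolve_channel(emg: TrialTensor, emg_channel) -> int:
    if isinstance(emg_channel, str):
        try:
            return emg.channel_labels.index(emg_channel)
        except ValueError:
            raise KeyError(
                f"EMG channel {emg_channel!r} not in {emg.channel_labels}"
            ) from None
    return int(emg_channel)


def train(
    model: DecoderModel,
    data: SessionData,
    split,
    emg_channel,
    cfg: TrainingConfig,
    attempt_index: int = 0,
) -> AttemptRecord:
    """Run ``cfg.steps`` full-batch ADAM steps on the SSE loss over training trials.

    ``split`` maps session id → SplitAssignment (a single assignment is
    accepted for single-session data).  After every step the model is scored
    (R², correlation) on Training, A, and B; the states maximizing R² on A
    and on B are retained as checkpoints.  A non-finite loss aborts the
    attempt, which is returned marked non-convergent with its partial record.
    """
    sids = list(data.keys())
    if not isinstance(split, dict):
        split = {sid: split for sid in sids}
    first_emg = data[sids[0]][1]
    ch = resolve_channel(first_emg, emg_channel)
    bin_width = first_emg.bin_width
    burn_in = int(round(cfg.burn_in_s / bin_width))

    sets = {
        "train": {sid: np.asarray(split[sid].train_idx) for sid in sids},
        "a": {sid: np.asarray(split[sid].a_idx) for sid in sids},
        "b": {sid: np.asarray(split[sid].b_idx) for sid in sids},
    }
    xs, ys = {}, {}
    for name, idx in sets.items():
        xs[name], ys[name] = _subset(data, idx, ch)

    params = model.get_state()
    model.set_state(params)  # model now aliases nothing external
    opt = {
        "t": 0,
        "m": {k: np.zeros_like(v) for k, v in params.items()},
        "v": {k: np.zeros_like(v) for k, v in params.items()},
    }

    rec = AttemptRecord(attempt_index=attempt_index)
    loss_tr, r2_tr, corr_tr = [], {"train": [], "a": [], "b": []}, {"train": [], "a": [], "b": []}
    best = {"a": -np.inf, "b": -np.inf}

    target_train = np.concatenate([ys["train"][sid] for sid in xs["train"]], axis=0)
    preds, cache = forward_cached(model, xs["train"])
    for step in range(cfg.steps):
        # gradient of SSE at the current state (burn-in bins excluded)
        grad_preds = {}
        for sid in xs["train"]:
            g = 2.0 * (preds[sid][:, :, 0] - ys["train"][sid])
            g[:, :burn_in] = 0.0
            grad_preds[sid] = g[:, :, None]
        grads = backward(model, cache, grad_preds)
        state = model.get_state()
        adam_step(state, grads, opt, cfg)
        model.set_state(state)

        # score the post-update model on all three sets
        preds, cache = forward_cached(model, xs["train"])
        p = np.concatenate([preds[sid][:, :, 0] for sid in xs["train"]], axis=0)
        loss = sse_loss(p, target_train, burn_in)
        if not np.isfinite(loss):
            rec.converged = False
            break
        loss_tr.append(loss)
        r2_tr["train"].append(r_squared(p, target_train, burn_in))
        corr_tr["train"].append(correlation(p, target_train, burn_in))
        for name in ("a", "b"):
            sp = forward_cached(model, xs[name])[0] if xs[name] else {}
            if sp:
                r2v, cv = _pooled_metrics(sp, ys[name], burn_in)
            else:
                r2v, cv = np.nan, np.nan
            r2_tr[name].append(r2v)
            corr_tr[name].append(cv)
            if np.isfinite(r2v) and r2v > best[name]:
                best[name] = r2v
                if name == "a":
                    rec.a_max_step, rec.a_max_state = step, model.get_state()
                else:
                    rec.b_max_step, rec.b_max_state = step, model.get_state()

    rec.loss = np.asarray(loss_tr)
    rec.r2 = {k: np.asarray(v) for k, v in r2_tr.items()}
    rec.corr = {k: np.asarray(v) for k, v in corr_tr.items()}
    return rec
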