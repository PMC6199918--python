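"""Two-fold, multi-restart validation protocol and its two controls.

Trials are split deterministically into sequential groups of five: the first
three of each group train the model, the fourth goes to held-out set A, the
fifth to held-out set B (60/20/20 when the trial count divides by five).
Training is restarted ``restarts`` times from independent initializations.
Each restart yields an A_max and a B_max checkpoint (early stopping on the
respective held-out set).  To score fold B, the A_max checkpoints are ranked
by the sum of their R² on Training and on A — no information from B — and
only the winner is evaluated on B; fold A is scored symmetrically.  The
session score is the mean of the two fold scores.

Controls run under the identical protocol:

* **linear control** — a pointwise affine decoder with no rectification and
  no temporal memory, fed neural envelopes low-pass filtered to the same
  cutoff as the EMG target;
* **shuffle control** — a single random permutation of all pooled
  (trial, bin) time slices of the neural tensor (channels move together),
  destroying temporal structure while preserving every instantaneous
  cross-channel sample exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gammadecoder.network import NetworkSpec, build_model
from gammadecoder.signal_prep import TrialTensor, zero_phase_butterworth
from gammadecoder.training_eval import (
    AttemptRecord,
    SessionData,
    TrainingConfig,
    train,
)

__all__ = [
    "SplitAssignment",
    "SessionScore",
    "split_trials",
    "run_protocol",
    "linear_control",
    "shuffle_control",
]


@dataclass
class SplitAssignment:
    """Disjoint per-session trial indices for Training / Set A / Set B."""

    train_idx: list[int]
    a_idx: list[int]
    b_idx: list[int]

    def __post_init__(self) -> None:
        groups = [set(self.train_idx), set(self.a_idx), set(self.b_idx)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("train/A/B index sets must be disjoint")


def split_trials(n_trials: int) -> SplitAssignment:
    """Deterministic sequential-groups-of-five split; no randomization.

    Within each group of five consecutive trials the pattern is
    (train, train, train, A, B); a trailing partial group follows the same
    truncated pattern.
    """
    if n_trials < 5:
        raise ValueError(f"need at least 5 trials to split, got {n_trials}")
    train_idx, a_idx, b_idx = [], [], []
    for start in range(0, n_trials, 5):
        group = list(range(start, min(start + 5, n_trials)))
        train_idx.extend(group[:3])
        if len(group) > 3:
            a_idx.append(group[3])
        if len(group) > 4:
            b_idx.append(group[4])
    return SplitAssignment(train_idx=train_idx, a_idx=a_idx, b_idx=b_idx)


@dataclass
class SessionScore:
    """Two-fold session performance: mean of A_max(B) and B_max(A)."""

    a_max_on_b_r2: float
    a_max_on_b_corr: float
    b_max_on_a_r2: float
    b_max_on_a_corr: float
    chosen_a_attempt: int | None
    chosen_b_attempt: int | None
    records: list[AttemptRecord] = field(default_factory=list)

    @property
    def overall_r2(self) -> float:
        return 0.5 * (self.a_max_on_b_r2 + self.b_max_on_a_r2)

    @property
    def overall_corr(self) -> float:
        return 0.5 * (self.a_max_on_b_corr + self.b_max_on_a_corr)


def _as_session_dict(data) -> SessionData:
    if isinstance(data, tuple):
        return {"s0": data}
    return dict(data)


def _select(records: list[AttemptRecord], val_set: str, test_set: str):
    """Pick the checkpoint with the highest R²(train) + R²(val); ties → lowest index.

    Returns (attempt index, R² on the untouched test set at that checkpoint,
    correlation on it).  Selection reads only Training and validation-set
    scores, never the test set.
    """
    best_sum, chosen, out_r2, out_corr = -np.inf, None, np.nan, np.nan
    for rec in records:
        step = rec.a_max_step if val_set == "a" else rec.b_max_step
        if step is None:
            continue
        s = rec.r2["train"][step] + rec.r2[val_set][step]
        if np.isfinite(s) and s > best_sum:
            best_sum = s
            chosen = rec.attempt_index
            out_r2 = rec.r2[test_set][step]
            out_corr = rec.corr[test_set][step]
    return chosen, float(out_r2), float(out_corr)


def run_protocol(
    data,
    emg_channel,
    cfg: TrainingConfig,
    net_spec: NetworkSpec | None = None,
    keep_records: bool = True,
) -> SessionScore:
    """Full restart protocol on one or more sessions for one EMG channel.

    ``data`` is either a single (neural, EMG) TrialTensor pair or a mapping
    session id → pair.  Each of ``cfg.restarts`` attempts starts from a fresh
    initialization seeded ``cfg.seed + attempt``; trial assignments never
    change between attempts.
    """
    data = _as_session_dict(data)
    sids = list(data.keys())
    first_neural = data[sids[0]][0]
    if net_spec is None:
        net_spec = NetworkSpec(bin_width=first_neural.bin_width)
    if net_spec.n_input_channels != first_neural.n_channels:
        raise ValueError(
            f"network expects {net_spec.n_input_channels} input channels, "
            f"data has {first_neural.n_channels}"
        )
    splits = {sid: split_trials(data[sid][0].n_trials) for sid in sids}

    records = []
    for attempt in range(cfg.restarts):
        model = build_model(net_spec, sids, rng_seed=cfg.seed + attempt)
        rec = train(model, data, splits, emg_channel, cfg, attempt_index=attempt)
        records.append(rec)

    if all(r.a_max_step is None and r.b_max_step is None for r in records):
        warnings.warn("no training attempt converged; session score is undefined")
    chosen_a, amax_b_r2, amax_b_corr = _select(records, val_set="a", test_set="b")
    chosen_b, bmax_a_r2, bmax_a_corr = _select(records, val_set="b", test_set="a")
    return SessionScore(
        a_max_on_b_r2=amax_b_r2,
        a_max_on_b_corr=amax_b_corr,
        b_max_on_a_r2=bmax_a_r2,
        b_max_on_a_corr=bmax_a_corr,
        chosen_a_attempt=chosen_a,
        chosen_b_attempt=chosen_b,
        records=records if keep_records else [],
    )


def lowpass_tensor(t: TrialTensor, cutoff: float, order: int = 3) -> TrialTensor:
    """Zero-phase low-pass along the bin axis of every trial and channel."""
    fs = t.rate
    data = np.moveaxis(t.data, 1, 0)  # (bins, trials, ch): filter along axis 0
    data = zero_phase_butterworth(
        data.reshape(t.n_bins, -1), fs=fs, cutoff=cutoff, order=order, mode="low"
    ).reshape(t.n_bins, t.n_trials, t.n_channels)
    return TrialTensor(
        np.moveaxis(data, 0, 1),
        bin_width=t.bin_width,
        channel_labels=list(t.channel_labels),
        session_id=t.session_id,
    )


def linear_control(
    data,
    emg_channel,
    cfg: TrainingConfig,
    lp_cutoff: float = 5.0,
    keep_records: bool = True,
) -> SessionScore:
    """Identical protocol with a pointwise linear decoder.

    The neural envelopes are first low-pass filtered to the EMG target's
    cutoff (they would otherwise be far noisier than the target); the decoder
    is a single affine map with a bias and no rectification, so any
    performance gap to the convolutional decoder reflects temporal memory
    and nonlinearity.
    """
    data = _as_session_dict(data)
    filtered = {
        sid: (lowpass_tensor(neural, lp_cutoff), emg)
        for sid, (neural, emg) in data.items()
    }
    n_ch = next(iter(filtered.values()))[0].n_channels
    spec = NetworkSpec(
        feature_widths=(n_ch,),
        regression_widths=(n_ch, 1),
        regression_kind="linear",
        bin_width=next(iter(filtered.values()))[0].bin_width,
    )
    return run_protocol(filtered, emg_channel, cfg, net_spec=spec, keep_records=keep_records)


def shuffle_control(neural: TrialTensor, seed: int) -> TrialTensor:
    """Time-permutation null: randomly switch time points of the neural envelopes.

    A single permutation over all pooled (trial, bin) positions moves whole
    cross-channel time slices, within and across trials.  The multiset of
    instantaneous samples — hence every per-channel mean and variance — is
    preserved exactly; only temporal structure is destroyed.
    """
    flat = neural.data.reshape(-1, neural.n_channels)
    if flat.shape[0] < 2:
        raise ValueError("need at least 2 time points to shuffle")
    perm = np.random.default_rng(seed).permutation(flat.shape[0])
    return TrialTensor(
        flat[perm].reshape(neural.data.shape).copy(),
        bin_width=neural.bin_width,
        channel_labels=list(neural.channel_labels),
        session_id=neural.session_id,
    )
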