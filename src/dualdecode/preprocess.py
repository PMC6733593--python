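"""Rule-based epoch screening.

Implements the screening pipeline applied before decoding: pre-stimulus
baseline correction, response-based rejection (errors, anticipations,
block-wise slow outliers), horizontal-EOG step detection for eye movements,
and high-frequency band-power rejection of muscle (EMG) artifacts. No
analysis filters are applied to the EEG itself.

Rejection rules run in a fixed order (response -> EOG -> EMG); each trial
carries the reason code of the first rule that fired. The RT and EMG rules
are single-pass: their statistics (block mean/SD, z-scores) are computed
once on the trials surviving the earlier rules, not iterated. Blink-related
component removal (ICA on real recordings) is a pass-through stage here,
exposed as a hook.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochsSet

__all__ = [
    "RejectionMask", "baseline_correct", "reject_by_response",
    "detect_eog_steps", "reject_emg", "screen_epochs", "remove_blink_components",
]

REASONS = ("ok", "rt_fast", "rt_slow", "incorrect", "eog_step", "emg", "visual")


@dataclass
class RejectionMask:
    """Per-trial keep flags with one reason code per rejected trial."""

    keep: np.ndarray          # bool, (n_trials,)
    reason: np.ndarray        # str, (n_trials,); 'ok' for kept trials

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=object)
        if self.keep.shape != self.reason.shape:
            raise ValueError("keep and reason must have equal length")
        if not set(np.unique(self.reason)) <= set(REASONS):
            raise ValueError("unknown reason code")
        if np.any((self.reason == "ok") != self.keep):
            raise ValueError("kept trials must have reason 'ok' and only those")

    @classmethod
    def all_ok(cls, n: int) -> "RejectionMask":
        return cls(np.ones(n, bool), np.array(["ok"] * n, dtype=object))

    def reject(self, index: np.ndarray, reason: str) -> None:
        """Flag trials (first rule wins: already-rejected trials keep theirs)."""
        index = np.asarray(index)
        fresh = index[self.keep[index]]
        self.keep[fresh] = False
        self.reason[fresh] = reason

    @property
    def n_rejected(self) -> int:
        return int((~self.keep).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"keep": self.keep, "reason": self.reason})


# ----------------------------------------------------------------------
def baseline_correct(epochs: EpochsSet,
                     window_ms: tuple[float, float] = (-100.0, 0.0)) -> EpochsSet:
    """Subtract the mean over the pre-stimulus window per trial and channel."""
    mask = epochs.time_mask(window_ms)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_by_response(trials: pd.DataFrame,
                       rt_fast_ms: float = 200.0,
                       slow_sd: float = 3.0) -> RejectionMask:
    """Flag incorrect responses, anticipations, and block-wise slow outliers.

    Rules fire in order: incorrect, RT < ``rt_fast_ms``, RT above the block
    mean + ``slow_sd`` * SD. The block statistics are computed once over that
    block's trials surviving the first two rules (single pass).
    """
    for col in ("rt_ms", "correct", "block"):
        if col not in trials.columns:
            raise KeyError(f"trial metadata lacks required column {col!r}")
    n = len(trials)
    mask = RejectionMask.all_ok(n)
    rt = trials["rt_ms"].to_numpy(dtype=float)
    mask.reject(np.flatnonzero(~trials["correct"].to_numpy(dtype=bool)),
                "incorrect")
    mask.reject(np.flatnonzero(rt < rt_fast_ms), "rt_fast")
    for _, idx in trials.groupby("block").groups.items():
        idx = np.asarray(idx)
        surv = idx[mask.keep[idx]]
        if len(surv) < 2:
            continue
        mu, sd = rt[surv].mean(), rt[surv].std(ddof=1)
        mask.reject(surv[rt[surv] > mu + slow_sd * sd], "rt_slow")
    return mask


def detect_eog_steps(heog: np.ndarray,
                     threshold_uv: float = 30.0,
                     window_ms: float = 100.0,
                     step_ms: float = 50.0,
                     scan_window_ms: tuple[float, float] = (0.0, 500.0),
                     *, times_ms: np.ndarray,
                     sample_rate: float) -> RejectionMask:
    """Sliding split-half step detector on the horizontal EOG.

    A window of ``window_ms`` advances in ``step_ms`` increments across the
    scan window; a trial is flagged ('eog_step') when the absolute difference
    between the mean of the second and the first half-window reaches
    ``threshold_uv`` anywhere. The statistic is a within-window difference,
    so it is invariant to any constant offset of the trace.
    """
    heog = np.atleast_2d(np.asarray(heog, dtype=float))
    times_ms = np.asarray(times_ms, dtype=float)
    if scan_window_ms[0] < times_ms[0] or scan_window_ms[1] > times_ms[-1] + 1e-9:
        raise ValueError("scan window lies outside the epoch")
    w = int(round(window_ms * sample_rate / 1000.0))
    step = max(1, int(round(step_ms * sample_rate / 1000.0)))
    half = w // 2
    start = int(np.searchsorted(times_ms, scan_window_ms[0]))
    stop = int(np.searchsorted(times_ms, scan_window_ms[1], side="right"))
    flagged = np.zeros(heog.shape[0], bool)
    for s in range(start, stop - w + 1, step):
        first = heog[:, s:s + half].mean(axis=1)
        second = heog[:, s + half:s + w].mean(axis=1)
        flagged |= np.abs(second - first) >= threshold_uv
    mask = RejectionMask.all_ok(heog.shape[0])
    mask.reject(np.flatnonzero(flagged), "eog_step")
    return mask


def reject_emg(epochs: EpochsSet,
               band_hz: tuple[float, float] = (110.0, 140.0),
               z_cutoff: float = 3.0,
               cutoff_scale: float = 3.0) -> RejectionMask:
    """Flag trials with excess high-frequency (muscle-band) power.

    Each trial is band-pass filtered (4th-order Butterworth, zero phase),
    summarized as mean squared amplitude over channels and samples, and
    z-scored across trials. The subject-specific cutoff is
    ``max(z_cutoff, cutoff_scale * SD(z))`` -- with plain z-scores SD(z) = 1,
    so the default reduces to a 3-SD rule, but a heavy-tailed trial
    distribution widens the cutoff rather than triggering mass rejection.
    """
    nyq = epochs.sample_rate / 2.0
    if band_hz[1] >= nyq:
        raise ValueError(
            f"band edge {band_hz[1]} Hz requires sample rate > {2 * band_hz[1]} Hz")
    sos = signal.butter(4, band_hz, btype="bandpass", fs=epochs.sample_rate,
                        output="sos")
    filt = signal.sosfiltfilt(sos, epochs.data, axis=2)
    power = np.mean(filt ** 2, axis=(1, 2))
    sd = power.std(ddof=1) if len(power) > 1 else 0.0
    mask = RejectionMask.all_ok(epochs.n_trials)
    if sd == 0.0:
        return mask
    z = (power - power.mean()) / sd
    cutoff = max(z_cutoff, cutoff_scale * z.std(ddof=1))
    mask.reject(np.flatnonzero(z > cutoff), "emg")
    return mask


def remove_blink_components(epochs: EpochsSet, hook=None) -> EpochsSet:
    """Blink-component removal stage (pass-through).

    Decomposition-based blink cleaning of real recordings is delegated to
    ``hook(epochs) -> EpochsSet`` when provided; otherwise the data pass
    through unchanged.
    """
    return hook(epochs) if hook is not None else epochs


# ----------------------------------------------------------------------
def screen_epochs(epochs: EpochsSet,
                  heog: np.ndarray | None = None,
                  baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
                  **emg_kwargs) -> tuple[EpochsSet, RejectionMask]:
    """Full screening pass: baseline, response, EOG, EMG, in that order.

    Returns the baseline-corrected epochs restricted to kept trials together
    with the combined mask (first rule that fired per trial). ``heog`` is a
    ``trials x samples`` horizontal-EOG array; when absent the EOG stage is
    skipped (simulated data carry no ocular channel).
    """
    corrected = baseline_correct(epochs, baseline_window_ms)
    mask = RejectionMask.all_ok(epochs.n_trials)

    resp = reject_by_response(epochs.trials)
    for idx in np.flatnonzero(~resp.keep):
        mask.reject(np.array([idx]), str(resp.reason[idx]))

    if heog is not None:
        eog = detect_eog_steps(heog, times_ms=epochs.times_ms,
                               sample_rate=epochs.sample_rate)
        mask.reject(np.flatnonzero(~eog.keep), "eog_step")

    kept = np.flatnonzero(mask.keep)
    emg = reject_emg(corrected.select_trials(kept), **emg_kwargs)
    mask.reject(kept[~emg.keep], "emg")

    return corrected.select_trials(np.flatnonzero(mask.keep)), mask
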