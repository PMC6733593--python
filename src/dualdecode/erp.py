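"""Conventional lateralized ERP (N2pc/SPCN) analysis.

The N2pc is quantified the classical way: at a lateral posterior electrode
pair (PO7/PO8 by default), the waveform ipsilateral to the horizontal target
is subtracted from the contralateral one, collapsed over the vertical target
position, yielding one contra-minus-ipsi difference wave per subject.
Amplitude and onset latency within the component window (200-350 ms) reuse
the jackknife fractional-peak machinery of :mod:`dualdecode.group_stats`;
the group test against zero is the cluster-corrected permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochsSet
from .group_stats import (cluster_permutation_test, jackknife_corrected_t,
                          jackknife_onset_latency)

__all__ = ["DifferenceWave", "lateralized_difference", "n2pc_metrics",
           "n2pc_latency_contrast"]


@dataclass
class DifferenceWave:
    """Contra-minus-ipsi voltage difference for one subject (microvolts)."""

    wave: np.ndarray                 # (n_samples,)
    times_ms: np.ndarray
    pair: tuple[str, str]            # (left-hemisphere, right-hemisphere)
    n_trials: int


def lateralized_difference(epochs: EpochsSet,
                           pair: tuple[str, str] = ("PO7", "PO8")
                           ) -> DifferenceWave:
    """Average contra-minus-ipsi wave at a lateral electrode pair.

    ``pair`` is (left-hemisphere electrode, right-hemisphere electrode).
    For left-target trials the contralateral electrode is the right one, so
    the difference is right - left; for right-target trials, left - right.
    Only trials with a lateral target label enter; the average collapses
    over the vertical target position.
    """
    li = epochs.channel_index(pair[0])
    ri = epochs.channel_index(pair[1])
    if "h_class" not in epochs.trials.columns:
        raise KeyError("trial metadata lacks 'h_class'")
    h = epochs.trials["h_class"].to_numpy()
    lateral = np.isin(h, ("left", "right"))
    if not lateral.any():
        raise ValueError("no trials with a lateral target")
    left = epochs.data[:, li, :]
    right = epochs.data[:, ri, :]
    sign = np.where(h == "left", 1.0, -1.0)[:, None]
    diff = sign * (right - left)
    return DifferenceWave(diff[lateral].mean(axis=0), epochs.times_ms,
                          pair, int(lateral.sum()))


def n2pc_metrics(waves: list[DifferenceWave] | np.ndarray,
                 times_ms: np.ndarray | None = None,
                 window_ms: tuple[float, float] = (200.0, 350.0),
                 fraction: float = 0.5,
                 polarity: float = 1.0,
                 n_perm: int = 5000,
                 alpha: float = 0.05,
                 seed: int | None = None) -> dict:
    """Group N2pc summary: amplitude, jackknife onsets, cluster test.

    ``waves`` is a list of per-subject :class:`DifferenceWave` or a
    ``subjects x samples`` array (then ``times_ms`` is required).
    ``polarity`` flips the sign searched for the peak (the recorded N2pc is
    a contralateral negativity, i.e. ``polarity=-1``; simulated kernels are
    injected positive contralaterally). Onsets use the shared fractional-peak
    estimator with chance level 0, restricted to the component window.
    """
    if isinstance(waves, (list, tuple)):
        times = waves[0].times_ms
        X = np.vstack([w.wave for w in waves])
    else:
        X = np.asarray(waves, dtype=float)
        if times_ms is None:
            raise ValueError("times_ms required with an array input")
        times = np.asarray(times_ms, dtype=float)

    win = (times >= window_ms[0]) & (times <= window_ms[1])
    signed = polarity * X
    mean_wave = signed.mean(axis=0)
    peak_idx = np.flatnonzero(win)[int(np.argmax(mean_wave[win]))]
    amplitude = float(polarity * mean_wave[peak_idx])

    onsets = jackknife_onset_latency(signed, times, window_ms,
                                     fraction=fraction, chance=0.0)
    cluster = cluster_permutation_test(X, popmean=0.0, n_perm=n_perm,
                                       alpha=alpha, times_ms=times, seed=seed)
    return {
        "amplitude_uv": amplitude,
        "peak_time_ms": float(times[peak_idx]),
        "onsets_ms": onsets,
        "mean_onset_ms": float(np.nanmean(onsets)),
        "cluster": cluster,
        "window_ms": window_ms,
    }


def n2pc_latency_contrast(waves_a, waves_b, times_ms=None,
                          window_ms: tuple[float, float] = (200.0, 350.0),
                          fraction: float = 0.5, polarity: float = 1.0):
    """Jackknife-corrected onset contrast between two sets of difference
    waves from the same cohort (shared code path with the decoding
    latencies)."""
    ons = []
    for waves in (waves_a, waves_b):
        if isinstance(waves, (list, tuple)):
            times = waves[0].times_ms
            X = np.vstack([w.wave for w in waves])
        else:
            X = np.asarray(waves, dtype=float)
            times = np.asarray(times_ms, dtype=float)
        ons.append(jackknife_onset_latency(polarity * X, times, window_ms,
                                           fraction=fraction, chance=0.0))
    return jackknife_corrected_t(ons[0], ons[1],
                                 window_ms=window_ms, fraction=fraction)
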