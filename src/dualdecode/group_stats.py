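"""Group-level inference on decoding time courses.

Two tools mirror the reference analysis. (1) Sample-wise one-sample (or
paired) t-tests across subjects corrected for multiple comparisons by a
cluster-based permutation test on temporally adjacent samples: contiguous
runs of supra-threshold samples are scored by their summed |t| mass and
compared against the permutation distribution of the maximum mass under
per-subject sign flips. (2) Onset latencies estimated by the jackknife
fractional-peak method: the group time course is averaged over all
leave-one-out subsamples, lightly smoothed (3-point moving average), and the
onset is the first sample in the search window at which the score reaches
50% of the peak elevation above chance; condition contrasts use the
jackknife-corrected t statistic (naive paired t divided by n - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .epochs import EpochsSet

__all__ = [
    "ClusterResult", "LatencyContrast", "cluster_permutation_test",
    "jackknife_onset_latency", "jackknife_corrected_t", "split_switch_repeat",
    "fractional_peak_onset",
]


# ----------------------------------------------------------------------
@dataclass
class ClusterResult:
    """Clusters of contiguous significant samples with permutation p-values."""

    clusters: list[dict]        # start_ms, end_ms, start, stop, mass, p_value
    alpha: float
    n_permutations: int
    t_values: np.ndarray        # pointwise t statistic, (T,)
    threshold: float            # cluster-forming |t| threshold

    def significant(self, alpha: float | None = None) -> list[dict]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c["p_value"] <= a]

    @property
    def significant_mask(self) -> np.ndarray:
        m = np.zeros_like(self.t_values, dtype=bool)
        for c in self.significant():
            m[c["start"]:c["stop"]] = True
        return m


def _runs(above: np.ndarray) -> list[tuple[int, int]]:
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        stops = stops + [len(above)]
    return list(zip(starts, stops))


def _clusters_from_t(t: np.ndarray, thresh: float) -> list[tuple[int, int]]:
    """Maximal same-sign runs of samples with |t| above the threshold.

    Positive and negative excursions are clustered separately, as is
    standard for cluster-level inference on signed statistics.
    """
    return sorted(_runs(t > thresh) + _runs(t < -thresh))


def _max_mass(t_rows: np.ndarray, thresh: float) -> np.ndarray:
    """Maximum cluster |t| mass per row of a (P, T) signed-t matrix."""
    out = np.zeros(t_rows.shape[0])
    for i, row in enumerate(t_rows):
        masses = [np.abs(row[a:b]).sum()
                  for a, b in _clusters_from_t(row, thresh)]
        if masses:
            out[i] = max(masses)
    return out


def cluster_permutation_test(subject_series: np.ndarray,
                             popmean: float = 0.0,
                             paired_with: np.ndarray | None = None,
                             n_perm: int = 5000,
                             alpha: float = 0.05,
                             times_ms: np.ndarray | None = None,
                             seed: int | None = None) -> ClusterResult:
    """Cluster-corrected test of per-subject time courses.

    One-sample mode tests ``subject_series`` (subjects x timepoints) against
    ``popmean`` (0.5 for AUC, 0 for differences or correlations); supplying
    ``paired_with`` tests the per-subject difference against 0, and the
    per-subject sign flip is then equivalent to swapping the two conditions.
    The cluster-forming threshold is the pointwise two-sided critical t at
    ``alpha``; cluster mass is the summed |t|; the p-value of each observed
    cluster is the proportion of permutation maximum masses at least as
    large, with the observed statistic included in the null set (so
    p >= 1/(n_perm + 1)).
    """
    X = np.asarray(subject_series, dtype=float)
    if paired_with is not None:
        X = X - np.asarray(paired_with, dtype=float)
    else:
        X = X - popmean
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a subjects x timepoints array with >= 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    n, T = X.shape
    times = (np.asarray(times_ms, dtype=float) if times_ms is not None
             else np.arange(T, dtype=float))

    df = n - 1
    thresh = stats.t.ppf(1.0 - alpha / 2.0, df)

    def _tstat(mean_rows):
        # sign flips leave per-subject squares untouched, so the sums of
        # squares are permutation-invariant and only the mean changes
        var = (ss - n * mean_rows ** 2) / df
        var = np.maximum(var, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean_rows / np.sqrt(var / n)
        return np.nan_to_num(t)

    ss = (X ** 2).sum(axis=0)
    t_obs = _tstat(X.mean(axis=0))
    obs_clusters = _clusters_from_t(t_obs, thresh)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_means = signs @ X / n
    perm_max = _max_mass(_tstat(perm_means), thresh)

    clusters = []
    for a, b in obs_clusters:
        mass = float(np.abs(t_obs[a:b]).sum())
        p = (1.0 + np.sum(perm_max >= mass)) / (n_perm + 1.0)
        clusters.append({
            "start": int(a), "stop": int(b),
            "start_ms": float(times[a]), "end_ms": float(times[b - 1]),
            "mass": mass, "p_value": float(p),
        })
    return ClusterResult(clusters, alpha, n_perm, t_obs, float(thresh))


# ----------------------------------------------------------------------
def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-point moving average (edges replicate the boundary sample)."""
    return uniform_filter1d(np.asarray(x, dtype=float), size=3,
                            mode="nearest", axis=-1)


def fractional_peak_onset(series: np.ndarray, times_ms: np.ndarray,
                          window_ms: tuple[float, float] = (150.0, 700.0),
                          fraction: float = 0.5,
                          chance: float = 0.5) -> float:
    """Onset of one time course: first sample reaching the fractional peak.

    The series is smoothed with a 3-point moving average, the peak located
    inside the search window, and the onset defined as the first in-window
    sample at or above ``chance + fraction * (peak - chance)`` -- the
    fractional criterion is referenced to the elevation above chance, since
    a raw-score criterion would be degenerate for measures that never fall
    below their chance level. Returns NaN (with a warning) when the series
    never rises above chance in the window.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    sm = _smooth3(series)
    times = np.asarray(times_ms, dtype=float)
    win = (times >= window_ms[0]) & (times <= window_ms[1])
    if not win.any():
        raise ValueError("search window contains no samples")
    idx = np.flatnonzero(win)
    peak_rel = int(np.argmax(sm[idx]))
    peak = sm[idx[peak_rel]]
    if peak <= chance:
        warnings.warn("series never exceeds chance in the window; onset NaN")
        return float("nan")
    if peak_rel in (0, len(idx) - 1):
        warnings.warn("peak at search-window edge; onset may be unreliable")
    thresh = chance + fraction * (peak - chance)
    cross = np.flatnonzero(sm[idx] >= thresh)
    return float(times[idx[cross[0]]])


def jackknife_onset_latency(group_series: np.ndarray, times_ms: np.ndarray,
                            window_ms: tuple[float, float] = (150.0, 700.0),
                            fraction: float = 0.5,
                            chance: float = 0.5) -> np.ndarray:
    """Leave-one-out fractional-peak onsets of a subjects x timepoints array.

    Element ``i`` is the onset of the group average computed over all
    subjects except ``i``. The reduced between-subsample variance is
    corrected downstream by :func:`jackknife_corrected_t`.
    """
    X = np.asarray(group_series, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 subjects for the jackknife")
    n = X.shape[0]
    total = X.sum(axis=0)
    onsets = np.empty(n)
    for i in range(n):
        loo = (total - X[i]) / (n - 1)
        onsets[i] = fractional_peak_onset(loo, times_ms, window_ms,
                                          fraction, chance)
    return onsets


@dataclass
class LatencyContrast:
    """Jackknife onset contrast between two conditions of one cohort."""

    onsets_a: np.ndarray
    onsets_b: np.ndarray
    difference_ms: float
    t_naive: float
    t_corrected: float
    p_value: float
    df: int
    window_ms: tuple[float, float] = (150.0, 700.0)
    fraction: float = 0.5

    @property
    def mean_onset_a(self) -> float:
        return float(np.mean(self.onsets_a))

    @property
    def mean_onset_b(self) -> float:
        return float(np.mean(self.onsets_b))


def jackknife_corrected_t(onsets_a: np.ndarray, onsets_b: np.ndarray,
                          **meta) -> LatencyContrast:
    """Paired contrast of leave-one-out onsets with jackknife correction.

    The naive paired t over leave-one-out estimates overstates the evidence
    because the subsamples overlap; dividing the t statistic by the degrees
    of freedom (n - 1) restores the correct error term. Two-sided p from the
    t distribution with df = n - 1.
    """
    a = np.asarray(onsets_a, dtype=float)
    b = np.asarray(onsets_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("onset vectors must come from the same cohort")
    n = len(a)
    if n < 3:
        raise ValueError("need >= 3 leave-one-out estimates")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("undefined onsets present; cannot contrast")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        t_naive = 0.0 if d.mean() == 0.0 else np.inf * np.sign(d.mean())
    else:
        t_naive = d.mean() / (sd / np.sqrt(n))
    t_c = t_naive / (n - 1)
    p = 1.0 if t_c == 0.0 else float(2.0 * stats.t.sf(abs(t_c), n - 1))
    return LatencyContrast(a, b, float(d.mean()), float(t_naive),
                           float(t_c), p, n - 1, **meta)


# ----------------------------------------------------------------------
def split_switch_repeat(epochs: EpochsSet) -> tuple[EpochsSet, EpochsSet]:
    """Partition trials by whether the target color switched from the
    previous trial; the first trial of each block has no predecessor and is
    excluded. Returns ``(switch, repeat)``."""
    for col in ("target_color", "block"):
        if col not in epochs.trials.columns:
            raise KeyError(f"trial metadata lacks required column {col!r}")
    color = epochs.trials["target_color"].to_numpy()
    block = epochs.trials["block"].to_numpy()
    prev_color = np.roll(color, 1)
    has_prev = np.r_[False, block[1:] == block[:-1]]
    switch = has_prev & (color != prev_color)
    repeat = has_prev & (color == prev_color)
    return (epochs.select_trials(np.flatnonzero(switch)),
            epochs.select_trials(np.flatnonzero(repeat)))
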