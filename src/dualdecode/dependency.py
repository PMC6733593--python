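"""Serial-vs-parallel diagnostic: correlating classifier confidence.

If the two targets compete for a single selection mechanism, a classifier
confident about the horizontal target position on a given trial should be
unconfident about the vertical one, and vice versa: trial-wise confidence of
the two decoders should correlate negatively. Parallel selection driven by a
common gain predicts a positive correlation; independent parallel selection
predicts none. The diagnostic therefore computes, per timepoint, the
Spearman rank correlation of the two decoders' confidence scores across
trials, tests the per-subject correlations against zero with the
cluster-corrected group test, and summarizes each subject at the timepoints
of maximal decoding performance.

Confidence scores are by default *correctness-referenced* before
correlating: the signed distance from the decision boundary is oriented
toward the trial's true class, so that a large value always means "confident
about the actual target position", making left/right and top/bottom trials
commensurable. The raw signed convention is available via ``orient='raw'``.

The SNR sensitivity sweep regenerates the full pipeline across injected
correlation modes and noise levels to establish at which decoding strength
a known correlation is reliably recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .decoding import DecodingResult, crossval_decode
from .group_stats import ClusterResult, cluster_permutation_test
from .simulate import SimulationConfig, child_seeds, generate_dataset

__all__ = [
    "DependencyResult", "trialwise_confidence_correlation",
    "timecourse_correlation", "peak_auc_correlation",
    "subject_dependency", "analyze_cohort_dependency",
    "snr_sensitivity_sweep",
]


# ----------------------------------------------------------------------
def _orient(conf: np.ndarray, y: np.ndarray, orient: str) -> np.ndarray:
    if orient == "raw":
        return conf
    if orient == "correct":
        return conf * np.where(np.asarray(y, dtype=bool), 1.0, -1.0)[:, None]
    raise ValueError("orient must be 'correct' or 'raw'")


def trialwise_confidence_correlation(conf_h: np.ndarray, conf_v: np.ndarray
                                     ) -> np.ndarray:
    """Spearman rho across trials at each timepoint.

    ``conf_h`` and ``conf_v`` are ``trials x timepoints`` confidence arrays
    over the *same* trials (already oriented as desired). Rank-based, hence
    invariant to strictly monotone transforms of either input.
    """
    A = np.asarray(conf_h, dtype=float)
    B = np.asarray(conf_v, dtype=float)
    if A.shape != B.shape:
        raise ValueError("confidence arrays must cover the same trials")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trials for a rank correlation")
    ra = rankdata(A, axis=0)
    rb = rankdata(B, axis=0)
    ra -= ra.mean(axis=0)
    rb -= rb.mean(axis=0)
    denom = np.sqrt((ra ** 2).sum(axis=0) * (rb ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra * rb).sum(axis=0) / denom
    return rho


def timecourse_correlation(auc_h: np.ndarray, auc_v: np.ndarray,
                           times_ms: np.ndarray,
                           window_ms: tuple[float, float] = (150.0, 700.0)
                           ) -> float:
    """Spearman rho between the two AUC time courses within a window."""
    times = np.asarray(times_ms, dtype=float)
    m = (times >= window_ms[0]) & (times <= window_ms[1])
    if not m.any():
        raise ValueError("window contains no samples")
    return float(spearmanr(np.asarray(auc_h)[m], np.asarray(auc_v)[m])[0])


def peak_auc_correlation(res_h: DecodingResult, res_v: DecodingResult,
                         rho_timecourse: np.ndarray,
                         window_ms: tuple[float, float] | None = None
                         ) -> dict:
    """Trial-wise rho at each dimension's peak-AUC timepoint (one subject)."""
    out = {}
    for res, key in ((res_h, "horizontal"), (res_v, "vertical")):
        times = res.times_ms
        m = (np.ones_like(times, bool) if window_ms is None
             else (times >= window_ms[0]) & (times <= window_ms[1]))
        idx = np.flatnonzero(m)[int(np.argmax(res.auc[m]))]
        out[key] = {"peak_auc": float(res.auc[idx]),
                    "peak_time_ms": float(times[idx]),
                    "rho_at_peak": float(rho_timecourse[idx])}
    return out


# ----------------------------------------------------------------------
def subject_dependency(res_h: DecodingResult, res_v: DecodingResult,
                       orient: str = "correct") -> np.ndarray:
    """Per-timepoint trial-wise rho for one subject's two decoders.

    Within-class balancing may retain different trials for the two
    dimensions; the correlation uses their intersection.
    """
    common, ia, ib = np.intersect1d(res_h.trial_index, res_v.trial_index,
                                    return_indices=True)
    if len(common) < 3:
        raise ValueError("fewer than 3 trials shared by the two decoders")
    ch = _orient(res_h.confidence[ia], res_h.y[ia], orient)
    cv = _orient(res_v.confidence[ib], res_v.y[ib], orient)
    return trialwise_confidence_correlation(ch, cv)


@dataclass
class DependencyResult:
    """Cohort-level confidence-dependency summary."""

    times_ms: np.ndarray
    rho_timecourse: np.ndarray        # subjects x timepoints
    group_rho: np.ndarray             # (T,) mean over subjects
    cluster: ClusterResult            # group test of rho against 0
    peak_pairs: list[dict]            # per subject, from peak_auc_correlation
    auc_series_rho: np.ndarray        # per-subject AUC-time-course rho

    @property
    def mean_auc_series_rho(self) -> float:
        return float(np.mean(self.auc_series_rho))


def analyze_cohort_dependency(results: list[tuple[DecodingResult, DecodingResult]],
                              orient: str = "correct",
                              window_ms: tuple[float, float] = (150.0, 700.0),
                              n_perm: int = 5000,
                              alpha: float = 0.05,
                              seed: int | None = None) -> DependencyResult:
    """Run the full dependency analysis over a cohort of decoded subjects."""
    times = results[0][0].times_ms
    rho = np.vstack([subject_dependency(h, v, orient) for h, v in results])
    cluster = cluster_permutation_test(rho, popmean=0.0, n_perm=n_perm,
                                       alpha=alpha, times_ms=times, seed=seed)
    peaks = [peak_auc_correlation(h, v, r, window_ms)
             for (h, v), r in zip(results, rho)]
    series_rho = np.array([
        timecourse_correlation(h.auc, v.auc, times, window_ms)
        for h, v in results])
    return DependencyResult(times, rho, rho.mean(axis=0), cluster,
                            peaks, series_rho)


# ----------------------------------------------------------------------
def snr_sensitivity_sweep(modes=("positive", "negative", "null"),
                          snr_grid=(4.0, 0.5, 0.05),
                          n_subjects: int = 8,
                          seed: int = 0,
                          base_config: SimulationConfig | None = None,
                          decode_window_ms: tuple[float, float] = (100.0, 700.0),
                          erp_window_ms: tuple[float, float] = (200.0, 600.0),
                          folds: int = 10,
                          n_perm: int = 1000,
                          alpha: float = 0.05,
                          orient: str = "correct") -> pd.DataFrame:
    """Sensitivity of the correlation diagnostic across SNR levels.

    For every (mode, SNR) cell a fresh cohort is simulated, both dimensions
    decoded, the trial-wise confidence correlation computed, and the group
    correlation tested against zero inside the ERP window. ``detected`` is
    True when a significant cluster with the injected sign exists inside
    that window (for null mode: any significant cluster -- the false-alarm
    rate of the diagnostic).
    """
    import dataclasses as _dc

    base = base_config or SimulationConfig()
    rows = []
    cell_seeds = child_seeds(seed, len(modes) * len(snr_grid))
    k = 0
    for mode in modes:
        for snr in snr_grid:
            cfg = _dc.replace(base, correlation_mode=mode, snr=float(snr),
                              seed=cell_seeds[k])
            subj_seeds = child_seeds(cell_seeds[k], n_subjects)
            k += 1
            pairs = []
            for s in subj_seeds:
                ep = generate_dataset(_dc.replace(cfg, seed=s))
                res_h = crossval_decode(ep, "horizontal", folds=folds,
                                        seed=s + 1, window_ms=decode_window_ms)
                res_v = crossval_decode(ep, "vertical", folds=folds,
                                        seed=s + 2, window_ms=decode_window_ms)
                pairs.append((res_h, res_v))
            dep = analyze_cohort_dependency(
                pairs, orient=orient, window_ms=erp_window_ms,
                n_perm=n_perm, alpha=alpha, seed=cell_seeds[k - 1] + 7)
            times = dep.times_ms
            win = (times >= erp_window_ms[0]) & (times <= erp_window_ms[1])
            peak_aucs = [
                max(p["horizontal"]["peak_auc"], p["vertical"]["peak_auc"])
                for p in dep.peak_pairs]
            want_sign = {"positive": 1.0, "negative": -1.0, "null": 0.0}[mode]
            detected = False
            for c in dep.cluster.significant():
                inside = win[c["start"]:c["stop"]].any()
                sign = np.sign(dep.cluster.t_values[c["start"]:c["stop"]].mean())
                if inside and (want_sign == 0.0 or sign == want_sign):
                    detected = True
            rows.append({
                "mode": mode, "snr": float(snr),
                "mean_peak_auc": float(np.mean(peak_aucs)),
                "mean_rho": float(dep.group_rho[win].mean()),
                "detected": bool(detected),
            })
    return pd.DataFrame(rows)
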