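"""Synthetic epoched-EEG generator with known ERP and correlation structure.

Simulates the attentional-selection ERP as half a cycle of a sine wave
(default 1 microvolt peak, 200-600 ms post stimulus) injected on 8 of 64
channels. Lateralization is modelled by adding the kernel with positive sign
on the channels contralateral to the target and negative sign ipsilaterally.
Horizontal (left/right) and vertical (top/bottom) target selection use an
orthogonal split of the signal channels, so the two spatial patterns are
orthogonal vectors in channel space and carry independent information.

Whether the ERP is present on a trial follows one of three correlation
modes between the two dimensions:

``positive``
    both targets selected or neither (each on exactly half the trials),
``negative``
    exactly one of the two selected per trial (half/half),
``null``
    presence drawn independently per dimension (Bernoulli 1/2).

Noise is i.i.d. per trial/channel/sample, bounded in magnitude by
``amplitude / snr`` -- the SNR is the ratio of peak ERP amplitude to maximum
noise amplitude (an amplitude, not power, convention). Uniform noise is the
default because a hard maximum is only well defined for bounded noise;
Gaussian noise (sigma = bound / 3) is available behind a flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import BIOSEMI64_NAMES, EpochsSet

__all__ = [
    "ErpKernel", "ChannelSplit", "SimulationConfig", "PAPER_SNR_GRID",
    "make_erp_kernel", "default_channel_split", "draw_presence",
    "generate_dataset", "generate_cohort", "child_seeds",
]

#: The 17 SNR levels of the published sensitivity sweep (peak amplitude over
#: maximum noise amplitude), from clearly decodable to far below threshold.
PAPER_SNR_GRID = (4, 2, 1.33, 1, 0.67, 0.5, 0.33, 0.25, 0.2, 0.17,
                  0.14, 0.13, 0.11, 0.1, 0.07, 0.05, 0.04)

MODES = ("positive", "negative", "null")


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ErpKernel:
    """Half-sine ERP template sampled on the epoch time grid.

    ``waveform[t] = amplitude * sin(pi * (t - onset) / (offset - onset))``
    inside ``[onset_ms, offset_ms]`` and zero elsewhere: zero at onset and
    offset with a single interior maximum at the window midpoint.
    """

    amplitude: float
    onset_ms: float
    offset_ms: float
    sample_rate: float
    waveform: np.ndarray


def make_erp_kernel(amplitude: float, onset_ms: float, offset_ms: float,
                    sample_rate: float, times_ms: np.ndarray) -> ErpKernel:
    """Evaluate the half-sine ERP kernel on an epoch time grid (ms)."""
    times_ms = np.asarray(times_ms, dtype=float)
    if offset_ms <= onset_ms:
        raise ValueError("offset_ms must exceed onset_ms")
    if onset_ms < times_ms[0] or offset_ms > times_ms[-1]:
        raise ValueError("ERP window lies outside the epoch time grid")
    phase = (times_ms - onset_ms) / (offset_ms - onset_ms)
    wave = np.where((phase >= 0.0) & (phase <= 1.0),
                    amplitude * np.sin(np.pi * np.clip(phase, 0.0, 1.0)),
                    0.0)
    return ErpKernel(amplitude, onset_ms, offset_ms, sample_rate, wave)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ChannelSplit:
    """Orthogonal partition of the 8 signal channels.

    ``h_contra`` holds the channels contralateral to a *left* target (right
    hemisphere); ``v_contra`` those contralateral to a *top* target. The two
    splits intersect evenly (|h_contra & v_contra| == |h_contra & v_ipsi|),
    which makes the +/- channel patterns of the two dimensions orthogonal.
    """

    h_contra: tuple[int, ...]
    h_ipsi: tuple[int, ...]
    v_contra: tuple[int, ...]
    v_ipsi: tuple[int, ...]

    def __post_init__(self):
        h = set(self.h_contra) | set(self.h_ipsi)
        v = set(self.v_contra) | set(self.v_ipsi)
        if set(self.h_contra) & set(self.h_ipsi) or \
           set(self.v_contra) & set(self.v_ipsi):
            raise ValueError("contra/ipsi halves must be disjoint")
        if h != v:
            raise ValueError("H and V splits must cover the same channels")
        a = len(set(self.h_contra) & set(self.v_contra))
        b = len(set(self.h_contra) & set(self.v_ipsi))
        if a != b:
            raise ValueError("splits are not orthogonal "
                             "(uneven intersection with the V halves)")

    @property
    def signal_channels(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.h_contra) | set(self.h_ipsi)))

    def pattern(self, dimension: str, n_channels: int) -> np.ndarray:
        """+1/-1 channel-space template for the first-listed class
        ('left' for horizontal, 'top' for vertical); zero elsewhere."""
        p = np.zeros(n_channels)
        contra, ipsi = ((self.h_contra, self.h_ipsi) if dimension == "horizontal"
                        else (self.v_contra, self.v_ipsi))
        p[list(contra)] = 1.0
        p[list(ipsi)] = -1.0
        return p


def default_channel_split(channel_names: list[str] | None = None) -> ChannelSplit:
    """Posterior 8-channel split with PO7/PO8 on the horizontal halves.

    Right-hemisphere electrodes (contralateral to left targets) form
    ``h_contra``; the vertical split pairs lateral (P7/P8/PO7/PO8) against
    medial-occipital (PO3/PO4/O1/O2) channels, intersecting each horizontal
    half in two channels.
    """
    names = channel_names or BIOSEMI64_NAMES
    idx = {n: i for i, n in enumerate(names)}
    h_contra = ("PO8", "P8", "PO4", "O2")   # right hemisphere
    h_ipsi = ("PO7", "P7", "PO3", "O1")     # left hemisphere
    v_contra = ("PO8", "P8", "PO7", "P7")
    v_ipsi = ("PO4", "O2", "PO3", "O1")
    try:
        return ChannelSplit(
            tuple(idx[n] for n in h_contra),
            tuple(idx[n] for n in h_ipsi),
            tuple(idx[n] for n in v_contra),
            tuple(idx[n] for n in v_ipsi),
        )
    except KeyError as e:
        raise ValueError(f"channel {e} required for the default split") from e


# ----------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """Everything needed to generate one simulated subject.

    ``snr`` is peak ERP amplitude divided by the maximum noise amplitude;
    ``noise_amplitude`` overrides the derived bound (needed e.g. for
    noise-only data where ``amplitude = 0``). ``seed`` controls every random
    draw; identical configs regenerate the tensor bit-exactly.
    """

    n_trials: int = 512
    n_channels: int = 64
    correlation_mode: str = "negative"
    snr: float = 4.0
    amplitude: float = 1.0          # microvolts, ERP peak
    erp_onset_ms: float = 200.0
    erp_offset_ms: float = 600.0
    epoch_window_ms: tuple[float, float] = (-300.0, 800.0)
    sample_rate: float = 512.0
    noise: str = "uniform"          # or "gaussian" (sigma = bound / 3)
    noise_amplitude: float | None = None
    channel_names: list[str] | None = None
    split: ChannelSplit | None = None
    condition: str = "2TMP-2TGT"
    seed: int = 0

    def __post_init__(self):
        if self.correlation_mode not in MODES:
            raise ValueError(f"correlation_mode must be one of {MODES}")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.n_trials % 2:
            raise ValueError("n_trials must be even")
        if self.noise not in ("uniform", "gaussian"):
            raise ValueError("noise must be 'uniform' or 'gaussian'")
        if not (self.epoch_window_ms[0] <= self.erp_onset_ms
                and self.erp_offset_ms <= self.epoch_window_ms[1]):
            raise ValueError("epoch window must contain the ERP window")

    @property
    def noise_bound(self) -> float:
        """Maximum noise magnitude in microvolts."""
        if self.noise_amplitude is not None:
            return float(self.noise_amplitude)
        return float(self.amplitude) / float(self.snr)

    def times_ms(self) -> np.ndarray:
        fs = self.sample_rate
        lo = int(np.round(self.epoch_window_ms[0] * fs / 1000.0))
        hi = int(np.round(self.epoch_window_ms[1] * fs / 1000.0))
        return np.arange(lo, hi + 1) * (1000.0 / fs)

    # -- plain-dict round trip for YAML/JSON configs -------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epoch_window_ms"] = list(self.epoch_window_ms)
        if self.split is not None:
            d["split"] = {k: list(v) for k, v in dataclasses.asdict(self.split).items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("split") is not None:
            d["split"] = ChannelSplit(**{k: tuple(v)
                                         for k, v in d["split"].items()})
        if "epoch_window_ms" in d:
            d["epoch_window_ms"] = tuple(d["epoch_window_ms"])
        return cls(**d)


# ----------------------------------------------------------------------
def draw_presence(correlation_mode: str, n_trials: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial ERP-presence flags for the two dimensions.

    positive: (present, present) on exactly half the trials, (absent, absent)
    on the other half. negative: exactly one present per trial, half/half.
    null: independent Bernoulli(1/2) per dimension.
    """
    if correlation_mode not in MODES:
        raise ValueError(f"unknown correlation mode {correlation_mode!r}")
    if n_trials % 2:
        raise ValueError("n_trials must be even")
    half = n_trials // 2
    if correlation_mode == "positive":
        h = np.r_[np.ones(half, bool), np.zeros(half, bool)]
        v = h.copy()
        perm = rng.permutation(n_trials)
        return h[perm], v[perm]
    if correlation_mode == "negative":
        h = np.r_[np.ones(half, bool), np.zeros(half, bool)]
        v = ~h
        perm = rng.permutation(n_trials)
        return h[perm], v[perm]
    # null: product measure, no forced balance
    return rng.random(n_trials) < 0.5, rng.random(n_trials) < 0.5


def _balanced_classes(levels: tuple[str, str], n: int,
                      rng: np.random.Generator) -> np.ndarray:
    reps = np.resize(np.array(levels), n)
    return reps[rng.permutation(n)]


def generate_dataset(config: SimulationConfig) -> EpochsSet:
    """Generate one simulated subject according to ``config``.

    Class labels (left/right, top/bottom) are counterbalanced jointly
    (n/4 per cell, as positions were counterbalanced in the experiment) and
    are independent of ERP presence: on ERP-absent trials the label carries
    no information (chance-level decoding by construction). Non-signal
    channels contain noise only.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    times = config.times_ms()
    n, n_ch, n_t = config.n_trials, config.n_channels, len(times)
    split = config.split or default_channel_split(config.channel_names)
    names = list(config.channel_names or BIOSEMI64_NAMES)[:n_ch]
    if len(names) < n_ch:
        names += [f"SIM{i}" for i in range(len(names), n_ch)]
    if max(split.signal_channels) >= n_ch:
        raise ValueError("split references channels beyond n_channels")

    kernel = make_erp_kernel(config.amplitude, config.erp_onset_ms,
                             config.erp_offset_ms, config.sample_rate, times)

    present_h, present_v = draw_presence(config.correlation_mode, n, rng)

    # joint counterbalance of the two position labels
    cells = [("left", "top"), ("left", "bottom"),
             ("right", "top"), ("right", "bottom")]
    cell_idx = np.resize(np.arange(4), n)[rng.permutation(n)]
    h_class = np.array([cells[c][0] for c in cell_idx])
    v_class = np.array([cells[c][1] for c in cell_idx])

    bound = config.noise_bound
    if bound > 0:
        if config.noise == "uniform":
            data = rng.uniform(-bound, bound, size=(n, n_ch, n_t))
        else:
            data = rng.normal(0.0, bound / 3.0, size=(n, n_ch, n_t))
    else:
        data = np.zeros((n, n_ch, n_t))

    pat_h = split.pattern("horizontal", n_ch)   # +contra/-ipsi for 'left'
    pat_v = split.pattern("vertical", n_ch)     # +contra/-ipsi for 'top'
    sign_h = np.where(h_class == "left", 1.0, -1.0) * present_h
    sign_v = np.where(v_class == "top", 1.0, -1.0) * present_v
    # data += sign[trial] * pattern[channel] * kernel[sample]
    data += sign_h[:, None, None] * pat_h[None, :, None] * kernel.waveform
    data += sign_v[:, None, None] * pat_v[None, :, None] * kernel.waveform

    # behavioural metadata: plausible RTs/accuracy so the screening rules
    # have something to act on; not part of the neural ground truth
    rt = np.clip(rng.normal(700.0, 120.0, size=n), 250.0, None)
    correct = rng.random(n) < 0.97
    block = np.arange(n) // 64
    color = rng.choice(["red", "green"], size=n)

    trials = pd.DataFrame({
        "condition": config.condition,
        "h_class": h_class,
        "v_class": v_class,
        "erp_present_h": present_h,
        "erp_present_v": present_v,
        "correct": correct,
        "rt_ms": rt,
        "block": block,
        "target_color": color,
    })
    return EpochsSet(data, config.sample_rate, times, names, trials)


# ----------------------------------------------------------------------
def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic independent child seeds (< 2**31) from a master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_cohort(config: SimulationConfig, n_subjects: int,
                    seed: int | None = None) -> list[EpochsSet]:
    """Generate ``n_subjects`` independent subjects.

    Each subject gets a distinct child seed derived deterministically from
    ``seed`` (default: ``config.seed``); rerunning with the same seed is
    bit-identical.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    master = config.seed if seed is None else seed
    out = []
    for s in child_seeds(master, n_subjects):
        out.append(generate_dataset(dataclasses.replace(config, seed=s)))
    return out
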