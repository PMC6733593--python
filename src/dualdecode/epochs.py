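"""Epoched multichannel EEG container and on-disk layout.

The central in-memory object is :class:`EpochsSet`: a
``trials x channels x samples`` voltage tensor (microvolts) plus a per-trial
metadata table. It round-trips losslessly through a documented HDF5 layout
(``/data``, ``/times_ms``, ``/channel_names``, ``/trials``) and converts to
and from :class:`mne.EpochsArray` for interoperability with standard epochs
formats (FIF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EpochsSet", "BIOSEMI64_NAMES"]

#: 64-channel 10-20 labels (BioSemi layout), used by the simulator so that
#: lateral electrode pairs such as PO7/PO8 resolve on synthetic data.
BIOSEMI64_NAMES = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]


@dataclass
class EpochsSet:
    """Epoched EEG: ``data[trial, channel, sample]`` in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltage in microvolts.
    sample_rate : float
        Sampling rate in Hz.
    times_ms : ndarray, shape (n_samples,)
        Per-sample timestamps in milliseconds relative to stimulus onset;
        strictly increasing, uniformly spaced at ``1000 / sample_rate``.
    channel_names : list of str
    trials : pandas.DataFrame
        One row per trial. Recognised columns include ``condition``,
        ``h_class`` ('left'/'right'), ``v_class`` ('top'/'bottom'),
        ``erp_present_h``/``erp_present_v`` (simulation ground truth),
        ``correct``, ``rt_ms``, ``block``, ``target_color``.
    """

    data: np.ndarray
    sample_rate: float
    times_ms: np.ndarray
    channel_names: list[str]
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n, c, s = self.data.shape
        if len(self.channel_names) != c:
            raise ValueError("channel_names length does not match data")
        if self.times_ms.shape != (s,):
            raise ValueError("times_ms length does not match data")
        dt = np.diff(self.times_ms)
        if len(dt) and (np.any(dt <= 0)
                        or not np.allclose(dt, 1000.0 / self.sample_rate,
                                           rtol=1e-6, atol=1e-6)):
            raise ValueError("times_ms must increase uniformly at 1000/fs")
        if len(self.trials) == 0:
            self.trials = pd.DataFrame(index=pd.RangeIndex(n))
        if len(self.trials) != n:
            raise ValueError("trials metadata length does not match data")

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for a closed time window in ms."""
        lo, hi = window_ms
        if lo > hi:
            raise ValueError("window start must not exceed end")
        return (self.times_ms >= lo) & (self.times_ms <= hi)

    def select_trials(self, index) -> "EpochsSet":
        """Positional trial subset; metadata index is reset."""
        index = np.asarray(index)
        return EpochsSet(
            data=self.data[index],
            sample_rate=self.sample_rate,
            times_ms=self.times_ms,
            channel_names=list(self.channel_names),
            trials=self.trials.iloc[index].reset_index(drop=True),
        )

    def copy(self) -> "EpochsSet":
        return EpochsSet(self.data.copy(), self.sample_rate,
                         self.times_ms.copy(), list(self.channel_names),
                         self.trials.copy())

    # ------------------------------------------------------------------
    # HDF5 round trip
    def save_h5(self, path) -> None:
        """Write the documented HDF5 layout (bit-exact round trip)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset(
                "channel_names",
                data=np.array(self.channel_names, dtype=h5py.string_dtype()),
            )
            f.attrs["sample_rate"] = self.sample_rate
            g = f.create_group("trials")
            for col in self.trials.columns:
                v = self.trials[col].to_numpy()
                if v.dtype == object:
                    v = v.astype(h5py.string_dtype())
                g.create_dataset(str(col), data=v)
            g.attrs["columns"] = np.array(
                [str(c) for c in self.trials.columns],
                dtype=h5py.string_dtype(),
            )

    @classmethod
    def load_h5(cls, path) -> "EpochsSet":
        import h5py

        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times_ms"][()]
            names = [s.decode() if isinstance(s, bytes) else s
                     for s in f["channel_names"][()]]
            fs = float(f.attrs["sample_rate"])
            g = f["trials"]
            cols = [s.decode() if isinstance(s, bytes) else s
                    for s in g.attrs["columns"]]
            tbl = {}
            for col in cols:
                v = g[col][()]
                if v.dtype.kind in ("S", "O"):
                    v = np.array([s.decode() if isinstance(s, bytes) else s
                                  for s in v])
                tbl[col] = v
            trials = pd.DataFrame(tbl, columns=cols)
        return cls(data, fs, times, names, trials)

    # ------------------------------------------------------------------
    # Conversion hook to the standard epochs container
    def to_mne(self):
        """Convert to :class:`mne.EpochsArray` (volts, metadata attached)."""
        import mne

        info = mne.create_info(self.channel_names, self.sample_rate, "eeg")
        ep = mne.EpochsArray(
            self.data * 1e-6, info,
            tmin=float(self.times_ms[0]) / 1000.0, verbose="error",
        )
        ep.metadata = self.trials.copy()
        return ep

    @classmethod
    def from_mne(cls, epochs) -> "EpochsSet":
        """Build from an MNE epochs object (e.g. read from FIF)."""
        data = epochs.get_data(copy=True) * 1e6
        trials = (epochs.metadata.reset_index(drop=True)
                  if epochs.metadata is not None else pd.DataFrame())
        return cls(
            data=data,
            sample_rate=float(epochs.info["sfreq"]),
            times_ms=epochs.times * 1000.0,
            channel_names=list(epochs.ch_names),
            trials=trials,
        )
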