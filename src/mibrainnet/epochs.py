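"""Epoched-EEG container, pipeline configuration, and container I/O.

The :class:`EpochSet` is the carrier type for the whole pipeline: a
``(n_trials, n_channels, n_samples)`` float tensor with integer class
labels, a sampling rate, channel names and a free-text provenance log that
each processing stage appends to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["EpochSet", "PipelineConfig", "read_epochs", "write_epochs", "repair_bad_channels"]


@dataclass
class EpochSet:
    """Labeled multichannel EEG trials.

    Parameters
    ----------
    data
        Real tensor of shape (n_trials, n_channels, n_samples).
    labels
        Integer class label per trial, values in 1..C.
    fs
        Sampling rate in Hz.
    channel_names
        Unique channel names; defaults to ``ch01..chNN``.
    provenance
        Free-text log, one entry per applied processing stage.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if self.labels.shape != (n_trials,):
            raise ValueError(
                f"label/trial count mismatch: {self.labels.shape[0] if self.labels.ndim else 0} "
                f"labels for {n_trials} trials"
            )
        if self.labels.size and self.labels.min() < 1:
            raise ValueError("labels must be positive integers 1..C")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if n_samples < 8:
            raise ValueError("n_samples must be >= 8 (3-level decomposition minimum)")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1:02d}" for i in range(n_channels)]
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if len(set(self.channel_names)) != n_channels:
            raise ValueError("channel_names must be unique")

    # -- convenience -----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def with_data(self, data: np.ndarray, note: str) -> "EpochSet":
        """New EpochSet with replaced tensor and one appended provenance entry."""
        return replace(
            self,
            data=np.asarray(data, dtype=float),
            labels=self.labels.copy(),
            channel_names=list(self.channel_names),
            provenance=[*self.provenance, note],
        )

    def select_channels(self, idx: list[int] | np.ndarray, note: str | None = None) -> "EpochSet":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            data=self.data[:, idx, :],
            labels=self.labels.copy(),
            channel_names=[self.channel_names[i] for i in idx],
            provenance=[*self.provenance, note or f"select_channels({idx.tolist()})"],
        )


@dataclass
class PipelineConfig:
    """Defaults for every tunable stage of the pipeline.

    The defaults encode the published operating point: 30% network sparsity,
    mutcorLasso learning rates alpha=0.5 / beta=0.1, 120->20->10 style
    selection (20 kept by the lasso stage, 10 by relief-f with k=6 neighbors
    and 60 rounds at a 30-40% sampling rate), and a 10-tree random forest.
    """

    band_low: float = 0.5
    band_high: float = 20.0
    wavelet_name: str = "db10"
    denoise_level: int = 3
    decomposition_levels: int = 3
    sparsity: float = 0.30
    alpha: float = 0.5
    beta: float = 0.1
    n_keep_lasso: int = 20
    n_keep_relief: int = 10
    relief_k: int = 6
    relief_iters: int = 60
    relief_sample_rate: float = 0.35
    mi_bins: int = 10
    csp_filters_per_pair: int = 2
    n_channels_keep: int = 8
    rf_trees: int = 10
    knn_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sparsity < 1:
            raise ValueError("sparsity must lie in (0, 1)")
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.n_keep_relief > self.n_keep_lasso:
            raise ValueError("n_keep_relief must not exceed n_keep_lasso")
        if not 0.30 <= self.relief_sample_rate <= 0.40:
            raise ValueError("relief_sample_rate must lie in [0.30, 0.40]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# -- container I/O -------------------------------------------------------

def write_epochs(path: str | Path, epochs: EpochSet) -> None:
    """Persist an EpochSet as a compressed array archive (.npz)."""
    np.savez_compressed(
        path,
        data=epochs.data,
        labels=epochs.labels,
        fs=np.asarray(epochs.fs, dtype=float),
        channel_names=np.asarray(epochs.channel_names),
        provenance=np.asarray(epochs.provenance),
    )


def read_epochs(path: str | Path, format: str = "npz", labels: np.ndarray | None = None) -> EpochSet:
    """Read an EpochSet from the native .npz container or an EDF file.

    EDF recordings carry no trial labels; for ``format="edf"`` each data
    record becomes one trial and ``labels`` must be supplied by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        from .edf import read_edf

        data, fs, names = read_edf(path)
        if labels is None:
            raise ValueError("unlabeled data: EDF carries no trial labels, pass labels=")
        return EpochSet(
            data, np.asarray(labels), fs, channel_names=names,
            provenance=[f"read_epochs(edf:{path})"],
        )
    if format != "npz":
        raise ValueError(f"unknown format {format!r}")
    with np.load(path, allow_pickle=False) as arc:
        if "labels" not in arc:
            raise ValueError("unlabeled data: container has no 'labels' key")
        if "fs" not in arc:
            raise ValueError("container missing 'fs'")
        names = [str(s) for s in arc["channel_names"]] if "channel_names" in arc else []
        prov = [str(s) for s in arc["provenance"]] if "provenance" in arc else []
        return EpochSet(
            arc["data"], arc["labels"], float(arc["fs"]),
            channel_names=names,
            provenance=[*prov, f"read_epochs({path})"],
        )


# -- bad-channel repair ---------------------------------------------------

def repair_bad_channels(epochs: EpochSet, z_thresh: float = 3.0) -> EpochSet:
    """Replace outlier channels by the mean of the clean channels.

    A channel is flagged when the z-score of its trial-pooled log-variance
    exceeds ``z_thresh`` in absolute value. Flagged channels are replaced,
    per trial, by the mean over the unflagged channels; the channel count is
    unchanged. Works without electrode geometry.
    """
    if epochs.n_channels < 2:
        raise ValueError("repair_bad_channels needs at least 2 channels")
    log_var = np.log(np.var(epochs.data, axis=2).mean(axis=0) + np.finfo(float).tiny)
    sd = log_var.std()
    z = (log_var - log_var.mean()) / sd if sd > 0 else np.zeros_like(log_var)
    bad = np.abs(z) > z_thresh
    if not bad.any():
        return epochs.with_data(epochs.data, f"repair_bad_channels(z>{z_thresh}): none flagged")
    if bad.all():
        raise ValueError("no clean reference channels: every channel flagged")
    data = epochs.data.copy()
    reference = data[:, ~bad, :].mean(axis=1)
    data[:, bad, :] = reference[:, None, :]
    names = [n for n, b in zip(epochs.channel_names, bad) if b]
    return epochs.with_data(data, f"repair_bad_channels(z>{z_thresh}): repaired {names}")
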