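"""Core in-memory containers shared across the pipeline.

A single LDI-MS acquisition is a :class:`RawSpectrum`; the preprocessing
chain turns collections of them into a :class:`FeatureMatrix` — the serum
metabolic fingerprint (SMF) table of samples x aligned m/z signals that
every downstream stage (classification, panel selection, stratification,
power analysis) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["RawSpectrum", "BinnedSpectrum", "PeakList", "FeatureMatrix"]


@dataclass
class RawSpectrum:
    """One acquisition: an ascending m/z grid with nonnegative intensities.

    Parameters
    ----------
    mz
        Strictly increasing m/z values in Da.
    intensity
        Nonnegative intensities (arbitrary units), same length as ``mz``.
    sample_id
        Identifier of the biological sample the acquisition belongs to.
    replicate
        1-based technical replicate index.
    batch
        Acquisition batch label.
    is_qc
        Whether this is a quality-control (standard serum) acquisition.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate: int = 1
    batch: str = ""
    is_qc: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class BinnedSpectrum:
    """A spectrum down-sampled onto a fixed half-open bin grid.

    Bin ``k`` covers ``[grid_start + k*bin_width, grid_start + (k+1)*bin_width)``.
    """

    grid_start: float
    grid_end: float
    bin_width: float
    intensity: np.ndarray
    sample_id: str = ""
    replicate: int = 1
    batch: str = ""
    is_qc: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = int(round((self.grid_end - self.grid_start) / self.bin_width))
        if len(self.intensity) != n:
            raise ValueError(
                f"expected {n} bins for range ({self.grid_start}, {self.grid_end}) "
                f"at width {self.bin_width}, got {len(self.intensity)}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.intensity)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.grid_start + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class PeakList:
    """Detected peaks of one spectrum: apex m/z, intensity and S/N."""

    peak_mz: np.ndarray
    peak_intensity: np.ndarray
    snr: np.ndarray
    sample_id: str = ""
    replicate: int = 1
    batch: str = ""
    is_qc: bool = False

    def __post_init__(self) -> None:
        self.peak_mz = np.asarray(self.peak_mz, dtype=float)
        self.peak_intensity = np.asarray(self.peak_intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if len(self.peak_mz) > 1 and not np.all(np.diff(self.peak_mz) > 0):
            raise ValueError("peak_mz must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_mz)


@dataclass
class FeatureMatrix:
    """Samples x aligned-signals intensity table (the SMF matrix).

    ``values[i, j]`` is the intensity of signal ``j`` (reference m/z
    ``signal_mz[j]``) in sample ``i``.  Absent peaks are encoded as 0, never
    as missing, so fold-change and t-test arithmetic stays total.
    """

    values: np.ndarray
    signal_mz: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None
    batch: np.ndarray | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.signal_mz = np.asarray(self.signal_mz, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x signals)")
        if self.values.shape[1] != len(self.signal_mz):
            raise ValueError("one signal_mz per column required")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("one sample_id per row required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("one label per row required")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_signals(self) -> int:
        return self.values.shape[1]

    def restrict(self, columns: np.ndarray) -> "FeatureMatrix":
        """Return a copy restricted to the given signal columns."""
        columns = np.asarray(columns)
        return FeatureMatrix(
            values=self.values[:, columns],
            signal_mz=self.signal_mz[columns],
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
            batch=None if self.batch is None else self.batch.copy(),
            provenance=dict(self.provenance),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{mz:.4f}" for mz in self.signal_mz],
        )
        if self.labels is not None:
            df.insert(0, "group", self.labels)
        if self.batch is not None:
            df.insert(1 if self.labels is not None else 0, "batch", self.batch)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = df.pop("group").to_numpy() if "group" in df.columns else None
        batch = df.pop("batch").to_numpy() if "batch" in df.columns else None
        return cls(
            values=df.to_numpy(dtype=float),
            signal_mz=np.array([float(c) for c in df.columns]),
            sample_ids=[str(s) for s in df.index],
            labels=labels,
            batch=batch,
        )
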