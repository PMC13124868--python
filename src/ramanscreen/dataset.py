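"""Spectral data containers and plain-text readers/writers.

A Raman monitoring campaign is represented by three aligned objects: a
:class:`SpectralDataset` (one spectrum per sample on a shared wavenumber
axis), a reference table of offline measurements (one row per sample), and
run metadata carried on the dataset itself (run id and sampling time per
sample).  Samples are joined to reference rows by explicit ``sample_id``
strings, never by row order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AxisError",
    "FormatError",
    "WindowError",
    "WavenumberAxis",
    "SpectralDataset",
    "AveragingWindow",
    "REFERENCE_COLUMNS",
    "PARAMETERS",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "average_presample_spectra",
]


class AxisError(ValueError):
    """Raised when a wavenumber axis is non-monotone or non-uniform."""


class FormatError(ValueError):
    """Raised on malformed spectral input files."""


class WindowError(ValueError):
    """Raised when a pre-sampling averaging window cannot be filled."""


#: The seven modelled bioprocess parameters, in reference-file column order.
PARAMETERS = ["Xv", "CV", "Gluc", "Lac", "Gln", "Glu", "NH4"]

#: Units carried in the reference CSV headers.
REFERENCE_COLUMNS = {
    "Xv": "Xv_1e5_cells_per_mL",
    "CV": "CV_pct",
    "Gluc": "Gluc_g_L",
    "Lac": "Lac_g_L",
    "Gln": "Gln_g_L",
    "Glu": "Glu_g_L",
    "NH4": "NH4_g_L",
}


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing, uniformly spaced Raman-shift axis (cm^-1)."""

    values: np.ndarray
    spacing_rtol: float = 1e-6

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise AxisError("axis needs at least two wavenumbers")
        d = np.diff(v)
        if np.any(d <= 0):
            raise AxisError("wavenumber axis must be strictly increasing")
        step = d.mean()
        if np.any(np.abs(d - step) > self.spacing_rtol * max(abs(step), 1.0)):
            raise AxisError("wavenumber axis must be uniformly spaced")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls) -> "WavenumberAxis":
        """Full-range axis 100-3425 cm^-1 at 1 cm^-1 (3326 channels)."""
        return cls(np.arange(100.0, 3426.0, 1.0))

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other) -> bool:  # axes compare by value
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:
        return hash((self.values.tobytes(), len(self.values)))


@dataclass
class SpectralDataset:
    """Intensity matrix ``[n_samples, n_wavenumbers]`` with sample metadata."""

    axis: WavenumberAxis
    intensities: np.ndarray
    sample_ids: list[str]
    run_ids: list[str] | None = None
    sample_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.intensities, dtype=float)
        if X.ndim != 2:
            raise FormatError("intensities must be a 2-D matrix")
        if X.shape[1] != len(self.axis):
            raise FormatError(
                f"{X.shape[1]} intensity columns but axis has {len(self.axis)}"
            )
        if X.shape[0] != len(self.sample_ids):
            raise FormatError("row count does not match sample_ids length")
        if np.isnan(X).any():
            raise FormatError("missing intensities are not allowed")
        if self.run_ids is not None and len(self.run_ids) != X.shape[0]:
            raise FormatError("run_ids length mismatch")
        if self.sample_times is not None:
            t = np.asarray(self.sample_times, dtype=float)
            if t.size != X.shape[0]:
                raise FormatError("sample_times length mismatch")
            self.sample_times = t
        self.intensities = X
        self.sample_ids = [str(s) for s in self.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def with_intensities(self, X: np.ndarray) -> "SpectralDataset":
        """Copy of the dataset with a replaced (same-shape) intensity matrix."""
        return dataclasses.replace(self, intensities=np.asarray(X, dtype=float))

    def subset(self, index: np.ndarray) -> "SpectralDataset":
        index = np.asarray(index)
        return SpectralDataset(
            axis=self.axis,
            intensities=self.intensities[index],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(index)],
            run_ids=None
            if self.run_ids is None
            else [self.run_ids[i] for i in np.atleast_1d(index)],
            sample_times=None
            if self.sample_times is None
            else self.sample_times[index],
        )


@dataclass(frozen=True)
class AveragingWindow:
    """Number of consecutive raw spectra averaged per calibration point."""

    n_spectra: int = 6

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")


def _validate_axis_column(wn: np.ndarray) -> WavenumberAxis:
    if np.unique(wn).size != wn.size:
        raise AxisError("duplicated wavenumber in axis column")
    return WavenumberAxis(wn)


def read_spectra(path, dialect: str = "wide") -> SpectralDataset:
    """Read a spectral matrix from CSV.

    ``wide``: first column ``wavenumber_cm-1``, one column per sample id.
    ``tidy``: long format with columns ``sample_id, wavenumber_cm-1,
    intensity``.  Files with a descending axis are flipped to ascending.
    """
    df = pd.read_csv(path)
    if dialect == "wide":
        if df.shape[1] < 2:
            raise FormatError("wide CSV needs a wavenumber column and >=1 sample")
        wn = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
        X = df.iloc[:, 1:].to_numpy(dtype=float).T
        sample_ids = [str(c) for c in df.columns[1:]]
        if wn.size >= 2 and wn[0] > wn[-1]:
            wn = wn[::-1]
            X = X[:, ::-1]
        axis = _validate_axis_column(wn)
        if np.isnan(X).any():
            raise FormatError("ragged or missing intensity values")
        return SpectralDataset(axis=axis, intensities=X, sample_ids=sample_ids)
    if dialect == "tidy":
        required = {"sample_id", "wavenumber_cm-1", "intensity"}
        if not required.issubset(df.columns):
            raise FormatError(f"tidy CSV must have columns {sorted(required)}")
        wide = df.pivot(index="sample_id", columns="wavenumber_cm-1", values="intensity")
        if wide.isna().any().any():
            raise FormatError("tidy CSV does not cover a full sample x axis grid")
        wn = wide.columns.to_numpy(dtype=float)
        order = np.argsort(wn)
        axis = _validate_axis_column(wn[order])
        return SpectralDataset(
            axis=axis,
            intensities=wide.to_numpy(dtype=float)[:, order],
            sample_ids=[str(s) for s in wide.index],
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectra(dataset: SpectralDataset, path, dialect: str = "wide") -> None:
    """Write a dataset back to CSV (inverse of :func:`read_spectra`)."""
    if dialect == "wide":
        df = pd.DataFrame(
            dataset.intensities.T,
            columns=dataset.sample_ids,
        )
        df.insert(0, "wavenumber_cm-1", dataset.axis.values)
        df.to_csv(path, index=False)
    elif dialect == "tidy":
        long = pd.DataFrame(
            {
                "sample_id": np.repeat(dataset.sample_ids, len(dataset.axis)),
                "wavenumber_cm-1": np.tile(dataset.axis.values, dataset.n_samples),
                "intensity": dataset.intensities.ravel(),
            }
        )
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_reference(path) -> pd.DataFrame:
    """Read the per-sample offline reference table.

    Columns: ``sample_id, run_id, time_h`` plus the seven parameter columns
    of :data:`REFERENCE_COLUMNS`.  Returned indexed by ``sample_id`` with the
    short parameter names.
    """
    df = pd.read_csv(path)
    missing = {"sample_id", "run_id", "time_h", *REFERENCE_COLUMNS.values()} - set(
        df.columns
    )
    if missing:
        raise FormatError(f"reference CSV missing columns: {sorted(missing)}")
    df = df.rename(columns={v: k for k, v in REFERENCE_COLUMNS.items()})
    df["sample_id"] = df["sample_id"].astype(str)
    cv = df["CV"].dropna()
    if ((cv < 0) | (cv > 100)).any():
        raise FormatError("CV must lie in [0, 100] %")
    conc = df[["Gluc", "Lac", "Gln", "Glu", "NH4", "Xv"]]
    if (conc.dropna() < 0).any().any():
        raise FormatError("concentrations must be non-negative")
    return df.set_index("sample_id")


def write_reference(ref: pd.DataFrame, path) -> None:
    df = ref.reset_index().rename(columns=REFERENCE_COLUMNS)
    df.to_csv(path, index=False)


def average_presample_spectra(
    raw: SpectralDataset,
    sampling_times: np.ndarray,
    window: AveragingWindow = AveragingWindow(),
) -> SpectralDataset:
    """Average the ``window.n_spectra`` latest spectra at or before each
    sampling time into one calibration spectrum.

    Emulates inline acquisition where spectra stream continuously and each
    offline sample is paired with the mean of the spectra collected
    immediately before it was drawn.
    """
    if raw.sample_times is None:
        raise WindowError("raw dataset must carry sample_times")
    t = raw.sample_times
    if np.any(np.diff(t) < 0):
        raise WindowError("raw spectra must be ordered by time")
    out_rows = []
    out_times = []
    for st in np.asarray(sampling_times, dtype=float):
        eligible = np.flatnonzero(t <= st)
        if eligible.size < window.n_spectra:
            raise WindowError(
                f"only {eligible.size} spectra precede t={st} h "
                f"(need {window.n_spectra})"
            )
        sel = eligible[-window.n_spectra :]
        out_rows.append(raw.intensities[sel].mean(axis=0))
        out_times.append(st)
    return SpectralDataset(
        axis=raw.axis,
        intensities=np.asarray(out_rows),
        sample_ids=[f"avg_{i}" for i in range(len(out_rows))],
        run_ids=None if raw.run_ids is None else [raw.run_ids[0]] * len(out_rows),
        sample_times=np.asarray(out_times),
    )
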