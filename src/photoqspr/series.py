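"""Spectral time-series container and CSV I/O.

A photodegradation experiment for one compound is a matrix of UV
absorbance values collected on a fixed wavelength grid at successive
irradiation times.  The matrix is stored time x wavelength, matching the
bilinear model D = C @ S.T in which rows of C are time points and rows of
S are wavelengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectralSeries", "read_series_csv"]


@dataclass
class SpectralSeries:
    """Absorbance of one compound over wavelength and irradiation time.

    Parameters
    ----------
    wavelengths : ndarray, shape (n_wavelengths,)
        Strictly increasing wavelength grid in nm.
    times : ndarray, shape (n_times,)
        Strictly increasing irradiation times in seconds, starting at 0.
    absorbance : ndarray, shape (n_times, n_wavelengths)
        Absorbance in AU; no missing values allowed.
    compound_id : str
        Label used in filenames and reports.
    truth : dict or None
        Ground-truth generating parameters for synthetic series
        (concentration profiles, pure spectra, rate constants); None for
        measured data.
    """

    wavelengths: np.ndarray
    times: np.ndarray
    absorbance: np.ndarray
    compound_id: str = "synthetic"
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.times.ndim != 1:
            raise ValueError("wavelengths and times must be 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.absorbance.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"(n_times={self.times.size}, n_wavelengths={self.wavelengths.size})"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorbance.shape

    def crop_wavelengths(self, lo: float = 215.0, hi: float = 450.0) -> "SpectralSeries":
        """Return a copy restricted to wavelengths in [lo, hi] nm.

        The short-wavelength end of a UV spectrum is dominated by solvent
        cut-off and instrumental noise, so analysis is restricted to the
        215-450 nm window by default.
        """
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise ValueError("no wavelengths left after cropping")
        return SpectralSeries(
            self.wavelengths[mask],
            self.times,
            self.absorbance[:, mask],
            self.compound_id,
            self.truth,
        )

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write wavelength x time CSV; truth (if any) goes to a JSON sidecar."""
        path = Path(path)
        cols = {"wavelength_nm": self.wavelengths}
        for j, t in enumerate(self.times):
            cols[f"t{int(round(t))}"] = self.absorbance[j]
        pd.DataFrame(cols).to_csv(path, index=False)
        if sidecar and self.truth is not None:
            meta = {k: v for k, v in self.truth.items() if np.isscalar(v) or isinstance(v, (str, list))}
            meta["compound_id"] = self.compound_id
            path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_series_csv(path: str | Path, compound_id: str | None = None,
                    crop: bool = True) -> SpectralSeries:
    """Read a SpectralSeries CSV (first column wavelength_nm, columns t<sec>).

    Wavelengths below 215 nm are dropped unless ``crop=False``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError("first column must be 'wavelength_nm'")
    times = np.array([float(c[1:]) for c in df.columns[1:]])
    series = SpectralSeries(
        df["wavelength_nm"].to_numpy(),
        times,
        df.iloc[:, 1:].to_numpy().T,
        compound_id or path.stem,
    )
    return series.crop_wavelengths() if crop else series
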