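"""Synthetic photodegradation spectra and QSPR datasets.

Emulates the data this pipeline consumes: bilinear UV spectral time
series D = C @ S.T in which the parent 1,4-dihydropyridine absorbs
around 350-370 nm and decays by first-order photolysis while its
aromatized pyridine photoproduct grows in around 260-280 nm, plus
descriptor/response tables with a known sparse linear structure for
exercising variable selection.

All randomness is seeded explicitly; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import SpectralSeries

__all__ = [
    "BandSpec",
    "KineticScheme",
    "NoiseModel",
    "DEFAULT_WAVELENGTHS",
    "DEFAULT_TIMES_MIN",
    "default_times_s",
    "gaussian_spectrum",
    "kinetic_profiles",
    "simulate_series",
    "simulate_qspr",
    "SimulatedQSPR",
]

# Analysis window: 215-450 nm at 1 nm; shorter wavelengths are discarded
# as instrumental noise before any resolution step.
DEFAULT_WAVELENGTHS = np.arange(215.0, 451.0, 1.0)

# Irradiation schedule: spectrum at preparation (t=0) then after
# 1..300 min of light exposure.  Stored in minutes, converted to seconds
# at the interface (rates are per second).
DEFAULT_TIMES_MIN = np.array(
    [0, 1, 2, 3, 4, 5, 10, 15, 20, 25, 30, 40, 50, 60,
     80, 100, 120, 150, 180, 210, 240, 270, 300], dtype=float
)


def default_times_s() -> np.ndarray:
    """The standard exposure grid in seconds (t=0 plus 22 exposure times)."""
    return DEFAULT_TIMES_MIN * 60.0


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (nm), width (SD, nm), amplitude (AU)."""

    center: float
    width: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude <= 0:
            raise ValueError("band amplitude must be > 0")


# Default band sets: parent dihydropyridine band in the 350-370 nm zone,
# aromatized photoproduct in the 260-280 nm zone, and a trace secondary
# product at <=10% of the parent amplitude.  Single well-separated
# Gaussians: each species has spectral regions where the others are
# negligible, which together with non-negativity makes the bilinear
# factorization essentially unique (no rotational ambiguity to speak
# of), mirroring the well-resolved parent/pyridine band structure of
# the compounds this emulates.
PARENT_BANDS = (BandSpec(360.0, 20.0, 1.0),)
PHP1_BANDS = (BandSpec(270.0, 20.0, 0.9),)
PHP2_BANDS = (BandSpec(300.0, 22.0, 0.1),)


@dataclass(frozen=True)
class KineticScheme:
    """First-order photodegradation scheme.

    ``single``:     A -> P1 with rate k1.
    ``sequential``: A -> P1 -> P2 with rates k1, k2 (k2 != k1; the
    equal-rate case makes the analytic two-step solution singular and is
    rejected).
    """

    scheme: str = "single"
    k1: float = 1e-3
    k2: float | None = None
    c0: float = 1.0

    def __post_init__(self) -> None:
        if self.scheme not in ("single", "sequential"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.k1 <= 0:
            raise ValueError("k1 must be > 0")
        if self.scheme == "sequential":
            if self.k2 is None or self.k2 <= 0:
                raise ValueError("sequential scheme requires k2 > 0")
            if self.k2 == self.k1:
                raise ValueError("k2 == k1 makes the two-step solution singular")

    @property
    def n_species(self) -> int:
        return 2 if self.scheme == "single" else 3


@dataclass(frozen=True)
class NoiseModel:
    """Homoscedastic Gaussian noise with SD = relative_sd * max|signal|."""

    relative_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")


def gaussian_spectrum(bands, wavelengths) -> np.ndarray:
    """Sum-of-Gaussians pure-component spectrum on a wavelength grid.

    s(lambda) = sum_b amplitude_b * exp(-(lambda - center_b)^2 / (2 width_b^2))
    """
    bands = list(bands)
    if not bands:
        raise ValueError("need at least one band")
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.ndim != 1 or np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelengths must be a strictly increasing 1-D grid")
    s = np.zeros_like(wavelengths)
    for b in bands:
        s += b.amplitude * np.exp(-((wavelengths - b.center) ** 2) / (2.0 * b.width**2))
    return s


def kinetic_profiles(scheme: KineticScheme, times) -> np.ndarray:
    """Closed-form concentration profiles, one column per species.

    single:      A(t) = c0 e^{-k1 t},  P1 = c0 - A.
    sequential:  A as above,
                 P1(t) = c0 k1/(k2-k1) (e^{-k1 t} - e^{-k2 t}),
                 P2 = c0 - A - P1     (two-step consecutive first-order
                 solution).  Rows sum to c0 exactly by construction.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times[0] != 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be increasing, non-negative, starting at 0")
    a = scheme.c0 * np.exp(-scheme.k1 * times)
    if scheme.scheme == "single":
        return np.column_stack([a, scheme.c0 - a])
    k1, k2 = scheme.k1, scheme.k2
    p1 = scheme.c0 * k1 / (k2 - k1) * (np.exp(-k1 * times) - np.exp(-k2 * times))
    return np.column_stack([a, p1, scheme.c0 - a - p1])


def simulate_series(
    spectra: np.ndarray,
    scheme: KineticScheme,
    times=None,
    noise: NoiseModel = NoiseModel(),
    wavelengths=None,
    compound_id: str = "synthetic",
    times_in_minutes: bool = False,
) -> SpectralSeries:
    """Bilinear spectral time series D = C @ S.T + E.

    Parameters
    ----------
    spectra : ndarray, shape (n_wavelengths, n_species)
        Pure-component spectra S (column order = species order of the
        scheme: parent, PhP1[, PhP2]).
    scheme : KineticScheme
    times : array-like or None
        Acquisition times; the standard 23-point grid when None.
    noise : NoiseModel
        Gaussian noise with SD = relative_sd * max|C @ S.T|.
    wavelengths : array-like or None
        Grid matching ``spectra`` rows; defaults to 215-450 nm step 1.
    times_in_minutes : bool
        Interpret ``times`` as minutes and convert.

    The returned series carries the generating truth (C, S, rates) in
    ``series.truth`` for recovery tests.
    """
    wavelengths = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    times = default_times_s() if times is None else np.asarray(times, dtype=float)
    if times_in_minutes:
        times = times * 60.0
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape != (wavelengths.size, scheme.n_species):
        raise ValueError(
            f"spectra must have shape (n_wavelengths={wavelengths.size}, "
            f"n_species={scheme.n_species}); got {spectra.shape}"
        )
    c = kinetic_profiles(scheme, times)
    clean = c @ spectra.T
    d = clean
    if noise.relative_sd > 0:
        rng = np.random.default_rng(noise.seed)
        sd = noise.relative_sd * np.max(np.abs(clean))
        d = clean + rng.normal(0.0, sd, size=clean.shape)
    truth = {
        "C": c, "S": spectra, "scheme": scheme.scheme,
        "k1": scheme.k1, "k2": scheme.k2, "c0": scheme.c0,
        "relative_sd": noise.relative_sd, "seed": noise.seed,
    }
    return SpectralSeries(wavelengths, times, d, compound_id, truth)


def default_component_spectra(wavelengths=None, n_species: int = 2) -> np.ndarray:
    """Pure spectra for the standard parent / PhP1 [/ trace PhP2] bands."""
    wavelengths = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    bandsets = [PARENT_BANDS, PHP1_BANDS, PHP2_BANDS][:n_species]
    return np.column_stack([gaussian_spectrum(b, wavelengths) for b in bandsets])


@dataclass
class SimulatedQSPR:
    """Descriptor table, response vector and the generating model."""

    X: pd.DataFrame
    y: pd.Series
    intercept: float
    coefficients: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def informative_indices(self) -> list[int]:
        return sorted(self.coefficients)


def simulate_qspr(
    n_samples: int,
    n_descriptors: int,
    informative: dict[int, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 0.0,
    descriptor_ranges: dict[str, tuple[float, float]] | None = None,
) -> SimulatedQSPR:
    """Descriptor matrix with a known sparse linear response.

    Columns are drawn standard-normal, or uniformly within named ranges
    when ``descriptor_ranges`` supplies (lo, hi) per descriptor (e.g.
    ranges observed in a real descriptor table).  The response is
    y = intercept + sum_j coef_j * x_j + N(0, noise_sd).
    """
    if n_samples < 3:
        raise ValueError("need n_samples >= 3")
    if informative and max(informative) >= n_descriptors:
        raise ValueError("informative index out of range")
    if n_samples < len(informative) + 2:
        raise ValueError("need n_samples >= number of informative variables + 2")
    rng = np.random.default_rng(seed)
    if descriptor_ranges:
        names = list(descriptor_ranges)
        if len(names) != n_descriptors:
            raise ValueError("descriptor_ranges length must equal n_descriptors")
        cols = [rng.uniform(lo, hi, n_samples) for lo, hi in descriptor_ranges.values()]
        x = np.column_stack(cols)
    else:
        names = [f"x{j}" for j in range(n_descriptors)]
        x = rng.standard_normal((n_samples, n_descriptors))
    y = np.full(n_samples, float(intercept))
    for j, coef in informative.items():
        y += coef * x[:, j]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_samples)
    ids = [f"s{i}" for i in range(n_samples)]
    return SimulatedQSPR(
        X=pd.DataFrame(x, columns=names, index=ids),
        y=pd.Series(y, index=ids, name="k"),
        intercept=float(intercept),
        coefficients=dict(informative),
        noise_sd=noise_sd,
        seed=seed,
    )
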