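"""Constrained Multivariate Curve Resolution - Alternating Least Squares.

Resolves a spectral time-series matrix D (time x wavelength) into
concentration profiles C and pure spectra S under the bilinear model
D ~= C @ S.T, alternating constrained least-squares updates of C and S.
Chemical constraints keep the factors physically meaningful:

* non-negativity of concentrations and of spectra (clip to zero);
* unimodality of each concentration profile (a species appears and
  disappears once; monotone flattening away from the column maximum);
* closure (mass balance of a unimolecular scheme: each row of C is
  rescaled to the total concentration at t=0).

Fit quality is reported as lack of fit and explained variance,

    lof% = 100 * sqrt(SS_res / SS_tot),   R2% = 100 * (1 - SS_res/SS_tot),

which satisfy R2 = 100 - lof^2/100 identically.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .series import SpectralSeries

__all__ = ["MCRALS", "MCRResult", "estimate_rank", "init_purest", "run_mcr_als", "fit_metrics"]


def fit_metrics(d: np.ndarray, c: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Lack of fit (%) and explained variance R2 (%) of D ~= C @ S.T."""
    d = np.asarray(d, float)
    ss_tot = float(np.sum(d * d))
    if ss_tot == 0:
        raise ValueError("data matrix is all zero")
    resid = d - np.asarray(c, float) @ np.asarray(s, float).T
    ratio = float(np.sum(resid * resid)) / ss_tot
    return 100.0 * np.sqrt(ratio), 100.0 * (1.0 - ratio)


def estimate_rank(series: SpectralSeries | np.ndarray, sv_ratio_threshold: float = 25.0) -> int:
    """Chemical rank: number of singular values carrying chemical signal.

    Counts leading singular values that are both within a factor
    ``sv_ratio_threshold`` of the largest and above a noise floor taken
    as 3x the median of the trailing half of the singular-value
    spectrum.  The trailing values sample the noise plateau, so the
    floor adapts to the actual noise level of the series.
    """
    d = series.absorbance if isinstance(series, SpectralSeries) else np.asarray(series, float)
    if d.size == 0 or not np.any(d):
        raise ValueError("cannot estimate rank of an empty or all-zero matrix")
    sv = np.linalg.svd(d, compute_uv=False)
    floor = 3.0 * np.median(sv[sv.size // 2:])
    keep = (sv >= sv[0] / sv_ratio_threshold) & (sv > floor)
    return max(int(np.count_nonzero(keep)), 1)


def init_purest(series: SpectralSeries | np.ndarray, n_components: int,
                offset_frac: float = 0.01) -> np.ndarray:
    """Purest-variable (SIMPLISMA-style) initial spectral estimates.

    Ranks wavelengths by purity = sd / (mean + offset) of their time
    profile, deflating each candidate's purity by its squared-sine angle
    to the span of already-chosen profiles so that successive picks are
    as mutually independent as possible.  The chosen profile columns are
    mapped to spectra by one least-squares step, clipped non-negative
    and scaled to unit maximum.

    Returns
    -------
    ndarray, shape (n_wavelengths, n_components)
    """
    d = series.absorbance if isinstance(series, SpectralSeries) else np.asarray(series, float)
    n_t, n_w = d.shape
    if n_components > min(n_t, n_w):
        raise ValueError("n_components exceeds matrix dimensions")
    if n_components > np.linalg.matrix_rank(d):
        raise ValueError("n_components exceeds the rank of the data matrix")
    mean = d.mean(axis=0)
    sd = d.std(axis=0)
    offset = offset_frac * mean.max()
    base_purity = sd / (mean + offset)

    chosen: list[int] = []
    q = np.zeros((n_t, 0))  # orthonormal basis of chosen profiles
    for _ in range(n_components):
        weights = np.ones(n_w)
        if chosen:
            norms = np.linalg.norm(d, axis=0)
            norms[norms == 0] = 1.0
            proj = q.T @ d
            weights = np.clip(1.0 - (proj**2).sum(axis=0) / norms**2, 0.0, 1.0)
        purity = base_purity * weights
        purity[chosen] = -np.inf
        j = int(np.argmax(purity))
        chosen.append(j)
        v = d[:, j].copy()
        if q.shape[1]:
            v -= q @ (q.T @ v)
        nv = np.linalg.norm(v)
        if nv > 0:
            q = np.column_stack([q, v / nv])

    c0 = d[:, chosen]  # profiles at the purest wavelengths
    s0, *_ = np.linalg.lstsq(c0, d, rcond=None)
    s0 = np.clip(s0.T, 0.0, None)  # (n_w, k)
    peaks = s0.max(axis=0)
    peaks[peaks == 0] = 1.0
    s0 /= peaks
    return _WithIndices(s0, chosen)


class _WithIndices(np.ndarray):
    """ndarray carrying the selected purest-wavelength indices."""

    def __new__(cls, arr, indices):
        obj = np.asarray(arr).view(cls)
        obj.purest_indices = list(indices)
        return obj

    def __array_finalize__(self, obj):
        if obj is not None:
            self.purest_indices = getattr(obj, "purest_indices", None)


def _unimodalize(col: np.ndarray) -> np.ndarray:
    """Enforce a single maximum by monotone flattening away from the peak.

    Walking outward from the column maximum, any value above the running
    minimum is replaced by it, so the profile is non-increasing on both
    sides of the peak.
    """
    out = col.copy()
    p = int(np.argmax(out))
    run = out[p]
    for i in range(p + 1, out.size):
        run = min(run, out[i])
        out[i] = min(out[i], run)
    run = out[p]
    for i in range(p - 1, -1, -1):
        run = min(run, out[i])
        out[i] = min(out[i], run)
    return out


class MCRResult:
    """Container mirroring the fitted attributes of :class:`MCRALS`."""

    def __init__(self, C, S, lof_percent, r2_percent, n_iter, converged):
        self.C = C
        self.S = S
        self.lof_percent = lof_percent
        self.r2_percent = r2_percent
        self.n_iter = n_iter
        self.converged = converged


class MCRALS(TransformerMixin, BaseEstimator):
    """Constrained MCR-ALS decomposition D ~= C @ S.T.

    Parameters
    ----------
    n_components : int
        Number of chemical species (use :func:`estimate_rank`).
    nonneg_c, nonneg_s : bool
        Non-negativity of concentrations / spectra.
    unimodal_c : bool
        Single-maximum constraint on every concentration profile.  A
        monotone parent decay has its maximum at t=0, so applying the
        constraint uniformly leaves it untouched while forcing each
        photoproduct to rise and fall at most once.
    closure_c : bool
        Rescale each row of C to the total concentration at t=0.
    init : 'purest' or ndarray (n_wavelengths, n_components)
        Initial spectral estimates.
    tol : float
        Convergence threshold on the relative change of lof between
        iterations.
    max_iter : int
        Iteration cap; the best iterate seen is returned even without
        convergence.

    Attributes
    ----------
    C_ : ndarray (n_times, n_components)
        Concentration profiles, parent first (components ordered by the
        time of their concentration maximum).
    S_ : ndarray (n_wavelengths, n_components)
        Pure spectra.
    lof_percent_, r2_percent_ : float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, n_components: int = 2, *, nonneg_c: bool = True,
                 nonneg_s: bool = True, unimodal_c: bool = False,
                 closure_c: bool = True, init="purest",
                 tol: float = 1e-3, max_iter: int = 500):
        self.n_components = n_components
        self.nonneg_c = nonneg_c
        self.nonneg_s = nonneg_s
        self.unimodal_c = unimodal_c
        self.closure_c = closure_c
        self.init = init
        self.tol = tol
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------

    def _solve_c(self, d: np.ndarray, s: np.ndarray) -> np.ndarray:
        c, _, rank, _ = np.linalg.lstsq(s, d.T, rcond=None)
        if rank < self.n_components:
            raise np.linalg.LinAlgError(
                "singular normal equations: the current spectral estimates are "
                "collinear; reduce n_components or provide independent initial spectra"
            )
        return c.T

    def _constrain_c(self, c: np.ndarray) -> np.ndarray:
        if self.nonneg_c:
            c = np.clip(c, 0.0, None)
        if self.unimodal_c:
            c = np.column_stack([_unimodalize(c[:, j]) for j in range(c.shape[1])])
        if self.closure_c:
            total = c[0].sum()
            if total > 0:
                sums = c.sum(axis=1)
                scale = np.where(sums > 0, total / np.where(sums > 0, sums, 1.0), 1.0)
                c = c * scale[:, None]
        return c

    def fit(self, X, y=None):
        """Fit the decomposition.  X: SpectralSeries or (time x wavelength) array."""
        d = X.absorbance if isinstance(X, SpectralSeries) else np.asarray(X, float)
        if d.ndim != 2 or min(d.shape) < self.n_components:
            raise ValueError("data matrix too small for requested n_components")
        if not np.all(np.isfinite(d)):
            raise ValueError("data matrix contains non-finite values")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")

        if isinstance(self.init, str) and self.init == "purest":
            s = np.asarray(init_purest(d, self.n_components), float)
        else:
            s = np.asarray(self.init, float)
            if s.shape != (d.shape[1], self.n_components):
                raise ValueError("provided init spectra have the wrong shape")

        best = None
        prev_lof = None
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            c = self._constrain_c(self._solve_c(d, s))
            st, _, rank, _ = np.linalg.lstsq(c, d, rcond=None)
            if rank < self.n_components:
                raise np.linalg.LinAlgError(
                    "singular normal equations: concentration profiles became "
                    "collinear; relax constraints or reduce n_components"
                )
            s = st.T
            if self.nonneg_s:
                s = np.clip(s, 0.0, None)
            lof, r2 = fit_metrics(d, c, s)
            if best is None or lof < best[0]:
                best = (lof, r2, c.copy(), s.copy(), n_iter)
            # relative-change criterion, with an absolute floor: once the
            # lack of fit is at machine precision its relative jitter is
            # meaningless
            if lof < 1e-7 or (
                prev_lof is not None and prev_lof > 0
                and abs(prev_lof - lof) / prev_lof < self.tol
            ):
                converged = True
                break
            prev_lof = lof

        lof, r2, c, s, _ = best
        # Reporting convention: parent first (concentration maximum at t=0),
        # photoproducts ordered by time of maximum.
        order = np.argsort([int(np.argmax(c[:, j])) for j in range(c.shape[1])], kind="stable")
        c, s = c[:, order], s[:, order]
        if not self.closure_c:
            # scale is otherwise unconstrained: unit-maximum spectra
            peaks = s.max(axis=0)
            peaks[peaks == 0] = 1.0
            s = s / peaks
            c = c * peaks
        self.C_, self.S_ = c, s
        self.lof_percent_, self.r2_percent_ = lof, r2
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def transform(self, X):
        """Concentration profiles of X given the fitted spectra S_."""
        check_is_fitted(self, "S_")
        d = X.absorbance if isinstance(X, SpectralSeries) else np.asarray(X, float)
        c = np.linalg.lstsq(self.S_, d.T, rcond=None)[0].T
        return np.clip(c, 0.0, None) if self.nonneg_c else c

    @property
    def result_(self) -> MCRResult:
        check_is_fitted(self, "C_")
        return MCRResult(self.C_, self.S_, self.lof_percent_, self.r2_percent_,
                         self.n_iter_, self.converged_)


def run_mcr_als(series: SpectralSeries, n_components: int = 2, **kwargs) -> MCRResult:
    """Functional wrapper: fit :class:`MCRALS` on a series, return MCRResult."""
    est = MCRALS(n_components=n_components, **kwargs).fit(series)
    return est.result_
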