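"""Unsupervised exploration of the descriptor matrix.

PCA of the (optionally autoscaled) descriptor table gives sample scores,
descriptor loadings and per-component explained variance; the Pearson
correlation matrix summarizes pairwise descriptor redundancy.  No
plotting lives here — :func:`biplot_data` returns plain coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PCAResult", "pca", "pearson_matrix", "biplot_data"]


@dataclass
class PCAResult:
    """Scores (sample x component), loadings (descriptor x component),
    explained variance per component in percent (sums to 100), and the
    centering/scaling applied to the input."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_percent: np.ndarray
    singular_values: np.ndarray
    means: np.ndarray
    sds: np.ndarray | None
    sample_ids: list
    descriptor_names: list

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(x, center: bool = True, scale: bool = True) -> PCAResult:
    """Full-rank PCA of a sample x descriptor matrix.

    Explained variance is 100 * sigma_i^2 / sum(sigma^2) over all
    non-trivial components, so the vector sums to 100.  Sign convention:
    the largest-magnitude entry of each loading column is positive.
    """
    if isinstance(x, pd.DataFrame):
        ids, names, mat = list(x.index), [str(c) for c in x.columns], x.to_numpy(float)
    else:
        mat = np.asarray(x, dtype=float)
        ids = list(range(mat.shape[0]))
        names = [str(j) for j in range(mat.shape[1])]
    n, p = mat.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    means = mat.mean(axis=0)
    sds = None
    work = mat - means if center else mat.copy()
    if scale:
        sds = mat.std(axis=0, ddof=1)
        if np.any(sds == 0):
            raise ValueError("zero-variance column; drop constant columns before scaling")
        work = work / sds

    if center:
        # work is centered already, so sklearn's internal centering is a no-op
        model = PCA(n_components=min(n - 1, p), svd_solver="full")
        scores = model.fit_transform(work)
        loadings = model.components_.T
        sv = model.singular_values_
        ev = 100.0 * model.explained_variance_ratio_
    else:
        # uncentered PCA is a plain SVD of the (scaled) data
        u, s, vt = np.linalg.svd(work, full_matrices=False)
        scores, loadings, sv = u * s, vt.T, s
        ev = 100.0 * sv**2 / np.sum(sv**2)

    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return PCAResult(scores * flip, loadings * flip, ev, sv, means,
                     sds, ids, names)


def pearson_matrix(x) -> pd.DataFrame:
    """Pairwise Pearson correlation of descriptor columns (signed r;
    symmetric with unit diagonal)."""
    if isinstance(x, pd.DataFrame):
        names, mat = [str(c) for c in x.columns], x.to_numpy(float)
    else:
        mat = np.asarray(x, dtype=float)
        names = [str(j) for j in range(mat.shape[1])]
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    if np.any(mat.std(axis=0) == 0):
        raise ValueError("constant column has undefined correlation")
    r = np.corrcoef(mat.T)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names)


def biplot_data(result: PCAResult, pc_x: int = 1, pc_y: int = 2) -> pd.DataFrame:
    """Joint score/loading coordinates for a biplot of two components.

    Components are 1-based.  Loadings are scaled by their singular value
    so samples and descriptors share one coordinate system; the caller
    does the plotting.
    """
    for pc in (pc_x, pc_y):
        if not 1 <= pc <= result.n_components:
            raise ValueError(f"component {pc} out of range 1..{result.n_components}")
    ix, iy = pc_x - 1, pc_y - 1
    rows = [
        {"kind": "sample", "id": sid, "x": result.scores[i, ix], "y": result.scores[i, iy]}
        for i, sid in enumerate(result.sample_ids)
    ] + [
        {"kind": "descriptor", "id": name,
         "x": result.loadings[j, ix] * result.singular_values[ix],
         "y": result.loadings[j, iy] * result.singular_values[iy]}
        for j, name in enumerate(result.descriptor_names)
    ]
    return pd.DataFrame(rows)
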