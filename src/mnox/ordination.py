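"""Low-dimensional ordination of lane-distance matrices.

Classical (Torgerson) MDS double-centers the squared distance matrix and
reads coordinates off the top eigenpairs; it is exact for Euclidean input
and supplies the starting configuration for non-metric MDS.

Non-metric MDS minimizes Kruskal stress-1,

    stress = sqrt( sum_ij (d_ij - dhat_ij)^2 / sum_ij d_ij^2 ),

over configurations, where d_ij are configuration distances and dhat_ij are
disparities obtained by isotonic (monotone) regression of the configuration
distances on the input dissimilarities (primary, averaging, tie handling).
Each iteration alternates an isotonic update with a Guttman transform; the
loop keeps the best configuration seen, so reported stress is non-increasing
across iterations.  Axis orientation and scale are arbitrary: only relative
distances between points are interpretable, and scales are not comparable
across ordinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .dgge import LaneDistanceMatrix

__all__ = ["OrdinationResult", "classical_mds", "nonmetric_mds", "procrustes_rmsd"]


@dataclass(frozen=True)
class OrdinationResult:
    """A k-dimensional embedding of lanes with its goodness-of-fit."""

    lane_ids: tuple[str, ...]
    coordinates: np.ndarray  # n x k, column-centered
    stress: float | None = None  # Kruskal stress-1 (non-metric only)
    eigenvalues: np.ndarray | None = None  # sorted descending (classical only)
    converged: bool = True
    n_iter: int = 0
    stress_history: tuple[float, ...] = ()  # accepted stress per iteration

    def to_frame(self):
        import pandas as pd

        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.lane_ids), columns=cols)


def classical_mds(d: LaneDistanceMatrix, k: int = 2) -> OrdinationResult:
    """Torgerson classical scaling of a distance matrix.

    Coordinates come from the top-``k`` non-negative eigenpairs of the
    double-centered squared-distance matrix; if fewer than ``k`` positive
    eigenvalues exist the remaining axes are zero (with a warning).
    Eigenvalues are reported in full so negative (non-Euclidean) mass is
    visible to the caller.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dm = d.values
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    n_pos = int(np.sum(eigval > 1e-12 * max(eigval.max(), 1.0)))
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; axes beyond {n_pos} are zero", stacklevel=2
        )
    coords = np.zeros((n, k))
    m = min(k, n_pos)
    if m > 0:
        coords[:, :m] = eigvec[:, :m] * np.sqrt(eigval[:m])
    coords -= coords.mean(axis=0)
    return OrdinationResult(
        lane_ids=d.lane_ids, coordinates=coords, eigenvalues=eigval, stress=None
    )


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def nonmetric_mds(
    d: LaneDistanceMatrix,
    k: int = 2,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Kruskal non-metric MDS of a distance matrix.

    Initialized from :func:`classical_mds` (with a tiny seeded jitter only if
    that start is degenerate), hence deterministic given ``seed``.  Returns
    the best (lowest-stress) configuration; ``converged`` is False if the
    relative stress change never fell below ``tol`` within ``max_iter``.
    """
    n = d.values.shape[0]
    delta = squareform(d.values, checks=False)  # condensed input dissimilarities
    if np.all(delta == 0):
        return OrdinationResult(
            lane_ids=d.lane_ids, coordinates=np.zeros((n, k)), stress=0.0, n_iter=0
        )

    x = classical_mds(d, k).coordinates.copy()
    if np.allclose(x, 0):
        rng = np.random.default_rng(seed)
        x = 1e-6 * rng.standard_normal((n, k))
        x -= x.mean(axis=0)

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    order = np.argsort(delta, kind="stable")
    best_x, best_stress = x.copy(), np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dist = pdist(x)
        # Disparities: monotone regression of distances on dissimilarities;
        # tied dissimilarities are pooled by averaging (primary approach).
        disp = np.empty_like(dist)
        disp[order] = iso.fit_transform(delta[order], dist[order])
        stress = _stress1(dist, disp)
        if stress < best_stress:
            prev_best = best_stress
            best_x, best_stress = x.copy(), stress
            history.append(stress)
            if prev_best < np.inf and (prev_best - stress) < tol * max(prev_best, 1e-30):
                converged = True
                break
        else:  # no improvement: majorization has stalled
            converged = True
            break
        if stress < 1e-12:
            converged = True
            break
        # Guttman transform with the current disparities.
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / dist, 0.0)
        bmat = -squareform(ratio, checks=False)
        np.fill_diagonal(bmat, -bmat.sum(axis=1))
        x = bmat @ x / n
        x -= x.mean(axis=0)

    best_x -= best_x.mean(axis=0)
    return OrdinationResult(
        lane_ids=d.lane_ids,
        coordinates=best_x,
        stress=best_stress,
        converged=converged,
        n_iter=it,
        stress_history=tuple(history),
    )


def procrustes_rmsd(a: np.ndarray, b: np.ndarray, scale: bool = True) -> float:
    """Root-mean-square deviation of ``b`` from ``a`` after optimal
    translation, rotation/reflection, and (optionally) isotropic scaling.

    Both configurations are first normalized to unit centered Frobenius norm
    so the residual is scale-free.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0 if na == nb else float("inf")
    a, b = a / na, b / nb
    u, s, vt = np.linalg.svd(b.T @ a)
    r = u @ vt
    b = b @ r
    if scale:
        b = b * s.sum()
    return float(np.sqrt(np.mean((a - b) ** 2)))
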