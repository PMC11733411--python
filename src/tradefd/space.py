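"""PCA functional space of the species pool and dimensionality diagnostics.

The functional space is a principal-component ordination of the z-scored
trait table of the full species pool.  Assemblage-level metrics (hull
volumes, distances to the pool centroid) are computed on the first ``m``
axes; the quality of a candidate ``m`` is judged by the cumulative variance
explained and by the mean squared deviation (MSD) between species pairwise
distances in the full trait space and in the reduced space.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .metrics import hull_volume_flagged

__all__ = ["FunctionalSpace", "build_space", "space_quality"]


@dataclass
class FunctionalSpace:
    """Species coordinates on ``m`` principal axes, plus pool summaries.

    ``centroid`` is the unweighted centroid of the full pool in the reduced
    space (numerically zero, since the traits are centred) and
    ``pool_volume`` the convex-hull volume of the whole pool — the
    denominator for percent functional richness.
    """

    coordinates: pd.DataFrame  # species x PC1..PCm
    eigenvalues: np.ndarray  # all n_trait eigenvalues, descending
    var_pct: np.ndarray  # % variance per axis, sums to 100 over all axes
    loadings: pd.DataFrame  # traits x kept axes
    centroid: np.ndarray
    pool_volume: float
    pool_degenerate: bool = False

    @property
    def m(self) -> int:
        return self.coordinates.shape[1]

    @property
    def species(self) -> list[str]:
        return list(self.coordinates.index)

    def cumulative_var_pct(self, m: int | None = None) -> float:
        m = self.m if m is None else m
        return float(self.var_pct[:m].sum())


def _pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the sample covariance, axes sign-fixed.

    Sign convention for reproducibility: in each eigenvector the element of
    largest magnitude is made positive.
    """
    S = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    for k in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, k]))
        if evecs[i, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return evals, evecs


def build_space(std, m: int) -> FunctionalSpace:
    """Project the standardized pool onto its first ``m`` principal axes.

    ``std`` is a :class:`~tradefd.traits.StandardizedTraits` or a complete
    numeric DataFrame (species x traits).  Deterministic up to nothing: the
    axis-sign convention makes repeated runs identical.
    """
    values = getattr(std, "values", std)
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(values)
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    if m > p:
        raise ValueError(f"m={m} exceeds the number of traits ({p})")
    if n <= m:
        raise ValueError(f"pool of {n} species cannot support {m} axes")
    Xc = X - X.mean(axis=0)
    evals, evecs = _pca(Xc)
    total = evals.sum()
    var_pct = 100.0 * evals / total if total > 0 else np.full(p, np.nan)
    coords = Xc @ evecs[:, :m]
    coordinates = pd.DataFrame(
        coords, index=values.index, columns=[f"PC{k + 1}" for k in range(m)]
    )
    loadings = pd.DataFrame(
        evecs[:, :m], index=values.columns, columns=coordinates.columns
    )
    centroid = coords.mean(axis=0)
    vol, degen = hull_volume_flagged(coords)
    return FunctionalSpace(
        coordinates=coordinates,
        eigenvalues=evals,
        var_pct=var_pct,
        loadings=loadings,
        centroid=centroid,
        pool_volume=vol,
        pool_degenerate=degen,
    )


def space_quality(
    std, m_candidates: Sequence[int] = (1, 2, 3, 4), deviation: str = "squared"
) -> pd.DataFrame:
    """Cumulative variance and distance distortion for candidate axis counts.

    For each candidate ``m`` the table reports the cumulative % variance of
    the first ``m`` axes and the mean (squared, or absolute with
    ``deviation="absolute"``) deviation between full trait-space pairwise
    distances and the ``m``-axis distances, over all species pairs.  MSD is
    zero at full rank and non-increasing in ``m``; the usual choice is the
    smallest ``m`` with high variance and low MSD.
    """
    values = getattr(std, "values", std)
    X = np.asarray(values, dtype=float)
    p = X.shape[1]
    if any(m < 1 or m > p for m in m_candidates):
        raise ValueError(f"candidates must lie in 1..{p}")
    Xc = X - X.mean(axis=0)
    evals, evecs = _pca(Xc)
    total = evals.sum()
    d_full = pdist(Xc)
    rows = []
    for m in m_candidates:
        d_m = pdist(Xc @ evecs[:, :m])
        dev = d_full - d_m
        msd = float(np.mean(dev**2 if deviation == "squared" else np.abs(dev)))
        rows.append(
            {
                "m": m,
                "cum_var_pct": float(100.0 * evals[:m].sum() / total),
                "msd": msd,
            }
        )
    return pd.DataFrame(rows).set_index("m")
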