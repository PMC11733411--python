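"""Functional-diversity metrics per assemblage: FRic, FSpe, SES FRic, hotspots.

FRic (functional richness) is the convex-hull volume spanned by an
assemblage's species in the reduced trait space — presence-based, so trade
volumes only decide which species are in.  FSpe (functional specialization)
is the volume-weighted mean distance of the assemblage's species from the
unweighted centroid of the whole species pool, so assemblages dominated by
trait-extreme species score high.  SES FRic standardizes an assemblage's
FRic against a null of equal-richness random assemblages drawn from the
full pool; values below -2 indicate trait filtering (under-dispersion),
above +2 over-dispersion.
"""

from __future__ import annotations

import zlib
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "TooFewSpeciesError",
    "NullSpec",
    "SESResult",
    "hull_volume",
    "hull_volume_flagged",
    "fric",
    "fspe",
    "ses_fric",
    "classify_ses",
    "hotspots",
    "assemblage_rng",
    "compute_fd",
]


class TooFewSpeciesError(ValueError):
    """Raised when an assemblage has too few species for the metric: it
    must contain at least one species more than the number of axes."""


def hull_volume_flagged(points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull volume and a degeneracy flag.

    Affinely degenerate point sets (all points in a lower-dimensional flat)
    have zero volume; the flag distinguishes that from a genuine small hull.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a k x m array")
    k, m = pts.shape
    if k < m + 1:
        raise TooFewSpeciesError(
            f"{k} points in {m} dimensions: an assemblage must contain at "
            "least one species more than the number of axes"
        )
    if m == 1:
        v = float(np.ptp(pts[:, 0]))
        return v, v == 0.0
    try:
        return float(ConvexHull(pts).volume), False
    except QhullError:
        # flat input: qhull cannot build a full-dimensional hull
        if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < m:
            return 0.0, True
        raise


def hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume of ``k`` points in ``m`` dimensions (k >= m+1).

    Returns 0.0 for affinely degenerate inputs; use
    :func:`hull_volume_flagged` to detect that case explicitly.
    """
    return hull_volume_flagged(points)[0]


def _present_coords(volumes: pd.Series, space) -> np.ndarray:
    coords = space.coordinates
    v = volumes.reindex(coords.index, fill_value=0.0)
    return coords.to_numpy(dtype=float)[v.to_numpy(dtype=float) > 0]


def fric(volumes: pd.Series, space, mode: str = "percent") -> float:
    """Functional richness of one assemblage.

    ``volumes`` gives WOE volume per species (indexed by species name; only
    positivity matters — FRic is presence-based).  ``mode="percent"``
    (default) expresses the hull volume as a percentage of the pool hull;
    ``mode="raw"`` returns the volume itself.
    """
    if mode not in ("raw", "percent"):
        raise ValueError("mode must be 'raw' or 'percent'")
    pts = _present_coords(volumes, space)
    vol, _ = hull_volume_flagged(pts)
    if mode == "raw":
        return vol
    if space.pool_volume <= 0:
        raise ValueError("pool hull volume is zero; percent FRic undefined")
    return 100.0 * vol / space.pool_volume


def fspe(volumes: pd.Series, space) -> float:
    """Functional specialization: volume-weighted mean distance to the
    pool centroid.

    Weights are volume shares, so rescaling all volumes by a constant leaves
    FSpe unchanged.  The centroid is the unweighted centroid of the full
    pool, not of the assemblage.
    """
    coords = space.coordinates
    v = volumes.reindex(coords.index, fill_value=0.0).to_numpy(dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("assemblage has zero total volume")
    d = np.linalg.norm(coords.to_numpy(dtype=float) - space.centroid, axis=1)
    return float((v / total) @ d)


@dataclass(frozen=True)
class NullSpec:
    """Randomization scheme for SES FRic.

    Each replicate draws, without replacement from the full pool (traded and
    non-traded species alike), as many species as the observed assemblage
    holds, and reassigns the observed volumes to them at random.  Because
    FRic is presence-based the volume permutation does not alter the null
    FRic values; the field is kept to document the scheme (and because the
    same nulls would weight an abundance-based metric).
    """

    n_rand: int = 999
    seed: int | None = None
    volume_assignment: str = "permute_observed"

    def __post_init__(self) -> None:
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")


@dataclass
class SESResult:
    ses: float | None  # None when the null SD is zero
    null_mean: float
    null_sd: float
    n_rand: int
    observed: float = field(default=np.nan)

    @property
    def defined(self) -> bool:
        return self.ses is not None


def ses_fric(
    volumes: pd.Series,
    space,
    null: NullSpec | None = None,
    rng: np.random.Generator | None = None,
) -> SESResult:
    """Standardized effect size of FRic against equal-richness random draws.

    SES = (observed FRic - mean null FRic) / SD(null FRic), with the null
    built from ``null.n_rand`` random assemblages of the same species
    richness.  Raw hull volumes are used; SES is invariant to the raw vs
    percent choice.  Reproducible under ``null.seed`` (or an explicit
    ``rng``, which takes precedence).
    """
    null = null or NullSpec()
    coords = space.coordinates.to_numpy(dtype=float)
    n = len(coords)
    k = int((volumes.reindex(space.coordinates.index, fill_value=0.0) > 0).sum())
    obs, _ = hull_volume_flagged(_present_coords(volumes, space))
    if rng is None:
        rng = np.random.default_rng(null.seed)
    vols = np.empty(null.n_rand)
    for i in range(null.n_rand):
        idx = rng.choice(n, size=k, replace=False)
        vols[i], _ = hull_volume_flagged(coords[idx])
    mean = float(vols.mean())
    sd = float(vols.std(ddof=1)) if null.n_rand > 1 else 0.0
    ses = (obs - mean) / sd if sd > 0 else None
    return SESResult(ses=ses, null_mean=mean, null_sd=sd, n_rand=null.n_rand, observed=obs)


def classify_ses(ses: float) -> str:
    """Classify an SES value: below -2 under-dispersed, above +2
    over-dispersed, otherwise not significant (strict inequalities)."""
    if ses < -2:
        return "under_dispersed"
    if ses > 2:
        return "over_dispersed"
    return "ns"


def hotspots(values: Mapping, pct: float = 5.0) -> set:
    """Keys whose metric value lies in the top ``pct`` percent.

    The cutoff is the (100 - pct)th percentile of the defined (non-NaN)
    values under numpy's linear-interpolation convention, applied
    inclusively: every key at or above the cutoff is a hotspot, so ties at
    the cutoff are all included.
    """
    items = [(key, v) for key, v in values.items() if v is not None and np.isfinite(v)]
    if not items:
        raise ValueError("no defined metric values")
    cutoff = np.percentile([v for _, v in items], 100.0 - pct)
    return {key for key, v in items if v >= cutoff}


def assemblage_rng(master_seed: int, key) -> np.random.Generator:
    """Per-assemblage random substream derived from one master seed.

    The substream is keyed by a stable hash of the assemblage key, so
    evaluating assemblages in any order (or in parallel) gives identical
    results per assemblage.
    """
    if isinstance(key, tuple):
        text = "|".join(str(part) for part in key)
    else:
        text = str(key)
    h = zlib.crc32(text.encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed & 0x7FFFFFFF, h]))


def compute_fd(
    matrix,
    space,
    null: NullSpec | None = None,
    master_seed: int = 0,
    fric_mode: str = "percent",
) -> pd.DataFrame:
    """FRic, FSpe and (optionally) SES FRic for every row of an assemblage
    matrix.

    Assemblages failing the minimum-richness rule get NaN metrics and a
    recorded reason instead of an exception, mirroring the exclusions a
    sparse-row filter would make.  When ``null`` is given, each assemblage
    uses its own seeded substream (see :func:`assemblage_rng`).
    """
    rows = []
    for key, volumes in matrix.data.iterrows():
        rec: dict = {"key": key, "species_richness": int((volumes > 0).sum())}
        try:
            rec["fric_raw"] = fric(volumes, space, mode="raw")
            rec["fric_pct"] = 100.0 * rec["fric_raw"] / space.pool_volume
            rec["fspe"] = fspe(volumes, space)
            rec["reason"] = ""
        except (TooFewSpeciesError, ValueError) as e:
            rec.update(fric_raw=np.nan, fric_pct=np.nan, fspe=np.nan, reason=str(e))
            rec.update(ses_fric=np.nan, null_mean=np.nan, null_sd=np.nan, n_null=0)
            rows.append(rec)
            continue
        if null is not None:
            res = ses_fric(
                volumes, space, null, rng=assemblage_rng(master_seed, key)
            )
            rec.update(
                ses_fric=res.ses if res.defined else np.nan,
                null_mean=res.null_mean,
                null_sd=res.null_sd,
                n_null=res.n_rand,
            )
        else:
            rec.update(ses_fric=np.nan, null_mean=np.nan, null_sd=np.nan, n_null=0)
        rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("key")
    return df
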