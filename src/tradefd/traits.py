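"""Species trait table: coverage, chained-equation imputation, standardization.

Four functional traits drive the analysis: body mass (g), clutch size,
maximum longevity (years) and habitat breadth (count of occupied habitat
categories).  The first three are heavy-tailed and are log10-transformed
before any regression or ordination; habitat breadth stays on its raw scale.
Missing values are filled by multivariate imputation by chained equations
(MICE) with predictive-mean matching, run on the log scale and without
phylogenetic information, producing several alternative complete tables so
downstream results can be checked against imputation spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "LOG10_TRAITS",
    "StandardizedTraits",
    "coverage",
    "impute_chained",
    "standardize",
]

TRAITS = ("body_mass", "clutch_size", "max_longevity", "habitat_breadth")
LOG10_TRAITS = ("body_mass", "clutch_size", "max_longevity")


def _check_table(table: pd.DataFrame) -> None:
    missing_cols = [t for t in TRAITS if t not in table.columns]
    if missing_cols:
        raise ValueError(f"trait table lacks columns: {missing_cols}")
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate species names: {dupes}")


def coverage(table: pd.DataFrame) -> pd.Series:
    """Percentage of species with a non-missing value, per trait.

    The denominator is the full pool (all rows of the table)."""
    _check_table(table)
    if len(table) == 0:
        raise ValueError("empty trait table")
    return table[list(TRAITS)].notna().mean() * 100.0


def impute_chained(
    table: pd.DataFrame,
    n_imputations: int = 4,
    max_iter: int = 10,
    k_donors: int = 5,
    seed: int | None = None,
    log_scale: bool = True,
) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations with predictive-mean matching.

    Each trait with missing values is regressed in turn on all other traits
    (linear model on the log10 scale for the logged traits when
    ``log_scale``); regression coefficients are perturbed by a draw from
    their sampling distribution, and each missing cell receives the observed
    value of a donor species sampled from the ``k_donors`` nearest predicted
    values (type-1 matching).  Because donors contribute observed values,
    imputed habitat breadths stay integral and all imputed values stay
    positive.  Observed cells are never modified.  Returns ``n_imputations``
    complete tables; reproducible under a fixed ``seed``.
    """
    _check_table(table)
    cols = list(TRAITS)
    X0 = table[cols].astype(float).to_numpy()
    obs = ~np.isnan(X0)
    for j, t in enumerate(cols):
        if obs[:, j].sum() == 0:
            raise ValueError(f"trait {t!r} has no observed values")
        vals = X0[obs[:, j], j]
        if np.any(vals <= 0):
            raise ValueError(f"trait {t!r} has non-positive values")

    work0 = X0.copy()
    if log_scale:
        for j, t in enumerate(cols):
            if t in LOG10_TRAITS:
                work0[:, j] = np.log10(work0[:, j])

    rng = np.random.default_rng(seed)
    out: list[pd.DataFrame] = []
    need = [j for j in range(len(cols)) if not obs[:, j].all()]
    for _ in range(n_imputations):
        X = work0.copy()
        # initialise missing cells with random draws from the observed values
        for j in need:
            n_mis = (~obs[:, j]).sum()
            X[~obs[:, j], j] = rng.choice(X[obs[:, j], j], size=n_mis, replace=True)
        for _ in range(max_iter if need else 0):
            for j in need:
                X[:, j] = _pmm_step(X, obs[:, j], j, k_donors, rng)
        filled = X.copy()
        if log_scale:
            for j, t in enumerate(cols):
                if t in LOG10_TRAITS:
                    filled[:, j] = 10.0 ** filled[:, j]
        # restore observed cells exactly (guard against fp round-trip)
        filled[obs] = X0[obs]
        result = table.copy()
        result[cols] = filled
        out.append(result)
    return out


def _pmm_step(
    X: np.ndarray, obs_j: np.ndarray, j: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """One conditional-regression + predictive-mean-matching update of column j."""
    others = [c for c in range(X.shape[1]) if c != j]
    D = np.column_stack([np.ones(len(X)), X[:, others]])
    y = X[:, j].copy()
    Do, yo = D[obs_j], y[obs_j]
    beta, _, rank, _ = np.linalg.lstsq(Do, yo, rcond=None)
    resid = yo - Do @ beta
    dof = max(len(yo) - rank, 1)
    sigma2 = float(resid @ resid) / dof
    # perturb coefficients by a draw from their approximate sampling distribution
    XtX = Do.T @ Do
    try:
        cov = sigma2 * np.linalg.inv(XtX + 1e-10 * np.eye(len(beta)))
        L = np.linalg.cholesky((cov + cov.T) / 2)
        beta_t = beta + L @ rng.standard_normal(len(beta))
    except np.linalg.LinAlgError:
        beta_t = beta
    pred_obs = Do @ beta
    pred_mis = D[~obs_j] @ beta_t
    # type-1 matching: donors are the k observed cases nearest in predicted value
    kk = min(k, len(yo))
    order = np.argsort(np.abs(pred_obs[None, :] - pred_mis[:, None]), axis=1)[:, :kk]
    picks = order[np.arange(len(pred_mis)), rng.integers(0, kk, size=len(pred_mis))]
    y[~obs_j] = yo[picks]
    return y


@dataclass
class StandardizedTraits:
    """Z-scored trait values plus the transform metadata needed to map model
    coefficients back to per-magnitude effects.

    ``values`` has one column per trait with mean 0 and sample SD 1 over the
    pool.  ``meta[trait]`` records whether the trait was log10-transformed
    and the mean and SD on the transformed scale.
    """

    values: pd.DataFrame
    meta: dict[str, dict]

    @property
    def species(self) -> list[str]:
        return list(self.values.index)


def standardize(
    table: pd.DataFrame,
    log10_traits: tuple[str, ...] = LOG10_TRAITS,
    ddof: int = 1,
) -> StandardizedTraits:
    """Log10-transform the heavy-tailed traits and z-score every trait.

    Requires a complete table (run after imputation).  Sample SD (``ddof=1``)
    is the default convention.  Pass ``log10_traits=()`` to z-score values
    that are already on their transformed scale, which makes the z-step
    idempotent.
    """
    _check_table(table)
    cols = list(TRAITS)
    X = table[cols].astype(float)
    if X.isna().any().any():
        raise ValueError("trait table has missing values; impute first")
    meta: dict[str, dict] = {}
    Z = pd.DataFrame(index=table.index, columns=cols, dtype=float)
    for t in cols:
        x = X[t].to_numpy(copy=True)
        logged = t in log10_traits
        if logged:
            if np.any(x <= 0):
                raise ValueError(f"trait {t!r} must be positive for log10")
            x = np.log10(x)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=ddof))
        if sd == 0:
            raise ValueError(f"trait {t!r} has zero variance")
        Z[t] = (x - mu) / sd
        meta[t] = {"logged": logged, "mean": mu, "sd": sd}
    return StandardizedTraits(values=Z, meta=meta)
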