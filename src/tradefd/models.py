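"""Hierarchical trait-trade association models.

Two regressions link a single standardized functional trait to trade:

* presence model — Bernoulli, logit P(traded) = a + b*z + g*year_c
  + u_year + u_taxon, optionally with per-continent trait slopes and
  year-by-continent controls;
* volume model — negative binomial on positive whole-organism-equivalent
  volumes (rounded to integer counts >= 1), log mean with the same linear
  structure.

Year enters both as a continuous fixed effect (centred/scaled) and as a
factor-level varying intercept; taxon group is a second varying intercept.
Priors are zero-centred and weakly regularizing: Normal(0, 1.5) on fixed
effects, half-Normal(0, 1) on group SDs, and half-Normal(0, 1) on the NB
*inverse* shape so the prior shrinks toward the Poisson limit.

The default backend is a deterministic marginal-Laplace approximation in the
style of glmmTMB/INLA: the varying intercepts are integrated out by an inner
Newton solve, the marginal posterior of the remaining parameters (fixed
effects, log group SDs, log inverse shape) is maximized and approximated by
a Gaussian at its mode, and posterior draws — arranged into chains so the
usual convergence summaries apply — are completed with conditional Gaussian
draws of the varying intercepts.  An ``emcee`` ensemble-MCMC backend over
the same marginal posterior is available via ``method="emcee"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln

__all__ = [
    "Priors",
    "FitResult",
    "ConvergenceError",
    "PerfectSeparationError",
    "fit_presence",
    "fit_volume",
    "prepare_volume_rows",
    "rescale_per_magnitude",
    "volume_pct_change",
    "posterior_predictive_check",
    "species_year_table",
    "species_year_table_by_continent",
    "volumes_by_year",
]


class ConvergenceError(RuntimeError):
    """The sampler or optimizer did not reach a trustworthy posterior."""


class PerfectSeparationError(ConvergenceError):
    """The trait perfectly separates traded from non-traded rows; the
    likelihood has no interior maximum and no estimate is returned."""


@dataclass(frozen=True)
class Priors:
    """Zero-centred, weakly regularizing defaults; all configurable."""

    fixed_sd: float = 1.5
    group_sd_scale: float = 1.0
    inv_shape_scale: float = 1.0  # half-Normal scale on the NB inverse shape


# ---------------------------------------------------------------------------
# data assembly


def volumes_by_year(matrix) -> pd.DataFrame:
    """Collapse an assemblage matrix with a ``year`` stratum to a
    year x species volume table (summing over the grouping keys)."""
    if "year" not in matrix.data.index.names:
        raise ValueError("matrix lacks a 'year' stratum")
    return matrix.data.groupby(level="year").sum()


def species_year_table(
    volumes: pd.DataFrame,
    std,
    trait: str,
    taxon: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Long species x year table for the global models.

    ``volumes`` is a year x species WOE table (see :func:`volumes_by_year`);
    ``std`` holds the standardized traits; ``taxon`` maps species to their
    taxonomic group.  Output columns: species, year, traded, volume, z,
    taxon.  Every pool species contributes one row per year (non-traded
    rows have traded = 0).
    """
    z = std.values[trait]
    taxon = pd.Series(taxon)
    rows = []
    for year in volumes.index:
        v = volumes.loc[year]
        for sp in std.species:
            vol = float(v.get(sp, 0.0))
            rows.append(
                {
                    "species": sp,
                    "year": int(year),
                    "traded": int(vol > 0),
                    "volume": vol,
                    "z": float(z[sp]),
                    "taxon": str(taxon[sp]),
                }
            )
    return pd.DataFrame(rows)


def species_year_table_by_continent(
    volumes_by_continent: Mapping[str, pd.DataFrame],
    std,
    trait: str,
    taxon: Mapping[str, str] | pd.Series,
    occurrence: Mapping[str, set],
) -> pd.DataFrame:
    """Long table for continent-interaction models.

    One row per species x year x continent, restricted to continents where
    the species occurs (``occurrence``), so absence rows reflect a species
    that could have been traded from that continent but was not.
    """
    parts = []
    for cont, vols in volumes_by_continent.items():
        tab = species_year_table(vols, std, trait, taxon)
        tab = tab[tab["species"].map(lambda s: cont in occurrence.get(s, set()))]
        tab = tab.assign(continent=cont)
        parts.append(tab)
    return pd.concat(parts, ignore_index=True)


def prepare_volume_rows(data: pd.DataFrame) -> pd.DataFrame:
    """Keep traded rows and round WOE volumes to integer counts >= 1."""
    out = data[data["volume"] > 0].copy()
    out["count"] = np.maximum(np.rint(out["volume"]), 1.0)
    return out


# ---------------------------------------------------------------------------
# design


@dataclass
class _Design:
    X: np.ndarray  # n x p fixed-effect columns
    fixed_names: list[str]
    groups: list[tuple[str, list, np.ndarray]]  # (name, levels, row->level idx)
    y: np.ndarray
    year_center: float
    year_scale: float
    family: str  # "bernoulli" | "negbinomial"

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def group_sizes(self) -> list[int]:
        return [len(levels) for _, levels, _ in self.groups]

    @property
    def n_u(self) -> int:
        return sum(self.group_sizes)

    @property
    def n_outer(self) -> int:
        """Fixed effects + one log SD per group + log inverse shape (NB)."""
        return self.n_fixed + len(self.groups) + (self.family == "negbinomial")

    def param_names(self) -> list[str]:
        names = list(self.fixed_names)
        for gname, levels, _ in self.groups:
            names += [f"u_{gname}[{lev}]" for lev in levels]
        names += [f"sd_{gname}" for gname, _, _ in self.groups]
        if self.family == "negbinomial":
            names.append("nb_shape")
        return names

    def split_outer(self, psi: np.ndarray):
        p = self.n_fixed
        b = psi[:p]
        ss = psi[p : p + len(self.groups)]
        log_kappa = psi[p + len(self.groups)] if self.family == "negbinomial" else None
        return b, ss, log_kappa

    def u_offsets(self) -> list[int]:
        off, pos = [], 0
        for size in self.group_sizes:
            off.append(pos)
            pos += size
        return off

    def eta(self, b: np.ndarray, u: np.ndarray) -> np.ndarray:
        eta = self.X @ b
        for off, (gname, levels, idx) in zip(self.u_offsets(), self.groups):
            eta = eta + u[off : off + len(levels)][idx]
        return eta


def _build_design(
    data: pd.DataFrame,
    family: str,
    response: str,
    continent_interaction: bool,
) -> _Design:
    for col in ("z", "year", "taxon", response):
        if col not in data.columns:
            raise ValueError(f"model data lacks column {col!r}")
    y = data[response].to_numpy(dtype=float)
    year = data["year"].to_numpy(dtype=float)
    yc_center = float(year.mean())
    yc_scale = float(year.std(ddof=1)) or 1.0
    yc = (year - yc_center) / yc_scale
    z = data["z"].to_numpy(dtype=float)

    cols = [np.ones(len(data))]
    names = ["intercept"]
    if continent_interaction:
        if "continent" not in data.columns:
            raise ValueError("continent interaction requested without a continent column")
        levels = sorted(data["continent"].unique())
        dummies = {c: (data["continent"] == c).to_numpy(dtype=float) for c in levels}
        for c in levels[1:]:  # treatment-coded main effects
            cols.append(dummies[c])
            names.append(f"continent[{c}]")
        for c in levels:  # one trait slope per continent
            cols.append(z * dummies[c])
            names.append(f"z[{c}]")
        cols.append(yc)
        names.append("year_c")
        for c in levels[1:]:  # year-by-continent control
            cols.append(yc * dummies[c])
            names.append(f"year_c:continent[{c}]")
    else:
        cols += [z, yc]
        names += ["z", "year_c"]
    X = np.column_stack(cols)

    groups = []
    for gname, col in (("year", "year"), ("taxon", "taxon")):
        levels = sorted(data[col].unique())
        lut = {lev: i for i, lev in enumerate(levels)}
        idx = data[col].map(lut).to_numpy(dtype=int)
        groups.append((gname, levels, idx))
    return _Design(
        X=X,
        fixed_names=names,
        groups=groups,
        y=y,
        year_center=yc_center,
        year_scale=yc_scale,
        family=family,
    )


# ---------------------------------------------------------------------------
# likelihood and inner (random-effect) Newton solve


def _lik(eta: np.ndarray, y: np.ndarray, family: str, phi: float | None):
    """Log likelihood, its gradient in eta, and the negative curvature W."""
    if family == "bernoulli":
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        p = expit(eta)
        return ll, y - p, p * (1.0 - p)
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    ll = float(
        np.sum(
            gammaln(y + phi)
            - gammaln(phi)
            - gammaln(y + 1.0)
            + phi * (np.log(phi) - np.log(phi + mu))
            + y * (np.log(mu) - np.log(phi + mu))
        )
    )
    grad = phi * (y - mu) / (phi + mu)
    W = phi * mu * (phi + y) / (phi + mu) ** 2
    return ll, grad, W


def _ztwz(d: _Design, W: np.ndarray) -> np.ndarray:
    """Dense Z' W Z over the stacked group indicator columns."""
    offs = d.u_offsets()
    nu = d.n_u
    H = np.zeros((nu, nu))
    for a, (off_a, (ga, lev_a, idx_a)) in enumerate(zip(offs, d.groups)):
        diag = np.bincount(idx_a, weights=W, minlength=len(lev_a))
        H[off_a : off_a + len(lev_a), off_a : off_a + len(lev_a)] += np.diag(diag)
        for off_b, (gb, lev_b, idx_b) in list(zip(offs, d.groups))[a + 1 :]:
            M = np.zeros((len(lev_a), len(lev_b)))
            np.add.at(M, (idx_a, idx_b), W)
            H[off_a : off_a + len(lev_a), off_b : off_b + len(lev_b)] += M
            H[off_b : off_b + len(lev_b), off_a : off_a + len(lev_a)] += M.T
    return H


def _grad_u(d: _Design, grad_eta: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [
            np.bincount(idx, weights=grad_eta, minlength=len(levels))
            for _, levels, idx in d.groups
        ]
    )


def _prior_prec_u(d: _Design, sigmas: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [np.full(size, 1.0 / s**2) for size, s in zip(d.group_sizes, sigmas)]
    )


def _solve_u(
    d: _Design,
    b: np.ndarray,
    sigmas: np.ndarray,
    phi: float | None,
    u0: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Inner Newton maximization of the penalized likelihood over the
    varying intercepts, with step halving.  Returns (u*, H at u*, ll at u*)."""
    prec = _prior_prec_u(d, sigmas)
    u = u0.copy()

    def pen_ll(u):
        ll, grad_eta, W = _lik(d.eta(b, u), d.y, d.family, phi)
        return ll - 0.5 * float(prec @ u**2), grad_eta, W

    f, grad_eta, W = pen_ll(u)
    for _ in range(max_iter):
        g = _grad_u(d, grad_eta) - prec * u
        if np.max(np.abs(g)) < tol:
            break
        H = _ztwz(d, W) + np.diag(prec)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = g / np.diag(H)
        t = 1.0
        for _ in range(30):
            f_new, ge_new, W_new = pen_ll(u + t * step)
            if f_new >= f - 1e-12:
                break
            t /= 2.0
        u = u + t * step
        f, grad_eta, W = f_new, ge_new, W_new
    H = _ztwz(d, W) + np.diag(prec)
    ll = f + 0.5 * float(prec @ u**2)
    return u, H, ll


def _marginal_neg_logpost(
    psi: np.ndarray, d: _Design, priors: Priors, u_cache: dict
) -> float:
    """- log of the Laplace-marginalized posterior of the outer parameters."""
    b, ss, log_kappa = d.split_outer(psi)
    sigmas = np.exp(ss)
    phi = float(np.exp(-log_kappa)) if log_kappa is not None else None
    u0 = u_cache.get("u", np.zeros(d.n_u))
    u, H, ll = _solve_u(d, b, sigmas, phi, u0)
    u_cache["u"] = u
    prec = _prior_prec_u(d, sigmas)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return 1e12
    # Laplace-integrated random effects (2*pi factors cancel against the
    # u-prior normalization)
    lp = (
        ll
        - 0.5 * float(prec @ u**2)
        - float(np.sum(np.array(d.group_sizes) * ss))
        - 0.5 * logdet
    )
    lp += float(-0.5 * np.sum(b**2) / priors.fixed_sd**2)
    for s, sigma in zip(ss, sigmas):
        lp += float(-0.5 * sigma**2 / priors.group_sd_scale**2 + s)
    if log_kappa is not None:
        kappa = float(np.exp(log_kappa))
        lp += -0.5 * kappa**2 / priors.inv_shape_scale**2 + log_kappa
    return -lp


def _fd_hessian(f, x: np.ndarray, rel_h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    n = len(x)
    h = rel_h * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return (H + H.T) / 2


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    """Posterior summaries of one trait-trade model fit.

    ``summary`` has one row per parameter (median, 2.5% / 97.5% quantiles,
    Rhat); ``direction_certain`` flags fixed effects with at least 97.5% of
    posterior mass on the median's side of zero.  ``converged`` is False
    whenever any Rhat >= 1.05 or the optimizer/Hessian was untrustworthy —
    flagged, never silently dropped.
    """

    summary: pd.DataFrame
    draws: dict[str, np.ndarray]  # name -> (chains, draws), natural scale
    converged: bool
    direction_certain: dict[str, bool]
    n_chains: int
    n_iter: int
    n_warmup: int
    family: str
    method: str
    map_estimate: dict[str, float]
    meta: dict = field(default_factory=dict)
    _design: _Design | None = field(default=None, repr=False)
    _raw: np.ndarray | None = field(default=None, repr=False)  # (c, n, b+u+s+k)

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "median"])

    def interval(self, name: str) -> tuple[float, float]:
        row = self.summary.loc[name]
        return float(row["q2.5"]), float(row["q97.5"])

    @property
    def max_rhat(self) -> float:
        return float(self.summary["rhat"].max())


def _rhat(chains: np.ndarray) -> float:
    """Split-Rhat (potential scale reduction factor) for one parameter."""
    c, n = chains.shape
    if n < 4:
        return np.nan
    half = n // 2
    parts = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    m, n2 = parts.shape
    means = parts.mean(axis=1)
    W = parts.var(axis=1, ddof=1).mean()
    B = n2 * means.var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt(((n2 - 1) / n2 * W + B / n2) / W))


# ---------------------------------------------------------------------------
# fitting


def _psi_bounds(d: _Design) -> list[tuple[float, float]]:
    bounds = [(-30.0, 30.0)] * d.n_fixed
    bounds += [(-6.0, 4.0)] * len(d.groups)
    if d.family == "negbinomial":
        bounds += [(-10.0, 6.0)]
    return bounds


def _conditional_u_draw(
    d: _Design,
    psi: np.ndarray,
    u_warm: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the varying intercepts from their Gaussian approximation
    conditional on one outer-parameter draw."""
    b, ss, log_kappa = d.split_outer(psi)
    phi = float(np.exp(-log_kappa)) if log_kappa is not None else None
    u_star, H, _ = _solve_u(d, b, np.exp(ss), phi, u_warm, max_iter=5, tol=1e-6)
    try:
        L = np.linalg.cholesky(H)
        zdraw = rng.standard_normal(d.n_u)
        return u_star + np.linalg.solve(L.T, zdraw)
    except np.linalg.LinAlgError:
        return u_star


def _assemble(
    d: _Design,
    psi_draws: np.ndarray,  # (chains, n_keep, n_outer)
    psi_map: np.ndarray,
    u_map: np.ndarray,
    converged_fit: bool,
    method: str,
    iterations: int,
    warmup: int,
    meta: dict,
    rng: np.random.Generator,
) -> FitResult:
    n_chains, n_keep, _ = psi_draws.shape
    p = d.n_fixed
    ng = len(d.groups)
    lo = np.array([b[0] for b in _psi_bounds(d)])
    hi = np.array([b[1] for b in _psi_bounds(d)])
    psi_draws = np.clip(psi_draws, lo, hi)

    raw = np.empty((n_chains, n_keep, p + d.n_u + ng + (d.family == "negbinomial")))
    u_warm = u_map
    for c in range(n_chains):
        for i in range(n_keep):
            psi = psi_draws[c, i]
            u = _conditional_u_draw(d, psi, u_warm, rng)
            u_warm = u
            raw[c, i, :p] = psi[:p]
            raw[c, i, p : p + d.n_u] = u
            raw[c, i, p + d.n_u : p + d.n_u + ng] = psi[p : p + ng]
            if d.family == "negbinomial":
                raw[c, i, -1] = psi[-1]

    nat = raw.copy()
    nat[:, :, p + d.n_u : p + d.n_u + ng] = np.exp(nat[:, :, p + d.n_u : p + d.n_u + ng])
    if d.family == "negbinomial":
        nat[:, :, -1] = np.exp(-raw[:, :, -1])

    names = d.param_names()
    rows, draws, direction = [], {}, {}
    for k, name in enumerate(names):
        ch = nat[:, :, k]
        flat = ch.ravel()
        med = float(np.median(flat))
        lo_q, hi_q = np.quantile(flat, [0.025, 0.975])
        rows.append(
            {"param": name, "median": med, "q2.5": lo_q, "q97.5": hi_q, "rhat": _rhat(ch)}
        )
        draws[name] = ch
        if k < p:
            share = float(np.mean(np.sign(flat) == np.sign(med))) if med != 0 else 0.0
            direction[name] = share >= 0.975
    summary = pd.DataFrame(rows).set_index("param")
    ok = converged_fit and bool((summary["rhat"].dropna() < 1.05).all())
    if np.any(np.abs(psi_map[:p]) > 15):
        ok = False

    nat_map = np.concatenate(
        [
            psi_map[:p],
            u_map,
            np.exp(psi_map[p : p + ng]),
            np.exp(-psi_map[p + ng :]) if d.family == "negbinomial" else [],
        ]
    )
    result = FitResult(
        summary=summary,
        draws=draws,
        converged=ok,
        direction_certain=direction,
        n_chains=n_chains,
        n_iter=iterations,
        n_warmup=warmup,
        family=d.family,
        method=method,
        map_estimate=dict(zip(names, nat_map)),
        meta=meta,
        _design=d,
        _raw=raw,
    )
    if not ok:
        warnings.warn(
            f"fit flagged non-converged (max Rhat {summary['rhat'].max():.3f})",
            RuntimeWarning,
        )
    return result


def _fit(
    data: pd.DataFrame,
    family: str,
    response: str,
    continent_interaction: bool,
    priors: Priors,
    method: str,
    chains: int,
    iterations: int,
    warmup: int,
    seed: int | None,
) -> FitResult:
    d = _build_design(data, family, response, continent_interaction)
    if family == "bernoulli":
        if d.y.min() == d.y.max():
            raise ConvergenceError("response has a single class; model is degenerate")
        z = data["z"].to_numpy(dtype=float)
        yb = d.y.astype(bool)
        if z[yb].min() > z[~yb].max() or z[yb].max() < z[~yb].min():
            raise PerfectSeparationError(
                "trait perfectly separates traded from non-traded rows"
            )
    else:
        if np.any(d.y < 1):
            raise ValueError("volume model requires responses >= 1")

    u_cache: dict = {}
    obj = lambda psi: _marginal_neg_logpost(psi, d, priors, u_cache)
    psi0 = np.zeros(d.n_outer)
    psi0[d.n_fixed : d.n_fixed + len(d.groups)] = np.log(0.5)
    res = minimize(
        obj,
        psi0,
        method="L-BFGS-B",
        bounds=_psi_bounds(d),
        options={"maxiter": 500},
    )
    psi_map = res.x
    b, ss, log_kappa = d.split_outer(psi_map)
    phi = float(np.exp(-log_kappa)) if log_kappa is not None else None
    u_map, _, _ = _solve_u(d, b, np.exp(ss), phi, u_cache.get("u", np.zeros(d.n_u)))

    n_keep = iterations - warmup
    rng = np.random.default_rng(seed)
    meta = {"year_center": d.year_center, "year_scale": d.year_scale}

    if method == "laplace":
        H = _fd_hessian(obj, psi_map)
        evals, evecs = np.linalg.eigh(H)
        pd_ok = bool(evals.min() > 0)
        evals = np.clip(evals, 1e-8, None)
        L = evecs @ np.diag(1.0 / np.sqrt(evals))
        sims = psi_map + rng.standard_normal((chains, n_keep, d.n_outer)) @ L.T
        return _assemble(
            d, sims, psi_map, u_map, res.success and pd_ok, "laplace",
            iterations, warmup, meta, rng,
        )
    if method == "emcee":
        import emcee

        ndim = d.n_outer
        nwalkers = max(2 * ndim + 2, 4 * chains)
        nwalkers += nwalkers % 2
        p0 = psi_map + 1e-3 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, lambda t: -obj(t))
        sampler.run_mcmc(p0, warmup + n_keep, progress=False)
        chain = sampler.get_chain(discard=warmup)  # (steps, walkers, ndim)
        per = nwalkers // chains
        steps_take = max(n_keep // per, 1)
        sims = np.stack(
            [
                chain[-steps_take:, c * per : (c + 1) * per, :].reshape(-1, ndim)
                for c in range(chains)
            ]
        )
        return _assemble(
            d, sims, psi_map, u_map, res.success, "emcee",
            iterations, warmup, meta, rng,
        )
    raise ValueError(f"unknown method {method!r}")


def fit_presence(
    data: pd.DataFrame,
    continent_interaction: bool = False,
    priors: Priors = Priors(),
    method: str = "laplace",
    chains: int = 4,
    iterations: int = 1000,
    warmup: int = 500,
    seed: int | None = None,
) -> FitResult:
    """Fit the Bernoulli trade-presence model.

    ``data`` is a long species x year (x continent) table with columns
    ``traded`` (0/1), ``z`` (one standardized trait), ``year``, ``taxon``
    and, when ``continent_interaction``, ``continent`` (per-continent trait
    slopes plus year-by-continent controls are then estimated).
    """
    return _fit(
        data, "bernoulli", "traded", continent_interaction, priors,
        method, chains, iterations, warmup, seed,
    )


def fit_volume(
    data: pd.DataFrame,
    priors: Priors = Priors(),
    method: str = "laplace",
    chains: int = 4,
    iterations: int = 1000,
    warmup: int = 500,
    seed: int | None = None,
) -> FitResult:
    """Fit the negative-binomial trade-volume model on traded rows only.

    ``data`` must contain the positive-volume rows, with WOE volumes rounded
    to integer counts >= 1 in a ``count`` column (see
    :func:`prepare_volume_rows`).
    """
    return _fit(
        data, "negbinomial", "count", False, priors,
        method, chains, iterations, warmup, seed,
    )


# ---------------------------------------------------------------------------
# interpretation and checking


def rescale_per_magnitude(beta_std: float, sd_transformed: float) -> float:
    """Convert a coefficient per 1-SD trait change to per order-of-magnitude.

    Divide by the SD of the log10 trait values (for the logged traits) or of
    the raw values (habitat breadth) — the SD stored by
    :func:`tradefd.traits.standardize`.
    """
    if sd_transformed == 0:
        raise ValueError("zero SD; per-magnitude rescaling undefined")
    return beta_std / sd_transformed


def volume_pct_change(beta_per_magnitude: float) -> float:
    """Percentage change in expected trade volume per order-of-magnitude
    trait increase implied by a log-link coefficient."""
    return 100.0 * float(np.expm1(beta_per_magnitude))


_PRESENCE_STATS = ("mean", "zero_frac")
_VOLUME_STATS = ("mean", "max", "dispersion")


def _stat(name: str, y: np.ndarray) -> float:
    if name == "mean":
        return float(np.mean(y))
    if name == "zero_frac":
        return float(np.mean(y == 0))
    if name == "max":
        return float(np.max(y))
    if name == "dispersion":
        m = float(np.mean(y))
        return float(np.var(y, ddof=1) / m) if m > 0 else np.nan
    raise ValueError(f"unknown statistic {name!r}")


def posterior_predictive_check(
    fit: FitResult,
    stats: Sequence[str] | None = None,
    n_rep: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate replicate responses from the posterior and compare summary
    statistics with the observed data.

    Reports, per statistic, the observed value, the replicate mean, and the
    upper-tail probability P(replicate >= observed); values near 0 or 1
    indicate a systematic discrepancy.  A constant observed response is
    flagged as degenerate.
    """
    d = fit._design
    if d is None or fit._raw is None:
        raise ValueError("fit carries no design; cannot simulate replicates")
    if stats is None:
        stats = _PRESENCE_STATS if d.family == "bernoulli" else _VOLUME_STATS
    y = d.y
    degenerate = bool(y.min() == y.max())
    rng = np.random.default_rng(seed)
    flat = fit._raw.reshape(-1, fit._raw.shape[-1])
    take = rng.choice(flat.shape[0], size=min(n_rep, flat.shape[0]), replace=False)
    p = d.n_fixed
    rows = {name: [] for name in stats}
    for t in take:
        theta = flat[t]
        eta = d.eta(theta[:p], theta[p : p + d.n_u])
        if d.family == "bernoulli":
            y_rep = rng.binomial(1, expit(eta))
        else:
            phi = float(np.exp(-theta[-1]))
            mu = np.exp(np.clip(eta, -30, 30))
            y_rep = rng.poisson(rng.gamma(phi, mu / phi))
        for name in stats:
            rows[name].append(_stat(name, y_rep))
    out = []
    for name in stats:
        reps = np.asarray(rows[name], dtype=float)
        obs = _stat(name, y)
        out.append(
            {
                "stat": name,
                "observed": obs,
                "rep_mean": float(np.nanmean(reps)),
                "p_tail": float(np.nanmean(reps >= obs)),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(out).set_index("stat")
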