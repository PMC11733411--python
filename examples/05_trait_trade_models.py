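"""Hierarchical trait-trade models: presence, volume, and rescaling.

Simulates a pool whose trade presence depends on body mass (beta = 0.8 per
SD) and whose volumes depend on clutch size (beta = 0.3 per SD), fits the
Bernoulli and negative-binomial models, and converts the coefficients to
per-order-of-magnitude effects and percentage volume changes.
"""

import dataclasses
import warnings

from tradefd import (
    fit_presence,
    fit_volume,
    gen_ledger,
    gen_pool,
    posterior_predictive_check,
    prepare_volume_rows,
    rescale_per_magnitude,
    species_year_table,
    standardize,
    volume_pct_change,
)
from tradefd.synth import scaled_config

warnings.filterwarnings("ignore", category=RuntimeWarning)

cfg = dataclasses.replace(scaled_config(600, seed=1), years=(2000, 2006))
pool = gen_pool(cfg)
ledger = gen_ledger(pool, cfg)
std = standardize(pool.truth)
taxon = pool.truth["taxon_group"]

data = species_year_table(ledger.volumes.T, std, "body_mass", taxon)
fit = fit_presence(data, seed=2)
lo, hi = fit.interval("z")
print(f"presence model (body mass): beta = {fit.coef('z'):.2f} "
      f"[{lo:.2f}, {hi:.2f}] per SD; direction certain: {fit.direction_certain['z']}; "
      f"max Rhat {fit.max_rhat:.3f}")
per_mag = rescale_per_magnitude(fit.coef("z"), std.meta["body_mass"]["sd"])
print(f"  = {per_mag:.2f} change in log odds of being traded per 10x body mass")

vol_rows = prepare_volume_rows(species_year_table(ledger.volumes.T, std, "clutch_size", taxon))
fitv = fit_volume(vol_rows, seed=3)
lo, hi = fitv.interval("z")
print(f"\nvolume model (clutch size, {len(vol_rows)} traded rows): "
      f"beta = {fitv.coef('z'):.2f} [{lo:.2f}, {hi:.2f}] per SD; "
      f"NB shape {fitv.coef('nb_shape'):.2f}")
pm = rescale_per_magnitude(fitv.coef("z"), std.meta["clutch_size"]["sd"])
print(f"  = {volume_pct_change(pm):.1f}% change in expected volume per 10x clutch size")

ppc = posterior_predictive_check(fitv, seed=4)
print("\nposterior predictive check (tail probabilities near 0 or 1 would "
      "flag misfit):")
print(ppc.round(3))
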