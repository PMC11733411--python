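"""Build the PCA functional space and choose the number of axes.

The quality table reports, per candidate dimensionality, the cumulative
variance explained and the mean squared deviation (MSD) between full
trait-space and reduced-space pairwise distances; the usual choice is the
smallest m combining high variance with low MSD.
"""

from tradefd import build_space, gen_pool, space_quality, standardize
from tradefd.synth import scaled_config

pool = gen_pool(scaled_config(500, seed=3, missingness={}))
std = standardize(pool.truth)

quality = space_quality(std, m_candidates=(1, 2, 3, 4))
print("axis-count diagnostics (cumulative % variance, distance MSD):")
print(quality.round(4))

space = build_space(std, m=3)
print(f"\n3-axis space: {space.cumulative_var_pct():.2f}% of variance, "
      f"pool hull volume {space.pool_volume:.2f}")
print("\ntrait loadings on the kept axes (sign fixed so the dominant trait "
      "loads positively):")
print(space.loadings.round(3))
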