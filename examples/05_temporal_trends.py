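"""Temporal trend smoothers and rank tests on subsection-1 series."""

import numpy as np

import isobeak as ib

rng = np.random.default_rng(3)

# corrected d13C of the first beak subsection across sampling years, with a
# deliberate decline after ~1990 (the kind of signal the smoother flags)
years = np.repeat(np.array([1900, 1930, 1977, 2004, 2014, 2019]), 8)
signal = np.where(years < 1990, -17.3, -17.3 - 0.015 * (years - 1990))
d13c = signal + rng.normal(0, 0.25, years.size)

fit = ib.fit_smoother(years, d13c, n_perm=999, seed=0, response="d13c_sub1")
print(f"selected basis dimension k={fit.k}, edf={fit.edf:.2f}")
print(f"intercept {fit.intercept:.2f} +/- {fit.intercept_se:.2f} permil")
print(f"deviance explained {100 * fit.deviance_explained:.1f}%, "
      f"permutation p = {fit.p_smooth:.4f}")

# the same comparison as a two-group rank test with effect size
early = d13c[years <= 1930]
late = d13c[years >= 2014]
mw = ib.mann_whitney(early, late)
print(f"\nMann-Whitney early vs late: U={mw.statistic:.0f}, "
      f"p={mw.p_value:.4f}, Cohen's d={mw.effect_size:.2f}")

print("\nA small permutation p for the smooth term and a significant U test "
      "both indicate a real temporal change in baseline-corrected d13C, "
      "i.e. an ecological signal not explained by the Suess decline.")
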