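"""Bayesian isotopic niches: size, directional overlap, categories."""

import numpy as np

import isobeak as ib

rng = np.random.default_rng(0)

# two synthetic groups in (corrected d13C, TP) space: a historical niche and
# a wider contemporary one shifted towards higher trophic position
historical = rng.multivariate_normal([-17.5, 3.9], [[0.20, 0.02],
                                                    [0.02, 0.05]], size=60)
contemporary = rng.multivariate_normal([-17.1, 4.2], [[0.45, 0.05],
                                                      [0.05, 0.12]], size=60)

post_h = ib.fit_niche_posterior(historical, n_draws=1000, seed=1,
                                label="historical")
post_c = ib.fit_niche_posterior(contemporary, n_draws=1000, seed=2,
                                label="contemporary")

for post in (post_h, post_c):
    size = ib.niche_size_distribution(post)
    print(f"{post.label:12s} 95% niche area: {size['mean']:.2f} "
          f"(95% CI {size['q025']:.2f}-{size['q975']:.2f}) permil x TP")

p_hc, p_ch = ib.overlap_probability(post_h, post_c, n_mc=2000, seed=3)
for name, p in (("historical->contemporary", p_hc),
                ("contemporary->historical", p_ch)):
    cat = ib.categorize_overlap(p)
    print(f"overlap {name}: {p:.2f} ({cat.value})")

print("\nThe directional overlap is the probability that a random member of "
      "one niche falls inside the other's 95% region; the narrow historical "
      "niche is largely contained in the wide contemporary one, but not "
      "vice versa.  Only 'large' (>= 0.61) counts as significant overlap.")
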