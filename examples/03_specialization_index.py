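"""Individual specialization from within- vs among-individual variance."""

import pandas as pd

import isobeak as ib
from isobeak.io import (corrected_frame, specimens_from_frame,
                        subsections_from_frame)

# simulate one time series, run the correction pipeline, then compute s
params = ib.PopulationParams(time_series="1970s", year=1977, n_individuals=8,
                             n_subsections_range=(10, 14))
data = ib.generate_population(params, seed=42)

frames = []
for sp in specimens_from_frame(data.beaks):
    subs = subsections_from_frame(data.subsections, sp.individual_id)
    frames.append(corrected_frame(ib.correct_profile(sp, subs), sp))
corrected = pd.concat(frames, ignore_index=True)

tab = ib.specialization_table(corrected)
summary = tab.groupby("metric")["s"].agg(["mean", "min", "max"])
print(summary.round(3))

s_true = ib.true_specialization(params.sigma_between_d13c,
                                params.sigma_within_d13c)
print(f"\ns = 1 means the individual spans the population's whole isotopic "
      f"breadth (generalist); s -> 0 an extreme specialist.  The generator's "
      f"detrended ground truth for d13C here is s_true = {s_true:.2f}; the "
      f"ontogenetic trend inflates the estimated within-individual variance, "
      f"so estimates sit above it.")
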