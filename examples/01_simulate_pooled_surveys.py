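"""Generate a synthetic pooled multi-survey dataset of girls' cut status.

Builds a 6x6 contiguity lattice (36 regions, national scale), draws true
spatial/smooth/fixed effects from the generative priors, and forward-
simulates girls nested within mothers across six survey rounds.
"""

import numpy as np

from geoadditive import draw_truth, make_lattice_graph, simulate_dataset

graph = make_lattice_graph(6, 6)
truth = draw_truth(graph, seed=1)
data = simulate_dataset(truth, graph, n_mothers=3000, seed=2)

print(f"{len(data)} girls from {data['mother_id'].nunique()} mothers "
      f"across {data['state'].nunique()} regions and {sorted(data['year'].unique())}")
print(f"overall prevalence: {data['fgm'].mean():.3f} "
      "(the stated world targets ~0.2, the national scale of the application)")
print(f"true structured spatial effect: sd {truth.f_str.std():.2f} on the logit scale")
print()
print(data.head(5).to_string())
# Each row is one girl: binary cut status, region, survey round, and her
# mother's covariates (shared between sisters, which is what makes the data
# clustered rather than iid).
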