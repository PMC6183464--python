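"""Environmental correlates of introgression: GLMM fits and AICc averaging.

Simulates per-fish introgression flags driven by known covariate effects
(+0.5 temperature, -0.5 pH on the logit scale, site random intercept),
fits the four standard candidate covariate sets with the random-intercept
logistic model, and averages the top two models by Akaike weight.
"""

import numpy as np
import pandas as pd

from hatchtrace import compare_and_average, fit_candidate_models

rng = np.random.default_rng(8)
n_sites, n_fish = 30, 50
cols = ["temperature", "dissolved_oxygen", "pH", "stream_width",
        "adult_density", "watershed_area", "distance_to_stocking"]
cov = pd.DataFrame(rng.normal(size=(n_sites, len(cols))), columns=cols,
                   index=pd.Index([f"site{j:02d}" for j in range(n_sites)],
                                  name="site"))
cov = (cov - cov.mean()) / cov.std(ddof=1)
u = rng.normal(0, 0.5, n_sites)
rows = []
for j, s in enumerate(cov.index):
    eta = -2.0 + 0.5 * cov.loc[s, "temperature"] - 0.5 * cov.loc[s, "pH"] + u[j]
    for v in rng.random(n_fish) < 1 / (1 + np.exp(-eta)):
        rows.append({"site": s, "introgressed": int(v)})
data = pd.DataFrame(rows)

models = fit_candidate_models(data, cov.reset_index())
comparison = compare_and_average(models, average_top=2)
print(comparison.table.round(3).to_string(), "\n")
print("consensus (Akaike-weight averaged) coefficients:")
print(comparison.consensus.round(3).to_string())
print("\nCIs covering zero mean the data cannot pin down the effect —")
print("expected when introgression is rare and site-level replication low.")
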