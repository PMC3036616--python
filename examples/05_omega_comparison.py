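"""Bayesian constant-omega comparison between sympatric and allopatric samples.

Runs two seeded MCMC chains per population under the calibrated pairwise
composite likelihood, combines them after the agreement check, and summarizes
the posterior distribution of the omega difference.  (Chains here are short
for a quick demonstration; defaults are 250,000 iterations thinned by 1,000.)
"""

from dataclasses import replace

import numpy as np

from rcdkit import omega
from rcdkit.synthetic import SyntheticConfig, generate_gene_dataset

g = generate_gene_dataset(SyntheticConfig(), "GRP", seed=41, gene_name="demo")
cfg = omega.MCMCConfig(iterations=2000, thinning=5, burn_in_fraction=0.25)

samples = {}
for name in ("sympatric_A", "allopatric_A"):
    r1 = omega.run_mcmc(g.populations[name], replace(cfg, seed=1), run_id=f"{name}_1")
    r2 = omega.run_mcmc(g.populations[name], replace(cfg, seed=2), run_id=f"{name}_2")
    combined = omega.combine_runs(r1, r2, tolerance=1.0)
    samples[name] = combined.sample if combined.ok else r1
    med = np.median(samples[name].omega)
    lo, hi = np.percentile(samples[name].omega, [2.5, 97.5])
    print(f"{name}: posterior omega median {med:.2f}, 95% CrI ({lo:.2f}, {hi:.2f})"
          f" [runs {'combined' if combined.ok else 'NOT combined'}]")

comp = omega.posterior_difference(
    samples["sympatric_A"], samples["allopatric_A"], seed=3
)
print(f"\nomega difference (sympatric - allopatric): mean {comp.mean_diff:.2f}, "
      f"95% CrI ({comp.cri_low:.2f}, {comp.cri_high:.2f})")
print("verdict:", "not significant (CrI contains 0)" if comp.contains_zero
      else "significant (CrI excludes 0)")
print(
    "Both samples share the same true omega here, so the credible interval of "
    "the difference should contain zero — the battery's second headline result."
)
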