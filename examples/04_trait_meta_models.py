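"""Do species traits explain who is temperature-sensitive?

Weighted least squares (weights 1/SD of onset date) of sensitivity on
voltinism, mean onset date and their interaction, with marginal
(Type III) tests, nested model comparison, and a taxonomic
variance-components decomposition.  Uses the full-size default study
(38 species, 1993-2020) so the meta-models have realistic power.
"""

import numpy as np

from flightline import (
    SimulationConfig,
    apply_inclusion,
    build_series,
    compare_models,
    deduplicate,
    estimate_onset,
    fit_sensitivities,
    fit_trait_models,
    meta_table,
    onset_table,
    simulate,
    spring_index,
    type3_anova,
    variance_components,
)

config = SimulationConfig(seed=11)
ds = simulate(config)
keys, _ = deduplicate(ds.records, counties=config.counties)
kept, _ = apply_inclusion(build_series(keys, year_range=config.years))
onsets = onset_table([estimate_onset(s) for s in kept])
spring = spring_index(ds.climate, counties=config.counties)
fits = fit_sensitivities(onsets, spring)

meta = meta_table(fits, ds.traits)
models = fit_trait_models(meta)

print("Type III tests, voltinism x mean-onset interaction model:")
print(type3_anova(models["interaction"]).round(4).to_string(index=False))
print()
f, df1, df2, p = compare_models(models["voltinism_only"], models["interaction"])
print(f"interaction model vs voltinism alone: F({df1},{df2:.0f}) = {f:.2f}, p = {p:.4f}")
f, df1, df2, p = compare_models(models["additive"], models["interaction"])
print(f"interaction model vs additive:        F({df1},{df2:.0f}) = {f:.2f}, p = {p:.4f}")
print()
vc = variance_components(meta)
pct = vc.percentages()
print("taxonomic variance shares (% of sensitivity variance):")
for level, share in pct.items():
    print(f"  {level:<10} {share:6.1f}")
print(f"  genus or below: {vc.pct_genus_or_below:.1f}%")
print()
print("The simulator plants a voltinism x mean-onset interaction in the\n"
      "sensitivities: late-emerging, multivoltine species respond most.\n"
      "A single 38-species study has limited power for a moderate planted\n"
      "effect, so the interaction term is not always significant in one\n"
      "draw; the mean-onset signal and the nested model comparison usually\n"
      "are. The test suite quantifies the error rates over hundreds of\n"
      "replicate studies.")
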