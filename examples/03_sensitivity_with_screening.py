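"""Phenological sensitivity with Cook's-distance outlier screening.

Regresses onset day on the March-June spring-temperature index for each
species.  Species-years whose Cook's distance on the initial fit exceeds
4/n — typically years distorted by a mass survey burst — are removed and
the model refit once; the refit slope is the sensitivity in days/degC.
"""

from flightline import (
    SimulationConfig,
    apply_inclusion,
    build_series,
    deduplicate,
    estimate_onset,
    fit_sensitivities,
    onset_table,
    simulate,
    spring_index,
)

config = SimulationConfig(seed=11, n_species=12, years=(2000, 2014), n_genera=12)
ds = simulate(config)

keys, _ = deduplicate(ds.records, counties=config.counties)
kept, _ = apply_inclusion(build_series(keys, year_range=config.years))
onsets = onset_table([estimate_onset(s) for s in kept])
spring = spring_index(ds.climate, counties=config.counties)

fits = fit_sensitivities(onsets, spring, predictor="temperature")
fits = fits.merge(ds.truth.species[["species", "beta"]], on="species")
cols = ["species", "slope", "beta", "r_squared", "p_value", "n_used", "n_removed"]
print(fits[cols].round(3).to_string(index=False))
print()
err = fits["slope"] - fits["beta"]
print(f"mean |slope - planted beta|: {err.abs().mean():.2f} days/degC")
print(f"species-years removed as influential: {int(fits['n_removed'].sum())}")
print()
print("Negative slopes mean earlier flight in warmer springs; 'beta' is\n"
      "the planted truth each slope should recover.")
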