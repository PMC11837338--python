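"""From raw reports to per-species-year flight-onset dates.

Deduplicates reports into observer x date x county x species records,
applies the inclusion rules (>= 10 unique observer dates per year,
>= 10 qualifying years per species), and estimates each species-year's
onset as the day by which 10% of its records accumulated.
"""

from flightline import (
    SimulationConfig,
    apply_inclusion,
    build_series,
    deduplicate,
    estimate_onset,
    onset_table,
    simulate,
)

config = SimulationConfig(seed=11, n_species=12, years=(2000, 2014), n_genera=12)
ds = simulate(config)

keys, rejects = deduplicate(ds.records, counties=config.counties)
print(f"{len(ds.records)} raw rows -> {len(keys)} records ({len(rejects)} rejected)")

series = build_series(keys, year_range=config.years)
kept, audit = apply_inclusion(series)
print(f"{len(series)} species-years -> {len(kept)} pass inclusion "
      f"({len(audit)} dropped)")

onsets = onset_table([estimate_onset(s) for s in kept])
truth = ds.truth.onsets.set_index(["species", "year"])["true_onset"]
onsets["true_onset"] = [
    round(truth.loc[(r.species, r.year)], 1) for r in onsets.itertuples()
]
print()
print("estimated vs true onset (day of year), first species:")
first = onsets[onsets["species"] == onsets["species"].iloc[0]]
print(first[["species", "year", "onset_doy", "true_onset", "n_records"]]
      .head(8).to_string(index=False))
print()
print("The 10%-of-records day tracks the planted onset to within a few "
      "days\ndespite uneven observer effort. Occasional years estimated far "
      "too early\n(e.g. a mass-survey burst) are exactly what the downstream "
      "influence\nscreening removes.")
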