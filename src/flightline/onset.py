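"""Flight-onset estimation: the day by which a fraction q of records accrued.

The first record of the season is notoriously sensitive to stray early
reports, so onset is instead estimated as the date on which 10% of a
species-year's records had been collected.  Records are dated events, so
the estimator is discrete: the onset is always one of the observed days,
never an interpolated value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .records import SpeciesYearSeries


@dataclass(frozen=True)
class OnsetEstimate:
    species: str
    year: int
    onset_doy: int
    quantile: float
    n_records: int


def estimate_onset(
    series: SpeciesYearSeries,
    q: float = 0.10,
    rule: str = "ceil",
) -> OnsetEstimate:
    """Estimate onset as the smallest day whose cumulative record count
    reaches the q-quantile.

    ``rule="ceil"`` (default) returns the smallest day d with
    cum(d) >= ceil(q*n); ``rule="strict"`` uses the strictly-greater
    variant cum(d) > q*n, which differs only when q*n is an integer.
    Days with many records are handled automatically by the cumulative
    count; the result is always an element of the observed days.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    n = series.n_records
    if n == 0:
        raise ValueError(f"empty series for {series.species} {series.year}")
    if rule == "ceil":
        k = math.ceil(q * n)
    elif rule == "strict":
        k = math.floor(q * n) + 1
    else:
        raise ValueError(f"unknown rule: {rule!r}")
    k = max(k, 1)
    doys = sorted(series.record_doys)
    onset = doys[k - 1]
    return OnsetEstimate(
        species=series.species,
        year=series.year,
        onset_doy=int(onset),
        quantile=q,
        n_records=n,
    )


def onset_table(estimates: list[OnsetEstimate]) -> pd.DataFrame:
    """Long-format onset table (species, year, onset_doy, n_records, quantile).

    Missing species-years are simply absent.  Duplicate (species, year)
    pairs indicate an upstream bug and raise.
    """
    df = pd.DataFrame(
        [
            {
                "species": e.species,
                "year": e.year,
                "onset_doy": e.onset_doy,
                "n_records": e.n_records,
                "quantile": e.quantile,
            }
            for e in estimates
        ],
        columns=["species", "year", "onset_doy", "n_records", "quantile"],
    )
    dup = df.duplicated(subset=["species", "year"])
    if dup.any():
        pairs = df.loc[dup, ["species", "year"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate species-year estimates: {pairs}")
    return df.sort_values(["species", "year"]).reset_index(drop=True)
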