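"""Ingest and canonicalize opportunistic observation records.

Raw community-science reports (one row per observer report, with an
individual count that is deliberately ignored) are reduced to *records*:
unique combinations of observer, date, county and species.  Collapsing
counts this way limits the outsized influence of mass survey events
(BioBlitzes, organised counts), whose large tallies would otherwise skew
the apparent start of the flight season.

Input schema (``records.csv``)::

    observer_id, date, county, species, count[, source]

Dates are ISO 8601.  ``count`` and ``source`` are optional and never used
after deduplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Counties of the North Carolina Triangle study region.
DEFAULT_COUNTIES: tuple[str, ...] = ("Durham", "Orange", "Wake")

#: Columns that define a record key.
KEY_COLUMNS: tuple[str, ...] = ("observer_id", "obs_date", "county", "species")


class NoSpeciesQualifyError(ValueError):
    """Raised when inclusion filtering leaves no species at all."""


@dataclass(frozen=True)
class SpeciesYearSeries:
    """Deduplicated record days for one species in one calendar year.

    ``record_doys`` is a sorted multiset of day-of-year integers, one per
    record.  ``n_observer_dates`` counts unique (observer, date) pairs,
    the unit of the inclusion threshold; ``n_records`` counts full
    (observer, date, county, species) keys.
    """

    species: str
    year: int
    record_doys: tuple[int, ...]
    n_records: int
    n_observer_dates: int

    def __post_init__(self) -> None:
        if self.n_records != len(self.record_doys):
            raise ValueError("n_records must equal len(record_doys)")
        if self.record_doys and not (
            1 <= min(self.record_doys) and max(self.record_doys) <= 366
        ):
            raise ValueError("day-of-year values must lie in 1..366")
        if self.n_observer_dates > self.n_records:
            raise ValueError("n_observer_dates cannot exceed n_records")


def load_records(path) -> pd.DataFrame:
    """Read a raw records CSV, leaving validation to :func:`deduplicate`."""
    df = pd.read_csv(path, dtype=str)
    required = {"observer_id", "date", "county", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    return df


def apply_aliases(species: pd.Series, aliases: dict[str, str] | None) -> pd.Series:
    """Map raw species names to canonical taxa (identity where unmapped).

    Taxon merges (e.g. sibling species observers separate mainly by time
    of year) are configuration data, not code.
    """
    if not aliases:
        return species
    return species.map(lambda s: aliases.get(s, s))


def deduplicate(
    records: pd.DataFrame,
    aliases: dict[str, str] | None = None,
    counties: tuple[str, ...] = DEFAULT_COUNTIES,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce raw reports to unique (observer, date, county, species) keys.

    Parameters
    ----------
    records
        Raw table with columns ``observer_id, date, county, species`` and
        optionally ``count``/``source`` (both ignored).
    aliases
        Raw-name -> canonical-taxon map, applied before keying.
    counties
        Allowed county set; rows outside it are rejected.
    strict
        If True, any invalid row raises instead of being logged and
        collected in the rejects report.

    Returns
    -------
    (keys, rejects)
        ``keys``: one row per distinct record key, columns
        ``observer_id, obs_date, county, species``, deterministically
        sorted by species, date, county, observer.
        ``rejects``: rejected input rows with a ``reject_reason`` column.

    Notes
    -----
    A single observer reporting six individuals of one species on one
    date in one county yields one record; two observers each reporting
    one individual of the species on that date in each of three counties
    yield six records.
    """
    df = records.copy()
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad_date = parsed.isna()
    bad_county = ~df["county"].isin(counties)

    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[bad_county] = "unknown county"
    reasons[bad_date] = "unparseable date"  # date problems take precedence
    bad = bad_date | bad_county
    if bad.any():
        if strict:
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid record at row {df.index[i]}: {reasons.iloc[i]}"
            )
        for idx in df.index[bad]:
            logger.warning("rejecting record row %s: %s", idx, reasons.loc[idx])

    rejects = df.loc[bad].assign(reject_reason=reasons[bad])
    keep = df.loc[~bad].copy()
    keep["obs_date"] = parsed[~bad].dt.normalize()
    keep["species"] = apply_aliases(keep["species"], aliases)

    keys = (
        keep[list(KEY_COLUMNS)]
        .drop_duplicates()
        .sort_values(["species", "obs_date", "county", "observer_id"])
        .reset_index(drop=True)
    )
    return keys, rejects.reset_index(drop=True)


def build_series(
    keys: pd.DataFrame,
    year_range: tuple[int, int] = (1993, 2020),
) -> list[SpeciesYearSeries]:
    """Group deduplicated keys into per-species-year day-of-year series.

    Day-of-year follows the actual calendar (Jan 1 = 1, leap-aware), so
    Dec 31 is 365 or 366 depending on the year.
    """
    lo, hi = year_range
    df = keys.copy()
    df["year"] = df["obs_date"].dt.year
    df = df[(df["year"] >= lo) & (df["year"] <= hi)]
    df["doy"] = df["obs_date"].dt.dayofyear

    out: list[SpeciesYearSeries] = []
    for (species, year), grp in df.groupby(["species", "year"], sort=True):
        doys = tuple(sorted(int(d) for d in grp["doy"]))
        n_obs_dates = grp[["observer_id", "obs_date"]].drop_duplicates().shape[0]
        out.append(
            SpeciesYearSeries(
                species=str(species),
                year=int(year),
                record_doys=doys,
                n_records=len(doys),
                n_observer_dates=int(n_obs_dates),
            )
        )
    return out


def apply_inclusion(
    series: list[SpeciesYearSeries],
    min_obs_dates_per_year: int = 10,
    min_years: int = 10,
    exclusions: tuple[str, ...] = (),
    count_unit: str = "observer_dates",
) -> tuple[list[SpeciesYearSeries], pd.DataFrame]:
    """Apply the species-year and species inclusion rules.

    A species-year qualifies with at least ``min_obs_dates_per_year``
    unique observer dates; a species is retained with at least
    ``min_years`` qualifying years and if not on the (e.g. migratory)
    exclusion list.  Thresholds are inclusive ("at least").

    ``count_unit`` selects what the per-year threshold counts:
    ``"observer_dates"`` (unique observer x date pairs, the default) or
    ``"records"`` (full record keys).

    Returns the surviving series and an audit table with one row per
    dropped species-year and the drop reason.

    Raises
    ------
    NoSpeciesQualifyError
        If nothing survives — an empty result would silently propagate.
    """
    if count_unit not in ("observer_dates", "records"):
        raise ValueError(f"unknown count_unit: {count_unit!r}")

    audit_rows: list[dict] = []
    excl = set(exclusions)

    def effort(s: SpeciesYearSeries) -> int:
        return s.n_observer_dates if count_unit == "observer_dates" else s.n_records

    per_species: dict[str, list[SpeciesYearSeries]] = {}
    for s in series:
        if s.species in excl:
            audit_rows.append(
                {"species": s.species, "year": s.year, "reason": "excluded species"}
            )
            continue
        if effort(s) < min_obs_dates_per_year:
            audit_rows.append(
                {
                    "species": s.species,
                    "year": s.year,
                    "reason": f"fewer than {min_obs_dates_per_year} observer dates",
                }
            )
            continue
        per_species.setdefault(s.species, []).append(s)

    kept: list[SpeciesYearSeries] = []
    for species in sorted(per_species):
        years = per_species[species]
        if len(years) < min_years:
            for s in years:
                audit_rows.append(
                    {
                        "species": s.species,
                        "year": s.year,
                        "reason": f"species has fewer than {min_years} qualifying years",
                    }
                )
            continue
        kept.extend(sorted(years, key=lambda s: s.year))

    audit = pd.DataFrame(audit_rows, columns=["species", "year", "reason"])
    for row in audit.itertuples(index=False):
        logger.info("dropped %s %s: %s", row.species, row.year, row.reason)
    if not kept:
        raise NoSpeciesQualifyError(
            "no species qualify under the inclusion thresholds"
        )
    return kept, audit


def series_summary(
    series: list[SpeciesYearSeries],
    audit: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format summary (one row per species-year) for ``series_summary.csv``."""
    rows = [
        {
            "species": s.species,
            "year": s.year,
            "n_records": s.n_records,
            "n_observer_dates": s.n_observer_dates,
            "included": True,
            "exclusion_reason": "",
        }
        for s in series
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "species",
            "year",
            "n_records",
            "n_observer_dates",
            "included",
            "exclusion_reason",
        ],
    )
    if audit is not None and len(audit):
        dropped = audit.rename(columns={"reason": "exclusion_reason"}).assign(
            included=False, n_records=pd.NA, n_observer_dates=pd.NA
        )
        df = pd.concat([df, dropped], ignore_index=True)
    return df.sort_values(["species", "year"]).reset_index(drop=True)
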