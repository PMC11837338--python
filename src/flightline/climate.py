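"""Spring temperature index: March-June monthly means averaged over counties.

A static 4-month window captures the span of spring conditions relevant
to adult emergence across both early- and late-flying species.  Months
and counties are equally weighted; when every county has all window
months, the index equals the grand mean of the county x month cells.

Input schema (``climate.csv``)::

    county, year, month, mean_temp_c
"""

from __future__ import annotations

import pandas as pd

from .records import DEFAULT_COUNTIES

DEFAULT_MONTHS: tuple[int, ...] = (3, 4, 5, 6)


def spring_index(
    climate: pd.DataFrame,
    years: list[int] | None = None,
    months: tuple[int, ...] = DEFAULT_MONTHS,
    counties: tuple[str, ...] = DEFAULT_COUNTIES,
    missing: str = "strict",
) -> pd.DataFrame:
    """Annual spring-temperature index.

    Per year: unweighted mean of the window months within each county,
    then unweighted mean across counties.

    Parameters
    ----------
    climate
        Table with columns ``county, year, month, mean_temp_c``, at most
        one row per (county, year, month).
    years
        Years to index; defaults to all years present.
    missing
        ``"strict"`` (default) raises naming the first missing
        (county, year, month) cell; ``"allow"`` averages whatever cells
        exist and reports ``n_months_used``/``n_counties_used``.

    Returns
    -------
    DataFrame with columns ``year, temp_c, n_months_used, n_counties_used``.
    """
    if missing not in ("strict", "allow"):
        raise ValueError(f"unknown missing-data policy: {missing!r}")

    df = climate.copy()
    dup = df.duplicated(subset=["county", "year", "month"])
    if dup.any():
        cell = df.loc[dup, ["county", "year", "month"]].iloc[0]
        raise ValueError(
            f"duplicate climate cell: {cell.county} {cell.year}-{cell.month:02d}"
        )
    df = df[df["county"].isin(counties) & df["month"].isin(months)]
    if years is None:
        years = sorted(df["year"].unique())

    rows = []
    for year in years:
        sub = df[df["year"] == year]
        county_means = []
        months_seen: set[int] = set()
        for county in counties:
            cells = sub[sub["county"] == county]
            if missing == "strict":
                absent = set(months) - set(cells["month"])
                if absent:
                    m = min(absent)
                    raise ValueError(
                        f"missing climate cell: {county} {year}-{m:02d}"
                    )
            if len(cells) == 0:
                continue
            county_means.append(cells["mean_temp_c"].mean())
            months_seen.update(int(m) for m in cells["month"])
        if not county_means:
            if missing == "strict":
                raise ValueError(f"no climate cells for year {year}")
            continue
        rows.append(
            {
                "year": int(year),
                "temp_c": float(sum(county_means) / len(county_means)),
                "n_months_used": len(months_seen),
                "n_counties_used": len(county_means),
            }
        )
    return pd.DataFrame(
        rows, columns=["year", "temp_c", "n_months_used", "n_counties_used"]
    )
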