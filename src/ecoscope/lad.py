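"""Lineage abundance distribution (LAD) analysis.

Occurrence/abundance summaries per lineage, the core-satellite occupancy
classification (core: detected in more than 90 libraries; satellite: fewer
than 50), and the index-of-dispersion test against chi-square confidence
limits that separates randomly (Poisson) distributed lineages from
aggregated ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import AbundanceTable, TaxonomyMap, to_relative

__all__ = [
    "FilterResult",
    "filter_libraries",
    "aggregate_to_lineages",
    "occurrence_and_abundance",
    "occurrence_rate_percent",
    "classify_core_satellite",
    "DispersionRecord",
    "dispersion_test",
    "dispersion_boundary",
    "lad_table",
]


class FilterResult(NamedTuple):
    table: AbundanceTable
    removed: tuple


def filter_libraries(table: AbundanceTable, min_sequences: int = 10) -> FilterResult:
    """Drop libraries with fewer than ``min_sequences`` total counts (strict <).

    Returns the filtered table together with the removal log.  Raises when
    nothing survives.
    """
    if table.mode != "counts":
        raise ValueError("library filtering applies to counts-mode tables")
    totals = table.row_totals()
    keep = totals >= min_sequences
    removed = tuple(str(i) for i in table.data.index[~keep])
    if not keep.any():
        raise ValueError("library filter removed every library")
    return FilterResult(
        AbundanceTable(data=table.data.loc[keep], mode="counts"), removed
    )


def aggregate_to_lineages(table: AbundanceTable, taxonomy: TaxonomyMap) -> AbundanceTable:
    """Sum taxon (OTU) columns into lineage columns using the taxonomy map."""
    lineages = [taxonomy.lineage_of(t) for t in table.taxa]
    agg = table.data.T.groupby(pd.Index(lineages, name="lineage"), sort=False).sum().T
    return AbundanceTable(data=agg, mode=table.mode)


def occurrence_and_abundance(
    table: AbundanceTable, taxonomy: TaxonomyMap | None = None
) -> pd.DataFrame:
    """Per-lineage occurrence and mean relative abundance (percent).

    Occurrence n counts libraries where the lineage is detected; the mean
    (and variance) of relative abundance are taken over those n libraries
    only.  Lineages absent everywhere get n = 0 and NaN moments (flagged).
    Requires a relative-mode table; pass a taxonomy to aggregate OTU columns
    first.
    """
    if taxonomy is not None:
        table = aggregate_to_lineages(table, taxonomy)
    if table.mode != "relative":
        raise ValueError("occurrence/abundance summaries need a relative-mode table")
    pct = table.data * 100.0
    rows = []
    for lineage in pct.columns:
        vals = pct[lineage].to_numpy()
        occupied = vals[vals > 0]
        n = int(len(occupied))
        rows.append(
            {
                "lineage": lineage,
                "occurrence": n,
                "mean_abundance_pct": float(occupied.mean()) if n else np.nan,
                "var_abundance_pct": float(occupied.var(ddof=1)) if n >= 2 else np.nan,
                "absent": n == 0,
            }
        )
    return pd.DataFrame(rows).set_index("lineage")


def occurrence_rate_percent(n_occupied: int, n_libraries: int, ndigits: int = 0) -> float:
    """Occurrence rate as a percentage, rounded as conventionally printed.

    116 of 133 libraries -> 87; 110 of 133 -> 83.
    """
    if n_libraries <= 0:
        raise ValueError("n_libraries must be positive")
    rate = round(100.0 * n_occupied / n_libraries, ndigits)
    return rate if ndigits > 0 else float(int(rate))


def classify_core_satellite(
    occurrence: pd.Series | pd.DataFrame, core_min: int = 90, satellite_max: int = 50
) -> pd.Series:
    """Label lineages core (n > core_min), satellite (n < satellite_max), else intermediate."""
    if satellite_max > core_min:
        raise ValueError("satellite_max must be <= core_min")
    n = occurrence["occurrence"] if isinstance(occurrence, pd.DataFrame) else occurrence
    return pd.Series(
        np.where(n > core_min, "core", np.where(n < satellite_max, "satellite", "intermediate")),
        index=n.index,
        name="class",
    )


@dataclass(frozen=True)
class DispersionRecord:
    lineage: str
    occurrence: int
    mean: float                  # mean relative abundance (%) over occupied libraries
    variance: float
    dispersion: float            # D = s^2 / mean
    statistic: float             # D * (n - 1), compared to chi-square(n - 1)
    lower: float                 # chi-square 2.5% quantile (df = n - 1)
    upper: float                 # chi-square 97.5% quantile
    region: str                  # below | within | above | untestable
    call: str                    # random | non-random | untestable


def dispersion_boundary(n: int, tail: str = "upper", alpha_tail: float = 0.025) -> float:
    """Chi-square confidence limit for the dispersion index at occurrence n.

    The boundary curve B(n) drawn through an occurrence-vs-dispersion
    diagram; ``tail`` selects the lower (alpha) or upper (1 - alpha)
    quantile, both divided by n - 1 so they are on the D scale.
    """
    if n < 2:
        raise ValueError("boundary undefined for n < 2")
    q = alpha_tail if tail == "lower" else 1.0 - alpha_tail
    return float(stats.chi2.ppf(q, n - 1) / (n - 1))


def dispersion_test(
    values,
    lineage: str = "",
    alpha_tail: float = 0.025,
    strict_two_sided: bool = False,
) -> DispersionRecord:
    """Index-of-dispersion test of the Poisson (random placement) hypothesis.

    ``values`` are a lineage's abundances over the libraries where it was
    detected.  D = s^2 / mean; the statistic D (n - 1) is referred to the
    chi-square distribution with n - 1 degrees of freedom.  Above the upper
    confidence limit the lineage is aggregated ("non-random").  By default
    everything at or below that limit is "random" (lineages falling below
    the limit line are randomly dispersed); ``strict_two_sided`` restricts
    "random" to the central [alpha, 1 - alpha] interval, the calibrated
    two-sided Poisson-consistency rule.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[vals > 0]
    n = len(vals)
    if n < 2:
        return DispersionRecord(
            lineage, n, float(vals.mean()) if n else np.nan, np.nan,
            np.nan, np.nan, np.nan, np.nan, "untestable", "untestable",
        )
    mean = float(vals.mean())
    var = float(vals.var(ddof=1))
    D = var / mean
    statistic = D * (n - 1)
    lower = float(stats.chi2.ppf(alpha_tail, n - 1))
    upper = float(stats.chi2.ppf(1.0 - alpha_tail, n - 1))
    if statistic > upper:
        region = "above"
    elif statistic < lower:
        region = "below"
    else:
        region = "within"
    if region == "above":
        call = "non-random"
    elif region == "within":
        call = "random"
    else:
        call = "under-dispersed" if strict_two_sided else "random"
    return DispersionRecord(
        lineage, n, mean, var, float(D), float(statistic), lower, upper, region, call
    )


def lad_table(
    table: AbundanceTable,
    taxonomy: TaxonomyMap | None = None,
    core_min: int = 90,
    satellite_max: int = 50,
    alpha_tail: float = 0.025,
    strict_two_sided: bool = False,
) -> pd.DataFrame:
    """Full LAD summary: occurrence, moments, dispersion test, and class per lineage.

    Counts-mode input is converted to relative abundances first.
    """
    if table.mode == "counts":
        table = to_relative(table)
    if taxonomy is not None:
        table = aggregate_to_lineages(table, taxonomy)
    pct = table.data * 100.0
    records = []
    for lineage in pct.columns:
        rec = dispersion_test(
            pct[lineage].to_numpy(), lineage=lineage,
            alpha_tail=alpha_tail, strict_two_sided=strict_two_sided,
        )
        records.append(rec.__dict__)
    df = pd.DataFrame(records).set_index("lineage")
    df["class"] = classify_core_satellite(
        df["occurrence"], core_min=core_min, satellite_max=satellite_max
    )
    return df
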