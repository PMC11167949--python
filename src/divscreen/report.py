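"""Summary tables: category counts, per-chromosome shares, set overlaps.

Every percentage cell is stored together with its numerator and denominator
and rounded to two decimals with half-up rounding, so each printed figure can
be audited from the table itself.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

SUMMARY_COLUMNS = ["name", "numerator", "denominator", "percent"]


class ConsistencyError(ValueError):
    pass


def percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator rounded half-up to two decimals."""
    if denominator == 0:
        return 0.0
    frac = Decimal(100) * Decimal(int(numerator)) / Decimal(int(denominator))
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def audit(table: pd.DataFrame) -> None:
    """Re-derive every percentage cell from its stored counts; raise on drift."""
    for row in table.itertuples(index=False):
        expect = percent(row.numerator, row.denominator)
        if row.percent != expect:
            raise ConsistencyError(
                f"cell {row.name!r}: stored {row.percent} != recomputed {expect}"
            )


def _row(name: str, num: int, den: int) -> tuple:
    return (name, int(num), int(den), percent(num, den))


def category_summary(
    category_counts: Mapping[str, int], total_snp_count: int
) -> pd.DataFrame:
    """Counts and percentages of total for each category and their unions.

    ``category_counts`` maps category names (A_SPECIFIC, A_PREDOMINANT,
    B_SPECIFIC, B_PREDOMINANT) to SNP counts; ``total_snp_count`` is the
    post-filter SNP total.  Adds combined rows per focal population
    (specific + predominant) and across both.
    """
    for name, count in category_counts.items():
        if count > total_snp_count:
            raise ConsistencyError(
                f"category {name} count {count} exceeds total {total_snp_count}"
            )
    rows = [
        _row(name, category_counts.get(name, 0), total_snp_count)
        for name in ("A_SPECIFIC", "A_PREDOMINANT", "B_SPECIFIC", "B_PREDOMINANT")
    ]
    comb_a = category_counts.get("A_SPECIFIC", 0) + category_counts.get("A_PREDOMINANT", 0)
    comb_b = category_counts.get("B_SPECIFIC", 0) + category_counts.get("B_PREDOMINANT", 0)
    rows.append(_row("A_COMBINED", comb_a, total_snp_count))
    rows.append(_row("B_COMBINED", comb_b, total_snp_count))
    rows.append(_row("ALL_COMBINED", comb_a + comb_b, total_snp_count))
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    audit(table)
    return table


def per_chromosome_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome share of each category (percent of the category total)."""
    rows = []
    for category, sub in classified.groupby("category", sort=True):
        total = len(sub)
        for chrom, chrom_sub in sub.groupby("chrom", sort=True):
            rows.append(_row(f"{category}:{chrom}", len(chrom_sub), total))
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    audit(table)
    return table


def overlap_report(gene_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Intersection/union counts for every combination of named gene sets.

    Duplicate identifiers within a set are dropped (their count is recorded in
    ``df.attrs["n_duplicates"]``).  Returns one row per non-empty combination
    of set names with the intersection count/members, the count of elements
    *exclusive* to that combination (the Venn region), and one union row.
    Inclusion-exclusion holds exactly: the exclusive counts sum to the union.
    """
    cleaned: dict[str, set[str]] = {}
    n_dup = 0
    for name, members in gene_sets.items():
        members = list(members)
        s = set(members)
        n_dup += len(members) - len(s)
        cleaned[name] = s
    names = list(cleaned)
    universe = set().union(*cleaned.values()) if cleaned else set()
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(cleaned[n] for n in combo))
            others = set().union(*(cleaned[n] for n in names if n not in combo)) if k < len(names) else set()
            exclusive = inter - others
            rows.append(
                (
                    "&".join(combo),
                    len(inter),
                    len(exclusive),
                    ",".join(sorted(inter)),
                )
            )
    rows.append(("UNION", len(universe), len(universe), ",".join(sorted(universe))))
    df = pd.DataFrame(rows, columns=["sets", "intersection", "exclusive", "members"])
    df.attrs["n_duplicates"] = n_dup
    return df
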