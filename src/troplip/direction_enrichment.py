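"""Direction-aware Fisher over-representation tests.

The headline question: is a pathway over-represented among the genes moving
in one direction (e.g. down in disease) relative to the rest of the tested
transcriptome?  The 2×2 table is

    a = pathway genes in the direction      b = pathway genes not
    c = background genes in the direction   d = background genes not

with the background *excluding* the pathway genes, the sample odds ratio
a·d / (b·c) (Haldane–Anscombe 0.5 correction only when a zero cell would
make it undefined, and only for the OR — the exact p always uses the raw
table), and a one-sided (greater) Fisher exact p.  The same machinery
serves cross-dataset DEG-overlap tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .diffexp import benjamini_hochberg
from .errors import DataError
from .io_formats import GeneSetCollection


@dataclass
class ContingencyTable:
    """2×2 counts; background excludes the pathway by construction."""

    a: int   # pathway genes in direction
    b: int   # pathway genes not in direction
    c: int   # background genes in direction
    d: int   # background genes not in direction
    label: str = ""
    excludes_pathway: bool = True

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise DataError(f"cell {name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def pathway_size(self) -> int:
        return self.a + self.b


@dataclass
class DirectionEnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    p: float
    or_corrected: bool = False
    padj: float | None = None

    @property
    def label(self) -> str:
        return self.table.label


def fisher_odds_ratio(table: ContingencyTable) -> DirectionEnrichmentResult:
    """Sample OR and one-sided (greater) Fisher exact p for one table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return DirectionEnrichmentResult(table, float(orr), float(p), corrected)


def build_direction_contingency(
    pathway: list[str],
    universe: list[str],
    in_direction,
    label: str = "",
) -> ContingencyTable:
    """Count pathway vs background genes moving in the chosen direction.

    ``in_direction`` is either a boolean per-gene Series indexed by gene or
    a set of gene ids in the direction.  Pathway members outside the tested
    universe are dropped (they cannot be counted); an empty pathway after
    restriction is an error.
    """
    uni = set(universe)
    members = [g for g in pathway if g in uni]
    if not members:
        raise DataError(f"pathway {label or '<unnamed>'} has no tested members")
    if isinstance(in_direction, pd.Series):
        moving = set(in_direction.index[in_direction.astype(bool)])
    else:
        moving = set(in_direction)
    moving &= uni
    member_set = set(members)
    a = len(member_set & moving)
    b = len(member_set) - a
    c = len(moving - member_set)
    d = len(uni) - len(member_set) - c
    return ContingencyTable(a, b, c, d, label=label)


def pathway_direction_tests(
    sets: GeneSetCollection,
    de: pd.DataFrame,
    direction: str = "down",
    use_significance: bool = False,
    lfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """Run the direction OR test for every pathway, BH across pathways.

    By default direction membership is the *sign* of the log2 fold change
    (any gene with log2FC below −``lfc_threshold`` counts as down), which
    mirrors "lower expression" irrespective of significance.  With
    ``use_significance=True`` the thresholded ``direction`` flag from the
    DE table is used instead.
    """
    if direction not in ("up", "down"):
        raise DataError("direction must be 'up' or 'down'")
    universe = list(de.index[~de["log2fc"].isna()])
    sub = de.loc[universe]
    if use_significance:
        moving = set(sub.index[sub["direction"] == direction])
    else:
        sign = 1.0 if direction == "up" else -1.0
        moving = set(sub.index[sign * sub["log2fc"] > lfc_threshold])

    rows = []
    for name, members in sets:
        kept = [g for g in members if g in de.index]
        if not kept:
            continue
        tab = build_direction_contingency(kept, universe, moving, label=name)
        res = fisher_odds_ratio(tab)
        rows.append({
            "set": name, "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
            "odds_ratio": res.odds_ratio, "p": res.p,
            "or_corrected": res.or_corrected,
        })
    out = pd.DataFrame(
        rows, columns=["set", "a", "b", "c", "d",
                       "odds_ratio", "p", "or_corrected"],
    )
    if len(out):
        out["padj"] = benjamini_hochberg(out["p"].to_numpy())
    else:
        out["padj"] = []
    return out


def deg_overlap_test(
    deg_a: list[str], deg_b: list[str], universe: list[str], label: str = ""
) -> DirectionEnrichmentResult:
    """Fisher test of DEG-set co-membership over a shared universe.

    Symmetric in A and B; the 2×2 crosses membership in A against
    membership in B over every universe gene.
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty universe")
    if not set(deg_a) <= uni or not set(deg_b) <= uni:
        raise DataError("DEG sets must be subsets of the universe")
    sa, sb = set(deg_a), set(deg_b)
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - a - b - c
    tab = ContingencyTable(a, b, c, d, label=label, excludes_pathway=False)
    return fisher_odds_ratio(tab)


def deg_overlap_tests(
    pairs: dict[str, tuple[list[str], list[str]]], universe: list[str]
) -> pd.DataFrame:
    """Several overlap tests with BH across the comparisons in the call."""
    rows = []
    for label, (da, db) in pairs.items():
        res = deg_overlap_test(da, db, universe, label=label)
        rows.append({
            "comparison": label, "a": res.table.a, "b": res.table.b,
            "c": res.table.c, "d": res.table.d,
            "n_overlap": res.table.a,
            "odds_ratio": res.odds_ratio, "p": res.p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = benjamini_hochberg(out["p"].to_numpy())
    return out
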