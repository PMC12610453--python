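"""Validated miRNA-target handling: convergence counts and over-representation.

Interactions are deduplicated on (mirna, gene_symbol); convergence counts the
distinct significant miRNAs targeting each gene within one direction; term
over-representation is an upper-tail hypergeometric test against a universe
built as the union of validated targets across all retained miRNAs, BH-adjusted
across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from mirpanel.diffexpr import bh_adjust

FUNCTIONAL_LABEL = "Functional MTI"
WEAK_LABEL = "Functional MTI (Weak)"

INTERACTION_COLUMNS = ("mirna", "gene_symbol", "support_type", "source")


@dataclass
class ConvergenceRanking:
    """Per-gene distinct-miRNA counts for one regulation direction."""

    direction: str
    table: pd.DataFrame  # columns: gene_symbol, n_mirnas; ranked

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.table.head(k).reset_index(drop=True)


def _dedupe(df: pd.DataFrame) -> pd.DataFrame:
    def _join(values: Iterable[str]) -> str:
        return ";".join(sorted(set(str(v) for v in values)))

    return (
        df.groupby(["mirna", "gene_symbol"], as_index=False)
        .agg(support_type=("support_type", _join), source=("source", _join))
        [list(INTERACTION_COLUMNS)]
    )


def load_interactions(
    path_or_frame,
    functional_only: bool = False,
    include_weak: bool = False,
) -> pd.DataFrame:
    """Load and deduplicate a validated-interaction snapshot.

    With ``functional_only`` only rows whose support label starts with
    "Functional MTI" are kept; the "(Weak)" variant is excluded unless
    ``include_weak`` is set. Duplicate (mirna, gene) pairs collapse to one row
    with sources concatenated.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep="\t", dtype=str)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    df = df[list(INTERACTION_COLUMNS)].astype(str)
    if functional_only:
        keep = df["support_type"].str.startswith(FUNCTIONAL_LABEL)
        if not include_weak:
            keep &= df["support_type"] != WEAK_LABEL
        df = df[keep]
    if df.empty:
        return pd.DataFrame(columns=list(INTERACTION_COLUMNS))
    return _dedupe(df).reset_index(drop=True)


def convergence_counts(
    interactions: pd.DataFrame,
    significant: Iterable[str],
    direction: str,
) -> ConvergenceRanking:
    """Count, per gene, the distinct significant miRNAs that target it.

    Counts use unique (mirna, gene) pairs; the ranking is descending by count
    with lexicographic gene-symbol tie-breaking.
    """
    significant = set(significant)
    if interactions.empty or not significant:
        empty = pd.DataFrame(columns=["gene_symbol", "n_mirnas"])
        return ConvergenceRanking(direction=direction, table=empty)
    sub = interactions[interactions["mirna"].isin(significant)]
    counts = (
        sub.drop_duplicates(["mirna", "gene_symbol"])
        .groupby("gene_symbol")
        .size()
        .rename("n_mirnas")
        .reset_index()
        .sort_values(["n_mirnas", "gene_symbol"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return ConvergenceRanking(direction=direction, table=counts)


def target_universe(interactions: pd.DataFrame) -> set[str]:
    """Union of validated target genes across all retained miRNAs."""
    if interactions.empty:
        return set()
    return set(interactions["gene_symbol"])


def hypergeom_enrich(
    target_set: Iterable[str],
    term_map: pd.DataFrame,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a gene set per term.

    ``term_map`` carries columns term_id, term_name, gene_symbol; term genes
    are intersected with the universe before testing and BH adjustment runs
    across all tested terms. Sorted by (fdr, p, term_id); re-sort by
    ``overlap_count`` for the gene-count display ordering.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    target_set = set(target_set)
    stray = target_set - universe
    if stray:
        raise ValueError(f"target genes outside the universe: {sorted(stray)[:5]}")
    cols = ["term_id", "term_name", "overlap_count", "set_size",
            "term_size_in_universe", "universe_size", "p", "fdr"]
    if not target_set:
        return pd.DataFrame(columns=cols)
    for col in ("term_id", "term_name", "gene_symbol"):
        if col not in term_map.columns:
            raise ValueError(f"term map missing column {col!r}")

    N, n = len(universe), len(target_set)
    rows = []
    for (term_id, term_name), grp in term_map.groupby(["term_id", "term_name"]):
        members = set(grp["gene_symbol"]) & universe
        if not members:
            continue
        K = len(members)
        k = len(members & target_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            dict(term_id=term_id, term_name=term_name, overlap_count=k,
                 set_size=n, term_size_in_universe=K, universe_size=N,
                 p=min(p, 1.0))
        )
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return (
        out.sort_values(["fdr", "p", "term_id"]).reset_index(drop=True)[cols]
    )
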