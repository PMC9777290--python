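"""Hypergeometric gene-set enrichment of a DEG list.

For a universe of N genes of which m belong to a pathway, drawing an n-gene
DEG list that contains k pathway genes has upper-tail probability

    p = sum_{j=k}^{min(m, n)}  C(m, j) C(N - m, n - j) / C(N, n)

(the one-sided Fisher exact test). The sum is evaluated with exact integer
arithmetic, so the result is correct to full double precision for any
problem size this pipeline meets. Pathways are then ranked by p and the
Benjamini-Hochberg FDR across tested pathways decides enrichment.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .dge import fdr_adjust
from .formats_io import GeneSetCollection


def hypergeom_upper_tail(k: int, N: int, m: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m, n), exact.

    Parameters follow the gene-set convention: N universe size, m annotated
    genes, n list size, k annotated genes in the list.
    """
    for name, val in (("k", k), ("N", N), ("m", m), ("n", n)):
        if int(val) != val or val < 0:
            raise ValueError(f"parameter {name} must be a non-negative integer, got {val}")
    k, N, m, n = int(k), int(N), int(m), int(n)
    if m > N:
        raise ValueError(f"parameter m={m} exceeds universe size N={N}")
    if n > N:
        raise ValueError(f"parameter n={n} exceeds universe size N={N}")
    if k > min(m, n):
        raise ValueError(f"parameter k={k} exceeds min(m, n)={min(m, n)}")
    if k < max(0, m + n - N):
        return 1.0
    numer = sum(comb(m, j) * comb(N - m, n - j) for j in range(k, min(m, n) + 1))
    return float(Fraction(numer, comb(N, n)))


def hypergeom_pmf(j: int, N: int, m: int, n: int) -> float:
    """Exact point mass P(X = j); zero outside the support."""
    if j < max(0, m + n - N) or j > min(m, n):
        return 0.0
    return float(Fraction(comb(m, j) * comb(N - m, n - j), comb(N, n)))


def build_universe(measured_genes, sets: GeneSetCollection, mode: str = "measured-annotated") -> set[str]:
    """Universe N for the hypergeometric test.

    ``measured-annotated`` (default) keeps genes that are both measured on
    the array and annotated to at least one pathway — unmeasurable genes
    cannot inflate significance. ``all-annotated`` is the literal
    genome-wide reading: every annotated gene regardless of the array.
    """
    annotated = set(sets.all_genes)
    if mode == "all-annotated":
        return annotated
    if mode == "measured-annotated":
        return set(measured_genes) & annotated
    raise ValueError(f"unknown universe mode {mode!r}")


def enrich(
    deg_list,
    sets: GeneSetCollection,
    universe,
    fdr_threshold: float = 0.05,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Test every pathway for DEG over-representation within ``universe``.

    DEG list and pathway memberships are intersected with the universe
    first; pathways left with no member in the universe are not tested.
    Returns one row per tested pathway (pathway_id, name, k, n, m, N, p,
    fdr, rank, enriched) sorted by ascending p with lexicographic
    tie-breaks.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    degs = set(deg_list) & universe
    N = len(universe)
    n = len(degs)
    if n == 0:
        import logging

        logging.getLogger(__name__).warning(
            "DEG list is empty after universe intersection; nothing to test"
        )
    rows = []
    for pid in sets.ids():
        members = sets.members(pid) & universe
        m = len(members)
        if m == 0:
            continue
        k = len(members & degs)
        p = hypergeom_upper_tail(k, N, m, n)
        rows.append((pid, sets.name(pid), k, n, m, N, p))
    table = pd.DataFrame(
        rows, columns=["pathway_id", "name", "k", "n", "m", "N", "p"]
    )
    if table.empty:
        table["fdr"] = []
        table["rank"] = []
        table["enriched"] = []
        return table
    table["fdr"] = fdr_adjust(table["p"].to_numpy(), method=fdr_method)
    table = table.sort_values(["p", "pathway_id"]).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["enriched"] = table["fdr"] < fdr_threshold
    return table


def enriched_ids(table: pd.DataFrame) -> list[str]:
    """Pathway ids flagged enriched, in rank order."""
    return list(table.loc[table["enriched"], "pathway_id"])


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
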