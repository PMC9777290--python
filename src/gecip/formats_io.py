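"""Readers/writers for the pipeline's external formats.

Gene identifiers are harmonized to uppercase symbol strings everywhere;
that string is the join key between the expression matrix, the gene-set
collection and the interaction network. Genes missing from one of the
inputs simply drop out of the corresponding downstream step (their counts
are logged, not raised).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
TARGET = "target"

#: The gene-set classes retained when class filtering is on; sets tagged
#: "human diseases" or "drug development" duplicate members of these and
#: are excluded to avoid double counting.
INCLUDED_CLASSES = frozenset(
    {
        "metabolism",
        "genetic information processing",
        "environmental information processing",
        "cellular processes",
        "organismal systems",
    }
)
EXCLUDED_CLASSES = frozenset({"human diseases", "drug development"})
UNKNOWN_CLASS = "unknown"


def harmonize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped, uppercased. Idempotent."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Gene x sample matrix (log2 scale) with a two-group sample annotation.

    ``values`` is indexed by harmonized gene symbol; ``groups`` maps each
    sample id to "control" or "target".
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols after harmonization")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples missing from group annotation: {missing}")
        bad = set(self.groups.unique()) - {CONTROL, TARGET}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for label in (CONTROL, TARGET):
            if len(self.sample_ids(label)) < 2:
                raise ValueError(f"group {label!r} has fewer than 2 samples")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_ids(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == label]

    def group_matrix(self, label: str) -> np.ndarray:
        """genes x samples array for one group."""
        return self.values[self.sample_ids(label)].to_numpy()


def read_expression(matrix_path, groups_path, log2: bool = False) -> ExpressionDataset:
    """Load a TSV expression matrix and its two-group sample annotation.

    The matrix has a header row of sample ids and gene symbols in the first
    column; the groups file maps sample id -> {control, target}. Rows with
    missing values are dropped, duplicate gene rows are collapsed by mean,
    and ``log2`` applies log2(x + 1) for raw-scale inputs.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", header=None, comment="#")
    if groups_df.iloc[0, 1] not in (CONTROL, TARGET):  # tolerate a header line
        groups_df = groups_df.iloc[1:]
    groups = pd.Series(
        groups_df.iloc[:, 1].astype(str).str.strip().str.lower().to_numpy(),
        index=groups_df.iloc[:, 0].astype(str).to_numpy(),
    )
    missing = [s for s in mat.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples missing from group annotation: {missing}")

    mat.index = [harmonize_symbol(g) for g in mat.index]
    n_na = int(mat.isna().any(axis=1).sum())
    if n_na:
        logger.info("dropping %d gene rows with missing values", n_na)
        mat = mat.dropna()
    n_dup = int(mat.index.duplicated().sum())
    if n_dup:
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        mat = mat.groupby(level=0, sort=False).mean()
    if log2:
        mat = np.log2(mat + 1.0)
    return ExpressionDataset(values=mat, groups=groups[list(mat.columns)])


def write_expression(data: ExpressionDataset, matrix_path, groups_path) -> None:
    data.values.to_csv(matrix_path, sep="\t")
    data.groups.to_csv(groups_path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets ("pathways") with an optional class tag per set."""

    sets: dict[str, tuple[str, frozenset[str]]]    # id -> (name, members)
    class_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {pid!r} has no members")
        self.class_of = {
            pid: self.class_of.get(pid, UNKNOWN_CLASS) for pid in self.sets
        }

    def members(self, pid: str) -> frozenset[str]:
        return self.sets[pid][1]

    def name(self, pid: str) -> str:
        return self.sets[pid][0]

    def ids(self) -> list[str]:
        return list(self.sets)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    def filter_classes(self, included=INCLUDED_CLASSES) -> "GeneSetCollection":
        """Keep only sets whose class tag is in ``included`` (or untagged)."""
        keep = {
            pid: v
            for pid, v in self.sets.items()
            if self.class_of[pid] in included or self.class_of[pid] == UNKNOWN_CLASS
        }
        dropped = len(self.sets) - len(keep)
        if dropped:
            logger.info("class filter removed %d gene sets", dropped)
        return GeneSetCollection(
            sets=keep, class_of={pid: self.class_of[pid] for pid in keep}
        )


def read_gmt(path, class_table=None) -> GeneSetCollection:
    """Parse a GMT file (set id, description, member genes per tab-separated line).

    ``class_table`` is an optional two-column TSV mapping set id -> class tag;
    untagged sets are classed "unknown".
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need id, description "
                    f"and at least one gene (got {len(fields)} fields)"
                )
            pid, name = fields[0], fields[1]
            members = frozenset(harmonize_symbol(g) for g in fields[2:] if g.strip())
            if not members:
                raise ValueError(f"{path}: line {lineno}: no gene symbols")
            sets[pid] = (name, members)
    class_of: dict[str, str] = {}
    if class_table is not None:
        tab = pd.read_csv(class_table, sep="\t", header=None, comment="#")
        class_of = {
            str(row[0]): str(row[1]).strip().lower() for row in tab.itertuples(index=False)
        }
    return GeneSetCollection(sets=sets, class_of=class_of)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in collection.ids():
            genes = "\t".join(sorted(collection.members(pid)))
            fh.write(f"{pid}\t{collection.name(pid)}\t{genes}\n")


def write_class_table(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in collection.ids():
            fh.write(f"{pid}\t{collection.class_of[pid]}\n")


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

@dataclass
class InteractionNetwork:
    """Undirected gene-gene network, binarized: an edge either exists or not.

    The optional per-edge confidence score survives as an edge attribute but
    plays no role downstream once the cutoff has been applied — adjacency
    is strictly 0/1.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def adjacency(self, order: list[str]) -> np.ndarray:
        """0/1 adjacency matrix in the given node order."""
        return nx.to_numpy_array(self.graph, nodelist=order, weight=None)

    @classmethod
    def from_edges(cls, edges, scores=None) -> "InteractionNetwork":
        g = nx.Graph()
        for i, (a, b) in enumerate(edges):
            a, b = harmonize_symbol(a), harmonize_symbol(b)
            if a == b:
                logger.info("dropping self-loop on %s", a)
                continue
            attrs = {"score": scores[i]} if scores is not None else {}
            g.add_edge(a, b, **attrs)
        return cls(graph=g)


def read_network(path, score_cutoff: float = 0.0, score_col=2) -> InteractionNetwork:
    """Read a TSV edge list (geneA, geneB, confidence score).

    Edges with score >= ``score_cutoff`` are kept and binarized; self-loops
    and duplicate edges (either orientation) collapse. ``score_col`` selects
    the score column by 0-based index or by header name.
    """
    g = nx.Graph()
    n_self = n_drop = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    header: list[str] | None = None
    if lines and not _looks_like_edge(lines[0]):
        header = lines[0].split("\t")
        start = 1
    if isinstance(score_col, str):
        if header is None or score_col not in header:
            raise ValueError(f"score column {score_col!r} not found in header")
        score_idx = header.index(score_col)
    else:
        score_idx = int(score_col)
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) <= score_idx:
            raise ValueError(f"{path}: line {lineno}: expected >= {score_idx + 1} columns")
        try:
            score = float(fields[score_idx])
        except ValueError as err:
            raise ValueError(
                f"{path}: line {lineno}: unparseable score {fields[score_idx]!r}"
            ) from err
        a, b = harmonize_symbol(fields[0]), harmonize_symbol(fields[1])
        if a == b:
            n_self += 1
            continue
        if score < score_cutoff:
            n_drop += 1
            continue
        g.add_edge(a, b, score=score)
    if n_self or n_drop:
        logger.info(
            "network load: dropped %d self-loops, %d edges below cutoff", n_self, n_drop
        )
    return InteractionNetwork(graph=g)


def _looks_like_edge(line: str) -> bool:
    fields = line.split("\t")
    if len(fields) < 3:
        return False
    try:
        float(fields[2])
    except ValueError:
        return False
    return True


def write_network(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b, attrs in net.graph.edges(data=True):
            score = attrs.get("score", 1.0)
            fh.write(f"{a}\t{b}\t{score}\n")


# ---------------------------------------------------------------------------
# pathway-pathway network export
# ---------------------------------------------------------------------------

def write_pathway_network(crosstalk, path, fmt: str = "sif") -> None:
    """Export the pathway-pathway crosstalk network for Cytoscape.

    One record per unordered pathway pair with CTdegree > 0; the edge weight
    attribute carries the raw CTdegree (the normalized score is written
    alongside for edge-thickness scaling). ``fmt`` is one of sif, graphml,
    tsv. For SIF the weights go to a companion ``<path>.edges.tsv`` file.
    """
    pairs = crosstalk.pairs()
    if pairs.empty:
        logger.warning("crosstalk result has no positive pairs; writing header only")
    if fmt == "tsv":
        pairs.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for row in pairs.itertuples(index=False):
                fh.write(f"{row.pathway_s}\tcrosstalk\t{row.pathway_t}\n")
        companion = f"{path}.edges.tsv"
        pairs.to_csv(companion, sep="\t", index=False)
    elif fmt == "graphml":
        g = nx.Graph()
        for pid in crosstalk.pathway_ids:
            g.add_node(pid)
        for row in pairs.itertuples(index=False):
            g.add_edge(
                row.pathway_s,
                row.pathway_t,
                ctdegree=float(row.ctdegree),
                ctdegree_normalized=float(row.ctdegree_normalized),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected sif, graphml or tsv)")


def read_pathway_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
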