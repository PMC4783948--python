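"""PPI edge-list ingestion and candidate-network construction.

A candidate network is the induced subgraph of the PPI edge list on a
differential protein group: genes screened as differentially expressed
(one-way ANOVA or fold change), augmented with outside proteins that are
densely connected to the group (more than ``min_links`` edges into it),
with isolated proteins removed.  Node order is deterministic (lexicographic)
so that interaction matrices index reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyInputError,
    EmptyNetworkError,
    InsufficientReplicatesError,
    ValidationError,
)
from .expression import ExpressionMatrix, group_means, log2_fold_change

# BioGRID TAB 2.0/3.0 header names we recognize (case-insensitive match).
_BIOGRID_SYMBOL_A = "official symbol interactor a"
_BIOGRID_SYMBOL_B = "official symbol interactor b"
_BIOGRID_ORGANISM_COLS = (
    "organism interactor a",
    "organism id interactor a",
    "organism name interactor a",
)


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    a, b = a.strip().upper(), b.strip().upper()
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPIEdgeList:
    """Deduplicated undirected protein pairs (no self-loops).

    Edges are stored as lexicographically ordered symbol tuples; symbols are
    upper-cased so they join against expression gene ids.
    """

    edges: frozenset

    def __post_init__(self):
        for a, b in self.edges:
            if not a or not b:
                raise ValidationError("empty protein id in edge list")
            if a == b:
                raise ValidationError(f"self-loop {a!r} in edge list")

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair) -> bool:
        return _canonical_edge(*pair) in self.edges

    def neighbors(self) -> dict:
        """Adjacency mapping protein -> set of interactors."""
        adj: dict = {}
        for a, b in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    @classmethod
    def from_pairs(cls, pairs) -> "PPIEdgeList":
        edges = set()
        for a, b in pairs:
            a, b = str(a).strip().upper(), str(b).strip().upper()
            if not a or not b or a == b:
                continue
            edges.add(_canonical_edge(a, b))
        return cls(frozenset(edges))


def read_ppi_edges(path, dialect: str = "plain_tsv", organism_filter: str | None = None) -> PPIEdgeList:
    """Read an undirected PPI edge list.

    ``plain_tsv``: two whitespace/tab-separated symbol columns, optional
    header.  ``biogrid_tab``: a BioGRID TAB 2.0/3.0 dump; the official symbol
    columns are used and rows are kept only when both interactors match
    ``organism_filter`` (compared against the taxid or organism-name columns)
    when a filter is given.

    Self-loops are dropped and reciprocal duplicates collapse to one edge.
    """
    if dialect == "plain_tsv":
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh):
                parts = line.replace(",", "\t").split()
                if not parts:
                    continue
                if len(parts) < 2:
                    raise ValidationError(
                        f"{path}:{lineno + 1}: expected two columns, got {parts!r}"
                    )
                a, b = parts[0], parts[1]
                if lineno == 0 and {a.lower(), b.lower()} & {
                    "protein_a",
                    "protein_b",
                    "source",
                    "target",
                }:
                    continue  # header row
                pairs.append((a, b))
    elif dialect == "biogrid_tab":
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
        cols = {c.lower().lstrip("#").strip(): c for c in df.columns}
        try:
            col_a = cols[_BIOGRID_SYMBOL_A]
            col_b = cols[_BIOGRID_SYMBOL_B]
        except KeyError as exc:
            raise ValidationError(
                "BioGRID table lacks official-symbol interactor columns"
            ) from exc
        if organism_filter is not None:
            org_key = next((k for k in _BIOGRID_ORGANISM_COLS if k in cols), None)
            if org_key is None:
                raise ValidationError("BioGRID table lacks organism columns")
            org_a = cols[org_key]
            org_b = cols[org_key.replace("interactor a", "interactor b")]
            wanted = str(organism_filter)
            df = df[(df[org_a].astype(str) == wanted) & (df[org_b].astype(str) == wanted)]
        pairs = list(zip(df[col_a].astype(str), df[col_b].astype(str)))
    else:
        raise ValidationError(f"unknown PPI dialect {dialect!r}")
    result = PPIEdgeList.from_pairs(pairs)
    if len(result) == 0:
        raise EmptyInputError(f"no PPI edges parsed from {path}")
    return result


def write_protein_set(proteins, path) -> None:
    """One protein id per line, sorted."""
    with open(path, "w") as fh:
        for p in sorted(proteins):
            fh.write(f"{p}\n")


# -- differential protein group --------------------------------------------


def select_differential_proteins(
    x: ExpressionMatrix,
    time_point: str,
    method: str = "fold_change",
    threshold: float = 1.5,
) -> set:
    """Screen genes differentially expressed between case and control.

    ``fold_change``: keep genes with |log2(case mean / control mean)| >
    log2(threshold), i.e. fold change above ``threshold`` in either
    direction.  ``anova``: keep genes whose classical one-way fixed-effects
    F-test across the two groups has p < threshold (requires >= 2 replicates
    per group).
    """
    case_ids = x.sample_ids("case", time_point)
    control_ids = x.sample_ids("control", time_point)
    means = group_means(x, time_point)
    if method == "fold_change":
        if threshold <= 1:
            raise ValidationError("fold-change threshold must be > 1")
        lfc = log2_fold_change(
            means["case_mean"].to_numpy(), means["control_mean"].to_numpy()
        )
        keep = np.abs(lfc) > np.log2(threshold)
    elif method == "anova":
        if len(case_ids) < 2 or len(control_ids) < 2:
            raise InsufficientReplicatesError(
                "one-way ANOVA needs >= 2 replicates per group"
            )
        if not 0 < threshold < 1:
            raise ValidationError("ANOVA p-value threshold must be in (0, 1)")
        case = x.values[case_ids].to_numpy()
        control = x.values[control_ids].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.f_oneway(case, control, axis=1)
        pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance genes: not differential
        keep = pvals < threshold
    else:
        raise ValidationError(f"unknown screening method {method!r}")
    return set(np.asarray(x.genes)[keep])


def augment_with_neighbors(core, edges: PPIEdgeList, min_links: int = 5) -> set:
    """Add outside proteins with more than ``min_links`` edges into the core.

    Strict inequality: a protein with exactly ``min_links`` links is not
    added.  Single pass — newly added proteins do not recruit further.
    """
    if min_links < 1:
        raise ValidationError("min_links must be >= 1")
    core = {str(p).upper() for p in core}
    counts: dict = {}
    for a, b in edges.edges:
        if a in core and b not in core:
            counts[b] = counts.get(b, 0) + 1
        elif b in core and a not in core:
            counts[a] = counts.get(a, 0) + 1
    return core | {p for p, c in counts.items() if c > min_links}


@dataclass
class CandidateNetwork:
    """Induced PPI subgraph defining the regression index.

    ``nodes`` fixes the matrix index (lexicographic order); ``neighbors``
    maps each protein to its ordered interactor list within the node set.
    Every node has at least one neighbor (isolated proteins are removed at
    construction).
    """

    nodes: list
    neighbors: dict = field(repr=False)

    @property
    def degrees(self) -> dict:
        return {p: len(nbrs) for p, nbrs in self.neighbors.items()}

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.neighbors.values()) // 2

    def node_index(self) -> dict:
        return {p: i for i, p in enumerate(self.nodes)}


def build_candidate_network(proteins, edges: PPIEdgeList) -> CandidateNetwork:
    """Induce the PPI subgraph on ``proteins`` and drop isolated nodes."""
    proteins = {str(p).upper() for p in proteins}
    if not proteins:
        raise ValidationError("empty protein set")
    induced = [(a, b) for a, b in edges.edges if a in proteins and b in proteins]
    if not induced:
        raise EmptyNetworkError("all candidate proteins are isolated in the PPI graph")
    adj: dict = {}
    for a, b in induced:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    nodes = sorted(adj)
    neighbors = {p: sorted(adj[p]) for p in nodes}
    return CandidateNetwork(nodes=nodes, neighbors=neighbors)
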