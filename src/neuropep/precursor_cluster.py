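"""Precursor similarity network and cluster extraction.

Families of neuropeptide precursors are recovered by an all-against-all
local-alignment search: every unordered pair of precursor sequences is
scored by optimal Smith-Waterman local alignment (BLOSUM62, affine gaps,
NCBI 11/1 convention), the score converted to an e-value with the
Karlin-Altschul formula

    E = K * m * n' * exp(-lambda * S)

using the published gapped-BLOSUM62 constants (lambda = 0.267, K = 0.041)
and an effective search space of query length times total database
residues, and an edge kept when E falls below the cutoff (default 1e-5).
Clusters are the connected components of the resulting graph — the network
tool used for the original visualization performs layout, not partitioning,
so components are this package's explicit interpretation of "cluster".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import math

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SimilarityEdge",
    "ClusterGraph",
    "local_align",
    "estimate_evalue",
    "build_graph",
    "components",
    "write_edge_table",
    "write_partition_table",
    "KARLIN_ALTSCHUL_PARAMS",
]

logger = logging.getLogger(__name__)

# (matrix, gap_open, gap_extend) -> (lambda, K); gapped values from the
# standard protein-search parameter tables
KARLIN_ALTSCHUL_PARAMS = {
    ("BLOSUM62", 11, 1): (0.267, 0.041),
}


@dataclass(frozen=True)
class SimilarityEdge:
    id_a: str
    id_b: str
    score: float
    evalue: float

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("self-edges are not allowed")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if self.id_a > self.id_b:  # store undirected edges canonically
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)


@dataclass
class ClusterGraph:
    nodes: list[str]
    edges: list[SimilarityEdge]
    cutoff: float

    def __post_init__(self):
        known = set(self.nodes)
        for e in self.edges:
            if e.id_a not in known or e.id_b not in known:
                raise ValueError(f"edge {e.id_a}-{e.id_b} references unknown node")
            if e.evalue > self.cutoff:
                raise ValueError("edge above the e-value cutoff")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (e.id_a, e.id_b, {"score": e.score, "evalue": e.evalue})
            for e in self.edges
        )
        return g


def _make_aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # NCBI convention: a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    bad = set(seq) - set(alphabet)
    if bad:
        logger.warning("non-standard residues %s mapped to X", sorted(bad))
        seq = "".join(c if c in alphabet else "X" for c in seq)
    return seq


def local_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Optimal Smith-Waterman local alignment score with affine gaps."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    return float(aligner.score(_sanitize(a, alphabet), _sanitize(b, alphabet)))


def estimate_evalue(
    score: float,
    len_a: int,
    len_b: int,
    db_residues: int | None = None,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Karlin-Altschul e-value for a local alignment score.

    ``db_residues`` is the total residue count of the database searched;
    when omitted the subject length stands in (single-pair search).
    """
    if score < 0:
        raise ValueError("score must be >= 0")
    key = (matrix, gap_open, gap_extend)
    if key not in KARLIN_ALTSCHUL_PARAMS:
        raise ValueError(
            f"no Karlin-Altschul parameters for regime {key}; "
            f"supported: {sorted(KARLIN_ALTSCHUL_PARAMS)}"
        )
    lam, k = KARLIN_ALTSCHUL_PARAMS[key]
    n_eff = db_residues if db_residues is not None else len_b
    return k * len_a * n_eff * math.exp(-lam * score)


def build_graph(
    precursors: dict[str, str],
    cutoff: float = 1e-5,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> ClusterGraph:
    """Similarity graph over all unordered precursor pairs at an e-value cutoff."""
    if not precursors:
        raise ValueError("need at least one precursor")
    ids = sorted(precursors)
    db_residues = sum(len(s) for s in precursors.values())
    edges = []
    for i, ia in enumerate(ids):
        for ib in ids[i + 1:]:
            s = local_align(precursors[ia], precursors[ib], matrix, gap_open, gap_extend)
            e = estimate_evalue(
                max(s, 0.0), len(precursors[ia]), len(precursors[ib]),
                db_residues=db_residues, matrix=matrix,
                gap_open=gap_open, gap_extend=gap_extend,
            )
            if e <= cutoff:
                edges.append(SimilarityEdge(id_a=ia, id_b=ib, score=s, evalue=e))
    return ClusterGraph(nodes=ids, edges=edges, cutoff=cutoff)


def components(graph: ClusterGraph) -> list[set[str]]:
    """Connected components, singletons included, deterministically ordered."""
    comps = [set(c) for c in nx.connected_components(graph.to_networkx())]
    return sorted(comps, key=lambda c: min(c))


def write_edge_table(graph: ClusterGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tscore\tevalue\n")
        for e in sorted(graph.edges, key=lambda e: (e.id_a, e.id_b)):
            fh.write(f"{e.id_a}\t{e.id_b}\t{e.score:g}\t{e.evalue:.6g}\n")


def write_partition_table(comps: list[set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcluster\n")
        for ci, comp in enumerate(comps):
            for node in sorted(comp):
                fh.write(f"{node}\t{ci}\n")
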