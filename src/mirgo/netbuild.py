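"""Construction of the global heterogeneous miRNA-protein network.

Three component networks are built from flat-file inputs and merged into one
weighted undirected graph:

* a miRNA co-expression network (Pearson correlation of expression profiles;
  non-positive correlations are discarded, the positive PCC is the edge weight),
* a protein-protein interaction network (STRING-style combined scores, rescaled
  to [0, 1]),
* a miRNA-target interaction network (experimentally validated links, weight 1).

The merged adjacency has the block layout ``[[M, MP], [MP^T, P]]`` where M is
the miRNA x miRNA co-expression block, P the protein x protein interaction
block and MP the bipartite miRNA-target block.  Node identifiers are prefixed
with their kind (``mirna:`` / ``protein:``) so the two namespaces can never
collide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

MIRNA = "mirna"
PROTEIN = "protein"

EDGE_KIND_MM = "mm"
EDGE_KIND_PP = "pp"
EDGE_KIND_MP = "mp"


def prefix_id(kind: str, node_id: str) -> str:
    return f"{kind}:{node_id}"


def strip_prefix(node_id: str) -> str:
    return node_id.split(":", 1)[1] if ":" in node_id else node_id


def node_kind(node_id: str) -> str:
    return node_id.split(":", 1)[0]


@dataclass
class ExpressionMatrix:
    """Expression profiles: one row per entity, one column per sample.

    Missing values are represented as NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate entity ids in expression matrix: {dups}")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="id")


class WeightedEdgeList:
    """Undirected weighted edges, stored once under canonical (sorted) ordering.

    Duplicate insertions keep the maximum weight; self-loops are rejected.
    Weights must lie in (0, 1].
    """

    def __init__(self) -> None:
        self._edges: dict[tuple[str, str], float] = {}

    def add(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if not (0.0 < weight <= 1.0):
            raise ValueError(f"edge weight {weight} outside (0, 1] for ({a}, {b})")
        key = (a, b) if a <= b else (b, a)
        prev = self._edges.get(key)
        if prev is None or weight > prev:
            self._edges[key] = float(weight)

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self):
        return iter(sorted((a, b, w) for (a, b), w in self._edges.items()))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        key = (a, b) if a <= b else (b, a)
        return key in self._edges

    def weight(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        return self._edges[key]

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._edges:
            out.add(a)
            out.add(b)
        return out


def average_precursor_profiles(
    precursor_expr: ExpressionMatrix, mapping: Mapping[str, str] | pd.DataFrame
) -> ExpressionMatrix:
    """Collapse precursor-level profiles to mature-miRNA profiles.

    Several precursor hairpins can yield the same mature miRNA; their expression
    rows are averaged entry-wise (arithmetic mean, NaN-aware) into a single
    mature row.  ``mapping`` is either a dict ``precursor -> mature`` or a
    two-column DataFrame ``(precursor_id, mature_id)``.
    """
    if isinstance(mapping, pd.DataFrame):
        pairs = list(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    else:
        pairs = list(mapping.items())
    if not pairs:
        raise ValueError("empty precursor->mature mapping")

    by_mature: dict[str, list[str]] = {}
    for prec, mat in pairs:
        by_mature.setdefault(mat, []).append(prec)

    known = set(precursor_expr.entity_ids)
    rows = {}
    for mature in sorted(by_mature):
        precs = [p for p in by_mature[mature] if p in known]
        if not precs:
            raise ValueError(
                f"mature miRNA {mature!r} has no mapped precursor in the expression matrix"
            )
        rows[mature] = precursor_expr.data.loc[precs].mean(axis=0, skipna=True)
    return ExpressionMatrix(pd.DataFrame(rows).T)


def read_mapping_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"mapping file {path} needs (precursor_id, mature_id) columns")
    return df.iloc[:, :2]


def compute_coexpression(
    expr: ExpressionMatrix, min_overlap: int = 3, pcc_min: float = 0.0
) -> WeightedEdgeList:
    """Pairwise Pearson co-expression network over the matrix rows.

    PCC is computed on pairwise-complete observations.  A pair produces an
    edge only if the overlap has at least ``min_overlap`` samples, neither
    profile is constant on the overlap, and the PCC is strictly positive
    (and > ``pcc_min`` when a floor is requested); the PCC itself is the
    edge weight.
    """
    values = expr.values
    ids = expr.entity_ids
    n, s = values.shape
    if s < 2:
        raise ValueError("expression matrix needs at least 2 samples")
    if n < 2:
        raise ValueError("expression matrix needs at least 2 rows")
    if min_overlap < 2:
        raise ValueError("min_overlap must be >= 2")

    edges = WeightedEdgeList()
    has_nan = bool(np.isnan(values).any())
    if not has_nan and s >= min_overlap:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values)
        for i in range(n):
            for j in range(i + 1, n):
                r = corr[i, j]
                if np.isfinite(r):
                    r = min(float(r), 1.0)
                    if r > 0.0 and r > pcc_min:
                        edges.add(ids[i], ids[j], r)
        return edges

    for i in range(n):
        xi = values[i]
        for j in range(i + 1, n):
            xj = values[j]
            mask = ~(np.isnan(xi) | np.isnan(xj))
            if int(mask.sum()) < min_overlap:
                continue
            a, b = xi[mask], xj[mask]
            sa, sb = a.std(), b.std()
            if sa == 0.0 or sb == 0.0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if np.isfinite(r):
                r = min(r, 1.0)
                if r > 0.0 and r > pcc_min:
                    edges.add(ids[i], ids[j], r)
    return edges


def load_ppi_edges(path_or_df, score_scale: float = 1000.0) -> WeightedEdgeList:
    """Read a (proteinA, proteinB, score) table; weight = score / score_scale.

    Duplicates keep the maximum weight; self-pairs are dropped; a score outside
    [0, score_scale] is an error naming the offending row.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError("PPI table needs (proteinA, proteinB, score) columns")
    edges = WeightedEdgeList()
    a_col = df.iloc[:, 0].astype(str).to_numpy()
    b_col = df.iloc[:, 1].astype(str).to_numpy()
    scores = pd.to_numeric(df.iloc[:, 2], errors="coerce").to_numpy()
    n_self = 0
    for row, (a, b, s) in enumerate(zip(a_col, b_col, scores), start=2):
        if not np.isfinite(s):
            raise ValueError(f"malformed PPI score at line {row}")
        if s < 0 or s > score_scale:
            raise ValueError(
                f"PPI score {s} at line {row} outside [0, {score_scale}]"
            )
        if a == b:
            n_self += 1
            continue
        w = float(s) / float(score_scale)
        if w > 0.0:
            edges.add(a, b, w)
    if n_self:
        logger.info("dropped %d PPI self-pairs", n_self)
    return edges


def load_target_edges(path_or_df) -> WeightedEdgeList:
    """Read a (miRNA, target) table of validated interactions; weight 1.0 each."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise ValueError("empty miRNA-target table")
    edges = WeightedEdgeList()
    for m, g in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        edges.add(prefix_id(MIRNA, m), prefix_id(PROTEIN, g), 1.0)
    return edges


@dataclass
class GlobalNetwork:
    """The merged heterogeneous graph over typed (kind-prefixed) nodes.

    ``edges`` maps a canonically ordered prefixed-id pair to (weight, kind),
    kind in {mm, pp, mp}.  ``node_ids`` is the sorted vertex list (miRNAs
    first, then proteins) and includes isolated nodes.
    """

    node_ids: list[str]
    edges: dict[tuple[str, str], tuple[float, str]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def mirna_ids(self) -> list[str]:
        return [n for n in self.node_ids if node_kind(n) == MIRNA]

    @property
    def protein_ids(self) -> list[str]:
        return [n for n in self.node_ids if node_kind(n) == PROTEIN]

    def edge_counts(self) -> dict[str, int]:
        out = {EDGE_KIND_MM: 0, EDGE_KIND_PP: 0, EDGE_KIND_MP: 0}
        for _, (_, kind) in self.edges.items():
            out[kind] += 1
        return out

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric sparse adjacency in node_ids order."""
        index = {n: i for i, n in enumerate(self.node_ids)}
        rows, cols, vals = [], [], []
        for (a, b), (w, _) in self.edges.items():
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        n = self.n_nodes
        return sparse.csr_matrix(
            (np.array(vals), (np.array(rows), np.array(cols))), shape=(n, n)
        )

    def neighbor_arrays(self):
        """CSR-style neighbor structure for the random-walk generator.

        Returns (indptr, neighbor_indices, weights) over node_ids order.
        """
        index = {n: i for i, n in enumerate(self.node_ids)}
        adj: list[list[tuple[int, float]]] = [[] for _ in self.node_ids]
        for (a, b), (w, _) in sorted(self.edges.items()):
            i, j = index[a], index[b]
            adj[i].append((j, w))
            adj[j].append((i, w))
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        nbr: list[int] = []
        wts: list[float] = []
        for i, lst in enumerate(adj):
            lst.sort()
            indptr[i + 1] = indptr[i] + len(lst)
            nbr.extend(j for j, _ in lst)
            wts.extend(w for _, w in lst)
        return indptr, np.array(nbr, dtype=np.int64), np.array(wts, dtype=float)

    def write_tsv(self, path) -> None:
        """Canonical edge-list TSV: node_a, node_b, weight (6 dp), edge_kind."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node_a\tnode_b\tweight\tedge_kind\n")
            for (a, b) in sorted(self.edges):
                w, kind = self.edges[(a, b)]
                fh.write(f"{a}\t{b}\t{w:.6f}\t{kind}\n")
            for node in sorted(set(self.node_ids) - self._connected_nodes()):
                fh.write(f"{node}\t{node}\t0.000000\tisolated\n")

    def _connected_nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @classmethod
    def read_tsv(cls, path) -> "GlobalNetwork":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        nodes: set[str] = set()
        edges: dict[tuple[str, str], tuple[float, str]] = {}
        for a, b, w, kind in zip(
            df["node_a"], df["node_b"], df["weight"].astype(float), df["edge_kind"]
        ):
            nodes.add(a)
            nodes.add(b)
            if kind == "isolated":
                continue
            key = (a, b) if a <= b else (b, a)
            edges[key] = (w, kind)
        mir = sorted(n for n in nodes if node_kind(n) == MIRNA)
        prot = sorted(n for n in nodes if node_kind(n) == PROTEIN)
        return cls(node_ids=mir + prot, edges=edges)


def assemble_global_network(
    m_edges: WeightedEdgeList,
    p_edges: WeightedEdgeList,
    mp_edges: WeightedEdgeList,
    mirna_nodes: Iterable[str] = (),
    protein_nodes: Iterable[str] = (),
) -> GlobalNetwork:
    """Merge the three component networks into the global block adjacency.

    ``m_edges`` and ``p_edges`` carry bare miRNA / protein ids; ``mp_edges``
    already carries kind-prefixed endpoints (see :func:`load_target_edges`).
    ``mirna_nodes`` / ``protein_nodes`` add vertices that may be isolated
    (expression-matrix miRNAs, PPI proteins).  Target-edge protein endpoints
    absent from the PPI namespace are kept and counted in the log.
    """
    ppi_proteins = {prefix_id(PROTEIN, p) for p in p_edges.nodes()} | {
        prefix_id(PROTEIN, p) for p in protein_nodes
    }

    nodes: set[str] = set(ppi_proteins)
    nodes.update(prefix_id(MIRNA, m) for m in m_edges.nodes())
    nodes.update(prefix_id(MIRNA, m) for m in mirna_nodes)

    edges: dict[tuple[str, str], tuple[float, str]] = {}

    def put(a: str, b: str, w: float, kind: str) -> None:
        key = (a, b) if a <= b else (b, a)
        prev = edges.get(key)
        if prev is None or w > prev[0]:
            edges[key] = (w, kind)

    for a, b, w in m_edges:
        put(prefix_id(MIRNA, a), prefix_id(MIRNA, b), w, EDGE_KIND_MM)
    for a, b, w in p_edges:
        put(prefix_id(PROTEIN, a), prefix_id(PROTEIN, b), w, EDGE_KIND_PP)

    n_unmatched = 0
    for a, b, w in mp_edges:
        if node_kind(a) == PROTEIN:
            a, b = b, a
        if node_kind(a) != MIRNA or node_kind(b) != PROTEIN:
            raise ValueError(f"miRNA-target edge with bad kinds: ({a}, {b})")
        if b not in ppi_proteins:
            n_unmatched += 1
        nodes.add(a)
        nodes.add(b)
        put(a, b, w, EDGE_KIND_MP)
    if n_unmatched:
        logger.info(
            "%d target-edge proteins not present in the PPI namespace (kept)",
            n_unmatched,
        )

    bare_m = {strip_prefix(n) for n in nodes if node_kind(n) == MIRNA}
    bare_p = {strip_prefix(n) for n in nodes if node_kind(n) == PROTEIN}
    overlap = bare_m & bare_p
    if overlap:
        logger.warning(
            "%d ids occur as both miRNA and protein; kept distinct via kind prefix",
            len(overlap),
        )

    mir = sorted(n for n in nodes if node_kind(n) == MIRNA)
    prot = sorted(n for n in nodes if node_kind(n) == PROTEIN)
    return GlobalNetwork(node_ids=mir + prot, edges=edges)
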