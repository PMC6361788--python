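"""Latent node representations via truncated random walks and SkipGram.

The global network is explored with short random walks (weight-proportional
neighbor sampling by default).  The walk corpus is then treated as a set of
sentences and a SkipGram model with hierarchical softmax is trained on it:
each vocabulary node is a leaf of a Huffman tree built on corpus frequencies,
and the probability of observing a context node given a center node factorizes
into per-branch sigmoids along the leaf's root path,

    Pr(v_j | Phi(v_i)) = prod_l sigma(s_l * Phi(v_i) . Psi(b_l)),

where Psi(b_l) is the vector of internal tree node b_l and s_l = +1/-1 encodes
the branch direction.  Only the leaf table Phi is emitted as the embedding.

``DeepWalkEmbedding`` wraps the whole procedure as a scikit-learn style
estimator (``fit`` on a :class:`~mirgo.netbuild.GlobalNetwork`, fitted
attributes ``node_ids_`` / ``embedding_``).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .netbuild import GlobalNetwork


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class WalkConfig:
    """Hyper-parameters of the walk + SkipGram stage.

    walks_per_node: number of walks started from every node (gamma).
    walk_length: number of nodes per walk (t).
    window: SkipGram context radius (w); must be < walk_length.
    dim: embedding dimensionality (d).
    weighted: sample the next node proportionally to edge weight.
    """

    walks_per_node: int = 100
    walk_length: int = 80
    window: int = 16
    dim: int = 512
    seed: int = 42
    weighted: bool = True

    def __post_init__(self) -> None:
        for name in ("walks_per_node", "walk_length", "window", "dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.window >= self.walk_length:
            raise ValueError("window must be smaller than walk_length")


@dataclass
class WalkCorpus:
    """A list of node-id sequences produced by the walk generator."""

    walks: list[list[str]]

    def __len__(self) -> int:
        return len(self.walks)

    def vocabulary_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for walk in self.walks:
            for node in walk:
                counts[node] = counts.get(node, 0) + 1
        return counts

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for walk in self.walks:
                fh.write(" ".join(walk) + "\n")

    @classmethod
    def read(cls, path) -> "WalkCorpus":
        with open(path, encoding="utf-8") as fh:
            return cls([line.split() for line in fh if line.strip()])


def generate_walks(g: GlobalNetwork, cfg: WalkConfig) -> WalkCorpus:
    """Run ``walks_per_node`` truncated random walks from every node.

    The next node is drawn from the current node's neighbors with probability
    proportional to edge weight (uniform when ``cfg.weighted`` is False).
    Isolated nodes yield the degenerate length-1 walk.  The node visit order is
    reshuffled on each outer pass; everything is driven by ``cfg.seed``.
    """
    if g.n_nodes == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(cfg.seed)
    indptr, nbr, wts = g.neighbor_arrays()
    n = g.n_nodes

    # per-node cumulative weights for O(log deg) sampling
    cumw: list[np.ndarray | None] = []
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        if hi == lo:
            cumw.append(None)
        elif cfg.weighted:
            cumw.append(np.cumsum(wts[lo:hi]))
        else:
            cumw.append(np.arange(1, hi - lo + 1, dtype=float))

    names = g.node_ids
    walks: list[list[str]] = []
    order = np.arange(n)
    for _ in range(cfg.walks_per_node):
        rng.shuffle(order)
        for root in order:
            cur = int(root)
            walk = [names[cur]]
            for _ in range(cfg.walk_length - 1):
                cw = cumw[cur]
                if cw is None:
                    break
                u = rng.random() * cw[-1]
                k = int(np.searchsorted(cw, u, side="right"))
                k = min(k, len(cw) - 1)
                cur = int(nbr[indptr[cur] + k])
                walk.append(names[cur])
            walks.append(walk)
    return WalkCorpus(walks)


@dataclass
class HSTree:
    """Huffman tree over the vocabulary for hierarchical softmax.

    ``paths[v]`` is the array of internal-node indices on the root path of
    leaf v and ``codes[v]`` the branch directions taken (0 = left, 1 = right).
    ``psi`` holds one d-vector per internal node, initialized to zero.
    """

    vocab: list[str]
    paths: dict[str, np.ndarray]
    codes: dict[str, np.ndarray]
    psi: np.ndarray  # (n_internal, d)

    @property
    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.vocab)}

    def depth(self, node: str) -> int:
        return len(self.paths[node])


def build_hs_tree(corpus: WalkCorpus | dict[str, int], d: int) -> HSTree:
    """Build the Huffman coding tree on corpus node frequencies.

    Ties in frequency are broken by lexicographic node id (leaves sort before
    internal nodes created later), making the tree fully deterministic.
    """
    counts = (
        corpus.vocabulary_counts() if isinstance(corpus, WalkCorpus) else dict(corpus)
    )
    vocab = sorted(counts)
    if len(vocab) < 2:
        raise ValueError("vocabulary must contain at least 2 nodes")

    # heap entries: (count, serial, payload); leaf serials follow lexicographic
    # order, internal serials continue past them in creation order.
    heap: list[tuple[int, int, object]] = [
        (counts[v], i, v) for i, v in enumerate(vocab)
    ]
    heapq.heapify(heap)
    serial = len(vocab)
    internal_children: dict[int, tuple[object, object]] = {}
    while len(heap) > 1:
        c1, _, left = heapq.heappop(heap)
        c2, _, right = heapq.heappop(heap)
        node_id = serial
        internal_children[node_id] = (left, right)
        heapq.heappush(heap, (c1 + c2, node_id, node_id))
        serial += 1

    # index internal nodes 0..n_internal-1; walk down from the root
    root = heap[0][2]
    paths: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    internal_index: dict[int, int] = {}

    def assign(node, path: list[int], code: list[int]) -> None:
        if isinstance(node, str):
            paths[node] = np.array(path, dtype=np.int64)
            codes[node] = np.array(code, dtype=np.int8)
            return
        idx = internal_index.setdefault(node, len(internal_index))
        path = path + [idx]
        left, right = internal_children[node]
        assign(left, path, code + [0])
        assign(right, path, code + [1])

    if isinstance(root, str):  # cannot happen for |V| >= 2
        raise ValueError("degenerate tree")
    assign(root, [], [])
    psi = np.zeros((len(internal_index), d), dtype=float)
    return HSTree(vocab=vocab, paths=paths, codes=codes, psi=psi)


def hs_probability(phi_v: np.ndarray, tree: HSTree, target: str) -> float:
    """Probability of ``target`` under the hierarchical softmax of ``tree``.

    Product over the target's root path of sigma(+-phi_v . psi(b_l)) with the
    sign set by the branch direction (left branches use +, right branches -).
    """
    path = tree.paths[target]
    code = tree.codes[target]
    if phi_v.shape[-1] != tree.psi.shape[1]:
        raise ValueError(
            f"dimension mismatch: vector has {phi_v.shape[-1]}, tree has {tree.psi.shape[1]}"
        )
    x = tree.psi[path] @ phi_v
    sign = 1.0 - 2.0 * code
    return float(np.prod(_sigmoid(sign * x)))


def window_loss(
    phi: np.ndarray,
    tree: HSTree,
    walk: list[str],
    center_index: int,
    w: int,
    vocab_index: dict[str, int] | None = None,
) -> float:
    """Negative log-likelihood of the window around one walk position.

    -sum over context positions j in [i-w, i+w], j != i (truncated at walk
    boundaries) of log Pr(walk[j] | phi[walk[i]]).
    """
    loss, _, _ = window_loss_and_grad(phi, tree, walk, center_index, w, vocab_index)
    return loss


def window_loss_and_grad(
    phi: np.ndarray,
    tree: HSTree,
    walk: list[str],
    center_index: int,
    w: int,
    vocab_index: dict[str, int] | None = None,
):
    """Window loss together with its analytic gradients.

    Returns (loss, grad_center, psi_grads) where grad_center is d(loss)/d(phi
    of the center node) and psi_grads maps internal-node index -> gradient
    vector.  Per-branch: with x = phi_c . psi_l and code c in {0,1},
    d(loss)/dx = sigma(x) - (1 - c).
    """
    if not (0 <= center_index < len(walk)):
        raise IndexError("center_index out of range")
    if w < 1:
        raise ValueError("window must be >= 1")
    index = vocab_index if vocab_index is not None else tree.index
    ci = index[walk[center_index]]
    phi_c = phi[ci]
    lo = max(0, center_index - w)
    hi = min(len(walk), center_index + w + 1)

    loss = 0.0
    grad_center = np.zeros_like(phi_c)
    psi_grads: dict[int, np.ndarray] = {}
    for j in range(lo, hi):
        if j == center_index:
            continue
        target = walk[j]
        path = tree.paths[target]
        code = tree.codes[target]
        x = tree.psi[path] @ phi_c
        sign = 1.0 - 2.0 * code
        # -log sigma(s*x) accumulated stably via log1p(exp(-s*x))
        loss += float(np.sum(np.log1p(np.exp(-sign * x))))
        g = _sigmoid(x) - (1.0 - code)  # (L,)
        grad_center += g @ tree.psi[path]
        for idx, gl in zip(path, g):
            acc = psi_grads.get(int(idx))
            if acc is None:
                psi_grads[int(idx)] = gl * phi_c.copy()
            else:
                acc += gl * phi_c
    return loss, grad_center, psi_grads


@dataclass
class EmbeddingMatrix:
    """The learned mapping Phi: node -> R^d as an ordered vocabulary + matrix."""

    node_ids: list[str]
    vectors: np.ndarray  # (|V|, d)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.node_ids) != self.vectors.shape[0]:
            raise ValueError("node_ids / vectors length mismatch")
        if not self._index:
            self._index = {v: i for i, v in enumerate(self.node_ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def vector(self, node: str) -> np.ndarray:
        return self.vectors[self._index[node]]

    def subset(self, nodes: list[str]) -> "EmbeddingMatrix":
        missing = [n for n in nodes if n not in self._index]
        if missing:
            raise KeyError(f"nodes absent from embedding vocabulary: {missing[:5]}")
        rows = [self._index[n] for n in nodes]
        return EmbeddingMatrix(list(nodes), self.vectors[rows].copy())

    def write(self, path) -> None:
        """Text format: header '<|V|> <d>', then 'node v1 ... vd' lines."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.node_ids)} {self.dim}\n")
            for node, vec in zip(self.node_ids, self.vectors):
                fh.write(node + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def read(cls, path) -> "EmbeddingMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            ids: list[str] = []
            vecs = np.empty((n, d), dtype=float)
            for i, line in enumerate(fh):
                parts = line.split()
                ids.append(parts[0])
                vecs[i] = [float(x) for x in parts[1:]]
        if len(ids) != n:
            raise ValueError("embedding file truncated")
        return cls(ids, vecs)


def corpus_loss(phi: np.ndarray, tree: HSTree, corpus: WalkCorpus, w: int) -> float:
    """Total window loss over every (walk, center) pair; no updates."""
    index = tree.index
    total = 0.0
    for walk in corpus.walks:
        for i in range(len(walk)):
            total += window_loss(phi, tree, walk, i, w, index)
    return total


def train_skipgram(
    corpus: WalkCorpus,
    cfg: WalkConfig,
    epochs: int = 1,
    lr0: float = 0.025,
    tree: HSTree | None = None,
) -> EmbeddingMatrix:
    """SGD on the window loss over all (walk, center) pairs.

    Phi is initialized Uniform(-0.5/d, 0.5/d) from ``cfg.seed``; the learning
    rate decays linearly from ``lr0`` to ``lr0/100`` over all scheduled
    updates.  The gradients of every context pair of one center are applied as
    a single step (one small matrix-vector product per center), keeping the
    trainer deterministic and single-threaded.
    """
    if len(corpus.walks) == 0:
        raise ValueError("empty walk corpus")
    if tree is None:
        tree = build_hs_tree(corpus, cfg.dim)
    d = cfg.dim
    vocab = tree.vocab
    index = {v: i for i, v in enumerate(vocab)}
    rng = np.random.default_rng(cfg.seed)
    phi = rng.uniform(-0.5 / d, 0.5 / d, size=(len(vocab), d))
    psi = tree.psi
    if psi.shape[1] != d:
        raise ValueError("tree dimensionality differs from cfg.dim")

    total_centers = epochs * sum(len(wk) for wk in corpus.walks)
    done = 0
    w = cfg.window
    paths = tree.paths
    codes = tree.codes
    lr_min_frac = 0.01

    for _ in range(epochs):
        for walk in corpus.walks:
            widx = [index[node] for node in walk]
            L = len(walk)
            for i in range(L):
                lr = lr0 * max(lr_min_frac, 1.0 - (1.0 - lr_min_frac) * done / total_centers)
                done += 1
                lo = max(0, i - w)
                hi = min(L, i + w + 1)
                if hi - lo <= 1:
                    continue
                ci = widx[i]
                phi_c = phi[ci]
                # concatenate the tree paths of all context nodes
                parts_p = []
                parts_c = []
                for j in range(lo, hi):
                    if j == i:
                        continue
                    node = walk[j]
                    parts_p.append(paths[node])
                    parts_c.append(codes[node])
                path = np.concatenate(parts_p)
                code = np.concatenate(parts_c).astype(float)
                rows = psi[path]
                x = rows @ phi_c
                g = _sigmoid(x) - (1.0 - code)
                if not np.all(np.isfinite(g)):
                    raise FloatingPointError(
                        f"non-finite gradient at update {done}; lower lr0"
                    )
                grad_c = g @ rows
                np.add.at(psi, path, (-lr * g)[:, None] * phi_c)
                phi[ci] = phi_c - lr * grad_c
    return EmbeddingMatrix(list(vocab), phi)


class DeepWalkEmbedding(BaseEstimator):
    """Random-walk + SkipGram node embedding as a scikit-learn estimator.

    Parameters mirror :class:`WalkConfig`.  ``fit`` takes a
    :class:`~mirgo.netbuild.GlobalNetwork` and exposes ``node_ids_`` and
    ``embedding_`` (|V| x dim).  ``transform`` maps node ids to their vectors.
    """

    def __init__(
        self,
        walks_per_node: int = 100,
        walk_length: int = 80,
        window: int = 16,
        dim: int = 512,
        epochs: int = 1,
        lr0: float = 0.025,
        weighted: bool = True,
        seed: int = 42,
    ):
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.window = window
        self.dim = dim
        self.epochs = epochs
        self.lr0 = lr0
        self.weighted = weighted
        self.seed = seed

    def _config(self) -> WalkConfig:
        return WalkConfig(
            walks_per_node=self.walks_per_node,
            walk_length=self.walk_length,
            window=self.window,
            dim=self.dim,
            seed=self.seed,
            weighted=self.weighted,
        )

    def fit(self, g: GlobalNetwork, y=None):
        cfg = self._config()
        self.corpus_ = generate_walks(g, cfg)
        emb = train_skipgram(self.corpus_, cfg, epochs=self.epochs, lr0=self.lr0)
        # isolated nodes may appear only as length-1 walks; they are still in
        # the corpus and hence in the vocabulary
        self.node_ids_ = emb.node_ids
        self.embedding_ = emb.vectors
        self.embedding_matrix_ = emb
        return self

    def transform(self, nodes: list[str]) -> np.ndarray:
        if not hasattr(self, "embedding_matrix_"):
            raise RuntimeError("estimator not fitted")
        return self.embedding_matrix_.subset(list(nodes)).vectors

    def fit_transform(self, g: GlobalNetwork, y=None) -> np.ndarray:
        return self.fit(g).embedding_
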