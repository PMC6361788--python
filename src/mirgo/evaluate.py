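"""Protein-centric style evaluation of miRNA GO predictions.

For each miRNA i and score threshold t the predicted set P_i(t) is the set of
terms scored >= t together with all their ancestors (is_a/part_of, namespace
roots excluded).  Against the true ancestor-closed set T_i,

    Pre_i(t) = |P_i(t) & T_i| / |P_i(t)|,   Rec_i(t) = |P_i(t) & T_i| / |T_i|.

Precision is averaged over the m(t) miRNAs with at least one prediction at t;
recall over the whole benchmark of N miRNAs (prediction-less miRNAs count 0).
Fmax is the maximum over thresholds of the harmonic mean of the two averages,
and coverage is the number of miRNAs with >=1 correct term at the Fmax
threshold.  Two methods are compared with a paired t-test over repeated
random subsamples of the benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import PredictionSet
from .ontology import PROPAGATING_RELATIONS, AnnotationSet, GOGraph

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


def predicted_set(
    scores: dict[str, float],
    t: float,
    go: GOGraph,
    relations: frozenset = PROPAGATING_RELATIONS,
    keep_roots: bool = False,
) -> frozenset:
    """Terms scored >= t, closed under ancestors, roots excluded by default.

    Terms unknown to the ontology are kept (with a warning) but contribute no
    ancestors.
    """
    roots = set() if keep_roots else go.roots(relations)
    out: set[str] = set()
    for term, score in scores.items():
        if score < t:
            continue
        if term not in go:
            logger.warning("predicted term %s not in ontology; kept bare", term)
            out.add(term)
            continue
        canon = go.canonical(term)
        if canon not in roots:
            out.add(canon)
        out.update(a for a in go.ancestors(canon, relations) if a not in roots)
    return frozenset(out)


def pr_single(P: frozenset, T: frozenset) -> tuple[float | None, float]:
    """(precision, recall) of one predicted set against one true set.

    Precision is None (undefined) when P is empty; empty T is an error since
    every benchmark entry must have at least one true term.
    """
    if not T:
        raise ValueError("empty true set: benchmark entries need >=1 true term")
    inter = len(P & T)
    rec = inter / len(T)
    pre = inter / len(P) if P else None
    return pre, rec


@dataclass
class ThresholdSweep:
    """Per-threshold benchmark averages over the score grid."""

    thresholds: np.ndarray
    m: np.ndarray  # miRNAs with >=1 prediction at t
    pre: np.ndarray  # NaN where m(t) == 0 (unusable)
    rec: np.ndarray
    n_benchmark: int

    def usable(self) -> np.ndarray:
        return self.m > 0

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("t\tm\tPre\tRec\tF\n")
            for t, m, p, r in zip(self.thresholds, self.m, self.pre, self.rec):
                f = f_measure(p, r) if m > 0 else float("nan")
                p_str = f"{p:.4f}" if np.isfinite(p) else "NA"
                f_str = f"{f:.4f}" if np.isfinite(f) else "NA"
                fh.write(f"{t:.2f}\t{int(m)}\t{p_str}\t{r:.4f}\t{f_str}\n")


@dataclass
class EvalResult:
    fmax: float
    t_at_fmax: float
    coverage: int
    sweep: ThresholdSweep


def f_measure(pre: float, rec: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if pre is None:
        return float("nan")
    if pre + rec == 0.0:
        return 0.0
    return 2.0 * pre * rec / (pre + rec)


def _truth_by_mirna(truth) -> dict[str, frozenset]:
    if isinstance(truth, AnnotationSet):
        return {e: frozenset(ts) for e, ts in truth.by_entity().items()}
    return {e: frozenset(ts) for e, ts in truth.items()}


def _restrict_namespace(terms: set[str] | frozenset, go: GOGraph, namespace: str):
    if namespace in (None, "all"):
        return frozenset(terms)
    return frozenset(t for t in terms if t in go and go.namespace(t) == namespace)


def per_mirna_sweep(
    predictions: PredictionSet,
    truth,
    go: GOGraph,
    grid: np.ndarray = DEFAULT_GRID,
    namespace: str | None = "BP",
    relations: frozenset = PROPAGATING_RELATIONS,
):
    """Per-miRNA precision/recall over the grid (building block of sweep).

    Returns (mirna_ids, nonempty, pre_i, rec_i): boolean and float arrays of
    shape (N, |grid|); pre_i is NaN where the predicted set is empty.
    """
    truth_map = _truth_by_mirna(truth)
    if not truth_map:
        raise ValueError("empty benchmark")
    mirnas = sorted(truth_map)
    grid = np.asarray(grid, dtype=float)
    n, g = len(mirnas), len(grid)
    nonempty = np.zeros((n, g), dtype=bool)
    pre_i = np.full((n, g), np.nan)
    rec_i = np.zeros((n, g))
    for i, mirna in enumerate(mirnas):
        T = _restrict_namespace(truth_map[mirna], go, namespace)
        if not T:
            raise ValueError(
                f"benchmark miRNA {mirna} has no true terms in namespace {namespace}"
            )
        scores = {
            t: s
            for t, s in predictions.scores_for(mirna).items()
            if namespace in (None, "all") or (t in go and go.namespace(t) == namespace)
        }
        for k, t in enumerate(grid):
            P = predicted_set(scores, t, go, relations)
            p, r = pr_single(P, T)
            rec_i[i, k] = r
            if P:
                nonempty[i, k] = True
                pre_i[i, k] = p
    return mirnas, nonempty, pre_i, rec_i


def sweep(
    predictions: PredictionSet,
    truth,
    go: GOGraph,
    grid: np.ndarray = DEFAULT_GRID,
    namespace: str | None = "BP",
    relations: frozenset = PROPAGATING_RELATIONS,
) -> ThresholdSweep:
    """Benchmark-averaged precision/recall over the threshold grid."""
    mirnas, nonempty, pre_i, rec_i = per_mirna_sweep(
        predictions, truth, go, grid, namespace, relations
    )
    grid = np.asarray(grid, dtype=float)
    m = nonempty.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pre = np.where(m > 0, np.nansum(np.where(nonempty, pre_i, 0.0), axis=0) / np.maximum(m, 1), np.nan)
    rec = rec_i.mean(axis=0)
    return ThresholdSweep(
        thresholds=grid, m=m.astype(int), pre=pre, rec=rec, n_benchmark=len(mirnas)
    )


def fmax(sw: ThresholdSweep) -> EvalResult:
    """Maximum F-measure over usable thresholds (smallest t on ties)."""
    usable = sw.usable()
    if not usable.any():
        raise ValueError("no usable threshold: m(t) == 0 everywhere")
    best_f, best_t = -1.0, None
    for t, m, p, r in zip(sw.thresholds, sw.m, sw.pre, sw.rec):
        if m == 0:
            continue
        f = f_measure(float(p), float(r))
        if f > best_f + 1e-12:
            best_f, best_t = f, float(t)
    return EvalResult(fmax=best_f, t_at_fmax=best_t, coverage=0, sweep=sw)


def coverage(
    predictions: PredictionSet,
    truth,
    go: GOGraph,
    t_at_fmax: float,
    namespace: str | None = "BP",
    relations: frozenset = PROPAGATING_RELATIONS,
) -> int:
    """Number of benchmark miRNAs with >=1 correct term at the Fmax threshold."""
    truth_map = _truth_by_mirna(truth)
    count = 0
    for mirna, T in truth_map.items():
        T = _restrict_namespace(T, go, namespace)
        scores = {
            t: s
            for t, s in predictions.scores_for(mirna).items()
            if namespace in (None, "all") or (t in go and go.namespace(t) == namespace)
        }
        P = predicted_set(scores, t_at_fmax, go, relations)
        if len(P & T) >= 1:
            count += 1
    return count


def evaluate_predictions(
    predictions: PredictionSet,
    truth,
    go: GOGraph,
    grid: np.ndarray = DEFAULT_GRID,
    namespace: str | None = "BP",
) -> EvalResult:
    """Full evaluation: sweep + Fmax + coverage at the Fmax threshold."""
    sw = sweep(predictions, truth, go, grid, namespace)
    result = fmax(sw)
    result.coverage = coverage(predictions, truth, go, result.t_at_fmax, namespace)
    return result


def _fmax_on_subset(nonempty, pre_i, rec_i, rows: np.ndarray) -> float:
    ne = nonempty[rows]
    m = ne.sum(axis=0)
    pre = np.where(
        m > 0,
        np.nansum(np.where(ne, pre_i[rows], 0.0), axis=0) / np.maximum(m, 1),
        np.nan,
    )
    rec = rec_i[rows].mean(axis=0)
    best = 0.0
    for mk, p, r in zip(m, pre, rec):
        if mk == 0:
            continue
        f = f_measure(float(p), float(r))
        if f > best:
            best = f
    return best


def paired_subsample_test(
    pred_a: PredictionSet,
    pred_b: PredictionSet,
    truth,
    go: GOGraph,
    draw_size: int = 50,
    reps: int = 30,
    seed: int = 0,
    grid: np.ndarray = DEFAULT_GRID,
    namespace: str | None = "BP",
) -> tuple[float, float]:
    """Two-tailed paired t-test on Fmax over repeated benchmark subsamples.

    ``reps`` seeded draws of ``draw_size`` miRNAs without replacement; Fmax of
    each method on each draw; paired t-test on the resulting pairs.  Identical
    methods give (0.0, 1.0).
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    mirnas_a, ne_a, pre_a, rec_a = per_mirna_sweep(pred_a, truth, go, grid, namespace)
    mirnas_b, ne_b, pre_b, rec_b = per_mirna_sweep(pred_b, truth, go, grid, namespace)
    if mirnas_a != mirnas_b:
        raise ValueError("the two methods must be evaluated on the same benchmark")
    n = len(mirnas_a)
    if n < draw_size:
        raise ValueError(f"benchmark size {n} < draw_size {draw_size}")
    rng = np.random.default_rng(seed)
    fa = np.empty(reps)
    fb = np.empty(reps)
    for r in range(reps):
        rows = rng.choice(n, size=draw_size, replace=False)
        fa[r] = _fmax_on_subset(ne_a, pre_a, rec_a, rows)
        fb[r] = _fmax_on_subset(ne_b, pre_b, rec_b, rows)
    diffs = fa - fb
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0
    t_stat, p = stats.ttest_rel(fa, fb)
    return float(t_stat), float(p)
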