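"""Staged pipeline: build-net -> embed -> trainsets -> train -> predict -> eval.

Each file-based stage is idempotent given identical inputs and seed, writes a
JSON manifest (inputs, parameters, seed, output checksums) next to its
outputs, and refuses to overwrite a *differing* prior output unless forced.
A single global seed fans out to per-stage seeds by fixed offsets so stages
can be rerun independently yet reproducibly.

``run_end_to_end`` is the in-memory equivalent used by the test-suite and the
acceptance script: it runs the whole flow on a directory of input files and
returns the intermediate objects plus the evaluation result.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import pickle
from dataclasses import dataclass

import numpy as np

from . import classify, evaluate, netbuild, ontology
from .classify import PredictionSet, TermClassifier
from .embedding import DeepWalkEmbedding, EmbeddingMatrix
from .netbuild import MIRNA, PROTEIN, GlobalNetwork, prefix_id, strip_prefix

logger = logging.getLogger(__name__)

SEED_OFFSETS = {
    "build_net": 0,
    "embed": 1,
    "trainsets": 2,
    "train": 3,
    "predict": 4,
    "eval": 5,
    "simulate": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1000 + SEED_OFFSETS[stage]) % (2**31 - 1)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def guarded_write(path: str, writer, force: bool = False) -> None:
    """Write via ``writer(tmp_path)``; refuse to replace a differing file."""
    tmp = path + ".tmp"
    writer(tmp)
    if os.path.exists(path) and not force:
        if _sha256(tmp) != _sha256(path):
            os.remove(tmp)
            raise FileExistsError(
                f"{path} exists with different content; rerun with --force to replace"
            )
    os.replace(tmp, path)


def write_manifest(out_dir: str, stage: str, params: dict, inputs: list[str], outputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "inputs": {p: _sha256(p) for p in inputs if os.path.exists(p)},
        "outputs": {p: _sha256(p) for p in outputs if os.path.exists(p)},
    }
    with open(os.path.join(out_dir, f"manifest_{stage}.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------- build-net


def build_network(
    expr_path: str,
    ppi_path: str | None,
    targets_path: str,
    mapping_path: str,
    min_overlap: int = 3,
    pcc_min: float = 0.0,
    score_scale: float = 1000.0,
    drop_ppi_edges: bool = False,
) -> GlobalNetwork:
    """Construct the global heterogeneous network from the four input files.

    ``drop_ppi_edges=True`` builds the ablated network with the PPI block
    zeroed: the protein vertex set is still read from the PPI file (so every
    protein keeps a feature vector), but no protein-protein edge is added.
    ``ppi_path=None`` omits the PPI file entirely; protein vertices then come
    from the target edges alone.
    """
    prec = netbuild.ExpressionMatrix.read_tsv(expr_path)
    mapping = netbuild.read_mapping_tsv(mapping_path)
    mature = netbuild.average_precursor_profiles(prec, mapping)
    m_edges = netbuild.compute_coexpression(mature, min_overlap=min_overlap, pcc_min=pcc_min)
    protein_nodes: list[str] = []
    if ppi_path is not None:
        p_edges = netbuild.load_ppi_edges(ppi_path, score_scale=score_scale)
        if drop_ppi_edges:
            protein_nodes = sorted(p_edges.nodes())
            p_edges = netbuild.WeightedEdgeList()
    else:
        p_edges = netbuild.WeightedEdgeList()
    mp_edges = netbuild.load_target_edges(targets_path)
    net = netbuild.assemble_global_network(
        m_edges, p_edges, mp_edges,
        mirna_nodes=mature.entity_ids, protein_nodes=protein_nodes,
    )
    counts = net.edge_counts()
    logger.info(
        "global network: %d nodes (%d miRNA, %d protein), edges mm=%d pp=%d mp=%d",
        net.n_nodes, len(net.mirna_ids), len(net.protein_ids),
        counts["mm"], counts["pp"], counts["mp"],
    )
    return net


def stage_build_net(cfg: dict, out_path: str, force: bool = False) -> None:
    net = build_network(
        cfg["expr"], cfg.get("ppi"), cfg["targets"], cfg["map"],
        min_overlap=cfg.get("min_overlap", 3),
        pcc_min=cfg.get("pcc_min", 0.0),
        score_scale=cfg.get("score_scale", 1000.0),
        drop_ppi_edges=cfg.get("drop_ppi_edges", False),
    )
    guarded_write(out_path, net.write_tsv, force)
    inputs = [p for p in (cfg["expr"], cfg.get("ppi"), cfg["targets"], cfg["map"]) if p]
    write_manifest(os.path.dirname(out_path) or ".", "build_net",
                   {k: v for k, v in cfg.items() if not isinstance(v, dict)},
                   inputs, [out_path])


# ------------------------------------------------------------------- embed


def embed_network(
    net: GlobalNetwork,
    walks_per_node: int = 100,
    walk_length: int = 80,
    window: int = 16,
    dim: int = 512,
    epochs: int = 1,
    lr0: float = 0.025,
    weighted: bool = True,
    seed: int = 42,
) -> DeepWalkEmbedding:
    est = DeepWalkEmbedding(
        walks_per_node=walks_per_node, walk_length=walk_length, window=window,
        dim=dim, epochs=epochs, lr0=lr0, weighted=weighted, seed=seed,
    )
    return est.fit(net)


def stage_embed(cfg: dict, net_path: str, out_path: str,
                walks_out: str | None = None, force: bool = False) -> None:
    net = GlobalNetwork.read_tsv(net_path)
    est = embed_network(
        net,
        walks_per_node=cfg.get("walks", 100),
        walk_length=cfg.get("length", 80),
        window=cfg.get("window", 16),
        dim=cfg.get("dim", 512),
        epochs=cfg.get("epochs", 1),
        weighted=not cfg.get("unweighted", False),
        seed=cfg.get("seed", 42),
    )
    guarded_write(out_path, est.embedding_matrix_.write, force)
    outputs = [out_path]
    if walks_out:
        guarded_write(walks_out, est.corpus_.write, force)
        outputs.append(walks_out)
    write_manifest(os.path.dirname(out_path) or ".", "embed", cfg, [net_path], outputs)


# --------------------------------------------------------------- trainsets


def stage_trainsets(cfg: dict, obo_path: str, gaf_path: str, out_dir: str,
                    force: bool = False) -> dict[str, ontology.TermTrainingSet]:
    os.makedirs(out_dir, exist_ok=True)
    go = ontology.parse_obo(obo_path)
    ann = ontology.load_annotations(gaf_path)
    if cfg.get("propagate_train", True):
        ann = ontology.propagate(ann, go)
    else:
        ann = ontology.AnnotationSet(pairs=set(ann.pairs), propagated=True)
    sets = ontology.build_all_training_sets(
        ann, go,
        min_pos=cfg.get("min_pos", 10),
        seed=cfg.get("seed", 42),
        namespace=cfg.get("namespace", "all"),
    )
    outputs = []
    for term, ts in sorted(sets.items()):
        path = os.path.join(out_dir, term.replace(":", "_") + ".tsv")
        guarded_write(path, ts.write_tsv, force)
        outputs.append(path)
    write_manifest(out_dir, "trainsets", {k: v for k, v in cfg.items()},
                   [obo_path, gaf_path], outputs)
    logger.info("wrote %d training sets to %s", len(sets), out_dir)
    return sets


# ------------------------------------------------------------------- train


def train_classifiers(
    emb: EmbeddingMatrix,
    training_sets: dict[str, ontology.TermTrainingSet],
    folds: int = 10,
    seed: int = 42,
    c_grid=classify.DEFAULT_C_GRID,
    g_grid=classify.DEFAULT_GAMMA_GRID,
) -> list[TermClassifier]:
    """Grid-search and fit one calibrated SVM per term.

    Training entities are bare protein ids; vectors are looked up under the
    ``protein:`` namespace.  Entities without an embedding are dropped (with a
    log line); a term left with too few entities per class is skipped.
    """
    out: list[TermClassifier] = []
    for term in sorted(training_sets):
        ts = training_sets[term]
        pos = [e for e in ts.positives if prefix_id(PROTEIN, e) in emb]
        neg = [e for e in ts.negatives if prefix_id(PROTEIN, e) in emb]
        dropped = (len(ts.positives) - len(pos)) + (len(ts.negatives) - len(neg))
        if dropped:
            logger.info("term %s: dropped %d entities without embeddings", term, dropped)
        if min(len(pos), len(neg)) < folds:
            logger.info("term %s: too few embedded entities for %d-fold CV; skipped",
                        term, folds)
            continue
        prefixed = ontology.TermTrainingSet(
            term=term,
            positives=[prefix_id(PROTEIN, e) for e in pos],
            negatives=[prefix_id(PROTEIN, e) for e in neg],
        )
        clf = classify.train_term_classifier(
            emb, prefixed, folds=folds, seed=seed, c_grid=c_grid, g_grid=g_grid
        )
        out.append(clf)
    return out


def stage_train(cfg: dict, emb_path: str, trainsets_dir: str, out_dir: str,
                force: bool = False) -> list[TermClassifier]:
    os.makedirs(out_dir, exist_ok=True)
    emb = EmbeddingMatrix.read(emb_path)
    sets = {}
    for fname in sorted(os.listdir(trainsets_dir)):
        if fname.endswith(".tsv") and fname.startswith("GO_"):
            ts = ontology.TermTrainingSet.read_tsv(os.path.join(trainsets_dir, fname))
            sets[ts.term] = ts
    grids = cfg.get("grids", {})
    classifiers = train_classifiers(
        emb, sets,
        folds=cfg.get("folds", 10),
        seed=cfg.get("seed", 42),
        c_grid=tuple(grids.get("C", classify.DEFAULT_C_GRID)),
        g_grid=tuple(grids.get("gamma", classify.DEFAULT_GAMMA_GRID)),
    )
    manifest_path = os.path.join(out_dir, "models.tsv")

    def write_model_manifest(path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tC\tgamma\tn_pos\tn_neg\tcv_accuracy\n")
            for clf in classifiers:
                fh.write(
                    f"{clf.term}\t{clf.params.C:g}\t{clf.params.kernel_gamma:g}"
                    f"\t{clf.n_pos}\t{clf.n_neg}\t{clf.cv_accuracy:.4f}\n"
                )

    guarded_write(manifest_path, write_model_manifest, force)
    for clf in classifiers:
        with open(os.path.join(out_dir, clf.term.replace(":", "_") + ".pkl"), "wb") as fh:
            pickle.dump(clf, fh)
    write_manifest(out_dir, "train", {k: v for k, v in cfg.items() if k != "grids"},
                   [emb_path], [manifest_path])
    return classifiers


def load_classifiers(models_dir: str) -> list[TermClassifier]:
    out = []
    for fname in sorted(os.listdir(models_dir)):
        if fname.endswith(".pkl"):
            with open(os.path.join(models_dir, fname), "rb") as fh:
                out.append(pickle.load(fh))
    return out


# ----------------------------------------------------------------- predict


def predict_for_mirnas(
    emb: EmbeddingMatrix, classifiers: list[TermClassifier],
    mirnas: list[str] | None = None,
) -> PredictionSet:
    """Score miRNA vectors against all trained terms (bare ids in the output)."""
    if mirnas is None:
        mirnas = sorted(strip_prefix(n) for n in emb.node_ids
                        if n.startswith(f"{MIRNA}:"))
    prefixed = [prefix_id(MIRNA, m) for m in mirnas]
    sub = emb.subset(prefixed)
    bare = EmbeddingMatrix([strip_prefix(n) for n in sub.node_ids], sub.vectors)
    return classify.predict_go_scores(bare, classifiers)


def stage_predict(emb_path: str, models_dir: str, out_path: str,
                  mirnas_path: str | None = None, force: bool = False) -> PredictionSet:
    emb = EmbeddingMatrix.read(emb_path)
    classifiers = load_classifiers(models_dir)
    mirnas = None
    if mirnas_path:
        with open(mirnas_path, encoding="utf-8") as fh:
            mirnas = [line.strip() for line in fh if line.strip()]
    preds = predict_for_mirnas(emb, classifiers, mirnas)
    guarded_write(out_path, preds.write_tsv, force)
    write_manifest(os.path.dirname(out_path) or ".", "predict", {},
                   [emb_path], [out_path])
    return preds


# -------------------------------------------------------------------- eval


def read_truth(path: str) -> dict[str, set[str]]:
    """Benchmark truth from a 2-column TSV (mirna_id, go_term) or a GAF file."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("!gaf"):
        ann = ontology.load_annotations(path, exclude_evidence=frozenset())
        return {e: set(ts) for e, ts in ann.by_entity().items()}
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            m, t = line.rstrip("\n").split("\t")[:2]
            out.setdefault(m, set()).add(t)
    return out


def stage_eval(pred_path: str, truth_path: str, obo_path: str, out_prefix: str,
               namespace: str = "BP", grid_step: float = 0.01,
               force: bool = False) -> evaluate.EvalResult:
    go = ontology.parse_obo(obo_path)
    preds = PredictionSet.read_tsv(pred_path)
    raw_truth = read_truth(truth_path)
    truth = {
        m: set(evaluate.predicted_set({t: 1.0 for t in ts}, 0.5, go))
        for m, ts in raw_truth.items()
    }
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    result = evaluate.evaluate_predictions(preds, truth, go, grid=grid, namespace=namespace)
    sweep_path = out_prefix + "_sweep.tsv"
    summary_path = out_prefix + "_summary.tsv"
    guarded_write(sweep_path, result.sweep.write_tsv, force)

    def write_summary(path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("Fmax\tt_at_fmax\tcoverage\tN\n")
            fh.write(f"{result.fmax:.4f}\t{result.t_at_fmax:.2f}"
                     f"\t{result.coverage}\t{result.sweep.n_benchmark}\n")

    guarded_write(summary_path, write_summary, force)
    write_manifest(os.path.dirname(out_prefix) or ".", "eval",
                   {"namespace": namespace, "grid_step": grid_step},
                   [pred_path, truth_path, obo_path], [sweep_path, summary_path])
    return result


# ------------------------------------------------------------- end-to-end


@dataclass
class EndToEndResult:
    network: GlobalNetwork
    embedding: EmbeddingMatrix
    classifiers: list[TermClassifier]
    predictions: PredictionSet
    eval_result: evaluate.EvalResult


def run_end_to_end(
    data_dir: str,
    use_ppi: bool = True,
    seed: int = 42,
    embed_params: dict | None = None,
    svm_params: dict | None = None,
    namespace: str = "BP",
    min_pos: int = 10,
) -> EndToEndResult:
    """Run the full in-memory flow on a directory of input files.

    Expects the file names written by :func:`mirgo.synthetic.simulate`
    (expression.tsv, mapping.tsv, ppi.tsv, targets.tsv, go.obo,
    annotations.gaf, truth_mirna_terms.tsv).
    """
    embed_params = dict(embed_params or {})
    svm_params = dict(svm_params or {})
    p = lambda name: os.path.join(data_dir, name)

    net = build_network(
        p("expression.tsv"), p("ppi.tsv"), p("targets.tsv"), p("mapping.tsv"),
        drop_ppi_edges=not use_ppi,
    )
    est = embed_network(net, seed=stage_seed(seed, "embed"), **embed_params)
    emb = est.embedding_matrix_

    go = ontology.parse_obo(p("go.obo"))
    ann = ontology.propagate(ontology.load_annotations(p("annotations.gaf")), go)
    sets = ontology.build_all_training_sets(
        ann, go, min_pos=min_pos, seed=stage_seed(seed, "trainsets"),
        namespace=namespace,
    )
    classifiers = train_classifiers(
        emb, sets, seed=stage_seed(seed, "train"), **svm_params
    )
    preds = predict_for_mirnas(emb, classifiers)
    truth = read_truth(p("truth_mirna_terms.tsv"))
    result = evaluate.evaluate_predictions(preds, truth, go, namespace=namespace)
    return EndToEndResult(
        network=net, embedding=emb, classifiers=classifiers,
        predictions=preds, eval_result=result,
    )
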