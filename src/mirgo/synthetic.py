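"""Self-contained synthetic inputs with planted community/function structure.

The generator emulates the statistical shape of the real inputs without any
download: miRNA expression follows a community latent-factor Gaussian model
(so within-community Pearson correlation concentrates near rho_in), the PPI
network is a stochastic block model over the same communities with
STRING-like integer scores, miRNA-target edges point into the miRNA's own
community with fidelity q, and a small two-level GO DAG assigns each
community a branch of terms.  Protein annotations carry the community's leaf
terms with occasional cross-community flips (noise epsilon) plus IEA/NOT rows
that downstream filtering must remove.  The planted truth (community of every
node, term->community map, ancestor-closed miRNA term sets) is emitted
alongside the six input files, so end-to-end recovery is measurable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import write_gaf

ROOT_TERM_OFFSET = 1000000


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic data set; all randomness from ``seed``."""

    n_mirna: int = 60
    n_protein: int = 120
    n_samples: int = 20
    n_communities: int = 3
    rho_in: float = 0.7  # expected within-community expression PCC
    rho_out: float = 0.0
    p_in: float = 0.3  # SBM edge probabilities for the PPI block
    p_out: float = 0.02
    q: float = 0.9  # probability a target edge stays in the miRNA's community
    targets_per_mirna: int = 4
    target_hub_frac: float = 0.2  # fraction of each community's proteins with validated targets
    n_terms: int = 12  # 1 root + n_communities mid terms + leaves
    annot_prob: float = 0.9  # per own-community leaf
    epsilon: float = 0.05  # cross-community annotation flip probability
    iea_prob: float = 0.3  # extra IEA rows (removed by evidence filtering)
    two_precursor_frac: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_communities > min(self.n_mirna, self.n_protein):
            raise ValueError("more communities than nodes")
        if self.n_terms < 1 + 2 * self.n_communities:
            raise ValueError("need at least one leaf term per community")
        for p in (self.rho_in, self.rho_out, self.p_in, self.p_out, self.q,
                  self.annot_prob, self.epsilon, self.iea_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if not (0.0 < self.target_hub_frac <= 1.0):
            raise ValueError("target_hub_frac must lie in (0, 1]")
        if self.rho_in <= self.rho_out:
            raise ValueError("rho_in must exceed rho_out for a recoverable instance")


@dataclass
class GroundTruth:
    """Planted structure consistent with the emitted files."""

    community: dict[str, int]  # bare node id -> community
    term_community: dict[str, int]  # non-root term -> community
    mirna_truth: dict[str, frozenset]  # mature miRNA -> ancestor-closed term set
    root_term: str = ""
    mid_terms: list[str] = field(default_factory=list)
    leaf_terms: list[str] = field(default_factory=list)


def _term_id(k: int) -> str:
    return f"GO:{ROOT_TERM_OFFSET + k:07d}"


def _make_dag(sc: SyntheticScenario):
    root = _term_id(0)
    mids = [_term_id(1 + c) for c in range(sc.n_communities)]
    n_leaves = sc.n_terms - 1 - sc.n_communities
    leaves = [_term_id(1 + sc.n_communities + i) for i in range(n_leaves)]
    leaf_comm = {leaf: i % sc.n_communities for i, leaf in enumerate(leaves)}
    return root, mids, leaves, leaf_comm


def write_obo(path, sc: SyntheticScenario) -> None:
    root, mids, leaves, leaf_comm = _make_dag(sc)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")

        def stanza(tid: str, name: str, parent: str | None) -> None:
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: biological_process\n")
            if parent:
                fh.write(f"is_a: {parent} ! parent\n")

        stanza(root, "synthetic biological process root", None)
        for c, mid in enumerate(mids):
            stanza(mid, f"community {c} process", root)
        for leaf in leaves:
            stanza(leaf, f"leaf process {leaf[-3:]}", mids[leaf_comm[leaf]])


def simulate(sc: SyntheticScenario, out_dir: str) -> GroundTruth:
    """Write the six input files plus ground-truth tables into ``out_dir``.

    Files: expression.tsv (precursor level), mapping.tsv, ppi.tsv,
    targets.tsv, go.obo, annotations.gaf, truth_communities.tsv,
    truth_mirna_terms.tsv, truth_term_communities.tsv.  Byte-identical given
    the same scenario.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(sc.seed)
    root, mids, leaves, leaf_comm = _make_dag(sc)

    mirnas = [f"mir-{i:04d}" for i in range(sc.n_mirna)]
    proteins = [f"PROT{i:04d}" for i in range(sc.n_protein)]
    m_comm = {m: i % sc.n_communities for i, m in enumerate(mirnas)}
    p_comm = {p: i % sc.n_communities for i, p in enumerate(proteins)}

    # --- expression: community latent factors + noise, precursor split ---
    g_factor = rng.normal(size=sc.n_samples)
    f_comm = rng.normal(size=(sc.n_communities, sc.n_samples))
    a_out = np.sqrt(sc.rho_out)
    a_in = np.sqrt(sc.rho_in - sc.rho_out)
    a_noise = np.sqrt(1.0 - sc.rho_in)
    mature_expr = {}
    for m in mirnas:
        eps = rng.normal(size=sc.n_samples)
        mature_expr[m] = a_out * g_factor + a_in * f_comm[m_comm[m]] + a_noise * eps

    mapping_rows = []
    expr_rows = {}
    for m in mirnas:
        n_prec = 2 if rng.random() < sc.two_precursor_frac else 1
        for k in range(n_prec):
            prec = f"pre-{m}-{chr(ord('a') + k)}"
            expr_rows[prec] = mature_expr[m] + rng.normal(scale=0.05, size=sc.n_samples)
            mapping_rows.append((prec, m))

    samples = [f"tissue{j:02d}" for j in range(sc.n_samples)]
    expr_df = pd.DataFrame.from_dict(expr_rows, orient="index", columns=samples)
    expr_df.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t",
                   index_label="precursor_id", float_format="%.6f")
    pd.DataFrame(mapping_rows, columns=["precursor_id", "mature_id"]).to_csv(
        os.path.join(out_dir, "mapping.tsv"), sep="\t", index=False
    )

    # --- PPI: stochastic block model with STRING-like scores ---
    ppi_rows = []
    for i in range(sc.n_protein):
        for j in range(i + 1, sc.n_protein):
            a, b = proteins[i], proteins[j]
            same = p_comm[a] == p_comm[b]
            if rng.random() < (sc.p_in if same else sc.p_out):
                mu, sd, lo, hi = (900, 50, 600, 999) if same else (400, 100, 150, 800)
                score = int(np.clip(rng.normal(mu, sd), lo, hi))
                ppi_rows.append((a, b, score))
    pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b", "score"]).to_csv(
        os.path.join(out_dir, "ppi.tsv"), sep="\t", index=False
    )

    # --- miRNA-target edges with fidelity q, restricted to hub proteins ---
    # only a small well-studied fraction of each community carries validated
    # targets, mirroring the sparse coverage of curated target databases
    by_comm: dict[int, list[str]] = {}
    for p in proteins:
        by_comm.setdefault(p_comm[p], []).append(p)
    hubs = {
        c: ps[: max(1, int(round(sc.target_hub_frac * len(ps))))]
        for c, ps in by_comm.items()
    }
    target_rows = []
    for m in mirnas:
        own = hubs[m_comm[m]]
        other = [p for c, ps in sorted(hubs.items()) if c != m_comm[m] for p in ps]
        seen = set()
        for _ in range(sc.targets_per_mirna):
            pool = own if rng.random() < sc.q else other
            tgt = pool[int(rng.integers(len(pool)))]
            if tgt not in seen:
                seen.add(tgt)
                target_rows.append((m, tgt))
    pd.DataFrame(target_rows, columns=["mirna_id", "target_id"]).to_csv(
        os.path.join(out_dir, "targets.tsv"), sep="\t", index=False
    )

    # --- ontology + protein annotations ---
    write_obo(os.path.join(out_dir, "go.obo"), sc)
    comm_leaves: dict[int, list[str]] = {}
    for leaf, c in leaf_comm.items():
        comm_leaves.setdefault(c, []).append(leaf)
    all_terms = mids + leaves
    gaf_rows = []
    for p in proteins:
        c = p_comm[p]
        direct = [leaf for leaf in comm_leaves[c] if rng.random() < sc.annot_prob]
        if not direct:
            direct = [comm_leaves[c][int(rng.integers(len(comm_leaves[c])))]]
        if rng.random() < sc.epsilon:
            wrong = [lf for lf in leaves if leaf_comm[lf] != c]
            direct.append(wrong[int(rng.integers(len(wrong)))])
        for leaf in direct:
            ev = "EXP" if rng.random() < 0.7 else "IDA"
            gaf_rows.append((p, "", leaf, ev))
        if rng.random() < sc.iea_prob:
            gaf_rows.append((p, "", all_terms[int(rng.integers(len(all_terms)))], "IEA"))
        if rng.random() < 0.02:
            gaf_rows.append((p, "NOT", all_terms[int(rng.integers(len(all_terms)))], "IDA"))
    write_gaf(os.path.join(out_dir, "annotations.gaf"), gaf_rows)

    # --- planted truth ---
    community = {**m_comm, **p_comm}
    term_community = {mid: c for c, mid in enumerate(mids)}
    term_community.update(leaf_comm)
    mirna_truth = {
        m: frozenset([mids[m_comm[m]]] + comm_leaves[m_comm[m]]) for m in mirnas
    }

    with open(os.path.join(out_dir, "truth_communities.tsv"), "w", encoding="utf-8") as fh:
        fh.write("node_id\tcommunity\n")
        for node in mirnas + proteins:
            fh.write(f"{node}\t{community[node]}\n")
    with open(os.path.join(out_dir, "truth_term_communities.tsv"), "w", encoding="utf-8") as fh:
        fh.write("go_term\tcommunity\n")
        for term in mids + leaves:
            fh.write(f"{term}\t{term_community[term]}\n")
    with open(os.path.join(out_dir, "truth_mirna_terms.tsv"), "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tgo_term\n")
        for m in mirnas:
            for term in sorted(mirna_truth[m]):
                fh.write(f"{m}\t{term}\n")

    return GroundTruth(
        community=community,
        term_community=term_community,
        mirna_truth=mirna_truth,
        root_term=root,
        mid_terms=mids,
        leaf_terms=leaves,
    )


def default_fixture(seed: int = 1) -> SyntheticScenario:
    """The canonical desk-scale scenario used by the acceptance suite."""
    return SyntheticScenario(seed=seed)


def fixture_pipeline_params() -> dict:
    """Desk-scale embedding/SVM settings paired with the default fixture.

    Small enough for the whole pipeline to run in minutes on one CPU while
    still recovering the planted structure; the CLI keeps the full-scale
    defaults (100 walks of length 80, window 16, 512 dims, full grids).
    """
    return {
        "walks_per_node": 20,
        "walk_length": 40,
        "window": 5,
        "dim": 64,
        "epochs": 1,
        "c_grid": tuple(2.0**e for e in range(-1, 10, 2)),
        "g_grid": tuple(2.0**e for e in range(-7, 4, 2)),
        "folds": 10,
        "min_pos": 10,
    }
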