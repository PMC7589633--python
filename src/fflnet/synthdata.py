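"""Synthetic inputs with planted ground truth for the whole pipeline.

The generators emulate the structure of a small paired-design study — a paired
two-condition microarray design (five donors, each profiled in both
conditions, gene and miRNA platforms as continuous log2 intensities)
over a mixed TF/miRNA/gene regulatory network — plus the downstream
inputs (pathway annotations, cancer DE lists, drug tables).  Every
generator is a pure function of its parameters and seed, and the
planted truth is serialized alongside the data so recall/precision/AUC
of every stage can be computed without re-reading generator internals.

Planted dysregulation has two components per planted FFL:

* node effects: each of the three nodes' case mean is shifted by
  ``±effect_lfc`` (sign alternating across planted nodes);
* coexpression change: a per-FFL latent factor with loadings
  ``(+a, +a, +a)`` on (TF, miRNA, gene) in the case condition and
  ``(+a, -a, +a)`` in the control condition, with ``a`` chosen so each
  factor-coupled pair attains correlation ``±coexpr_delta``.  The
  TF-miRNA and miRNA-gene pairs therefore flip from ``+delta`` to
  ``-delta`` across conditions; the TF-gene pair stays at ``+delta`` in
  both (a three-variable correlation matrix with all pairs at a large
  negative value is not positive definite, so a full sign flip of all
  three pairs is unrealizable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .netio import (
    GeneSetCollection,
    NetworkError,
    Regulation,
    RegulatoryNetwork,
    build_network,
)
from .expr import ExpressionStudy
from .pancancer import RankedSignature

#: per-feature biological noise and shared donor effect, log2 scale
DONOR_SD = 0.5
BASELINE_MEAN = 8.0
BASELINE_SD = 1.5

FFL_TYPE_CYCLE = ("TF_FFL", "MIRNA_FFL", "FB_FFL")


@dataclass
class SynthTruth:
    """Ground truth planted by the generators."""

    planted_ffls: list[dict] = field(default_factory=list)
    node_effects: dict[str, float] = field(default_factory=dict)
    edge_coexpr: dict[str, dict[str, float]] = field(default_factory=dict)
    cancer_labels: dict[str, str] = field(default_factory=dict)
    drug_winner: str | None = None

    def planted_keys(self) -> set[tuple[str, str, str]]:
        return {(f["tf"], f["mirna"], f["gene"]) for f in self.planted_ffls}

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthTruth":
        with Path(path).open(encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(**data)


def _preferential_edges(
    sources: list[str],
    targets: list[str],
    n_edges: int,
    edge_class: str,
    rng: np.random.Generator,
) -> list[Regulation]:
    """Random typed edges with preferential attachment on target in-degree."""
    n_possible = len(sources) * len(targets)
    n_edges = min(n_edges, n_possible)
    weights = np.ones(len(targets))
    chosen: set[tuple[int, int]] = set()
    edges: list[Regulation] = []
    while len(edges) < n_edges:
        si = int(rng.integers(len(sources)))
        ti = int(rng.choice(len(targets), p=weights / weights.sum()))
        if (si, ti) in chosen or sources[si] == targets[ti]:
            continue
        chosen.add((si, ti))
        weights[ti] += 1.0  # rich get richer
        edges.append(Regulation(sources[si], targets[ti], edge_class, "synthetic"))
    return edges


def synth_network(
    n_tf: int = 50,
    n_mirna: int = 80,
    n_gene: int = 300,
    edge_density: float = 0.06,
    n_planted_ffls: int = 10,
    seed: int = 0,
) -> tuple[RegulatoryNetwork, SynthTruth]:
    """Random typed network (preferential attachment per class) with planted FFLs.

    ``edge_density`` is the expected fraction of possible (source, target)
    pairs realized in each of the four edge classes; 0 yields only the
    planted motif edges.  Planted FFLs use class-distinct node triples
    (types cycling TF_FFL, MIRNA_FFL, FB_FFL) and their edges are added
    on top of the random background.
    """
    if min(n_tf, n_mirna, n_gene) < 1:
        raise NetworkError("node counts must be >= 1")
    if not 0.0 <= edge_density < 1.0:
        raise NetworkError("edge_density must be in [0, 1)")
    if n_planted_ffls > min(n_tf, n_mirna, n_gene):
        raise NetworkError(
            f"cannot plant {n_planted_ffls} node-disjoint FFLs in "
            f"({n_tf} TF, {n_mirna} miRNA, {n_gene} gene)"
        )
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i:04d}" for i in range(1, n_tf + 1)]
    mirnas = [f"miR{i:04d}" for i in range(1, n_mirna + 1)]
    genes = [f"G{i:04d}" for i in range(1, n_gene + 1)]

    regs: list[Regulation] = []
    for sources, targets, cls in (
        (tfs, genes, "tf_gene"),
        (tfs, mirnas, "tf_mirna"),
        (mirnas, genes, "mirna_gene"),
        (mirnas, tfs, "mirna_tf"),
    ):
        n_edges = int(round(edge_density * len(sources) * len(targets)))
        regs.extend(_preferential_edges(sources, targets, n_edges, cls, rng))

    truth = SynthTruth()
    p_tfs = rng.choice(tfs, size=n_planted_ffls, replace=False)
    p_mirnas = rng.choice(mirnas, size=n_planted_ffls, replace=False)
    p_genes = rng.choice(genes, size=n_planted_ffls, replace=False)
    # background TF<->miRNA edges between a planted pair could upgrade its
    # motif type (e.g. MIRNA_FFL -> FB_FFL); drop them so truth types hold
    planted_pairs = {(str(p_tfs[i]), str(p_mirnas[i])) for i in range(n_planted_ffls)}
    regs = [
        r
        for r in regs
        if not (
            (r.edge_class == "tf_mirna" and (r.source, r.target) in planted_pairs)
            or (r.edge_class == "mirna_tf" and (r.target, r.source) in planted_pairs)
        )
    ]
    for i in range(n_planted_ffls):
        tf, m, g = str(p_tfs[i]), str(p_mirnas[i]), str(p_genes[i])
        ffl_type = FFL_TYPE_CYCLE[i % 3]
        regs.append(Regulation(tf, g, "tf_gene", "planted"))
        regs.append(Regulation(m, g, "mirna_gene", "planted"))
        if ffl_type in ("TF_FFL", "FB_FFL"):
            regs.append(Regulation(tf, m, "tf_mirna", "planted"))
        if ffl_type in ("MIRNA_FFL", "FB_FFL"):
            regs.append(Regulation(m, tf, "mirna_tf", "planted"))
        truth.planted_ffls.append({"tf": tf, "mirna": m, "gene": g, "ffl_type": ffl_type})
    return build_network(regs), truth


def synth_expression(
    network: RegulatoryNetwork,
    truth: SynthTruth,
    n_pairs: int = 5,
    effect_lfc: float = 2.0,
    coexpr_delta: float = 0.8,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionStudy, SynthTruth]:
    """Paired two-condition log2 expression for every network node.

    Genes and TFs populate the gene matrix, miRNAs the miRNA matrix.
    Values are baseline + donor effect + noise, plus the planted node
    shifts and latent-factor coexpression described in the module
    docstring.  The realized shifts and target correlations are recorded
    into the returned truth.
    """
    if n_pairs < 4:
        raise NetworkError("edge scoring needs n_pairs >= 4 (variance term requires n > 3)")
    if noise_sd <= 0:
        raise NetworkError("noise_sd must be > 0")
    if not 0.0 <= coexpr_delta < 1.0:
        raise NetworkError("coexpr_delta must be in [0, 1)")
    rng = np.random.default_rng(seed)

    gene_features = sorted(n for n, c in network.nodes.items() if c in ("gene", "TF"))
    mirna_features = network.nodes_of_class("miRNA")
    features = gene_features + mirna_features
    fidx = {f: i for i, f in enumerate(features)}
    n_feat = len(features)

    donors = [f"D{i}" for i in range(1, n_pairs + 1)]
    case_cols = [f"{d}_case" for d in donors]
    ctrl_cols = [f"{d}_control" for d in donors]

    base = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_feat)
    donor_eff = rng.normal(0.0, DONOR_SD, size=(n_feat, n_pairs))
    case = base[:, None] + donor_eff + rng.normal(0.0, noise_sd, size=(n_feat, n_pairs))
    ctrl = base[:, None] + donor_eff + rng.normal(0.0, noise_sd, size=(n_feat, n_pairs))

    # planted node shifts, sign alternating over the flattened node list
    sign = 1.0
    for ffl in truth.planted_ffls:
        for node in (ffl["tf"], ffl["mirna"], ffl["gene"]):
            if node in truth.node_effects:
                continue
            case[fidx[node]] += sign * effect_lfc
            truth.node_effects[node] = sign * effect_lfc
            sign = -sign

    # planted coexpression via one latent factor per FFL per condition
    if coexpr_delta > 0:
        resid_var = noise_sd**2 + DONOR_SD**2
        a = np.sqrt(coexpr_delta / (1.0 - coexpr_delta) * resid_var)
        for ffl in truth.planted_ffls:
            f_case = rng.normal(0.0, 1.0, size=n_pairs)
            f_ctrl = rng.normal(0.0, 1.0, size=n_pairs)
            loads_case = {"tf": a, "mirna": a, "gene": a}
            loads_ctrl = {"tf": a, "mirna": -a, "gene": a}
            for role in ("tf", "mirna", "gene"):
                i = fidx[ffl[role]]
                case[i] += loads_case[role] * f_case
                ctrl[i] += loads_ctrl[role] * f_ctrl
            key = "|".join([ffl["tf"], ffl["mirna"], ffl["gene"]])
            truth.edge_coexpr[key] = {
                "r_case_tm": coexpr_delta,
                "r_case_tg": coexpr_delta,
                "r_case_mg": coexpr_delta,
                "r_control_tm": -coexpr_delta,
                "r_control_tg": coexpr_delta,
                "r_control_mg": -coexpr_delta,
            }

    matrix = np.concatenate([case, ctrl], axis=1)
    all_cols = case_cols + ctrl_cols
    frame = pd.DataFrame(matrix, index=pd.Index(features, name="feature"), columns=all_cols)
    samples = pd.DataFrame(
        {
            "condition": ["case"] * n_pairs + ["control"] * n_pairs,
            "pair_id": donors + donors,
        },
        index=pd.Index(all_cols, name="sample"),
    )
    study = ExpressionStudy(
        genes=frame.loc[gene_features],
        mirnas=frame.loc[mirna_features],
        samples=samples,
    )
    return study, truth


def synth_annotations(
    network: RegulatoryNetwork,
    truth: SynthTruth,
    n_systems: int = 5,
    pathways_per_system: int = 2,
    coverage: float = 0.25,
    n_general: int = 2,
    seed: int = 0,
) -> tuple[GeneSetCollection, dict[str, set[str]]]:
    """Pathway annotations plus a system map covering the planted FFLs.

    Each system gets ``pathways_per_system`` pathways of random network
    nodes (fraction ``coverage`` of all nodes).  Planted FFL nodes are
    additionally injected: planted FFL *i* into system ``i mod
    n_systems``; the first ``n_general`` planted FFLs into three systems,
    making them system-general at the default sharing threshold.
    """
    rng = np.random.default_rng(seed)
    all_nodes = sorted(network.nodes)
    systems = [f"system{i}" for i in range(1, n_systems + 1)]
    sets: dict[str, set[str]] = {}
    system_map: dict[str, set[str]] = {s: set() for s in systems}
    for si, system in enumerate(systems):
        for pi in range(pathways_per_system):
            name = f"{system}_pw{pi + 1}"
            size = max(3, int(round(coverage * len(all_nodes))))
            members = set(map(str, rng.choice(all_nodes, size=min(size, len(all_nodes)), replace=False)))
            sets[name] = members
            system_map[system].add(name)
    for i, ffl in enumerate(truth.planted_ffls):
        nodes = {ffl["tf"], ffl["mirna"], ffl["gene"]}
        targets = [systems[i % n_systems]]
        if i < n_general:
            targets = [systems[j % n_systems] for j in range(i, i + 3)]
        for system in targets:
            pw = sorted(system_map[system])[0]
            sets[pw] |= nodes
    return GeneSetCollection(sets=sets), system_map


def synth_cancer_de(
    signature: RankedSignature,
    pattern: str = "consistent",
    n_up: int = 30,
    n_down: int = 30,
    enrichment_strength: float = 6.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, str]:
    """A synthetic cancer DE list with a known concordance pattern.

    ``consistent`` samples the cancer's up genes with weights decaying in
    perturbation rank (top-heavy) and its down genes with increasing
    weights (bottom-heavy); ``reverse`` swaps the two; ``null`` samples
    uniformly.  Returns (gene, log2FC, FDR, direction) and the label.
    """
    if pattern not in ("consistent", "reverse", "null"):
        raise NetworkError(f"unknown pattern {pattern!r}")
    N = len(signature)
    if n_up + n_down > N:
        raise NetworkError("n_up + n_down exceeds the signature universe")
    rng = np.random.default_rng(seed)
    genes = np.array(signature.genes)
    rel_rank = np.arange(N) / max(N - 1, 1)  # 0 = top (most up in perturbation)
    top_heavy = np.exp(-enrichment_strength * rel_rank)
    bottom_heavy = np.exp(enrichment_strength * (rel_rank - 1.0))
    uniform = np.ones(N)
    if pattern == "consistent":
        w_up, w_down = top_heavy, bottom_heavy
    elif pattern == "reverse":
        w_up, w_down = bottom_heavy, top_heavy
    else:
        w_up, w_down = uniform, uniform

    available = np.ones(N, dtype=bool)
    rows = []
    for direction, n_pick, w in (("up", n_up, w_up), ("down", n_down, w_down)):
        if n_pick == 0:
            continue
        weights = w * available
        idx = rng.choice(N, size=n_pick, replace=False, p=weights / weights.sum())
        available[idx] = False
        for i in sorted(idx):
            lfc = float(rng.uniform(1.0, 4.0))
            rows.append(
                {
                    "gene": str(genes[i]),
                    "log2FC": lfc if direction == "up" else -lfc,
                    "FDR": float(rng.uniform(0.0, 0.05)),
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "log2FC", "FDR", "direction"]), pattern


def synth_drug_tables(
    pert_de: dict[str, set[str]],
    target_mirnas: set[str],
    n_drugs: int = 8,
    p_hit: float = 0.2,
    min_reversed: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, dict[str, str]], SynthTruth]:
    """Drug->miRNA effects and drug gene signatures with one designed winner.

    ``DRUG001`` is the designed winner: it downregulates every target
    miRNA and reverses every perturbation DE gene.  Decoys hit targets
    and genes at rate ``p_hit`` with random directions, and are capped
    strictly below the winner in both screens so the planted ranking is
    unambiguous.
    """
    if n_drugs < 1:
        raise NetworkError("n_drugs must be >= 1")
    if not 0.0 <= p_hit < 1.0:
        raise NetworkError("p_hit must be in [0, 1)")
    rng = np.random.default_rng(seed)
    drugs = [f"DRUG{i:03d}" for i in range(1, n_drugs + 1)]
    winner = drugs[0]
    targets = sorted(target_mirnas)
    up, down = sorted(pert_de.get("up", set())), sorted(pert_de.get("down", set()))
    pert_genes = up + down

    mirna_rows = []
    signatures: dict[str, dict[str, str]] = {}
    for m in targets:
        mirna_rows.append({"drug": winner, "mirna": m, "effect": "down", "provenance": "synthetic"})
    signatures[winner] = {g: "down" for g in up} | {g: "up" for g in down}

    n_rev_winner = len(pert_genes)
    for drug in drugs[1:]:
        downs = [m for m in targets if rng.random() < p_hit and rng.random() < 0.5]
        if len(downs) >= len(targets):
            downs = downs[:-1]  # decoys never match the winner's coverage
        for m in targets:
            if m in downs:
                mirna_rows.append({"drug": drug, "mirna": m, "effect": "down", "provenance": "synthetic"})
            elif rng.random() < p_hit:
                mirna_rows.append({"drug": drug, "mirna": m, "effect": "up", "provenance": "synthetic"})
        sig: dict[str, str] = {}
        for g in pert_genes:
            if rng.random() < p_hit:
                sig[g] = str(rng.choice(["up", "down"]))
        reversed_count = sum(
            1 for g in up if sig.get(g) == "down"
        ) + sum(1 for g in down if sig.get(g) == "up")
        while reversed_count >= max(n_rev_winner, 1):
            victim = next(g for g in sig if (g in up and sig[g] == "down") or (g in down and sig[g] == "up"))
            del sig[victim]
            reversed_count -= 1
        if sig:
            signatures[drug] = sig
    table = pd.DataFrame(mirna_rows, columns=["drug", "mirna", "effect", "provenance"])
    truth = SynthTruth(drug_winner=winner)
    return table, signatures, truth
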