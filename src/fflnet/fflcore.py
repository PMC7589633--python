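"""FFL enumeration, dysregulation scoring and permutation significance.

A feed-forward loop (FFL) is a (TF, miRNA, gene) triple in which both
regulators target the gene and at least one regulates the other:

* TF-FFL:    tf -> mirna (only)
* miRNA-FFL: mirna -> tf (only)
* FB-FFL:    tf -> mirna and mirna -> tf (mutual)

Each FFL is scored by combining the differential expression of its three
nodes with the differential coexpression of its three edges.

Node score: with ``Diff = (-log10 p) * |log2FC| >= 0``,

    S_node = Phi^-1( 2*Phi(Diff) - 1 )

(the inner probability ``1 - 2*(1 - Phi(Diff))`` is clamped away from 0
and 1 so the score stays finite).

Edge score: within-condition Spearman correlations ``r_case``,
``r_control`` are Fisher-transformed, ``F(r) = atanh(r)``, and the
standardized difference

    D = (F(r_case) - F(r_control)) / sqrt(1.06/(n_case-3) + 1.06/(n_control-3))

is folded through the same inverse-normal map with |D| in place of Diff.
The 1.06 factor inflates the asymptotic variance of the Fisher z of a
Spearman correlation relative to a Pearson one.

FFL score: a weighted sum of the node and edge means,

    s_FFL = gamma * mean(S_node) + (1 - gamma) * mean(S_edge),

gamma = 0.5 by default.  Significance is assessed against a single shared
permutation null: random composition-matched triples (one TF, one miRNA,
one gene, uniform within class) scored identically, whether or not the
regulations exist; the empirical p-value of a real FFL is the proportion
of null scores strictly larger than its score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expr import ExpressionStudy
from .netio import Regulation, RegulatoryNetwork, build_network

FFL_TYPES = ("TF_FFL", "MIRNA_FFL", "FB_FFL")


class ScoringError(ValueError):
    """Invalid scoring parameters or inputs."""


@dataclass
class ScoreParams:
    """Tuning knobs of the FFL score.

    gamma
        Weight of the node term in (0, 1); 0.5 weighs differential
        expression and differential coexpression equally.
    clamp_eps
        Floor/ceiling for the inner tail probabilities of the
        inverse-normal maps; keeps scores finite at Diff = 0 or D = 0.
    spearman_clamp
        |r| bound applied before the Fisher transform, which diverges at 1.
    """

    gamma: float = 0.5
    clamp_eps: float = 1e-15
    spearman_clamp: float = 1.0 - 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ScoringError(f"gamma must be in (0,1), got {self.gamma}")
        if not 0.0 < self.clamp_eps < 0.5:
            raise ScoringError(f"clamp_eps must be in (0,0.5), got {self.clamp_eps}")
        if not 0.0 < self.spearman_clamp < 1.0:
            raise ScoringError("spearman_clamp must be in (0,1)")


@dataclass
class NullDistribution:
    """Scores of random composition-matched triples, one shared null."""

    scores: np.ndarray
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.n_draws,):
            raise ScoringError("null length must equal n_draws")


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_ffls(network: RegulatoryNetwork) -> pd.DataFrame:
    """Enumerate every FFL triple exactly once, typed.

    Returns a DataFrame with columns ``tf, mirna, gene, ffl_type``, sorted
    by (tf, mirna, gene).  A mutually-regulating TF/miRNA pair yields one
    FB_FFL record per shared target, never separate TF_FFL/MIRNA_FFL rows.
    """
    tf_gene = network.successors("tf_gene")
    tf_mirna = network.successors("tf_mirna")
    mirna_gene = network.successors("mirna_gene")
    mirna_tf = network.successors("mirna_tf")
    gene_class = network.nodes

    pairs: dict[tuple[str, str], str] = {}
    for tf, mirnas in tf_mirna.items():
        for m in mirnas:
            pairs[(tf, m)] = "TF_FFL"
    for m, tfs in mirna_tf.items():
        for tf in tfs:
            key = (tf, m)
            pairs[key] = "FB_FFL" if key in pairs else "MIRNA_FFL"

    rows = []
    for (tf, m), ffl_type in pairs.items():
        # shared targets must be genuine gene-class targets of both
        shared = tf_gene.get(tf, set()) & mirna_gene.get(m, set())
        for g in shared:
            if gene_class.get(g) == "gene":
                rows.append((tf, m, g, ffl_type))
    out = pd.DataFrame(rows, columns=["tf", "mirna", "gene", "ffl_type"])
    return out.sort_values(["tf", "mirna", "gene"], ignore_index=True)


def brute_force_ffls(network: RegulatoryNetwork) -> pd.DataFrame:
    """Independent oracle: scan all TF x miRNA x gene triples directly."""
    tfs = network.nodes_of_class("TF")
    mirnas = network.nodes_of_class("miRNA")
    genes = network.nodes_of_class("gene")
    rows = []
    for tf in tfs:
        for m in mirnas:
            t2m = network.has_edge(tf, m, "tf_mirna")
            m2t = network.has_edge(m, tf, "mirna_tf")
            if not (t2m or m2t):
                continue
            ffl_type = "FB_FFL" if (t2m and m2t) else ("TF_FFL" if t2m else "MIRNA_FFL")
            for g in genes:
                if network.has_edge(tf, g, "tf_gene") and network.has_edge(m, g, "mirna_gene"):
                    rows.append((tf, m, g, ffl_type))
    out = pd.DataFrame(rows, columns=["tf", "mirna", "gene", "ffl_type"])
    return out.sort_values(["tf", "mirna", "gene"], ignore_index=True)


# ---------------------------------------------------------------------------
# score primitives
# ---------------------------------------------------------------------------

def _inv_normal_fold(x: np.ndarray | float, clamp_eps: float) -> np.ndarray | float:
    """Phi^-1(clamp(2*Phi(x) - 1)) for x >= 0."""
    inner = 2.0 * stats.norm.cdf(x) - 1.0
    inner = np.clip(inner, clamp_eps, 1.0 - clamp_eps)
    return stats.norm.ppf(inner)


def node_score(diff_score: float | np.ndarray, clamp_eps: float = 1e-15) -> float | np.ndarray:
    """Inverse-normal transform of the two-sided tail of Diff = (-log10 p)*|log2FC|."""
    diff = np.asarray(diff_score, dtype=float)
    if np.any(diff < 0):
        raise ScoringError("diff_score must be >= 0")
    out = _inv_normal_fold(diff, clamp_eps)
    return float(out) if np.isscalar(diff_score) else out


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher transformation F(r) = (1/2) ln((1+r)/(1-r)) = atanh(r)."""
    out = np.arctanh(r)
    return float(out) if np.isscalar(r) else out


@dataclass
class EdgeScoreParts:
    """Intermediate quantities of one edge's differential-coexpression score."""

    r_case: float
    r_control: float
    z_case: float
    z_control: float
    D: float
    s_edge: float


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks; constant input -> 0 with a warning."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant expression vector: Spearman undefined, using r = 0")
        return 0.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def edge_score(
    x_src_case: np.ndarray,
    x_tgt_case: np.ndarray,
    x_src_control: np.ndarray,
    x_tgt_control: np.ndarray,
    params: ScoreParams | None = None,
) -> EdgeScoreParts:
    """Differential-coexpression score of one regulator/target pair.

    Spearman correlations within each condition, Fisher-transformed, then
    the standardized difference D with the 1.06 variance inflation; the
    edge score folds |D| through the inverse-normal map.  Both conditions
    need more than 3 samples for the variance term to be positive.
    """
    params = params or ScoreParams()
    n_case, n_control = len(x_src_case), len(x_src_control)
    if n_case <= 3 or n_control <= 3:
        raise ScoringError("edge scoring requires > 3 samples per condition")
    r_case = _spearman(np.asarray(x_src_case, float), np.asarray(x_tgt_case, float))
    r_control = _spearman(np.asarray(x_src_control, float), np.asarray(x_tgt_control, float))
    c = params.spearman_clamp
    z_case = float(fisher_z(np.clip(r_case, -c, c)))
    z_control = float(fisher_z(np.clip(r_control, -c, c)))
    denom = np.sqrt(1.06 / (n_case - 3) + 1.06 / (n_control - 3))
    D = (z_case - z_control) / denom
    s = float(_inv_normal_fold(abs(D), params.clamp_eps))
    return EdgeScoreParts(r_case, r_control, z_case, z_control, float(D), s)


def ffl_score(node_scores: Sequence[float], edge_scores: Sequence[float], gamma: float = 0.5) -> float:
    """s_FFL = gamma * mean(node scores) + (1 - gamma) * mean(edge scores)."""
    if not 0.0 < gamma < 1.0:
        raise ScoringError(f"gamma must be in (0,1), got {gamma}")
    node_scores = np.asarray(node_scores, dtype=float)
    edge_scores = np.asarray(edge_scores, dtype=float)
    if node_scores.shape != (3,) or edge_scores.shape != (3,):
        raise ScoringError("an FFL has exactly 3 node scores and 3 edge scores")
    return float(gamma * node_scores.mean() + (1.0 - gamma) * edge_scores.mean())


# ---------------------------------------------------------------------------
# vectorised triple scoring over an expression study
# ---------------------------------------------------------------------------

class TripleScorer:
    """Precomputed machinery to score many (TF, miRNA, gene) triples fast.

    Expression rows are rank-transformed within each condition and
    standardized so that a Spearman correlation is a dot product; node
    scores are precomputed from the DE tables.  Triples whose nodes lack
    expression or DE entries are reported via :attr:`missing_nodes`.
    """

    def __init__(
        self,
        study: ExpressionStudy,
        de_tables: dict[str, pd.DataFrame],
        params: ScoreParams | None = None,
    ) -> None:
        self.params = params or ScoreParams()
        self.study = study
        case_cols = study.condition_columns("case")
        ctrl_cols = study.condition_columns("control")
        self.n_case, self.n_control = len(case_cols), len(ctrl_cols)
        if self.n_case <= 3 or self.n_control <= 3:
            raise ScoringError("edge scoring requires > 3 samples per condition")

        frames = []
        for cls in ("gene", "miRNA"):
            mat = study.matrix(cls)
            frames.append(mat)
        combined = pd.concat(frames)
        if combined.index.duplicated().any():
            raise ScoringError("feature ids must be unique across gene and miRNA matrices")
        self.feature_index = {f: i for i, f in enumerate(combined.index)}
        self._ranks_case = self._standardized_ranks(combined[case_cols].to_numpy(float))
        self._ranks_ctrl = self._standardized_ranks(combined[ctrl_cols].to_numpy(float))

        diff = pd.concat([de_tables["gene"]["diff_score"], de_tables["miRNA"]["diff_score"]])
        diff = diff.reindex(combined.index)
        self._node_scores = np.where(
            diff.notna().to_numpy(),
            _inv_normal_fold(diff.fillna(0.0).to_numpy(float), self.params.clamp_eps),
            np.nan,
        )
        self._has_de = diff.notna().to_numpy()
        self.missing_nodes: set[str] = set()

    @staticmethod
    def _standardized_ranks(mat: np.ndarray) -> np.ndarray:
        """Center each row's average ranks and scale to unit norm (0 if constant)."""
        ranks = stats.rankdata(mat, axis=1)
        ranks = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(ranks, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(norms > 0, ranks / np.where(norms == 0, 1.0, norms), 0.0)
        return out

    def resolve(self, names: Iterable[str]) -> np.ndarray:
        """Map feature names to row indices; -1 where absent."""
        return np.array([self.feature_index.get(n, -1) for n in names], dtype=np.int64)

    def _pair_edge_scores(self, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
        c = self.params.spearman_clamp
        r_case = np.einsum("ij,ij->i", self._ranks_case[ia], self._ranks_case[ib])
        r_ctrl = np.einsum("ij,ij->i", self._ranks_ctrl[ia], self._ranks_ctrl[ib])
        z = np.arctanh(np.clip(r_case, -c, c)) - np.arctanh(np.clip(r_ctrl, -c, c))
        denom = np.sqrt(1.06 / (self.n_case - 3) + 1.06 / (self.n_control - 3))
        return _inv_normal_fold(np.abs(z / denom), self.params.clamp_eps)

    def score_triples(self, tf_idx: np.ndarray, mi_idx: np.ndarray, g_idx: np.ndarray) -> dict[str, np.ndarray]:
        """Score index triples; all indices must be valid rows with DE entries."""
        s_nodes = np.stack(
            [self._node_scores[tf_idx], self._node_scores[mi_idx], self._node_scores[g_idx]]
        )
        s_edges = np.stack(
            [
                self._pair_edge_scores(tf_idx, mi_idx),
                self._pair_edge_scores(tf_idx, g_idx),
                self._pair_edge_scores(mi_idx, g_idx),
            ]
        )
        gamma = self.params.gamma
        total = gamma * s_nodes.mean(axis=0) + (1 - gamma) * s_edges.mean(axis=0)
        return {"node_scores": s_nodes, "edge_scores": s_edges, "score": total}


def score_ffls(
    ffls: pd.DataFrame,
    study: ExpressionStudy,
    de_tables: dict[str, pd.DataFrame],
    params: ScoreParams | None = None,
    scorer: TripleScorer | None = None,
) -> pd.DataFrame:
    """Attach node scores, edge scores and s_FFL to enumerated FFLs.

    FFLs with any node missing from the expression matrices or DE tables
    are skipped; the skip count is reported in ``DataFrame.attrs['n_skipped']``.
    """
    scorer = scorer or TripleScorer(study, de_tables, params)
    ti = scorer.resolve(ffls["tf"])
    mi = scorer.resolve(ffls["mirna"])
    gi = scorer.resolve(ffls["gene"])
    def scorable(idx: np.ndarray) -> np.ndarray:
        return (idx >= 0) & scorer._has_de[np.clip(idx, 0, None)]

    ok = scorable(ti) & scorable(mi) & scorable(gi)
    for col, idx in (("tf", ti), ("mirna", mi), ("gene", gi)):
        scorer.missing_nodes.update(ffls[col][~scorable(idx)])
    out = ffls.loc[ok].reset_index(drop=True).copy()
    parts = scorer.score_triples(ti[ok], mi[ok], gi[ok])
    out[["s_node_tf", "s_node_mirna", "s_node_gene"]] = parts["node_scores"].T
    out[["s_edge_tm", "s_edge_tg", "s_edge_mg"]] = parts["edge_scores"].T
    out["score"] = parts["score"]
    out.attrs["n_skipped"] = int((~ok).sum())
    return out


def permutation_null(
    network: RegulatoryNetwork,
    study: ExpressionStudy,
    de_tables: dict[str, pd.DataFrame],
    n_draws: int = 100_000,
    seed: int = 0,
    params: ScoreParams | None = None,
    composition_matched: bool = True,
    scorer: TripleScorer | None = None,
) -> NullDistribution:
    """Score ``n_draws`` random triples to form the shared null.

    Composition-matched draws take one TF, one miRNA and one gene
    uniformly from their classes (restricted to nodes with expression and
    DE entries); the unconstrained variant draws any three distinct
    molecules.  Edges are scored from expression alone — the sampled
    regulations need not exist in the network.
    """
    if n_draws < 1:
        raise ScoringError("n_draws must be >= 1")
    scorer = scorer or TripleScorer(study, de_tables, params)

    def usable(names: list[str]) -> np.ndarray:
        idx = scorer.resolve(names)
        keep = (idx >= 0) & scorer._has_de[np.clip(idx, 0, None)]
        return idx[keep]

    rng = np.random.default_rng(seed)
    if composition_matched:
        pools = [usable(network.nodes_of_class(c)) for c in ("TF", "miRNA", "gene")]
        for cls, pool in zip(("TF", "miRNA", "gene"), pools):
            if pool.size == 0:
                raise ScoringError(f"no scorable nodes of class {cls}")
        ti = rng.choice(pools[0], size=n_draws)
        mi = rng.choice(pools[1], size=n_draws)
        gi = rng.choice(pools[2], size=n_draws)
    else:
        pool = usable(sorted(network.nodes))
        if pool.size < 3:
            raise ScoringError("need >= 3 scorable nodes")
        draws = np.array([rng.choice(pool, size=3, replace=False) for _ in range(n_draws)])
        ti, mi, gi = draws[:, 0], draws[:, 1], draws[:, 2]
    scores = scorer.score_triples(ti, mi, gi)["score"]
    return NullDistribution(scores=scores, n_draws=n_draws, seed=seed)


def node_disjoint_ffls(ffls: pd.DataFrame) -> pd.DataFrame:
    """Greedy maximal subset of FFLs sharing no node.

    FFLs that share a TF, miRNA or gene have correlated scores (they reuse
    the same expression rows), so calibration diagnostics that assume
    independent observations should run on a node-disjoint subset.
    """
    used: set[str] = set()
    keep = []
    for idx, row in ffls.iterrows():
        nodes = {row["tf"], row["mirna"], row["gene"]}
        if nodes & used:
            continue
        used |= nodes
        keep.append(idx)
    return ffls.loc[keep]


def empirical_pvalues(
    real_scores: np.ndarray | pd.Series,
    null: NullDistribution,
    pseudocount: bool = False,
) -> np.ndarray:
    """p = #{null > s} / n_draws per FFL (strict inequality, plain proportion).

    ``pseudocount=True`` switches to (#{null > s} + 1) / (n_draws + 1),
    which never returns an exact zero.
    """
    null_sorted = np.sort(null.scores)
    s = np.asarray(real_scores, dtype=float)
    n_greater = len(null_sorted) - np.searchsorted(null_sorted, s, side="right")
    if pseudocount:
        return (n_greater + 1.0) / (null.n_draws + 1.0)
    return n_greater / float(null.n_draws)


def flag_dysregulated(
    scored: pd.DataFrame,
    null: NullDistribution,
    alpha: float = 0.05,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Attach empirical p-values and the dysregulated flag (p <= alpha)."""
    out = scored.copy()
    out["empirical_p"] = empirical_pvalues(out["score"].to_numpy(), null, pseudocount=pseudocount)
    out["dysregulated"] = out["empirical_p"] <= alpha
    return out


# ---------------------------------------------------------------------------
# dysregulated-network assembly
# ---------------------------------------------------------------------------

def ffl_edges(row: pd.Series | dict) -> list[tuple[str, str, str]]:
    """The typed edges of one FFL record (FB contributes both TF-miRNA directions)."""
    tf, m, g, t = row["tf"], row["mirna"], row["gene"], row["ffl_type"]
    edges = [(tf, g, "tf_gene"), (m, g, "mirna_gene")]
    if t in ("TF_FFL", "FB_FFL"):
        edges.append((tf, m, "tf_mirna"))
    if t in ("MIRNA_FFL", "FB_FFL"):
        edges.append((m, tf, "mirna_tf"))
    return edges


def dysregulated_network(ffls: pd.DataFrame) -> tuple[RegulatoryNetwork, dict[str, int]]:
    """Merge flagged FFLs into one network; report per-type counts."""
    flagged = ffls[ffls["dysregulated"]] if "dysregulated" in ffls.columns else ffls
    if flagged.empty:
        raise ScoringError("no dysregulated FFLs to merge")
    regs = []
    for _, row in flagged.iterrows():
        for src, tgt, cls in ffl_edges(row):
            regs.append(Regulation(src, tgt, cls, "dysregulated_ffl"))
    net = build_network(regs)
    counts = {t: int((flagged["ffl_type"] == t).sum()) for t in FFL_TYPES}
    counts["total"] = int(len(flagged))
    return net, counts


def hub_ffls(
    ffls: pd.DataFrame,
    merged: RegulatoryNetwork,
    min_degree: int = 10,
) -> tuple[pd.DataFrame, RegulatoryNetwork | None]:
    """FFLs whose three nodes all have degree >= min_degree in the merged network."""
    deg: dict[str, int] = {n: 0 for n in merged.nodes}
    for e in merged.edges:
        deg[e.source] += 1
        deg[e.target] += 1
    flagged = ffls[ffls["dysregulated"]] if "dysregulated" in ffls.columns else ffls
    is_hub = [
        min(deg.get(r["tf"], 0), deg.get(r["mirna"], 0), deg.get(r["gene"], 0)) >= min_degree
        for _, r in flagged.iterrows()
    ]
    hubs = flagged.loc[np.asarray(is_hub, dtype=bool)].reset_index(drop=True)
    if hubs.empty:
        return hubs, None
    regs = [Regulation(s, t, c, "hub_ffl") for _, row in hubs.iterrows() for s, t, c in ffl_edges(row)]
    return hubs, build_network(regs)


def cancer_gene_enrichment(
    subset_genes: set[str],
    background_genes: set[str],
    known_cancer_genes: set[str],
) -> dict:
    """Fisher exact test of known-cancer-gene overrepresentation in a subset.

    The 2x2 table partitions the background by subset membership and
    known-cancer status; p is the two-sided Fisher exact probability.
    """
    if not subset_genes <= background_genes:
        raise ScoringError("subset must be contained in background")
    known = known_cancer_genes & background_genes
    a = len(subset_genes & known)
    b = len(subset_genes - known)
    c = len(known - subset_genes)
    d = len(background_genes - subset_genes - known)
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "p_value": float(p)}


def write_ffl_table(ffls: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write the FFL record table as TSV with optional ``#`` header lines."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        ffls.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_ffl_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
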