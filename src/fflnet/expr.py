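"""Expression preprocessing and moderated differential expression.

The study design is a paired two-condition comparison: the same donors
profiled once per condition (``case`` vs ``control``), on two platforms
(a gene array, which also carries the TFs, and a miRNA array).  Values
are continuous log2 intensities.

Differential expression uses an empirical-Bayes moderated t: per-feature
sample variances are squeezed toward a pooled prior whose degrees of
freedom are estimated by fitting a scaled F distribution to the observed
variances (moment matching on log variances).  The moderated statistic is

    t~ = log2FC / (s_post * u),    s_post^2 = (d0*s0^2 + d*s^2) / (d0 + d)

with d0 the estimated prior df, d the residual df and u the unscaled
standard error (1/sqrt(n) for paired differences).  Two-sided p-values
come from the t distribution on d0 + d df.  Each feature also gets a
differential-expression magnitude

    diff_score = (-log10 p) * |log2FC|

which downstream node scoring consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

_P_TINY = np.finfo(float).tiny  # floor for p before -log10


class ExpressionError(ValueError):
    """Malformed expression input or degenerate design."""


@dataclass
class ExpressionStudy:
    """Paired two-condition expression matrices with sample metadata.

    Parameters
    ----------
    genes, mirnas
        Feature x sample matrices of log2 intensities.  Columns of both
        matrices must be the same sample ids in the same order.
    samples
        One row per sample (index = sample id) with columns ``condition``
        (``case``/``control``) and ``pair_id`` (donor).  Every pair id
        must appear exactly once per condition.
    """

    genes: pd.DataFrame
    mirnas: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        for name, mat in (("genes", self.genes), ("mirnas", self.mirnas)):
            if list(mat.columns) != list(self.samples.index):
                raise ExpressionError(f"{name} columns do not match the sample sheet")
            if mat.isna().any().any():
                raise ExpressionError(f"{name} matrix contains missing values")
        conds = set(self.samples["condition"])
        if conds != {"case", "control"}:
            raise ExpressionError(f"conditions must be case/control, got {sorted(conds)}")
        for cond in ("case", "control"):
            pairs = self.samples.loc[self.samples["condition"] == cond, "pair_id"]
            if pairs.duplicated().any():
                raise ExpressionError(f"duplicate pair_id within condition {cond}")
        case_pairs = set(self.samples.loc[self.samples["condition"] == "case", "pair_id"])
        ctrl_pairs = set(self.samples.loc[self.samples["condition"] == "control", "pair_id"])
        if case_pairs != ctrl_pairs:
            raise ExpressionError("pair ids differ between conditions")

    @property
    def n_pairs(self) -> int:
        return int((self.samples["condition"] == "case").sum())

    def matrix(self, feature_class: str) -> pd.DataFrame:
        if feature_class == "gene":
            return self.genes
        if feature_class == "miRNA":
            return self.mirnas
        raise ExpressionError(f"unknown feature class {feature_class!r}")

    def condition_columns(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of per-rank row means.

    After normalisation the sorted value vector of each column equals the
    reference vector (mean across columns of the k-th smallest values).
    Ties within a column receive the mean of their ranks' reference values.
    """
    if matrix.shape[1] < 2:
        raise ExpressionError("quantile normalisation needs >=2 columns")
    if matrix.isna().any().any():
        raise ExpressionError("matrix contains missing values")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # tied values all receive the mean of their ranks' reference values
        _, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(
    matrix: pd.DataFrame,
    probe_to_feature: dict[str, str] | list[tuple[str, str]],
) -> pd.DataFrame:
    """Average probe rows mapping to the same feature; unmapped probes are dropped.

    The mapping may be a dict or (probe, feature) pairs.  A probe may map
    to at most one feature; multi-mapping must be resolved upstream and
    raises here.
    """
    pairs = probe_to_feature.items() if isinstance(probe_to_feature, dict) else probe_to_feature
    seen: dict[str, str] = {}
    for probe, feat in pairs:
        if probe in seen and seen[probe] != feat:
            raise ExpressionError(f"probe {probe!r} mapped to two features")
        seen[probe] = feat
    probe_to_feature = seen
    mapped = matrix.index.isin(probe_to_feature)
    sub = matrix.loc[mapped]
    features = pd.Index([probe_to_feature[p] for p in sub.index], name="feature")
    collapsed = sub.groupby(features, sort=True).mean()
    return collapsed


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


@dataclass
class VarianceShrinkage:
    """Empirical-Bayes variance squeeze: prior df and prior variance."""

    prior_df: float
    prior_var: float
    posterior_var: np.ndarray = field(repr=False, default=None)


def squeeze_variances(s2: np.ndarray, df: float, prior_df: float | None = None) -> VarianceShrinkage:
    """Squeeze per-feature variances toward a common prior.

    The prior df ``d0`` and prior variance ``s0^2`` are estimated by moment
    matching on ``log s^2`` (mean via digamma, spread via trigamma); the
    posterior variance is the df-weighted average of prior and observed.
    ``prior_df`` may be forced: 0 recovers the ordinary statistic, ``inf``
    the pooled (z-like) one.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        # fully degenerate input (e.g. identical case/control matrices):
        # nothing to moderate, every feature keeps its zero variance
        return VarianceShrinkage(prior_df=0.0, prior_var=0.0, posterior_var=np.zeros_like(s2))
    z = np.log(s2[ok])
    e_mean = float(z.mean()) - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    if prior_df is None:
        evar = float(z.var(ddof=1)) - float(special.polygamma(1, df / 2.0)) if z.size > 1 else 0.0
        d0 = 2.0 * _trigamma_inverse(evar) if evar > 0 else np.inf
    else:
        d0 = float(prior_df)
    if np.isinf(d0):
        s0 = np.exp(e_mean)
    elif d0 == 0.0:
        s0 = np.exp(e_mean)  # irrelevant: posterior equals observed
    else:
        s0 = np.exp(e_mean + float(special.digamma(d0 / 2.0)) - np.log(d0 / 2.0))
    if np.isinf(d0):
        post = np.full_like(s2, s0)
    else:
        post = (d0 * s0 + df * s2) / (d0 + df)
    return VarianceShrinkage(prior_df=d0, prior_var=float(s0), posterior_var=post)


def moderated_de(
    study: ExpressionStudy,
    feature_class: str = "gene",
    paired: bool = True,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated differential expression, case minus control.

    Returns a DataFrame indexed by feature with columns ``feature_class``,
    ``log2FC``, ``t``, ``p_value``, ``fdr`` (Benjamini-Hochberg within this
    feature class) and ``diff_score``.  All-constant features get
    ``log2FC = 0, p = 1`` by contract.
    """
    mat = study.matrix(feature_class)
    case_cols = study.condition_columns("case")
    ctrl_cols = study.condition_columns("control")
    if paired:
        pair_of = study.samples["pair_id"]
        order = sorted(set(pair_of))
        case_by_pair = {pair_of[c]: c for c in case_cols}
        ctrl_by_pair = {pair_of[c]: c for c in ctrl_cols}
        diffs = (
            mat[[case_by_pair[p] for p in order]].to_numpy()
            - mat[[ctrl_by_pair[p] for p in order]].to_numpy()
        )
        n = diffs.shape[1]
        if n < 2:
            raise ExpressionError("paired design needs >=2 pairs (zero residual df)")
        lfc = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        df = n - 1
        u = 1.0 / np.sqrt(n)
    else:
        a = mat[case_cols].to_numpy()
        b = mat[ctrl_cols].to_numpy()
        n1, n2 = a.shape[1], b.shape[1]
        if n1 < 2 or n2 < 2:
            raise ExpressionError("unpaired design needs >=2 samples per group")
        lfc = a.mean(axis=1) - b.mean(axis=1)
        s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (n1 + n2 - 2)
        df = n1 + n2 - 2
        u = np.sqrt(1.0 / n1 + 1.0 / n2)

    shrink = squeeze_variances(s2, df, prior_df=prior_df)
    post = shrink.posterior_var
    df_total = df + shrink.prior_df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (np.sqrt(post) * u)
    constant = (s2 == 0) & (lfc == 0)
    t = np.where(constant, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, _P_TINY, 1.0)
    p = np.where(constant, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    diff_score = -np.log10(p) * np.abs(lfc)
    return pd.DataFrame(
        {
            "feature_class": feature_class,
            "log2FC": lfc,
            "t": t,
            "p_value": p,
            "fdr": fdr,
            "diff_score": diff_score,
        },
        index=pd.Index(mat.index, name="feature"),
    )


def de_sets(records: pd.DataFrame, p_max: float = 0.05, lfc_min: float = 1.0) -> dict[str, set[str]]:
    """Split features into up/down sets at p and |log2FC| thresholds."""
    if p_max <= 0 or lfc_min <= 0:
        raise ExpressionError("thresholds must be positive")
    sig = records["p_value"] <= p_max
    up = set(records.index[sig & (records["log2FC"] >= lfc_min)])
    down = set(records.index[sig & (records["log2FC"] <= -lfc_min)])
    return {"up": up, "down": down}


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV: first column feature id, header = sample ids."""
    mat = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        raise ExpressionError(f"duplicate feature ids: {dups[:5]}")
    return mat


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV: sample, condition, pair_id."""
    sheet = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    missing = {"condition", "pair_id"} - set(sheet.columns)
    if missing:
        raise ExpressionError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def load_study(genes_path: str | Path, mirnas_path: str | Path, samples_path: str | Path) -> ExpressionStudy:
    samples = read_sample_sheet(samples_path)
    genes = read_expression(genes_path)[list(samples.index)]
    mirnas = read_expression(mirnas_path)[list(samples.index)]
    return ExpressionStudy(genes=genes, mirnas=mirnas, samples=samples)


def write_de_table(records: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        records.to_csv(fh, sep="\t", float_format="%.6g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
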