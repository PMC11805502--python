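"""Two-group microarray differential expression with empirical-Bayes moderation.

Pipeline (in this order): log2 transform -> median-expression filter ->
replicate-probe averaging -> gene-wise two-group linear fit -> empirical-Bayes
variance moderation -> DEG classification.

The moderation step shrinks gene-wise residual variances s_g^2 toward a
prior estimated from all genes.  The prior is the conjugate scaled
inverse-chi-square with degrees of freedom d0 and scale s0^2, estimated by
matching the first two moments of log s_g^2: with residual df d_g,

    e_g   = log s_g^2 - digamma(d_g/2) + log(d_g/2)
    E[e]  = log s0^2 + digamma(d0/2) - log(d0/2)
    Var[e]= trigamma(d_g/2) + trigamma(d0/2)

so trigamma(d0/2) is recovered from the excess spread of e_g (inverted by
monotone bisection) and s0^2 from its mean.  The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

yields a moderated t-statistic with d0 + d_g degrees of freedom — the usual
gain in power for small two-group designs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModeratedFitParams",
    "ModeratedTTest",
    "log2_transform",
    "filter_low_expression",
    "average_replicate_probes",
    "fit_two_group",
    "ebayes_moderate",
    "classify_degs",
    "differential_expression",
    "read_series_matrix",
    "GSE26051_SHEATHED_SAMPLES",
]

#: GSM accessions of the sheathed-tendon samples excluded from the GSE26051
#: reanalysis (sheathed tendons are organized into different sub-compartments
#: than the non-sheathed tendons kept in the comparison).
GSE26051_SHEATHED_SAMPLES = (
    "GSM639749",
    "GSM639751",
    "GSM639756",
    "GSM639761",
    "GSM639765",
    "GSM639772",
    "GSM639774",
    "GSM639779",
    "GSM639784",
    "GSM639788",
)


@dataclass
class ModeratedFitParams:
    """Gene-wise two-group fit: effect sizes and residual variances."""

    effect: pd.Series  # log2 fold change, case - control
    sigma2: pd.Series  # pooled residual variance per gene
    df_residual: int  # n1 + n2 - 2
    n1: int
    n2: int


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 of raw (linear-scale) intensities; values must be positive."""
    values = matrix.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("log2 transform requires strictly positive intensities")
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)


def filter_low_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop genes not expressed in more than two samples.

    Half of the genes on an array are assumed not expressed, so the cutoff
    is the median over *all* values of the (log2) matrix; a gene counts as
    expressed in a sample when its value is strictly above the cutoff, and
    is kept when it is expressed in more than two samples (i.e. >= 3).
    """
    if matrix.size == 0:
        raise ValueError("empty expression matrix")
    values = matrix.to_numpy(dtype=float)
    cutoff = np.median(values)
    n_expressed = (values > cutoff).sum(axis=1)
    return matrix.loc[n_expressed > 2]


def average_replicate_probes(matrix: pd.DataFrame, probe_map) -> pd.DataFrame:
    """Collapse replicated probes of a gene to their arithmetic mean.

    ``probe_map`` maps probe id -> gene id (a Series, dict, or a DataFrame
    with ``probe_id``/``gene_id`` columns).  Probes without a mapping are
    retained under their probe id.
    """
    if isinstance(probe_map, pd.DataFrame):
        probe_map = probe_map.set_index("probe_id")["gene_id"]
    probe_map = pd.Series(probe_map)
    gene_ids = matrix.index.to_series().map(probe_map)
    gene_ids = gene_ids.fillna(matrix.index.to_series())
    out = matrix.groupby(gene_ids.to_numpy()).mean()
    out.index.name = "gene_id"
    return out


def fit_two_group(
    matrix: pd.DataFrame,
    groups: pd.Series,
    control: str = "control",
) -> ModeratedFitParams:
    """Gene-wise two-group linear model (equivalent to per-gene least squares).

    ``groups`` maps sample id -> group label; the label equal to ``control``
    is the reference, the other the case.  Effect size is mean(case) -
    mean(control) per gene; ``sigma2`` is the pooled residual variance on
    n1 + n2 - 2 df.
    """
    groups = pd.Series(groups).reindex(matrix.columns)
    if groups.isna().any():
        missing = list(matrix.columns[groups.isna()])
        raise ValueError(f"samples without group label: {missing}")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group labels, got {levels}")
    if control not in levels:
        raise ValueError(f"control label {control!r} not among {levels}")
    case = next(l for l in levels if l != control)
    x1 = matrix.loc[:, groups == control].to_numpy(dtype=float)
    x2 = matrix.loc[:, groups == case].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    effect = x2.mean(axis=1) - x1.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    return ModeratedFitParams(
        effect=pd.Series(effect, index=matrix.index, name="log2fc"),
        sigma2=pd.Series(ss / df, index=matrix.index, name="sigma2"),
        df_residual=df,
        n1=n1,
        n2=n2,
    )


def _solve_trigamma(target: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = target for x > 0 by monotone bisection."""
    if target <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    # trigamma is strictly decreasing on (0, inf)
    while special.polygamma(1, lo) < target:
        lo /= 10.0
    while special.polygamma(1, hi) > target:
        hi *= 10.0
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_prior(sigma2: np.ndarray, df_residual: int) -> tuple[float, float]:
    """Method-of-moments estimate of the variance prior (d0, s0^2).

    Works on log variances so the estimate is robust to the heavy right
    tail of chi-square-distributed sample variances.  Genes with zero
    residual variance are excluded from estimation; if all variances are
    zero the prior is not estimable.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    positive = sigma2[sigma2 > 0]
    if positive.size == 0:
        raise ValueError("all residual variances are zero: prior not estimable")
    dg = df_residual
    e = np.log(positive) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, dg / 2.0)
    if excess > 0:
        half_d0 = _solve_trigamma(excess)
        d0 = 2.0 * half_d0
        s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        # no excess spread: variances are effectively exchangeable
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def ebayes_moderate(
    fit: ModeratedFitParams,
    prior_df: float | None = None,
    prior_scale: float | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics from a two-group fit.

    The prior (d0, s0^2) is estimated from the data unless supplied.
    Forcing ``prior_df=0`` reproduces the ordinary pooled two-sample t-test
    (degenerate prior, no shrinkage).

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``t``,
    ``pvalue``, ``padj`` (Benjamini-Hochberg) plus the prior recorded in
    ``DataFrame.attrs``: ``prior_df``, ``prior_scale``, ``df_total``.
    """
    sigma2 = fit.sigma2.to_numpy(dtype=float)
    dg = fit.df_residual
    if prior_df is None:
        d0, s0_sq = estimate_prior(sigma2, dg)
        if prior_scale is not None:
            s0_sq = float(prior_scale)
    else:
        d0 = float(prior_df)
        s0_sq = float(prior_scale) if prior_scale is not None else (
            estimate_prior(sigma2, dg)[1] if d0 > 0 else 0.0
        )

    if np.isinf(d0):
        posterior = np.full_like(sigma2, s0_sq)
        df_total = 1e6  # effectively normal
    elif d0 == 0:
        posterior = sigma2
        df_total = float(dg)
    else:
        posterior = (d0 * s0_sq + dg * sigma2) / (d0 + dg)
        df_total = d0 + dg

    stderr = np.sqrt(posterior * (1.0 / fit.n1 + 1.0 / fit.n2))
    effect = fit.effect.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(stderr > 0, effect / stderr, np.where(effect == 0, 0.0, np.inf * np.sign(effect)))
    pvalue = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvalue = np.clip(pvalue, np.finfo(float).tiny, 1.0)
    padj = multipletests(pvalue, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"log2fc": effect, "t": t, "pvalue": pvalue, "padj": padj},
        index=fit.effect.index,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_scale"] = s0_sq
    out.attrs["df_total"] = df_total
    return out


def classify_degs(
    de: pd.DataFrame,
    p_threshold: float = 0.05,
    lfc_threshold: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify genes as up / down / ns using strict inequalities.

    With ``lfc_threshold=None`` classification uses p < p_threshold and the
    sign of the effect (the convention behind the headline up/down/unchanged
    partition); with a threshold, |log2FC| must strictly exceed it as well
    (the volcano-plot convention).
    """
    if p_threshold <= 0:
        raise ValueError("p_threshold must be > 0")
    if lfc_threshold is not None and lfc_threshold <= 0:
        raise ValueError("lfc_threshold must be > 0 when given")
    lfc = de["log2fc"].to_numpy(dtype=float)
    p = de["pvalue"].to_numpy(dtype=float)
    sig = p < p_threshold
    if lfc_threshold is None:
        up = sig & (lfc > 0)
        down = sig & (lfc < 0)
    else:
        up = sig & (lfc > lfc_threshold)
        down = sig & (lfc < -lfc_threshold)
    cls = np.where(up, "up", np.where(down, "down", "ns"))
    out = de.copy()
    out["class"] = cls
    counts = {
        "up": int(up.sum()),
        "down": int(down.sum()),
        "ns": int(len(de) - up.sum() - down.sum()),
    }
    return out, counts


class ModeratedTTest(BaseEstimator):
    """sklearn-style estimator for moderated two-group differential expression.

    ``fit(X, y)`` takes a samples x genes matrix (DataFrame or array) and a
    vector of two group labels; gene-wise effect sizes, moderated t, p and
    BH-adjusted p become fitted attributes.  The prior can be forced through
    ``prior_df`` / ``prior_scale`` (``prior_df=0`` gives the ordinary pooled
    t-test).
    """

    def __init__(
        self,
        control: str = "control",
        prior_df: float | None = None,
        prior_scale: float | None = None,
        p_threshold: float = 0.05,
        lfc_threshold: float | None = None,
    ):
        self.control = control
        self.prior_df = prior_df
        self.prior_scale = prior_scale
        self.p_threshold = p_threshold
        self.lfc_threshold = lfc_threshold

    def fit(self, X, y) -> "ModeratedTTest":
        if isinstance(X, pd.DataFrame):
            matrix = X.T
        else:
            X = np.asarray(X, dtype=float)
            matrix = pd.DataFrame(
                X.T,
                index=[f"g{i}" for i in range(X.shape[1])],
                columns=[f"s{i}" for i in range(X.shape[0])],
            )
        groups = pd.Series(np.asarray(y), index=matrix.columns)
        fitres = fit_two_group(matrix, groups, control=self.control)
        de = ebayes_moderate(fitres, prior_df=self.prior_df, prior_scale=self.prior_scale)
        de, counts = classify_degs(de, self.p_threshold, self.lfc_threshold)
        self.results_ = de
        self.counts_ = counts
        self.effect_ = de["log2fc"]
        self.t_ = de["t"]
        self.pvalue_ = de["pvalue"]
        self.qvalue_ = de["padj"]
        self.sigma2_ = fitres.sigma2
        self.prior_df_ = de.attrs["prior_df"]
        self.prior_scale_ = de.attrs["prior_scale"]
        self.df_total_ = de.attrs["df_total"]
        return self


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series,
    probe_map=None,
    control: str = "control",
    already_log2: bool = True,
    p_threshold: float = 0.05,
    lfc_threshold: float | None = None,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full pipeline: (log2) -> filter -> probe averaging -> fit ->
    moderation -> classification.  Returns the per-gene result table and the
    up/down/ns counts."""
    if not already_log2:
        matrix = log2_transform(matrix)
    matrix = filter_low_expression(matrix)
    if probe_map is not None:
        matrix = average_replicate_probes(matrix, probe_map)
    fit = fit_two_group(matrix, groups, control=control)
    de = ebayes_moderate(fit, prior_df=prior_df)
    return classify_degs(de, p_threshold=p_threshold, lfc_threshold=lfc_threshold)


def read_series_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GEO series-matrix file (plain-text SOFT dialect).

    Returns ``(matrix, samples)``: the probe x sample expression table from
    the block between ``!series_matrix_table_begin`` / ``_end``, and a
    sample-metadata table assembled from the ``!Sample_*`` header lines
    (one row per sample, columns named after the SOFT keys).
    """
    path = Path(path)
    header: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *values = line.split("\t")
                key = key.lstrip("!")
                values = [v.strip('"') for v in values]
                base = key
                i = 1
                while key in header:  # repeated keys (e.g. characteristics)
                    i += 1
                    key = f"{base}.{i}"
                header[key] = values
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix table found")
    from io import StringIO

    matrix = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    matrix.columns = [c.strip('"') for c in matrix.columns]
    matrix.index = [str(i).strip('"') for i in matrix.index]
    matrix.index.name = "probe_id"
    n = matrix.shape[1]
    samples = pd.DataFrame(
        {k: v for k, v in header.items() if len(v) == n},
        index=matrix.columns,
    )
    return matrix, samples
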