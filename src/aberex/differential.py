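"""Negative-binomial differential statistics.

Two tests share the same machinery:

* gene-level differential expression (``dge_wald``): per-gene NB log-link GLM
  of counts on condition plus covariates, with median-of-ratios size-factor
  offsets, a mean-dispersion trend ``alpha(mu) = a0 + a1/mu``, Wald z tests
  and Benjamini-Hochberg adjustment; and
* per-bin differential exon usage (``deu_test``): for each exonic portion,
  the two-row profile (this bin vs. the sum of its sibling bins) per sample
  is modelled with an NB GLM containing a bin main effect and a
  bin-by-condition interaction; the interaction estimate is the usage
  log2 fold change.

Candidate/significance criteria are boundary-inclusive:
|log2FC| >= 0.5, q <= 0.05, and (for gene candidates) mean count >= 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from scipy import stats

_DISP_FLOOR = 1e-8
_DISP_CEIL = 10.0


@dataclass
class AnalysisThresholds:
    """Default decision thresholds for every stage of the analysis."""

    q_max: float = 0.05
    lfc_min: float = 0.5
    count_min: float = 10.0
    deu_padj_max: float = 0.05
    deu_lfc_min: float = 0.5
    pfs_cutoff_months: float = 60.0
    pca_top_n: int = 5000
    gsea_min_mean_reads: float = 1.0
    gsea_q_max: float = 0.05

    def __post_init__(self) -> None:
        for name, val in self.__dict__.items():
            if val <= 0:
                raise ValueError(f"threshold {name} must be positive, got {val}")


@dataclass
class DispersionModel:
    """Raw, trend and shrunk per-row NB dispersions."""

    raw: pd.Series
    trend_a0: float
    trend_a1: float
    shrunk: pd.Series

    def trend(self, mu: np.ndarray) -> np.ndarray:
        return np.clip(self.trend_a0 + self.trend_a1 / np.maximum(mu, 1e-8),
                       _DISP_FLOOR, _DISP_CEIL)


# ---------------------------------------------------------------------------
# Gene exclusion by biotype
# ---------------------------------------------------------------------------

DEFAULT_EXCLUDED_BIOTYPES = (
    r"pseudogene",
    r"Mt_rRNA",
    r"Mt_tRNA",
    r"^rRNA",
    r"^IG_V",
    r"^TR_",
)


def exclude_genes(genes, biotype_rules=DEFAULT_EXCLUDED_BIOTYPES):
    """Drop genes whose biotype matches any configured pattern.

    The default rules remove pseudogenes, mitochondrial and ribosomal RNA,
    immunoglobulin variable-chain and T-cell-receptor genes.
    """
    import re

    pats = [re.compile(p) for p in biotype_rules]
    return [g for g in genes if not any(p.search(g.biotype) for p in pats)]


# ---------------------------------------------------------------------------
# Normalization and dispersion
# ---------------------------------------------------------------------------


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample: median of count / geometric-row-mean over rows whose
    geometric mean is positive (i.e. rows with no zero).  If no such row
    exists, the median is taken per sample over that sample's positive rows.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = np.log(counts.values.astype(float))
        log_geo = logc.mean(axis=1)
    finite = np.isfinite(log_geo)
    if finite.any():
        ratios = logc[finite] - log_geo[finite, None]
        sf = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no row with all-positive counts; falling back to positive-subset medians"
        )
        sf = np.empty(counts.shape[1])
        pos_geo = np.nanmean(np.where(np.isfinite(logc), logc, np.nan), axis=1)
        for j in range(counts.shape[1]):
            mask = np.isfinite(logc[:, j]) & np.isfinite(pos_geo)
            sf[j] = np.exp(np.median(logc[mask, j] - pos_geo[mask]))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame, size_factors: pd.Series
) -> DispersionModel:
    """Method-of-moments dispersions with a 1/mu trend and geometric shrinkage.

    Per row, on size-factor-normalized counts z: ``alpha_raw =
    (var(z) - mu * mean(1/sf)) / mu^2``.  The trend ``alpha(mu) = a0 + a1/mu``
    is least-squares fitted on rows with mu >= 1 and positive raw estimates
    (one trimming pass removes gross outliers); the per-row value used for
    testing is the geometric mean of raw and trend (trend alone when the raw
    moment estimate is non-positive), floored at 1e-8.
    """
    sf = size_factors.values.astype(float)
    z = counts.values / sf
    mu = z.mean(axis=1)
    var = z.var(axis=1, ddof=1)
    xim = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu * xim) / mu**2
    raw = pd.Series(raw, index=counts.index, name="dispersion_raw")

    usable = (mu >= 1.0) & (raw.values > 0)
    if usable.sum() >= 10:
        x = 1.0 / mu[usable]
        y = raw.values[usable]
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        keep = np.abs(resid) <= 3 * np.std(resid)
        if keep.sum() >= 10:
            coef, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        a0 = float(max(coef[0], _DISP_FLOOR))
        a1 = float(max(coef[1], 0.0))
    else:  # degenerate input; fall back to a flat weak trend
        a0, a1 = max(float(np.nanmedian(raw[raw > 0])) if (raw > 0).any() else 0.01,
                     _DISP_FLOOR), 0.0

    trend = np.clip(a0 + a1 / np.maximum(mu, 1e-8), _DISP_FLOOR, _DISP_CEIL)
    shrunk = np.where(
        raw.values > 0,
        np.exp(0.5 * (np.log(np.maximum(raw.values, _DISP_FLOOR)) + np.log(trend))),
        trend,
    )
    shrunk = np.clip(shrunk, _DISP_FLOOR, _DISP_CEIL)
    return DispersionModel(
        raw=raw,
        trend_a0=a0,
        trend_a1=a1,
        shrunk=pd.Series(shrunk, index=counts.index, name="dispersion"),
    )


# ---------------------------------------------------------------------------
# NB GLM fit
# ---------------------------------------------------------------------------


def _nb_wald(y, X, offset, alpha, coef_idx):
    """Fit an NB log-link GLM with fixed dispersion; return (betas, se, z, p).

    Returns NaNs when the fit fails or the design is degenerate.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(
                y, X,
                family=sm.families.NegativeBinomial(alpha=max(alpha, _DISP_FLOOR)),
                offset=offset,
            )
            res = model.fit(maxiter=100, tol=1e-8)
        beta = res.params
        se = res.bse
        if not np.all(np.isfinite(se)) or se[coef_idx] <= 0:
            return beta, se, np.nan, np.nan
        zval = beta[coef_idx] / se[coef_idx]
        pval = 2.0 * stats.norm.sf(abs(zval))
        return beta, se, zval, pval
    except Exception:
        k = X.shape[1]
        return np.full(k, np.nan), np.full(k, np.nan), np.nan, np.nan


def _nb_irls(y, X, offset, alpha_at, maxiter=50, tol=1e-10):
    """IRLS fit of an NB log-link GLM with per-observation dispersion.

    ``alpha_at(mu)`` returns the dispersion at each fitted mean, so the
    two rows of an exon-usage profile (bin vs. sum of siblings) each get a
    variance appropriate to their own scale.  Returns (beta, se) or NaNs on
    failure; the Wald covariance is the inverse Fisher information.
    """
    n, k = X.shape
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta = np.zeros(k)
    for _ in range(maxiter):
        alpha = np.maximum(alpha_at(mu), _DISP_FLOOR)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(xw.T @ X, xw.T @ z)
        except np.linalg.LinAlgError:
            return np.full(k, np.nan), np.full(k, np.nan)
        if not np.all(np.isfinite(beta_new)):
            return np.full(k, np.nan), np.full(k, np.nan)
        step = beta_new - beta
        beta = beta_new
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        if np.max(np.abs(step)) < tol:
            break
    alpha = np.maximum(alpha_at(mu), _DISP_FLOOR)
    w = mu / (1.0 + alpha * mu)
    try:
        cov = np.linalg.inv((X * w[:, None]).T @ X)
    except np.linalg.LinAlgError:
        return beta, np.full(k, np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return beta, se


def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values; NaN p-values propagate NaN and
    are excluded from the number of tests."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


# ---------------------------------------------------------------------------
# Differential gene expression
# ---------------------------------------------------------------------------

LN2 = float(np.log(2.0))


def dge_wald(
    counts: pd.DataFrame,
    condition,
    covariates: pd.DataFrame | None = None,
    thresholds: AnalysisThresholds | None = None,
    size_factors: pd.Series | None = None,
    test_level: str | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``condition`` with optional batch covariates.

    Positive fold changes mean higher expression in ``test_level`` (default:
    the first level encountered, e.g. the mutant group when its samples come
    first) relative to the other level.  Returns a frame indexed by gene id
    with columns ``base_mean``, ``log2fc`` (MLE), ``log2fc_shrunk``
    (posterior mode under a zero-centered normal prior whose scale is the
    MAD of the MLE estimates), ``wald_stat``, ``p``, ``q`` and ``candidate``.
    All-zero genes are excluded from testing and from the BH denominator.
    """
    thresholds = thresholds or AnalysisThresholds()
    cond = pd.Series(np.asarray(condition), index=counts.columns)
    levels = pd.unique(cond)
    if len(levels) != 2:
        raise ValueError(f"condition must have exactly 2 levels, got {list(levels)}")
    test_level = test_level if test_level is not None else levels[0]
    x_cond = (cond == test_level).astype(float).values

    cols = [np.ones(counts.shape[1]), x_cond]
    names = ["intercept", "condition"]
    if covariates is not None:
        dummies = pd.get_dummies(covariates.astype("category"), drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].astype(float).values)
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix (condition + covariates) is not full rank")

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    offset = np.log(size_factors.values.astype(float))

    nonzero = counts.sum(axis=1) > 0
    tested = counts.loc[nonzero]
    disp = estimate_dispersions(tested, size_factors)

    base_mean = (counts.values / size_factors.values).mean(axis=1)
    n_genes = counts.shape[0]
    lfc = np.full(n_genes, np.nan)
    se_l2 = np.full(n_genes, np.nan)
    wald = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)

    row_pos = {g: i for i, g in enumerate(counts.index)}
    for g in tested.index:
        i = row_pos[g]
        y = tested.loc[g].values.astype(float)
        beta, se, zval, pval = _nb_wald(y, X, offset, disp.shrunk[g], coef_idx=1)
        lfc[i] = beta[1] / LN2
        se_l2[i] = se[1] / LN2
        wald[i] = zval
        pvals[i] = pval

    qvals = bh_adjust(pvals)

    # normal-prior shrinkage of the condition log2FC
    ok = np.isfinite(lfc) & np.isfinite(se_l2)
    if ok.any():
        tau = float(stats.median_abs_deviation(lfc[ok], scale="normal"))
        tau = max(tau, 1e-3)
        shrunk = np.where(ok, lfc * tau**2 / (tau**2 + np.where(ok, se_l2, 1.0) ** 2),
                          np.nan)
    else:
        shrunk = np.full(n_genes, np.nan)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": lfc,
            "log2fc_shrunk": shrunk,
            "wald_stat": wald,
            "p": pvals,
            "q": qvals,
        },
        index=counts.index,
    )
    out["candidate"] = candidate_filter(out, thresholds)
    return out


def candidate_filter(
    results: pd.DataFrame, thresholds: AnalysisThresholds | None = None
) -> pd.Series:
    """Boundary-inclusive gene-candidate rule:
    |shrunk log2FC| >= 0.5, q <= 0.05, mean normalized count >= 10."""
    t = thresholds or AnalysisThresholds()
    lfc = results["log2fc_shrunk"].where(
        results["log2fc_shrunk"].notna(), results.get("log2fc")
    )
    return (
        (lfc.abs() >= t.lfc_min)
        & (results["q"] <= t.q_max)
        & (results["base_mean"] >= t.count_min)
    ).fillna(False)


def intersect_cohorts(
    results_a: pd.DataFrame, results_b: pd.DataFrame, q_max: float = 0.05
) -> pd.DataFrame:
    """Genes significant (q <= q_max) in both cohorts, with sign concordance."""
    sig_a = results_a.index[results_a["q"] <= q_max]
    sig_b = results_b.index[results_b["q"] <= q_max]
    shared = sig_a.intersection(sig_b)
    return pd.DataFrame(
        {
            "log2fc_a": results_a.loc[shared, "log2fc"],
            "log2fc_b": results_b.loc[shared, "log2fc"],
            "concordant": np.sign(results_a.loc[shared, "log2fc"])
            == np.sign(results_b.loc[shared, "log2fc"]),
        },
        index=shared,
    )


# ---------------------------------------------------------------------------
# Differential exon usage
# ---------------------------------------------------------------------------


def deu_test(
    bin_counts: pd.DataFrame,
    gene_map: pd.Series,
    condition,
    thresholds: AnalysisThresholds | None = None,
    novelty: pd.Series | None = None,
    test_level: str | None = None,
) -> pd.DataFrame:
    """Per-portion differential exon usage via an NB interaction model.

    For each portion the response is the stacked two-row profile (this bin;
    sum of the group's other bins) per sample, offset by the log of the
    sample's group total; the design holds an intercept, condition and bin
    main effects, and the bin-by-condition interaction whose estimate divided
    by ln 2 is the usage log2 fold change.  The dispersion varies with the
    fitted mean along the cohort-wide trend (rescaled by the bin's own
    shrunk-to-trend ratio), so the bin row and the much larger sibling-sum
    row each get a variance appropriate to their scale.  Portions in
    single-bin groups are reported untested (NaN).
    """
    t = thresholds or AnalysisThresholds()
    cond = pd.Series(np.asarray(condition), index=bin_counts.columns)
    levels = pd.unique(cond)
    if len(levels) != 2:
        raise ValueError("condition must have exactly 2 levels")
    test_level = test_level if test_level is not None else levels[0]
    x_cond = (cond == test_level).astype(float).values
    n = bin_counts.shape[1]

    gene_map = gene_map.reindex(bin_counts.index)
    sf = estimate_size_factors(bin_counts) if n >= 2 else None
    disp = estimate_dispersions(bin_counts, sf)

    group_totals = bin_counts.groupby(gene_map).transform("sum")
    group_sizes = gene_map.map(gene_map.value_counts())

    # stacked design: first n rows = this bin, last n rows = others
    x_bin = np.concatenate([np.ones(n), np.zeros(n)])
    X = np.column_stack(
        [
            np.ones(2 * n),
            np.concatenate([x_cond, x_cond]),
            x_bin,
            x_bin * np.concatenate([x_cond, x_cond]),
        ]
    )

    # The sibling-sum row is a sum of many bins, so its dispersion is well
    # below the bin-level trend; each row class therefore gets its own
    # dispersion model, and each observation the value at its own mean
    # (rescaled by the row's shrunk-to-trend ratio).
    others_counts = group_totals - bin_counts
    disp_oth = estimate_dispersions(others_counts, sf)

    def _ratio(d: DispersionModel, mat: pd.DataFrame) -> pd.Series:
        m = (mat.values / sf.values).mean(axis=1)
        return pd.Series(
            np.clip(d.shrunk.values / d.trend(m), 0.25, 4.0), index=mat.index
        )

    ratio_bin = _ratio(disp, bin_counts)
    ratio_oth = _ratio(disp_oth, others_counts)

    usage_lfc = np.full(len(bin_counts), np.nan)
    pvals = np.full(len(bin_counts), np.nan)
    for i, pid in enumerate(bin_counts.index):
        if group_sizes[pid] < 2:
            continue
        this = bin_counts.loc[pid].values.astype(float)
        total = group_totals.loc[pid].values.astype(float)
        others = total - this
        if total.min() <= 0:
            continue
        y = np.concatenate([this, others])
        offset = np.log(np.concatenate([total, total]))
        rb, ro = float(ratio_bin[pid]), float(ratio_oth[pid])

        def alpha_at(mu, rb=rb, ro=ro):
            a = np.empty_like(mu)
            a[:n] = rb * disp.trend(mu[:n])
            a[n:] = ro * disp_oth.trend(mu[n:])
            return a

        beta, se = _nb_irls(y, X, offset, alpha_at)
        if np.isfinite(se[3]) and se[3] > 0:
            usage_lfc[i] = beta[3] / LN2
            zval = beta[3] / se[3]
            pvals[i] = 2.0 * stats.norm.sf(abs(zval))

    padj = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "group_id": gene_map.values,
            "usage_log2fc": usage_lfc,
            "p": pvals,
            "padj": padj,
        },
        index=bin_counts.index,
    )
    out["significant"] = (
        (out["padj"] <= t.deu_padj_max) & (out["usage_log2fc"].abs() >= t.deu_lfc_min)
    ).fillna(False)
    if novelty is not None:
        out["novelty"] = novelty.reindex(out.index)
    return out


# ---------------------------------------------------------------------------
# PCA and clustering
# ---------------------------------------------------------------------------


def pca_top_variable(
    counts: pd.DataFrame,
    size_factors: pd.Series | None = None,
    batch=None,
    top_n: int = 5000,
    n_components: int = 10,
):
    """PCA of samples on the ``top_n`` most-variable genes.

    Counts are log2(normalized + 1) transformed; when a batch vector is
    given, each gene's per-batch means are removed (additive adjustment)
    before variance ranking and the centered SVD.

    Returns ``(scores, explained_variance_ratio)``.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    x = np.log2(counts.values / size_factors.values + 1.0)

    if batch is not None:
        b = pd.Series(np.asarray(batch), index=counts.columns)
        grand = x.mean(axis=1, keepdims=True)
        adj = x.copy()
        for level in pd.unique(b):
            mask = (b == level).values
            adj[:, mask] -= adj[:, mask].mean(axis=1, keepdims=True)
        x = adj + grand

    variances = x.var(axis=1)
    if top_n > len(variances):
        warnings.warn(
            f"top_n={top_n} exceeds {len(variances)} available rows; using all"
        )
        top_n = len(variances)
    top = np.argsort(variances, kind="mergesort")[::-1][:top_n]
    sub = x[top]
    centered = (sub - sub.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=counts.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    var = s**2 / (centered.shape[0] - 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    return scores, ratio[:k]


def cluster_deu_heatmap_input(
    deu_results: pd.DataFrame,
    bin_counts: pd.DataFrame,
    size_factors: pd.Series | None = None,
):
    """Row z-scores of normalized counts for significant bins plus Ward
    leaf orders over samples and bins (Euclidean distance, Ward linkage).

    Returns ``(zscores, sample_order, bin_order)``.
    """
    sig = deu_results.index[deu_results["significant"].astype(bool)]
    if len(sig) == 0:
        raise ValueError("no significant bins to cluster")
    if size_factors is None:
        size_factors = estimate_size_factors(bin_counts)
    x = bin_counts.loc[sig].values / size_factors.values
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant bin(s) from z-scoring")
    x = x[keep]
    rows = sig[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    zdf = pd.DataFrame(z, index=rows, columns=bin_counts.columns)
    if len(rows) >= 2:
        bin_order = sch.leaves_list(sch.linkage(z, method="ward"))
    else:
        bin_order = np.array([0])
    if bin_counts.shape[1] >= 2:
        sample_order = sch.leaves_list(sch.linkage(z.T, method="ward"))
    else:
        sample_order = np.array([0])
    return zdf, sample_order, bin_order
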