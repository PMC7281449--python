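"""Association of circRNA expression with phenotype and genotype.

Group contrasts follow a per-row (per-feature) scheme: an F-test of variance
equality decides between the pooled-variance and Welch two-sided t-test,
p-values are Bonferroni-corrected over the features actually tested, and
features whose mean is exactly zero in either group are excluded from
testing beforehand (they are reported as group-exclusive instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import CountMatrix, ValidationError


@dataclass
class ProliferationClasses:
    labels: pd.Series  # cell line -> fast | slow | intermediate
    fast: list[str]
    slow: list[str]
    fast_cut: float
    slow_cut: float


def cell_line_proliferation(meta: pd.DataFrame) -> pd.Series:
    """72-h proliferation fold per cell line (replicates share one value)."""
    return meta.groupby("cell_line")["proliferation_fold_72h"].first()


def classify_fast_slow(
    meta: pd.DataFrame, fast_cut: float = 5.0, slow_cut: float = 3.0
) -> ProliferationClasses:
    """Split cell lines by 72-h proliferation fold.

    Inclusive thresholds: fold >= fast_cut -> fast, fold <= slow_cut -> slow;
    lines in between are intermediate and sit out the two-group contrast.
    """
    if fast_cut <= slow_cut:
        raise ValidationError("fast_cut must exceed slow_cut")
    folds = cell_line_proliferation(meta)
    labels = pd.Series("intermediate", index=folds.index, name="proliferation_class")
    labels[folds >= fast_cut] = "fast"
    labels[folds <= slow_cut] = "slow"
    return ProliferationClasses(
        labels=labels,
        fast=sorted(labels.index[labels == "fast"]),
        slow=sorted(labels.index[labels == "slow"]),
        fast_cut=fast_cut,
        slow_cut=slow_cut,
    )


def proliferation_correlation(
    matrix: CountMatrix, meta: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Pearson correlation of each feature with the proliferation fold.

    Zeros count as expression values. Zero-variance features are excluded;
    the second return value counts them.
    """
    folds = cell_line_proliferation(meta)
    missing = [c for c in matrix.samples if c not in folds.index]
    if missing:
        raise ValidationError(f"no proliferation value for cell line(s): {missing}")
    x = folds.loc[matrix.samples].to_numpy(dtype=float)
    v = matrix.values.to_numpy(dtype=float)
    sd = v.std(axis=1)
    ok = sd > 0
    vc = v - v.mean(axis=1, keepdims=True)
    xc = x - x.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc * xc).sum(axis=1) / np.sqrt((vc**2).sum(axis=1) * (xc**2).sum())
    per_feature = pd.Series(r, index=matrix.features)[ok]
    return per_feature, int((~ok).sum())


FC_CLASSES = ("only_slow", "only_fast", "band", "other")


def group_fold_change(
    matrix: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    band: tuple[float, float] = (0.5, 2.0),
) -> pd.DataFrame:
    """Fold change mean(A)/mean(B) per feature with band classification.

    Group A is the "fast"/case group, B the "slow"/reference group. Features
    seen only in one group are classed only_fast / only_slow; those with both
    means zero are dropped. The band test is inclusive.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups need at least one cell line")
    a = matrix.values[list(group_a)].mean(axis=1)
    b = matrix.values[list(group_b)].mean(axis=1)
    expressed = (a > 0) | (b > 0)
    a, b = a[expressed], b[expressed]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = a / b
    cls = pd.Series("other", index=a.index, name="fc_class")
    cls[(b == 0) & (a > 0)] = "only_fast"
    cls[(a == 0) & (b > 0)] = "only_slow"
    in_band = (fc >= band[0]) & (fc <= band[1]) & (a > 0) & (b > 0)
    cls[in_band] = "band"
    return pd.DataFrame({"mean_fast": a, "mean_slow": b, "fold_change": fc, "fc_class": cls})


@dataclass
class GroupComparison:
    """Per-feature two-group test results after zero-mean exclusion."""

    table: pd.DataFrame  # mean_a, mean_b, fold_change, log2_fc, equal_var, t, p, neg_log10_p, significant
    label: str
    n_tested: int
    n_excluded: int
    alpha: float
    bonferroni_threshold: float

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def differential_tests(
    matrix: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    label: str = "",
    f_alpha: float = 0.05,
) -> GroupComparison:
    """Per-row F-test-routed two-sided t-tests with Bonferroni correction.

    For every feature: a two-sided F-test of variance equality at ``f_alpha``
    chooses the pooled-variance t-test (variances compatible) or the Welch
    t-test (not). Features with mean exactly 0 in either group are excluded
    before testing; the Bonferroni threshold is alpha / n_tested.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 cell lines")
    a = matrix.values[list(group_a)].to_numpy(dtype=float)
    b = matrix.values[list(group_b)].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    tested = (mean_a != 0) & (mean_b != 0)
    n_excluded = int((~tested).sum())
    a, b = a[tested], b[tested]
    index = matrix.features[tested]

    na, nb = a.shape[1], b.shape[1]
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = var_a / var_b
        cdf = stats.f.cdf(f_stat, na - 1, nb - 1)
        f_p = 2 * np.minimum(cdf, 1 - cdf)
    # zero-variance rows make F degenerate; route them to Welch
    equal_var = np.where(np.isfinite(f_p), f_p, 0.0) >= f_alpha

    t_pooled = stats.ttest_ind(a, b, axis=1, equal_var=True)
    t_welch = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.where(equal_var, t_pooled.statistic, t_welch.statistic)
    p = np.where(equal_var, t_pooled.pvalue, t_welch.pvalue)

    n_tested = int(tested.sum())
    threshold = alpha / n_tested if n_tested else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a[tested] / mean_b[tested]
        log2_fc = np.log2(fc)
        neg_log10_p = -np.log10(p)
    table = pd.DataFrame(
        {
            "mean_a": mean_a[tested],
            "mean_b": mean_b[tested],
            "fold_change": fc,
            "log2_fc": log2_fc,
            "equal_var": equal_var,
            "t": t,
            "p": p,
            "neg_log10_p": neg_log10_p,
            "significant": p < threshold,
        },
        index=index,
    )
    return GroupComparison(
        table=table,
        label=label,
        n_tested=n_tested,
        n_excluded=n_excluded,
        alpha=alpha,
        bonferroni_threshold=threshold,
    )


def contrast_groups(meta: pd.DataFrame, contrast: str) -> tuple[list[str], list[str], str]:
    """Resolve a named contrast to (group_a, group_b) cell-line lists.

    Contrasts: 'transformed' (tumor vs non-transformed), 'histology'
    (LUAD vs other NSCLC), or a genotype gene (mut vs wt; 'unknown' lines
    are left out).
    """
    per_line = meta.groupby("cell_line").first()
    if contrast == "transformed":
        a = per_line.index[per_line["histology"] != "non_transformed"]
        b = per_line.index[per_line["histology"] == "non_transformed"]
        label = "tumor_vs_non_transformed"
    elif contrast == "histology":
        tumor = per_line[per_line["histology"] != "non_transformed"]
        a = tumor.index[tumor["histology"] == "LUAD"]
        b = tumor.index[tumor["histology"] == "NSCLC_other"]
        label = "LUAD_vs_NSCLC_other"
    elif contrast in ("EGFR", "KRAS", "TP53", "BRAF"):
        a = per_line.index[per_line[contrast] == "mut"]
        b = per_line.index[per_line[contrast] == "wt"]
        label = f"{contrast}_mut_vs_wt"
    else:
        raise ValidationError(f"unknown contrast {contrast!r}")
    return sorted(a), sorted(b), label


@dataclass
class CgcEnrichment:
    """How cancer-census genes participate in the circRNA landscape."""

    fraction_genes_cgc: float
    fraction_junctions_cgc: float
    expected_fraction: float | None
    mean_cgc: float
    mean_non_cgc: float
    fold_change: float
    p_value: float
    ratio_bins: pd.DataFrame | None


def cgc_enrichment(
    gene_matrix: CountMatrix,
    junction_gene: pd.Series,
    cgc_genes: set[str],
    coding_gene_total: int | None = None,
    ratio_summary: pd.DataFrame | None = None,
    f_alpha: float = 0.05,
) -> CgcEnrichment:
    """Cancer Gene Census membership of circRNA-producing genes.

    Reports the CGC fraction among detected genes and among individual
    junctions, the fold difference in mean normalized counts (CGC vs rest,
    F-test-routed two-sided t-test), and optionally CGC frequency across
    log10 bins of the circ/total ratio from a :class:`RatioTable` summary.
    """
    detected = set(gene_matrix.features)
    in_cgc = detected & set(cgc_genes)
    if not in_cgc:
        import warnings

        warnings.warn("CGC set does not intersect detected genes", stacklevel=2)
    frac_genes = len(in_cgc) / len(detected) if detected else float("nan")
    jg = pd.Series(junction_gene)
    frac_junctions = float(jg.isin(cgc_genes).mean()) if len(jg) else float("nan")
    expected = len(cgc_genes) / coding_gene_total if coding_gene_total else None

    per_gene_mean = gene_matrix.values.mean(axis=1)
    is_cgc = per_gene_mean.index.isin(cgc_genes)
    x, y = per_gene_mean[is_cgc], per_gene_mean[~is_cgc]
    if len(x) >= 2 and len(y) >= 2:
        f_p = _var_f_test(x.to_numpy(), y.to_numpy())
        res = stats.ttest_ind(x, y, equal_var=bool(f_p >= f_alpha))
        p_value = float(res.pvalue)
    else:
        p_value = float("nan")
    mean_cgc = float(x.mean()) if len(x) else float("nan")
    mean_non = float(y.mean()) if len(y) else float("nan")

    bins = None
    if ratio_summary is not None and len(ratio_summary):
        ratios = ratio_summary["avg_ratio"].dropna()
        ratios = ratios[ratios > 0]
        if len(ratios):
            log_r = np.log10(ratios)
            edges = np.arange(np.floor(log_r.min()), np.ceil(log_r.max()) + 1)
            genes = ratio_summary.loc[ratios.index, "gene"]
            cut = pd.cut(log_r, bins=edges, include_lowest=True)
            flag = genes.isin(cgc_genes).to_numpy()
            grouped = pd.DataFrame({"bin": cut, "cgc": flag}).groupby("bin", observed=False)
            bins = pd.DataFrame(
                {
                    "n_cgc": grouped["cgc"].sum().astype(int),
                    "n_total": grouped["cgc"].size().astype(int),
                }
            )
            bins["cgc_fraction"] = bins["n_cgc"] / bins["n_total"].where(bins["n_total"] > 0)
    return CgcEnrichment(
        fraction_genes_cgc=frac_genes,
        fraction_junctions_cgc=frac_junctions,
        expected_fraction=expected,
        mean_cgc=mean_cgc,
        mean_non_cgc=mean_non,
        fold_change=mean_cgc / mean_non if mean_non else float("nan"),
        p_value=p_value,
        ratio_bins=bins,
    )


def _var_f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test p-value for equality of variances."""
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy == 0 and vx == 0:
        return 1.0
    if vy == 0 or vx == 0:
        return 0.0
    f = vx / vy
    cdf = stats.f.cdf(f, len(x) - 1, len(y) - 1)
    return float(2 * min(cdf, 1 - cdf))
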