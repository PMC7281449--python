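"""Positional, ratio, correlation and sequence statistics of the landscape.

Covers where along the transcript circRNAs start (acceptor exon) and end
(donor exon), how circular expression relates to the gene's linear (total)
expression across cell lines, and a circular polyA-stretch scan.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import BacksplicedJunction, CountMatrix, TranscriptModel, ValidationError

_VALID_SEQ = frozenset("ACGTN")


@dataclass
class ExonRoleProfile:
    """Acceptor/donor usage counts along the transcript.

    ``donor_from_end`` indexes the donor exon from the transcript end
    (last = 1, second-to-last = 2, ...), the natural axis for last-exon
    depletion. Fold ratios are NaN when the denominator count is zero.
    """

    acceptor_by_index: pd.Series
    donor_by_index: pd.Series
    donor_from_end: pd.Series
    n_circles: int
    filter_tag: str
    fold_acceptor_second_vs_first: float
    fold_donor_secondlast_vs_last: float


def exon_role_counts(
    junctions: list[BacksplicedJunction],
    catalog: dict[str, TranscriptModel],
    min_reads: int = 1,
    min_exons: int = 1,
) -> ExonRoleProfile:
    """Count acceptor and donor exon usage over annotated circRNAs.

    Filters: total backsplice reads >= min_reads and host transcript with
    >= min_exons exons. Unannotated junctions are ignored.
    """
    acc: dict[int, int] = {}
    don: dict[int, int] = {}
    don_end: dict[int, int] = {}
    n = 0
    for j in junctions:
        if j.unannotated or j.acceptor_exon is None or j.donor_exon is None:
            continue
        model = catalog.get(j.gene)
        if model is None or model.n_exons < min_exons:
            continue
        if j.total_reads < min_reads:
            continue
        n += 1
        acc[j.acceptor_exon] = acc.get(j.acceptor_exon, 0) + 1
        don[j.donor_exon] = don.get(j.donor_exon, 0) + 1
        dist = model.n_exons - j.donor_exon + 1  # last exon -> 1
        don_end[dist] = don_end.get(dist, 0) + 1
    if n == 0:
        warnings.warn("no annotated junctions pass the exon-role filter", stacklevel=2)

    def as_series(d: dict[int, int], name: str) -> pd.Series:
        top = max(d) if d else 1
        s = pd.Series(d, dtype=int).reindex(range(1, top + 1), fill_value=0)
        s.index.name = name
        return s

    acc_s = as_series(acc, "exon_index")
    don_s = as_series(don, "exon_index")
    don_end_s = as_series(don_end, "exons_from_end")
    return ExonRoleProfile(
        acceptor_by_index=acc_s,
        donor_by_index=don_s,
        donor_from_end=don_end_s,
        n_circles=n,
        filter_tag=f"min{min_reads}reads_min{min_exons}exons",
        fold_acceptor_second_vs_first=_fold(acc_s.get(2, 0), acc_s.get(1, 0)),
        fold_donor_secondlast_vs_last=_fold(don_end_s.get(2, 0), don_end_s.get(1, 0)),
    )


def _fold(numerator: float, denominator: float) -> float:
    return numerator / denominator if denominator else float("nan")


def decile_bin(exon_index: int, n_exons: int) -> int:
    """Map exon i of n to a decile bin 1..10: ceil(10*i/n).

    The last exon always lands in bin 10, so every transcript contributes to
    the final decile.
    """
    if not 1 <= exon_index <= n_exons:
        raise ValidationError(
            f"exon index {exon_index} outside transcript of {n_exons} exons"
        )
    return math.ceil(10 * exon_index / n_exons)


def exon_decile_profile(
    junctions: list[BacksplicedJunction], catalog: dict[str, TranscriptModel]
) -> pd.DataFrame:
    """Acceptor and donor usage counts per relative-position decile (1-10)."""
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, 11, name="decile"), columns=["acceptor", "donor"]
    )
    for j in junctions:
        if j.unannotated or j.acceptor_exon is None or j.donor_exon is None:
            continue
        model = catalog.get(j.gene)
        if model is None:
            continue
        counts.loc[decile_bin(j.acceptor_exon, model.n_exons), "acceptor"] += 1
        counts.loc[decile_bin(j.donor_exon, model.n_exons), "donor"] += 1
    return counts


@dataclass
class RatioTable:
    """circRNA / total-RNA ratios per feature.

    ``per_line`` holds the per-cell-line ratio (NaN where FPKM = 0);
    ``summary`` one row per feature with the across-cell-line average ratio
    (mean of circ values over cell lines with FPKM > 0, divided by the mean
    FPKM over those lines), occurrence, and the supporting means. Features
    expressed circularly but with zero linear signal everywhere are tallied,
    not scored.
    """

    per_line: pd.DataFrame
    summary: pd.DataFrame
    median_ratio: float
    n_circ_only: int


def circ_total_ratio(
    circ: CountMatrix,
    linear_fpkm: pd.DataFrame,
    junction_gene: pd.Series | None = None,
) -> RatioTable:
    """Relative circ/total expression: normalized backsplice reads / FPKM.

    At backsplice level pass ``junction_gene`` so each junction inherits its
    host gene's linear FPKM. This is a relative quantity, not a molar ratio:
    numerator counts only junction-spanning reads, denominator is
    length-normalized.
    """
    gene_of = (
        pd.Series(junction_gene)
        if junction_gene is not None
        else pd.Series(circ.features, index=circ.features)
    )
    common = [c for c in circ.samples if c in linear_fpkm.columns]
    if not common:
        raise ValidationError("no overlapping cell lines between circ and linear matrices")
    feats = [f for f in circ.features if gene_of.get(f) in linear_fpkm.index]
    circ_v = circ.values.loc[feats, common]
    lin_v = linear_fpkm.loc[gene_of.loc[feats], common]
    lin_v.index = circ_v.index
    per_line = circ_v / lin_v.where(lin_v > 0)

    expressed_lin = lin_v > 0
    n_lin = expressed_lin.sum(axis=1)
    mean_circ = circ_v.where(expressed_lin).sum(axis=1) / n_lin.where(n_lin > 0)
    mean_fpkm = lin_v.where(expressed_lin).sum(axis=1) / n_lin.where(n_lin > 0)
    avg_ratio = mean_circ / mean_fpkm

    circ_only = (circ_v.sum(axis=1) > 0) & (n_lin == 0)
    occurrence = (circ_v > 0).sum(axis=1)
    summary = pd.DataFrame(
        {
            "gene": gene_of.loc[feats].to_numpy(),
            "mean_circ": mean_circ,
            "mean_fpkm": mean_fpkm,
            "avg_ratio": avg_ratio,
            "occurrence": occurrence,
        }
    )
    defined = summary["avg_ratio"].dropna()
    return RatioTable(
        per_line=per_line,
        summary=summary,
        median_ratio=float(defined.median()) if len(defined) else float("nan"),
        n_circ_only=int(circ_only.sum()),
    )


@dataclass
class CorrelationResult:
    per_feature: pd.Series
    median: float
    q1: float
    q3: float
    fraction_positive: float
    n_excluded: int


def circ_linear_correlation(
    circ: CountMatrix,
    linear_fpkm: pd.DataFrame,
    junction_gene: pd.Series | None = None,
    min_cell_lines: int = 1,
) -> CorrelationResult:
    """Pearson correlation of circ vs linear expression across cell lines.

    Each feature (gene or junction) is paired with the linear FPKM of its
    co-derived gene. Features expressed in fewer than ``min_cell_lines``
    lines, or with zero variance on either side, are excluded and counted.
    """
    gene_of = (
        pd.Series(junction_gene)
        if junction_gene is not None
        else pd.Series(circ.features, index=circ.features)
    )
    common = [c for c in circ.samples if c in linear_fpkm.columns]
    if len(common) < 3:
        raise ValidationError("need at least 3 shared cell lines for correlation")
    feats = [f for f in circ.features if gene_of.get(f) in linear_fpkm.index]
    circ_v = circ.values.loc[feats, common].to_numpy(dtype=float)
    lin_v = linear_fpkm.loc[gene_of.loc[feats], common].to_numpy(dtype=float)

    occ = (circ_v > 0).sum(axis=1)
    sd_c = circ_v.std(axis=1)
    sd_l = lin_v.std(axis=1)
    ok = (occ >= min_cell_lines) & (sd_c > 0) & (sd_l > 0)
    n_excluded = int((~ok).sum())

    cc = circ_v - circ_v.mean(axis=1, keepdims=True)
    ll = lin_v - lin_v.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (cc * ll).sum(axis=1) / np.sqrt(
            (cc**2).sum(axis=1) * (ll**2).sum(axis=1)
        )
    per_feature = pd.Series(r, index=pd.Index(feats, name=circ.values.index.name))[ok]
    if len(per_feature):
        q1, med, q3 = per_feature.quantile([0.25, 0.5, 0.75])
        frac_pos = float((per_feature > 0).mean())
    else:
        q1 = med = q3 = frac_pos = float("nan")
    return CorrelationResult(
        per_feature=per_feature,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        fraction_positive=frac_pos,
        n_excluded=n_excluded,
    )


def polya_stretch_flag(sequence: str, min_run: int = 5) -> bool:
    """Does a circular sequence contain >= min_run consecutive As?

    The sequence is circular: a run may span the backsplice junction, so the
    scan extends min_run - 1 bases past the origin.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_SEQ
    if bad:
        raise ValidationError(f"invalid character(s) {sorted(bad)} in sequence")
    if min_run < 1:
        raise ValidationError("min_run must be >= 1")
    extended = seq + seq[: min_run - 1]
    return "A" * min_run in extended


def polya_set_fraction(sequences: dict[str, str] | list[str], min_run: int = 5) -> float:
    """Fraction of circles containing a polyA run of >= min_run."""
    seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    if not seqs:
        return float("nan")
    return sum(polya_stretch_flag(s, min_run) for s in seqs) / len(seqs)
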