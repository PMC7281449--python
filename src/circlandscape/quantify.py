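"""Backsplice- and gene-level circRNA count matrices.

The pipeline order is deliberate: per-sample raw counts are first normalized
to library size (reads per million), then replicates are averaged into one
column per cell line, then junctions are pooled into genes. Normalizing
before averaging keeps each replicate's weight independent of its sequencing
depth; pooling after averaging is equivalent to pooling before (both are
linear) but keeps the two levels exactly consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import BacksplicedJunction, CountMatrix, ValidationError


@dataclass
class LandscapeDataset:
    """All matrices of one dataset, at both levels, plus the sample table."""

    junctions: list[BacksplicedJunction]
    junction_gene: pd.Series  # junction id -> gene symbol
    backsplice_raw: CountMatrix  # per sample, raw counts
    backsplice_cpm: CountMatrix  # per sample, reads per million
    backsplice_cell_line: CountMatrix  # per cell line, replicate-averaged
    gene_cell_line: CountMatrix  # per cell line, junctions pooled per gene
    meta: pd.DataFrame
    linear_fpkm: pd.DataFrame | None = None  # genes x cell lines


def merge_junctions(
    per_sample: dict[str, list[BacksplicedJunction]]
) -> list[BacksplicedJunction]:
    """Merge per-sample junction calls into one feature list.

    Identity is the canonical junction id (gene, exon pair, coordinates);
    per-sample read counts are collected on the merged record.
    """
    merged: dict[str, BacksplicedJunction] = {}
    for sample_id, junctions in per_sample.items():
        for j in junctions:
            key = j.junction_id
            if key not in merged:
                merged[key] = BacksplicedJunction(
                    chrom=j.chrom,
                    start=j.start,
                    end=j.end,
                    strand=j.strand,
                    gene=j.gene,
                    reads={},
                    acceptor_exon=j.acceptor_exon,
                    donor_exon=j.donor_exon,
                    unannotated=j.unannotated,
                )
            merged[key].reads[sample_id] = merged[key].reads.get(sample_id, 0) + j.reads.get(
                sample_id, 0
            )
    return list(merged.values())


def build_backsplice_matrix(
    junctions: list[BacksplicedJunction], sample_ids: list[str]
) -> CountMatrix:
    """Raw backsplice counts, one row per junction, one column per sample."""
    ids = [j.junction_id for j in junctions]
    data = np.zeros((len(junctions), len(sample_ids)))
    col = {s: i for i, s in enumerate(sample_ids)}
    for row, j in enumerate(junctions):
        for sample, n in j.reads.items():
            if sample in col:
                data[row, col[sample]] = n
    df = pd.DataFrame(data, index=pd.Index(ids, name="junction"), columns=sample_ids)
    return CountMatrix(values=df, level="backsplice", normalization="raw")


def normalize_per_million(matrix: CountMatrix, meta: pd.DataFrame) -> CountMatrix:
    """Scale each sample column to reads per million mapped reads."""
    if matrix.normalization != "raw":
        raise ValidationError("normalize_per_million expects a raw matrix")
    missing = [s for s in matrix.samples if s not in meta.index]
    if missing:
        raise ValidationError(f"no library size for sample(s): {missing}")
    libs = meta.loc[matrix.samples, "library_size"].astype(float)
    values = matrix.values * (1e6 / libs)
    return CountMatrix(values=values, level=matrix.level, normalization="per_million")


def average_replicates(matrix: CountMatrix, meta: pd.DataFrame) -> CountMatrix:
    """Average replicate columns into one column per cell line."""
    missing = [s for s in matrix.samples if s not in meta.index]
    if missing:
        raise ValidationError(f"sample(s) not in metadata: {missing}")
    lines = meta.loc[matrix.samples, "cell_line"]
    groups = lines.groupby(lines).groups
    if not groups:
        raise ValidationError("no cell lines to average")
    cols = {}
    for line in sorted(groups):
        samples = list(groups[line])
        cols[line] = matrix.values[samples].mean(axis=1)
    df = pd.DataFrame(cols)
    df.index.name = matrix.values.index.name
    return CountMatrix(values=df, level=matrix.level, normalization=matrix.normalization)


def aggregate_gene_level(
    matrix: CountMatrix, junction_gene: pd.Series | dict[str, str]
) -> CountMatrix:
    """Pool backsplice rows into genes by summation.

    Accumulation is sequential in the matrix's row order (unbuffered
    ``np.add.at``), so for every gene the value is bitwise-identical to an
    in-order ``+=`` over its junction rows — the conservation contract the
    tests hold this to.
    """
    if matrix.level != "backsplice":
        raise ValidationError("aggregate_gene_level expects a backsplice-level matrix")
    mapping = pd.Series(junction_gene)
    unmapped = [f for f in matrix.features if f not in mapping.index]
    if unmapped:
        raise ValidationError(f"junction id(s) with no gene mapping: {unmapped[:5]}")
    genes = mapping.loc[matrix.features]
    gene_index = pd.Index(sorted(genes.unique()), name="gene")
    gene_pos = {g: i for i, g in enumerate(gene_index)}
    row_to_gene = np.array([gene_pos[g] for g in genes])
    out = np.zeros((len(gene_index), matrix.values.shape[1]))
    np.add.at(out, row_to_gene, matrix.values.to_numpy())
    df = pd.DataFrame(out, index=gene_index, columns=matrix.values.columns)
    return CountMatrix(values=df, level="gene", normalization=matrix.normalization)


def occurrence(matrix: CountMatrix) -> tuple[pd.Series, pd.Series]:
    """Per feature: in how many cell lines it is expressed (> 0).

    Returns (per-feature occurrence, histogram over occurrence values
    0..n_cell_lines).
    """
    occ = (matrix.values > 0).sum(axis=1).astype(int)
    hist = occ.value_counts().reindex(
        range(0, matrix.values.shape[1] + 1), fill_value=0
    )
    hist.index.name = "n_cell_lines"
    return occ, hist


def filter_min_cell_lines(matrix: CountMatrix, k: int = 30) -> CountMatrix:
    """Keep features expressed in at least k cell lines (inclusive)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > matrix.values.shape[1]:
        warnings.warn(
            f"k={k} exceeds the {matrix.values.shape[1]} available cell lines; "
            "result is empty",
            stacklevel=2,
        )
    occ, _ = occurrence(matrix)
    kept = matrix.values.loc[occ >= k]
    return CountMatrix(values=kept, level=matrix.level, normalization=matrix.normalization)


def backsplice_sites_per_gene(
    junctions: list[BacksplicedJunction],
) -> tuple[pd.Series, dict[str, float]]:
    """Distinct backsplice sites per gene, with mean/median/max summary."""
    per_gene: dict[str, set[str]] = {}
    for j in junctions:
        per_gene.setdefault(j.gene, set()).add(j.junction_id)
    counts = pd.Series(
        {g: len(ids) for g, ids in per_gene.items()}, name="n_backsplice_sites"
    ).sort_index()
    summary = {
        "mean": float(counts.mean()),
        "median": float(counts.median()),
        "max": int(counts.max()),
        "min": int(counts.min()),
        "n_genes": int(len(counts)),
    }
    return counts, summary


def top_expressed(matrix: CountMatrix, n: int = 100) -> list[str]:
    """Features ranked by total expression over cell lines, descending.

    Ties break by feature id so the ranking is deterministic.
    """
    totals = matrix.values.sum(axis=1)
    order = sorted(totals.index, key=lambda f: (-totals[f], f))
    return order[:n]


def replicate_concordance(
    matrix: CountMatrix, meta: pd.DataFrame
) -> tuple[pd.Series, list[str]]:
    """Reproducibility of replicates of the same cell line.

    Returns (per-cell-line mean pairwise Pearson correlation between its
    replicate columns — NaN for single-replicate lines) and a list of flagged
    samples whose most-correlated other sample belongs to a different cell
    line.
    """
    lines = meta.loc[matrix.samples, "cell_line"]
    corr = matrix.values.corr(method="pearson")
    scores = {}
    for line, samples in lines.groupby(lines).groups.items():
        samples = list(samples)
        if len(samples) < 2:
            scores[line] = np.nan
            continue
        pairs = [
            corr.loc[a, b]
            for i, a in enumerate(samples)
            for b in samples[i + 1 :]
        ]
        scores[line] = float(np.mean(pairs))
    flagged = []
    for sample in matrix.samples:
        others = corr.loc[sample].drop(sample)
        if others.isna().all():
            continue
        best = others.idxmax()
        if lines[best] != lines[sample]:
            flagged.append(sample)
    return pd.Series(scores, name="replicate_concordance").sort_index(), flagged


def build_dataset(
    per_sample: dict[str, list[BacksplicedJunction]],
    meta: pd.DataFrame,
    linear_fpkm: CountMatrix | None = None,
) -> LandscapeDataset:
    """Assemble the full dataset: merge, normalize, average, aggregate.

    ``linear_fpkm`` is a genes x samples matrix; it is replicate-averaged to
    cell lines here so circular and linear values line up column-wise.
    """
    junctions = merge_junctions(per_sample)
    sample_ids = [s for s in meta.index if s in per_sample]
    raw = build_backsplice_matrix(junctions, sample_ids)
    cpm = normalize_per_million(raw, meta)
    per_line = average_replicates(cpm, meta)
    junction_gene = pd.Series(
        {j.junction_id: j.gene for j in junctions}, name="gene"
    )
    gene_level = aggregate_gene_level(per_line, junction_gene)
    linear_per_line = None
    if linear_fpkm is not None:
        lin_cols = [s for s in linear_fpkm.values.columns if s in meta.index]
        linear_per_line = average_replicates(
            CountMatrix(
                values=linear_fpkm.values[lin_cols],
                level="gene",
                normalization="fpkm",
            ),
            meta,
        ).values
    return LandscapeDataset(
        junctions=junctions,
        junction_gene=junction_gene,
        backsplice_raw=raw,
        backsplice_cpm=cpm,
        backsplice_cell_line=per_line,
        gene_cell_line=gene_level,
        meta=meta,
        linear_fpkm=linear_per_line,
    )
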