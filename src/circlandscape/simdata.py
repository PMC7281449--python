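"""Synthetic circRNA landscape generator.

Emulates the statistical structure of a deep rRNA-depleted RNA-seq panel of
~60 lung cell lines with 2-3 replicates each: a heavy-tailed number of
backsplice sites per gene, strong first-exon acceptor and last-exon donor
depletion, negative-binomial backsplice counts whose latent abundance is
log-normally coupled to the gene's linear expression, high cell-line
specificity for most circRNAs, a cancer-gene subset with elevated
circularization, planted group effects, and proliferation classes of chosen
sizes. Every draw flows from one seeded generator, so a config plus seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circorf import STOP_CODONS, CircularSequence
from .formats import (
    BacksplicedJunction,
    CountMatrix,
    GENOTYPE_GENES,
    TranscriptModel,
    write_fasta,
    write_junctions,
    write_sample_metadata,
)


@dataclass(frozen=True)
class GroupEffect:
    """A planted multiplicative expression effect for one contrast.

    ``contrast`` is one of transformed, histology, EGFR, KRAS, TP53, BRAF or
    proliferation (fast lines form the positive group); ``fraction`` of all
    junctions are affected; their latent rate is multiplied by ``fold`` in
    positive-group cell lines.
    """

    contrast: str
    fraction: float
    fold: float


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the study conditions
    (60 lines: 50 LUAD / 7 other NSCLC / 3 non-transformed; 2-3 replicates;
    fast >= 5-fold and slow <= 3-fold proliferation classes of 11 and 21
    lines; 78-fold exon-2 vs exon-1 acceptor preference; 62-fold
    second-to-last vs last donor preference; circ-linear coupling 0.4;
    ~2.8% of genes cancer-census with 2.1-fold higher circ output)."""

    seed: int = 0
    # gene models
    n_genes: int = 300
    exon_count_range: tuple[int, int] = (1, 50)
    exon_count_log_mean: float = math.log(9.0)
    exon_count_log_sd: float = 0.6
    exon_length_log_mean: float = math.log(150.0)
    exon_length_log_sd: float = 0.5
    intron_length_log_mean: float = math.log(1500.0)
    intron_length_log_sd: float = 0.8
    genes_per_chromosome: int = 50
    # panel
    n_cell_lines: int = 60
    replicate_choices: tuple[int, ...] = (2, 3)
    replicate_probs: tuple[float, ...] = (0.1, 0.9)
    library_size_range: tuple[float, float] = (2.0e7, 4.0e7)
    histology_proportions: tuple[float, float, float] = (50 / 60, 7 / 60, 3 / 60)
    genotype_mut_probs: dict = field(
        default_factory=lambda: {"EGFR": 0.15, "KRAS": 0.30, "TP53": 0.50, "BRAF": 0.05}
    )
    genotype_unknown_prob: float = 0.05
    # proliferation
    n_fast: int = 11
    n_slow: int = 21
    fast_fold_range: tuple[float, float] = (5.0, 8.0)
    slow_fold_range: tuple[float, float] = (1.5, 3.0)
    intermediate_fold_range: tuple[float, float] = (3.2, 4.8)
    # circRNA structure
    circ_per_gene_log_mean: float = math.log(5.0)
    circ_per_gene_log_sd: float = 1.32
    circ_per_gene_max: int = 50
    acceptor_first_weight: float = 1 / 78
    acceptor_decay: float = 0.85
    donor_last_weight: float = 1 / 62
    donor_decay: float = 0.85
    # expression model
    fpkm_log_mean: float = 1.0
    fpkm_sigma_gene: float = 1.0
    fpkm_sigma_line: float = 0.7
    fpkm_replicate_sigma: float = 0.1
    coupling_rho: float = 0.4
    circ_rate_log_mean: float = 0.0  # per-million units
    circ_rate_log_sd: float = 1.0
    sparsity: float = 0.45
    dispersion: float = 0.3
    # planted effects
    group_effects: tuple[GroupEffect, ...] = ()
    prolif_effect_fraction: float = 0.0
    prolif_beta: float = 0.0
    cgc_fraction: float = 0.028
    cgc_multiplier: float = 2.1

    def __post_init__(self) -> None:
        if self.n_fast + self.n_slow > self.n_cell_lines:
            raise ValueError("planted fast+slow class sizes exceed n_cell_lines")
        for p in (self.sparsity, self.cgc_fraction, self.prolif_effect_fraction):
            if not 0 <= p <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for eff in self.group_effects:
            if not 0 <= eff.fraction <= 1:
                raise ValueError("group effect fraction must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "group_effects" in d:
            d["group_effects"] = tuple(
                GroupEffect(**e) if isinstance(e, dict) else e
                for e in d["group_effects"]
            )
        for key in (
            "exon_count_range",
            "library_size_range",
            "histology_proportions",
            "fast_fold_range",
            "slow_fold_range",
            "intermediate_fold_range",
            "replicate_choices",
            "replicate_probs",
        ):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SimulatedLandscape:
    config: SimulationConfig
    catalog: dict[str, TranscriptModel]
    junctions_by_sample: dict[str, list[BacksplicedJunction]]
    linear_fpkm: CountMatrix  # genes x samples
    meta: pd.DataFrame
    truth: dict


def latent_coupling(rho: float, sigma: float) -> float:
    """Log-scale correlation producing value-scale Pearson ``rho`` for a
    bivariate lognormal with equal log-sd ``sigma``.

    Inverts corr(X,Y) = (exp(rho_log * s^2) - 1) / (exp(s^2) - 1). Counting
    noise on top attenuates the realized correlation slightly below target.
    """
    if rho == 0 or sigma == 0:
        return float(rho)
    s2 = sigma * sigma
    rho_log = math.log1p(rho * math.expm1(s2)) / s2
    return max(-1.0, min(1.0, rho_log))


# ---------------------------------------------------------------------------
# catalog


def simulate_catalog(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, TranscriptModel]:
    """Synthetic gene models: one transcript per gene on synthetic chromosomes."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.exon_count_range
    catalog: dict[str, TranscriptModel] = {}
    cursor: dict[str, int] = {}
    for i in range(config.n_genes):
        gene = f"g{i + 1:04d}"
        chrom = f"chr{i // config.genes_per_chromosome + 1}"
        n_exons = int(
            np.clip(
                round(rng.lognormal(config.exon_count_log_mean, config.exon_count_log_sd)),
                lo,
                hi,
            )
        )
        pos = cursor.get(chrom, 10_000)
        exons = []
        for k in range(n_exons):
            length = max(
                30,
                int(round(rng.lognormal(config.exon_length_log_mean, config.exon_length_log_sd))),
            )
            exons.append((pos, pos + length))
            intron = max(
                50,
                int(round(rng.lognormal(config.intron_length_log_mean, config.intron_length_log_sd))),
            )
            pos += length + intron
        cursor[chrom] = pos + 5_000
        strand = "+" if rng.random() < 0.5 else "-"
        ordered = tuple(exons if strand == "+" else exons[::-1])
        catalog[gene] = TranscriptModel(
            gene=gene,
            transcript_id=f"{gene}.t1",
            chrom=chrom,
            strand=strand,
            exons=ordered,
        )
    return catalog


def write_gtf(catalog: dict[str, TranscriptModel], path: str | Path) -> None:
    """Write the catalog as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for gene in sorted(catalog):
            model = catalog[gene]
            genomic = sorted(model.exons)
            g_start, g_end = genomic[0][0] + 1, genomic[-1][1]
            attrs = f'gene_id "{model.gene}"; transcript_id "{model.transcript_id}";'
            fh.write(
                f"{model.chrom}\tsim\ttranscript\t{g_start}\t{g_end}\t.\t{model.strand}\t.\t{attrs}\n"
            )
            for s, e in genomic:
                fh.write(
                    f"{model.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# panel metadata


def _simulate_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_cell_lines
    width = len(str(n))
    lines = [f"CL{i + 1:0{width}d}" for i in range(n)]

    p_luad, p_other, _ = config.histology_proportions
    n_luad = int(round(p_luad * n))
    n_other = int(round(p_other * n))
    n_nt = max(n - n_luad - n_other, 0)
    hist_pool = (
        ["LUAD"] * n_luad + ["NSCLC_other"] * n_other + ["non_transformed"] * n_nt
    )[:n]
    histology = dict(zip(rng.permutation(lines), hist_pool))

    order = rng.permutation(lines)
    folds: dict[str, float] = {}
    for i, line in enumerate(order):
        if i < config.n_fast:
            rg = config.fast_fold_range
        elif i < config.n_fast + config.n_slow:
            rg = config.slow_fold_range
        else:
            rg = config.intermediate_fold_range
        folds[line] = float(rng.uniform(*rg))

    genotypes: dict[str, dict[str, str]] = {}
    for line in lines:
        flags = {}
        for g in GENOTYPE_GENES:
            if rng.random() < config.genotype_unknown_prob:
                flags[g] = "unknown"
            elif rng.random() < config.genotype_mut_probs.get(g, 0.0):
                flags[g] = "mut"
            else:
                flags[g] = "wt"
        genotypes[line] = flags

    rows = []
    probs = np.asarray(config.replicate_probs, dtype=float)
    probs = probs / probs.sum()
    for line in lines:
        n_rep = int(rng.choice(config.replicate_choices, p=probs))
        for r in range(1, n_rep + 1):
            lib = float(rng.uniform(*config.library_size_range))
            rows.append(
                {
                    "sample_id": f"{line}_r{r}",
                    "cell_line": line,
                    "replicate": r,
                    "library_size": int(round(lib)),
                    "histology": histology[line],
                    **genotypes[line],
                    "proliferation_fold_72h": round(folds[line], 3),
                }
            )
    meta = pd.DataFrame(rows)
    return meta.set_index("sample_id", drop=False)


def _positive_lines(meta: pd.DataFrame, contrast: str, config: SimulationConfig) -> list[str]:
    per_line = meta.groupby("cell_line").first()
    if contrast == "transformed":
        return sorted(per_line.index[per_line["histology"] != "non_transformed"])
    if contrast == "histology":
        return sorted(per_line.index[per_line["histology"] == "LUAD"])
    if contrast in GENOTYPE_GENES:
        return sorted(per_line.index[per_line[contrast] == "mut"])
    if contrast == "proliferation":
        folds = per_line["proliferation_fold_72h"]
        return sorted(folds.index[folds >= config.fast_fold_range[0]])
    raise ValueError(f"unknown contrast {contrast!r} in group effect")


# ---------------------------------------------------------------------------
# landscape


def _draw_junctions(
    config: SimulationConfig, catalog: dict[str, TranscriptModel], rng: np.random.Generator
) -> list[BacksplicedJunction]:
    junctions: list[BacksplicedJunction] = []
    for gene in sorted(catalog):
        model = catalog[gene]
        n = model.n_exons
        acc_w = np.array(
            [
                config.acceptor_first_weight
                if i == 1
                else config.acceptor_decay ** (i - 2)
                for i in range(1, n + 1)
            ]
        )
        don_w = np.array(
            [
                config.donor_last_weight
                if j == n
                else config.donor_decay ** (n - 1 - j)
                for j in range(1, n + 1)
            ]
        )
        if n == 1:
            acc_w[:] = 1.0
            don_w[:] = 1.0
        k = int(
            np.clip(
                round(rng.lognormal(config.circ_per_gene_log_mean, config.circ_per_gene_log_sd)),
                1,
                config.circ_per_gene_max,
            )
        )
        seen: set[tuple[int, int]] = set()
        p_acc = acc_w / acc_w.sum()
        for _ in range(k):
            a = int(rng.choice(n, p=p_acc)) + 1
            tail = don_w[a - 1 :]
            d = a + int(rng.choice(n - a + 1, p=tail / tail.sum()))
            if (a, d) in seen:
                continue
            seen.add((a, d))
            acc_exon = model.exons[a - 1]
            don_exon = model.exons[d - 1]
            start = min(acc_exon[0], don_exon[0])
            end = max(acc_exon[1], don_exon[1])
            junctions.append(
                BacksplicedJunction(
                    chrom=model.chrom,
                    start=start,
                    end=end,
                    strand=model.strand,
                    gene=gene,
                    reads={},
                    acceptor_exon=a,
                    donor_exon=d,
                )
            )
    return junctions


def simulate_junction_structures(
    config: SimulationConfig, catalog: dict[str, TranscriptModel] | None = None
) -> tuple[dict[str, TranscriptModel], list[BacksplicedJunction]]:
    """Draw only the junction structures (no expression, no censoring).

    Useful for positional-statistics recovery, where detection would censor
    rare exon classes.
    """
    rng = np.random.default_rng(config.seed)
    if catalog is None:
        catalog = simulate_catalog(config, rng)
    return catalog, _draw_junctions(config, catalog, rng)


def simulate_landscape(
    config: SimulationConfig, catalog: dict[str, TranscriptModel] | None = None
) -> SimulatedLandscape:
    """Generate the full synthetic dataset.

    One seeded generator drives, in fixed order: catalog, metadata, junction
    structures, latent expression, planted effects, and counts.
    """
    rng = np.random.default_rng(config.seed)
    if catalog is None:
        catalog = simulate_catalog(config, rng)
    meta = _simulate_metadata(config, rng)
    junctions = _draw_junctions(config, catalog, rng)

    genes = sorted(catalog)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes, n_lines = len(genes), config.n_cell_lines
    lines = sorted(meta["cell_line"].unique())
    line_pos = {c: i for i, c in enumerate(lines)}

    # latent log-normal abundance, circ coupled to linear through a shared factor
    gene_mu = rng.normal(config.fpkm_log_mean, config.fpkm_sigma_gene, n_genes)
    z_lin = rng.standard_normal((n_genes, n_lines))
    z_extra = rng.standard_normal((n_genes, n_lines))
    rho_log = latent_coupling(config.coupling_rho, config.fpkm_sigma_line)
    z_circ = rho_log * z_lin + math.sqrt(max(0.0, 1 - rho_log**2)) * z_extra
    lin_line = np.exp(gene_mu[:, None] + config.fpkm_sigma_line * z_lin)
    circ_factor = np.exp(config.fpkm_sigma_line * z_circ)

    n_junc = len(junctions)
    base = rng.lognormal(config.circ_rate_log_mean, config.circ_rate_log_sd, n_junc)
    cgc_genes = sorted(
        str(g)
        for g in rng.choice(
            genes, size=int(round(config.cgc_fraction * n_genes)), replace=False
        )
    )
    cgc_set = set(cgc_genes)
    gene_idx = np.array([gene_pos[j.gene] for j in junctions])
    rate = base[:, None] * circ_factor[gene_idx, :]
    is_cgc = np.array([j.gene in cgc_set for j in junctions])
    rate[is_cgc] *= config.cgc_multiplier

    truth: dict = {
        "coupling_rho": config.coupling_rho,
        "coupling_rho_log": rho_log,
        "cgc_genes": cgc_genes,
        "class_sizes": {"fast": config.n_fast, "slow": config.n_slow},
        "affected": {},
        "prolif_features": [],
        "specific_junctions": [],
    }

    junction_ids = [j.junction_id for j in junctions]
    for eff in config.group_effects:
        positive = _positive_lines(meta, eff.contrast, config)
        pos_cols = np.array([line_pos[c] for c in positive], dtype=int)
        n_aff = int(round(eff.fraction * n_junc))
        aff = rng.choice(n_junc, size=n_aff, replace=False)
        rate[np.ix_(aff, pos_cols)] *= eff.fold
        truth["affected"][f"{eff.contrast}:{eff.fold}"] = sorted(
            junction_ids[i] for i in aff
        )

    if config.prolif_effect_fraction > 0 and config.prolif_beta != 0:
        folds = meta.groupby("cell_line")["proliferation_fold_72h"].first().loc[lines]
        z = (folds - folds.mean()) / folds.std()
        n_aff = int(round(config.prolif_effect_fraction * n_junc))
        aff = rng.choice(n_junc, size=n_aff, replace=False)
        rate[aff, :] *= np.exp(config.prolif_beta * z.to_numpy())[None, :]
        truth["prolif_features"] = sorted(junction_ids[i] for i in aff)

    if config.sparsity > 0:
        specific = rng.random(n_junc) < config.sparsity
        home = rng.integers(0, n_lines, size=n_junc)
        mask = np.ones((n_junc, n_lines), dtype=bool)
        mask[specific] = False
        mask[np.arange(n_junc)[specific], home[specific]] = True
        rate = rate * mask
        truth["specific_junctions"] = sorted(
            junction_ids[i] for i in np.flatnonzero(specific)
        )

    # per-sample counts: negative binomial as gamma-mixed Poisson
    samples = list(meta.index)
    junctions_by_sample: dict[str, list[BacksplicedJunction]] = {}
    fpkm_cols: dict[str, np.ndarray] = {}
    for sample in samples:
        line = meta.loc[sample, "cell_line"]
        lib = float(meta.loc[sample, "library_size"])
        mean = rate[:, line_pos[line]] * (lib / 1e6)
        if config.dispersion > 0:
            lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mean)
        else:
            lam = mean
        counts = rng.poisson(lam)
        calls = []
        for i in np.flatnonzero(counts):
            j = junctions[i]
            calls.append(
                BacksplicedJunction(
                    chrom=j.chrom,
                    start=j.start,
                    end=j.end,
                    strand=j.strand,
                    gene=j.gene,
                    reads={sample: int(counts[i])},
                    acceptor_exon=j.acceptor_exon,
                    donor_exon=j.donor_exon,
                )
            )
        junctions_by_sample[sample] = calls
        rep_noise = np.exp(
            rng.normal(0.0, config.fpkm_replicate_sigma, n_genes)
        )
        fpkm_cols[sample] = lin_line[:, line_pos[line]] * rep_noise

    linear = CountMatrix(
        values=pd.DataFrame(fpkm_cols, index=pd.Index(genes, name="gene")),
        level="gene",
        normalization="fpkm",
    )
    return SimulatedLandscape(
        config=config,
        catalog=catalog,
        junctions_by_sample=junctions_by_sample,
        linear_fpkm=linear,
        meta=meta,
        truth=truth,
    )


def write_outputs(sim: SimulatedLandscape, outdir: str | Path) -> list[Path]:
    """Write GTF, per-sample junction TSVs, FPKM, metadata, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    gtf = outdir / "annotation.gtf"
    write_gtf(sim.catalog, gtf)
    written.append(gtf)
    jdir = outdir / "junctions"
    jdir.mkdir(exist_ok=True)
    for sample, calls in sim.junctions_by_sample.items():
        p = jdir / f"{sample}.tsv"
        write_junctions(calls, p, sample)
        written.append(p)
    fpkm = outdir / "fpkm.tsv"
    sim.linear_fpkm.values.to_csv(fpkm, sep="\t")
    written.append(fpkm)
    metap = outdir / "metadata.tsv"
    write_sample_metadata(sim.meta, metap)
    written.append(metap)
    cgc = outdir / "cgc_genes.txt"
    cgc.write_text("".join(g + "\n" for g in sim.truth["cgc_genes"]))
    written.append(cgc)
    truthp = outdir / "truth.json"
    truthp.write_text(json.dumps(sim.truth, indent=1, default=str))
    written.append(truthp)
    return written


# ---------------------------------------------------------------------------
# planted rolling-circle ORF circles


def simulate_circle_with_orf(
    L: int,
    orf_start: int,
    peptide_len: int,
    seed: int = 0,
    name: str = "synthetic_circle",
) -> CircularSequence:
    """Construct a circle whose unique longest rolling-circle ORF is planted.

    The ORF starts at ``orf_start`` (0 = first base after the backsplice
    junction), encodes exactly ``peptide_len`` residues, and ends in a TAA
    stop; reading may wrap the circle up to three times. The only ATG on the
    circle is the planted start and the only reachable in-frame stop is the
    planted one, so the ORF finder must recover exactly this geometry.
    Filler bases are drawn from {A, C, G} (no T), which structurally rules
    out unplanned starts and stops.
    """
    if L < 3:
        raise ValueError("circle length must be >= 3")
    if not 0 <= orf_start < L:
        raise ValueError("orf_start must lie in [0, L)")
    total = 3 * (peptide_len + 1)
    if total > 3 * L:
        raise ValueError(
            f"ORF of {total} nt does not fit within three wraps of a {L}-nt circle"
        )
    if peptide_len < 1:
        raise ValueError("peptide_len must be >= 1")

    rng = np.random.default_rng(seed)
    seq: list[str | None] = [None] * L

    def plant(pos: int, bases: str) -> None:
        for off, b in enumerate(bases):
            p = (pos + off) % L
            if seq[p] is not None and seq[p] != b:
                raise ValueError(
                    "infeasible geometry: planted start and stop codons overlap "
                    "inconsistently on the circle"
                )
            seq[p] = b

    plant(orf_start, "ATG")
    stop_pos = (orf_start + 3 * peptide_len) % L
    plant(stop_pos, "TAA")

    # Any T read at codon phase 0 before the planted stop could open a stop
    # codon. The two planted Ts sit at orf_start+1 and stop_pos; walk every
    # in-frame codon of the ORF and make sure neither produces an early stop.
    for off in range(0, total - 3, 3):
        p = (orf_start + off) % L
        if seq[p] == "T":
            if p == stop_pos:
                raise ValueError(
                    "infeasible geometry: the stop codon is read in frame "
                    "before the ORF end (premature termination)"
                )
            # T of the ATG read in frame on a later pass: next base is the
            # planted G; force the base after it to avoid TGA.
            follow = (p + 2) % L
            if seq[follow] is None:
                seq[follow] = "C"
            elif seq[follow] == "A" and seq[(p + 1) % L] == "G":
                raise ValueError(
                    "infeasible geometry: unavoidable premature stop codon"
                )

    filler = "ACG"
    for p in range(L):
        if seq[p] is None:
            seq[p] = filler[rng.integers(0, 3)]
    sequence = "".join(seq)  # type: ignore[arg-type]

    doubled = sequence + sequence
    starts = [i for i in range(L) if doubled[i : i + 3] == "ATG"]
    if starts != [orf_start]:
        raise ValueError("infeasible geometry: could not keep the start codon unique")
    template = sequence * 4
    for off in range(0, total - 3, 3):
        if template[orf_start + off : orf_start + off + 3] in STOP_CODONS:
            raise ValueError("infeasible geometry: premature in-frame stop remains")
    if template[orf_start + total - 3 : orf_start + total] not in STOP_CODONS:
        raise ValueError("infeasible geometry: planted stop codon was clobbered")
    return CircularSequence(sequence=sequence, name=name)
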