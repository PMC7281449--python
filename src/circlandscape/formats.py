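"""File formats and domain types for the circRNA landscape pipeline.

Readers validate external tables into domain objects; writers round-trip
values at full precision. Genomic coordinates are 0-based half-open (BED
convention) throughout; exon indices are 1-based in transcript order, so
"exon 2" means the second exon read 5'->3' along the mRNA regardless of
strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

HISTOLOGY_LABELS = ("LUAD", "NSCLC_other", "non_transformed")
GENOTYPE_GENES = ("EGFR", "KRAS", "TP53", "BRAF")
GENOTYPE_LABELS = ("mut", "wt", "unknown")

JUNCTION_COLUMNS = ("chrom", "start", "end", "strand", "gene", "readNumber")
OPTIONAL_JUNCTION_COLUMNS = ("acceptorExon", "donorExon")

METADATA_COLUMNS = (
    "sample_id",
    "cell_line",
    "replicate",
    "library_size",
    "histology",
    "EGFR",
    "KRAS",
    "TP53",
    "BRAF",
    "proliferation_fold_72h",
)


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


class ValidationError(ValueError):
    """A well-formed file carries values violating a domain invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class BacksplicedJunction:
    """One detected circRNA: a backsplice joining a donor exon back to an
    upstream acceptor exon.

    ``start``/``end`` span the circle on the genome (0-based half-open:
    start of the acceptor exon to end of the donor exon). ``reads`` maps
    sample id -> backsplice-spanning read count. Exon indices are 1-based in
    transcript order and may be absent until :func:`annotate_exons` runs.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene: str
    reads: dict[str, int] = field(default_factory=dict)
    acceptor_exon: int | None = None
    donor_exon: int | None = None
    unannotated: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"junction start must be < end ({self.chrom}:{self.start}-{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        for sample, n in self.reads.items():
            if n < 0:
                raise ValidationError(
                    f"negative read count {n} for sample {sample!r} "
                    f"({self.chrom}:{self.start}-{self.end})"
                )
        if (
            self.acceptor_exon is not None
            and self.donor_exon is not None
            and self.acceptor_exon > self.donor_exon
        ):
            raise ValidationError(
                f"acceptor exon {self.acceptor_exon} must not exceed donor exon "
                f"{self.donor_exon} ({self.gene})"
            )

    @property
    def junction_id(self) -> str:
        """Canonical id: gene:acceptor-donor@chrom:start-end."""
        acc = self.acceptor_exon if self.acceptor_exon is not None else "."
        don = self.donor_exon if self.donor_exon is not None else "."
        return f"{self.gene}:{acc}-{don}@{self.chrom}:{self.start}-{self.end}"

    @property
    def display_name(self) -> str:
        """Field-style display, donor exon first: circSMAD2-6,2."""
        if self.acceptor_exon is None or self.donor_exon is None:
            return f"circ{self.gene}"
        return f"circ{self.gene}-{self.donor_exon},{self.acceptor_exon}"

    @property
    def total_reads(self) -> int:
        return sum(self.reads.values())


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon list of a gene's canonical transcript.

    ``exons`` are (start, end) genomic intervals 0-based half-open, listed in
    transcript (5'->3') order: ascending genomic start on '+', descending
    on '-'.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        starts = [e[0] for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(
            starts, reverse=True
        )
        if not ordered:
            raise ValidationError(
                f"exons of {self.transcript_id} are not in transcript order"
            )
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"empty exon interval in {self.transcript_id}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class CountMatrix:
    """Features x samples (or cell lines) table with level/normalization tags.

    ``level`` is 'gene' or 'backsplice'; ``normalization`` one of 'raw',
    'per_million', 'fpkm'.
    """

    values: pd.DataFrame
    level: str
    normalization: str

    def __post_init__(self) -> None:
        if self.level not in ("gene", "backsplice"):
            raise ValidationError(f"unknown level {self.level!r}")
        if self.normalization not in ("raw", "per_million", "fpkm"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate feature ids in count matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate column ids in count matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative values in count matrix")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# junction tables


def read_junctions(path: str | Path, sample_id: str) -> list[BacksplicedJunction]:
    """Read one sample's backsplice call table (BED-like TSV).

    Columns: chrom, start, end, strand, gene, readNumber, optionally
    acceptorExon and donorExon. A header row is detected and honored;
    otherwise columns are taken positionally. All reads are attributed to
    ``sample_id``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        return []
    first = lines[0].rstrip("\n").split("\t")
    have_header = not _is_int(first[1] if len(first) > 1 else "")
    if have_header:
        missing = [c for c in JUNCTION_COLUMNS if c not in first]
        if missing:
            raise FormatError(
                f"{path}: missing mandatory column(s) {', '.join(missing)}"
            )
        col_of = {name: first.index(name) for name in first}
        body = lines[1:]
        offset = 2
    else:
        if len(first) < len(JUNCTION_COLUMNS):
            raise FormatError(
                f"{path}: expected at least {len(JUNCTION_COLUMNS)} columns "
                f"(chrom, start, end, strand, gene, readNumber), got {len(first)}"
            )
        names = list(JUNCTION_COLUMNS) + list(
            OPTIONAL_JUNCTION_COLUMNS[: len(first) - len(JUNCTION_COLUMNS)]
        )
        col_of = {name: i for i, name in enumerate(names)}
        body = lines
        offset = 1

    junctions: list[BacksplicedJunction] = []
    problems: list[str] = []
    for lineno, line in enumerate(body, start=offset):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            start = int(fields[col_of["start"]])
            end = int(fields[col_of["end"]])
            count = int(fields[col_of["readNumber"]])
            acc = don = None
            if "acceptorExon" in col_of and len(fields) > col_of["acceptorExon"]:
                raw = fields[col_of["acceptorExon"]]
                acc = int(raw) if raw not in ("", ".") else None
            if "donorExon" in col_of and len(fields) > col_of["donorExon"]:
                raw = fields[col_of["donorExon"]]
                don = int(raw) if raw not in ("", ".") else None
            junctions.append(
                BacksplicedJunction(
                    chrom=fields[col_of["chrom"]],
                    start=start,
                    end=end,
                    strand=fields[col_of["strand"]],
                    gene=fields[col_of["gene"]],
                    reads={sample_id: count},
                    acceptor_exon=acc,
                    donor_exon=don,
                )
            )
        except (IndexError, ValueError) as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        raise FormatError(f"{path}: malformed line(s): " + "; ".join(problems))
    return junctions


def write_junctions(
    junctions: list[BacksplicedJunction], path: str | Path, sample_id: str
) -> None:
    """Write one sample's junction table (header included)."""
    with open(path, "w") as fh:
        fh.write("\t".join(JUNCTION_COLUMNS + OPTIONAL_JUNCTION_COLUMNS) + "\n")
        for j in junctions:
            acc = "." if j.acceptor_exon is None else str(j.acceptor_exon)
            don = "." if j.donor_exon is None else str(j.donor_exon)
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t{j.gene}\t"
                f"{j.reads.get(sample_id, 0)}\t{acc}\t{don}\n"
            )


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path) -> dict[str, TranscriptModel]:
    """Read a GTF and pick one canonical transcript per gene.

    The canonical transcript is the one with the most exons; ties go to the
    greatest total exon length, then the lexicographically smallest
    transcript id. Genes without exon features are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_transcript: dict[tuple[str, str], dict] = {}
    for exon in db.features_of_type("exon"):
        gene = exon.attributes.get("gene_name", exon.attributes.get("gene_id", ["?"]))[0]
        tx = exon.attributes.get("transcript_id", ["?"])[0]
        rec = per_transcript.setdefault(
            (gene, tx),
            {"chrom": exon.seqid, "strand": exon.strand, "exons": []},
        )
        # gffutils keeps GTF 1-based inclusive coords; convert to 0-based half-open
        rec["exons"].append((exon.start - 1, exon.end))

    by_gene: dict[str, list[tuple[str, dict]]] = {}
    for (gene, tx), rec in per_transcript.items():
        by_gene.setdefault(gene, []).append((tx, rec))

    catalog: dict[str, TranscriptModel] = {}
    for gene, candidates in by_gene.items():
        def rank(item: tuple[str, dict]) -> tuple[int, int, str]:
            tx, rec = item
            n = len(rec["exons"])
            total = sum(e - s for s, e in rec["exons"])
            return (-n, -total, tx)

        tx, rec = min(candidates, key=rank)
        exons = sorted(rec["exons"], reverse=(rec["strand"] == "-"))
        catalog[gene] = TranscriptModel(
            gene=gene,
            transcript_id=tx,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(exons),
        )
    return catalog


def annotate_exons(
    junction: BacksplicedJunction, model: TranscriptModel, slack: int = 0
) -> BacksplicedJunction:
    """Resolve a junction's genomic edges to 1-based transcript exon indices.

    The acceptor exon is the transcript-order exon whose 5' boundary matches
    the circle's upstream (5'-most in transcript orientation) edge; the donor
    exon's 3' boundary matches the downstream edge. On '-', the transcript
    runs right-to-left on the genome, so the acceptor matches ``end`` and the
    donor matches ``start``. Junctions matching no exon boundary (within
    ``slack`` nt) are flagged unannotated rather than rejected: they still
    count in expression matrices but not in exon-position analyses.
    """
    if model.strand == "+":
        acc_target, don_target = junction.start, junction.end
        acc = _match_boundary(model, acc_target, edge=0, slack=slack)
        don = _match_boundary(model, don_target, edge=1, slack=slack)
    else:
        acc = _match_boundary(model, junction.end, edge=1, slack=slack)
        don = _match_boundary(model, junction.start, edge=0, slack=slack)
    if acc is None or don is None or acc > don:
        return replace(junction, acceptor_exon=None, donor_exon=None, unannotated=True)
    return replace(junction, acceptor_exon=acc, donor_exon=don, unannotated=False)


def _match_boundary(
    model: TranscriptModel, coord: int, edge: int, slack: int
) -> int | None:
    """1-based transcript index of the exon whose genomic boundary (edge 0 =
    start, 1 = end of the (start, end) tuple) is within slack of coord."""
    for i, exon in enumerate(model.exons, start=1):
        if abs(exon[edge] - coord) <= slack:
            return i
    return None


# ---------------------------------------------------------------------------
# metadata, matrices, sequences, gene lists


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata TSV, validated, indexed by sample_id."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing column(s): {', '.join(missing)}")
    bad_hist = set(meta["histology"]) - set(HISTOLOGY_LABELS)
    if bad_hist:
        raise ValidationError(
            f"unknown histology label(s) {sorted(bad_hist)}; "
            f"allowed: {', '.join(HISTOLOGY_LABELS)}"
        )
    for g in GENOTYPE_GENES:
        bad = set(meta[g]) - set(GENOTYPE_LABELS)
        if bad:
            raise ValidationError(
                f"unknown genotype label(s) {sorted(bad)} for {g}; "
                f"allowed: {', '.join(GENOTYPE_LABELS)}"
            )
    if (meta["library_size"] <= 0).any():
        bad = meta.loc[meta["library_size"] <= 0, "sample_id"].tolist()
        raise ValidationError(f"non-positive library size for sample(s): {bad}")
    if (meta["proliferation_fold_72h"] <= 0).any():
        raise ValidationError("proliferation_fold_72h must be positive")
    rep_counts = meta.groupby("cell_line").size()
    odd = rep_counts[(rep_counts < 2) | (rep_counts > 3)]
    if len(odd):
        warnings.warn(
            f"cell line(s) without 2-3 replicates: {dict(odd)}", stacklevel=2
        )
    return meta.set_index("sample_id", drop=False)


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_linear_matrix(path: str | Path) -> CountMatrix:
    """Read the linear (total) expression matrix: genes x samples, FPKM."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(values=df, level="gene", normalization="fpkm")


def read_matrix(path: str | Path, level: str, normalization: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(values=df, level=level, normalization=normalization)


def write_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write a matrix TSV; values round-trip at full precision."""
    matrix.values.to_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a gene list (one symbol per line, CGC style)."""
    genes = {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }
    if not genes:
        warnings.warn(f"gene list {path} is empty; gene-set analyses will be skipped",
                      stacklevel=2)
    return genes


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences (uppercased) keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
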