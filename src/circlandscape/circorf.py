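"""Open reading frames on circular RNA templates.

A circRNA is a covalently closed circle; a ribosome that reads through the
backsplice junction continues on the same molecule. When the circle length L
is not a multiple of 3, every pass over the junction shifts the codon phase,
so a single ORF can visit up to three reading frames before hitting a stop
("rolling-circle" translation). This module finds all such ORFs, reports how
often each crosses the junction and how many distinct frames it visits, and
translates them with an average-mass estimate of the product.

Coordinate convention: position 0 of a :class:`CircularSequence` is the first
base downstream of the backsplice junction (the first base of the acceptor
exon), so "crossing the junction" means passing position 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_NT = frozenset("ACGT")


@dataclass(frozen=True)
class CircularSequence:
    """A circRNA exonic sequence with origin at the backsplice junction."""

    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_NT
        if bad:
            raise ValueError(
                f"invalid nucleotide(s) {sorted(bad)} in circular sequence"
                + (f" {self.name!r}" if self.name else "")
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CircOrf:
    """One ORF on a circle, possibly wrapping the junction several times.

    ``length_nt`` runs from the A of the start codon through the stop codon
    inclusive; ``peptide`` excludes the stop. ``unbounded`` marks an ORF that
    never reached a stop within the wrap limit (only possible when L is a
    multiple of 3, where the frame never shifts).
    """

    start: int
    length_nt: int
    crossings: int
    frames_visited: int
    peptide: str
    mass_kda: float
    unbounded: bool = False
    name: str = field(default="", compare=False)


def junction_crossings(start: int, length_nt: int, L: int) -> int:
    """Number of times an ORF passes the backsplice junction.

    An ORF whose stop codon ends exactly on the junction counts that terminal
    pass: the ribosome reads its last codon up to the junction.
    """
    if not 0 <= start < L:
        raise ValueError(f"start must be in [0, L); got start={start}, L={L}")
    if length_nt < 3:
        raise ValueError(f"length_nt must be >= 3; got {length_nt}")
    return (start + length_nt) // L - start // L


def frames_visited(start: int, length_nt: int, L: int) -> int:
    """Count distinct codon phases over the wraps an ORF actually occupies.

    Wrap k covers circle copy k of the concatenated reading; its phase is
    (start + k*L) mod 3. Wraps whose segment within the ORF is empty (an ORF
    ending exactly on the junction) contribute no frame. If L % 3 == 0 the
    phase never shifts and the result is 1.
    """
    if not 0 <= start < L:
        raise ValueError(f"start must be in [0, L); got start={start}, L={L}")
    if length_nt < 3:
        raise ValueError(f"length_nt must be >= 3; got {length_nt}")
    end = start + length_nt
    phases = {
        (start + k * L) % 3
        for k in range(end // L + 1)
        if max(start, k * L) < min(end, (k + 1) * L)
    }
    return len(phases)


def translate_and_mass(orf_nt: str) -> tuple[str, float]:
    """Translate an ORF (standard code) and estimate the product's mass.

    The input must end in the single stop codon; the peptide excludes it.
    Mass is the average (not monoisotopic) molecular weight in kDa.
    """
    if len(orf_nt) % 3 != 0:
        raise ValueError("ORF length must be divisible by 3")
    orf_nt = orf_nt.upper()
    if len(orf_nt) < 6:
        raise ValueError("ORF must encode at least one residue plus a stop")
    if orf_nt[-3:] not in STOP_CODONS:
        raise ValueError("ORF must end in a stop codon")
    peptide = str(Seq(orf_nt[:-3]).translate())
    if "*" in peptide:
        raise ValueError("internal stop codon in ORF")
    mass = molecular_weight(peptide, seq_type="protein", monoisotopic=False)
    return peptide, mass / 1000.0


def _peptide_mass_kda(peptide: str) -> float:
    return molecular_weight(peptide, seq_type="protein", monoisotopic=False) / 1000.0


def rolling_circle_orfs(circ: CircularSequence, max_wraps: int = 3) -> list[CircOrf]:
    """Find every ORF on a circle, reading through the junction.

    For each ATG on the circle, codons are read over consecutive copies of the
    sequence until the first in-frame stop, or until the ORF length would
    exceed ``max_wraps * L`` (then the ORF is flagged ``unbounded`` and
    truncated at the limit). Three wraps suffice to decide: when L % 3 != 0
    all three phases are visited within three passes, and when L % 3 == 0 a
    stop-free first pass repeats forever.

    Returns ORFs sorted by length (longest first), ties by smaller start.
    """
    L = circ.length
    if L < 3:
        raise ValueError(f"circular sequence must be at least 3 nt, got {L}")
    if max_wraps < 1:
        raise ValueError("max_wraps must be >= 1")
    template = circ.sequence * (max_wraps + 1)
    limit = max_wraps * L
    orfs: list[CircOrf] = []
    for s in range(L):
        if template[s : s + 3] != START_CODON:
            continue
        codons: list[str] = []
        stop_found = False
        pos = s
        while pos + 3 - s <= limit:
            codon = template[pos : pos + 3]
            if codon in STOP_CODONS:
                stop_found = True
                codons.append(codon)
                break
            codons.append(codon)
            pos += 3
        if stop_found:
            length_nt = len(codons) * 3
            peptide = str(Seq("".join(codons[:-1])).translate())
            unbounded = False
        else:
            codons = codons[: limit // 3]
            length_nt = len(codons) * 3
            peptide = str(Seq("".join(codons)).translate())
            unbounded = True
        orfs.append(
            CircOrf(
                start=s,
                length_nt=length_nt,
                crossings=junction_crossings(s, length_nt, L),
                frames_visited=frames_visited(s, length_nt, L),
                peptide=peptide,
                mass_kda=_peptide_mass_kda(peptide) if peptide else 0.0,
                unbounded=unbounded,
                name=circ.name,
            )
        )
    orfs.sort(key=lambda o: (-o.length_nt, o.start))
    return orfs


def longest_orf(circ: CircularSequence, max_wraps: int = 3) -> CircOrf | None:
    """The single longest ORF of a circle, or None if it has no ATG."""
    found = rolling_circle_orfs(circ, max_wraps=max_wraps)
    return found[0] if found else None
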