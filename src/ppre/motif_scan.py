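"""Degenerate-consensus motif scanning over genomic FASTA sequences.

The scanner locates every occurrence of an IUPAC consensus (default
``AGGTCANAGGTCA``, the DR1-type PPAR response element: two AGGTCA
half-sites separated by one spacer base) on both strands of each
sequence, reporting forward-strand coordinates in the BED convention
(0-based, half-open).

Matching semantics are set-based.  Every IUPAC letter denotes a set of
concrete bases (``N`` = {A,C,G,T}, ``R`` = {A,G}, ...).  Under the
default *strict* mode a genome base matches a pattern position iff the
genome base's set is a subset of the pattern position's set — so an
assembly-gap ``N`` in the genome matches only a pattern ``N``, never a
literal half-site base, and cannot manufacture spurious exact matches.
The *intersection* mode relaxes this to non-empty set overlap.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "DEFAULT_MOTIF",
    "IUPACPattern",
    "SequenceRecord",
    "GenomicSite",
    "ScanSummary",
    "reverse_complement",
    "match_at",
    "scan_sequence",
    "scan_genome",
    "read_fasta",
]

DEFAULT_MOTIF = "AGGTCANAGGTCA"

#: IUPAC nucleotide codes mapped to the set of concrete bases they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Complement map over the full IUPAC alphabet (R<->Y, S<->S, W<->W, K<->M,
#: B<->V, D<->H, N<->N), both cases.
IUPAC_COMPLEMENT: dict[str, str] = {}
for _a, _b in [
    ("A", "T"), ("C", "G"), ("R", "Y"), ("S", "S"), ("W", "W"),
    ("K", "M"), ("B", "V"), ("D", "H"), ("N", "N"),
]:
    IUPAC_COMPLEMENT[_a] = _b
    IUPAC_COMPLEMENT[_b] = _a
for _u in list(IUPAC_COMPLEMENT):
    IUPAC_COMPLEMENT[_u.lower()] = IUPAC_COMPLEMENT[_u].lower()


def reverse_complement(seq: str, iupac_aware: bool = True, uppercase: bool = False) -> str:
    """Return the reverse complement of ``seq``, preserving case.

    With ``iupac_aware`` (default) every IUPAC ambiguity code is mapped
    to its complement; otherwise only A/C/G/T/N are accepted.  Invalid
    characters are rejected with their position.
    """
    allowed = IUPAC_COMPLEMENT if iupac_aware else {
        c: IUPAC_COMPLEMENT[c] for c in "ACGTNacgtn"
    }
    out = []
    for i, ch in enumerate(seq):
        try:
            out.append(allowed[ch])
        except KeyError:
            raise ValueError(
                f"invalid nucleotide character {ch!r} at position {i}"
            ) from None
    return "".join(reversed(out)).upper() if uppercase else "".join(reversed(out))


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate nucleotide consensus over the IUPAC alphabet."""

    text: str

    def __post_init__(self) -> None:
        up = self.text.upper()
        for i, ch in enumerate(up):
            if ch not in IUPAC_SETS:
                raise ValueError(
                    f"invalid IUPAC character {self.text[i]!r} at position {i}"
                )
        if not up:
            raise ValueError("pattern must be non-empty")
        object.__setattr__(self, "text", up)

    @property
    def length(self) -> int:
        return len(self.text)

    def reverse_complement(self) -> "IUPACPattern":
        return IUPACPattern(reverse_complement(self.text))

    def is_palindromic(self) -> bool:
        """True iff the consensus equals its own reverse complement."""
        return self.text == reverse_complement(self.text)


@dataclass
class SequenceRecord:
    """One named nucleotide sequence (a chromosome or contig)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single motif occurrence in forward-strand coordinates.

    ``matched_seq`` is the forward-strand genome substring of
    ``[start, end)`` exactly as it appears in the input (case retained);
    for a ``-`` site its reverse complement matches the pattern.
    """

    chrom: str
    start: int
    end: int
    strand: str
    matched_seq: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass
class ScanSummary:
    """Per-strand and per-chromosome occurrence tallies."""

    total_sites: int = 0
    positive_count: int = 0
    negative_count: int = 0
    per_chromosome_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def add_chromosome(self, chrom: str, positive: int, negative: int) -> None:
        self.per_chromosome_counts[chrom] = (positive, negative)
        self.positive_count += positive
        self.negative_count += negative
        self.total_sites += positive + negative

    def to_dict(self) -> dict:
        return {
            "total_sites": self.total_sites,
            "positive_count": self.positive_count,
            "negative_count": self.negative_count,
            "per_chromosome_counts": {
                c: {"positive": p, "negative": n}
                for c, (p, n) in self.per_chromosome_counts.items()
            },
        }


def _genome_letters_for(pattern_char: str, mode: str) -> set[str]:
    """Uppercase genome letters that satisfy one pattern position."""
    pset = IUPAC_SETS[pattern_char]
    letters = set()
    for g, gset in IUPAC_SETS.items():
        if mode == "strict":
            ok = gset <= pset
        elif mode == "intersection":
            ok = bool(gset & pset)
        else:
            raise ValueError(f"unknown genome-ambiguity mode {mode!r}")
        if ok:
            letters.add(g)
    return letters


def match_at(
    pattern: IUPACPattern,
    seq: str,
    pos: int,
    *,
    genome_ambiguity: str = "strict",
    respect_softmask: bool = False,
) -> bool:
    """Position-by-position test of the pattern against ``seq`` at ``pos``.

    This is the reference O(m) matcher; :func:`scan_sequence` compiles
    the same semantics to a regular expression for whole-sequence scans.
    """
    if not (0 <= pos <= len(seq) - pattern.length):
        raise ValueError(
            f"position {pos} out of range for sequence of length {len(seq)}"
        )
    for i, pch in enumerate(pattern.text):
        gch = seq[pos + i]
        if respect_softmask and gch.islower():
            return False
        gset = IUPAC_SETS.get(gch.upper())
        if gset is None:
            return False
        pset = IUPAC_SETS[pch]
        if genome_ambiguity == "strict":
            if not gset <= pset:
                return False
        elif genome_ambiguity == "intersection":
            if not gset & pset:
                return False
        else:
            raise ValueError(f"unknown genome-ambiguity mode {genome_ambiguity!r}")
    return True


def _compile(pattern: IUPACPattern, genome_ambiguity: str, respect_softmask: bool,
             overlapping: bool) -> re.Pattern:
    parts = []
    for pch in pattern.text:
        letters = _genome_letters_for(pch, genome_ambiguity)
        if not respect_softmask:
            letters |= {c.lower() for c in letters}
        parts.append("[" + "".join(sorted(letters)) + "]")
    body = "".join(parts)
    return re.compile(f"(?=({body}))" if overlapping else body)


def scan_sequence(
    pattern: IUPACPattern,
    record: SequenceRecord,
    strands: str = "both",
    *,
    genome_ambiguity: str = "strict",
    respect_softmask: bool = False,
    overlapping: bool = True,
) -> list[GenomicSite]:
    """All pattern occurrences in one sequence, both strands by default.

    Minus-strand occurrences are found by matching the reverse-complement
    consensus against the forward text, so all coordinates are
    forward-strand.  Overlapping occurrences are all reported unless
    ``overlapping=False`` (greedy left-to-right suppression).  Output is
    sorted by (start, strand).
    """
    if strands not in ("both", "+", "-"):
        raise ValueError(f"strands must be 'both', '+' or '-', got {strands!r}")
    seq = record.residues
    m = pattern.length
    sites: list[GenomicSite] = []
    jobs = []
    if strands in ("both", "+"):
        jobs.append((pattern, "+"))
    if strands in ("both", "-"):
        jobs.append((pattern.reverse_complement(), "-"))
    for pat, strand in jobs:
        rx = _compile(pat, genome_ambiguity, respect_softmask, overlapping)
        for hit in rx.finditer(seq):
            s = hit.start()
            sites.append(GenomicSite(record.id, s, s + m, strand, seq[s:s + m]))
    sites.sort(key=lambda x: (x.start, x.strand))
    return sites


def scan_genome(
    pattern: IUPACPattern,
    genome: Iterable[SequenceRecord],
    strands: str = "both",
    **kwargs,
) -> tuple[list[GenomicSite], ScanSummary]:
    """Scan every record of a genome; memory stays bounded by one
    chromosome plus the accumulated site list.

    Returns the concatenated per-chromosome site lists (input record
    order) and a :class:`ScanSummary`.  Duplicate sequence ids are
    rejected.
    """
    seen: set[str] = set()
    summary = ScanSummary()
    all_sites: list[GenomicSite] = []
    for record in genome:
        if record.id in seen:
            raise ValueError(f"duplicate chromosome id {record.id!r}")
        seen.add(record.id)
        sites = scan_sequence(pattern, record, strands, **kwargs)
        pos = sum(1 for s in sites if s.strand == "+")
        summary.add_chromosome(record.id, pos, len(sites) - pos)
        all_sites.extend(sites)
    return all_sites, summary


def read_fasta(path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file (plain or gzip), one at a time."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    try:
        fh = opener(path, "rt")
    except OSError as exc:
        raise ValueError(f"cannot read FASTA file {path!r}: {exc}") from exc
    with fh:
        for header, seq in SimpleFastaParser(fh):
            rec_id = header.split()[0] if header.split() else ""
            if not rec_id:
                raise ValueError(f"{path}: empty FASTA record identifier")
            yield SequenceRecord(rec_id, seq)
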