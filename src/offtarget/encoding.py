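"""Nucleotide codecs, the base-4 k-mer hash, and FASTA ingestion.

Sequences are handled as plain uppercase strings over ``{A, C, G, T, N}``.
k-mers that enter the index are mapped to integers with a positional base-4
code (A=0, C=1, G=2, T=3, leftmost base most significant), so a 16-mer
prefix fits in 32 bits and a 4-mer tail in 8. The mapping is a bijection:
every code is decodable back to exactly one k-mer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

NUCLEOTIDES = "ACGT"

_DIGIT = {c: i for i, c in enumerate(NUCLEOTIDES)}
_ENCODE_TRANS = str.maketrans("ACGT", "0123")
_COMPLEMENT_TRANS = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes (other than N) and gap characters are folded to N at
# ingestion; any window containing N is excluded from indexing and matching.
_FOLD_TO_N = "RYSWKMBDHVU-."
_FOLD_TRANS = str.maketrans(_FOLD_TO_N, "N" * len(_FOLD_TO_N))

_VALID_BASES = frozenset("ACGTN")


class EncodingError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


class FastaFormatError(ValueError):
    """The input is not valid FASTA; the message names the offending line."""


@dataclass(frozen=True)
class KmerCode:
    """A k-mer identified by its base-4 positional code.

    ``k`` travels with the value so that 16-mer prefix codes and 4-mer tail
    codes cannot be confused.
    """

    value: int
    k: int

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not 0 <= self.value < 4**self.k:
            raise ValueError(
                f"code {self.value} out of range for k={self.k} "
                f"(must be in [0, {4 ** self.k}))"
            )


def kmer_to_code(seq: str) -> KmerCode:
    """Map a k-mer over {A,C,G,T} to its integer code.

    The code is ``sum(digit(seq[j]) * 4**(k-1-j))`` with A=0, C=1, G=2, T=3,
    i.e. the k-mer read as a base-4 number, leftmost base most significant.
    """
    if not seq:
        raise EncodingError("cannot encode an empty k-mer")
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise EncodingError(
            f"k-mer contains characters outside ACGT: {sorted(bad)!r}"
        )
    return KmerCode(value=int(seq.translate(_ENCODE_TRANS), 4), k=len(seq))


def code_to_kmer(code: KmerCode) -> str:
    """Invert :func:`kmer_to_code`: recover the unique k-mer for a code."""
    value, k = code.value, code.k
    out = []
    for _ in range(k):
        value, d = divmod(value, 4)
        out.append(NUCLEOTIDES[d])
    return "".join(reversed(out))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N. An involution."""
    bad = set(seq) - _VALID_BASES
    if bad:
        raise EncodingError(
            f"sequence contains characters outside ACGTN: {sorted(bad)!r}"
        )
    return seq.translate(_COMPLEMENT_TRANS)[::-1]


@dataclass
class Genome:
    """An in-memory genome: ordered chromosomes plus a name -> ordinal map.

    Chromosome ordinals follow FASTA record order and are the 5-bit
    chromosome ids stored in packed site records.
    """

    chromosomes: list[tuple[str, str]]
    chrom_id: dict[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.chrom_id is None:
            self.chrom_id = {name: i for i, (name, _) in enumerate(self.chromosomes)}

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def sequence(self, name: str) -> str:
        return self.chromosomes[self.chrom_id[name]][1]


def _fold_line(raw: str, lineno: int) -> str:
    """Uppercase a sequence line and fold IUPAC/gap characters to N."""
    seq = raw.upper().translate(_FOLD_TRANS)
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FastaFormatError(
            f"line {lineno}: invalid sequence character(s) {sorted(bad)!r}"
        )
    return seq


def read_fasta(path: Union[str, Path, io.TextIOBase]) -> Genome:
    """Read a (multi-record, optionally line-wrapped) FASTA file.

    Lowercase (soft-masked) bases are uppercased and indexed like any other;
    IUPAC ambiguity codes and gap characters fold to N. Structural problems
    (no records, duplicate names, sequence data before the first header,
    characters outside the DNA alphabet) raise :class:`FastaFormatError`
    naming the offending line.
    """
    if isinstance(path, (str, Path)):
        handle = open(path, "rt", encoding="ascii")
        close = True
    else:
        handle, close = path, False

    chromosomes: list[tuple[str, str]] = []
    seen: set[str] = set()
    name: str | None = None
    parts: list[str] = []

    def flush() -> None:
        if name is not None:
            chromosomes.append((name, "".join(parts)))

    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FastaFormatError(f"line {lineno}: empty record name")
                if name in seen:
                    raise FastaFormatError(
                        f"line {lineno}: duplicate record name {name!r}"
                    )
                seen.add(name)
                parts = []
            else:
                if name is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before any '>' header "
                        "(not FASTA?)"
                    )
                parts.append(_fold_line(line, lineno))
        flush()
    finally:
        if close:
            handle.close()

    if not chromosomes:
        raise FastaFormatError("line 1: no FASTA records found (empty file?)")
    return Genome(chromosomes=chromosomes)


def write_fasta(genome: Genome, path: Union[str, Path], width: int = 70) -> None:
    """Write a genome as wrapped FASTA (inverse of :func:`read_fasta`)."""
    with open(path, "wt", encoding="ascii") as fh:
        for name, seq in genome.chromosomes:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
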