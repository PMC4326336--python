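"""The off-line stage: prefix-hash index over all PAM-adjacent genomic 20-mers.

Every 20-mer on either strand of the genome that is immediately followed
(3' on its own strand) by one of the indexed PAM patterns contributes one
site record per matching pattern. Records are grouped by the base-4 code of
their 16-nt prefix:

* **Table A** maps a 16-mer prefix code to the ``[start, end)`` range of its
  group in Table B. The canonical dense realization is one offset per
  possible 16-mer (4^16 cells, tens of GB — server-scale); the default here
  is a sparse map over occupied prefixes with identical semantics.
* **Table B** is a flat array of bit-packed 64-bit site records holding the
  4-nt tail, PAM id, captured unspecified PAM bases, chromosome ordinal,
  strand, and 0-based position. The 16-nt prefix is *not* stored: it is
  recovered by inverting the hash of the group's key.

Construction scans the genome twice: the first pass counts sites per prefix
and lays out the group offsets, the second fills the records.
"""

from __future__ import annotations

import struct
from collections import Counter
from dataclasses import dataclass
from typing import BinaryIO, Iterable, Iterator, NamedTuple

import numpy as np

from .encoding import Genome, KmerCode, code_to_kmer
from .pam import PamCapture, PamPattern, parse_pam

GUIDE_LEN = 20
PREFIX_LEN = 16
TAIL_LEN = 4

MAX_CHROMS = 32  # 5-bit chromosome id
MAX_POSITION = 1 << 28  # 28-bit position

# Bit layout of a packed site record (low to high):
#   bits 0-27  position           bits 34-36 pam_id
#   bit  28    strand             bits 37-44 pam bases (2 bits each,
#   bits 29-33 chromosome                     pattern order, low bits first)
#                                 bits 45-52 tail 4-mer code
_POS_MASK = MAX_POSITION - 1
_STRAND_SHIFT = 28
_CHROM_SHIFT = 29
_PAMID_SHIFT = 34
_PAMBASE_SHIFT = 37
_TAIL_SHIFT = 45

_BASE_DIGIT = {"A": 0, "C": 1, "G": 2, "T": 3}
_ENC_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _d in _BASE_DIGIT.items():
    _ENC_TABLE[ord(_b)] = _d
_COMP_DIGIT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

MAGIC = b"OFFSPOT1"
FORMAT_VERSION = 1


class CapacityError(ValueError):
    """Genome exceeds a bit-field capacity of the record layout."""


class PackingError(ValueError):
    """A site record field exceeds its declared bit width."""


class IndexFormatError(ValueError):
    """An index file is corrupt, truncated, or of the wrong version."""


@dataclass(frozen=True)
class SiteRecord:
    """One unpacked Table B entry."""

    tail_code: KmerCode  # k=4, bases 17..20 of the protospacer
    pam_id: int
    pam_bases: str  # concrete bases at the pattern's unspecified positions
    chrom: int  # chromosome ordinal, 0-based FASTA order
    strand: int  # 0 forward, 1 reverse
    position: int  # 0-based forward-strand leftmost base of the 20-mer


class SiteTuple(NamedTuple):
    """One (20-mer window, matching PAM) occurrence emitted by the scan."""

    prefix_code: int
    tail_code: int
    capture: PamCapture
    chrom: int
    strand: int
    position: int


def pack_record(r: SiteRecord) -> int:
    """Pack a site record into one 64-bit word (bijective with unpack)."""
    checks = (
        ("position", r.position, MAX_POSITION),
        ("strand", r.strand, 2),
        ("chrom", r.chrom, MAX_CHROMS),
        ("pam_id", r.pam_id, 8),
    )
    for name, value, bound in checks:
        if not 0 <= value < bound:
            raise PackingError(f"field {name}={value} exceeds range [0, {bound})")
    if r.tail_code.k != TAIL_LEN:
        raise PackingError(f"tail_code must have k={TAIL_LEN}, got k={r.tail_code.k}")
    if len(r.pam_bases) > 4:
        raise PackingError(
            f"field pam_bases holds at most 4 captured bases, got {len(r.pam_bases)}"
        )
    word = (
        r.position
        | (r.strand << _STRAND_SHIFT)
        | (r.chrom << _CHROM_SHIFT)
        | (r.pam_id << _PAMID_SHIFT)
        | (r.tail_code.value << _TAIL_SHIFT)
    )
    for j, base in enumerate(r.pam_bases):
        try:
            word |= _BASE_DIGIT[base] << (_PAMBASE_SHIFT + 2 * j)
        except KeyError:
            raise PackingError(f"field pam_bases contains non-ACGT base {base!r}")
    return word


def unpack_record(word: int, pam_table: list[PamPattern]) -> SiteRecord:
    """Invert :func:`pack_record`; the PAM table supplies capture widths."""
    pam_id = (word >> _PAMID_SHIFT) & 7
    pattern = next((p for p in pam_table if p.pam_id == pam_id), None)
    if pattern is None:
        raise IndexFormatError(f"record references unknown pam_id {pam_id}")
    n_unspec = len(pattern.unspecified_positions)
    bases = "".join(
        "ACGT"[(word >> (_PAMBASE_SHIFT + 2 * j)) & 3] for j in range(n_unspec)
    )
    return SiteRecord(
        tail_code=KmerCode(value=(word >> _TAIL_SHIFT) & 0xFF, k=TAIL_LEN),
        pam_id=pam_id,
        pam_bases=bases,
        chrom=(word >> _CHROM_SHIFT) & 31,
        strand=(word >> _STRAND_SHIFT) & 1,
        position=word & _POS_MASK,
    )


def _encode_digits(seq: str) -> np.ndarray:
    """Sequence -> uint8 digit array (A=0 C=1 G=2 T=3, N and friends = 4)."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_strand(
    digits: np.ndarray, pattern: PamPattern
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All PAM-adjacent 20-mer windows on one already-oriented sequence.

    Returns (window starts, prefix codes, tail codes, captured base digits)
    with starts expressed on the scanned sequence. Windows whose 20-mer or
    PAM region contains N are dropped.
    """
    n = len(digits)
    w = GUIDE_LEN + pattern.length
    empty = (
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.uint32),
        np.empty(0, dtype=np.uint8),
        np.empty((0, len(pattern.unspecified_positions)), dtype=np.uint8),
    )
    if n < w:
        return empty
    m = n - w + 1

    # windows free of N across protospacer + PAM
    is_n = (digits >= 4).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    ok = (cum[w:] - cum[:-w]) == 0

    # fixed / purine PAM positions
    for p, symbol in enumerate(pattern.text):
        col = digits[GUIDE_LEN + p : GUIDE_LEN + p + m]
        if symbol in _BASE_DIGIT:
            ok = ok & (col == _BASE_DIGIT[symbol])
        elif symbol == "R":
            ok = ok & ((col == 0) | (col == 2))
        # N: any base; N-freedom already enforced
    starts = np.nonzero(ok)[0].astype(np.int64)
    if starts.size == 0:
        return empty

    prefix = np.zeros(starts.size, dtype=np.uint32)
    for j in range(PREFIX_LEN):
        prefix |= digits[starts + j].astype(np.uint32) << np.uint32(
            2 * (PREFIX_LEN - 1 - j)
        )
    tail = np.zeros(starts.size, dtype=np.uint8)
    for j in range(TAIL_LEN):
        tail |= digits[starts + PREFIX_LEN + j] << np.uint8(2 * (TAIL_LEN - 1 - j))
    if pattern.unspecified_positions:
        captures = np.stack(
            [digits[starts + GUIDE_LEN + u] for u in pattern.unspecified_positions],
            axis=1,
        )
    else:
        captures = np.empty((starts.size, 0), dtype=np.uint8)
    return starts, prefix, tail, captures


def _check_capacity(genome: Genome) -> None:
    if len(genome.chromosomes) > MAX_CHROMS:
        raise CapacityError(
            f"{len(genome.chromosomes)} chromosomes exceed the 5-bit limit of "
            f"{MAX_CHROMS} sequences per index"
        )
    for name, seq in genome.chromosomes:
        if len(seq) > MAX_POSITION:
            raise CapacityError(
                f"chromosome {name!r} has {len(seq)} bases, beyond the 28-bit "
                f"position limit of {MAX_POSITION}"
            )


def scan_pam_sites(
    genome: Genome, pams: Iterable[PamPattern]
) -> Iterator[SiteTuple]:
    """Enumerate every (20-mer window, matching PAM pattern) pair, both strands.

    Reverse-strand protospacers are read as the reverse complement of their
    forward window, with the PAM 3' of the protospacer on the reverse strand
    (i.e. at lower forward coordinates). The reported position is always the
    forward-strand leftmost coordinate of the 20-mer. A window matching two
    patterns yields two tuples.
    """
    pams = list(pams)
    _check_capacity(genome)
    for chrom_ord, (_, seq) in enumerate(genome.chromosomes):
        fwd = _encode_digits(seq)
        rev = _COMP_DIGIT[fwd][::-1]
        n = len(seq)
        for strand, digits in ((0, fwd), (1, rev)):
            for pattern in pams:
                starts, prefixes, tails, captures = _scan_strand(digits, pattern)
                for i in range(starts.size):
                    s = int(starts[i])
                    position = s if strand == 0 else n - s - GUIDE_LEN
                    yield SiteTuple(
                        prefix_code=int(prefixes[i]),
                        tail_code=int(tails[i]),
                        capture=PamCapture(
                            pam_id=pattern.pam_id,
                            bases="".join("ACGT"[d] for d in captures[i]),
                        ),
                        chrom=chrom_ord,
                        strand=strand,
                        position=position,
                    )


class TableA:
    """Prefix code -> ``[start, end)`` range in Table B.

    The sparse form keeps only occupied prefixes (sorted codes + start
    offsets); the dense form expands them into one offset per possible
    16-mer, the layout the original server-scale implementation uses. Both
    answer :meth:`range` identically.
    """

    def __init__(
        self,
        prefixes: np.ndarray,
        starts: np.ndarray,
        total: int,
        dense: bool = False,
    ):
        self.prefixes = np.asarray(prefixes, dtype=np.uint32)
        self.starts = np.asarray(starts, dtype=np.uint64)
        self.total = int(total)
        self.dense = bool(dense)
        ends = np.concatenate((self.starts[1:], [np.uint64(self.total)]))
        self._map = {
            int(p): (int(s), int(e))
            for p, s, e in zip(self.prefixes, self.starts, ends)
        }
        self._offsets: np.ndarray | None = None
        if dense:
            # One offset per possible 16-mer (4^16 + 1 cells): needs tens of
            # GB, mirroring the original all-in-RAM deployment.
            offsets = np.zeros(4**PREFIX_LEN + 1, dtype=np.uint64)
            sizes = ends - self.starts
            offsets[self.prefixes.astype(np.int64) + 1] = sizes
            np.cumsum(offsets, out=offsets)
            self._offsets = offsets

    def range(self, prefix_code: int) -> tuple[int, int]:
        """The Table B slice for a prefix; empty ``(s, s)`` when unoccupied."""
        if self._offsets is not None:
            return (
                int(self._offsets[prefix_code]),
                int(self._offsets[prefix_code + 1]),
            )
        hit = self._map.get(prefix_code)
        if hit is None:
            return (0, 0)
        return hit

    def __len__(self) -> int:
        return len(self.prefixes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TableA):
            return NotImplemented
        return (
            self.dense == other.dense
            and self.total == other.total
            and np.array_equal(self.prefixes, other.prefixes)
            and np.array_equal(self.starts, other.starts)
        )


@dataclass
class OffTargetIndex:
    """Table A + Table B plus the PAM table and genome metadata."""

    table_a: TableA
    table_b: np.ndarray  # uint64 packed site records, grouped by prefix
    pam_table: list[PamPattern]
    genome_meta: list[tuple[str, int]]  # (chromosome name, length), FASTA order

    def __post_init__(self) -> None:
        self._digit_cache: np.ndarray | None = None

    def group_range(self, prefix_code: int) -> tuple[int, int]:
        return self.table_a.range(prefix_code)

    def pam_by_text(self, text: str) -> PamPattern:
        text = text.upper()
        for p in self.pam_table:
            if p.text == text:
                return p
        available = ", ".join(p.text for p in self.pam_table)
        raise KeyError(
            f"PAM {text!r} is not in this index; available patterns: {available}"
        )

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.genome_meta]

    @property
    def occupied_prefixes(self) -> np.ndarray:
        return self.table_a.prefixes

    def prefix_digit_matrix(self) -> np.ndarray:
        """(n_groups, 16) base digits of the occupied prefixes (cached)."""
        if self._digit_cache is None:
            shifts = np.array(
                [2 * (PREFIX_LEN - 1 - j) for j in range(PREFIX_LEN)],
                dtype=np.uint32,
            )
            self._digit_cache = (
                (self.occupied_prefixes[:, None] >> shifts[None, :]) & 3
            ).astype(np.uint8)
        return self._digit_cache

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OffTargetIndex):
            return NotImplemented
        return (
            self.table_a == other.table_a
            and np.array_equal(self.table_b, other.table_b)
            and self.pam_table == other.pam_table
            and self.genome_meta == other.genome_meta
        )


def _sort_key(chrom: int, position: int, strand: int, pam_id: int) -> int:
    # within-group order: (chrom, position, strand, pam_id) ascending
    return (((chrom << 28 | position) << 1 | strand) << 3) | pam_id


def build_index(
    genome: Genome, pams: list[PamPattern], dense: bool = False
) -> OffTargetIndex:
    """Two-pass construction of the index.

    Pass 1 counts sites per 16-mer prefix to allocate Table B and lay out the
    group offsets; pass 2 packs the records. Within a group records are
    sorted by (chrom, position, strand, pam_id), so rebuilding the same
    genome is bit-identical.
    """
    if not pams:
        raise ValueError("at least one PAM pattern is required")
    ids = [p.pam_id for p in pams]
    if len(set(ids)) != len(ids):
        raise ValueError("PAM table contains duplicate pam_ids")
    _check_capacity(genome)

    # pass 1: per-prefix counts -> offsets
    counts: Counter[int] = Counter()
    for site in scan_pam_sites(genome, pams):
        counts[site.prefix_code] += 1
    prefixes = np.array(sorted(counts), dtype=np.uint32)
    sizes = np.array([counts[int(p)] for p in prefixes], dtype=np.uint64)
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1])).astype(np.uint64)
    total = int(sizes.sum())

    # pass 2: pack records, then order by (prefix group, within-group key)
    words = np.empty(total, dtype=np.uint64)
    group = np.empty(total, dtype=np.uint32)
    key = np.empty(total, dtype=np.uint64)
    for i, site in enumerate(scan_pam_sites(genome, pams)):
        word = (
            site.position
            | (site.strand << _STRAND_SHIFT)
            | (site.chrom << _CHROM_SHIFT)
            | (site.capture.pam_id << _PAMID_SHIFT)
            | (site.tail_code << _TAIL_SHIFT)
        )
        for j, base in enumerate(site.capture.bases):
            word |= _BASE_DIGIT[base] << (_PAMBASE_SHIFT + 2 * j)
        words[i] = word
        group[i] = site.prefix_code
        key[i] = _sort_key(site.chrom, site.position, site.strand,
                           site.capture.pam_id)
    order = np.lexsort((key, group))
    table_b = words[order]

    table_a = TableA(prefixes, starts, total, dense=dense)
    meta = [(name, len(seq)) for name, seq in genome.chromosomes]
    return OffTargetIndex(
        table_a=table_a, table_b=table_b, pam_table=list(pams), genome_meta=meta
    )


def sites_per_chromosome(index: OffTargetIndex) -> dict[str, int]:
    """Record counts keyed by chromosome name (for build logging/reports)."""
    if index.table_b.size == 0:
        return {name: 0 for name, _ in index.genome_meta}
    chroms = ((index.table_b >> np.uint64(_CHROM_SHIFT)) & np.uint64(31)).astype(int)
    counts = np.bincount(chroms, minlength=len(index.genome_meta))
    return {name: int(counts[i]) for i, (name, _) in enumerate(index.genome_meta)}


# ---------------------------------------------------------------------------
# binary serialization


def _write(fh: BinaryIO, fmt: str, *values) -> None:
    fh.write(struct.pack(fmt, *values))


def _read_exact(fh: BinaryIO, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise IndexFormatError(
            f"truncated index file: wanted {n} bytes, got {len(data)}"
        )
    return data


def _read(fh: BinaryIO, fmt: str):
    return struct.unpack(fmt, _read_exact(fh, struct.calcsize(fmt)))


def save_index(index: OffTargetIndex, path) -> None:
    """Write the index: magic, version, PAM table, genome metadata, tables."""
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        _write(fh, "<I", FORMAT_VERSION)
        _write(fh, "<B", len(index.pam_table))
        for p in index.pam_table:
            text = p.text.encode("ascii")
            _write(fh, "<BH", p.pam_id, len(text))
            fh.write(text)
        _write(fh, "<I", len(index.genome_meta))
        for name, length in index.genome_meta:
            raw = name.encode("utf-8")
            _write(fh, "<H", len(raw))
            fh.write(raw)
            _write(fh, "<Q", length)
        _write(fh, "<B", 1 if index.table_a.dense else 0)
        _write(fh, "<Q", len(index.table_a))
        fh.write(index.table_a.prefixes.astype("<u4").tobytes())
        fh.write(index.table_a.starts.astype("<u8").tobytes())
        _write(fh, "<Q", index.table_b.size)
        fh.write(index.table_b.astype("<u8").tobytes())


def load_index(path) -> OffTargetIndex:
    """Read an index written by :func:`save_index`."""
    with open(path, "rb") as fh:
        magic = _read_exact(fh, len(MAGIC))
        if magic != MAGIC:
            raise IndexFormatError(
                f"not an off-target index file (bad magic {magic!r})"
            )
        (version,) = _read(fh, "<I")
        if version != FORMAT_VERSION:
            raise IndexFormatError(
                f"index format version {version} unsupported "
                f"(this build reads version {FORMAT_VERSION})"
            )
        (n_pams,) = _read(fh, "<B")
        pam_table = []
        for _ in range(n_pams):
            pam_id, text_len = _read(fh, "<BH")
            text = _read_exact(fh, text_len).decode("ascii")
            pam_table.append(parse_pam(text, pam_id=pam_id))
        (n_chroms,) = _read(fh, "<I")
        meta = []
        for _ in range(n_chroms):
            (name_len,) = _read(fh, "<H")
            name = _read_exact(fh, name_len).decode("utf-8")
            (length,) = _read(fh, "<Q")
            meta.append((name, length))
        (dense_tag,) = _read(fh, "<B")
        (n_groups,) = _read(fh, "<Q")
        prefixes = np.frombuffer(
            _read_exact(fh, 4 * n_groups), dtype="<u4"
        ).astype(np.uint32)
        starts = np.frombuffer(
            _read_exact(fh, 8 * n_groups), dtype="<u8"
        ).astype(np.uint64)
        (n_records,) = _read(fh, "<Q")
        table_b = np.frombuffer(
            _read_exact(fh, 8 * n_records), dtype="<u8"
        ).astype(np.uint64)
    table_a = TableA(prefixes, starts, int(n_records), dense=bool(dense_tag))
    return OffTargetIndex(
        table_a=table_a, table_b=table_b, pam_table=pam_table, genome_meta=meta
    )


def reconstruct_sequence(prefix_code: int, word: int) -> str:
    """Reconstitute the full 20-mer of a record from its group's prefix."""
    prefix = code_to_kmer(KmerCode(value=prefix_code, k=PREFIX_LEN))
    tail = code_to_kmer(KmerCode(value=(word >> _TAIL_SHIFT) & 0xFF, k=TAIL_LEN))
    return prefix + tail
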