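"""The on-line stage: mismatch-constrained off-target lookup in the index.

Given a 20-nt guide, a PAM pattern, a mismatch budget M (at most 5) and an
optional seed mask (guide positions that must match exactly), the engine
reports every genomic site whose 20-mer differs from the guide at <= M
positions, agrees with it at all seed positions, and is immediately
followed by the PAM.

Two exact lookup strategies are available:

* ``enumerate`` — generate every 16-mer within the mismatch budget of the
  guide's prefix (substituting only at non-seed positions) and follow each
  one's Table A pointer; tail mismatches are then checked against the
  stored 4-mer tail codes. This is the classical Hamming-ball walk.
* ``scan`` — Hamming-test the occupied prefixes of the index directly.
  Cheaper whenever the genome occupies fewer prefixes than the ball holds
  (always the case for small genomes); identical output by construction.

``auto`` picks whichever touches fewer prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations, product
from math import comb
from typing import Iterator, Sequence

import numpy as np

from .encoding import KmerCode, code_to_kmer, kmer_to_code, reverse_complement
from .index import (
    GUIDE_LEN,
    PREFIX_LEN,
    TAIL_LEN,
    _CHROM_SHIFT,
    _PAMBASE_SHIFT,
    _PAMID_SHIFT,
    _POS_MASK,
    _STRAND_SHIFT,
    _TAIL_SHIFT,
    OffTargetIndex,
)
from .pam import PamCapture, PamPattern, dereference_pam, pam_match

MAX_MISMATCHES = 5

MIN_TARGET_SEQ = GUIDE_LEN
MAX_TARGET_SEQ = 500


@dataclass(frozen=True)
class SeedMask:
    """Guide positions (0 = 5'-most base) that must match exactly.

    An empty mask means no seed constraint. The wet-lab literature counts
    seeds from the PAM-proximal (3') end; :meth:`parse` accepts the
    ``"3prime:k"`` shorthand for positions {20-k .. 19} as well as an
    explicit comma-separated position list.
    """

    positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        bad = [p for p in self.positions if not 0 <= p < GUIDE_LEN]
        if bad:
            raise ValueError(
                f"seed positions {sorted(bad)} outside the guide range 0..19"
            )

    @classmethod
    def parse(cls, spec: str) -> "SeedMask":
        spec = spec.strip()
        if not spec:
            return cls()
        if spec.lower().startswith("3prime:"):
            k = int(spec.split(":", 1)[1])
            if not 0 <= k <= GUIDE_LEN:
                raise ValueError(f"3' seed length {k} outside 0..{GUIDE_LEN}")
            return cls(frozenset(range(GUIDE_LEN - k, GUIDE_LEN)))
        return cls(frozenset(int(tok) for tok in spec.split(",") if tok.strip()))


@dataclass(frozen=True)
class OffTargetHit:
    """One reported off-target site."""

    chrom_name: str
    strand: str  # "+" or "-"
    position: int  # 0-based forward-strand leftmost base of the 20-mer
    sequence: str  # reconstituted genomic 20-mer (protospacer strand)
    mismatch_positions: frozenset[int]
    mismatch_count: int
    pam_instance: str  # fully dereferenced PAM at the site
    gc_content: float
    annotation: tuple = field(default=(), compare=False)


class QueryInputError(ValueError):
    """A query parameter violates the engine's input contract."""


def _validate_guide(guide: str) -> str:
    guide = guide.upper()
    if len(guide) != GUIDE_LEN:
        raise QueryInputError(
            f"guide must be exactly {GUIDE_LEN} nt, got {len(guide)}"
        )
    bad = set(guide) - set("ACGT")
    if bad:
        raise QueryInputError(
            f"guide contains characters outside ACGT: {sorted(bad)!r}"
        )
    return guide


def gc_content(seq: str) -> float:
    """Fraction of G/C bases in a sequence (off-targets report it per 20-mer)."""
    if not seq:
        raise QueryInputError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise QueryInputError(f"sequence contains non-ACGT: {sorted(bad)!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def hamming_ball_size(k: int, max_mm: int) -> int:
    """Number of k-mers within Hamming distance ``max_mm`` of a fixed k-mer.

    Closed form ``sum_{i=0..M} C(k, i) * 3^i``; this bounds how many Table A
    pointers a query can ever follow.
    """
    return sum(comb(k, i) * 3**i for i in range(min(max_mm, k) + 1))


def _variant_codes(
    code: int, k: int, free_positions: Sequence[int], max_mm: int
) -> Iterator[tuple[int, tuple[int, ...]]]:
    """All codes within ``max_mm`` substitutions at ``free_positions``.

    Yields (variant code, substituted positions); each variant exactly once,
    the original first with no substitutions.
    """
    yield code, ()
    digits = [(code >> (2 * (k - 1 - p))) & 3 for p in range(k)]
    for m in range(1, max_mm + 1):
        for combo in combinations(free_positions, m):
            shifts = [2 * (k - 1 - p) for p in combo]
            base = code
            for s in shifts:
                base &= ~(3 << s)
            alternatives = [
                [d for d in range(4) if d != digits[p]] for p in combo
            ]
            for repl in product(*alternatives):
                variant = base
                for s, d in zip(shifts, repl):
                    variant |= d << s
                yield variant, combo


def enumerate_prefix_variants(
    prefix: str, max_mm: int, seed: SeedMask = SeedMask()
) -> Iterator[tuple[str, int]]:
    """Every 16-mer within ``max_mm`` mismatches of ``prefix``.

    Substitutions are never placed at seed positions (seed ∩ {0..15}); each
    variant is yielded once with its exact distance, the original prefix
    first with distance 0.
    """
    if len(prefix) != PREFIX_LEN:
        raise QueryInputError(f"prefix must be {PREFIX_LEN} nt, got {len(prefix)}")
    if not 0 <= max_mm <= MAX_MISMATCHES:
        raise QueryInputError(f"max_mm must be 0..{MAX_MISMATCHES}, got {max_mm}")
    code = kmer_to_code(prefix).value
    free = [p for p in range(PREFIX_LEN) if p not in seed.positions]
    for variant, combo in _variant_codes(code, PREFIX_LEN, free, max_mm):
        yield code_to_kmer(KmerCode(value=variant, k=PREFIX_LEN)), len(combo)


def _tail_lookup(
    guide: str, seed: SeedMask
) -> list[tuple[int, tuple[int, ...], bool]]:
    """Per tail code: (mismatch count vs guide, positions, seed-compatible)."""
    guide_tail = [(("ACGT").index(guide[PREFIX_LEN + j])) for j in range(TAIL_LEN)]
    seed_tail = {p - PREFIX_LEN for p in seed.positions if p >= PREFIX_LEN}
    table = []
    for t in range(4**TAIL_LEN):
        digits = [(t >> (2 * (TAIL_LEN - 1 - j))) & 3 for j in range(TAIL_LEN)]
        mm = tuple(
            PREFIX_LEN + j for j in range(TAIL_LEN) if digits[j] != guide_tail[j]
        )
        seed_ok = not any((p - PREFIX_LEN) in seed_tail for p in mm)
        table.append((len(mm), mm, seed_ok))
    return table


def _candidate_prefixes_enumerate(
    index: OffTargetIndex, guide: str, max_mm: int, seed: SeedMask
) -> Iterator[tuple[int, tuple[int, ...]]]:
    code = kmer_to_code(guide[:PREFIX_LEN]).value
    free = [p for p in range(PREFIX_LEN) if p not in seed.positions]
    for variant, combo in _variant_codes(code, PREFIX_LEN, free, max_mm):
        s, e = index.group_range(variant)
        if e > s:
            yield variant, combo


def _candidate_prefixes_scan(
    index: OffTargetIndex, guide: str, max_mm: int, seed: SeedMask
) -> Iterator[tuple[int, tuple[int, ...]]]:
    occupied = index.occupied_prefixes
    if occupied.size == 0:
        return
    digits = index.prefix_digit_matrix()
    gp = np.array(
        [("ACGT").index(guide[p]) for p in range(PREFIX_LEN)], dtype=np.uint8
    )
    diff = digits != gp[None, :]
    keep = diff.sum(axis=1) <= max_mm
    seed_cols = sorted(p for p in seed.positions if p < PREFIX_LEN)
    if seed_cols:
        keep &= ~diff[:, seed_cols].any(axis=1)
    for row in np.nonzero(keep)[0]:
        yield int(occupied[row]), tuple(int(p) for p in np.nonzero(diff[row])[0])


def find_offtargets(
    index: OffTargetIndex,
    guide: str,
    pam: PamPattern | str,
    max_mm: int,
    seed: SeedMask = SeedMask(),
    strategy: str = "auto",
) -> list[OffTargetHit]:
    """All indexed sites within ``max_mm`` of ``guide`` under ``seed`` + PAM.

    The result is complete and duplicate-free (one hit per stored record of
    the requested pattern), sorted by (chromosome ordinal, position, strand).
    """
    guide = _validate_guide(guide)
    if not 0 <= max_mm <= MAX_MISMATCHES:
        raise QueryInputError(f"max_mm must be 0..{MAX_MISMATCHES}, got {max_mm}")
    if isinstance(pam, PamPattern):
        pattern = index.pam_by_text(pam.text)
    else:
        pattern = index.pam_by_text(pam)

    tail_info = _tail_lookup(guide, seed)
    n_free = PREFIX_LEN - sum(1 for p in seed.positions if p < PREFIX_LEN)
    if strategy == "auto":
        ball = hamming_ball_size(n_free, max_mm)
        strategy = "enumerate" if ball <= max(len(index.table_a), 1) else "scan"
    if strategy == "enumerate":
        candidates = _candidate_prefixes_enumerate(index, guide, max_mm, seed)
    elif strategy == "scan":
        candidates = _candidate_prefixes_scan(index, guide, max_mm, seed)
    else:
        raise QueryInputError(f"unknown strategy {strategy!r}")

    names = index.chrom_names
    n_unspec = len(pattern.unspecified_positions)
    decorated: list[tuple[int, int, int, OffTargetHit]] = []
    for prefix_code, prefix_mm in candidates:
        s, e = index.group_range(prefix_code)
        if e <= s:
            continue
        budget = max_mm - len(prefix_mm)
        prefix_str: str | None = None
        for word in index.table_b[s:e]:
            word = int(word)
            if (word >> _PAMID_SHIFT) & 7 != pattern.pam_id:
                continue
            tail_count, tail_mm, seed_ok = tail_info[(word >> _TAIL_SHIFT) & 0xFF]
            if not seed_ok or tail_count > budget:
                continue
            if prefix_str is None:
                prefix_str = code_to_kmer(KmerCode(value=prefix_code, k=PREFIX_LEN))
            tail_str = code_to_kmer(
                KmerCode(value=(word >> _TAIL_SHIFT) & 0xFF, k=TAIL_LEN)
            )
            sequence = prefix_str + tail_str
            bases = "".join(
                "ACGT"[(word >> (_PAMBASE_SHIFT + 2 * j)) & 3]
                for j in range(n_unspec)
            )
            chrom = (word >> _CHROM_SHIFT) & 31
            strand_bit = (word >> _STRAND_SHIFT) & 1
            position = word & _POS_MASK
            hit = OffTargetHit(
                chrom_name=names[chrom],
                strand="-" if strand_bit else "+",
                position=position,
                sequence=sequence,
                mismatch_positions=frozenset(prefix_mm) | frozenset(tail_mm),
                mismatch_count=len(prefix_mm) + tail_count,
                pam_instance=dereference_pam(
                    PamCapture(pam_id=pattern.pam_id, bases=bases), pattern
                ),
                gc_content=gc_content(sequence),
            )
            decorated.append((chrom, position, strand_bit, hit))
    decorated.sort(key=lambda t: t[:3])
    return [hit for *_, hit in decorated]


def mismatch_histogram(hits: Sequence[OffTargetHit], max_mm: int) -> list[int]:
    """counts[i] = number of hits with exactly i mismatches; sums to |hits|."""
    counts = [0] * (max_mm + 1)
    for hit in hits:
        if hit.mismatch_count > max_mm:
            raise ValueError(
                f"hit with {hit.mismatch_count} mismatches exceeds max_mm={max_mm}"
            )
        counts[hit.mismatch_count] += 1
    return counts


def extract_guides(
    target_seq: str, pam: PamPattern
) -> list[tuple[str, str, int]]:
    """All candidate guides in a target sequence (<= 500 nt), both strands.

    Returns (20-mer, strand, offset) triples where offset is the 0-based
    forward-strand coordinate of the 20-mer window within the input; each
    20-mer is immediately followed (3' on its strand) by a PAM match.
    Windows containing N are skipped.
    """
    seq = target_seq.upper()
    lo = GUIDE_LEN + pam.length
    if len(seq) > MAX_TARGET_SEQ:
        raise QueryInputError(
            f"target sequence is {len(seq)} nt; at most {MAX_TARGET_SEQ} allowed"
        )
    if len(seq) < lo:
        raise QueryInputError(
            f"target sequence is {len(seq)} nt; needs at least {lo} "
            f"(20-mer + {pam.length}-nt PAM)"
        )
    bad = set(seq) - set("ACGTN")
    if bad:
        raise QueryInputError(f"target contains non-ACGTN: {sorted(bad)!r}")

    out: list[tuple[str, str, int]] = []
    n = len(seq)

    def scan(oriented: str, strand: str) -> None:
        for i in range(len(oriented) - lo + 1):
            window = oriented[i : i + GUIDE_LEN]
            if "N" in window:
                continue
            if pam_match(oriented[i + GUIDE_LEN : i + lo], pam) is not None:
                offset = i if strand == "+" else n - i - GUIDE_LEN
                out.append((window, strand, offset))

    scan(seq, "+")
    scan(reverse_complement(seq), "-")
    out.sort(key=lambda t: (t[2], t[1]))
    return out


def drop_self_hit(
    hits: Sequence[OffTargetHit], chrom_name: str, position: int, strand: str
) -> list[OffTargetHit]:
    """Post-processing helper: remove the guide's own intended site."""
    return [
        h
        for h in hits
        if not (
            h.chrom_name == chrom_name
            and h.position == position
            and h.strand == strand
            and h.mismatch_count == 0
        )
    ]
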