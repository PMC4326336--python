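"""Brute-force reference for off-target search.

A naive sliding-window scan of both strands with no index, no hashing, no
neighborhood enumeration: a window qualifies iff its PAM matches, its
Hamming distance to the guide is within budget, and it agrees with the
guide at every seed position. The oracle shares only the nucleotide codecs
and PAM matcher with the indexed path, so agreement between the two is
evidence of correctness rather than a tautology.

Deliberately unoptimized — clarity over speed; intended for test genomes
of tens of kilobases, not production use.
"""

from __future__ import annotations

from .encoding import Genome, reverse_complement
from .index import GUIDE_LEN
from .pam import PamPattern, dereference_pam, pam_match
from .query import MAX_MISMATCHES, OffTargetHit, QueryInputError, SeedMask, gc_content


def brute_force_offtargets(
    genome: Genome,
    guide: str,
    pam: PamPattern,
    max_mm: int,
    seed: SeedMask = SeedMask(),
) -> list[OffTargetHit]:
    """All genomic sites matching ``guide`` within ``max_mm``, seed + PAM held.

    Output order matches the indexed engine: (chromosome ordinal, position,
    strand) ascending, position being the forward-strand leftmost base of
    the 20-mer on either strand.
    """
    guide = guide.upper()
    if len(guide) != GUIDE_LEN or set(guide) - set("ACGT"):
        raise QueryInputError(f"guide must be a 20-mer over ACGT, got {guide!r}")
    if not 0 <= max_mm <= MAX_MISMATCHES:
        raise QueryInputError(f"max_mm must be 0..{MAX_MISMATCHES}, got {max_mm}")

    hits: list[tuple[int, int, int, OffTargetHit]] = []
    L = pam.length

    def consider(
        window: str, pam_window: str, chrom: int, name: str, strand: str, pos: int
    ) -> None:
        if "N" in window:
            return
        capture = pam_match(pam_window, pam)
        if capture is None:
            return
        mm = frozenset(j for j in range(GUIDE_LEN) if window[j] != guide[j])
        if len(mm) > max_mm or mm & seed.positions:
            return
        hit = OffTargetHit(
            chrom_name=name,
            strand=strand,
            position=pos,
            sequence=window,
            mismatch_positions=mm,
            mismatch_count=len(mm),
            pam_instance=dereference_pam(capture, pam),
            gc_content=gc_content(window),
        )
        hits.append((chrom, pos, 0 if strand == "+" else 1, hit))

    for chrom, (name, seq) in enumerate(genome.chromosomes):
        n = len(seq)
        # forward strand: protospacer [i, i+20), PAM [i+20, i+20+L)
        for i in range(0, n - GUIDE_LEN - L + 1):
            consider(
                seq[i : i + GUIDE_LEN],
                seq[i + GUIDE_LEN : i + GUIDE_LEN + L],
                chrom, name, "+", i,
            )
        # reverse strand: protospacer read as revcomp of [i, i+20); its PAM
        # lies 3' on the reverse strand, i.e. forward coords [i-L, i)
        for i in range(L, n - GUIDE_LEN + 1):
            consider(
                reverse_complement(seq[i : i + GUIDE_LEN]),
                reverse_complement(seq[i - L : i]),
                chrom, name, "-", i,
            )

    hits.sort(key=lambda t: t[:3])
    return [hit for *_, hit in hits]
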