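"""Synthetic genomes and planted off-target sites with known ground truth.

The generator emulates the only genome feature the search engine depends
on: base composition. Chromosomes are i.i.d. draws with a chosen GC bias,
into which protospacer+PAM windows are overwritten at requested
coordinates with controlled mismatch sets. Random background sequence can
contain additional chance look-alikes, so the returned ground truth is a
*subset* of the true hit set; :func:`make_exact_fixture` searches seeds
until the brute-force oracle confirms the planted set is the whole truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoding import Genome, reverse_complement
from .index import GUIDE_LEN
from .oracle import brute_force_offtargets
from .pam import PamPattern, pam_match
from .query import OffTargetHit, SeedMask, gc_content

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MIN_CHROM_LEN = 30


@dataclass(frozen=True)
class PlantSite:
    """One requested off-target planting location."""

    chrom: int  # chromosome ordinal
    position: int  # forward-strand leftmost base of the 20-mer
    strand: str  # "+" or "-"
    mismatch_positions: tuple[int, ...]  # guide positions to mutate (<= 5)
    pam_instance: str  # concrete PAM to write 3' of the protospacer


@dataclass(frozen=True)
class PlantSpec:
    guide: str
    sites: tuple[PlantSite, ...]


def synth_genome(
    length: int, num_chroms: int = 1, gc_bias: float = 0.5, rng_seed: int = 0
) -> Genome:
    """Random genome: ``num_chroms`` chromosomes of ``length`` nt each.

    Bases are i.i.d. with P(G) = P(C) = gc_bias/2; reproducible for a fixed
    seed.
    """
    if length < MIN_CHROM_LEN:
        raise ValueError(
            f"chromosome length {length} below the minimum of {MIN_CHROM_LEN} nt"
        )
    if num_chroms < 1:
        raise ValueError(f"num_chroms must be >= 1, got {num_chroms}")
    if not 0.0 <= gc_bias <= 1.0:
        raise ValueError(f"gc_bias must be in [0, 1], got {gc_bias}")
    rng = np.random.default_rng(rng_seed)
    at, gc = (1.0 - gc_bias) / 2.0, gc_bias / 2.0
    probs = [at, gc, gc, at]  # A C G T
    chroms = []
    for c in range(num_chroms):
        draw = rng.choice(4, size=length, p=probs)
        chroms.append((f"chr{c + 1}", _BASES[draw].tobytes().decode("ascii")))
    return Genome(chromosomes=chroms)


def _site_extent(site: PlantSite, pam_len: int) -> tuple[int, int]:
    """Forward-strand interval the planting overwrites (protospacer + PAM)."""
    if site.strand == "+":
        return site.position, site.position + GUIDE_LEN + pam_len
    return site.position - pam_len, site.position + GUIDE_LEN


def plant_offtargets(
    genome: Genome, spec: PlantSpec, pam: PamPattern, rng_seed: int = 0
) -> tuple[Genome, list[OffTargetHit]]:
    """Overwrite the genome with controlled off-target sites.

    Each site's protospacer window becomes the guide mutated at exactly the
    requested positions (mutated bases drawn to differ from the guide), and
    the adjacent PAM window becomes the requested concrete PAM instance.
    Returns the modified genome and the planted hits as ground truth —
    a subset of the full hit set, since random background may contain
    additional chance matches.
    """
    guide = spec.guide.upper()
    if len(guide) != GUIDE_LEN or set(guide) - set("ACGT"):
        raise ValueError(f"guide must be a 20-mer over ACGT, got {guide!r}")
    rng = np.random.default_rng(rng_seed)
    extents: dict[int, list[tuple[int, int]]] = {}
    sequences = [bytearray(seq, "ascii") for _, seq in genome.chromosomes]

    truth: list[tuple[int, int, int, OffTargetHit]] = []
    for site in spec.sites:
        if len(site.mismatch_positions) > 5:
            raise ValueError(
                f"at most 5 mismatches per planted site, got "
                f"{len(site.mismatch_positions)}"
            )
        if site.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {site.strand!r}")
        if not 0 <= site.chrom < len(sequences):
            raise ValueError(f"chromosome ordinal {site.chrom} out of range")
        if pam_match(site.pam_instance, pam) is None:
            raise ValueError(
                f"pam_instance {site.pam_instance!r} does not match "
                f"pattern {pam.text!r}"
            )
        start, end = _site_extent(site, pam.length)
        if start < 0 or end > len(sequences[site.chrom]):
            raise ValueError(
                f"site at {site.position}{site.strand} does not fit within "
                f"chromosome {site.chrom}"
            )
        for s, e in extents.setdefault(site.chrom, []):
            if start < e and s < end:
                raise ValueError(
                    f"planted sites overlap on chromosome {site.chrom}: "
                    f"[{start},{end}) vs [{s},{e})"
                )
        extents[site.chrom].append((start, end))

        mutated = list(guide)
        for p in site.mismatch_positions:
            alternatives = [b for b in "ACGT" if b != guide[p]]
            mutated[p] = alternatives[rng.integers(len(alternatives))]
        protospacer = "".join(mutated)

        buf = sequences[site.chrom]
        if site.strand == "+":
            window = protospacer + site.pam_instance
            buf[start:end] = window.encode("ascii")
        else:
            window = reverse_complement(protospacer + site.pam_instance)
            buf[start:end] = window.encode("ascii")

        hit = OffTargetHit(
            chrom_name=genome.chromosomes[site.chrom][0],
            strand=site.strand,
            position=site.position,
            sequence=protospacer,
            mismatch_positions=frozenset(site.mismatch_positions),
            mismatch_count=len(site.mismatch_positions),
            pam_instance=site.pam_instance,
            gc_content=gc_content(protospacer),
        )
        truth.append(
            (site.chrom, site.position, 0 if site.strand == "+" else 1, hit)
        )

    truth.sort(key=lambda t: t[:3])
    planted = Genome(
        chromosomes=[
            (name, bytes(buf).decode("ascii"))
            for (name, _), buf in zip(genome.chromosomes, sequences)
        ]
    )
    return planted, [hit for *_, hit in truth]


def make_exact_fixture(
    spec: PlantSpec,
    pam: PamPattern,
    length: int = 5000,
    num_chroms: int = 1,
    gc_bias: float = 0.5,
    rng_seed: int = 0,
    max_mm: int = 5,
    seed_mask: SeedMask = SeedMask(),
    max_attempts: int = 50,
) -> tuple[Genome, list[OffTargetHit]]:
    """A planted fixture whose ground truth is the *exact* hit set.

    Draws background genomes from successive seeds until the brute-force
    oracle confirms the planted sites are the only hits for the guide under
    the given budget; raises after ``max_attempts`` failures.
    """
    for attempt in range(max_attempts):
        background = synth_genome(
            length, num_chroms, gc_bias, rng_seed + attempt
        )
        planted, truth = plant_offtargets(
            background, spec, pam, rng_seed + attempt
        )
        found = brute_force_offtargets(planted, spec.guide, pam, max_mm, seed_mask)
        if found == truth:
            return planted, truth
    raise RuntimeError(
        f"no chance-hit-free background found in {max_attempts} attempts; "
        "use a longer guide-distinct background or accept subset semantics"
    )


def write_ground_truth_tsv(hits: list[OffTargetHit], path: str | Path) -> None:
    """Persist planted ground truth as a plain TSV (for CLI round-trips)."""
    with open(path, "wt", encoding="ascii") as fh:
        fh.write(
            "chromosome\tstrand\tposition\tsequence\tmismatch_positions"
            "\tmismatches\tpam\tgc_content\n"
        )
        for h in hits:
            positions = ",".join(str(p) for p in sorted(h.mismatch_positions))
            fh.write(
                f"{h.chrom_name}\t{h.strand}\t{h.position}\t{h.sequence}\t"
                f"{positions}\t{h.mismatch_count}\t{h.pam_instance}\t"
                f"{h.gc_content:.2f}\n"
            )
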