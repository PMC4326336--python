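"""Optional annotation stage: tag hits with overlapping genomic features.

Annotations come from a GTF (1-based, inclusive coordinates, converted on
read) or BED (0-based, half-open) file; internally everything is 0-based
half-open and organized as one interval tree per chromosome. A hit is
tagged with every feature its 20-nt window overlaps by at least one base,
regardless of feature strand; an empty list means intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

from intervaltree import IntervalTree

from .index import GUIDE_LEN
from .query import OffTargetHit

#: GTF feature-column values mapped to the reported region classes.
_GTF_CLASS = {
    "five_prime_utr": "5UTR",
    "5utr": "5UTR",
    "cds": "CDS",
    "three_prime_utr": "3UTR",
    "3utr": "3UTR",
    "exon": "exon",
}

FEATURE_CLASSES = ("5UTR", "CDS", "3UTR", "exon", "lincRNA", "other")


class AnnotationFormatError(ValueError):
    """Malformed GTF/BED input; the message carries the line number."""


@dataclass(frozen=True)
class Feature:
    """One annotated interval (0-based, half-open)."""

    start: int
    end: int
    gene_id: str
    transcript_id: str
    gene_name: str
    feature_class: str


@dataclass
class FeatureIndex:
    """Per-chromosome interval trees over :class:`Feature` records."""

    trees: dict[str, IntervalTree]

    @property
    def n_features(self) -> int:
        return sum(len(t) for t in self.trees.values())


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if '"' in chunk:
            key, _, rest = chunk.partition(" ")
            attrs[key] = rest.strip().strip('"')
        else:
            parts = chunk.split("=") if "=" in chunk else chunk.split()
            if len(parts) == 2:
                attrs[parts[0]] = parts[1].strip('"')
    return attrs


def _gtf_feature_class(feature_col: str, attrs: dict[str, str]) -> str:
    biotype = attrs.get("transcript_biotype") or attrs.get("gene_biotype") or ""
    mapped = _GTF_CLASS.get(feature_col.lower())
    if mapped in ("5UTR", "CDS", "3UTR"):
        return mapped
    if biotype == "lincRNA":
        return "lincRNA"
    return mapped or "other"


def load_annotation(path: Union[str, Path]) -> FeatureIndex:
    """Read a GTF or BED file into a :class:`FeatureIndex`.

    Format is chosen by extension (``.bed`` -> BED, anything else -> GTF).
    GTF rows keep their gene/transcript/name attributes and derive a region
    class from the feature column (five_prime_utr, CDS, three_prime_utr,
    exon; lincRNA via transcript biotype). BED rows carry their name column
    as gene_id with class "other".
    """
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    trees: dict[str, IntervalTree] = {}

    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if is_bed:
                    if len(fields) < 3:
                        raise ValueError("BED needs at least 3 columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else ""
                    feature = Feature(
                        start=start, end=end, gene_id=name, transcript_id="",
                        gene_name=name, feature_class="other",
                    )
                else:
                    if len(fields) < 8:
                        raise ValueError("GTF needs at least 8 columns")
                    chrom = fields[0]
                    # GTF is 1-based inclusive; convert to 0-based half-open
                    start, end = int(fields[3]) - 1, int(fields[4])
                    attrs = (
                        _parse_gtf_attributes(fields[8]) if len(fields) > 8 else {}
                    )
                    feature = Feature(
                        start=start, end=end,
                        gene_id=attrs.get("gene_id", ""),
                        transcript_id=attrs.get("transcript_id", ""),
                        gene_name=attrs.get("gene_name", ""),
                        feature_class=_gtf_feature_class(fields[2], attrs),
                    )
                if start < 0 or end < start:
                    raise ValueError(f"bad interval [{start}, {end})")
            except ValueError as exc:
                raise AnnotationFormatError(f"line {lineno}: {exc}") from exc
            if end > start:  # intervaltree rejects empty intervals
                trees.setdefault(chrom, IntervalTree()).addi(start, end, feature)
    return FeatureIndex(trees=trees)


def annotate_hit(hit: OffTargetHit, idx: FeatureIndex) -> list[Feature]:
    """Every feature overlapping the hit's 20-mer window by >= 1 base.

    Feature strand is ignored; an unknown chromosome yields an empty list
    (annotation files may legitimately cover a subset of the genome).
    """
    tree = idx.trees.get(hit.chrom_name)
    if tree is None:
        return []
    found = [iv.data for iv in tree.overlap(hit.position, hit.position + GUIDE_LEN)]
    found.sort(
        key=lambda f: (f.start, f.end, f.gene_id, f.transcript_id, f.feature_class)
    )
    return found
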