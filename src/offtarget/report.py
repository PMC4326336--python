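"""Tabular report construction for the CLI (per-guide and summary TSVs)."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .query import OffTargetHit, mismatch_histogram

HIT_COLUMNS = [
    "guide",
    "chromosome",
    "strand",
    "position",
    "sequence",
    "mismatches",
    "pam",
    "gc_content",
    "gene_ids",
    "transcript_ids",
    "feature_classes",
]


def lowercase_mismatches(sequence: str, positions: frozenset[int]) -> str:
    """Render an off-target 20-mer with its mismatched bases lowercased."""
    return "".join(
        c.lower() if i in positions else c for i, c in enumerate(sequence)
    )


def _join_unique(values: Sequence[str]) -> str:
    seen: list[str] = []
    for v in values:
        if v and v not in seen:
            seen.append(v)
    return ";".join(seen)


def hits_dataframe(
    guide: str, hits: Sequence[OffTargetHit], one_based: bool = False
) -> pd.DataFrame:
    """One row per hit, in engine order, with annotation columns flattened."""
    offset = 1 if one_based else 0
    rows = []
    for h in hits:
        rows.append(
            {
                "guide": guide,
                "chromosome": h.chrom_name,
                "strand": h.strand,
                "position": h.position + offset,
                "sequence": lowercase_mismatches(h.sequence, h.mismatch_positions),
                "mismatches": h.mismatch_count,
                "pam": h.pam_instance,
                "gc_content": f"{h.gc_content:.2f}",
                "gene_ids": _join_unique([f.gene_id for f in h.annotation]),
                "transcript_ids": _join_unique(
                    [f.transcript_id for f in h.annotation]
                ),
                "feature_classes": _join_unique(
                    [f.feature_class for f in h.annotation]
                ),
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def summary_dataframe(
    entries: Sequence[tuple[str, str, str, Sequence[OffTargetHit]]], max_mm: int
) -> pd.DataFrame:
    """Per-guide summary: totals plus the mismatch histogram.

    ``entries`` holds (guide, strand, offset) as strings — strand/offset are
    blank in guide-list mode and filled in target-sequence mode — plus the
    guide's hits.
    """
    columns = ["guide", "strand", "offset", "total_hits"] + [
        f"mm_{i}" for i in range(max_mm + 1)
    ]
    rows = []
    for guide, strand, offset, hits in entries:
        histogram = mismatch_histogram(hits, max_mm)
        row = {
            "guide": guide,
            "strand": strand,
            "offset": offset,
            "total_hits": len(hits),
        }
        row.update({f"mm_{i}": histogram[i] for i in range(max_mm + 1)})
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)
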