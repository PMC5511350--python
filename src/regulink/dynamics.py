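"""Open-chromatin opening dynamics across haematopoietic differentiation.

Classifies a reference cell type's open-chromatin peaks (e.g. MK ATAC-seq
peaks) by their presence in the progenitor compartments (HSC, CMP, MEP) and
in the other terminal cell type (EB), using a minimum overlap of 1 bp:

* category I   — present in all five cell types, pattern (1,1,1,1)
* category II  — open throughout differentiation but closed in the other
  terminal cell, pattern (1,1,1,0)
* category III — opened only at the final stage, only in the reference
  cell, pattern (0,0,0,0)
* category IV  — opened at the final stage in both terminal cells,
  pattern (0,0,0,1)
* every other pattern is reported as UNCATEGORIZED, never dropped.

Annotation labels: CTCF from unpadded overlap; enhancer-state and
progenitor-acetylation labels from overlap after extending peaks by ±500 bp
(the pad accounts for the spatial shift between open chromatin and the
flanking H3K27ac signal).
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping

import pandas as pd

from .genome import GenomeLayout, IntervalSet, extend, overlaps

__all__ = [
    "OpeningCategory",
    "presence_patterns",
    "categorize_opening",
    "annotate_labels",
    "category_summary",
]

PROGENITORS = ("HSC", "CMP", "MEP")


class OpeningCategory(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNCATEGORIZED = "UNCATEGORIZED"


_PATTERN_TO_CATEGORY = {
    (True, True, True, True): OpeningCategory.I,
    (True, True, True, False): OpeningCategory.II,
    (False, False, False, False): OpeningCategory.III,
    (False, False, False, True): OpeningCategory.IV,
}


def categorize_opening(pattern: tuple[bool, bool, bool, bool]) -> OpeningCategory:
    """Map a (HSC, CMP, MEP, other-terminal) presence pattern to a category.

    Total and pure: every one of the 16 patterns maps to exactly one
    category; the 12 unnamed patterns map to UNCATEGORIZED.
    """
    key = tuple(bool(b) for b in pattern)
    if len(key) != 4:
        raise ValueError("presence pattern must have exactly four booleans")
    return _PATTERN_TO_CATEGORY.get(key, OpeningCategory.UNCATEGORIZED)


def presence_patterns(
    reference_peaks: IntervalSet,
    progenitor_peaks: Mapping[str, IntervalSet],
    terminal_peaks: IntervalSet,
) -> pd.DataFrame:
    """Presence of each reference peak in HSC/CMP/MEP and the other terminal
    cell type, by >=1 bp overlap.  Rows follow the canonical peak order."""
    missing = [c for c in PROGENITORS if c not in progenitor_peaks]
    if missing:
        raise KeyError(f"missing progenitor cell type(s): {', '.join(missing)}")
    cols = {}
    for cell in PROGENITORS:
        cols[cell.lower()] = overlaps(reference_peaks, progenitor_peaks[cell], min_bp=1).flags
    cols["terminal"] = overlaps(reference_peaks, terminal_peaks, min_bp=1).flags
    df = pd.DataFrame(cols)
    df.insert(0, "peak_id", [iv.label or f"peak{i}" for i, iv in enumerate(reference_peaks)])
    df.insert(1, "chrom", [iv.chrom for iv in reference_peaks])
    df.insert(2, "start", [iv.start for iv in reference_peaks])
    df.insert(3, "end", [iv.end for iv in reference_peaks])
    df["category"] = [
        categorize_opening((h, c, m, t)).value
        for h, c, m, t in zip(df.hsc, df.cmp, df.mep, df.terminal)
    ]
    return df


def annotate_labels(
    reference_peaks: IntervalSet,
    ctcf_peaks: IntervalSet,
    enhancer_segments: IntervalSet,
    progenitor_h3k27ac_peaks: IntervalSet,
    layout: GenomeLayout,
    pad: int = 500,
) -> pd.DataFrame:
    """Per-peak flags: CTCF (unpadded overlap); enhancer state and
    progenitor H3K27ac (overlap after extending peaks by ``pad``)."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    padded = extend(reference_peaks, pad, layout)
    df = pd.DataFrame(
        {
            "peak_id": [iv.label or f"peak{i}" for i, iv in enumerate(reference_peaks)],
            "ctcf": overlaps(reference_peaks, ctcf_peaks, min_bp=1).flags,
            "enhancer": overlaps(padded, enhancer_segments, min_bp=1).flags,
            "progenitor_h3k27ac": overlaps(
                padded, progenitor_h3k27ac_peaks, min_bp=1
            ).flags,
        }
    )
    return df


def category_summary(patterns: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per opening category."""
    counts = patterns["category"].value_counts()
    order = [c.value for c in OpeningCategory]
    rows = [
        {"category": c, "count": int(counts.get(c, 0)),
         "fraction": float(counts.get(c, 0)) / max(1, len(patterns))}
        for c in order
    ]
    return pd.DataFrame(rows)
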