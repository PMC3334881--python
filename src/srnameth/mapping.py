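"""Exact-match read mapping and small RNA class assignment.

Reads are placed on the reference by exact string matching (full length
first; otherwise the maximal templated prefix, delegated to the 3'-end
resolver). Mapped reads are assigned to one of the canonical
C. elegans small RNA classes by templated length, 5' nucleotide and
annotation overlap: annotated miRNA matures win; 21-nt 5'U reads sense
to a piRNA locus are piRNAs; 26-nt 5'G reads antisense to a 26G source
locus are primary siRNAs of that locus's pathway (ERGO-1 or ALG-3/4
class); 22-nt 5'G reads antisense to a transcript locus are secondary
(22G) siRNAs; everything else mapped is 'other'.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import (
    TRANSCRIPT_CLASSES,
    AlignmentRecord,
    ClassAssignment,
    Feature,
    ReferenceSet,
    SmallRNARead,
)
from .tailing import resolve_3prime


def map_read(
    read: SmallRNARead, ref: ReferenceSet, min_prefix: int = 15
) -> list[AlignmentRecord]:
    """Place a read on the reference by exact matching.

    Full-length matches (either strand) come first by construction:
    the maximal-prefix search starts at the full read length. All
    equally long placements are reported in (contig, start, strand)
    order; an empty list means unmapped.
    """
    if not ref.sequences:
        raise ValueError("empty reference")
    calls = resolve_3prime(read, ref, min_prefix=min_prefix)
    return [
        AlignmentRecord(
            read_id=call.read_id,
            contig=call.contig,
            start=call.start,
            strand=call.strand,
            templated_prefix_length=call.templated_prefix_length,
            tail_sequence=call.tail_sequence,
        )
        for call in calls
    ]


def _mature_span(feat: Feature) -> tuple[int, int]:
    """Interval of the annotated mature species within the feature."""
    length = feat.mature_length or len(feat)
    if feat.strand == "+":
        return (feat.start, feat.start + length)
    return (feat.end - length, feat.end)


def _overlaps(aln: AlignmentRecord, feat: Feature) -> bool:
    lo, hi = aln.span
    return aln.contig == feat.contig and lo < feat.end and feat.start < hi


def classify_read(
    alignments: list[AlignmentRecord],
    features: list[Feature],
    read: SmallRNARead,
) -> ClassAssignment:
    """Assign a read to its small RNA class.

    Rules in priority order over all reported placements; the
    classification length is the genome-templated prefix length, so a
    3'-tailed read keeps the class of its templated species.
    """
    if not alignments:
        return ClassAssignment(read.read_id, "unmapped")
    length = alignments[0].templated_prefix_length
    first_nt = read.sequence[0]

    for aln in alignments:
        for feat in features:
            if feat.cls == "mirna_mature" and aln.contig == feat.contig:
                if aln.strand == feat.strand and aln.span == _mature_span(feat):
                    return ClassAssignment(read.read_id, "miRNA")
    if length == 21 and first_nt == "T":
        for aln in alignments:
            for feat in features:
                if (
                    feat.cls == "pirna_locus"
                    and aln.strand == feat.strand
                    and _overlaps(aln, feat)
                ):
                    return ClassAssignment(read.read_id, "piRNA_21U")
    if length == 26 and first_nt == "G":
        for cls, label in (
            ("sirna26g_ergo1_locus", "siRNA_26G_ERGO1"),
            ("sirna26g_alg34_locus", "siRNA_26G_ALG34"),
        ):
            for aln in alignments:
                for feat in features:
                    if feat.cls == cls and aln.strand != feat.strand and _overlaps(aln, feat):
                        return ClassAssignment(read.read_id, label)
    if length == 22 and first_nt == "G":
        for aln in alignments:
            for feat in features:
                if (
                    feat.cls in TRANSCRIPT_CLASSES
                    and aln.strand != feat.strand
                    and _overlaps(aln, feat)
                ):
                    return ClassAssignment(read.read_id, "siRNA_22G")
    return ClassAssignment(read.read_id, "other")


def classify_library(
    reads: Iterable[SmallRNARead],
    ref: ReferenceSet,
    min_prefix: int = 15,
) -> tuple[dict[str, str], dict[str, list[AlignmentRecord]]]:
    """Map and classify every read.

    Returns (read id -> class label, read id -> alignment records).
    The class labels partition the library: every read receives exactly
    one label, 'unmapped' included.
    """
    assignments: dict[str, str] = {}
    alignments: dict[str, list[AlignmentRecord]] = {}
    for read in reads:
        alns = map_read(read, ref, min_prefix=min_prefix)
        alignments[read.read_id] = alns
        assignments[read.read_id] = classify_read(alns, ref.features, read).cls
    return assignments, alignments


def size_firstnt_profile(
    reads: Iterable[SmallRNARead],
    assignments: Optional[dict[str, str]] = None,
    cls: Optional[str] = None,
    feature: Optional[Feature] = None,
    alignments: Optional[dict[str, list[AlignmentRecord]]] = None,
    size_min: int = 18,
    size_max: int = 28,
) -> pd.DataFrame:
    """Copy-count matrix over (read length, 5' nucleotide).

    Optionally restricted to one class (via ``assignments``) or to the
    reads placed within one feature (via ``alignments``). Columns are
    reported in the RNA alphabet (U for T). Reads outside the length
    window are not counted.
    """
    lengths = list(range(size_min, size_max + 1))
    cols = ["A", "C", "G", "U"]
    mat = pd.DataFrame(0, index=pd.Index(lengths, name="length"), columns=cols)
    for read in reads:
        if cls is not None and (assignments or {}).get(read.read_id) != cls:
            continue
        if feature is not None:
            alns = (alignments or {}).get(read.read_id, [])
            if not any(_overlaps(a, feature) for a in alns):
                continue
        L = len(read.sequence)
        if not (size_min <= L <= size_max):
            continue
        nt = read.sequence[0]
        mat.loc[L, "U" if nt == "T" else nt] += read.count
    return mat


def coverage_track(
    alignments: Iterable[AlignmentRecord],
    feature: Feature,
    counts: dict[str, int],
    strand: Optional[str] = None,
) -> np.ndarray:
    """Per-position summed copy counts of templated spans along a feature.

    ``counts`` maps read id to copy count. ``strand`` restricts to
    placements on that genomic strand (None: both). Position 0 of the
    track is ``feature.start`` regardless of the feature's strand.
    """
    track = np.zeros(len(feature), dtype=np.int64)
    for aln in alignments:
        if strand is not None and aln.strand != strand:
            continue
        if not _overlaps(aln, feature):
            continue
        lo = max(aln.span[0], feature.start) - feature.start
        hi = min(aln.span[1], feature.end) - feature.start
        track[lo:hi] += counts.get(aln.read_id, 1)
    return track


def class_copy_totals(
    reads: Iterable[SmallRNARead], assignments: dict[str, str]
) -> dict[str, int]:
    """Summed copy counts per class; values total the library's copies."""
    totals: dict[str, int] = {}
    for read in reads:
        cls = assignments.get(read.read_id, "unmapped")
        totals[cls] = totals.get(cls, 0) + read.count
    return totals
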