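"""3' end decomposition: templated prefix, trimming and untemplated tails.

Each read is decomposed at its best genomic placement into a
genome-templated 5' prefix and a (possibly empty) untemplated 3' tail.
The templated prefix is maximal, so the first tail nucleotide is
guaranteed not to be templated at the placement: if the genome
continued with that nucleotide, a longer prefix would also place.
Trimming (3'->5' shortening) is measured against the annotated mature
species length where one is known.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .model import ReferenceSet, SmallRNARead, TailCall, revcomp


def _occurrences(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def resolve_3prime(
    read: SmallRNARead, ref: ReferenceSet, min_prefix: int = 15
) -> list[TailCall]:
    """All placements of the read's maximal templated 5' prefix.

    Searches both strands for the longest read prefix (length k) that
    matches the reference exactly, with k at least ``min_prefix``; the
    remaining suffix is the untemplated tail. All placements achieving
    the maximal k are returned in deterministic (contig, start, strand)
    order. An empty list means the read is unplaced.
    """
    if not ref.sequences:
        raise ValueError("empty reference")
    seq = read.sequence
    for k in range(len(seq), min_prefix - 1, -1):
        prefix = seq[:k]
        rc = revcomp(prefix)
        placements: list[tuple[str, int, str]] = []
        for contig in sorted(ref.sequences):
            genome = ref.sequences[contig]
            for start in _occurrences(genome, prefix):
                placements.append((contig, start, "+"))
            for start in _occurrences(genome, rc):
                placements.append((contig, start, "-"))
        if placements:
            placements.sort()
            tail = seq[k:]
            return [
                TailCall(
                    read_id=read.read_id,
                    contig=contig,
                    start=start,
                    strand=strand,
                    templated_prefix_length=k,
                    tail_sequence=tail,
                )
                for contig, start, strand in placements
            ]
    return []


def trim_length(call: TailCall, annotated_mature_length: Optional[int]) -> Optional[int]:
    """3'->5' shortening relative to the annotated mature species.

    None when no annotation is known; floored at zero (reads longer
    than the annotated species are not negative trims).
    """
    if annotated_mature_length is None:
        return None
    return max(annotated_mature_length - call.templated_prefix_length, 0)


def call_library(
    reads: Iterable[SmallRNARead],
    ref: ReferenceSet,
    min_prefix: int = 15,
    mature_lengths: Optional[dict[str, int]] = None,
) -> tuple[dict[str, TailCall], list[str]]:
    """One tail call per read (deterministic first placement).

    ``mature_lengths`` maps read id to the annotated mature species
    length for trim measurement (when known). Returns the calls keyed
    by read id plus the ids of unplaced reads.
    """
    calls: dict[str, TailCall] = {}
    unplaced: list[str] = []
    for read in reads:
        placements = resolve_3prime(read, ref, min_prefix=min_prefix)
        if not placements:
            unplaced.append(read.read_id)
            continue
        call = placements[0]
        annotated = (mature_lengths or {}).get(read.read_id)
        if annotated is not None:
            call = TailCall(
                read_id=call.read_id,
                contig=call.contig,
                start=call.start,
                strand=call.strand,
                templated_prefix_length=call.templated_prefix_length,
                tail_sequence=call.tail_sequence,
                trim_length=trim_length(call, annotated),
                feature_id=call.feature_id,
            )
        calls[read.read_id] = call
    return calls, unplaced


def tailed_proportion(
    calls: dict[str, TailCall],
    reads: Iterable[SmallRNARead],
    assignments: dict[str, str],
    cls: str,
) -> float:
    """Fraction of placed copies of a class carrying a 3' untemplated tail.

    Tailed copies over the combined total of tailed and untailed placed
    copies; 0.0 when the class has no placed copies.
    """
    tailed = total = 0
    for read in reads:
        if assignments.get(read.read_id) != cls:
            continue
        call = calls.get(read.read_id)
        if call is None:
            continue
        total += read.count
        if len(call.tail_sequence) >= 1:
            tailed += read.count
    return tailed / total if total else 0.0


def tail_table(
    calls: dict[str, TailCall],
    reads: Iterable[SmallRNARead],
    assignments: dict[str, str],
) -> pd.DataFrame:
    """Per-class tailed and trimmed proportions over placed copies."""
    rows: dict[str, dict[str, float]] = {}
    for read in reads:
        call = calls.get(read.read_id)
        if call is None:
            continue
        cls = assignments.get(read.read_id, "other")
        row = rows.setdefault(
            cls, {"placed_copies": 0, "tailed_copies": 0, "trimmed_copies": 0}
        )
        row["placed_copies"] += read.count
        if call.tail_sequence:
            row["tailed_copies"] += read.count
        if call.trim_length is not None and call.trim_length > 0:
            row["trimmed_copies"] += read.count
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if df.empty:
        return pd.DataFrame(
            columns=[
                "placed_copies",
                "tailed_copies",
                "trimmed_copies",
                "tailed_proportion",
                "trimmed_proportion",
            ]
        )
    df["tailed_proportion"] = df["tailed_copies"] / df["placed_copies"]
    df["trimmed_proportion"] = df["trimmed_copies"] / df["placed_copies"]
    df.index.name = "class"
    return df


def tail_composition(
    calls: dict[str, TailCall], reads: Iterable[SmallRNARead]
) -> pd.DataFrame:
    """Nucleotide composition of tails, weighted by copy count.

    Reported with U (not T): tails are untemplated ribonucleotide
    additions, dominated by uridylation in this system.
    """
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    by_id = {read.read_id: read.count for read in reads}
    for read_id, call in calls.items():
        for nt in call.tail_sequence:
            counts["U" if nt == "T" else nt] += by_id.get(read_id, 1)
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "tail_nt_copies": counts,
            "fraction": {k: (v / total if total else 0.0) for k, v in counts.items()},
        }
    )
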