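"""Readers and writers for the package's on-disk formats.

Collapsed small RNA libraries use the FASTA header dialect
``>{read_id} count={n}``; FASTQ input is accepted with one copy per
record. References travel as plain FASTA plus GFF3 (and BED) feature
annotations. The collapsed-FASTA parser is purpose-built so malformed
records can be reported with their line number.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

from .model import Feature, ReferenceSet, SmallRNARead, normalize_seq

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class LibraryParseError(ValueError):
    """Raised for malformed collapsed-FASTA input; message carries the line number."""


def write_library(reads: Iterable[SmallRNARead], path: PathLike) -> None:
    """Write collapsed reads as FASTA with ``count=`` headers."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id} count={read.count}\n{read.sequence}\n")


def _parse_count(header: str, lineno: int) -> tuple[str, int]:
    parts = header[1:].split()
    if not parts or not parts[0]:
        raise LibraryParseError(f"line {lineno}: empty FASTA header")
    read_id = parts[0]
    for token in parts[1:]:
        if token.startswith("count="):
            value = token[len("count=") :]
            if not value.isdigit() or int(value) < 1:
                raise LibraryParseError(
                    f"line {lineno}: bad count {value!r} in header for {read_id}"
                )
            return read_id, int(value)
    logger.warning("line %d: header for %s lacks count=, defaulting to 1", lineno, read_id)
    return read_id, 1


def read_library(path: PathLike) -> list[SmallRNARead]:
    """Read a collapsed library (FASTA with count headers, or FASTQ).

    Records whose sequence contains characters outside ACGTU are
    rejected individually; the rejection total is logged. RNA input (U)
    is normalised to DNA.
    """
    path = Path(path)
    if path.suffix.lower() in (".fastq", ".fq"):
        reads = []
        for rec in SeqIO.parse(str(path), "fastq"):
            seq = normalize_seq(str(rec.seq))
            if set(seq) - set("ACGT"):
                logger.warning("rejected FASTQ record %s: non-ACGTU characters", rec.id)
                continue
            reads.append(SmallRNARead(read_id=rec.id, sequence=seq, count=1))
        return reads

    reads = []
    rejected = 0
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        nonlocal rejected
        if header is None:
            return
        read_id, count = _parse_count(header, header_line)
        seq = normalize_seq("".join(chunks))
        if not seq:
            raise LibraryParseError(f"line {header_line}: record {read_id} has no sequence")
        if set(seq) - set("ACGT"):
            logger.warning(
                "line %d: rejected record %s: non-ACGTU characters", header_line, read_id
            )
            rejected += 1
            return
        reads.append(SmallRNARead(read_id=read_id, sequence=seq, count=count))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header, header_line, chunks = line, lineno, []
            elif header is None:
                raise LibraryParseError(f"line {lineno}: sequence before first header")
            else:
                chunks.append(line)
        flush()
    if rejected:
        logger.warning("rejected %d record(s) from %s", rejected, path)
    return reads


def write_truth(reads: Iterable[SmallRNARead], path: PathLike) -> None:
    """Sidecar TSV carrying simulation ground truth (class, methylation,
    trim/tail) so treatment simulation can run on a re-read library."""
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_class\tmethylated\ttrue_trim\ttrue_tail\tsource_feature\n")
        for read in reads:
            if read.truth is None:
                continue
            t = read.truth
            fh.write(
                f"{read.read_id}\t{t.true_class}\t{int(t.methylated)}\t{t.true_trim}"
                f"\t{t.true_tail}\t{t.source_feature or ''}\n"
            )


def attach_truth(reads: list[SmallRNARead], path: PathLike) -> list[SmallRNARead]:
    """Re-attach sidecar truth to reads loaded from a collapsed library."""
    from .model import ReadTruth

    table: dict[str, ReadTruth] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}: not a truth sidecar file")
        for line in fh:
            rid, cls, meth, trim, tail, src = line.rstrip("\n").split("\t")
            table[rid] = ReadTruth(
                true_class=cls,
                methylated=bool(int(meth)),
                true_trim=int(trim),
                true_tail=tail,
                source_feature=src or None,
            )
    for read in reads:
        read.truth = table.get(read.read_id)
    return reads


def write_reference_fasta(ref: ReferenceSet, path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in sorted(ref.sequences):
            fh.write(f">{contig}\n")
            seq = ref.sequences[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(ref: ReferenceSet, path: PathLike) -> None:
    """Emit features as GFF3 (1-based, closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(ref.sequences):
            fh.write(f"##sequence-region {contig} 1 {len(ref.sequences[contig])}\n")
        for feat in ref.features:
            attrs = f"ID={feat.feature_id};class={feat.cls}"
            if feat.mature_length is not None:
                attrs += f";mature_length={feat.mature_length}"
            fh.write(
                "\t".join(
                    [
                        feat.contig,
                        "srnameth",
                        feat.cls,
                        str(feat.start + 1),
                        str(feat.end),
                        ".",
                        feat.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed(ref: ReferenceSet, path: PathLike) -> None:
    """Emit features as BED6 (0-based, half-open — native coordinates)."""
    with open(path, "w") as fh:
        for feat in ref.features:
            fh.write(
                f"{feat.contig}\t{feat.start}\t{feat.end}\t{feat.feature_id}\t0\t{feat.strand}\n"
            )


def read_reference(fasta_path: PathLike, gff3_path: PathLike | None = None) -> ReferenceSet:
    """Load a reference from FASTA (+ optional GFF3 annotations)."""
    sequences = {
        rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    features: list[Feature] = []
    if gff3_path is not None:
        with open(gff3_path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                mature = attrs.get("mature_length")
                features.append(
                    Feature(
                        contig=cols[0],
                        start=int(cols[3]) - 1,
                        end=int(cols[4]),
                        strand=cols[6],
                        cls=cols[2],
                        feature_id=attrs.get("ID", f"{cols[0]}:{cols[3]}-{cols[4]}"),
                        mature_length=int(mature) if mature else None,
                    )
                )
    return ReferenceSet(sequences=sequences, features=features)
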