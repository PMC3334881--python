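"""Synthetic reference and small RNA library generation.

The generator emulates the structure of a C. elegans small RNA
sequencing experiment: class-specific read geometry (21-nt 5'U piRNAs,
22-nt 5'G secondary siRNAs, 26-nt 5'G primary siRNAs, annotated miRNA
matures), per-class 3' 2'-O-methylation status, 3' trimming and
untemplated tailing, an X-cluster-like locus carrying repeated copies of
a 26-nt target motif, and a separate trigger gene emitting a partially
complementary 26-nt guide. Periodate/beta-elimination treatment is
modelled at the ligation step: copies whose 3' end is oxidised (free
2',3'-OH, i.e. unmethylated) mostly fail adapter ligation and drop out
of the treated library, while 2'-O-methylated 3' ends resist.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    Feature,
    ReadTruth,
    ReferenceSet,
    SmallRNARead,
    revcomp,
)

_NT = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SizingError(ValueError):
    """A requested locus does not fit in its contig."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ClassSim:
    """Per-class simulation parameters.

    length/first_nt of None means "use the annotated mature species"
    (miRNAs). Copy counts are geometric with the given mean; tail
    lengths are 1 + Poisson(tail_len_mean - 1) nt, trim lengths
    1 + Poisson(trim_len_mean - 1) nt.
    """

    n_species: int = 0
    length: Optional[int] = None
    first_nt: Optional[str] = None
    copy_mean: float = 20.0
    meth_prob: float = 0.0
    tail_rate: float = 0.0
    tail_len_mean: float = 1.0
    tail_len_dist: str = "poisson"  # or "constant"
    trim_rate: float = 0.0
    trim_len_mean: float = 1.0
    trim_len_dist: str = "poisson"

    def __post_init__(self) -> None:
        for name in ("meth_prob", "tail_rate", "trim_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: Which feature classes source each read class, and the read's
#: orientation relative to the feature strand.
CLASS_SOURCES = {
    "miRNA": (("mirna_mature",), "sense"),
    "piRNA_21U": (("pirna_locus",), "sense"),
    "siRNA_22G": (("coding_locus", "xcluster_locus"), "antisense"),
    "siRNA_26G_ERGO1": (("sirna26g_ergo1_locus",), "antisense"),
    "siRNA_26G_ALG34": (("sirna26g_alg34_locus",), "antisense"),
}


def default_class_sims(n_species: int = 50, copy_mean: float = 20.0) -> dict[str, ClassSim]:
    """Default per-class parameters for a wild-type-like library.

    Methylation follows the biology: piRNAs and ERGO-1 class 26G
    siRNAs carry a 3' 2'-O-methyl; miRNAs, 22G siRNAs and ALG-3/4
    class 26G siRNAs do not. Tailing is a minor species everywhere,
    somewhat higher for 26G classes; trimming is off by default
    (a property of mutant libraries, enabled explicitly).
    """
    return {
        "miRNA": ClassSim(n_species, None, None, copy_mean, 0.0, tail_rate=0.01),
        "piRNA_21U": ClassSim(n_species, 21, "T", copy_mean, 1.0, tail_rate=0.02),
        "siRNA_22G": ClassSim(n_species, 22, "G", copy_mean, 0.0, tail_rate=0.02),
        "siRNA_26G_ERGO1": ClassSim(n_species, 26, "G", copy_mean, 1.0, tail_rate=0.10),
        "siRNA_26G_ALG34": ClassSim(n_species, 26, "G", copy_mean, 0.0, tail_rate=0.05),
    }


@dataclass
class LibraryConfig:
    """Simulation parameters for one library plus the treatment model."""

    classes: dict[str, ClassSim] = field(default_factory=default_class_sims)
    size_min: int = 18
    size_max: int = 28
    #: untemplated-tail composition, uridylation-biased
    tail_weights: dict[str, float] = field(
        default_factory=lambda: {"T": 0.7, "A": 0.2, "C": 0.05, "G": 0.05}
    )
    p_meth: float = 1.0
    p_unmeth: float = 0.1


@dataclass
class ReferenceSpec:
    """Layout of the synthetic reference."""

    n_mirna: int = 10
    mirna_length: int = 22
    n_pirna: int = 60
    n_sirna26g_ergo1: int = 4
    n_sirna26g_alg34: int = 4
    n_coding: int = 6
    coding_length: int = 300
    sirna_locus_length: int = 200
    n_motif_copies: int = 7
    xcluster_spacer: int = 20
    include_trigger: bool = True
    spacer: int = 30
    #: optional hard cap on the main contig; loci that do not fit are an error
    contig_length: Optional[int] = None
    #: threshold used when scrubbing the X-cluster background of
    #: spurious guide-complementary windows (G:U counted as paired)
    scan_threshold: float = 0.69


# ---------------------------------------------------------------------------
# reference construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _make_guide_and_motif(rng: np.random.Generator) -> tuple[str, str]:
    """A 26-nt 5'G guide and its partially complementary target motif.

    Pairing pattern (guide positions, 5'->3'): Watson-Crick at 1-10 and
    14-21 except G:U wobbles at 5 and 16; mispairs at 11-13 and 22-26.
    18 of 26 positions paired -> 69.2% complementarity with G:U counted
    as paired.
    """
    guide = list(_random_seq(rng, 26))
    guide[0] = "G"
    guide[4] = "G"   # G:U partner below
    guide[15] = "T"  # U:G partner below
    wc = set(range(0, 10)) | set(range(13, 21))
    gu = {4, 15}
    motif = ["N"] * 26
    for i in range(26):
        g = guide[i]
        if i in gu:
            t = "T" if g == "G" else "G"
        elif i in wc:
            t = _COMP[g]
        else:  # mispair: same nucleotide never pairs
            t = g
        # guide position i+1 pairs with motif position 26-(i+1)+1 (antiparallel)
        motif[25 - i] = t
    return "".join(guide), "".join(motif)


def _paired_fraction(guide: str, window: str) -> float:
    from .pairing import pair_state  # local import to avoid a cycle

    L = len(guide)
    paired = sum(
        1 for i in range(L) if pair_state(guide[i], window[L - 1 - i]) in ("WC", "GU")
    )
    return paired / L


def _scrub_background(
    seq: list[str],
    guide: str,
    motif_starts: list[int],
    threshold: float,
    rng: np.random.Generator,
) -> None:
    """Mutate background positions until no non-motif window of the
    X-cluster transcript pairs with the guide at or above ``threshold``.

    Needed because with G:U counted as paired, random 26-mers reach the
    threshold at a small but non-negligible per-window rate, which would
    break the exactly-n-sites-by-construction contract of the locus.
    """
    L = len(guide)
    motif_positions = set()
    for s in motif_starts:
        motif_positions.update(range(s, s + L))
    for _ in range(10000):
        offending = None
        for j in range(len(seq) - L + 1):
            if j in motif_starts:
                continue
            window = "".join(seq[j : j + L])
            if _paired_fraction(guide, window) >= threshold:
                offending = j
                break
        if offending is None:
            return
        mutable = [p for p in range(offending, offending + L) if p not in motif_positions]
        p = mutable[rng.integers(0, len(mutable))]
        # setting the target nt equal to its guide partner forces a mispair
        seq[p] = guide[25 - (p - offending)]
    raise RuntimeError("X-cluster background scrub did not converge")


def build_reference(spec: ReferenceSpec, seed: int) -> ReferenceSet:
    """Generate a synthetic reference with typed loci.

    The main contig carries miRNA matures, piRNA loci (5' T enforced on
    the annotated strand), 26G source loci and coding loci. A second
    contig holds the X-cluster: ``n_motif_copies`` exact copies of one
    26-nt target motif separated by spacers. A third contig holds the
    trigger gene whose annotated 26-nt species is the guide partially
    complementary to that motif.
    """
    rng = np.random.default_rng(seed)
    features: list[Feature] = []
    chunks: list[str] = []
    pos = 0

    def emit(seq: str) -> int:
        nonlocal pos
        chunks.append(seq)
        start = pos
        pos += len(seq)
        return start

    emit(_random_seq(rng, spec.spacer))
    for i in range(spec.n_mirna):
        start = emit(_random_seq(rng, spec.mirna_length))
        features.append(
            Feature("chrI", start, start + spec.mirna_length, "+", "mirna_mature",
                    f"mir-{i + 1}", mature_length=spec.mirna_length)
        )
        emit(_random_seq(rng, spec.spacer))
    for i in range(spec.n_pirna):
        start = emit("T" + _random_seq(rng, 20))
        features.append(
            Feature("chrI", start, start + 21, "+", "pirna_locus",
                    f"21ur-{i + 1}", mature_length=21)
        )
        emit(_random_seq(rng, spec.spacer))
    for cls, label, count in (
        ("sirna26g_ergo1_locus", "ergo1-src", spec.n_sirna26g_ergo1),
        ("sirna26g_alg34_locus", "alg34-src", spec.n_sirna26g_alg34),
    ):
        for i in range(count):
            start = emit(_random_seq(rng, spec.sirna_locus_length))
            features.append(
                Feature("chrI", start, start + spec.sirna_locus_length, "+", cls,
                        f"{label}-{i + 1}")
            )
            emit(_random_seq(rng, spec.spacer))
    for i in range(spec.n_coding):
        strand = "-" if i % 3 == 2 else "+"  # exercise both strands
        start = emit(_random_seq(rng, spec.coding_length))
        features.append(
            Feature("chrI", start, start + spec.coding_length, strand,
                    "coding_locus", f"gene-{i + 1}")
        )
        emit(_random_seq(rng, spec.spacer))
    chr1 = "".join(chunks)
    if spec.contig_length is not None:
        if len(chr1) > spec.contig_length:
            raise SizingError(
                f"requested loci need {len(chr1)} nt but contig_length is "
                f"{spec.contig_length}"
            )
        chr1 += _random_seq(rng, spec.contig_length - len(chr1))
    sequences = {"chrI": chr1}

    if spec.n_motif_copies < 1:
        raise ValueError("n_motif_copies must be >= 1")
    guide, motif = _make_guide_and_motif(rng)
    xparts: list[str] = [_random_seq(rng, spec.xcluster_spacer)]
    motif_starts: list[int] = []
    off = spec.xcluster_spacer
    for _ in range(spec.n_motif_copies):
        motif_starts.append(off)
        xparts.append(motif)
        off += 26
        xparts.append(_random_seq(rng, spec.xcluster_spacer))
        off += spec.xcluster_spacer
    xseq = list("".join(xparts))
    _scrub_background(xseq, guide, motif_starts, spec.scan_threshold, rng)
    lead = _random_seq(rng, spec.spacer)
    chrx = lead + "".join(xseq) + _random_seq(rng, spec.spacer)
    features.append(
        Feature("chrX", len(lead), len(lead) + len(xseq), "+", "xcluster_locus",
                "xcluster")
    )
    sequences["chrX"] = chrx

    if spec.include_trigger:
        lead = _random_seq(rng, spec.spacer)
        # guide is transcribed antisense to the + strand trigger annotation
        body = revcomp(guide)
        tail = _random_seq(rng, spec.spacer)
        sequences["chrT"] = lead + body + tail
        features.append(
            Feature("chrT", len(lead), len(lead) + 26, "-", "trigger_locus",
                    "trigger-26g", mature_length=26)
        )

    return ReferenceSet(sequences=sequences, features=features)


def trigger_guide(ref: ReferenceSet) -> str:
    """The trigger gene's 26-nt guide sequence (5'->3')."""
    feats = ref.features_of_class("trigger_locus")
    if not feats:
        raise ValueError("reference has no trigger_locus")
    return ref.feature_seq(feats[0])


def xcluster_transcript(ref: ReferenceSet) -> str:
    """The X-cluster transcript sequence (5'->3' on its annotated strand)."""
    feats = ref.features_of_class("xcluster_locus")
    if not feats:
        raise ValueError("reference has no xcluster_locus")
    return ref.feature_seq(feats[0])


# ---------------------------------------------------------------------------
# library simulation


def _valid_starts(seq: str, feat: Feature, length: int, first_nt: str) -> list[int]:
    """Window starts (contig coordinates) inside ``feat`` such that the
    antisense read of ``length`` nt begins with ``first_nt``."""
    starts = []
    for s in range(feat.start, feat.end - length + 1):
        if feat.strand == "+":
            # antisense read is revcomp(seq[s:s+L]); its 5' nt complements seq[s+L-1]
            if _COMP[seq[s + length - 1]] == first_nt:
                starts.append(s)
        else:
            if seq[s] == first_nt:
                starts.append(s)
    return starts


def _draw_tail(
    rng: np.random.Generator,
    length: int,
    weights: dict[str, float],
    forbidden_first: Optional[str],
) -> str:
    nts = list(weights)
    p = np.array([weights[n] for n in nts], dtype=float)
    p /= p.sum()
    tail = [str(x) for x in rng.choice(nts, size=length, p=p)]
    if forbidden_first is not None:
        for _ in range(100):
            if tail[0] != forbidden_first:
                break
            tail[0] = str(rng.choice(nts, p=p))
        else:  # pragma: no cover - degenerate weights
            tail[0] = next(n for n in "ACGT" if n != forbidden_first)
    return "".join(tail)


def simulate_library(
    ref: ReferenceSet, config: LibraryConfig, seed: int
) -> list[SmallRNARead]:
    """Draw a collapsed small RNA library from the reference.

    Each species is drawn from a locus of its class in the orientation
    the class prescribes (siRNAs antisense to their source transcript,
    miRNAs and piRNAs sense to the annotated species), with the class's
    length and 5' nucleotide. Trimming and tailing are per-copy events:
    a species' copies are split binomially into untouched, trimmed,
    tailed and trimmed+tailed variant species, so copy-level tailed and
    trimmed fractions are exactly binomial in the configured rates.
    Tails append untemplated nucleotides — the first tail nucleotide is
    guaranteed to differ from the next templated base, so the tail is
    strictly untemplated at the source placement. Hidden truth fields
    record class, methylation and the trim/tail event.
    """
    rng = np.random.default_rng(seed)
    reads: list[SmallRNARead] = []
    for cls in sorted(config.classes):
        sim = config.classes[cls]
        if sim.n_species == 0:
            continue
        if cls not in CLASS_SOURCES:
            raise ValueError(f"unknown read class {cls!r}")
        src_classes, orientation = CLASS_SOURCES[cls]
        loci = [f for f in ref.features if f.cls in src_classes]
        if not loci:
            raise ValueError(f"no locus of class {src_classes} for requested {cls} reads")

        if orientation == "sense":
            # annotated species: each locus yields one species, so sample
            # loci without replacement while they last
            order = list(rng.permutation(len(loci)))
            picks = [loci[order[i % len(loci)]] for i in range(sim.n_species)]
        else:
            picks = [loci[int(rng.integers(0, len(loci)))] for _ in range(sim.n_species)]

        for i, feat in enumerate(picks):
            seq = ref.sequences[feat.contig]
            if orientation == "sense":
                length = sim.length or feat.mature_length or len(feat)
                if feat.strand == "+":
                    s = feat.start
                    templated = seq[s : s + length]
                else:
                    s = feat.end - length
                    templated = revcomp(seq[s : s + length])
                read_strand = feat.strand
                span = (s, s + length)
            else:
                length = sim.length or 22
                starts = _valid_starts(seq, feat, length, sim.first_nt or "G")
                if not starts:
                    raise ValueError(
                        f"locus {feat.feature_id} has no valid {cls} start positions"
                    )
                s = starts[int(rng.integers(0, len(starts)))]
                if feat.strand == "+":
                    templated = revcomp(seq[s : s + length])
                    read_strand = "-"
                else:
                    templated = seq[s : s + length]
                    read_strand = "+"
                span = (s, s + length)

            count = int(rng.geometric(1.0 / sim.copy_mean))
            methylated = bool(rng.random() < sim.meth_prob)

            n_trimmed = int(rng.binomial(count, sim.trim_rate)) if sim.trim_rate else 0
            subgroups = [(0, count - n_trimmed), (1, n_trimmed)]
            variant = 0
            for trimmed_flag, sub_count in subgroups:
                if sub_count == 0 and not (trimmed_flag == 0 and count == 0):
                    continue
                trim = 0
                sub_templated, sub_span = templated, span
                if trimmed_flag:
                    trim = _draw_len(rng, sim.trim_len_mean, sim.trim_len_dist)
                    trim = min(trim, len(templated) - 15)
                    if trim <= 0:
                        continue
                    sub_templated = templated[: len(templated) - trim]
                    if read_strand == "+":
                        sub_span = (span[0], span[1] - trim)
                    else:
                        sub_span = (span[0] + trim, span[1])
                n_tailed = (
                    int(rng.binomial(sub_count, sim.tail_rate)) if sim.tail_rate else 0
                )
                for tailed_flag, n in ((0, sub_count - n_tailed), (1, n_tailed)):
                    if n == 0:
                        continue
                    tail = ""
                    if tailed_flag:
                        tail_len = _draw_len(rng, sim.tail_len_mean, sim.tail_len_dist)
                        if read_strand == "+":
                            nxt = seq[sub_span[1]] if sub_span[1] < len(seq) else None
                        else:
                            nxt = _COMP[seq[sub_span[0] - 1]] if sub_span[0] > 0 else None
                        tail = _draw_tail(rng, tail_len, config.tail_weights, nxt)
                    full = sub_templated + tail
                    if not (config.size_min <= len(full) <= config.size_max):
                        continue  # size selection
                    variant += 1
                    reads.append(
                        SmallRNARead(
                            read_id=f"sim_{cls}_{i + 1:04d}.{variant}",
                            sequence=full,
                            count=n,
                            truth=ReadTruth(
                                true_class=cls,
                                methylated=methylated,
                                true_trim=trim,
                                true_tail=tail,
                                source_feature=feat.feature_id,
                            ),
                        )
                    )
    return _collapse(reads)


def _draw_len(rng: np.random.Generator, mean: float, dist: str) -> int:
    """Trim/tail length: 1 + Poisson(mean-1), or a constant."""
    if dist == "constant":
        return int(round(mean))
    if dist == "poisson":
        return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
    raise ValueError(f"unknown length distribution {dist!r}")


def _collapse(reads: list[SmallRNARead]) -> list[SmallRNARead]:
    """Merge species with identical sequence, summing copy counts."""
    by_seq: dict[str, SmallRNARead] = {}
    for read in reads:
        if read.sequence in by_seq:
            kept = by_seq[read.sequence]
            kept.count += read.count
        else:
            by_seq[read.sequence] = read
    return list(by_seq.values())


def apply_beta_elimination(
    reads: list[SmallRNARead],
    p_meth: float = 1.0,
    p_unmeth: float = 0.1,
    seed: int = 0,
) -> list[SmallRNARead]:
    """Simulate periodate oxidation / beta-elimination at the ligation step.

    Each copy survives adapter ligation independently with probability
    ``p_meth`` if its species carries a 3' 2'-O-methyl, else
    ``p_unmeth``. Species with no surviving copies are dropped. The
    input list is left untouched.
    """
    if not 0.0 <= p_unmeth <= p_meth <= 1.0:
        raise ValueError(
            f"need 0 <= p_unmeth <= p_meth <= 1 (methylation protects); got "
            f"p_meth={p_meth}, p_unmeth={p_unmeth}"
        )
    rng = np.random.default_rng(seed)
    out: list[SmallRNARead] = []
    for read in reads:
        if read.truth is None:
            raise ValueError(
                f"read {read.read_id} has no methylation truth; "
                "beta-elimination simulation requires simulated reads"
            )
        p = p_meth if read.truth.methylated else p_unmeth
        if p == 1.0:
            surviving = read.count
        else:
            surviving = int(rng.binomial(read.count, p))
        if surviving > 0:
            out.append(read.with_count(surviving))
    return out
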