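"""Core domain types for small RNA library analysis.

Coordinates are 0-based, half-open, stranded ('+'/'-') throughout the
package; GFF3 output converts to the 1-based closed convention of that
format. All sequences are stored in the DNA alphabet (U is normalised to
T on input).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Feature (locus) classes recognised by the classifier and simulator.
FEATURE_CLASSES = frozenset(
    {
        "mirna_mature",
        "pirna_locus",
        "sirna26g_ergo1_locus",
        "sirna26g_alg34_locus",
        "coding_locus",
        "xcluster_locus",
        "trigger_locus",
    }
)

#: Small RNA read classes; together they partition any library.
READ_CLASSES = (
    "miRNA",
    "piRNA_21U",
    "siRNA_22G",
    "siRNA_26G_ERGO1",
    "siRNA_26G_ALG34",
    "other",
    "unmapped",
)

#: Locus classes whose annotated interval represents a transcribed unit;
#: 22G siRNAs are antisense to these.
TRANSCRIPT_CLASSES = frozenset(
    {
        "coding_locus",
        "xcluster_locus",
        "trigger_locus",
        "sirna26g_ergo1_locus",
        "sirna26g_alg34_locus",
    }
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class Feature:
    """A stranded genomic interval with a locus class label."""

    contig: str
    start: int
    end: int
    strand: str
    cls: str
    feature_id: str
    mature_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be '+' or '-'")
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"feature {self.feature_id}: unknown class {self.cls!r}")
        if self.mature_length is not None and self.mature_length > self.end - self.start:
            raise ValueError(
                f"feature {self.feature_id}: mature_length exceeds interval"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceSet:
    """Reference sequences plus typed feature annotations.

    Ground truth for mapping and classification: ``sequences`` maps
    contig id to an ACGT string and ``features`` lists the annotated
    loci (miRNA matures, piRNA loci, 26G source loci, coding loci, the
    X-cluster and its trigger gene).
    """

    sequences: dict[str, str]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for feat in self.features:
            self._check_feature(feat)

    def _check_feature(self, feat: Feature) -> None:
        if feat.contig not in self.sequences:
            raise ValueError(f"feature {feat.feature_id}: unknown contig {feat.contig}")
        if feat.end > len(self.sequences[feat.contig]):
            raise ValueError(
                f"feature {feat.feature_id}: interval exceeds contig bounds"
            )

    def features_of_class(self, cls: str) -> list[Feature]:
        return [f for f in self.features if f.cls == cls]

    def feature_seq(self, feat: Feature) -> str:
        """Feature sequence, 5'->3' on the feature's own strand."""
        seq = self.sequences[feat.contig][feat.start : feat.end]
        return seq if feat.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class ReadTruth:
    """Hidden simulation ground truth attached to synthetic reads."""

    true_class: str
    methylated: bool
    true_trim: int = 0
    true_tail: str = ""
    source_feature: Optional[str] = None


@dataclass
class SmallRNARead:
    """One collapsed read species: sequence, copy count, optional truth."""

    read_id: str
    sequence: str
    count: int = 1
    truth: Optional[ReadTruth] = None

    def __post_init__(self) -> None:
        self.sequence = normalize_seq(self.sequence)
        if self.count < 1:
            raise ValueError(f"read {self.read_id}: count must be >= 1")
        if not (15 <= len(self.sequence) <= 35):
            raise ValueError(
                f"read {self.read_id}: length {len(self.sequence)} outside 15-35 nt"
            )

    def with_count(self, count: int) -> "SmallRNARead":
        new = replace(self)
        new.count = count
        return new


@dataclass(frozen=True)
class AlignmentRecord:
    """Placement of a read on the reference.

    ``templated_prefix_length`` is the number of 5' read nucleotides that
    match the genome at this placement; ``tail_sequence`` is the remaining
    3' suffix (empty for full-length matches). ``start`` is the leftmost
    genomic coordinate of the templated span on the forward strand.
    """

    read_id: str
    contig: str
    start: int
    strand: str
    templated_prefix_length: int
    tail_sequence: str = ""
    trim_length: Optional[int] = None
    feature_id: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval covered by the templated prefix."""
        return (self.start, self.start + self.templated_prefix_length)


@dataclass(frozen=True)
class ClassAssignment:
    read_id: str
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in READ_CLASSES:
            raise ValueError(f"unknown read class {self.cls!r}")


@dataclass(frozen=True)
class TailCall:
    """3' decomposition of a read: templated prefix, untemplated tail and
    (when the mature species length is annotated) trimmed length."""

    read_id: str
    contig: str
    start: int
    strand: str
    templated_prefix_length: int
    tail_sequence: str
    trim_length: Optional[int] = None
    feature_id: Optional[str] = None


@dataclass(frozen=True)
class EnrichmentResult:
    """Treated-vs-untreated abundance comparison for one feature or class."""

    unit_id: str
    rpm_untreated: float
    rpm_treated: float
    log2_ratio: float
    status: str
    pseudocount: float = 0.0
    flagged_zero: bool = False


@dataclass(frozen=True)
class DdCtResult:
    """Relative quantification by the 2^-ddCt method."""

    ct_target_condition: float
    ct_reference_condition: float
    ct_target_control: float
    ct_reference_control: float
    fold_change: float
    fold_range: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class GuideTargetSite:
    """Per-position pairing of a guide against a target window.

    ``states`` has one entry per guide position, 5'->3' (position 1 is
    the guide 5' nucleotide), each in {'WC', 'GU', 'MM', 'guide-bulge',
    'target-bulge'}. ``complementarity`` counts WC and GU positions as
    paired; ``complementarity_wc`` counts WC only.
    """

    guide_id: str
    target_id: str
    window_start: int
    window_end: int
    strand: str
    states: tuple[str, ...]
    complementarity: float
    complementarity_wc: float
    predicted_call: Optional[str] = None

    @property
    def state_string(self) -> str:
        """Compact one-letter encoding: W/G/M/b(guide-bulge)/B(target-bulge)."""
        code = {"WC": "W", "GU": "G", "MM": "M", "guide-bulge": "b", "target-bulge": "B"}
        return "".join(code[s] for s in self.states)
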