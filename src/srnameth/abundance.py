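"""Normalized abundance, beta-elimination enrichment and 2^-ddCt.

Libraries are normalized to reads per million (RPM); the denominator
is the library's genome-mapping copy total (a documented choice, since
"per million total reads" is ambiguous between raw and mapped totals —
both are derivable from the run manifest). Enrichment of a feature or
class in a beta-eliminated library over its untreated counterpart is
the log2 ratio of RPM values; methylated species are enriched
(methylation protects the 3' end from periodate oxidation, so their
copies survive adapter ligation), unmethylated species are depleted.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import pandas as pd

from .model import DdCtResult, EnrichmentResult, SmallRNARead


def rpm(count: float, library_total: float) -> float:
    """Reads-per-million normalization."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count * 1_000_000 / library_total


def feature_log2_ratio(rpm_treated: float, rpm_untreated: float, eps: float = 0.0) -> float:
    """log2((treated + eps) / (untreated + eps)); antisymmetric in its arguments."""
    num, den = rpm_treated + eps, rpm_untreated + eps
    if num <= 0 or den <= 0:
        raise ValueError("log2 ratio requires positive values (use a pseudocount)")
    return math.log2(num / den)


def call_status(log2_ratio: float, threshold: float = 0.0) -> str:
    """Enriched above +threshold, depleted below -threshold, else unchanged.

    With the default threshold of 0 the call is the strict sign; a
    ratio of exactly 0 is 'unchanged'.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if log2_ratio > threshold:
        return "enriched"
    if log2_ratio < -threshold:
        return "depleted"
    return "unchanged"


def percent_depletion(rpm_untreated: float, rpm_treated: float) -> float:
    """Percent loss of normalized signal after treatment.

    100 * (1 - treated/untreated); negative values mean enrichment.
    """
    if rpm_untreated <= 0:
        raise ValueError("untreated RPM must be positive")
    return 100.0 * (1.0 - rpm_treated / rpm_untreated)


def ddct_fold_change(
    ct_target_condition: float,
    ct_reference_condition: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative abundance by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) within each sample; ddCt is the
    condition dCt minus the control dCt; the fold change is 2^-ddCt.
    """
    ddct = (ct_target_condition - ct_reference_condition) - (
        ct_target_control - ct_reference_control
    )
    return 2.0 ** (-ddct)


def ddct_result(
    ct_target_condition: float,
    ct_reference_condition: float,
    ct_target_control: float,
    ct_reference_control: float,
    sd: Optional[float] = None,
) -> DdCtResult:
    """Full 2^-ddCt record, optionally with a +/-1 SD fold-change range."""
    fold = ddct_fold_change(
        ct_target_condition, ct_reference_condition, ct_target_control, ct_reference_control
    )
    ddct = -math.log2(fold)
    fold_range = None
    if sd is not None:
        fold_range = (2.0 ** (-(ddct + sd)), 2.0 ** (-(ddct - sd)))
    return DdCtResult(
        ct_target_condition=ct_target_condition,
        ct_reference_condition=ct_reference_condition,
        ct_target_control=ct_target_control,
        ct_reference_control=ct_reference_control,
        fold_change=fold,
        fold_range=fold_range,
    )


# ---------------------------------------------------------------------------
# library-level comparisons


def _copy_totals(reads: Iterable[SmallRNARead]) -> dict[str, int]:
    return {read.read_id: read.count for read in reads}


def mapped_total(reads: Iterable[SmallRNARead], assignments: dict[str, str]) -> int:
    """Total genome-mapping copies (the RPM denominator)."""
    return sum(
        read.count for read in reads if assignments.get(read.read_id) != "unmapped"
    )


def class_rpm(
    reads: Iterable[SmallRNARead],
    assignments: dict[str, str],
    cls: str,
    denominator: Optional[int] = None,
) -> float:
    """Summed RPM of one class. Denominator defaults to mapped copies."""
    reads = list(reads)
    if denominator is None:
        denominator = mapped_total(reads, assignments)
    total = sum(read.count for read in reads if assignments.get(read.read_id) == cls)
    return rpm(total, denominator)


def class_ratio(
    treated: Iterable[SmallRNARead],
    untreated: Iterable[SmallRNARead],
    cls: str,
    assignments_treated: dict[str, str],
    assignments_untreated: dict[str, str],
) -> Optional[float]:
    """Ratio of summed class RPM, treated over untreated.

    None (missing) when the class has no untreated signal.
    """
    rpm_u = class_rpm(untreated, assignments_untreated, cls)
    if rpm_u == 0:
        return None
    rpm_t = class_rpm(treated, assignments_treated, cls)
    return rpm_t / rpm_u


def class_ratio_table(
    treated: list[SmallRNARead],
    untreated: list[SmallRNARead],
    assignments_treated: dict[str, str],
    assignments_untreated: dict[str, str],
    classes: Optional[list[str]] = None,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-class RPM in both libraries with ratio, log2 ratio and status."""
    if classes is None:
        classes = sorted(
            {c for c in assignments_treated.values() if c != "unmapped"}
            | {c for c in assignments_untreated.values() if c != "unmapped"}
        )
    rows = []
    for cls in classes:
        rpm_u = class_rpm(untreated, assignments_untreated, cls)
        rpm_t = class_rpm(treated, assignments_treated, cls)
        ratio = (rpm_t / rpm_u) if rpm_u > 0 else float("nan")
        log2r = math.log2(ratio) if rpm_u > 0 and rpm_t > 0 else float("nan")
        status = call_status(log2r, threshold) if not math.isnan(log2r) else "missing"
        rows.append(
            {
                "class": cls,
                "rpm_untreated": rpm_u,
                "rpm_treated": rpm_t,
                "ratio": ratio,
                "log2_ratio": log2r,
                "status": status,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def feature_enrichment(
    counts_treated: dict[str, int],
    counts_untreated: dict[str, int],
    total_treated: int,
    total_untreated: int,
    threshold: float = 0.0,
) -> list[EnrichmentResult]:
    """Per-feature enrichment with the zero-handling pseudocount policy.

    Features observed in both libraries use eps = 0; a feature at zero
    in exactly one library uses eps = 1 RPM-equivalent and is flagged.
    Features absent from both are skipped.
    """
    units = sorted(set(counts_treated) | set(counts_untreated))
    results = []
    for unit in units:
        rpm_t = rpm(counts_treated.get(unit, 0), total_treated)
        rpm_u = rpm(counts_untreated.get(unit, 0), total_untreated)
        if rpm_t == 0 and rpm_u == 0:
            continue
        flagged = rpm_t == 0 or rpm_u == 0
        eps = 1.0 if flagged else 0.0
        log2r = feature_log2_ratio(rpm_t, rpm_u, eps=eps)
        results.append(
            EnrichmentResult(
                unit_id=unit,
                rpm_untreated=rpm_u,
                rpm_treated=rpm_t,
                log2_ratio=log2r,
                status=call_status(log2r, threshold),
                pseudocount=eps,
                flagged_zero=flagged,
            )
        )
    return results


def feature_copy_counts(
    reads: list[SmallRNARead],
    alignments: dict[str, list],
    features: list,
) -> dict[str, int]:
    """Copy counts attributed to features.

    A read's copies count once toward every feature its templated span
    overlaps (any strand), never more than once per feature.
    """
    from .mapping import _overlaps

    counts: dict[str, int] = {}
    by_id = {read.read_id: read.count for read in reads}
    for read_id, alns in alignments.items():
        seen: set[str] = set()
        for aln in alns:
            for feat in features:
                if feat.feature_id in seen:
                    continue
                if _overlaps(aln, feat):
                    counts[feat.feature_id] = counts.get(feat.feature_id, 0) + by_id.get(
                        read_id, 1
                    )
                    seen.add(feat.feature_id)
    return counts
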