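"""Guide-target complementarity scoring and silencing prediction.

A guide (siRNA/miRNA, given 5'->3') is aligned antiparallel against a
target window (given 5'->3' on the target transcript): guide position 1
(the 5' nucleotide) pairs with the 3'-most nucleotide of the window.
Pair states are Watson-Crick (WC), G:U wobble (GU) or mispair (MM);
G:U counts toward the complementarity fraction but is tracked
separately. A single bulged nucleotide on either side can be
accommodated and is recorded as a 'guide-bulge' (unpaired guide
nucleotide; the target window is one shorter) or 'target-bulge'
(looped-out target nucleotide; the window is one longer).

Predicted silencing uses a positional rule table derived from sensor
mutagenesis of an endogenous 22-nt siRNA: near-perfect pairing is
required at the guide 5' end (the seed-like region), a block of central
mispairs abolishes or weakens silencing depending on position, single
disruptions around position 13 are tolerated, and pairing at the guide
3' terminus is dispensable.
"""

from __future__ import annotations

from typing import Optional

from .model import GuideTargetSite, normalize_seq, revcomp

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def pair_state(guide_nt: str, target_nt: str) -> str:
    """Classify one guide:target nucleotide pair as WC, GU or MM."""
    pair = (normalize_seq(guide_nt), normalize_seq(target_nt))
    if pair in _WC:
        return "WC"
    if pair in _GU:
        return "GU"
    return "MM"


def _ungapped_states(guide: str, window: str) -> tuple[str, ...]:
    L = len(guide)
    return tuple(pair_state(guide[i], window[L - 1 - i]) for i in range(L))


def _score(states: tuple[str, ...]) -> int:
    return sum(1 for s in states if s in ("WC", "GU"))


def _bulge_states(guide: str, window: str, bulge_pos: int, kind: str) -> tuple[str, ...]:
    """State vector with one bulge at guide position ``bulge_pos`` (1-based).

    For a guide-bulge, guide position b is unpaired and the remaining
    guide nucleotides pair with the (L-1)-nt window. For a target-bulge,
    one target nucleotide loops out opposite guide position b; position
    b is marked 'target-bulge' and the flanking guide nucleotides pair
    with the rest of the (L+1)-nt window.
    """
    L = len(guide)
    t = window[::-1]  # t[j] is the target nt opposite guide position j+1
    states: list[str] = []
    if kind == "guide-bulge":
        for i in range(L):
            pos = i + 1
            if pos == bulge_pos:
                states.append("guide-bulge")
            elif pos < bulge_pos:
                states.append(pair_state(guide[i], t[i]))
            else:
                states.append(pair_state(guide[i], t[i - 1]))
    elif kind == "target-bulge":
        for i in range(L):
            pos = i + 1
            if pos == bulge_pos:
                states.append("target-bulge")
            elif pos < bulge_pos:
                states.append(pair_state(guide[i], t[i]))
            else:
                states.append(pair_state(guide[i], t[i + 1]))
    else:
        raise ValueError(f"unknown bulge kind {kind!r}")
    return tuple(states)


def align_guide(
    guide: str,
    window: str,
    max_bulges: int = 1,
    guide_id: str = "guide",
    target_id: str = "target",
    window_start: int = 0,
    strand: str = "+",
) -> GuideTargetSite:
    """Align a guide against a target window and return the site.

    Equal lengths give the ungapped state vector. A length difference
    of one is resolved by the single bulge placement maximising the
    paired (WC+GU) count, ties broken toward the 3'-most guide
    position. Larger differences than ``max_bulges`` are an error.
    """
    guide = normalize_seq(guide)
    window = normalize_seq(window)
    L = len(guide)
    diff = len(window) - L
    if abs(diff) > max_bulges:
        raise ValueError(
            f"window length {len(window)} differs from guide length {L} by more "
            f"than max_bulges={max_bulges}"
        )
    if diff == 0:
        states = _ungapped_states(guide, window)
    else:
        kind = "target-bulge" if diff == 1 else "guide-bulge"
        best: Optional[tuple[str, ...]] = None
        best_key = (-1, -1)
        for pos in range(1, L + 1):
            cand = _bulge_states(guide, window, pos, kind)
            key = (_score(cand), pos)  # ties -> 3'-most bulge
            if key > best_key:
                best, best_key = cand, key
        assert best is not None
        states = best
    paired = _score(states)
    wc_only = sum(1 for s in states if s == "WC")
    return GuideTargetSite(
        guide_id=guide_id,
        target_id=target_id,
        window_start=window_start,
        window_end=window_start + len(window),
        strand=strand,
        states=states,
        complementarity=paired / L,
        complementarity_wc=wc_only / L,
    )


def _max_contiguous_mm(states: tuple[str, ...], lo: int, hi: int) -> int:
    """Longest run of MM states lying entirely within guide positions [lo, hi]."""
    best = run = 0
    for pos in range(lo, hi + 1):
        if pos <= len(states) and states[pos - 1] == "MM":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def predict_silencing(site: GuideTargetSite, threshold: float = 0.69) -> str:
    """Predict the silencing outcome of a site: functional, partial or
    nonfunctional.

    Rules, evaluated in order on the per-position state vector:

    1. any mispair or bulge within guide positions 1-5 -> nonfunctional
       (5'/seed-region pairing is essential);
    2. >=3 contiguous mispairs within 12-14 -> nonfunctional;
    3. >=3 contiguous mispairs within 9-11 -> partial;
    4. a single target-bulge within 13-15 -> partial;
    5. a single mispair at 13, or a single guide-bulge at 13 -> functional;
    6. mispairs confined to positions 20-22 -> functional (3'-terminal
       pairing is dispensable);
    7. otherwise functional iff the complementarity fraction (G:U
       counted as paired) reaches ``threshold``.
    """
    states = site.states
    L = len(states)
    for pos in range(1, min(5, L) + 1):
        if states[pos - 1] != "WC" and states[pos - 1] != "GU":
            return "nonfunctional"
    if _max_contiguous_mm(states, 12, 14) >= 3:
        return "nonfunctional"
    if _max_contiguous_mm(states, 9, 11) >= 3:
        return "partial"
    bulge_positions = [i + 1 for i, s in enumerate(states) if s.endswith("bulge")]
    mm_positions = [i + 1 for i, s in enumerate(states) if s == "MM"]
    if (
        len(bulge_positions) == 1
        and states[bulge_positions[0] - 1] == "target-bulge"
        and 13 <= bulge_positions[0] <= 15
        and not mm_positions
    ):
        return "partial"
    if not bulge_positions and mm_positions == [13]:
        return "functional"
    if (
        len(bulge_positions) == 1
        and states[bulge_positions[0] - 1] == "guide-bulge"
        and bulge_positions[0] == 13
        and not mm_positions
    ):
        return "functional"
    if mm_positions and not bulge_positions and all(20 <= p <= 22 for p in mm_positions):
        return "functional"
    return "functional" if site.complementarity >= threshold else "nonfunctional"


def call_site(site: GuideTargetSite, threshold: float = 0.69) -> GuideTargetSite:
    """Attach the predicted silencing call to a site."""
    from dataclasses import replace

    return replace(site, predicted_call=predict_silencing(site, threshold))


def scan_transcript(
    guide: str,
    transcript: str,
    min_complementarity: float = 0.69,
    max_bulges: int = 0,
    guide_id: str = "guide",
    target_id: str = "target",
    count_gu_as_paired: bool = True,
) -> list[GuideTargetSite]:
    """Slide the guide over all transcript windows and keep target sites.

    Windows whose complementarity fraction reaches ``min_complementarity``
    are retained (with ``count_gu_as_paired=False`` the stricter
    WC-only fraction is used instead); overlapping candidates are
    reduced to local maxima (non-maximum suppression on the fraction,
    ties to the leftmost window). Sites come back sorted by position
    with silencing calls attached.
    """
    guide = normalize_seq(guide)
    transcript = normalize_seq(transcript)
    L = len(guide)
    lengths = {L}
    if max_bulges >= 1:
        lengths |= {L - 1, L + 1}
    candidates: list[GuideTargetSite] = []
    for wlen in sorted(lengths):
        for start in range(0, len(transcript) - wlen + 1):
            site = align_guide(
                guide,
                transcript[start : start + wlen],
                max_bulges=max_bulges,
                guide_id=guide_id,
                target_id=target_id,
                window_start=start,
            )
            frac = site.complementarity if count_gu_as_paired else site.complementarity_wc
            if frac >= min_complementarity:
                candidates.append(site)
    # non-maximum suppression over overlapping windows
    key = (lambda s: s.complementarity) if count_gu_as_paired else (
        lambda s: s.complementarity_wc
    )
    kept: list[GuideTargetSite] = []
    for site in sorted(candidates, key=lambda s: (-key(s), s.window_start)):
        if all(
            site.window_end <= other.window_start or site.window_start >= other.window_end
            for other in kept
        ):
            kept.append(site)
    kept.sort(key=lambda s: s.window_start)
    return [call_site(s) for s in kept]


# ---------------------------------------------------------------------------
# sensor mutagenesis variants


def _mutate_mm(window: str, guide: str, positions: list[int]) -> str:
    """Force mispairs at the given guide positions by substituting the
    partner target nucleotide with a copy of the guide nucleotide
    (identical nucleotides never pair, even as wobbles)."""
    L = len(guide)
    w = list(window)
    for pos in positions:
        w[L - pos] = guide[pos - 1]
    return "".join(w)


def sensor_variant_sites(guide: Optional[str] = None) -> dict[str, GuideTargetSite]:
    """Target-site variants of the siRNA sensor mutagenesis panel.

    Builds, for a 22-nt guide (default: an arbitrary 5'G 22-mer), the
    ten sensor target windows — wild type, substitution blocks at guide
    positions 1-3, 4-5, 9-11, 12-14 and 20-22, a single substitution at
    13, and single-nucleotide deletion/insertion variants (4del, 13del,
    13ins) — and returns the aligned sites keyed by variant name.
    """
    if guide is None:
        guide = "GTAGATCGGAAGTCCAAGTTCA"  # synthetic 22-mer, 5' G
    guide = normalize_seq(guide)
    L = len(guide)
    wild = revcomp(guide)
    windows: dict[str, str] = {
        "wild_type": wild,
        "1-3sub": _mutate_mm(wild, guide, [1, 2, 3]),
        "4-5sub": _mutate_mm(wild, guide, [4, 5]),
        "9-11sub": _mutate_mm(wild, guide, [9, 10, 11]),
        "12-14sub": _mutate_mm(wild, guide, [12, 13, 14]),
        "13sub": _mutate_mm(wild, guide, [13]),
        "20-22sub": _mutate_mm(wild, guide, [20, 21, 22]),
        # deletion of the target nt pairing guide position p -> guide bulge
        "4del": wild[: L - 4] + wild[L - 3 :],
        "13del": wild[: L - 13] + wild[L - 12 :],
        # insertion of one target nt between the partners of 13 and 14
        "13ins": wild[: L - 13] + "A" + wild[L - 13 :],
    }
    return {
        name: call_site(align_guide(guide, window, max_bulges=1, target_id=name))
        for name, window in windows.items()
    }


#: Qualitative outcomes of the sensor panel used as a fidelity check.
SENSOR_EXPECTED_CALLS = {
    "wild_type": "functional",
    "13sub": "functional",
    "13del": "functional",
    "20-22sub": "functional",
    "9-11sub": "partial",
    "13ins": "partial",
    "1-3sub": "nonfunctional",
    "4-5sub": "nonfunctional",
    "4del": "nonfunctional",
    "12-14sub": "nonfunctional",
}
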