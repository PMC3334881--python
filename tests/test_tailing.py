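"""3' prefix/tail decomposition against an exhaustive split oracle,
trim measurement and per-class tailing proportions."""

import numpy as np
import pytest

from srnameth import (
    ClassSim,
    LibraryConfig,
    ReferenceSet,
    SmallRNARead,
    classify_library,
    resolve_3prime,
    revcomp,
    simulate_library,
    tail_table,
    tailed_proportion,
    trim_length,
)
from srnameth.tailing import call_library


def exhaustive_split_oracle(seq: str, ref: ReferenceSet, min_prefix: int = 15):
    """Enumerate every (prefix, suffix) split and every genomic offset;
    return placements of the longest exactly-matching prefix."""
    found = {}
    for k in range(min_prefix, len(seq) + 1):
        prefix = seq[:k]
        rc = revcomp(prefix)
        for contig in ref.sequences:
            genome = ref.sequences[contig]
            for start in range(len(genome) - k + 1):
                if genome[start : start + k] == prefix:
                    found.setdefault(k, []).append((contig, start, "+"))
                if genome[start : start + k] == rc:
                    found.setdefault(k, []).append((contig, start, "-"))
    if not found:
        return []
    k = max(found)
    return [(c, s, st, k, seq[k:]) for c, s, st in sorted(found[k])]


@pytest.fixture(scope="module")
def toy_ref():
    rng = np.random.default_rng(99)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    return ReferenceSet(sequences={"c1": seq}, features=[])


def test_tailed_read_decomposed(toy_ref):
    genome = toy_ref.sequences["c1"]
    body = genome[50:72]
    nxt = genome[72]
    tail_nt = next(n for n in "ACGT" if n != nxt)
    calls = resolve_3prime(SmallRNARead("r", body + tail_nt * 2), toy_ref)
    (call,) = calls
    assert call.templated_prefix_length == 22
    assert call.tail_sequence == tail_nt * 2
    assert (call.contig, call.start, call.strand) == ("c1", 50, "+")


def test_exact_read_has_empty_tail(toy_ref):
    calls = resolve_3prime(SmallRNARead("r", toy_ref.sequences["c1"][50:72]), toy_ref)
    assert calls[0].tail_sequence == ""


def test_templated_first_tail_nt_extends_prefix(toy_ref):
    """A 'tail' starting with the next genomic base is templated, so the
    prefix absorbs it (maximality) and only the rest remains as tail."""
    genome = toy_ref.sequences["c1"]
    body = genome[100:120]
    nxt = genome[120]
    bad = next(n for n in "ACGT" if n != genome[121])
    calls = resolve_3prime(SmallRNARead("r", body + nxt + bad), toy_ref)
    (call,) = calls
    assert call.templated_prefix_length == 21
    assert call.tail_sequence == bad


def test_agrees_with_exhaustive_split_oracle(ref):
    """Simulated reads with tails/trims decompose exactly as the
    brute-force enumeration of all (prefix, suffix) splits."""
    cfg = LibraryConfig(
        classes={
            "siRNA_26G_ERGO1": ClassSim(
                80, 26, "G", 10.0, tail_rate=0.5, trim_rate=0.3, trim_len_mean=2
            ),
            "piRNA_21U": ClassSim(40, 21, "T", 10.0, tail_rate=0.3),
        }
    )
    lib = simulate_library(ref, cfg, seed=31)
    assert len(lib) > 100
    for read in lib:
        got = [
            (c.contig, c.start, c.strand, c.templated_prefix_length, c.tail_sequence)
            for c in resolve_3prime(read, ref)
        ]
        assert got == exhaustive_split_oracle(read.sequence, ref), read.read_id


def test_unplaced_read_returns_empty(toy_ref):
    assert resolve_3prime(SmallRNARead("r", "A" * 22), toy_ref) == []


def test_maximality_no_templated_tail_start(ref, library):
    for read in library[:80]:
        for call in resolve_3prime(read, ref):
            if not call.tail_sequence:
                continue
            genome = ref.sequences[call.contig]
            if call.strand == "+":
                pos = call.start + call.templated_prefix_length
                nxt = genome[pos] if pos < len(genome) else None
            else:
                nxt = (
                    revcomp(genome[call.start - 1]) if call.start > 0 else None
                )
            assert nxt != call.tail_sequence[0]


def test_prefix_plus_tail_conserves_length(ref, library):
    for read in library[:80]:
        for call in resolve_3prime(read, ref):
            assert call.templated_prefix_length + len(call.tail_sequence) == len(
                read.sequence
            )


def test_raising_min_prefix_never_places_more(ref, library):
    placed = []
    for mp in (15, 18, 21):
        n = sum(1 for r in library if resolve_3prime(r, ref, min_prefix=mp))
        placed.append(n)
    assert placed == sorted(placed, reverse=True)


class TestTrimLength:
    def test_two_nt_trim(self):
        from srnameth.model import TailCall

        call = TailCall("r", "c", 0, "+", 24, "")
        assert trim_length(call, 26) == 2

    def test_full_length_no_trim(self):
        from srnameth.model import TailCall

        call = TailCall("r", "c", 0, "+", 26, "")
        assert trim_length(call, 26) == 0
        assert trim_length(call, None) is None

    def test_simulated_trims_recovered(self, ref):
        cfg = LibraryConfig(
            classes={
                "siRNA_26G_ERGO1": ClassSim(60, 26, "G", 10.0, trim_rate=0.4, trim_len_mean=2)
            }
        )
        lib = simulate_library(ref, cfg, seed=33)
        trimmed = [r for r in lib if r.truth.true_trim and not r.truth.true_tail]
        assert trimmed
        for read in trimmed:
            calls = resolve_3prime(read, ref)
            if len(calls) != 1:
                continue  # ambiguous placements excluded by design
            assert trim_length(calls[0], 26) == read.truth.true_trim


class TestTailedProportion:
    def test_simple_fraction(self):
        from srnameth.model import TailCall

        reads = [SmallRNARead(f"r{i}", "G" * 22, 1) for i in range(10)]
        calls = {
            f"r{i}": TailCall(f"r{i}", "c", 0, "+", 22, "T" if i < 3 else "")
            for i in range(10)
        }
        asg = {f"r{i}": "siRNA_22G" for i in range(10)}
        assert tailed_proportion(calls, reads, asg, "siRNA_22G") == pytest.approx(0.3)

    def test_no_tails_zero(self, ref):
        cfg = LibraryConfig(classes={"piRNA_21U": ClassSim(20, 21, "T", 10.0)})
        lib = simulate_library(ref, cfg, seed=35)
        asg, _ = classify_library(lib, ref)
        calls, _ = call_library(lib, ref)
        assert tailed_proportion(calls, lib, asg, "piRNA_21U") == 0.0

    def test_recovers_class_specific_rates(self, ref):
        """Configured per-class tailing rates come back within 3 binomial
        SD of the estimate (26G high, miRNA low, as in this system)."""
        rates = {"miRNA": 0.05, "siRNA_26G_ERGO1": 0.4}
        cfg = LibraryConfig(
            classes={
                "miRNA": ClassSim(10, None, None, 200.0, tail_rate=rates["miRNA"]),
                "siRNA_26G_ERGO1": ClassSim(
                    80, 26, "G", 25.0, tail_rate=rates["siRNA_26G_ERGO1"]
                ),
            }
        )
        lib = simulate_library(ref, cfg, seed=36)
        asg, _ = classify_library(lib, ref)
        calls, unplaced = call_library(lib, ref)
        assert not unplaced
        table = tail_table(calls, lib, asg)
        for cls, rate in rates.items():
            n = table.loc[cls, "placed_copies"]
            got = table.loc[cls, "tailed_proportion"]
            assert n > 1000
            assert abs(got - rate) < 3 * np.sqrt(rate * (1 - rate) / n), cls
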