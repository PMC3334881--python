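"""Exact-match mapping, class assignment and profiles against
brute-force oracles and simulation truth."""

from collections import Counter

import numpy as np
import pytest

from srnameth import (
    Feature,
    ReferenceSet,
    SmallRNARead,
    classify_library,
    classify_read,
    class_copy_totals,
    coverage_track,
    map_read,
    revcomp,
    size_firstnt_profile,
    xcluster_transcript,
)


def naive_placements(seq: str, ref: ReferenceSet, min_prefix: int = 15):
    """Independent oracle: position-wise comparison of the read against
    every genomic offset on both strands; returns the placements of the
    longest matching prefix (>= min_prefix)."""
    best_k, hits = 0, []
    for contig in ref.sequences:
        genome = ref.sequences[contig]
        for start in range(len(genome)):
            # forward: read prefix equals genome going right
            k = 0
            while (
                k < len(seq) and start + k < len(genome) and genome[start + k] == seq[k]
            ):
                k += 1
            if k >= min_prefix:
                if k > best_k:
                    best_k, hits = k, []
                if k == best_k:
                    hits.append((contig, start, "+", k))
            # reverse: read prefix equals revcomp of genome going left from `start`
            k = 0
            while (
                k < len(seq)
                and start - k >= 0
                and genome[start - k] == "TGCA"["ACGT".index(seq[k])]
            ):
                k += 1
            if k >= min_prefix:
                if k > best_k:
                    best_k, hits = k, []
                if k == best_k:
                    hits.append((contig, start - k + 1, "-", k))
    return sorted(set(hits))


@pytest.fixture(scope="module")
def toy_ref():
    rng = np.random.default_rng(77)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
    return ReferenceSet(sequences={"c1": seq}, features=[])


def test_unique_forward_match(toy_ref):
    seq = toy_ref.sequences["c1"][100:122]
    read = SmallRNARead("r", seq)
    alns = map_read(read, toy_ref)
    assert len(alns) == 1
    aln = alns[0]
    assert (aln.contig, aln.start, aln.strand) == ("c1", 100, "+")
    assert aln.tail_sequence == "" and aln.templated_prefix_length == 22


def test_reverse_strand_match(toy_ref):
    window = toy_ref.sequences["c1"][200:222]
    read = SmallRNARead("r", revcomp(window))
    alns = map_read(read, toy_ref)
    assert [(a.start, a.strand) for a in alns] == [(200, "-")]


def test_multimapper_motif_has_seven_placements(ref):
    """The antisense 22-mer of the repeated X-cluster motif places at
    every motif copy; count and coordinates match brute-force search."""
    tx = xcluster_transcript(ref)
    motif = Counter(tx[i : i + 26] for i in range(len(tx) - 25)).most_common(1)[0][0]
    read = SmallRNARead("sir1", revcomp(motif)[:22])
    alns = map_read(read, ref)
    oracle = naive_placements(read.sequence, ref)
    assert len(alns) == 7
    assert [(a.contig, a.start, a.strand, a.templated_prefix_length) for a in alns] == oracle


def test_mapper_agrees_with_oracle_on_random_reads(ref):
    """200 random reads (genomic windows, reverse complements, tailed
    variants, unmappable randoms) place identically to the oracle."""
    rng = np.random.default_rng(5)
    contigs = sorted(ref.sequences)
    for _ in range(200):
        kind = rng.integers(0, 4)
        if kind == 3:
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 22)])
        else:
            contig = contigs[rng.integers(0, len(contigs))]
            genome = ref.sequences[contig]
            L = int(rng.integers(18, 27))
            s = int(rng.integers(0, len(genome) - L))
            seq = genome[s : s + L]
            if kind == 1:
                seq = revcomp(seq)
            if kind == 2:
                seq = seq[: L - 2] + "".join(
                    np.array(list("ACGT"))[rng.integers(0, 4, 2)]
                )
        read = SmallRNARead(f"rnd", seq)
        got = [
            (a.contig, a.start, a.strand, a.templated_prefix_length)
            for a in map_read(read, ref)
        ]
        assert got == naive_placements(seq, ref), seq


def test_empty_reference_rejected():
    with pytest.raises(ValueError, match="empty reference"):
        map_read(SmallRNARead("r", "ACGTACGTACGTACGTACGT"), ReferenceSet({}, []))


class TestClassifyRead:
    def test_pirna_geometry(self, ref):
        feat = ref.features_of_class("pirna_locus")[0]
        read = SmallRNARead("p", ref.feature_seq(feat))
        alns = map_read(read, ref)
        assert classify_read(alns, ref.features, read).cls == "piRNA_21U"

    def test_22g_antisense_to_coding(self, ref):
        feat = next(
            f for f in ref.features_of_class("coding_locus") if f.strand == "+"
        )
        genome = ref.sequences[feat.contig]
        start = next(
            s
            for s in range(feat.start, feat.end - 22)
            if genome[s + 21] == "C"
        )
        read = SmallRNARead("s", revcomp(genome[start : start + 22]))
        alns = map_read(read, ref)
        assert classify_read(alns, ref.features, read).cls == "siRNA_22G"

    def test_unmapped(self, ref):
        read = SmallRNARead("u", "TTTTTTTTTTACCCCCCCCCGA")
        assert classify_read([], ref.features, read).cls == "unmapped"

    def test_mirna_annotation_wins(self, ref):
        feat = ref.features_of_class("mirna_mature")[0]
        read = SmallRNARead("m", ref.feature_seq(feat))
        alns = map_read(read, ref)
        assert classify_read(alns, ref.features, read).cls == "miRNA"


def test_classes_partition_library_copies(ref, library):
    assignments, _ = classify_library(library, ref)
    totals = class_copy_totals(library, assignments)
    assert sum(totals.values()) == sum(r.count for r in library)


def test_classification_recovers_simulation_truth(ref, library):
    """>= 99% of simulated copies are assigned their true class."""
    assignments, _ = classify_library(library, ref)
    good = sum(r.count for r in library if assignments[r.read_id] == r.truth.true_class)
    assert good / sum(r.count for r in library) >= 0.99


class TestSizeProfile:
    def test_single_cell(self):
        reads = [SmallRNARead(f"r{i}", "T" + "ACGTC" * 4, 10) for i in range(5)]
        mat = size_firstnt_profile(reads)
        assert mat.loc[21, "U"] == 50
        assert mat.values.sum() == 50

    def test_empty_library_all_zero(self):
        assert size_firstnt_profile([]).values.sum() == 0

    def test_row_sums_match_independent_tally(self, library):
        mat = size_firstnt_profile(library)
        tally = Counter()
        for r in library:
            if 18 <= len(r.sequence) <= 28:
                tally[len(r.sequence)] += r.count
        for length in mat.index:
            assert mat.loc[length].sum() == tally.get(length, 0)


class TestCoverageTrack:
    def test_single_read_block(self, toy_ref):
        feat = Feature("c1", 0, 50, "+", "coding_locus", "g")
        seq = toy_ref.sequences["c1"][10:32]
        read = SmallRNARead("r", seq, 3)
        alns = map_read(read, toy_ref)
        track = coverage_track(alns, feat, {"r": 3})
        assert len(track) == 50
        assert list(np.flatnonzero(track)) == list(range(10, 32))
        assert set(track[10:32]) == {3}

    def test_no_reads_zero_track(self, toy_ref):
        feat = Feature("c1", 0, 40, "+", "coding_locus", "g")
        assert coverage_track([], feat, {}).sum() == 0

    def test_totals_match_per_position_recount(self, ref, library):
        feat = ref.features_of_class("xcluster_locus")[0]
        assignments, alignments = classify_library(library, ref)
        alns = [a for read_alns in alignments.values() for a in read_alns]
        counts = {r.read_id: r.count for r in library}
        track = coverage_track(alns, feat, counts)
        # independent recount per position
        for pos in range(0, len(feat), 37):
            g = feat.start + pos
            expect = sum(
                counts[a.read_id]
                for a in alns
                if a.contig == feat.contig and a.span[0] <= g < a.span[1]
            )
            assert track[pos] == expect
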