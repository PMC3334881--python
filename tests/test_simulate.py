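"""Synthetic reference / library generator: construction contracts,
determinism, and the beta-elimination treatment model."""

from collections import Counter
from pathlib import Path

import numpy as np
import pytest

from srnameth import (
    ClassSim,
    LibraryConfig,
    ReferenceSpec,
    apply_beta_elimination,
    build_reference,
    simulate_library,
    trigger_guide,
    xcluster_transcript,
)
from srnameth.io import write_gff3, write_reference_fasta
from srnameth.simulate import SizingError


@pytest.mark.parametrize("n_copies", [1, 3, 7])
def test_xcluster_contains_exactly_n_motif_copies(n_copies):
    """The repeated 26-mer appears exactly n times in the X-cluster
    transcript (independently counted over all windows)."""
    ref = build_reference(ReferenceSpec(n_motif_copies=n_copies), seed=1)
    tx = xcluster_transcript(ref)
    windows = Counter(tx[i : i + 26] for i in range(len(tx) - 25))
    motif, count = windows.most_common(1)[0]
    if n_copies == 1:
        assert max(windows.values()) == 1
    else:
        assert count == n_copies
        # no second 26-mer repeats
        assert list(windows.values()).count(count) == 1


def test_zero_pirna_loci_requested(ref):
    no_pirna = build_reference(ReferenceSpec(n_pirna=0), seed=1)
    assert no_pirna.features_of_class("pirna_locus") == []
    assert ref.features_of_class("pirna_locus")  # default has them


def test_reference_determinism_byte_identical(tmp_path):
    spec = ReferenceSpec()
    for tag in ("a", "b"):
        r = build_reference(spec, seed=42)
        write_reference_fasta(r, tmp_path / f"{tag}.fa")
        write_gff3(r, tmp_path / f"{tag}.gff3")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()


def test_oversized_locus_request_rejected():
    with pytest.raises(SizingError):
        build_reference(ReferenceSpec(contig_length=100), seed=1)


def test_trigger_guide_partial_complementarity(ref):
    """The trigger guide is 26 nt, 5'G, and pairs with the motif at
    18/26 positions (G:U counted as paired)."""
    from srnameth import align_guide

    guide = trigger_guide(ref)
    assert len(guide) == 26 and guide[0] == "G"
    tx = xcluster_transcript(ref)
    windows = Counter(tx[i : i + 26] for i in range(len(tx) - 25))
    motif = windows.most_common(1)[0][0]
    site = align_guide(guide, motif)
    assert site.complementarity == pytest.approx(18 / 26)
    assert site.states.count("GU") == 2
    assert [i + 1 for i, s in enumerate(site.states) if s == "MM"][:3] == [11, 12, 13]


def test_pirna_only_library_forces_class_geometry(ref):
    cfg = LibraryConfig(classes={"piRNA_21U": ClassSim(50, 21, "T", 20.0, 1.0)})
    lib = simulate_library(ref, cfg, seed=2)
    assert len(lib) == 50
    assert all(len(r.sequence) == 21 and r.sequence[0] == "T" for r in lib)
    assert all(r.truth.true_class == "piRNA_21U" for r in lib)


def test_tail_rate_one_constant_length(ref):
    cfg = LibraryConfig(
        classes={
            "siRNA_22G": ClassSim(
                30, 22, "G", 20.0, tail_rate=1.0, tail_len_mean=2, tail_len_dist="constant"
            )
        }
    )
    lib = simulate_library(ref, cfg, seed=3)
    assert lib and all(len(r.truth.true_tail) == 2 for r in lib)
    assert all(len(r.sequence) == 24 for r in lib)


def test_tailed_copy_fraction_binomial(ref):
    """Tailed-copy fraction at rate 0.3 over ~1e4 copies lies within
    3 binomial standard deviations (independent closed-form CI)."""
    cfg = LibraryConfig(
        classes={"siRNA_22G": ClassSim(100, 22, "G", 100.0, tail_rate=0.3)}
    )
    lib = simulate_library(ref, cfg, seed=4)
    n = sum(r.count for r in lib)
    tailed = sum(r.count for r in lib if r.truth.true_tail)
    assert n > 5000
    assert abs(tailed / n - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)


def test_requesting_class_without_locus_errors():
    ref = build_reference(ReferenceSpec(n_pirna=0), seed=1)
    cfg = LibraryConfig(classes={"piRNA_21U": ClassSim(5, 21, "T")})
    with pytest.raises(ValueError, match="pirna_locus"):
        simulate_library(ref, cfg, seed=1)


def test_untailed_reads_map_exactly_to_source(ref, library):
    """Truth consistency: every species without tail or trim occurs
    verbatim in the reference (brute-force string search, either strand)."""
    from srnameth import revcomp

    genome = list(ref.sequences.values())
    for read in library:
        if read.truth.true_tail == "" and read.truth.true_trim == 0:
            assert any(
                read.sequence in g or revcomp(read.sequence) in g for g in genome
            ), read.read_id


class TestBetaElimination:
    def test_full_protection_no_residual(self, library):
        treated = apply_beta_elimination(library, p_meth=1.0, p_unmeth=0.0, seed=1)
        expect = {r.read_id: r.count for r in library if r.truth.methylated}
        assert {r.read_id: r.count for r in treated} == expect

    def test_identity_when_everything_survives(self, library):
        treated = apply_beta_elimination(library, p_meth=1.0, p_unmeth=1.0, seed=1)
        assert [(r.read_id, r.count) for r in treated] == [
            (r.read_id, r.count) for r in library
        ]

    def test_residual_survival_binomial(self, ref):
        cfg = LibraryConfig(
            classes={"siRNA_22G": ClassSim(100, 22, "G", 100.0, meth_prob=0.0)}
        )
        lib = simulate_library(ref, cfg, seed=5)
        n = sum(r.count for r in lib)
        treated = apply_beta_elimination(lib, p_meth=1.0, p_unmeth=0.1, seed=6)
        surviving = sum(r.count for r in treated)
        assert abs(surviving - 0.1 * n) < 3 * np.sqrt(n * 0.1 * 0.9)

    def test_never_increases_counts_and_preserves_input(self, library):
        before = [(r.read_id, r.count) for r in library]
        treated = apply_beta_elimination(library, p_meth=0.8, p_unmeth=0.2, seed=7)
        by_id = {r.read_id: r.count for r in library}
        assert all(r.count <= by_id[r.read_id] for r in treated)
        assert [(r.read_id, r.count) for r in library] == before

    def test_inverted_probabilities_rejected(self, library):
        with pytest.raises(ValueError, match="protect"):
            apply_beta_elimination(library, p_meth=0.2, p_unmeth=0.9, seed=1)


def test_library_determinism(ref):
    a = simulate_library(ref, LibraryConfig(), seed=9)
    b = simulate_library(ref, LibraryConfig(), seed=9)
    assert [(r.read_id, r.sequence, r.count) for r in a] == [
        (r.read_id, r.sequence, r.count) for r in b
    ]


def test_size_selection_window(ref):
    lib = simulate_library(ref, LibraryConfig(size_min=18, size_max=28), seed=10)
    assert all(18 <= len(r.sequence) <= 28 for r in lib)
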