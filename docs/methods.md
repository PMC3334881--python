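# Methods

## The treatment model

Periodate oxidation followed by β-elimination removes the 3′-terminal
nucleoside of an RNA whose 3′ ribose carries free 2′,3′-hydroxyls, leaving a
3′ phosphate that cannot be ligated to a sequencing adapter. A 3′-terminal
2′-O-methyl blocks the oxidation. We model the treatment **at the ligation
step**: each copy of a species survives into the treated library
independently with probability `p_meth` (methylated 3′ end) or `p_unmeth`
(unmethylated), and species with no surviving copies disappear. The 1-nt
shortening itself is not represented in the output reads, because shortened
molecules are unligatable and therefore unobservable; the library-level
observable is depletion, which the copy-dropout model captures directly.

Defaults: `p_meth = 1.0` (methylation fully protects) and `p_unmeth = 0.1`.
Treatment in practice depletes rather than eliminates unmethylated species —
an unmethylated 22G siRNA retains roughly a fifth of its normalized signal —
so a residual ligation probability of 0.1 is a realistic, deliberately
conservative choice. It is a free model parameter, not a measured constant,
and the enrichment direction (not its exact magnitude) is the claim the
package tests. The model constraint `p_unmeth ≤ p_meth` is enforced
(methylation protects; the reverse is chemically meaningless here).

## The synthetic data generator

`build_reference` lays out typed loci on three contigs: miRNA matures
(22 nt, annotated), piRNA loci (21 nt, genomic 5′ T on the annotated
strand), ERGO-1-class and ALG-3/4-class 26G source loci (200 nt), coding
loci (300 nt, both strands represented), an X-cluster locus carrying
`n_motif_copies` exact copies of one 26-nt target motif separated by 20-nt
spacers, and a trigger gene whose annotated 26-nt species is a 5′ G guide
partially complementary to that motif. The guide–motif pairing is built
with Watson–Crick pairs at guide positions 1–10 and 14–21 except G:U
wobbles at 5 and 16, and mispairs at 11–13 and 22–26: 18 of 26 positions
paired, i.e. 69.2 % complementarity with wobbles counted as pairing.

Because a random 26-mer reaches 69 % "complementarity with G:U allowed" at
a per-window rate of roughly 5×10⁻⁴, the X-cluster background is
rejection-scrubbed after assembly: any non-motif window reaching the scan
threshold against the guide has one background position mutated to its
guide-identical (never-pairing) nucleotide, until no spurious window
remains. This makes "exactly `n_motif_copies` scan sites" a construction
invariant at any seed rather than a high-probability event.

`simulate_library` draws collapsed species per class with the canonical
geometry (piRNA 21 nt/5′ U sense to its locus; 22G 22 nt/5′ G antisense to
transcript loci; 26G 26 nt/5′ G antisense to their source loci; miRNA = the
annotated mature). Copy counts are geometric (mean 20 by default — a
heavy-tailed stand-in for the skewed abundance of real libraries).
Trimming and tailing are **per-copy** events: a species' copies are split
binomially into untouched/trimmed/tailed/trimmed+tailed variant species, so
copy-level tailed and trimmed fractions are exactly binomial in the
configured rates and admit closed-form error bands. Tail lengths are
1 + Poisson(mean − 1) nt (or constant, configurable), composition
uridylation-biased (U 0.7, A 0.2, C/G 0.05); the first tail nucleotide is
drawn to differ from the next templated base, making tails strictly
untemplated at the source placement. Default per-class methylation follows
the biology (piRNA and ERGO-1-class 26G = 1.0, others = 0.0); default
tailing is a minor species (1–10 %, highest for ERGO-1-class 26G) and
default trimming is zero — substantial trimming is a property of
methylation-mutant libraries and is switched on explicitly. A 18–28 nt
size-selection window is applied to the output, mirroring a typical small
RNA gel cut.

What the generator does **not** emulate: sequencing error, adapter
artefacts, quality scores, expression heterogeneity between loci of a
class, partial methylation within a species, and genomic repeat structure
beyond the X-cluster. Passing tests therefore demonstrate correctness of
the analysis logic under clean, fully observed conditions, not robustness
to real-library noise.

## Mapping and classification

Reads are placed by exact string matching on both strands; no mismatches
are tolerated (real pipelines of this kind permit none or one; exactness
keeps the mapper a checkable primitive, and the brute-force oracle tests
enforce placement-for-placement equality). A read that fails to match
full-length is decomposed into its **maximal** templated prefix (≥ 15 nt,
configurable) plus a 3′ tail; maximality guarantees the first tail
nucleotide is untemplated, because a templated continuation would extend
the prefix. All placements achieving the maximal prefix length are
reported in deterministic (contig, start, strand) order; library-level
tallies attribute multi-mappers once (first placement), per-feature counts
once per overlapped feature.

Class assignment applies, in priority order: exact coordinate match to an
annotated miRNA mature; 21 nt/5′ U sense within a piRNA locus; 26 nt/5′ G
antisense to a 26G source locus (ERGO-1 before ALG-3/4); 22 nt/5′ G
antisense to any transcript locus; otherwise `other`; no placement →
`unmapped`. The classification length is the **templated prefix length**,
not the raw read length, so a tailed read keeps the class of its templated
species — without this, every tailed read would fall out of its class and
tailed-proportion estimates per class would be impossible. The labels
partition the library exactly (one label per read).

## Abundance and enrichment

RPM uses the library's genome-mapping copy total as denominator ("per
million total reads" is ambiguous between raw and mapped totals; the mapped
total is recorded in the run manifest so either convention can be
reproduced). Per-feature log₂ ratios use ε = 0 when the feature is observed
in both libraries; a feature at zero in exactly one library gets ε = 1
RPM-equivalent and is flagged rather than silently clamped. Status calls
are sign-based at a configurable threshold (default 0: strict sign, ties →
`unchanged`). Class ratios are ratios of summed class RPM; a class with no
untreated signal is reported missing, not infinite. 2^−ΔΔCt is the standard
closed form; an optional ±1 SD range is reported as
[2^−(ΔΔCt+SD), 2^−(ΔΔCt−SD)] since no single variance convention dominates.

## Guide–target pairing

Pairing is antiparallel: guide position 1 (5′ nt) against the 3′-most
window nucleotide. States are WC, G:U wobble, or mispair; G:U counts toward
the complementarity fraction but is tracked separately (and the scanner can
be switched to WC-only accounting), because wobbles are pairing-competent
in this pathway and the 69 % figure for the trigger-guide sites is only
reached when they count. One bulged nucleotide is supported on either
side; the placement maximising paired positions is chosen, ties broken
toward the guide 3′ end. The state vector always has one entry per guide
position; a target bulge occupies the guide position opposite the loop
(a 1×1-loop abstraction that keeps positional rules applicable).

The silencing rule table (see `predict_silencing`) encodes the sensor
mutagenesis outcomes: any 5′-region (positions 1–5) disruption abolishes
silencing; three contiguous central mispairs abolish (12–14) or weaken
(9–11) it; a single target bulge around 13–15 weakens it; a single mispair
or guide bulge at 13 and mispairs confined to 20–22 are tolerated;
otherwise a site is functional iff its complementarity fraction reaches
0.69 (the level at which the endogenous trigger guide works). Mapping
fluorescence-level readouts onto three discrete calls is this package's
abstraction: "only a very modest increase" is binned as functional and
"partial derepression" as partial — a documented judgment call at the
boundary, configurable via the rule threshold.

Scanning slides all windows (± one-bulge lengths when enabled), keeps
those at or above the threshold, and reduces overlapping candidates to
local maxima (greedy non-maximum suppression, ties to the leftmost
window), returning sites sorted by position.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GFF3 output is 1-based
  closed, BED stays native.
- All generators are pure functions of (config, seed); the pipeline fans a
  single seed out with fixed per-stage offsets (+0 reference, +1 library,
  +2 treatment) recorded in the manifest, and reruns are byte-identical.
- U is normalised to T on input; outputs are DNA except the tail
  composition table, which reports U (tails are ribonucleotide additions).
- Collapsed libraries use `>{id} count={n}` FASTA headers; a missing count
  defaults to 1 with a warning; records containing N are rejected
  individually and counted in the log.
- `min_prefix` = 15 nt for placement balances false tails against lost
  reads and is recorded in the manifest.
- Problem sizes in the shipped checks (default library ≈ 5×10³ copies;
  replicated enrichment experiment 20 × ~2×10⁵ copies; oracle comparison
  1,000 reads vs ~50 kb) are chosen so closed-form binomial error bands
  are tight enough to detect real defects while the whole suite stays
  interactive.

## Known limitations

- Exact matching only: a single sequencing error unmaps a read; there is
  no mismatch-tolerant alignment.
- The treatment model ignores partial protection within a species and any
  sequence dependence of ligation efficiency.
- Tail-length truncation by the size-selection window can bias tailed
  proportions when long tails are configured near the window edge (the
  default 1-nt-mean tails are unaffected).
- The rule table is distilled from a single guide's mutagenesis panel;
  positional indices are guide-length-relative and untested for guides
  far from 22 nt.
- 5′ phosphorylation state (mono- vs triphosphate) is not modelled — it is
  invisible in standard read data.
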