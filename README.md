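# srnameth

Small RNA classification, 3′ 2′-O-methylation enrichment, trimming/tailing
and guide–target pairing analysis for *C. elegans*-style small RNA
sequencing experiments.

## The problem

*C. elegans* produces several small RNA classes with distinct geometry:
piRNAs (21 nt, 5′ U, PRG-1/PIWI-bound), secondary 22G siRNAs (22 nt, 5′
triphosphorylated G, antisense to their target transcripts), primary 26G
siRNAs (26 nt, 5′ G; ERGO-1 class or ALG-3/4 class), and miRNAs. A subset of
these — the PIWI-pathway species — carry a HEN1-family 2′-O-methyl on the 3′
terminal ribose. Periodate oxidation/β-elimination removes the 3′ nucleoside
of RNAs with a free 2′,3′-OH and leaves an end incompatible with adapter
ligation, so in a treated sequencing library unmethylated species drop out
while methylated species persist: comparing treated to untreated libraries
reads out methylation status genome-wide.

This package implements the computational side of such an experiment,
driven by a synthetic-data generator with known ground truth:

- **`simulate`** — synthetic reference (typed loci including an X-cluster-like
  repeat locus and its *trans*-acting trigger gene), collapsed small RNA
  libraries with per-class methylation/trimming/tailing truth, and the
  β-elimination treatment model (per-copy ligation survival: `p_meth` for
  methylated, `p_unmeth` for unmethylated species).
- **`mapping`** — exact-match placement, class assignment by templated length,
  5′ nucleotide and annotation overlap, size × 5′-nt profiles, coverage tracks.
- **`abundance`** — reads-per-million normalization, per-feature and per-class
  log₂(treated/untreated) enrichment with status calls
  (`log2 r = log2((RPM_t + ε)/(RPM_u + ε))`), percent depletion
  `100·(1 − RPM_t/RPM_u)`, and 2^−ΔΔCt relative quantification.
- **`tailing`** — maximal templated-prefix decomposition of each read's 3′ end
  into templated + untemplated tail, trim lengths against annotated mature
  species, per-class tailed/trimmed proportions.
- **`pairing`** — guide:target pair states (Watson–Crick / G:U wobble /
  mispair / single bulges), positional silencing rules from sensor
  mutagenesis, and transcript scanning for partially complementary sites.
- **`pipeline` / CLI** — `srnameth run` orchestrates
  simulate → treat → classify → enrich → tail/trim → scan with a YAML config,
  seed fan-out, stage TSVs, a run manifest and a plain-text report.

## Worked example

```python
from srnameth import (ReferenceSpec, LibraryConfig, build_reference,
                      simulate_library, apply_beta_elimination,
                      classify_library, class_ratio_table, percent_depletion)

ref = build_reference(ReferenceSpec(), seed=1)
untreated = simulate_library(ref, LibraryConfig(), seed=2)
treated = apply_beta_elimination(untreated, p_meth=1.0, p_unmeth=0.1, seed=3)
asg_u, _ = classify_library(untreated, ref)
asg_t, _ = classify_library(treated, ref)
print(class_ratio_table(treated, untreated, asg_t, asg_u).round(3))
```

prints

```
                 rpm_untreated  rpm_treated  ratio  log2_ratio    status
class
miRNA               246961.976    48697.138  0.197      -2.342  depleted
piRNA_21U           164837.319   359248.185  2.179       1.124  enriched
siRNA_22G           184437.475    40580.948  0.220      -2.184  depleted
siRNA_26G_ALG34     168561.348    38872.277  0.231      -2.116  depleted
siRNA_26G_ERGO1     235201.882   512601.452  2.179       1.124  enriched
```

The two methylated classes (piRNAs, ERGO-1-class 26G siRNAs) are enriched
after treatment; the unmethylated classes are depleted — the library-level
signature of PIWI-pathway-restricted 3′ methylation. For a single species,
`percent_depletion(1270, 257)` → `79.8`: a 22G siRNA observed at 1270 RPM
untreated and 257 RPM treated is ~80% depleted, i.e. unmethylated.

More narrative scripts live in `examples/` (one per capability); run the
whole pipeline with `srnameth run -c examples/demo_config.yaml -o out`.

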