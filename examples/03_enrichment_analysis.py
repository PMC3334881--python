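"""Beta-elimination enrichment: which classes are 3' 2'-O-methylated?

Compares treated vs untreated class abundances (RPM) and reproduces the
worked percent-depletion arithmetic for an unmethylated 22G siRNA
species observed at 1270 RPM untreated and 257 RPM after treatment.
"""

from srnameth import (
    LibraryConfig,
    ReferenceSpec,
    apply_beta_elimination,
    build_reference,
    class_ratio_table,
    classify_library,
    percent_depletion,
    simulate_library,
)

ref = build_reference(ReferenceSpec(), seed=1)
untreated = simulate_library(ref, LibraryConfig(), seed=2)
treated = apply_beta_elimination(untreated, p_meth=1.0, p_unmeth=0.1, seed=3)

asg_u, _ = classify_library(untreated, ref)
asg_t, _ = classify_library(treated, ref)
table = class_ratio_table(treated, untreated, asg_t, asg_u)
print(table.round(3))
print("-> 'enriched' classes carry the 3' 2'-O-methyl; 'depleted' ones do not\n")

d = percent_depletion(1270, 257)
print(f"worked example: 1270 RPM -> 257 RPM is a {d:.1f}% depletion (~80%)")
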