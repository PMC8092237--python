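"""Off-target enumeration and SNV dependence classification on a toy genome.

Plants PAM-adjacent loci at known mismatch counts, scans for candidates
within the 4-mismatch prediction cap, simulates SNVs with truth labels,
classifies them by the 15-of-20 similarity rule, and compares predicted
candidates with observed variants.
"""

from bhsgrna import (
    GenomeConfig,
    Spacer,
    classify_snvs,
    compare_predicted_observed,
    make_toy_genome,
    scan_offtargets,
    simulate_snvs,
    snv_type_ratio,
)

spacer = Spacer("ATCAGCTACCGGTCAGATCA")
genome, truth = make_toy_genome(
    spacer,
    GenomeConfig(seed=17, genome_length=30_000,
                 planted=((0, "+"), (2, "-"), (4, "+"), (5, "+"), (6, "-"))),
)
print("planted loci:")
print(truth.to_string(index=False))

candidates = scan_offtargets(genome, spacer, pam="NGG", max_mm=4)
print(f"\nscan (<=4 mismatches, NGG): {len(candidates)} candidates")
for c in candidates:
    print(f"  {c.contig}:{c.start}-{c.end}({c.strand})  {c.n_mismatches} mm "
          f"at protospacer positions {c.mismatch_positions}")
# the 5- and 6-mismatch loci exceed the prediction cap and are not returned

snvs, labels = simulate_snvs(genome, truth, n_dependent=3, n_independent=4, seed=23)
classified, summary = classify_snvs(snvs, genome, spacer, min_matches=15)
print(f"\nSNV classes: {dict(summary)}")
print("classifier agrees with simulation truth:",
      [s.classification for s in classified] == labels)

venn = compare_predicted_observed(candidates, classified)
print("predicted-vs-observed overlap:", venn)

dependent = [s for s in classified if s.classification == "sgRNA_dependent"]
if dependent:
    print(f"C:G->T:A signature among dependent SNVs: {snv_type_ratio(dependent):.2f}")
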