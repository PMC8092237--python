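"""Check that a designed guide folds the way it was intended.

Folds the 5' region (extension + loop + spacer) by base-pair
maximization and reports whether the intended hairpin stem appears in a
maximum-pairing structure and whether the bubble stays open.
"""

from bhsgrna import DesignSpec, Spacer, build_bh_sgrna, hairpin_report, nussinov_maxpairs

spacer = Spacer("TGGTGTTAACCTTACTATAC")
design = build_bh_sgrna(spacer, DesignSpec.default("CBE"))

report = hairpin_report(design)
print("design        :", design.name)
print("molecule      :", design.five_prime_region)
print("dot-bracket   :", report.structure.dot_bracket)
print("pair count    :", report.structure.n_pairs)
print(f"intended stem : {report.n_intended_found}/{report.n_intended} pairs present")
print("bubble paired :", report.n_bubble_paired)
print("verdict       :", report.verdict)
# PASS means every intended stem pair occurs in some maximum-pairing
# structure and no bubble position can pair its opposing stem residue;
# guides with strong spacer self-structure can fail and should be redesigned.

structure = nussinov_maxpairs("GGGAAACCC")
print("\nstandalone fold of GGGAAACCC:", structure.dot_bracket,
      f"({structure.n_pairs} pairs)")
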