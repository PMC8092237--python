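"""Design bubble-hairpin guides for a 20-nt spacer.

Builds the optimized default designs for both editor classes and a small
piece of the H/B/P parameter grid, and prints the constructed molecules.
"""

from bhsgrna import DesignSpec, Spacer, build_bh_sgrna, enumerate_series

# a genomic protospacer (DNA); it is transcribed to RNA automatically
spacer = Spacer("ATCAGCTACCGGTCAGATCA")

print("spacer (RNA):", spacer)
for editor in ("CBE", "ABE"):
    design = build_bh_sgrna(spacer, DesignSpec.default(editor))
    print(f"\n{editor} default design {design.name}")
    print("  extension :", design.extension)
    print("  molecule  :", design.five_prime_region)
    print("  bubble at hairpin positions", sorted(design.bubble_hairpin_positions),
          "= protospacer positions", sorted(design.bubble_protospacer_positions))

# The extension is the reverse complement of the spacer's first 12 nt,
# joined by the ACAA tetraloop; the bubble residues are chosen so they can
# pair the opposing guide position neither Watson-Crick nor G-U wobble,
# leaving the editing window open.

print("\nhairpin-length series (no bubble):")
for d in enumerate_series(spacer, H_set=[0, 2, 4, 8, 12], B_set=[], P_set=[]):
    print(f"  {d.name:>4}  {d.five_prime_region}")
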