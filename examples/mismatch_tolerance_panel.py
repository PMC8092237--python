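"""Build a mismatched-guide panel for probing off-target tolerance.

Generates guides differing from an on-target spacer by 1-3 nucleotides
at defined positions (transversion-first substitutions), the classic
panel for measuring how editing activity decays with guide-target
mismatches inside and outside the seed region.
"""

from bhsgrna import Spacer, enumerate_mismatched_guides
from bhsgrna.design import adjacent_mismatch_blocks, single_mismatch_scan

spacer = Spacer("ATCAGCTACCGGTCAGATCA")

print("single-mismatch scan (positions 1, 5, 10, 15, 20):")
panel = enumerate_mismatched_guides(spacer, [(p,) for p in (1, 5, 10, 15, 20)])
for guide, positions, muts in panel:
    print(f"  pos {positions[0]:>2} -> {muts}   {guide}")

print("\ntriple-mismatch blocks (PAM-distal, middle, seed):")
blocks = [b for b in adjacent_mismatch_blocks(20, 3) if b[0] in (1, 9, 18)]
for guide, positions, muts in enumerate_mismatched_guides(spacer, blocks):
    print(f"  positions {positions} -> {muts}   {guide}")

print(f"\nfull Hamming-1 panel size: {len(single_mismatch_scan(20))} guides")
# each guide differs from the spacer at exactly the requested positions;
# mismatches in the PAM-proximal seed (~positions 11-20) are expected to
# abolish editing, PAM-distal mismatches are tolerated by ordinary guides
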