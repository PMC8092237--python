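# bhsgrna

Design and analysis toolkit for **bubble-hairpin single guide RNAs
(BH-sgRNAs)** — an sgRNA engineering strategy that improves the precision
of CRISPR base editors (cytosine base editors such as BE3, adenine base
editors such as ABE7.10) without touching the protein components.

## The idea

A base editor exposes the protospacer's editing window (protospacer
positions 4–8 for CBE, 4–7 for ABE, counting the PAM-distal end as
position 1) as single-stranded DNA inside the R-loop, where the fused
deaminase converts C→T (CBE) or A→G (ABE). A BH-sgRNA prepends to the
ordinary 20-nt spacer the reverse complement of the spacer's own
5′-most *H* nucleotides, joined by a 5′-ACAA-3′ tetraloop, so the guide
folds into a hairpin. The stem raises the cost of completing the R-loop:
at a perfectly matched on-target site the hairpin is displaced and
editing proceeds; at mismatched off-target sites it is not, and editing
drops. Because the stem would also occlude the editing window, a
*bubble* of *B* deliberately non-pairing nucleotides (no Watson–Crick
**and no G-U wobble** pairs) is opened in the extension opposite
protospacer positions *P*…*P+B−1*. Designs are named `H{H}-B{B}-P{P}`;
the optimized defaults are **H12-B3-P5** for CBE (bubble opposite
protospacer 5–7, i.e. hairpin positions 6–8) and **H12-B3-P4** for ABE
(protospacer 4–6, hairpin 7–9). Hairpin position *p* (5′ end of the
molecule = 1) faces protospacer position *H + 1 − p*.

## What the package does

* **design** — construct WT, hairpin (`H#`), and bubble-hairpin
  (`H#-B#-P#`) guides; enumerate the H/B/P grid; build deliberately
  mismatched guide panels (1–3 mismatches, transversion-first).
* **structure** — validate designs by base-pair maximization (Nussinov
  dynamic programming with G-U wobble): does the intended stem occur in
  a maximum-pairing structure, and does the bubble stay open?
* **quant** — quantify editing from amplicon reads (FASTQ): semi-global
  alignment, per-position substitution frequencies (the `C[number]`
  convention), window editing frequency (reads with ≥1 canonical edit in
  the window), indel frequency, by-product typing, on:off ratios and
  fold reductions, replicate mean ± SEM and Student's two-tailed t test.
* **offtarget** — enumerate candidate loci within a mismatch budget
  (default ≤4, NGG PAM, both strands) and classify SNVs as on-target,
  sgRNA-dependent (inside a locus sharing ≥15 of 20 positions with the
  target) or sgRNA-independent; compare predicted vs observed loci.
* **simulate** — seeded generators for edited amplicon reads, toy
  genomes with planted off-target loci (rejection-sampled clean
  background), and SNV sets with known truth labels.

## Worked example

```python
from bhsgrna import DesignSpec, Spacer, build_bh_sgrna, hairpin_report

spacer = Spacer("ATCAGCTACCGGTCAGATCA")   # DNA in, transcribed to RNA
design = build_bh_sgrna(spacer, DesignSpec.default("CBE"))
print(design.name, design.five_prime_region)
print(sorted(design.bubble_hairpin_positions),
      sorted(design.bubble_protospacer_positions))
print(hairpin_report(design).verdict)
```

prints

```
H12-B3-P5 CCGGUCCAUGAUACAAAUCAGCUACCGGUCAGAUCA
[6, 7, 8] [5, 6, 7]
PASS
```

The molecule is extension (`CCGGUCCAUGAU`, the reverse complement of the
spacer's first 12 nt with the bubble substituted at hairpin positions
6–8) + `ACAA` loop + the 20-nt spacer. The bubble faces protospacer
positions 5–7 — the middle of the CBE editing window — and `PASS` means
the full 9-pair intended stem occurs in a maximum-pairing secondary
structure with the bubble unpaired.

The scripts in `examples/` walk through each capability (design series,
structure validation, editing quantification with planted rates,
off-target scanning and SNV classification, mismatched-guide panels) and
print the numbers they compute. A `bhsgrna` console command exposes the
same operations as subcommands (`design`, `fold`, `quant`, `scan`,
`classify`, `simulate`); run `bhsgrna --help`.

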