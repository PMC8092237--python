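# Methods

This note records the models, conventions, parameter choices and known
limitations behind `bhsgrna`, in the order the pipeline uses them.

## Coordinates and alphabets

All user-facing coordinates are 1-based: protospacer positions count the
PAM-distal end as position 1 (so the PAM-proximal end of a 20-nt spacer
is position 20), hairpin positions count the 5′ end of the molecule as
position 1, and VCF positions are standard 1-based. Internally
everything is 0-based half-open. Guides are RNA; DNA input is
transcribed (T→U) on construction. The ambiguity code N is accepted only
in PAM patterns. The pairing predicate treats Watson–Crick pairs as
pairs always and G-U wobble as a pair only when asked: wobble is a real
RNA pair and therefore counts during folding, but it is excluded when
choosing bubble residues, because a wobble pair would quietly close the
bubble.

## Guide design

The extension of an `H{H}-B{B}-P{P}` design is the reverse complement of
the spacer's 5′-most H nucleotides (H ≤ 12), joined to the spacer by a
5′-ACAA-3′ tetraloop; hairpin position p faces protospacer position
H+1−p, an involution that the tests exercise in both directions.
Defaults are H12-B3-P5 (CBE) and H12-B3-P4 (ABE), placing the bubble
opposite the middle of each editor's window (CBE 4–8, ABE 4–7).

**Bubble residue choice.** The published rule says only that bubble
positions are replaced with non-pairing nucleotides avoiding G-U. To
make designs deterministic we exclude the Watson–Crick partner and, if
one exists, the wobble partner of the opposing spacer residue, then take
the first survivor in the fixed priority order C, A, G, U (pyrimidine
first, never a wobble risk). At most two of four residues are ever
excluded, so a choice always exists. A caller may supply an explicit
bubble sequence; it is validated with the same predicate. This rule is
one valid instantiation of the constraint, not a claim about any
particular published construct.

**Grids and panels.** The hairpin-length series defaults to even lengths
2–12 plus WT (the published series shows the H2 and H12 endpoints; the
full list is configurable). Bubble sizes 1–3 and start positions 4–8 are
enumerated with combinations whose bubble would leave the paired region
dropped. Mismatched-guide panels substitute by a transversion-first rule
(A↔C, G↔U) with per-position overrides; panels of exactly 1–3 mismatches
are supported, matching how guide-mismatch tolerance is usually probed.

**Degenerate inputs.** Spacer lengths outside 18–24 are rejected,
non-20 lengths warn; B=0 with a bubble start set warns and ignores the
start; H=0 yields the unmodified guide named `WT`. Scaffold sequence is
not part of any published design rule, so designs are emitted
spacer-region-only by default with an optional scaffold appended for
oligo export; folding always excludes it.

## Secondary-structure validation

Folding is base-pair maximization (Nussinov dynamic programming) over
the extension + loop + spacer, with `min_loop = 3` unpaired residues
enclosed by any pair and wobble allowed. We chose pair maximization over
thermodynamic free-energy folding because the structural claims a design
makes are topological — the stem forms, the bubble is open — and
maximization is exactly testable: the suite checks pair counts against
brute-force enumeration of *all* non-crossing structures for sequences
up to length 14. Sequences can be exported for an external
thermodynamic folder, but no result here depends on one.

`hairpin_report` answers two questions with exact semantics:

* For each intended stem pair, *is it contained in some
  maximum-pairing structure?* Computed with a weighted variant of the
  DP (the queried pair scores 3, others 2; the weighted optimum exceeds
  twice the plain optimum by 1 iff the answer is yes), verified against
  brute-force enumeration of all structures.
* Can any bubble position pair with the stem residue it faces in a
  maximum-pairing structure? For rule-built designs the answer is no by
  construction; the check exists to catch user-forced bubbles.

The verdict is PASS when the intended-pair fraction reaches the
configured threshold (default 1.0) and no bubble-opposing pair occurs.
An important empirical caveat: under pure pair maximization the full
intended stem survives for weakly self-structured spacers, but heavily
self-complementary spacers admit wobble-rich alternative pairings with
*more* total pairs than any stem-containing structure, in which case the
report honestly returns FAIL with the achieved fraction. On uniformly
random 20-mers roughly a third of default designs are flagged this way.
Treat FAIL as "the hairpin register is not unambiguously favored for
this spacer", a useful design screen, not as a statement about
free-energy folding.

## Editing quantification

Reads are aligned to the amplicon reference semi-globally (free end gaps
on the read) with affine scoring: match +2, mismatch −2, gap open −6
(first gapped base), gap extend −1, via Biopython's pairwise aligner;
the top-scoring alignment is taken deterministically and indels are then
left-shifted through repeat context, the standard variant-normalization
convention. Reads must span the full protospacer and have mean quality
≥ Q20; individual substitutions below Q20 are masked (they still count
toward depth). Both thresholds are configurable; threshold 0 reproduces
unmasked counts exactly.

The window statistic counts a read as edited iff it carries at least one
canonical conversion (C→T for CBE, A→G for ABE, evaluated on the
protospacer strand) at an editing-window position. Whether non-canonical
substitutions should also count is ambiguous in the source convention;
the default counts canonical conversions only, and an
`--any-substitution` flag flips it. Indel frequency counts reads with an
indel overlapping the protospacer interval (configurable ± flank), not
the whole amplicon. Minus-strand loci are handled by complementing
substitutions onto the protospacer strand and reflecting coordinates; a
metamorphic test checks that a − strand locus and its mirrored + strand
locus give identical profiles.

By-product tables report, per substrate base (C for CBE, A for ABE), the
canonical conversion fraction and the summed non-canonical ("undesired")
fraction; uncovered positions are reported as missing rather than zero.
Fold reductions between runs guard division with a detection floor of
0.1% — a test frequency below the floor yields a `≥` lower bound
computed at the floor. Replicate summaries are mean ± SEM (sample sd/√n)
and the equal-variance two-tailed Student t test (scipy); the degenerate
zero-variance equal-mean case returns t = 0, p = 1.

## Off-target enumeration and SNV classification

The scan enumerates every PAM-adjacent L-mer on both strands within a
Hamming budget of the spacer (default ≤4 mismatches, NGG). It is
vectorized with numpy sliding windows and checked for exact set equality
against a per-position string-comparison oracle on planted toy genomes
for all budgets 0–6. Bulges (guide or DNA) are not modeled. Minus-strand
candidates report the protospacer as read on the minus strand together
with its plus-strand interval; ordering is (contig, start, strand).

SNV dependence uses the similarity rule: a variant inside a PAM-adjacent
locus matching the spacer at ≥15 of 20 positions (i.e. ≤5 mismatches) is
sgRNA-dependent; inside the on-target protospacer it is on-target;
otherwise sgRNA-independent. Two stated ambiguities are resolved as
defaults with escape hatches: the threshold is inclusive (≥15; a strict
mode requires >15), and a PAM is required for a locus to qualify (a flag
drops it, since the rule as phrased mentions only sequence similarity).
The attribution flank around a qualifying locus defaults to 0 (the SNV
must fall inside the protospacer). Predicted-vs-observed comparison
intersects loci by identity (contig, start, strand); observed SNVs
outside every candidate each count as their own observed-only locus. The
deamination-signature ratio counts C→T and G→A (strand-collapsed)
changes among a class.

## Synthetic data

The simulators exist so every stage has fixtures with known truth and no
external data. All are driven by `numpy.random.default_rng(seed)` and
are byte-reproducible.

* **Amplicon reads**: single-end, full-length, constant Q30 qualities.
  Each configured protospacer position converts canonically with its
  rate, or non-canonically with an independent undesired rate; at most
  one deletion (length 1–3) may be planted uniformly inside the
  protospacer per read; uniform per-base sequencing error is applied
  last and is deliberately decoupled from the quality string. The truth
  table records planted events per read before sequencing error.
* **Toy genomes**: uniform i.i.d. background, rejection-sampled so that
  no window on either strand comes within (clean margin − 1) = 5
  mismatches of the spacer except the planted sites, which carry exact
  requested mismatch counts at uniform positions with a concrete NGG PAM
  (AGG). Planting is verified by a PAM-agnostic rescan; infeasible
  packings raise. This guarantee is what makes the scan-oracle and
  classifier-recovery tests exact rather than probabilistic.
* **SNVs**: dependent variants are placed inside qualifying planted
  protospacers (preferring imperfect loci; C:G positions preferred, with
  the C→T / G→A signature), independent variants at least 20 bp from
  every qualifying locus. Labels follow the locus (a variant inside the
  perfect site is labeled on-target).

What the simulators do *not* emulate: Illumina error profiles, paired
ends and merging, PCR duplicates, coverage nonuniformity, structural
variants, or bulged off-target sites. Tests passing on these fixtures
show the estimators and classifiers are correct under their own model
assumptions; they do not certify behavior on real sequencing artifacts.

## Problem sizes and numerical choices

The test suite uses sizes chosen to make the statistical checks sharp
while keeping the whole suite fast: rate recovery uses 10,000 reads per
run and exact binomial 99% intervals (conversion rates and indel rates
are planted in separate runs — a deletion inside a homopolymer next to
an edited base creates genuine alignment ambiguity that left-
normalization resolves by reassignment, which is an alignment reality
rather than an estimator defect, and mixing the two would blur the
interval check); the scan oracle covers 50 random 20–50 kb genomes with
planted 0–6-mismatch sites; the folding oracle covers 200 random
sequences up to length 14, the largest size at which full enumeration is
comfortable. Deterministic tie-breaks throughout: traceback prefers
pairing the 5′-most position with its intended partner first, then the
smallest partner index; scan output is sorted; bubble and mismatch
substitutions follow fixed priority rules.

## Known limitations

* Pair maximization is a topological screen, not thermodynamics; see the
  caveat above.
* Mismatch-only off-target model (no bulges), as in the ≤4-mismatch
  prediction convention it follows.
* The quantifier assumes pre-merged single reads; paired-end merging and
  adapter trimming are upstream concerns.
* WGS alignment/variant calling is out of scope: SNV classification
  starts from an existing variant list (minimal VCF or TSV).
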