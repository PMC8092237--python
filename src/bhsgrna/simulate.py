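"""Synthetic fixtures with known truth for every pipeline stage.

Three generators, all seeded and byte-reproducible:

* ``simulate_amplicon_reads`` — edited amplicon read sets with planted
  per-position canonical conversion rates, undesired substitutions,
  indels and uniform sequencing error, so the quantifier's estimates can
  be checked against exact binomial expectations;
* ``make_toy_genome`` — random genomes carrying planted PAM-adjacent
  sites at exact mismatch counts, with the background rejection-sampled
  so no accidental near-match exists (off-target scans on these genomes
  have a known exact answer);
* ``simulate_snvs`` — point variants planted inside qualifying loci
  (sgRNA-dependent, CBE-signature-biased) or far from any locus
  (sgRNA-independent), with truth labels.

The read model is deliberately simple: single-end full-length amplicons,
constant base quality, independent errors.  It emulates the *measured
quantities* of base-editor amplicon experiments, not Illumina error
structure, PCR duplicates or coverage nonuniformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .alphabet import complement, reverse_complement
from .design import CANONICAL_EDIT, Spacer
from .quant import AmpliconLocus
from .seqio import SNVRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the amplicon-read simulator; all rates are per read."""

    seed: int
    n_reads: int = 1000
    #: protospacer position -> probability of a canonical conversion
    edit_rates: dict[int, float] = field(default_factory=dict)
    #: probability that an editable position converts non-canonically
    undesired_rate: float = 0.0
    #: probability a read carries one indel inside the protospacer
    indel_rate: float = 0.0
    indel_lengths: tuple[int, ...] = (1, 2, 3)
    #: per-base uniform sequencing error rate
    error_rate: float = 0.0
    base_quality: int = 30

    def __post_init__(self):
        for r in (*self.edit_rates.values(), self.undesired_rate, self.indel_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")


def simulate_amplicon_reads(
    locus: AmpliconLocus, cfg: SimulationConfig
) -> tuple[list[tuple[str, str, list[int]]], pd.DataFrame]:
    """Simulate edited amplicon reads; returns (reads, truth table).

    Each read starts as the reference; every configured protospacer
    position independently converts canonically (C->T for CBE / A->G for
    ABE, on the protospacer strand) with its rate, or to a random
    non-canonical base with ``undesired_rate``; one deletion of random
    length may be planted inside the protospacer; finally uniform
    sequencing errors are applied.  The truth table records what was
    planted per read (before sequencing error).
    """
    rng = np.random.default_rng(cfg.seed)
    ref_from, ref_to = CANONICAL_EDIT[locus.editor]
    proto = locus.protospacer_sequence()
    editable = sorted(
        p for p in cfg.edit_rates if proto[p - 1] == ref_from
    )
    skipped = set(cfg.edit_rates) - set(editable)
    if skipped:
        raise ValueError(
            f"edit rates at positions {sorted(skipped)} do not sit on a "
            f"{ref_from} of the protospacer"
        )
    wlo, whi = locus.window
    reads: list[tuple[str, str, list[int]]] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        seq = list(locus.reference)
        edited_positions: list[int] = []
        undesired_positions: list[int] = []
        for p in editable:
            ref_pos = locus.ref_position(p)  # 1-based on reference
            u = rng.random()
            if u < cfg.edit_rates[p]:
                new = ref_to
                edited_positions.append(p)
            elif u < cfg.edit_rates[p] + cfg.undesired_rate:
                choices = [b for b in "ACGT" if b not in (ref_from, ref_to)]
                new = choices[rng.integers(len(choices))]
                undesired_positions.append(p)
            else:
                continue
            seq[ref_pos - 1] = new if locus.strand == "+" else complement(new)

        has_indel = bool(rng.random() < cfg.indel_rate)
        indel_len = 0
        if has_indel:
            indel_len = int(cfg.indel_lengths[rng.integers(len(cfg.indel_lengths))])
            lo = locus.proto_start - 1
            hi = locus.proto_end - indel_len
            start0 = int(rng.integers(lo, max(lo + 1, hi + 1)))
            del seq[start0 : start0 + indel_len]

        seq_arr = np.array(seq)
        if cfg.error_rate > 0:
            err = rng.random(len(seq_arr)) < cfg.error_rate
            if err.any():
                shifts = rng.integers(1, 4, size=int(err.sum()))
                idx = np.nonzero(err)[0]
                codes = np.searchsorted(_BASES, seq_arr[idx])
                seq_arr[idx] = _BASES[(codes + shifts) % 4]
        read_seq = "".join(seq_arr)
        quals = [cfg.base_quality] * len(read_seq)
        name = f"{locus.name}_read{i:05d}"
        reads.append((name, read_seq, quals))
        truth_rows.append(
            {
                "read": name,
                "edited_positions": ",".join(map(str, edited_positions)),
                "undesired_positions": ",".join(map(str, undesired_positions)),
                "window_edited": any(wlo <= p <= whi for p in edited_positions),
                "has_indel": has_indel,
                "indel_length": indel_len,
            }
        )
    return reads, pd.DataFrame(truth_rows)


@dataclass
class GenomeConfig:
    """Knobs of the toy-genome generator."""

    seed: int
    genome_length: int = 20_000
    #: list of (mismatch count, strand) sites to plant
    planted: tuple[tuple[int, str], ...] = ()
    pam: str = "AGG"  # a concrete NGG instance
    #: background guaranteed >= clean_margin + scan budget mismatches away
    clean_min_mismatches: int = 6
    contig: str = "toy1"


def _mutate(spacer_dna: str, k: int, rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
    """Plant exactly k substitutions at uniform distinct positions."""
    L = len(spacer_dna)
    positions = sorted(rng.choice(L, size=k, replace=False).tolist()) if k else []
    seq = list(spacer_dna)
    for p in positions:
        alts = [b for b in "ACGT" if b != seq[p]]
        seq[p] = alts[rng.integers(3)]
    return "".join(seq), tuple(p + 1 for p in positions)


def make_toy_genome(
    spacer: Spacer | str, cfg: GenomeConfig
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with planted PAM-adjacent sites at exact mismatch
    counts; returns ({contig: sequence}, truth table of planted loci).

    The background is rejection-sampled: any window within
    ``clean_min_mismatches - 1`` mismatches of the spacer next to a PAM
    (either strand) is re-randomized, so the only loci a scan can find
    are the planted ones.  Planting is deterministic given the seed.
    """
    from .offtarget import scan_offtargets, _spacer_dna  # local import: cycle

    sp = _spacer_dna(spacer)
    L = len(sp)
    site_len = L + len(cfg.pam)
    n_sites = len(cfg.planted)
    if cfg.genome_length < (site_len + 10) * (n_sites + 1):
        raise ValueError("genome too short for the requested planted sites")
    rng = np.random.default_rng(cfg.seed)

    for attempt in range(50):
        genome = "".join(rng.choice(_BASES, size=cfg.genome_length))
        # scrub accidental near-matches from the background
        for _ in range(100):
            hits = scan_offtargets(
                {cfg.contig: genome}, sp, pam="NNN", max_mm=cfg.clean_min_mismatches - 1
            )
            if not hits:
                break
            g = list(genome)
            for h in hits:
                for k in range(h.start - 1, h.end):
                    g[k] = str(rng.choice(_BASES))
            genome = "".join(g)
        else:  # pragma: no cover - rejection loop exhausted
            continue

        # evenly spaced slots, jittered, non-overlapping
        slot = cfg.genome_length // (n_sites + 1) if n_sites else 0
        truth_rows = []
        g = list(genome)
        ok = True
        for idx, (k, strand) in enumerate(cfg.planted):
            site, positions = _mutate(sp, k, rng)
            insert = site + cfg.pam
            if strand == "-":
                insert = reverse_complement(insert)
            start0 = slot * (idx + 1) + int(rng.integers(0, max(1, slot - site_len - 1)))
            if start0 + site_len > cfg.genome_length:
                ok = False
                break
            g[start0 : start0 + site_len] = insert
            if strand == "+":
                proto_start = start0 + 1
            else:
                proto_start = start0 + len(cfg.pam) + 1
            truth_rows.append(
                {
                    "contig": cfg.contig,
                    "start": proto_start,
                    "end": proto_start + L - 1,
                    "strand": strand,
                    "n_mismatches": k,
                    "mismatch_positions": ",".join(map(str, positions)),
                }
            )
        if not ok:
            continue
        genome = "".join(g)

        # verify (PAM-agnostic): the scan at the cleanliness budget finds
        # exactly the planted loci, so oracle tests are exact
        found = scan_offtargets(
            {cfg.contig: genome}, sp, pam="NNN", max_mm=cfg.clean_min_mismatches - 1
        )
        found_ids = {(c.start, c.strand, c.n_mismatches) for c in found}
        want_ids = {
            (r["start"], r["strand"], r["n_mismatches"])
            for r in truth_rows
            if r["n_mismatches"] < cfg.clean_min_mismatches
        }
        if found_ids == want_ids:
            truth = pd.DataFrame(
                truth_rows,
                columns=[
                    "contig", "start", "end", "strand",
                    "n_mismatches", "mismatch_positions",
                ],
            )
            return {cfg.contig: genome}, truth
    raise RuntimeError("could not build a clean toy genome (infeasible packing)")


def simulate_snvs(
    genome: dict[str, str],
    planted_truth: pd.DataFrame,
    n_dependent: int,
    n_independent: int,
    seed: int,
    min_matches: int = 15,
    spacer_length: int = 20,
) -> tuple[list[SNVRecord], list[str]]:
    """Plant SNVs with known dependence labels on a toy genome.

    Dependent SNVs go inside qualifying planted protospacers (those with
    <= L - min_matches mismatches), biased to the CBE C->T signature
    (G->A when the variant base is G on the plus strand); independent
    SNVs go at least L bp from every qualifying locus.  Returns
    (records, truth labels aligned with the records).
    """
    rng = np.random.default_rng(seed)
    budget = spacer_length - min_matches
    qualifying = planted_truth[planted_truth["n_mismatches"] <= budget]
    # prefer imperfect loci: an SNV inside the 0-mismatch (on-target)
    # locus is labeled on_target, not dependent
    offsites = qualifying[qualifying["n_mismatches"] > 0]
    pool = offsites if len(offsites) else qualifying
    if n_dependent > 0 and pool.empty:
        raise ValueError("dependent SNVs require >= 1 qualifying planted locus")

    records: list[SNVRecord] = []
    labels: list[str] = []
    for i in range(n_dependent):
        row = pool.iloc[int(rng.integers(len(pool)))]
        contig = row["contig"]
        seq = genome[contig]
        span = list(range(int(row["start"]), int(row["end"]) + 1))
        # prefer a C:G position for the deamination signature
        cg = [p for p in span if seq[p - 1] in "CG"]
        pos = int((cg or span)[int(rng.integers(len(cg or span)))])
        ref = seq[pos - 1]
        alt = {"C": "T", "G": "A"}.get(ref)
        if alt is None:
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
        records.append(SNVRecord(contig, pos, ref, alt, frequency=float(rng.uniform(0.05, 0.9))))
        labels.append(
            "on_target" if int(row["n_mismatches"]) == 0 else "sgRNA_dependent"
        )

    exclusion: list[tuple[str, int, int]] = [
        (r["contig"], int(r["start"]) - spacer_length, int(r["end"]) + spacer_length)
        for _, r in qualifying.iterrows()
    ]
    contigs = sorted(genome)
    placed = 0
    while placed < n_independent:
        contig = contigs[int(rng.integers(len(contigs)))]
        pos = int(rng.integers(1, len(genome[contig]) + 1))
        if any(c == contig and lo <= pos <= hi for c, lo, hi in exclusion):
            continue
        ref = genome[contig][pos - 1]
        alt = {"C": "T", "G": "A"}.get(ref)
        if alt is None:
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
        records.append(SNVRecord(contig, pos, ref, alt, frequency=float(rng.uniform(0.05, 0.9))))
        labels.append("sgRNA_independent")
        placed += 1
    return records, labels
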