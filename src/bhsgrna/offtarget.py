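"""Off-target candidate enumeration and SNV dependence classification.

``scan_offtargets`` enumerates every PAM-adjacent L-mer on either genome
strand within a Hamming-distance budget of the spacer (bulges are not
modeled).  ``classify_snvs`` applies the similarity rule used to call a
variant guide-directed: an SNV falling inside a PAM-adjacent locus that
matches the spacer at >= ``min_matches`` of its L positions (default 15
of 20, i.e. <= 5 mismatches) is sgRNA-dependent; an SNV inside the
on-target protospacer itself is on-target; anything else is
sgRNA-independent (attributed to guide-free deaminase activity).

Coordinates are 1-based inclusive on the plus strand; minus-strand
candidates report the protospacer as read on the minus strand together
with its plus-strand interval.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import reverse_complement, validate
from .design import Spacer
from .seqio import SNVRecord

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class OffTargetCandidate:
    """A PAM-adjacent genomic locus similar to the spacer."""

    contig: str
    start: int  # 1-based plus-strand start of the protospacer interval
    end: int  # 1-based plus-strand end (inclusive)
    strand: str
    protospacer: str  # as read 5'->3' on `strand`
    pam: str
    n_mismatches: int
    mismatch_positions: tuple[int, ...]  # protospacer coords, PAM-distal = 1

    @property
    def locus_id(self) -> tuple[str, int, str]:
        return (self.contig, self.start, self.strand)

    def contains(self, contig: str, pos: int, flank: int = 0) -> bool:
        return (
            contig == self.contig
            and self.start - flank <= pos <= self.end + flank
        )


def _spacer_dna(spacer: Spacer | str) -> str:
    if isinstance(spacer, Spacer):
        return spacer.sequence.replace("U", "T")
    return validate(spacer.upper().replace("U", "T"), "DNA")


def _scan_strand(
    seq: str,
    spacer: str,
    pam: str,
    max_mm: int,
) -> Iterable[tuple[int, str, str, int, tuple[int, ...]]]:
    """Yield (0-based window start, protospacer, pam, n_mm, mm positions)
    for one already-oriented sequence (protospacer 5'->3', PAM 3')."""
    L, M = len(spacer), len(pam)
    n = len(seq)
    if n < L + M:
        return
    arr = _encode(seq)
    sp = _encode(spacer)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)[: n - L - M + 1]
    mm = (windows != sp).sum(axis=1)
    # PAM check, vectorized over fixed pattern positions
    pam_ok = np.ones(len(windows), dtype=bool)
    for k, p in enumerate(pam):
        if p == "N":
            continue
        pam_ok &= arr[L + k : L + k + len(windows)] == ord(p)
    hits = np.nonzero((mm <= max_mm) & pam_ok)[0]
    for i in hits:
        proto = seq[i : i + L]
        positions = tuple(
            int(q) + 1 for q in np.nonzero(windows[i] != sp)[0]
        )
        yield int(i), proto, seq[i + L : i + L + M], int(mm[i]), positions


def scan_offtargets(
    genome: dict[str, str] | str,
    spacer: Spacer | str,
    pam: str = "NGG",
    max_mm: int = 4,
) -> list[OffTargetCandidate]:
    """Enumerate candidate protospacers within ``max_mm`` mismatches.

    ``genome`` is {contig: sequence} (or a single sequence, reported as
    contig "seq").  Both strands are scanned; each PAM-adjacent L-mer is
    reported exactly once, ordered by (contig, plus-strand start, strand).
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
    pam = validate(pam, "DNA", allow_n=True)
    sp = _spacer_dna(spacer)
    L, M = len(sp), len(pam)
    out: list[OffTargetCandidate] = []
    for contig in sorted(genome):
        seq = validate(genome[contig], "DNA")
        n = len(seq)
        if n < L + M:
            continue
        for i, proto, pam_seq, n_mm, positions in _scan_strand(seq, sp, pam, max_mm):
            out.append(
                OffTargetCandidate(
                    contig, i + 1, i + L, "+", proto, pam_seq, n_mm, positions
                )
            )
        rc = reverse_complement(seq)
        for i, proto, pam_seq, n_mm, positions in _scan_strand(rc, sp, pam, max_mm):
            # window occupies rc[i : i+L] -> plus strand [n-i-L, n-i)
            start = n - i - L + 1
            out.append(
                OffTargetCandidate(
                    contig, start, start + L - 1, "-", proto, pam_seq, n_mm, positions
                )
            )
    out.sort(key=lambda c: (c.contig, c.start, c.strand))
    return out


def classify_snvs(
    snvs: Sequence[SNVRecord],
    genome: dict[str, str] | str,
    spacer: Spacer | str,
    on_target: OffTargetCandidate | None = None,
    pam: str = "NGG",
    min_matches: int = 15,
    strict: bool = False,
    require_pam: bool = True,
    window_flank: int = 0,
) -> tuple[list[SNVRecord], Counter]:
    """Partition SNVs into on-target / sgRNA-dependent / sgRNA-independent.

    Qualifying loci are found by a mismatch scan with budget
    ``L - min_matches`` (``min_matches`` defaults to 15 of 20; ``strict``
    demands > 15, i.e. >= 16 matches).  ``require_pam`` controls whether
    similarity alone suffices or a PAM must flank the locus (default: PAM
    required).  ``on_target`` defaults to the best (fewest-mismatch) hit.
    Returns the records with ``classification`` filled plus class counts.
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
    sp = _spacer_dna(spacer)
    L = len(sp)
    eff_min = min_matches + 1 if strict else min_matches
    budget = L - eff_min
    if budget < 0:
        raise ValueError("min_matches exceeds spacer length")
    scan_pam = pam if require_pam else "N" * len(pam)
    loci = scan_offtargets(genome, sp, pam=scan_pam, max_mm=budget)

    if on_target is None:
        perfect = [c for c in loci if c.n_mismatches == 0]
        if perfect:
            on_target = perfect[0]

    for s in snvs:
        if s.contig not in genome:
            raise ValueError(f"SNV contig {s.contig!r} not in genome")
        if not 1 <= s.pos <= len(genome[s.contig]):
            raise ValueError(f"SNV position {s.pos} off contig {s.contig}")
        if on_target is not None and on_target.contains(s.contig, s.pos):
            s.classification = "on_target"
        elif any(c.contains(s.contig, s.pos, flank=window_flank) for c in loci):
            s.classification = "sgRNA_dependent"
        else:
            s.classification = "sgRNA_independent"
    return list(snvs), Counter(s.classification for s in snvs)


def compare_predicted_observed(
    candidates: Sequence[OffTargetCandidate],
    snvs: Sequence[SNVRecord],
) -> dict[str, int]:
    """Venn counts between predicted candidate loci and loci with observed
    SNVs (on-target loci excluded from both sides).

    An observed SNV is attributed to the candidate locus containing it;
    SNVs outside every candidate each count as their own observed-only
    locus.
    """
    predicted = {c.locus_id for c in candidates if c.n_mismatches > 0}
    observed: set = set()
    for s in snvs:
        if s.classification == "on_target":
            continue
        hit = next(
            (c for c in candidates if c.n_mismatches > 0 and c.contains(s.contig, s.pos)),
            None,
        )
        observed.add(hit.locus_id if hit else (s.contig, s.pos, "."))
    both = predicted & observed
    return {
        "predicted_only": len(predicted - observed),
        "observed_only": len(observed - predicted),
        "both": len(both),
    }


def snv_type_ratio(snvs: Sequence[SNVRecord]) -> float:
    """Fraction of C:G -> T:A changes (C->T or G->A, strand-collapsed)
    among the given SNVs — the canonical CBE deamination signature."""
    if not snvs:
        raise ValueError("no SNVs in class; ratio undefined")
    canonical = sum(1 for s in snvs if (s.ref, s.alt) in (("C", "T"), ("G", "A")))
    return canonical / len(snvs)


def candidates_to_frame(candidates: Sequence[OffTargetCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": c.contig,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "protospacer": c.protospacer,
            "pam": c.pam,
            "n_mismatches": c.n_mismatches,
            "mismatch_positions": ",".join(map(str, c.mismatch_positions)),
        }
        for c in candidates
    )


def snvs_to_frame(snvs: Sequence[SNVRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": s.contig,
            "pos": s.pos,
            "ref": s.ref,
            "alt": s.alt,
            "frequency": s.frequency,
            "classification": s.classification,
        }
        for s in snvs
    )
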