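"""Quantification of base-editing outcomes from amplicon reads.

The measured quantities mirror standard amplicon deep-sequencing
reporting for base editors:

* per-protospacer-position substitution frequencies (the C[number] /
  A[number] convention, PAM-distal position 1);
* window editing frequency — the fraction of passing reads with at least
  one canonical conversion (C->T for CBE, A->G for ABE, evaluated on the
  protospacer strand) inside the editing window;
* indel frequency — reads with an indel overlapping the protospacer;
* by-product breakdown — canonical vs undesired conversions per target
  base;
* replicate mean +/- SEM and the equal-variance two-tailed t test.

Reads are aligned to the amplicon reference semi-globally (free end gaps
on the read) with affine scoring +2/-2, gap open -6, extend -1; indels
are left-normalized so placements are deterministic.  Reads must cover
the full protospacer and pass a mean-quality filter; individual
substitutions under the base-quality threshold (default Q20) are masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .alphabet import complement, reverse_complement, validate
from .design import CANONICAL_EDIT, EDITING_WINDOWS

DEFAULT_MIN_QUAL = 20
DETECTION_FLOOR = 0.001  # frequencies below this are reported as <= floor


@dataclass(frozen=True)
class AmpliconLocus:
    """An amplicon reference with its protospacer annotation.

    ``proto_start``/``proto_end`` are 1-based inclusive on the reference
    plus strand.  On the + strand the PAM is 3' of the interval and
    protospacer position 1 (PAM-distal) is ``proto_start``; on the -
    strand the PAM is 5' of the interval on the plus strand and position
    1 is ``proto_end``.
    """

    name: str
    reference: str
    proto_start: int
    proto_end: int
    strand: str = "+"
    editor: str = "CBE"
    window: tuple[int, int] | None = None

    def __post_init__(self):
        object.__setattr__(self, "reference", validate(self.reference, "DNA"))
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not (1 <= self.proto_start <= self.proto_end <= len(self.reference)):
            raise ValueError("protospacer interval outside reference")
        if self.window is None:
            object.__setattr__(self, "window", EDITING_WINDOWS[self.editor])
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.length):
            raise ValueError("editing window outside protospacer")

    @property
    def length(self) -> int:
        return self.proto_end - self.proto_start + 1

    @property
    def pam_side(self) -> str:
        """'right' (3' on reference) for + strand loci, 'left' for -."""
        return "right" if self.strand == "+" else "left"

    def protospacer_sequence(self) -> str:
        """The protospacer 5'->3' on its own strand."""
        sub = self.reference[self.proto_start - 1 : self.proto_end]
        return sub if self.strand == "+" else reverse_complement(sub)

    def ref_position(self, proto_pos: int) -> int:
        """1-based reference position of a protospacer coordinate."""
        if not 1 <= proto_pos <= self.length:
            raise ValueError(f"protospacer position {proto_pos} out of range")
        if self.strand == "+":
            return self.proto_start + proto_pos - 1
        return self.proto_end - proto_pos + 1

    def proto_position(self, ref_pos: int) -> int | None:
        """Inverse of :meth:`ref_position`; None outside the protospacer."""
        if not self.proto_start <= ref_pos <= self.proto_end:
            return None
        if self.strand == "+":
            return ref_pos - self.proto_start + 1
        return self.proto_end - ref_pos + 1


@dataclass
class ReadAlignment:
    """Substitutions and indels of one read against the amplicon reference."""

    query_id: str
    # (ref_pos 1-based, ref_base, read_base, base_quality) on the + strand
    substitutions: list[tuple[int, str, str, int]]
    # (ref_pos 1-based of the base *after* which the event sits for
    #  insertions / first deleted base for deletions, kind, length, seq)
    indels: list[tuple[int, str, int, str]]
    covers_protospacer: bool
    mean_quality: float
    score: float

    def passes(self, min_qual: int = DEFAULT_MIN_QUAL) -> bool:
        return self.covers_protospacer and self.mean_quality >= min_qual


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -2
    a.open_gap_score = -6
    a.extend_gap_score = -1
    # free end gaps on the read: the reference may extend past the read
    a.open_left_deletion_score = 0
    a.extend_left_deletion_score = 0
    a.open_right_deletion_score = 0
    a.extend_right_deletion_score = 0
    return a


_ALIGNER = _make_aligner()


def _left_shift(ref: str, pos0: int, allele: str) -> int:
    """Left-normalize an indel: shift while the flanking base repeats.

    ``pos0`` is the 0-based reference position where the event starts
    (first deleted base, or the base the insertion precedes); ``allele``
    is the deleted/inserted sequence.
    """
    while pos0 > 0 and ref[pos0 - 1] == allele[-1]:
        allele = ref[pos0 - 1] + allele[:-1]
        pos0 -= 1
    return pos0


def align_read(
    read: str,
    qualities: Sequence[int] | None,
    locus: AmpliconLocus,
    query_id: str = "read",
) -> ReadAlignment:
    """Semi-globally align one read to the amplicon reference.

    Failures (not covering the protospacer) are flags on the returned
    record, never exceptions.  The top-scoring alignment is taken with
    the aligner's deterministic ordering; indels are then left-shifted
    through repeat context so placement is reproducible.
    """
    read = validate(read, "DNA")
    if qualities is None:
        qualities = [40] * len(read)
    aln = _ALIGNER.align(locus.reference, read)[0]
    ref_blocks, read_blocks = aln.aligned

    subs: list[tuple[int, str, str, int]] = []
    covered: set[int] = set()
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        for k in range(re_ - rs):
            rpos, qpos = rs + k, qs + k
            covered.add(rpos + 1)
            if locus.reference[rpos] != read[qpos]:
                subs.append(
                    (rpos + 1, locus.reference[rpos], read[qpos], qualities[qpos])
                )

    indels: list[tuple[int, str, int, str]] = []
    for b in range(1, len(ref_blocks)):
        prev_r, prev_q = ref_blocks[b - 1][1], read_blocks[b - 1][1]
        next_r, next_q = ref_blocks[b][0], read_blocks[b][0]
        if next_r > prev_r:  # deletion from the read
            allele = locus.reference[prev_r:next_r]
            pos0 = _left_shift(locus.reference, prev_r, allele)
            indels.append((pos0 + 1, "del", len(allele), allele))
        if next_q > prev_q:  # insertion in the read
            allele = read[prev_q:next_q]
            pos0 = _left_shift(locus.reference, prev_r, allele)
            indels.append((pos0 + 1, "ins", len(allele), allele))

    proto = set(range(locus.proto_start, locus.proto_end + 1))
    # a deletion inside the protospacer removes coverage; the read still
    # "covers" the interval if its aligned span brackets it
    span_ok = bool(covered) and min(covered) <= locus.proto_start and max(
        covered
    ) >= locus.proto_end
    covers = span_ok or proto <= covered
    meanq = float(np.mean(qualities)) if len(qualities) else 0.0
    return ReadAlignment(query_id, subs, indels, covers, meanq, float(aln.score))


def _indel_overlaps(
    indel: tuple[int, str, int, str], locus: AmpliconLocus, flank: int = 0
) -> bool:
    pos, kind, length, _ = indel
    lo, hi = locus.proto_start - flank, locus.proto_end + flank
    if kind == "del":
        return pos <= hi and pos + length - 1 >= lo
    return lo <= pos <= hi + 1  # insertion breakpoint inside the interval


@dataclass
class EditingProfile:
    """Per-position substitution counts and read-level tallies for one locus."""

    locus: AmpliconLocus
    # protospacer position -> read base (protospacer strand) -> count
    position_counts: dict[int, dict[str, int]] = field(default_factory=dict)
    depth: dict[int, int] = field(default_factory=dict)
    n_reads_pass: int = 0
    n_reads_window_edited: int = 0
    n_reads_indel: int = 0

    @property
    def window_frequency(self) -> float:
        return 0.0 if self.n_reads_pass == 0 else self.n_reads_window_edited / self.n_reads_pass

    @property
    def indel_frequency(self) -> float:
        return 0.0 if self.n_reads_pass == 0 else self.n_reads_indel / self.n_reads_pass

    def substitution_frequency(self, proto_pos: int, read_base: str) -> float | None:
        """Frequency of a specific substitution at a protospacer position;
        None where there is no coverage."""
        d = self.depth.get(proto_pos, 0)
        if d == 0:
            return None
        return self.position_counts.get(proto_pos, {}).get(read_base, 0) / d

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-position table: position, ref base, depth, counts, %."""
        proto = self.locus.protospacer_sequence()
        rows = []
        for pos in range(1, self.locus.length + 1):
            ref_base = proto[pos - 1]
            d = self.depth.get(pos, 0)
            counts = self.position_counts.get(pos, {})
            for base in "ACGT":
                if base == ref_base:
                    continue
                c = counts.get(base, 0)
                rows.append(
                    {
                        "position": pos,
                        "ref_base": ref_base,
                        "read_base": base,
                        "depth": d,
                        "count": c,
                        "frequency": c / d if d else float("nan"),
                    }
                )
        return pd.DataFrame(rows)


def tally(
    alignments: Iterable[ReadAlignment],
    locus: AmpliconLocus,
    min_qual: int = DEFAULT_MIN_QUAL,
    any_substitution: bool = False,
    indel_flank: int = 0,
) -> EditingProfile:
    """Aggregate read alignments into an :class:`EditingProfile`.

    A read counts as window-edited iff it carries >=1 canonical
    conversion at an editing-window position (or any substitution there,
    with ``any_substitution``); as an indel read iff >=1 indel overlaps
    the protospacer (+/- ``indel_flank``).  Substitutions below
    ``min_qual`` are masked; masked positions still count toward depth.
    """
    ref_from, ref_to = CANONICAL_EDIT[locus.editor]  # DNA, protospacer strand
    wlo, whi = locus.window
    profile = EditingProfile(locus)

    for aln in alignments:
        if not aln.passes(min_qual):
            continue
        profile.n_reads_pass += 1
        # coverage: protospacer positions aligned in this read
        sub_at: dict[int, tuple[str, str]] = {}
        for ref_pos, ref_base, read_base, qual in aln.substitutions:
            p = locus.proto_position(ref_pos)
            if p is None or qual < min_qual:
                continue
            if locus.strand == "-":
                ref_base = complement(ref_base)
                read_base = complement(read_base)
            sub_at[p] = (ref_base, read_base)
        deleted = set()
        for pos, kind, length, _ in aln.indels:
            if kind == "del":
                for rp in range(pos, pos + length):
                    p = locus.proto_position(rp)
                    if p is not None:
                        deleted.add(p)
        for p in range(1, locus.length + 1):
            if p in deleted:
                continue
            profile.depth[p] = profile.depth.get(p, 0) + 1
            if p in sub_at:
                _, read_base = sub_at[p]
                bucket = profile.position_counts.setdefault(p, {})
                bucket[read_base] = bucket.get(read_base, 0) + 1

        edited = False
        for p, (rb, qb) in sub_at.items():
            if not wlo <= p <= whi:
                continue
            if any_substitution or (rb == ref_from and qb == ref_to):
                edited = True
                break
        if edited:
            profile.n_reads_window_edited += 1
        if any(_indel_overlaps(i, locus, indel_flank) for i in aln.indels):
            profile.n_reads_indel += 1
    return profile


def byproduct_table(profile: EditingProfile) -> pd.DataFrame:
    """Canonical vs undesired conversion per target base.

    For each protospacer position whose reference base is the editor's
    substrate (C for CBE, A for ABE), report the canonical conversion
    fraction and the summed non-canonical ("undesired") fraction.
    Positions without coverage are reported with NaN fractions.
    """
    locus = profile.locus
    ref_from, ref_to = CANONICAL_EDIT[locus.editor]
    proto = locus.protospacer_sequence()
    rows = []
    for pos in range(1, locus.length + 1):
        if proto[pos - 1] != ref_from:
            continue
        d = profile.depth.get(pos, 0)
        counts = profile.position_counts.get(pos, {})
        canonical = counts.get(ref_to, 0)
        undesired = sum(c for b, c in counts.items() if b != ref_to)
        rows.append(
            {
                "position": pos,
                "target_base": f"{ref_from}{pos}",
                "depth": d,
                "canonical_fraction": canonical / d if d else float("nan"),
                "undesired_fraction": undesired / d if d else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def fold_reduction(
    comparator_freq: float, test_freq: float, floor: float = DETECTION_FLOOR
) -> tuple[float, str]:
    """Comparator / test off-target frequency ratio with a detection floor.

    Returns (value, qualifier) where qualifier is '' for a plain ratio or
    '>=' when the test frequency fell below the floor, in which case the
    ratio is a lower bound computed at the floor.
    """
    if test_freq < floor:
        return comparator_freq / floor, ">="
    return comparator_freq / test_freq, ""


def specificity_metrics(
    on: EditingProfile,
    offs: Sequence[EditingProfile],
    comparator_on: EditingProfile,
    comparator_offs: Sequence[EditingProfile],
    floor: float = DETECTION_FLOOR,
) -> pd.DataFrame:
    """On:off ratios and per-off-target fold reduction vs a comparator run
    (typically a plain WT-guide experiment on the same loci)."""
    if len(offs) != len(comparator_offs):
        raise ValueError("test and comparator off-target lists differ in length")
    rows = []
    for off, comp in zip(offs, comparator_offs):
        if off.locus.name != comp.locus.name:
            raise ValueError(
                f"locus mismatch: {off.locus.name} vs {comp.locus.name}"
            )
        fr, qual = fold_reduction(comp.window_frequency, off.window_frequency, floor)
        off_freq = off.window_frequency
        rows.append(
            {
                "off_target": off.locus.name,
                "on_frequency": on.window_frequency,
                "off_frequency": off_freq if off_freq >= floor else floor,
                "off_below_floor": off_freq < floor,
                "on_off_ratio": on.window_frequency / max(off_freq, floor),
                "comparator_off_frequency": comp.window_frequency,
                "fold_reduction": fr,
                "fold_reduction_qualifier": qual,
            }
        )
    return pd.DataFrame(rows)


def replicate_stats(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sd / sqrt(n), sample sd) of replicates."""
    if len(values) < 2:
        raise ValueError("need >= 2 replicates for SEM")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))


def two_sample_ttest(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Equal-variance two-tailed Student t test; returns (t, p)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 observations per group")
    import warnings

    with warnings.catch_warnings():
        # zero pooled variance triggers a precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(group_a, group_b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero pooled variance
        if np.isclose(np.mean(group_a), np.mean(group_b)):
            return 0.0, 1.0
        return float("inf"), 0.0
    return t, p
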