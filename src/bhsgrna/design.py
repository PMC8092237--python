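"""Construction of hairpin and bubble-hairpin single guide RNAs.

A bubble-hairpin sgRNA (BH-sgRNA) carries, 5' of the ordinary 20-nt
spacer, the reverse complement of the spacer's own 5'-most H nucleotides,
joined by a 5'-ACAA-3' tetraloop.  The extension folds back onto the
spacer as a hairpin stem, which raises the energetic cost of R-loop
completion at mismatched (off-target) genomic sites.  For base editors
the stem would also occlude the editing window, so a "bubble" of B
deliberately non-pairing nucleotides is opened in the extension opposite
protospacer positions P..P+B-1, leaving the editing window accessible.

Coordinate conventions
----------------------
* Protospacer positions count the PAM-distal end as position 1; the
  PAM-proximal end of a 20-nt spacer is position 20.
* Hairpin (extension) positions count the 5' end of the molecule as
  position 1.  Because the extension is a reverse complement, hairpin
  position p sits opposite protospacer position H + 1 - p.
* A design is named ``H{H}-B{B}-P{P}`` (hairpin length, bubble size,
  first protospacer position of the bubble); ``H{H}`` for a plain
  hairpin with no bubble, and ``WT`` for an unmodified guide.

Defaults follow the optimized designs: cytosine base editors (CBE) use
H12-B3-P5 (bubble opposite protospacer 5-7, i.e. hairpin positions 6-8);
adenine base editors (ABE) use H12-B3-P4 (protospacer 4-6, hairpin 7-9),
matching their respective editing windows (CBE 4-8, ABE 4-7).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alphabet import (
    NucSeq,
    WC_PARTNER,
    WOBBLE_PARTNER,
    pairs,
    reverse_complement,
    transcribe,
    validate,
)

DEFAULT_LOOP = "ACAA"
#: editing windows in protospacer coordinates (inclusive), PAM-distal = 1
EDITING_WINDOWS = {"CBE": (4, 8), "ABE": (4, 7)}
#: canonical conversions on the protospacer strand
CANONICAL_EDIT = {"CBE": ("C", "T"), "ABE": ("A", "G")}
DEFAULT_BUBBLE_START = {"CBE": 5, "ABE": 4}

#: residue priority when picking a bubble nucleotide (see choose_bubble_nt)
_BUBBLE_PRIORITY = "CAGU"


@dataclass(frozen=True)
class Spacer:
    """A guide spacer (RNA); DNA input is transcribed on construction.

    The protospacer DNA and PAM may be attached for bookkeeping; they do
    not influence the design.
    """

    sequence: str
    protospacer: str | None = None
    pam: str | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        if "T" in seq:
            seq = transcribe(seq)
        seq = validate(seq, "RNA")
        if not 18 <= len(seq) <= 24:
            raise ValueError(
                f"spacer length {len(seq)} outside supported range 18-24"
            )
        if len(seq) != 20:
            warnings.warn(
                f"non-standard spacer length {len(seq)} (SpCas9 guides are 20 nt)",
                stacklevel=2,
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence

    def residue(self, position: int) -> str:
        """Residue at a 1-based protospacer position (PAM-distal = 1)."""
        if not 1 <= position <= len(self):
            raise ValueError(f"protospacer position {position} out of 1..{len(self)}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one hairpin / bubble-hairpin design."""

    editor: str = "CBE"  # CBE | ABE
    hairpin_len: int = 12  # H, loop excluded
    bubble_size: int = 3  # B; 0 = plain hairpin
    bubble_start: int | None = None  # P, protospacer coordinate
    loop: str = DEFAULT_LOOP

    def __post_init__(self):
        if self.editor not in ("CBE", "ABE"):
            raise ValueError(f"unknown editor {self.editor!r}")
        if not 0 <= self.hairpin_len <= 12:
            raise ValueError("hairpin length must be 0..12")
        if not 0 <= self.bubble_size <= self.hairpin_len:
            raise ValueError("bubble size must be 0..hairpin length")
        validate(self.loop, "RNA")
        if self.bubble_size == 0:
            if self.bubble_start is not None:
                warnings.warn("bubble_start ignored for B=0 design", stacklevel=2)
                object.__setattr__(self, "bubble_start", None)
        else:
            p = (
                self.bubble_start
                if self.bubble_start is not None
                else DEFAULT_BUBBLE_START[self.editor]
            )
            object.__setattr__(self, "bubble_start", p)
            if p < 1 or p + self.bubble_size - 1 > self.hairpin_len:
                raise ValueError(
                    f"bubble (P={p}, B={self.bubble_size}) outside the "
                    f"{self.hairpin_len}-nt paired region"
                )

    @classmethod
    def default(cls, editor: str = "CBE") -> "DesignSpec":
        """The optimized default: H12-B3-P5 for CBE, H12-B3-P4 for ABE."""
        return cls(editor=editor)

    @property
    def name(self) -> str:
        return name_design(self)

    @property
    def bubble_protospacer_positions(self) -> frozenset[int]:
        if self.bubble_size == 0:
            return frozenset()
        return frozenset(
            range(self.bubble_start, self.bubble_start + self.bubble_size)
        )

    @property
    def bubble_hairpin_positions(self) -> frozenset[int]:
        return frozenset(
            protospacer_to_hairpin(q, self.hairpin_len)
            for q in self.bubble_protospacer_positions
        )


@dataclass(frozen=True)
class BHsgRNA:
    """A constructed guide: extension + loop + spacer (+ optional scaffold)."""

    spacer: Spacer
    spec: DesignSpec
    extension: str  # RNA, length H; empty for WT
    scaffold: str | None = None
    name: str = field(default="")

    @property
    def loop(self) -> str:
        return self.spec.loop if self.spec.hairpin_len > 0 else ""

    @property
    def five_prime_region(self) -> str:
        """Extension + loop + spacer — the part that folds."""
        return self.extension + self.loop + self.spacer.sequence

    @property
    def full_sequence(self) -> str:
        return self.five_prime_region + (self.scaffold or "")

    @property
    def bubble_hairpin_positions(self) -> frozenset[int]:
        """Bubble positions, 1-based from the 5' end of the molecule."""
        return self.spec.bubble_hairpin_positions

    @property
    def bubble_protospacer_positions(self) -> frozenset[int]:
        return self.spec.bubble_protospacer_positions


def hairpin_to_protospacer(p: int, hairpin_len: int) -> int:
    """Map a hairpin (extension) position to the protospacer position opposite it.

    Hairpin position 1 is the 5' end of the molecule; the extension is the
    reverse complement of the spacer's first ``hairpin_len`` nucleotides,
    so position p faces protospacer position ``H + 1 - p``.  The map is an
    involution on 1..H.
    """
    if not 1 <= p <= hairpin_len:
        raise ValueError(f"hairpin position {p} out of 1..{hairpin_len}")
    return hairpin_len + 1 - p


# the inverse map is the same reflection; alias for readability
protospacer_to_hairpin = hairpin_to_protospacer


def choose_bubble_nt(opposing: str) -> str:
    """Pick a bubble residue guaranteed not to pair with ``opposing``.

    Both Watson-Crick and G-U wobble partners of the opposing spacer
    residue are excluded (a wobble pair would quietly close the bubble);
    the first survivor in the fixed priority order C, A, G, U is returned,
    so designs are deterministic.
    """
    opposing = opposing.upper().replace("T", "U")
    excluded = {WC_PARTNER[opposing]}
    if opposing in WOBBLE_PARTNER:
        excluded.add(WOBBLE_PARTNER[opposing])
    for r in _BUBBLE_PRIORITY:
        if r not in excluded:
            return r
    raise AssertionError("unreachable: at most 2 of 4 residues are excluded")


def build_bh_sgrna(
    spacer: Spacer,
    spec: DesignSpec,
    bubble_sequence: str | None = None,
    scaffold: str | None = None,
) -> BHsgRNA:
    """Construct the guide described by ``spec`` on ``spacer``.

    The extension is the reverse complement of the spacer's 5'-most H
    nucleotides; bubble positions are then substituted with non-pairing
    residues (``choose_bubble_nt``, or ``bubble_sequence`` given 5'->3'
    along the extension, validated with the same predicate).
    """
    H, B = spec.hairpin_len, spec.bubble_size
    if H > len(spacer):
        raise ValueError(f"hairpin length {H} exceeds spacer length {len(spacer)}")
    if scaffold is not None:
        scaffold = validate(scaffold, "RNA")
    if H == 0:
        return BHsgRNA(spacer, spec, extension="", scaffold=scaffold, name="WT")

    extension = list(reverse_complement(spacer.sequence[:H], "RNA"))
    bubble_hp = sorted(spec.bubble_hairpin_positions)
    if bubble_sequence is not None:
        bubble_sequence = validate(bubble_sequence, "RNA")
        if len(bubble_sequence) != B:
            raise ValueError(
                f"bubble sequence length {len(bubble_sequence)} != bubble size {B}"
            )
    for i, p in enumerate(bubble_hp):
        opposing = spacer.residue(hairpin_to_protospacer(p, H))
        if bubble_sequence is not None:
            r = bubble_sequence[i]
            if pairs(r, opposing, allow_wobble=True):
                raise ValueError(
                    f"user bubble residue {r} at hairpin position {p} pairs "
                    f"with spacer residue {opposing}"
                )
        else:
            r = choose_bubble_nt(opposing)
        extension[p - 1] = r
    return BHsgRNA(
        spacer,
        spec,
        extension="".join(extension),
        scaffold=scaffold,
        name=name_design(spec),
    )


DEFAULT_H_SET = (0, 2, 4, 6, 8, 10, 12)
DEFAULT_B_SET = (1, 2, 3)
DEFAULT_P_SET = (4, 5, 6, 7, 8)


def enumerate_series(
    spacer: Spacer,
    editor: str = "CBE",
    H_set: Sequence[int] = DEFAULT_H_SET,
    B_set: Sequence[int] = DEFAULT_B_SET,
    P_set: Sequence[int] = DEFAULT_P_SET,
    loop: str = DEFAULT_LOOP,
) -> list[BHsgRNA]:
    """Build the design grid: plain hairpins for each H plus every valid
    (H, B, P) bubble combination; combinations whose bubble would fall
    outside the paired region are silently dropped.  Deterministic order,
    deduplicated by name.
    """
    if not H_set:
        raise ValueError("empty hairpin-length set")
    designs: dict[str, BHsgRNA] = {}
    for H in sorted(set(H_set)):
        if H == 0:
            spec = DesignSpec(editor=editor, hairpin_len=0, bubble_size=0, loop=loop)
            designs.setdefault("WT", build_bh_sgrna(spacer, spec))
            continue
        spec = DesignSpec(editor=editor, hairpin_len=H, bubble_size=0, loop=loop)
        designs.setdefault(spec.name, build_bh_sgrna(spacer, spec))
        for B in sorted(set(B_set)):
            for P in sorted(set(P_set)):
                if P < 1 or P + B - 1 > H:
                    continue
                spec = DesignSpec(
                    editor=editor,
                    hairpin_len=H,
                    bubble_size=B,
                    bubble_start=P,
                    loop=loop,
                )
                designs.setdefault(spec.name, build_bh_sgrna(spacer, spec))
    return list(designs.values())


#: transversion-first substitution used for deliberately mismatched guides
MISMATCH_SUBSTITUTION = {"A": "C", "C": "A", "G": "U", "U": "G"}


def enumerate_mismatched_guides(
    spacer: Spacer,
    position_sets: Iterable[Sequence[int]],
    substitutions: dict[int, str] | None = None,
) -> list[tuple[Spacer, tuple[int, ...], str]]:
    """Build guides that differ from ``spacer`` at exactly the requested
    protospacer positions (1..3 mismatches each).

    Each element of ``position_sets`` is a tuple of distinct positions;
    the substituted residue defaults to the transversion-first rule
    (A<->C, G<->U) and can be overridden per position via
    ``substitutions``.  Returns (guide, positions, mutated residues).
    """
    out = []
    for positions in position_sets:
        positions = tuple(sorted(positions))
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate mismatch positions {positions}")
        if not 1 <= len(positions) <= 3:
            raise ValueError("1 to 3 mismatches per guide")
        seq = list(spacer.sequence)
        muts = []
        for p in positions:
            if not 1 <= p <= len(spacer):
                raise ValueError(f"position {p} outside spacer")
            old = seq[p - 1]
            new = (substitutions or {}).get(p, MISMATCH_SUBSTITUTION[old])
            if new == old:
                raise ValueError(f"substitution at {p} equals the spacer residue")
            seq[p - 1] = new
            muts.append(new)
        out.append((Spacer("".join(seq)), positions, "".join(muts)))
    return out


def single_mismatch_scan(L: int = 20) -> list[tuple[int, ...]]:
    """Position sets for a full single-mismatch scan (Hamming-1 panel)."""
    return [(p,) for p in range(1, L + 1)]


def adjacent_mismatch_blocks(L: int = 20, k: int = 2) -> list[tuple[int, ...]]:
    """Position sets of k adjacent mismatches sliding along the spacer."""
    return [tuple(range(p, p + k)) for p in range(1, L - k + 2)]


_NAME_RE = re.compile(r"^H(?P<H>\d+)(?:-B(?P<B>\d+)-P(?P<P>\d+))?$")


def name_design(spec: DesignSpec) -> str:
    """``H{H}-B{B}-P{P}``; ``H{H}`` when B=0; ``WT`` when H=0."""
    if spec.hairpin_len == 0:
        return "WT"
    if spec.bubble_size == 0:
        return f"H{spec.hairpin_len}"
    return f"H{spec.hairpin_len}-B{spec.bubble_size}-P{spec.bubble_start}"


def parse_design_name(name: str, editor: str = "CBE", loop: str = DEFAULT_LOOP) -> DesignSpec:
    """Inverse of :func:`name_design` (the editor is not encoded in names)."""
    name = name.strip()
    if name.upper() == "WT":
        return DesignSpec(editor=editor, hairpin_len=0, bubble_size=0, loop=loop)
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"malformed design name {name!r}")
    H = int(m.group("H"))
    if m.group("B") is None:
        return DesignSpec(editor=editor, hairpin_len=H, bubble_size=0, loop=loop)
    return DesignSpec(
        editor=editor,
        hairpin_len=H,
        bubble_size=int(m.group("B")),
        bubble_start=int(m.group("P")),
        loop=loop,
    )
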