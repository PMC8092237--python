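"""Nucleotide alphabets, complementation and base-pairing predicates.

Everything downstream (guide design, folding, quantification, off-target
scanning) shares these conventions:

* DNA alphabet ``{A, C, G, T}``, RNA alphabet ``{A, C, G, U}``.  The
  ambiguity code ``N`` is legal only inside PAM patterns, never in guides.
* User-facing coordinates are 1-based (protospacer position 1 is the end
  distal to the PAM); internal string indices are 0-based.
* ``pairs`` implements Watson-Crick pairing with optional G-U wobble,
  which matters twice: wobble pairs are *allowed* when folding (they are
  real RNA pairs) but *forbidden* inside a designed bubble, which must be
  genuinely unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")
PAM_ALPHABET = frozenset("ACGTN")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Watson-Crick partners on the RNA alphabet.
WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: G-U wobble partners (only G and U have one).
WOBBLE_PARTNER = {"G": "U", "U": "G"}


class AlphabetError(ValueError):
    """A residue outside the declared alphabet, reported with its position."""

    def __init__(self, residue: str, position: int, alphabet: str):
        self.residue = residue
        self.position = position  # 1-based
        self.alphabet = alphabet
        super().__init__(
            f"invalid {alphabet} residue {residue!r} at position {position}"
        )


def validate(seq: str, alphabet: str = "DNA", allow_n: bool = False) -> str:
    """Return ``seq`` upper-cased, or raise :class:`AlphabetError`.

    ``alphabet`` is ``"DNA"`` or ``"RNA"``; ``allow_n`` admits the
    ambiguity code N (PAM patterns only).
    """
    if alphabet not in ("DNA", "RNA"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if not seq:
        raise ValueError("empty sequence")
    residues = DNA_ALPHABET if alphabet == "DNA" else RNA_ALPHABET
    if allow_n:
        residues = residues | {"N"}
    seq = seq.upper()
    for i, r in enumerate(seq):
        if r not in residues:
            raise AlphabetError(r, i + 1, alphabet)
    return seq


@dataclass(frozen=True)
class NucSeq:
    """An immutable validated nucleotide sequence with an alphabet tag."""

    residues: str
    alphabet: str = "DNA"

    def __post_init__(self):
        object.__setattr__(
            self, "residues", validate(self.residues, self.alphabet)
        )

    def __str__(self) -> str:
        return self.residues

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self, out_alphabet: str | None = None) -> "NucSeq":
        out = out_alphabet or self.alphabet
        return NucSeq(reverse_complement(self.residues, self.alphabet, out), out)


def transcribe(seq: str) -> str:
    """DNA -> RNA (T becomes U); validates the input as DNA."""
    return validate(seq, "DNA").replace("T", "U")


def back_transcribe(seq: str) -> str:
    """RNA -> DNA (U becomes T); validates the input as RNA."""
    return validate(seq, "RNA").replace("U", "T")


def complement(seq: str, alphabet: str = "DNA") -> str:
    seq = validate(seq, alphabet)
    table = _DNA_COMPLEMENT if alphabet == "DNA" else _RNA_COMPLEMENT
    return seq.translate(table)


def reverse_complement(
    seq: str, alphabet: str = "DNA", out_alphabet: str | None = None
) -> str:
    """Reverse complement, optionally crossing alphabets (DNA <-> RNA).

    With a fixed alphabet the operation is an involution.
    """
    out_alphabet = out_alphabet or alphabet
    rc = complement(seq, alphabet)[::-1]
    if alphabet == out_alphabet:
        return rc
    if alphabet == "DNA" and out_alphabet == "RNA":
        return rc.replace("T", "U")
    if alphabet == "RNA" and out_alphabet == "DNA":
        return rc.replace("U", "T")
    raise ValueError(f"unknown alphabet {out_alphabet!r}")


def pairs(a: str, b: str, allow_wobble: bool = True) -> bool:
    """True iff residues ``a`` and ``b`` can base-pair.

    Watson-Crick pairs always count; G-U wobble counts only when
    ``allow_wobble`` is set.  T is treated as U, so the predicate works on
    either alphabet.  Symmetric in its arguments.
    """
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    for r in (a, b):
        if r not in RNA_ALPHABET:
            raise AlphabetError(r, 1, "RNA")
    if WC_PARTNER[a] == b:
        return True
    if allow_wobble and WOBBLE_PARTNER.get(a) == b:
        return True
    return False


def matches_pam(site: str, pattern: str) -> bool:
    """True iff DNA ``site`` matches a PAM ``pattern`` (N is a wildcard)."""
    if len(site) != len(pattern):
        return False
    return all(p == "N" or s == p for s, p in zip(site.upper(), pattern.upper()))
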