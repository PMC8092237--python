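"""Secondary-structure validation of designed guides.

The structural claims a hairpin design makes are topological — the
intended stem forms, the bubble stays open — so folding here is base-pair
maximization (Nussinov dynamic programming) rather than thermodynamic
free-energy minimization.  Pair maximization is exactly checkable against
brute-force enumeration, which the test suite does.  Sequences can be
exported for external thermodynamic folding if a comparison is wanted;
nothing in the package depends on one.

G-U wobble pairs count as pairs during folding (they are real RNA pairs)
even though the designer forbids them inside the bubble.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import pairs, validate
from .design import BHsgRNA, hairpin_to_protospacer

DEFAULT_MIN_LOOP = 3  # minimum unpaired residues enclosed by a pair


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing pair set over one sequence, with its dot-bracket."""

    sequence: str
    pair_set: frozenset[tuple[int, int]]  # 0-based (i, j), i < j
    min_loop: int = DEFAULT_MIN_LOOP

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pair_set:
            if not (0 <= i < j < len(self.sequence)):
                raise ValueError(f"pair ({i},{j}) outside sequence")
            if j - i <= self.min_loop:
                raise ValueError(f"pair ({i},{j}) violates min_loop {self.min_loop}")
            if i in seen or j in seen:
                raise ValueError("index in more than one pair")
            seen.update((i, j))
        for i, j in self.pair_set:
            for k, l in self.pair_set:
                if i < k < j < l:
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_set)

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pair_set:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


def nussinov_maxpairs(
    seq: str,
    min_loop: int = DEFAULT_MIN_LOOP,
    allow_wobble: bool = True,
    prefer_pairs: frozenset[tuple[int, int]] | None = None,
) -> SecondaryStructure:
    """Fold ``seq`` (RNA; T read as U) maximizing the number of base pairs.

    The pair count is the unique optimum; the traceback is deterministic:
    at each subproblem the 5'-most position is paired if any optimal
    structure pairs it, preferring a partner from ``prefer_pairs`` (used
    to ask "does some maximum-pairing structure contain the intended
    stem?"), then the smallest partner index.
    """
    seq = validate(seq.replace("T", "U").replace("t", "u"), "RNA")
    n = len(seq)
    can_pair = [
        [pairs(seq[i], seq[j], allow_wobble) for j in range(n)] for i in range(n)
    ]
    # N[i][j] = max pairs in seq[i..j]
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair[i][k]:
                    inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    outer = N[k + 1][j] if k + 1 < j else 0
                    cand = 1 + inner + outer
                    if cand > best:
                        best = cand
            N[i][j] = best

    preferred: dict[int, int] = {}
    for i, j in prefer_pairs or ():
        preferred[i] = j

    pair_list: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue

        def _paired_score(k: int) -> int:
            inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
            outer = N[k + 1][j] if k + 1 < j else 0
            return 1 + inner + outer

        chosen = None
        pk = preferred.get(i)
        if (
            pk is not None
            and i + min_loop + 1 <= pk <= j
            and can_pair[i][pk]
            and _paired_score(pk) == N[i][j]
        ):
            chosen = pk
        else:
            for k in range(i + min_loop + 1, j + 1):
                if can_pair[i][k] and _paired_score(k) == N[i][j]:
                    chosen = k
                    break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pair_list.append((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))

    return SecondaryStructure(seq, frozenset(pair_list), min_loop)


def pair_in_some_max_structure(
    seq: str,
    pair: tuple[int, int],
    min_loop: int = DEFAULT_MIN_LOOP,
    allow_wobble: bool = True,
) -> bool:
    """Exact test: does some maximum-cardinality structure contain ``pair``?

    Runs a weighted variant of the DP in which the queried pair scores
    1 + bonus; the weighted optimum exceeds the plain optimum iff a
    structure of maximum pair count containing the pair exists.
    """
    seq = validate(seq.replace("T", "U").replace("t", "u"), "RNA")
    n = len(seq)
    qi, qj = pair
    if not (0 <= qi < qj < n) or qj - qi <= min_loop:
        return False
    if not pairs(seq[qi], seq[qj], allow_wobble):
        return False
    can_pair = [
        [pairs(seq[i], seq[j], allow_wobble) for j in range(n)] for i in range(n)
    ]
    # weight: ordinary pair = 2, queried pair = 3.  With integer weights,
    # weighted_max == 2 * plain_max + 1 iff the queried pair is in some
    # maximum-cardinality structure (the +1 cannot buy an extra pair).
    plain = [[0] * n for _ in range(n)]
    wtd = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best_p, best_w = plain[i + 1][j], wtd[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if can_pair[i][k]:
                    ip = plain[i + 1][k - 1] if k - 1 > i + 1 else 0
                    op = plain[k + 1][j] if k + 1 < j else 0
                    iw = wtd[i + 1][k - 1] if k - 1 > i + 1 else 0
                    ow = wtd[k + 1][j] if k + 1 < j else 0
                    w = 3 if (i, k) == (qi, qj) else 2
                    best_p = max(best_p, 1 + ip + op)
                    best_w = max(best_w, w + iw + ow)
            plain[i][j] = best_p
            wtd[i][j] = best_w
    return wtd[0][n - 1] == 2 * plain[0][n - 1] + 1


def intended_pairing(design: BHsgRNA) -> frozenset[tuple[int, int]]:
    """The stem pairs the design intends, 0-based over the 5' region.

    Non-bubble extension position p (1-based) should pair with the spacer
    residue at protospacer position H+1-p, which sits at full-molecule
    position H + len(loop) + (H + 1 - p).
    """
    H = design.spec.hairpin_len
    if H == 0:
        return frozenset()
    loop_len = len(design.loop)
    out = []
    for p in range(1, H + 1):
        if p in design.bubble_hairpin_positions:
            continue
        q = hairpin_to_protospacer(p, H)  # protospacer position
        out.append((p - 1, H + loop_len + q - 1))
    return frozenset(out)


@dataclass(frozen=True)
class HairpinReport:
    design_name: str
    structure: SecondaryStructure
    n_intended: int
    n_intended_found: int
    n_bubble_paired: int  # bubble positions paired with their opposing residue
    verdict: str  # PASS | FAIL

    @property
    def intended_fraction(self) -> float:
        return 1.0 if self.n_intended == 0 else self.n_intended_found / self.n_intended


def hairpin_report(
    design: BHsgRNA,
    min_loop: int = DEFAULT_MIN_LOOP,
    required_fraction: float = 1.0,
) -> HairpinReport:
    """Fold the 5' region and check the design's structural intent.

    PASS iff at least ``required_fraction`` of intended stem pairs occur
    in some maximum-pairing structure (each pair tested exactly with
    :func:`pair_in_some_max_structure`) and no bubble position can pair
    with the stem residue it faces in any maximum-pairing structure.
    """
    intended = intended_pairing(design)
    seq = design.five_prime_region
    structure = nussinov_maxpairs(seq, min_loop=min_loop, prefer_pairs=intended)
    found = sum(
        1
        for p in intended
        if p in structure.pair_set
        or pair_in_some_max_structure(seq, p, min_loop=min_loop)
    )

    H = design.spec.hairpin_len
    loop_len = len(design.loop)
    bubble_opposing = frozenset(
        (p - 1, H + loop_len + hairpin_to_protospacer(p, H) - 1)
        for p in design.bubble_hairpin_positions
    )
    n_bubble_paired = sum(
        1
        for p in bubble_opposing
        if p in structure.pair_set
        or pair_in_some_max_structure(seq, p, min_loop=min_loop)
    )

    n_intended = len(intended)
    frac = 1.0 if n_intended == 0 else found / n_intended
    verdict = "PASS" if frac >= required_fraction and n_bubble_paired == 0 else "FAIL"
    return HairpinReport(
        design.name, structure, n_intended, found, n_bubble_paired, verdict
    )
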