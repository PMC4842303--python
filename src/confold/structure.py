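"""Secondary-structure primitives: dot-bracket strings, loop decomposition.

A secondary structure is represented as a set of 1-based position pairs
``(i, j)`` with ``i < j``, no shared endpoints and no crossing pairs
(pseudo-knot free).  The unique loop decomposition of such a pair set is
the unit of energy evaluation throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .grammar import DecompStep


class StructureError(ValueError):
    """Raised for malformed pair sets or dot-bracket strings."""


PairSet = frozenset


def normalize_pairs(pairs: Iterable[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    return frozenset((min(i, j), max(i, j)) for i, j in pairs)


def check_pairs(n: int, pairs: Iterable[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    """Validate a pair set: bounds, shared endpoints, crossings."""
    ps = normalize_pairs(pairs)
    seen: set[int] = set()
    for i, j in ps:
        if not (1 <= i < j <= n):
            raise StructureError(f"pair ({i},{j}) out of range 1..{n}")
        if i in seen or j in seen:
            raise StructureError(f"position reused by pair ({i},{j})")
        seen.update((i, j))
    sp = sorted(ps)
    for a in range(len(sp)):
        i, j = sp[a]
        for b in range(a + 1, len(sp)):
            k, l = sp[b]
            if k > j:
                break
            if i < k <= j < l:
                raise StructureError(f"crossing pairs ({i},{j}) and ({k},{l})")
    return ps


def dotbracket_to_pairs(db: str) -> frozenset[tuple[int, int]]:
    """Parse a dot-bracket string into a pair set (1-based)."""
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"unexpected character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return frozenset(pairs)


def pairs_to_dotbracket(n: int, pairs: Iterable[tuple[int, int]]) -> str:
    chars = ["."] * (n + 1)
    for i, j in normalize_pairs(pairs):
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars[1:])


@dataclass(frozen=True)
class Loop:
    """One loop of the decomposition.

    kind: 'exterior', 'hairpin', 'interior' (incl. stacks/bulges) or
    'multibranch'.  ``closing`` is None for the exterior loop.
    """

    kind: str
    closing: tuple[int, int] | None
    enclosed: tuple[tuple[int, int], ...]
    unpaired: tuple[int, ...]


def loop_decomposition(n: int, pairs: Iterable[tuple[int, int]]) -> list[Loop]:
    """Decompose a valid structure into its loops (exterior loop first)."""
    ps = check_pairs(n, pairs)
    partner = [0] * (n + 2)
    for i, j in ps:
        partner[i] = j
        partner[j] = i

    loops: list[Loop] = []

    def scan(lo: int, hi: int, closing: tuple[int, int] | None) -> None:
        enclosed: list[tuple[int, int]] = []
        unpaired: list[int] = []
        x = lo
        while x <= hi:
            if partner[x] == 0:
                unpaired.append(x)
                x += 1
            else:
                enclosed.append((x, partner[x]))
                x = partner[x] + 1
        if closing is None:
            kind = "exterior"
        elif not enclosed:
            kind = "hairpin"
        elif len(enclosed) == 1:
            kind = "interior"
        else:
            kind = "multibranch"
        loops.append(Loop(kind, closing, tuple(enclosed), tuple(unpaired)))
        for i, j in enclosed:
            scan(i + 1, j - 1, (i, j))

    scan(1, n, None)
    return loops


def derivation_steps(
    n: int, pairs: Iterable[tuple[int, int]]
) -> Iterator[tuple[DecompStep, int, int, int, int]]:
    """The unique grammar derivation of a structure, as (step, i, j, k, l).

    Used by the declarative oracle to evaluate generic per-step soft
    constraints on an explicitly given structure, independently of the
    dynamic programming recursions.
    """
    ps = check_pairs(n, pairs)
    partner = [0] * (n + 2)
    for i, j in ps:
        partner[i] = j
        partner[j] = i

    # exterior walk
    x = 1
    while x <= n:
        if partner[x] == 0:
            yield (DecompStep.EXT_UNPAIRED, x, 0, 0, 0)
            x += 1
        else:
            yield (DecompStep.EXT_STEM, x, partner[x], 0, 0)
            x = partner[x] + 1

    def close(i: int, j: int) -> Iterator[tuple[DecompStep, int, int, int, int]]:
        enclosed = []
        x = i + 1
        while x < j:
            if partner[x] == 0:
                x += 1
            else:
                enclosed.append((x, partner[x]))
                x = partner[x] + 1
        if not enclosed:
            yield (DecompStep.HAIRPIN_LOOP, i, j, 0, 0)
            return
        if len(enclosed) == 1:
            k, l = enclosed[0]
            yield (DecompStep.INTERIOR_LOOP, i, j, k, l)
            yield from close(k, l)
            return
        # multibranch: closing step, then the M region up to the last branch,
        # then the rightmost component M1.
        last = enclosed[-1]
        yield (DecompStep.MULTI_CLOSING, i, j, last[0], 0)
        x = i + 1
        for idx, (bi, bj) in enumerate(enclosed[:-1]):
            while x < bi:
                yield (DecompStep.ML_UNPAIRED, x, 0, 0, 0)
                x += 1
            more_branches = idx < len(enclosed) - 2
            if more_branches:
                yield (DecompStep.ML_SPLIT, bi, bj, last[0] - 1, 0)
            else:
                yield (DecompStep.ML_STEM, bi, bj, last[0] - 1, 0)
                for u in range(bj + 1, last[0]):
                    yield (DecompStep.ML_UNPAIRED, u, 0, 0, 0)
            x = bj + 1
        yield (DecompStep.M1_STEM, last[0], last[1], 0, 0)
        for u in range(last[1] + 1, j):
            yield (DecompStep.M1_UNPAIRED, u, 0, 0, 0)
        for bi, bj in enclosed:
            yield from close(bi, bj)

    x = 1
    while x <= n:
        if partner[x] == 0:
            x += 1
        else:
            yield from close(x, partner[x])
            x = partner[x] + 1
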