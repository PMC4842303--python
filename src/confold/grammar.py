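"""Folding-grammar vocabulary shared by the constraint layer and the engine.

The search space is generated by the classic four-nonterminal grammar

    F  -> . F | C F          (exterior loop)
    C  -> hairpin | interior(C) | a M M1   (loop closed by a pair)
    M  -> . M | C M | C ...  (multibranch components, left to right)
    M1 -> C | M1 .           (rightmost multibranch component)

Hard and soft constraints attach to individual productions, so both layers
need a common enumeration of the decomposition steps and of the contexts a
base pair or an unpaired nucleotide can appear in.
"""

from __future__ import annotations

import enum


class PairContext(enum.IntFlag):
    """The six roles a base pair can play in the loop decomposition."""

    EXTERIOR = 1           # pair enclosed in the exterior loop
    HAIRPIN_CLOSING = 2
    INTERIOR_CLOSING = 4
    INTERIOR_ENCLOSED = 8
    MULTI_CLOSING = 16
    MULTI_ENCLOSED = 32
    ALL = 63


#: contexts in which a pair closes a loop; the context-free pair bonus
#: (Delta_ij) is charged exactly once, at the closing evaluation.
CLOSING_CONTEXTS = (
    PairContext.HAIRPIN_CLOSING
    | PairContext.INTERIOR_CLOSING
    | PairContext.MULTI_CLOSING
)


class UnpairedContext(enum.IntFlag):
    """The four loop types an unpaired nucleotide can sit in."""

    EXTERIOR = 1
    HAIRPIN = 2
    INTERIOR = 4
    MULTI = 8
    ALL = 15


class DecompStep(enum.Enum):
    """The ten decomposition cases of the folding grammar.

    Generic constraint callbacks receive one of these plus up to four
    delimiting 1-based positions ``(i, j, k, l)``; unused slots are 0.
    Position conventions:

    ==================  =============================================
    step                positions
    ==================  =============================================
    EXT_UNPAIRED        i unpaired in the exterior loop
    EXT_STEM            (i, j) pair enclosed in the exterior loop
    HAIRPIN_LOOP        (i, j) closing pair of a hairpin
    INTERIOR_LOOP       (i, j) closing, (k, l) enclosed pair
    MULTI_CLOSING       (i, j) closing pair, k start of last branch
    ML_UNPAIRED         i unpaired inside a multibranch loop (M part)
    ML_SPLIT            branch (i, j) followed by more branches up to k
    ML_STEM             last M branch (i, j), trailing run up to k
    M1_STEM             rightmost multibranch component is the pair (i, j)
    M1_UNPAIRED         i unpaired right of the rightmost branch
    ==================  =============================================
    """

    EXT_UNPAIRED = "ext_unpaired"
    EXT_STEM = "ext_stem"
    HAIRPIN_LOOP = "hairpin_loop"
    INTERIOR_LOOP = "interior_loop"
    MULTI_CLOSING = "multi_closing"
    ML_UNPAIRED = "ml_unpaired"
    ML_SPLIT = "ml_split"
    ML_STEM = "ml_stem"
    M1_STEM = "m1_stem"
    M1_UNPAIRED = "m1_unpaired"


#: map of single-letter loop-context codes used in constraint files
CONTEXT_LETTERS = {
    "E": (UnpairedContext.EXTERIOR, PairContext.EXTERIOR),
    "H": (UnpairedContext.HAIRPIN, PairContext.HAIRPIN_CLOSING),
    "I": (
        UnpairedContext.INTERIOR,
        PairContext.INTERIOR_CLOSING | PairContext.INTERIOR_ENCLOSED,
    ),
    "M": (
        UnpairedContext.MULTI,
        PairContext.MULTI_CLOSING | PairContext.MULTI_ENCLOSED,
    ),
}


def parse_context_letters(letters: str) -> tuple[UnpairedContext, PairContext]:
    """Translate a string of context letters (subset of ``EHIM``) to masks."""
    if not letters:
        return UnpairedContext.ALL, PairContext.ALL
    umask = UnpairedContext(0)
    pmask = PairContext(0)
    for ch in letters:
        try:
            u, p = CONTEXT_LETTERS[ch.upper()]
        except KeyError:
            raise ValueError(f"unknown loop-context letter {ch!r}") from None
        umask |= u
        pmask |= p
    return umask, pmask
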