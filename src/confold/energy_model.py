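"""Loop-decomposed nearest-neighbor free energy model.

The total standard free energy E0(psi) of a structure psi is the sum of the
free energies of the loops in its unique loop decomposition: hairpin loops,
interior loops (including stacks and bulges), multibranch loops and the
exterior loop (which contributes 0 here).

The parameter set is deliberately compact: a full table of canonical
stacking energies plus six scalar loop coefficients.  It follows the shape
of the Turner nearest-neighbor model (logarithmic hairpin size penalty,
linear multibranch decomposition, size+asymmetry interior penalty) but
drops dangling ends, terminal mismatches and special small-loop tables, so
that an exhaustive enumeration oracle can reproduce every number exactly.
All parameters can be overridden through a flat key/value config file; the
constraint machinery on top is parameter-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .structure import StructureError, check_pairs, loop_decomposition

CANONICAL_PAIRS = ("CG", "GC", "GU", "UG", "AU", "UA")

#: symmetric stack table S[p1][p2] where p1 = pair (i,j) read 5'->3' and
#: p2 = pair (l,k), i.e. the enclosed pair read 3'->5'.  kcal/mol at 37 C.
_STACK_SYM = {
    ("CG", "CG"): -2.4, ("CG", "GC"): -3.3, ("CG", "GU"): -2.1,
    ("CG", "UG"): -1.4, ("CG", "AU"): -2.1, ("CG", "UA"): -2.1,
    ("GC", "GC"): -3.4, ("GC", "GU"): -2.5, ("GC", "UG"): -1.5,
    ("GC", "AU"): -2.2, ("GC", "UA"): -2.4,
    ("GU", "GU"): 1.3, ("GU", "UG"): -0.5, ("GU", "AU"): -1.4,
    ("GU", "UA"): -1.3,
    ("UG", "UG"): 0.3, ("UG", "AU"): -0.6, ("UG", "UA"): -1.0,
    ("AU", "AU"): -1.1, ("AU", "UA"): -0.9,
    ("UA", "UA"): -1.3,
}


def _default_stacks() -> dict[tuple[str, str], float]:
    """Expand the symmetric table to all 36 ordered (outer, inner) keys.

    Keys are ``(pair(i,j), pair(k,l))`` with both pairs read 5'->3'; the
    physical symmetry E[(i,j),(k,l)] = E[(l,k),(j,i)] is built in.
    """
    sym = dict(_STACK_SYM)
    for (a, b), e in list(sym.items()):
        sym[(b, a)] = e
    table = {}
    for outer in CANONICAL_PAIRS:
        for inner in CANONICAL_PAIRS:
            table[(outer, inner)] = sym[(outer, inner[::-1])]
    return table


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and gas constant; RT in kcal/mol is derived."""

    temperature: float = 310.15           # K
    gas_constant: float = 1.98717e-3      # kcal/(mol K)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature


class Sequence:
    """A validated RNA sequence (1-based access).

    DNA input is accepted (T -> U) and lowercase is uppercased.  The
    pairing predicate defines the admissible pair set B(x): Watson-Crick
    plus wobble GU/UG.
    """

    __slots__ = ("residues",)

    def __init__(self, residues: str):
        s = residues.strip().upper().replace("T", "U")
        bad = set(s) - set("ACGU")
        if bad:
            raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
        self.residues = s

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __repr__(self) -> str:
        return f"Sequence({self.residues!r})"

    def residue(self, i: int) -> str:
        """1-based residue access."""
        return self.residues[i - 1]

    def pair_type(self, i: int, j: int) -> str:
        return self.residues[i - 1] + self.residues[j - 1]

    def pairable(self, i: int, j: int) -> bool:
        return self.pair_type(i, j) in CANONICAL_PAIRS


@dataclass
class NearestNeighborModel:
    """Compact nearest-neighbor parameter set (kcal/mol)."""

    stack_energies: dict[tuple[str, str], float] = field(default_factory=_default_stacks)
    hairpin_base: float = 5.6
    hairpin_log_coeff: float = 1.08
    interior_size_coeff: float = 0.5
    interior_asymmetry_coeff: float = 0.5
    multiloop_closing: float = 3.4
    multiloop_branch: float = 0.4
    multiloop_unpaired: float = 0.0
    min_hairpin_unpaired: int = 3

    def __post_init__(self) -> None:
        if self.min_hairpin_unpaired < 0:
            raise ValueError("min_hairpin_unpaired must be >= 0")
        for outer in CANONICAL_PAIRS:
            for inner in CANONICAL_PAIRS:
                if (outer, inner) not in self.stack_energies:
                    raise ValueError(f"missing stack energy for {outer}/{inner}")

    @classmethod
    def default(cls) -> "NearestNeighborModel":
        return cls()

    @classmethod
    def zero(cls) -> "NearestNeighborModel":
        """All parameters 0 -- every structure has E0 = 0."""
        stacks = {k: 0.0 for k in _default_stacks()}
        return cls(stack_energies=stacks, hairpin_base=0.0, hairpin_log_coeff=0.0,
                   interior_size_coeff=0.0, interior_asymmetry_coeff=0.0,
                   multiloop_closing=0.0, multiloop_branch=0.0,
                   multiloop_unpaired=0.0)

    @classmethod
    def from_config(cls, source: Mapping[str, str] | str) -> "NearestNeighborModel":
        """Build a model from a flat key/value config.

        ``source`` is either a mapping or a path to a text file of
        ``key value`` (or ``key = value``) lines; ``#`` starts a comment.
        Scalar keys are named exactly as the model fields; stack entries
        use ``stack_XY_ZW`` (outer pair XY, inner pair ZW, both 5'->3').
        """
        if isinstance(source, str):
            entries: dict[str, str] = {}
            with open(source) as fh:
                for lineno, raw in enumerate(fh, start=1):
                    line = raw.split("#", 1)[0].strip()
                    if not line:
                        continue
                    parts = line.replace("=", " ").split()
                    if len(parts) != 2:
                        raise ValueError(f"{source}:{lineno}: expected 'key value'")
                    entries[parts[0]] = parts[1]
            source = entries
        model = cls()
        for key, value in source.items():
            if key.startswith("stack_"):
                _, outer, inner = key.split("_")
                if outer not in CANONICAL_PAIRS or inner not in CANONICAL_PAIRS:
                    raise ValueError(f"bad stack key {key!r}")
                model.stack_energies[(outer, inner)] = float(value)
            elif key == "min_hairpin_unpaired":
                model.min_hairpin_unpaired = int(value)
            elif hasattr(model, key) and key != "stack_energies":
                setattr(model, key, float(value))
            else:
                raise ValueError(f"unknown model parameter {key!r}")
        return model


def eval_hairpin(seq: Sequence, i: int, j: int, model: NearestNeighborModel) -> float:
    """Free energy of the hairpin loop closed by (i, j).

    Logarithmic size dependence: base + coeff * ln(size / min_size).
    """
    size = j - i - 1
    if size < model.min_hairpin_unpaired:
        raise ValueError(
            f"hairpin ({i},{j}) has {size} unpaired nucleotides; "
            f"at least {model.min_hairpin_unpaired} required"
        )
    if not seq.pairable(i, j):
        raise ValueError(f"({i},{j}) is not an admissible pair")
    if size == model.min_hairpin_unpaired:
        return model.hairpin_base
    return model.hairpin_base + model.hairpin_log_coeff * math.log(
        size / model.min_hairpin_unpaired
    )


def eval_interior(
    seq: Sequence, i: int, j: int, k: int, l: int, model: NearestNeighborModel
) -> float:
    """Free energy of the interior loop (i, j; k, l), stacks included."""
    if not (i < k <= l < j):
        raise ValueError(f"interior loop indices must satisfy i<k<=l<j, got {(i, j, k, l)}")
    if not (seq.pairable(i, j) and seq.pairable(k, l)):
        raise ValueError(f"interior loop pairs {(i, j)}/{(k, l)} violate the pairing rules")
    u1 = k - i - 1
    u2 = j - l - 1
    if u1 == 0 and u2 == 0:
        return model.stack_energies[(seq.pair_type(i, j), seq.pair_type(k, l))]
    return (
        model.interior_size_coeff * (u1 + u2)
        + model.interior_asymmetry_coeff * abs(u1 - u2)
    )


def eval_multiloop(branches: int, unpaired: int, model: NearestNeighborModel) -> float:
    """Linear multibranch loop energy; ``branches`` excludes the closing pair."""
    return (
        model.multiloop_closing
        + model.multiloop_branch * (branches + 1)
        + model.multiloop_unpaired * unpaired
    )


def eval_structure(
    seq: Sequence,
    pairs: Iterable[tuple[int, int]],
    model: NearestNeighborModel,
) -> float:
    """Standard-model energy E0(psi): sum over the loop decomposition."""
    n = len(seq)
    ps = check_pairs(n, pairs)
    for i, j in ps:
        if not seq.pairable(i, j):
            raise StructureError(f"({i},{j}) violates the pairing rules")
        if j - i - 1 < model.min_hairpin_unpaired:
            raise StructureError(f"pair ({i},{j}) closes a too-short loop")
    total = 0.0
    for loop in loop_decomposition(n, ps):
        if loop.kind == "exterior":
            continue
        i, j = loop.closing
        if loop.kind == "hairpin":
            total += eval_hairpin(seq, i, j, model)
        elif loop.kind == "interior":
            (k, l), = loop.enclosed
            total += eval_interior(seq, i, j, k, l, model)
        else:
            total += eval_multiloop(len(loop.enclosed), len(loop.unpaired), model)
    return total
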