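"""Hard and soft folding constraints.

Hard constraints restrict the search space: an upper-triangular matrix of
per-pair bit masks (one bit per pair context) plus per-position unpaired
bit masks (one bit per loop type).  The folding recursions skip any term
whose bit is cleared.  Soft constraints are additive pseudo-energies: a
per-position term delta_i charged to unpaired nucleotides, a per-pair term
Delta_ij charged once at the closing evaluation of the loop the pair
closes, optional loop-type-specific variants of both, generic per
decomposition-step callbacks, and interval binding sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence as TSequence

import numpy as np

from .energy_model import Sequence, ThermoParams
from .grammar import (
    CLOSING_CONTEXTS,
    DecompStep,
    PairContext,
    UnpairedContext,
    parse_context_letters,
)

PAIR_ALL = int(PairContext.ALL)
UNP_ALL = int(UnpairedContext.ALL)


class ConstraintError(ValueError):
    """Malformed constraint input."""


class InconsistentConstraintError(ConstraintError):
    """Mutually contradictory constraint directives."""


# --------------------------------------------------------------------------
# directives

_DIRECTIVE_KINDS = frozenset({
    "forbid_pair", "enforce_pair", "force_unpaired", "force_paired",
    "force_paired_upstream", "force_paired_downstream",
    "enforce_interior_loop", "forbid_interior_loop",
    "span_limit", "multiloop_degree_limit",
})


@dataclass(frozen=True)
class ConstraintDirective:
    """One declarative hard-constraint command.

    ``pos`` carries the positions the kind needs: (i, j) for pair kinds,
    (i,) for positional kinds, (u', u'', v', v'') for interior-loop kinds,
    (L,) for span_limit and (d,) for multiloop_degree_limit.  The context
    masks default to "all contexts", which reproduces the classic
    loop-type-unaware behaviour.
    """

    kind: str
    pos: tuple[int, ...]
    pair_context: PairContext = PairContext.ALL
    unpaired_context: UnpairedContext = UnpairedContext.ALL

    def __post_init__(self) -> None:
        if self.kind not in _DIRECTIVE_KINDS:
            raise ConstraintError(f"unknown directive kind {self.kind!r}")


def forbid_pair(i: int, j: int, context: PairContext = PairContext.ALL) -> ConstraintDirective:
    return ConstraintDirective("forbid_pair", (min(i, j), max(i, j)), pair_context=context)


def enforce_pair(i: int, j: int, context: PairContext = PairContext.ALL) -> ConstraintDirective:
    return ConstraintDirective("enforce_pair", (min(i, j), max(i, j)), pair_context=context)


def force_unpaired(i: int) -> ConstraintDirective:
    return ConstraintDirective("force_unpaired", (i,))


def force_paired(i: int, context: UnpairedContext = UnpairedContext.ALL) -> ConstraintDirective:
    return ConstraintDirective("force_paired", (i,), unpaired_context=context)


def force_paired_downstream(i: int) -> ConstraintDirective:
    return ConstraintDirective("force_paired_downstream", (i,))


def force_paired_upstream(i: int) -> ConstraintDirective:
    return ConstraintDirective("force_paired_upstream", (i,))


def span_limit(L: int) -> ConstraintDirective:
    return ConstraintDirective("span_limit", (L,))


# --------------------------------------------------------------------------
# hard-constraint matrix


class HardConstraintMatrix:
    """Bit-packed pair/unpaired context masks X^tau plus sparse loop bans.

    ``pair[i, j]`` (i < j) holds six bits, one per :class:`PairContext`;
    ``unpaired[i]`` holds four bits, one per :class:`UnpairedContext`.
    A cleared bit means the corresponding recursion term is skipped.
    Forbidden interior loops are kept in a sparse set of (i, j, k, l)
    tuples, never as a dense O(n^4) array.
    """

    def __init__(self, n: int):
        self.n = n
        self.pair = np.zeros((n + 1, n + 1), dtype=np.uint8)
        self.unpaired = np.full(n + 1, UNP_ALL, dtype=np.uint8)
        self.unpaired[0] = 0
        self.forbidden_interior_loops: set[tuple[int, int, int, int]] = set()
        self.multiloop_degree_limit: int | None = None
        self._enforced_pairs: set[tuple[int, int]] = set()

    @classmethod
    def permissive(cls, seq: Sequence, min_hairpin_unpaired: int = 3) -> "HardConstraintMatrix":
        """Every bit set except pairs violating B(x) or the hairpin span rule."""
        n = len(seq)
        m = cls(n)
        for i in range(1, n + 1):
            for j in range(i + min_hairpin_unpaired + 1, n + 1):
                if seq.pairable(i, j):
                    m.pair[i, j] = PAIR_ALL
        return m

    # -- queries ----------------------------------------------------------
    def pair_mask(self, i: int, j: int) -> int:
        return int(self.pair[i, j])

    def allows_pair(self, i: int, j: int, context: PairContext) -> bool:
        return bool(self.pair[i, j] & int(context))

    def allows_unpaired(self, i: int, context: UnpairedContext) -> bool:
        return bool(self.unpaired[i] & int(context))

    def any_pair(self, i: int, j: int) -> bool:
        return bool(self.pair[i, j])

    def any_unpaired(self, i: int) -> bool:
        return bool(self.unpaired[i])

    def copy(self) -> "HardConstraintMatrix":
        m = HardConstraintMatrix(self.n)
        m.pair = self.pair.copy()
        m.unpaired = self.unpaired.copy()
        m.forbidden_interior_loops = set(self.forbidden_interior_loops)
        m.multiloop_degree_limit = self.multiloop_degree_limit
        m._enforced_pairs = set(self._enforced_pairs)
        return m

    # -- mutation helpers -------------------------------------------------
    def clear_pair(self, i: int, j: int, mask: int = PAIR_ALL) -> None:
        if i > j:
            i, j = j, i
        self.pair[i, j] &= ~np.uint8(mask)

    def clear_unpaired(self, i: int, mask: int = UNP_ALL) -> None:
        self.unpaired[i] &= ~np.uint8(mask)

    def _clear_all_partners(self, i: int, keep: int | None = None) -> None:
        for k in range(1, i):
            if k != keep:
                self.pair[k, i] = 0
        for k in range(i + 1, self.n + 1):
            if k != keep:
                self.pair[i, k] = 0


def compile_constraints(
    seq: Sequence,
    directives: Iterable[ConstraintDirective],
    min_hairpin_unpaired: int = 3,
) -> HardConstraintMatrix:
    """Build and propagate the hard-constraint matrix for ``seq``.

    The pairing-rule and hairpin-span bits are cleared first; directives
    are then applied in order.  Total work is O(n^3) for any directive
    list (each enforced pair clears at most O(n^2) bits and a structure
    admits fewer than n/2 enforced pairs).  Raises
    :class:`InconsistentConstraintError` when a pair is both enforced and
    forbidden.
    """
    n = len(seq)
    m = HardConstraintMatrix.permissive(seq, min_hairpin_unpaired)
    forbidden: set[tuple[int, int]] = set()

    def check_range(*positions: int) -> None:
        for p in positions:
            if not (1 <= p <= n):
                raise ConstraintError(f"position {p} outside sequence 1..{n}")

    def do_enforce_pair(i: int, j: int, ctx: PairContext) -> None:
        if (i, j) in forbidden or not m.any_pair(i, j):
            raise InconsistentConstraintError(
                f"pair ({i},{j}) is enforced but cannot be formed"
            )
        m.clear_unpaired(i)
        m.clear_unpaired(j)
        m._clear_all_partners(i, keep=j)
        m._clear_all_partners(j, keep=i)
        # pairs crossing (i,j) are inconsistent with it
        for a in range(1, n + 1):
            for b in range(a + 1, n + 1):
                if (a < i < b < j) or (i < a < j < b):
                    m.pair[a, b] = 0
        m.pair[i, j] &= np.uint8(int(ctx))
        if not m.any_pair(i, j):
            raise InconsistentConstraintError(
                f"pair ({i},{j}) is enforced but every context is forbidden"
            )
        m._enforced_pairs.add((i, j))

    for d in directives:
        kind = d.kind
        if kind == "forbid_pair":
            i, j = d.pos
            check_range(i, j)
            if (i, j) in m._enforced_pairs and d.pair_context == PairContext.ALL:
                raise InconsistentConstraintError(
                    f"pair ({i},{j}) is both enforced and forbidden"
                )
            m.clear_pair(i, j, int(d.pair_context))
            forbidden.add((i, j))
        elif kind == "enforce_pair":
            i, j = d.pos
            check_range(i, j)
            do_enforce_pair(i, j, d.pair_context)
        elif kind == "force_unpaired":
            (i,) = d.pos
            check_range(i)
            m._clear_all_partners(i)
        elif kind == "force_paired":
            (i,) = d.pos
            check_range(i)
            m.clear_unpaired(i, int(d.unpaired_context))
        elif kind == "force_paired_downstream":
            # '<': the partner lies strictly downstream of i
            (i,) = d.pos
            check_range(i)
            m.clear_unpaired(i)
            for k in range(1, i):
                m.pair[k, i] = 0
        elif kind == "force_paired_upstream":
            (i,) = d.pos
            check_range(i)
            m.clear_unpaired(i)
            for k in range(i + 1, n + 1):
                m.pair[i, k] = 0
        elif kind == "enforce_interior_loop":
            u1, u2, v1, v2 = d.pos
            check_range(u1, u2, v1, v2)
            if not (u1 < v1 < v2 < u2):
                raise ConstraintError(
                    f"interior loop needs u' < v' < v'' < u'', got {d.pos}"
                )
            do_enforce_pair(u1, u2, PairContext.ALL)
            do_enforce_pair(v1, v2, PairContext.ALL)
            # (u1,u2) may only close an interior loop
            m.clear_pair(u1, u2, int(PairContext.HAIRPIN_CLOSING | PairContext.MULTI_CLOSING))
            for w in range(u1 + 1, v1):
                m._clear_all_partners(w)
            for w in range(v2 + 1, u2):
                m._clear_all_partners(w)
        elif kind == "forbid_interior_loop":
            i, j, k, l = d.pos
            check_range(i, j, k, l)
            m.forbidden_interior_loops.add((i, j, k, l))
        elif kind == "span_limit":
            (L,) = d.pos
            for i in range(1, n + 1):
                for j in range(i + L, n + 1):  # span j-i+1 > L
                    m.pair[i, j] = 0
        elif kind == "multiloop_degree_limit":
            (deg,) = d.pos
            if deg != 2:
                raise ConstraintError("only a multibranch degree limit of 2 is supported")
            m.multiloop_degree_limit = 2
    return m


def check_consistency(matrix: HardConstraintMatrix) -> list[int]:
    """Necessary consistency condition: every position can be unpaired or
    paired with at least one partner.  Returns the violating positions
    (empty list = condition holds; the condition is not sufficient)."""
    bad = []
    for i in range(1, matrix.n + 1):
        if matrix.any_unpaired(i):
            continue
        if matrix.pair[1:i, i].any() or matrix.pair[i, i + 1:].any():
            continue
        bad.append(i)
    return bad


def unpaired_run_index(matrix: HardConstraintMatrix) -> np.ndarray:
    """index[i] = number of consecutive positions starting at i that may be
    unpaired (any context bit).  Enables O(1) loop feasibility checks."""
    n = matrix.n
    idx = np.zeros(n + 2, dtype=np.int64)
    for i in range(n, 0, -1):
        idx[i] = idx[i + 1] + 1 if matrix.any_unpaired(i) else 0
    return idx[1:n + 1]


# --------------------------------------------------------------------------
# soft constraints


@dataclass
class GenericConstraintCallback:
    """A per-decomposition-step constraint f(step, i, j, k, l, payload).

    Soft callbacks return a bonus energy (kcal/mol); hard callbacks return
    True to allow the decomposition and False to skip it.  ``init`` (if
    given) is invoked as ``init(payload, seq, model, thermo)`` before a
    fold starts.  Multiple soft callbacks compose additively, hard ones
    conjunctively.
    """

    function: Callable[[DecompStep, int, int, int, int, object], float | bool]
    payload: object = None
    init: Callable[..., None] | None = None
    is_hard: bool = False


@dataclass(frozen=True)
class BindingSite:
    """An interval [p, q] that a ligand/protein may occupy as a unit."""

    p: int
    q: int
    beta: float
    contexts: UnpairedContext = (
        UnpairedContext.HAIRPIN | UnpairedContext.INTERIOR | UnpairedContext.MULTI
    )


@dataclass
class BindingSiteSet:
    sites: list[BindingSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def add(self, p: int, q: int, beta: float,
            contexts: UnpairedContext | None = None) -> None:
        if not (1 <= p <= q):
            raise ConstraintError(f"bad binding site interval [{p},{q}]")
        if not math.isfinite(beta):
            raise ConstraintError("binding-site bonus must be finite")
        if contexts is None:
            contexts = BindingSite.__dataclass_fields__["contexts"].default
        if contexts & UnpairedContext.EXTERIOR:
            raise ConstraintError(
                "binding sites are supported in hairpin, interior and "
                "multibranch loops only"
            )
        self.sites.append(BindingSite(p, q, beta, contexts))

    def ending_at(self, x: int, context: UnpairedContext) -> list[BindingSite]:
        return [s for s in self.sites if s.q == x and s.contexts & context]


_UCTX_BITS = (UnpairedContext.EXTERIOR, UnpairedContext.HAIRPIN,
              UnpairedContext.INTERIOR, UnpairedContext.MULTI)
_PCTX_BITS = (PairContext.EXTERIOR, PairContext.HAIRPIN_CLOSING,
              PairContext.INTERIOR_CLOSING, PairContext.INTERIOR_ENCLOSED,
              PairContext.MULTI_CLOSING, PairContext.MULTI_ENCLOSED)


class SoftConstraintSet:
    """Additive pseudo-energies delta_i / Delta_ij (+ per-loop-type variants),
    generic callbacks and binding sites.

    Only the reduced parameters are stored: per Eqs. delta_i = b^u_i - b^p_i
    and Delta_ij = b^p_ij - b^u_ij the paired/unpaired bonus pairs collapse
    to a single parameter each, and the structure-independent constant E'
    never influences the ensemble.  Prefix sums of the unpaired terms give
    O(1) energies for unpaired runs.
    """

    def __init__(self, n: int):
        self.n = n
        self.delta_unpaired = np.zeros(n + 1)
        self.delta_pair = np.zeros((n + 1, n + 1))
        self._unpaired_ctx: dict[UnpairedContext, np.ndarray] = {}
        self._pair_ctx: dict[PairContext, np.ndarray] = {}
        self.callbacks: list[GenericConstraintCallback] = []
        self.binding_sites = BindingSiteSet()
        self._cum: dict[int, np.ndarray] = {}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_paired_unpaired(cls, n: int, b_unpaired: TSequence[float],
                             b_paired: TSequence[float]) -> "SoftConstraintSet":
        """Reduce raw per-position bonuses (b^u_i, b^p_i) to delta_i.

        ``b_unpaired[i-1]``/``b_paired[i-1]`` are charged when position i
        is unpaired/paired.  The constant E' = sum_i b^p_i is dropped: it
        shifts every structure equally and leaves the ensemble unchanged.
        """
        sc = cls(n)
        for i in range(1, n + 1):
            sc.delta_unpaired[i] = b_unpaired[i - 1] - b_paired[i - 1]
        return sc

    def add_unpaired(self, i: int, energy: float,
                     context: UnpairedContext = UnpairedContext.ALL) -> None:
        if context == UnpairedContext.ALL:
            self.delta_unpaired[i] += energy
        else:
            for bit in _UCTX_BITS:
                if context & bit:
                    arr = self._unpaired_ctx.setdefault(bit, np.zeros(self.n + 1))
                    arr[i] += energy
        self._cum.clear()

    def add_pair(self, i: int, j: int, energy: float,
                 context: PairContext = PairContext.ALL) -> None:
        if i > j:
            i, j = j, i
        if context == PairContext.ALL:
            self.delta_pair[i, j] += energy
        else:
            for bit in _PCTX_BITS:
                if context & bit:
                    arr = self._pair_ctx.setdefault(bit, np.zeros((self.n + 1, self.n + 1)))
                    arr[i, j] += energy
        self._cum.clear()

    def add_callback(self, cb: GenericConstraintCallback) -> None:
        self.callbacks.append(cb)

    # -- queries (engine side) -------------------------------------------
    @property
    def cumulative_unpaired(self) -> np.ndarray:
        """Prefix sums of the context-free unpaired pseudo-energies."""
        return np.cumsum(self.delta_unpaired)

    def _cum_for(self, bit: UnpairedContext) -> np.ndarray:
        key = int(bit)
        if key not in self._cum:
            arr = self.delta_unpaired.copy()
            ctx = self._unpaired_ctx.get(bit)
            if ctx is not None:
                arr = arr + ctx
            self._cum[key] = np.cumsum(arr)
        return self._cum[key]

    def unpaired_energy(self, i: int, context: UnpairedContext) -> float:
        e = self.delta_unpaired[i]
        ctx = self._unpaired_ctx.get(context)
        if ctx is not None:
            e += ctx[i]
        return float(e)

    def run_energy(self, a: int, b: int, context: UnpairedContext) -> float:
        """Sum of unpaired pseudo-energies over positions a..b (O(1))."""
        if b < a:
            return 0.0
        cum = self._cum_for(context)
        return float(cum[b] - cum[a - 1])

    def pair_energy(self, i: int, j: int, context: PairContext) -> float:
        e = 0.0
        if context & CLOSING_CONTEXTS:
            e += self.delta_pair[i, j]
        ctx = self._pair_ctx.get(context)
        if ctx is not None:
            e += ctx[i, j]
        return float(e)

    @property
    def soft_callbacks(self) -> list[GenericConstraintCallback]:
        return [cb for cb in self.callbacks if not cb.is_hard]

    @property
    def hard_callbacks(self) -> list[GenericConstraintCallback]:
        return [cb for cb in self.callbacks if cb.is_hard]

    def callback_energy(self, step: DecompStep, i: int, j: int = 0,
                        k: int = 0, l: int = 0) -> float:
        return sum(cb.function(step, i, j, k, l, cb.payload)
                   for cb in self.callbacks if not cb.is_hard)

    def hard_allowed(self, step: DecompStep, i: int, j: int = 0,
                     k: int = 0, l: int = 0) -> bool:
        return all(cb.function(step, i, j, k, l, cb.payload)
                   for cb in self.callbacks if cb.is_hard)

    def is_empty(self) -> bool:
        return (not self.callbacks and not len(self.binding_sites)
                and not self._unpaired_ctx and not self._pair_ctx
                and not self.delta_unpaired.any() and not self.delta_pair.any())


# --------------------------------------------------------------------------
# input formats

_PSEUDO_DB_CHARS = set("<>.|()x")


def parse_pseudo_dotbracket(text: str) -> list[ConstraintDirective]:
    """Parse the pseudo-dot-bracket constraint dialect.

    ``.`` no constraint, ``x`` unpaired, ``|`` paired (partner anywhere),
    ``<`` paired with a partner strictly downstream, ``>`` strictly
    upstream, matched ``(``/``)`` an enforced pair.
    """
    directives: list[ConstraintDirective] = []
    stack: list[int] = []
    for pos, ch in enumerate(text.strip(), start=1):
        if ch == ".":
            continue
        if ch == "x":
            directives.append(force_unpaired(pos))
        elif ch == "|":
            directives.append(force_paired(pos))
        elif ch == "<":
            directives.append(force_paired_downstream(pos))
        elif ch == ">":
            directives.append(force_paired_upstream(pos))
        elif ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ConstraintError(f"unbalanced ')' at position {pos}")
            directives.append(enforce_pair(stack.pop(), pos))
        else:
            raise ConstraintError(f"invalid constraint character {ch!r} at position {pos}")
    if stack:
        raise ConstraintError(f"unbalanced '(' at position {stack[-1]}")
    # report enforced pairs outermost-first for readability
    directives.sort(key=lambda d: d.pos[0])
    return directives


@dataclass(frozen=True)
class SoftEntry:
    """A soft-energy record from a constraint command file."""

    pos: tuple[int, ...]          # (i,) or (i, j)
    energy: float
    unpaired_context: UnpairedContext = UnpairedContext.ALL
    pair_context: PairContext = PairContext.ALL

    def apply(self, soft: SoftConstraintSet) -> None:
        if len(self.pos) == 1:
            soft.add_unpaired(self.pos[0], self.energy, self.unpaired_context)
        else:
            soft.add_pair(*self.pos, self.energy, self.pair_context)


def parse_constraint_file(
    lines: Iterable[str],
) -> tuple[list[ConstraintDirective], list[SoftEntry]]:
    """Parse the line-oriented constraint command file.

    Records (1-based positions, ``#`` comments, blank lines skipped)::

        P i j k [ctx]   prohibit the helix (i,j), (i+1,j-1) ... k pairs
        P i 0 k [ctx]   prohibit pairing of positions i .. i+k-1
        F i j k [ctx]   force the helix (i,j) ... k pairs
        F i 0 k         force positions i .. i+k-1 to pair
        E i e [ctx]     soft energy e (kcal/mol) for i unpaired
        E i j e [ctx]   soft energy e for the pair (i, j)
        S L             hard span limit L
        D 2             restrict multibranch loops to degree 2

    ``ctx`` is an optional string over {E,H,I,M} selecting loop contexts.
    Returns hard directives and soft entries separately.
    """
    directives: list[ConstraintDirective] = []
    soft: list[SoftEntry] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        cmd = fields[0].upper()
        args = fields[1:]
        ctx_letters = ""
        if args and args[-1].isalpha():
            ctx_letters = args.pop()
        try:
            umask, pmask = parse_context_letters(ctx_letters)
            if cmd == "P":
                i, j, k = (int(a) for a in args)
                if j == 0:
                    directives.extend(force_unpaired(p) for p in range(i, i + k))
                else:
                    directives.extend(
                        forbid_pair(i + t, j - t, pmask) for t in range(k)
                    )
            elif cmd == "F":
                i, j, k = (int(a) for a in args)
                if j == 0:
                    directives.extend(
                        force_paired(p, umask) for p in range(i, i + k)
                    )
                else:
                    directives.extend(
                        enforce_pair(i + t, j - t, pmask) for t in range(k)
                    )
            elif cmd == "E":
                if len(args) == 2:
                    soft.append(SoftEntry((int(args[0]),), float(args[1]), umask, pmask))
                elif len(args) == 3:
                    soft.append(SoftEntry((int(args[0]), int(args[1])),
                                          float(args[2]), umask, pmask))
                else:
                    raise ValueError("E record needs 2 or 3 arguments")
            elif cmd == "S":
                (L,) = (int(a) for a in args)
                directives.append(span_limit(L))
            elif cmd == "D":
                (deg,) = (int(a) for a in args)
                directives.append(ConstraintDirective("multiloop_degree_limit", (deg,)))
            else:
                raise ValueError(f"unknown command {cmd!r}")
        except (ValueError, TypeError) as exc:
            raise ConstraintError(f"constraint file line {lineno}: {exc}") from exc
    return directives, soft


def read_shape_file(path: str) -> dict[int, float]:
    """Read whitespace-separated ``position value`` reactivity lines."""
    values: dict[int, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ConstraintError(f"{path}:{lineno}: expected 'position value'")
            try:
                values[int(parts[0])] = float(parts[1])
            except ValueError as exc:
                raise ConstraintError(f"{path}:{lineno}: {exc}") from exc
    return values


# --------------------------------------------------------------------------
# probing-signal conversion

_EPS = 1e-6


def shape_to_soft(
    reactivities: Mapping[int, float],
    n: int,
    method: str = "deigan",
    *,
    slope: float = 1.8,
    intercept: float = -0.6,
    thermo: ThermoParams | None = None,
) -> SoftConstraintSet:
    """Convert per-position probing data into unpaired pseudo-energies.

    ``deigan``: the classic linear-log conversion charges
    m*ln(reactivity+1) + b to each PAIRED nucleotide; by the delta
    reduction this is equivalent to delta_i = -(m*ln(r_i+1) + b) on the
    unpaired state, which is how it is stored here (the compact energy
    model has no per-stack hook, so the term is attached per paired
    nucleotide rather than per stack).

    ``log_odds``: reactivities are interpreted as unpaired probabilities
    p_i in (0,1) and converted to delta_i = -RT ln(p_i/(1-p_i)); values
    outside (0,1) are clamped to [eps, 1-eps] with a warning.

    Positions without data contribute nothing.
    """
    soft = SoftConstraintSet(n)
    if method == "deigan":
        for i, r in reactivities.items():
            if not (1 <= i <= n):
                raise ConstraintError(f"reactivity position {i} outside 1..{n}")
            paired_penalty = slope * math.log(r + 1.0) + intercept
            soft.add_unpaired(i, -paired_penalty)
    elif method == "log_odds":
        rt = (thermo or ThermoParams()).RT
        for i, p in reactivities.items():
            if not (1 <= i <= n):
                raise ConstraintError(f"probability position {i} outside 1..{n}")
            if not (0.0 < p < 1.0):
                warnings.warn(
                    f"unpaired probability {p} at position {i} outside (0,1); clamped"
                )
                p = min(max(p, _EPS), 1.0 - _EPS)
            soft.add_unpaired(i, -rt * math.log(p / (1.0 - p)))
    else:
        raise ConstraintError(f"unknown SHAPE conversion method {method!r}")
    return soft


def _ternary_callback(step: DecompStep, i: int, j: int, k: int, l: int,
                      payload: dict) -> float:
    """Charge delta^t to the nucleotides of stem-terminal pairs.

    A pair is stem-terminal iff it closes a loop that is not a stack, or
    appears inside a loop that is not a stack; with lonely pairs excluded
    these cases are disjoint and every pair is charged at most once.
    """
    dt = payload["dt"]
    if step is DecompStep.HAIRPIN_LOOP or step is DecompStep.MULTI_CLOSING:
        return dt[i] + dt[j]
    if step is DecompStep.INTERIOR_LOOP:
        if k == i + 1 and l == j - 1:      # stack: neither pair is terminal here
            return 0.0
        return dt[i] + dt[j] + dt[k] + dt[l]
    if step in (DecompStep.EXT_STEM, DecompStep.ML_SPLIT,
                DecompStep.ML_STEM, DecompStep.M1_STEM):
        return dt[i] + dt[j]
    return 0.0


def shape_ternary_soft(
    signal: Mapping[int, float],
    n: int,
    converter: Callable[[float], tuple[float, float, float]],
    *,
    no_lonely_pairs: bool,
) -> SoftConstraintSet:
    """Ternary probing model: distinct bonuses for unpaired nucleotides,
    stem-interior nucleotides and stem-terminal nucleotides.

    ``converter(value)`` returns (b_u, b_t, b_s); only the differences
    delta^u = b_u - b_s and delta^t = b_t - b_s enter the ensemble (the
    stack-interior baseline is the dropped constant E').  delta^u is
    attached to unpaired nucleotides, delta^t via a generic callback to
    the nucleotides of loop-closing pairs and of enclosed pairs that are
    not stacked pairs.  Stem-terminal classification is unique only
    without lonely pairs, so the caller must fold with the lonely-pair
    filter enabled.
    """
    if not no_lonely_pairs:
        raise ConstraintError(
            "the ternary stem-end model requires lonely pairs to be "
            "disallowed; with isolated pairs the stem-terminal "
            "classification is not unique"
        )
    soft = SoftConstraintSet(n)
    dt = np.zeros(n + 1)
    for i, v in signal.items():
        if not (1 <= i <= n):
            raise ConstraintError(f"signal position {i} outside 1..{n}")
        b_u, b_t, b_s = converter(v)
        soft.add_unpaired(i, b_u - b_s)
        dt[i] = b_t - b_s
    soft.add_callback(GenericConstraintCallback(_ternary_callback, payload={"dt": dt}))
    return soft


# --------------------------------------------------------------------------
# span down-weighting


@dataclass(frozen=True)
class SpanWeightParams:
    """gamma(i,j) = alpha1 * (exp(-(j-i-1)/alpha2) - 1) + 1."""

    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if self.alpha2 <= 0:
            raise ValueError("alpha2 must be positive")

    def gamma(self, i: int, j: int) -> float:
        return self.alpha1 * (math.exp(-(j - i - 1) / self.alpha2) - 1.0) + 1.0


def _span_weight_fn(step: DecompStep, i: int, j: int, k: int, l: int,
                    payload: dict) -> float:
    from .energy_model import eval_hairpin, eval_interior  # local: avoid cycle

    params: SpanWeightParams = payload["params"]
    seq = payload.get("seq")
    model = payload.get("model")
    if seq is None or model is None:
        return 0.0
    if step is DecompStep.HAIRPIN_LOOP:
        e_loop = eval_hairpin(seq, i, j, model)
    elif step is DecompStep.INTERIOR_LOOP:
        e_loop = eval_interior(seq, i, j, k, l, model)
    elif step is DecompStep.MULTI_CLOSING:
        # closing-step share of the linear multibranch energy
        e_loop = model.multiloop_closing + model.multiloop_branch
    else:
        return 0.0
    return (params.gamma(i, j) - 1.0) * e_loop


def _span_weight_init(payload: dict, seq, model, thermo) -> None:
    payload["seq"] = seq
    payload["model"] = model


def span_weight_callback(params: SpanWeightParams) -> GenericConstraintCallback:
    """Down-weight long-range loop energies multiplicatively.

    The additive soft-constraint layer realises the multiplicative factor
    gamma(i,j) by returning the difference (gamma-1)*E^L at each
    loop-closing step, i.e. subtracting E^L and adding gamma*E^L.  For
    multibranch loops only the closing-step share of the linear energy is
    reweighted (the remainder is not known at that decomposition step).
    With alpha1 = 0 the callback returns exactly 0 for every step.
    """
    return GenericConstraintCallback(
        _span_weight_fn, payload={"params": params}, init=_span_weight_init
    )
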