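"""Brute-force reference implementations and synthetic instance generators.

Everything the dynamic-programming engine computes is re-derived here by
explicit enumeration of the structure ensemble, with constraints applied
to each structure *declaratively* (via its loop decomposition) rather than
through recursion pruning.  Agreement between the two routes is the core
correctness argument of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .constraints import (
    ConstraintDirective,
    HardConstraintMatrix,
    SoftConstraintSet,
    compile_constraints,
    check_consistency,
    enforce_pair,
    forbid_pair,
    force_unpaired,
)
from .energy_model import (
    NearestNeighborModel,
    Sequence,
    ThermoParams,
    eval_structure,
)
from .grammar import PairContext, UnpairedContext
from .structure import derivation_steps, loop_decomposition

_ORACLE_GUARD = 20


def _admissible_pairs(seq: Sequence, hard: HardConstraintMatrix,
                      no_lonely_pairs: bool = False) -> list[tuple[int, int]]:
    n = len(seq)
    raw = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)
           if hard.any_pair(i, j)]
    if not no_lonely_pairs:
        return raw
    rawset = {p for p in raw}
    out = []
    for i, j in raw:
        inside = (i + 1, j - 1) in rawset
        outside = (i - 1, j + 1) in rawset
        if inside or outside:
            out.append((i, j))
    return out


def _loop_context_ok(n: int, pairs: frozenset, hard: HardConstraintMatrix,
                     degree_limit: int | None) -> bool:
    """Declarative meaning of the context-resolved hard constraints."""
    for loop in loop_decomposition(n, pairs):
        if loop.kind == "exterior":
            u_ctx, enc_ctx = UnpairedContext.EXTERIOR, PairContext.EXTERIOR
        elif loop.kind == "hairpin":
            u_ctx, enc_ctx = UnpairedContext.HAIRPIN, None
            if not hard.allows_pair(*loop.closing, PairContext.HAIRPIN_CLOSING):
                return False
        elif loop.kind == "interior":
            u_ctx, enc_ctx = UnpairedContext.INTERIOR, PairContext.INTERIOR_ENCLOSED
            if not hard.allows_pair(*loop.closing, PairContext.INTERIOR_CLOSING):
                return False
            (k, l), = loop.enclosed
            i, j = loop.closing
            if (i, j, k, l) in hard.forbidden_interior_loops:
                return False
        else:
            u_ctx, enc_ctx = UnpairedContext.MULTI, PairContext.MULTI_ENCLOSED
            if not hard.allows_pair(*loop.closing, PairContext.MULTI_CLOSING):
                return False
            if degree_limit == 2 and len(loop.enclosed) > 2:
                return False
        for u in loop.unpaired:
            if not hard.allows_unpaired(u, u_ctx):
                return False
        if enc_ctx is not None:
            for p in loop.enclosed:
                if not hard.allows_pair(*p, enc_ctx):
                    return False
    return True


def declarative_soft_energy(seq: Sequence, pairs: frozenset,
                            soft: SoftConstraintSet) -> float:
    """Soft pseudo-energy of an explicit structure: per-loop delta/Delta
    terms from the loop decomposition plus generic callbacks evaluated on
    the structure's unique grammar derivation."""
    n = len(seq)
    e = 0.0
    for loop in loop_decomposition(n, pairs):
        if loop.kind == "exterior":
            u_ctx = UnpairedContext.EXTERIOR
            for p in loop.enclosed:
                e += soft.pair_energy(*p, PairContext.EXTERIOR)
        elif loop.kind == "hairpin":
            u_ctx = UnpairedContext.HAIRPIN
            e += soft.pair_energy(*loop.closing, PairContext.HAIRPIN_CLOSING)
        elif loop.kind == "interior":
            u_ctx = UnpairedContext.INTERIOR
            e += soft.pair_energy(*loop.closing, PairContext.INTERIOR_CLOSING)
            e += soft.pair_energy(*loop.enclosed[0], PairContext.INTERIOR_ENCLOSED)
        else:
            u_ctx = UnpairedContext.MULTI
            e += soft.pair_energy(*loop.closing, PairContext.MULTI_CLOSING)
            for p in loop.enclosed:
                e += soft.pair_energy(*p, PairContext.MULTI_ENCLOSED)
        for u in loop.unpaired:
            e += soft.unpaired_energy(u, u_ctx)
    if soft.soft_callbacks:
        for step, i, j, k, l in derivation_steps(n, pairs):
            e += soft.callback_energy(step, i, j, k, l)
    return e


@dataclass
class EnumeratedEnsemble:
    """The complete constrained structure ensemble of a short sequence."""

    seq: Sequence
    structures: list[frozenset]

    @property
    def count(self) -> int:
        return len(self.structures)

    def energies(self, model: NearestNeighborModel,
                 soft: SoftConstraintSet | None = None) -> list[float]:
        out = []
        for ps in self.structures:
            e = eval_structure(self.seq, ps, model)
            if soft is not None:
                e += declarative_soft_energy(self.seq, ps, soft)
            out.append(e)
        return out

    def mfe(self, model, soft=None) -> tuple[frozenset, float]:
        es = self.energies(model, soft)
        idx = int(np.argmin(es))
        return self.structures[idx], es[idx]

    def boltzmann_with_sites(self, model, soft: SoftConstraintSet,
                             thermo: ThermoParams | None = None) -> float:
        """Z over (structure, site-arrangement) pairs, by explicit
        enumeration of non-overlapping fully-contained site subsets per
        maximal unpaired run of each loop.  Covered positions lose their
        per-position soft terms; the standard-model energy is unchanged."""
        from itertools import combinations as _combos

        rt = (thermo or ThermoParams()).RT
        n = len(self.seq)
        sites = soft.binding_sites.sites
        ctx_of = {"exterior": UnpairedContext.EXTERIOR,
                  "hairpin": UnpairedContext.HAIRPIN,
                  "interior": UnpairedContext.INTERIOR,
                  "multibranch": UnpairedContext.MULTI}
        Z = 0.0
        for ps in self.structures:
            e_base = eval_structure(self.seq, ps, model)
            runs: list[tuple[int, int, UnpairedContext]] = []
            for loop in loop_decomposition(n, ps):
                ctx = ctx_of[loop.kind]
                if loop.kind == "hairpin":
                    e_base += soft.pair_energy(*loop.closing, PairContext.HAIRPIN_CLOSING)
                elif loop.kind == "interior":
                    e_base += soft.pair_energy(*loop.closing, PairContext.INTERIOR_CLOSING)
                    e_base += soft.pair_energy(*loop.enclosed[0], PairContext.INTERIOR_ENCLOSED)
                elif loop.kind == "multibranch":
                    e_base += soft.pair_energy(*loop.closing, PairContext.MULTI_CLOSING)
                    for p in loop.enclosed:
                        e_base += soft.pair_energy(*p, PairContext.MULTI_ENCLOSED)
                else:
                    for p in loop.enclosed:
                        e_base += soft.pair_energy(*p, PairContext.EXTERIOR)
                up = sorted(loop.unpaired)
                a = prev = None
                for u in up:
                    if a is None:
                        a = prev = u
                    elif u == prev + 1:
                        prev = u
                    else:
                        runs.append((a, prev, ctx))
                        a = prev = u
                if a is not None:
                    runs.append((a, prev, ctx))
            w = 1.0
            for a, b, ctx in runs:
                if ctx == UnpairedContext.EXTERIOR:
                    w *= math.exp(-sum(soft.unpaired_energy(u, ctx)
                                       for u in range(a, b + 1)) / rt)
                    continue
                cands = [s for s in sites if s.p >= a and s.q <= b
                         and s.contexts & ctx]
                wrun = 0.0
                for r in range(len(cands) + 1):
                    for combo in _combos(cands, r):
                        ivs = sorted((s.p, s.q) for s in combo)
                        if any(ivs[x][1] >= ivs[x + 1][0]
                               for x in range(len(ivs) - 1)):
                            continue
                        covered = {u for p, q in ivs for u in range(p, q + 1)}
                        e = sum(s.beta for s in combo)
                        e += sum(soft.unpaired_energy(u, ctx)
                                 for u in range(a, b + 1) if u not in covered)
                        wrun += math.exp(-e / rt)
                w *= wrun
            Z += math.exp(-e_base / rt) * w
        return Z

    def boltzmann(self, model, soft=None, thermo: ThermoParams | None = None):
        """(Z, bpp, unpaired probabilities, per-structure probabilities)."""
        rt = (thermo or ThermoParams()).RT
        n = len(self.seq)
        ws = [math.exp(-e / rt) for e in self.energies(model, soft)]
        Z = sum(ws)
        bpp = np.zeros((n + 1, n + 1))
        unpaired = np.zeros(n + 1)
        for ps, w in zip(self.structures, ws):
            for i, j in ps:
                bpp[i, j] += w
            paired = {x for p in ps for x in p}
            for i in range(1, n + 1):
                if i not in paired:
                    unpaired[i] += w
        bpp /= Z
        unpaired /= Z
        probs = [w / Z for w in ws]
        return Z, bpp, unpaired, probs


def enumerate_structures(
    seq: Sequence,
    hard: HardConstraintMatrix | None = None,
    min_hairpin: int = 3,
    degree_limit: int | None = None,
    no_lonely_pairs: bool = False,
) -> EnumeratedEnsemble:
    """Every admissible structure exactly once (recursive inside/outside
    enumeration over the interval decomposition).  Guarded at n <= 20."""
    n = len(seq)
    if n > _ORACLE_GUARD:
        raise ValueError(f"enumeration oracle refuses n={n} > {_ORACLE_GUARD}")
    if hard is None:
        hard = HardConstraintMatrix.permissive(seq, min_hairpin)
    adm = set(_admissible_pairs(seq, hard, no_lonely_pairs))
    if degree_limit is None:
        degree_limit = hard.multiloop_degree_limit

    memo: dict[tuple[int, int], list[frozenset]] = {}

    def structs(i: int, j: int) -> list[frozenset]:
        if j <= i:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(structs(i + 1, j))
        for k in range(i + 1, j + 1):
            if (i, k) not in adm:
                continue
            for inner in structs(i + 1, k - 1):
                for outer in structs(k + 1, j):
                    out.append(frozenset({(i, k)}) | inner | outer)
        memo[key] = out
        return out

    kept = [ps for ps in structs(1, n)
            if _loop_context_ok(n, ps, hard, degree_limit)]
    return EnumeratedEnsemble(seq, kept)


def enumerate_by_subsets(
    seq: Sequence,
    hard: HardConstraintMatrix | None = None,
    min_hairpin: int = 3,
) -> EnumeratedEnsemble:
    """Independent second oracle: filter all subsets of admissible pairs
    for non-crossing/non-sharing (O(2^P); tiny sequences only)."""
    n = len(seq)
    if n > 12:
        raise ValueError("subset oracle is limited to n <= 12")
    if hard is None:
        hard = HardConstraintMatrix.permissive(seq, min_hairpin)
    adm = _admissible_pairs(seq, hard)
    kept = []
    for r in range(len(adm) + 1):
        for combo in combinations(adm, r):
            seen: set[int] = set()
            ok = True
            for i, j in combo:
                if i in seen or j in seen:
                    ok = False
                    break
                seen.update((i, j))
            if not ok:
                continue
            for (i, j), (k, l) in combinations(combo, 2):
                if (i < k <= j < l) or (k < i <= l < j):
                    ok = False
                    break
            if ok:
                ps = frozenset(combo)
                if _loop_context_ok(n, ps, hard, hard.multiloop_degree_limit):
                    kept.append(ps)
    return EnumeratedEnsemble(seq, kept)


# --------------------------------------------------------------------------
# random instances


def random_instance(
    n: int,
    gc_bias: float = 0.5,
    constraint_density: float = 0.15,
    seed: int = 0,
    soft_range: float = 3.0,
    loop_type_soft: bool = False,
):
    """A reproducible random (sequence, directives, soft set) triple.

    Directives are sampled from {forbid_pair, force_unpaired, enforce_pair}
    and post-filtered for mutual consistency: the compiled matrix must
    exist and satisfy the necessary per-position condition.  Soft energies
    are uniform in [-soft_range, +soft_range] kcal/mol.
    """
    if n > _ORACLE_GUARD:
        raise ValueError(f"random_instance is for oracle use, n <= {_ORACLE_GUARD}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
    seq = Sequence("".join(rng.choice(list("ACGU"), size=n, p=probs)))

    cand = [(i, j) for i in range(1, n + 1) for j in range(i + 4, n + 1)
            if seq.pairable(i, j)]
    n_dir = int(round(constraint_density * n))
    directives: list[ConstraintDirective] = []
    for _ in range(n_dir):
        for _attempt in range(20):
            kind = rng.choice(["forbid_pair", "force_unpaired", "enforce_pair"],
                              p=[0.45, 0.4, 0.15])
            if kind == "force_unpaired":
                d = force_unpaired(int(rng.integers(1, n + 1)))
            elif not cand:
                continue
            else:
                i, j = cand[int(rng.integers(len(cand)))]
                d = forbid_pair(i, j) if kind == "forbid_pair" else enforce_pair(i, j)
            trial = directives + [d]
            try:
                m = compile_constraints(seq, trial)
            except Exception:
                continue
            if check_consistency(m):
                continue
            directives = trial
            break

    soft = SoftConstraintSet(n)
    for i in range(1, n + 1):
        if rng.random() < 0.5:
            if loop_type_soft and rng.random() < 0.3:
                ctx = [UnpairedContext.EXTERIOR, UnpairedContext.HAIRPIN,
                       UnpairedContext.INTERIOR, UnpairedContext.MULTI][int(rng.integers(4))]
            else:
                ctx = UnpairedContext.ALL
            soft.add_unpaired(i, float(rng.uniform(-soft_range, soft_range)), ctx)
    for i, j in cand:
        if rng.random() < 0.3:
            if loop_type_soft and rng.random() < 0.3:
                ctx = [PairContext.EXTERIOR, PairContext.HAIRPIN_CLOSING,
                       PairContext.INTERIOR_CLOSING, PairContext.INTERIOR_ENCLOSED,
                       PairContext.MULTI_CLOSING, PairContext.MULTI_ENCLOSED][int(rng.integers(6))]
            else:
                ctx = PairContext.ALL
            soft.add_pair(i, j, float(rng.uniform(-soft_range, soft_range)), ctx)
    return seq, directives, soft


# --------------------------------------------------------------------------
# modified-tRNA scenario fixture


_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}

#: cloverleaf layout (1-based): 5'-strand start, 3'-partner of that start,
#: stem length.  Acceptor stem, D-stem, anticodon stem, T-stem.
_TRNA_STEMS = ((1, 63, 7), (10, 21, 4), (24, 38, 5), (41, 55, 5))
_TRNA_N = 63
#: GC-rich 5' strand letters per stem, patterns chosen to disfavour
#: alternative helix registers
_TRNA_STRANDS = ("GGCGCGG", "GCGC", "GGCAC", "GCCGG")


def modified_trna_fixture(seed: int = 0):
    """A cloverleaf-capable synthetic sequence with planted 'chemically
    modified' positions that must stay unpaired.

    Returns (sequence, directives, reference pair set).  The sequence is
    generated from the planted cloverleaf: stem 3' strands are the exact
    complements of GC-rich 5' strands, loops and linkers are A runs.  The
    modified positions are drawn from stem-interior positions, so the
    unconstrained MFE pairs them while the constrained fold cannot; the
    triple demonstrates (not benchmarks) the sensitivity/PPV shift of
    constraint-aware prediction.  Deterministic under ``seed``.
    """
    res = ["A"] * (_TRNA_N + 1)
    reference: set[tuple[int, int]] = set()
    for (i0, j0, length), strand in zip(_TRNA_STEMS, _TRNA_STRANDS):
        for t in range(length):
            i, j = i0 + t, j0 - t
            res[i] = strand[t]
            res[j] = _COMPLEMENT[strand[t]]
            reference.add((i, j))
    seq = Sequence("".join(res[1:]))
    rng = np.random.default_rng(seed)
    # interior stem positions (terminal pairs excluded) on the 5' strands
    candidates = [i0 + t for i0, _, length in _TRNA_STEMS
                  for t in range(1, length - 1)]
    modified = sorted(rng.choice(candidates, size=3, replace=False).tolist())
    directives = [force_unpaired(int(i)) for i in modified]
    return seq, directives, frozenset(reference)


def sensitivity_ppv(reference: frozenset, predicted: frozenset) -> tuple[float, float]:
    """Base-pair sensitivity TP/(TP+FN) and PPV TP/(TP+FP)."""
    tp = len(reference & predicted)
    sens = tp / len(reference) if reference else 1.0
    ppv = tp / len(predicted) if predicted else 1.0
    return sens, ppv
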