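"""Constrained folding recursions over the F/C/M/M1 grammar.

One set of recursions serves four computations: exact structure counting,
minimum free energy with traceback, the McCaskill partition function with
base-pair probabilities (inside/outside), and Boltzmann stochastic
backtracking.  Hard constraints prune recursion terms before they are
evaluated; soft pseudo-energies and generic per-step callbacks are added
during energy evaluation; interval binding sites switch the multibranch
and loop recursions to a variant grammar that consumes maximal unpaired
runs as units, scoring site arrangements with an auxiliary 1-D DP.

Tables are 1-based and intervals closed.  The grammar is unambiguous, so
the counting mode yields exact integer structure counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constraints import HardConstraintMatrix, SoftConstraintSet
from .energy_model import (
    NearestNeighborModel,
    Sequence,
    ThermoParams,
    eval_hairpin,
    eval_interior,
    eval_structure,
)
from .grammar import DecompStep, PairContext, UnpairedContext
from .structure import pairs_to_dotbracket

INF = float("inf")


class FoldingError(RuntimeError):
    """Numeric failure or malformed engine state."""


class NoAdmissibleStructureError(FoldingError):
    """The hard constraints admit no structure at all."""


@dataclass
class FoldOptions:
    """Engine options.

    max_interior_unpaired caps the unpaired nucleotides per interior-loop
    side (the customary sparsification of the O(n^4) interior sum);
    multiloop_degree_limit=2 forbids the M split term so multibranch
    loops keep at most two enclosed branches; no_lonely_pairs applies the
    canonical heuristic that a pair is admissible only if it could stack
    inside or outside.
    """

    thermo: ThermoParams = field(default_factory=ThermoParams)
    max_interior_unpaired: int = 30
    multiloop_degree_limit: int | None = None
    no_lonely_pairs: bool = False
    pf_scale: float | None = None


@dataclass
class FoldResult:
    structure: str
    energy_total: float
    energy_standard: float
    energy_soft: float
    pairs: frozenset[tuple[int, int]] = frozenset()
    occupied_sites: tuple[tuple[int, int], ...] = ()


@dataclass
class EnsembleResult:
    Z: float
    log_Z: float
    free_energy: float                    # -RT ln Z, kcal/mol
    bpp: np.ndarray                       # upper triangular p_ij
    unpaired_prob: np.ndarray             # per position, index 1..n
    _state: "_Fold" = None

    def pair_probability(self, i: int, j: int) -> float:
        return float(self.bpp[min(i, j), max(i, j)])


@dataclass
class DPMatrices:
    """The filled recursion tables (mode-dependent value semantics)."""

    F: list
    C: list
    M: list
    M1: list
    mode: str


_UC = UnpairedContext
_PC = PairContext


class _Fold:
    """One fill of the constrained recursions in a given mode.

    mode: 'count' (integer semiring), 'mfe' (min-plus) or 'pf'
    (sum-product over Boltzmann factors with optional per-nucleotide
    rescaling).
    """

    def __init__(
        self,
        seq: Sequence,
        model: NearestNeighborModel,
        hard: HardConstraintMatrix,
        soft: SoftConstraintSet,
        options: FoldOptions,
        mode: str,
    ):
        self.seq = seq
        self.model = model
        self.hard = hard
        self.soft = soft
        self.opts = options
        self.mode = mode
        self.n = len(seq)
        self.RT = options.thermo.RT
        self.binding = len(soft.binding_sites) > 0
        self.degree_limit = (
            options.multiloop_degree_limit
            if options.multiloop_degree_limit is not None
            else hard.multiloop_degree_limit
        )
        self._has_cb = bool(soft.soft_callbacks)
        self._has_hard_cb = bool(soft.hard_callbacks)
        for cb in soft.callbacks:
            if cb.init is not None:
                cb.init(cb.payload, seq, model, options.thermo)

        n = self.n
        # admissible pair predicate (bits already encode B(x), hairpin span,
        # span limits and explicit bans); optionally the lonely-pair filter
        allow = hard.pair.astype(bool)
        if options.no_lonely_pairs:
            raw = hard.pair.astype(bool)
            filt = np.zeros_like(allow)
            for i in range(1, n + 1):
                for j in range(i + 1, n + 1):
                    if not raw[i, j]:
                        continue
                    inside = i + 1 < j - 1 and raw[i + 1, j - 1]
                    outside = i - 1 >= 1 and j + 1 <= n and raw[i - 1, j + 1]
                    if inside or outside:
                        filt[i, j] = True
            allow = filt
        self.allow = allow

        # per-context unpaired run index: run[c][i] = longest run starting
        # at i whose positions may all be unpaired in context c
        self.runs = {}
        for bit in (_UC.EXTERIOR, _UC.HAIRPIN, _UC.INTERIOR, _UC.MULTI):
            r = np.zeros(n + 2, dtype=np.int64)
            for i in range(n, 0, -1):
                r[i] = r[i + 1] + 1 if hard.allows_unpaired(i, bit) else 0
            self.runs[bit] = r

        # semiring
        if mode == "count":
            self.ZERO, self.ONE = 0, 1
        elif mode == "mfe":
            self.ZERO, self.ONE = INF, 0.0
        elif mode == "pf":
            self.ZERO, self.ONE = 0.0, 1.0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        self.sigma = 1.0
        if mode == "pf":
            if options.pf_scale is not None:
                self.sigma = options.pf_scale
            elif n > 200:
                est = _Fold(seq, model, hard, soft, options, "mfe").mfe_energy()
                if est < 0:
                    self.sigma = math.exp(1.05 * est / (n * self.RT))

        self._fill()

    # -- semiring helpers -------------------------------------------------
    def wt(self, energy: float, consumed: int):
        if self.mode == "count":
            return 1
        if self.mode == "mfe":
            return energy
        w = math.exp(-energy / self.RT)
        if self.sigma != 1.0 and consumed:
            w *= self.sigma ** consumed
        return w

    def _mul(self, a, b):
        return a + b if self.mode == "mfe" else a * b

    def _acc(self, a, b):
        return min(a, b) if self.mode == "mfe" else a + b

    # -- per-step energies (None = hard-forbidden) ------------------------
    def _cb(self, step, i, j=0, k=0, l=0) -> float:
        return self.soft.callback_energy(step, i, j, k, l) if self._has_cb else 0.0

    def e_ext_unpaired(self, i):
        if not self.hard.allows_unpaired(i, _UC.EXTERIOR):
            return None
        if self._has_hard_cb and not self.soft.hard_allowed(DecompStep.EXT_UNPAIRED, i):
            return None
        return self.soft.unpaired_energy(i, _UC.EXTERIOR) + self._cb(DecompStep.EXT_UNPAIRED, i)

    def e_ext_stem(self, i, j):
        if not self.hard.allows_pair(i, j, _PC.EXTERIOR):
            return None
        if self._has_hard_cb and not self.soft.hard_allowed(DecompStep.EXT_STEM, i, j):
            return None
        return self.soft.pair_energy(i, j, _PC.EXTERIOR) + self._cb(DecompStep.EXT_STEM, i, j)

    def e_hairpin(self, i, j):
        size = j - i - 1
        if size < self.model.min_hairpin_unpaired:
            return None
        if not self.hard.allows_pair(i, j, _PC.HAIRPIN_CLOSING):
            return None
        if self.runs[_UC.HAIRPIN][i + 1] < size:
            return None
        if self._has_hard_cb and not self.soft.hard_allowed(DecompStep.HAIRPIN_LOOP, i, j):
            return None
        e = eval_hairpin(self.seq, i, j, self.model)
        e += self.soft.pair_energy(i, j, _PC.HAIRPIN_CLOSING)
        if not self.binding:
            # with sites active the per-position soft terms move to the site DP
            e += self.soft.run_energy(i + 1, j - 1, _UC.HAIRPIN)
        return e + self._cb(DecompStep.HAIRPIN_LOOP, i, j)

    def e_interior(self, i, j, k, l):
        if not self.hard.allows_pair(i, j, _PC.INTERIOR_CLOSING):
            return None
        if not self.hard.allows_pair(k, l, _PC.INTERIOR_ENCLOSED):
            return None
        if k - i - 1 > 0 and self.runs[_UC.INTERIOR][i + 1] < k - i - 1:
            return None
        if j - l - 1 > 0 and self.runs[_UC.INTERIOR][l + 1] < j - l - 1:
            return None
        if self.hard.forbidden_interior_loops and \
                (i, j, k, l) in self.hard.forbidden_interior_loops:
            return None
        if self._has_hard_cb and not self.soft.hard_allowed(DecompStep.INTERIOR_LOOP, i, j, k, l):
            return None
        e = eval_interior(self.seq, i, j, k, l, self.model)
        e += self.soft.pair_energy(i, j, _PC.INTERIOR_CLOSING)
        e += self.soft.pair_energy(k, l, _PC.INTERIOR_ENCLOSED)
        if not self.binding:
            e += self.soft.run_energy(i + 1, k - 1, _UC.INTERIOR)
            e += self.soft.run_energy(l + 1, j - 1, _UC.INTERIOR)
        return e + self._cb(DecompStep.INTERIOR_LOOP, i, j, k, l)

    def e_multi_close(self, i, j, k):
        if not self.hard.allows_pair(i, j, _PC.MULTI_CLOSING):
            return None
        if self._has_hard_cb and not self.soft.hard_allowed(DecompStep.MULTI_CLOSING, i, j, k):
            return None
        e = self.model.multiloop_closing + self.model.multiloop_branch
        e += self.soft.pair_energy(i, j, _PC.MULTI_CLOSING)
        return e + self._cb(DecompStep.MULTI_CLOSING, i, j, k)

    def e_ml_unpaired(self, i):
        if not self.hard.allows_unpaired(i, _UC.MULTI):
            return None
        if self._has_hard_cb and not self.soft.hard_allowed(DecompStep.ML_UNPAIRED, i):
            return None
        return (self.model.multiloop_unpaired
                + self.soft.unpaired_energy(i, _UC.MULTI)
                + self._cb(DecompStep.ML_UNPAIRED, i))

    def e_ml_run(self, a, b, step=DecompStep.ML_UNPAIRED):
        """Whole unpaired run a..b in multibranch context (None if barred)."""
        if b < a:
            return 0.0
        if self.runs[_UC.MULTI][a] < b - a + 1:
            return None
        e = (b - a + 1) * self.model.multiloop_unpaired
        e += self.soft.run_energy(a, b, _UC.MULTI)
        if self._has_cb or self._has_hard_cb:
            for u in range(a, b + 1):
                if self._has_hard_cb and not self.soft.hard_allowed(step, u):
                    return None
                e += self._cb(step, u)
        return e

    def e_ml_branch(self, i, j, region_end, step):
        if not self.hard.allows_pair(i, j, _PC.MULTI_ENCLOSED):
            return None
        if self._has_hard_cb and not self.soft.hard_allowed(step, i, j, region_end):
            return None
        return (self.model.multiloop_branch
                + self.soft.pair_energy(i, j, _PC.MULTI_ENCLOSED)
                + self._cb(step, i, j, region_end))

    def e_m1_stem(self, i, j):
        if not self.hard.allows_pair(i, j, _PC.MULTI_ENCLOSED):
            return None
        if self._has_hard_cb and not self.soft.hard_allowed(DecompStep.M1_STEM, i, j):
            return None
        return (self.model.multiloop_branch
                + self.soft.pair_energy(i, j, _PC.MULTI_ENCLOSED)
                + self._cb(DecompStep.M1_STEM, i, j))

    def e_m1_unpaired(self, i):
        if not self.hard.allows_unpaired(i, _UC.MULTI):
            return None
        if self._has_hard_cb and not self.soft.hard_allowed(DecompStep.M1_UNPAIRED, i):
            return None
        return (self.model.multiloop_unpaired
                + self.soft.unpaired_energy(i, _UC.MULTI)
                + self._cb(DecompStep.M1_UNPAIRED, i))

    # -- binding-site arrangement DP --------------------------------------
    def site_dp(self, a: int, b: int, context: UnpairedContext):
        """Score all arrangements of non-overlapping, fully contained
        binding sites over the maximal unpaired run a..b.

        Uncovered positions contribute their unpaired pseudo-energy (plus
        the multibranch per-unpaired standard term in MULTI context, which
        is charged to covered positions as well: an occupied site masks
        only the soft per-position terms).  Returns the semiring value, or
        ZERO if some position may not be unpaired.
        """
        if b < a:
            return self.ONE
        key = (a, b, int(context))
        cached = self._site_cache.get(key)
        if cached is not None:
            return cached
        c_ml = self.model.multiloop_unpaired if context == _UC.MULTI else 0.0
        vals = [self.ZERO] * (b - a + 2)   # vals[x-a+1] = run a..x
        vals[0] = self.ONE
        for x in range(a, b + 1):
            acc = self.ZERO
            if self.hard.allows_unpaired(x, context):
                e = c_ml + self.soft.unpaired_energy(x, context)
                prev = vals[x - a]
                if prev != self.ZERO:
                    acc = self._acc(acc, self._mul(prev, self.wt(e, 1)))
            for site in self.soft.binding_sites.ending_at(x, context):
                if site.p < a:
                    continue
                ok = all(self.hard.allows_unpaired(u, context)
                         for u in range(site.p, site.q + 1))
                if not ok:
                    continue
                prev = vals[site.p - a]
                if prev == self.ZERO:
                    continue
                cov = site.q - site.p + 1
                e = site.beta + c_ml * cov
                acc = self._acc(acc, self._mul(prev, self.wt(e, cov)))
            vals[x - a + 1] = acc
        self._site_cache[key] = vals[-1]
        self._site_vals[key] = vals
        return vals[-1]

    def _site_traceback(self, a: int, b: int, context: UnpairedContext):
        """Recover the minimum-energy site arrangement of a run (mfe mode)."""
        occupied = []
        if b < a:
            return occupied
        self.site_dp(a, b, context)
        vals = self._site_vals[(a, b, int(context))]
        c_ml = self.model.multiloop_unpaired if context == _UC.MULTI else 0.0
        x = b
        while x >= a:
            target = vals[x - a + 1]
            if self.hard.allows_unpaired(x, context):
                e = c_ml + self.soft.unpaired_energy(x, context)
                if abs(vals[x - a] + e - target) < 1e-9:
                    x -= 1
                    continue
            hit = None
            for site in self.soft.binding_sites.ending_at(x, context):
                if site.p < a:
                    continue
                e = site.beta + c_ml * (site.q - site.p + 1)
                if vals[site.p - a] != self.ZERO and \
                        abs(vals[site.p - a] + e - target) < 1e-9:
                    hit = site
                    break
            if hit is None:
                raise FoldingError("site arrangement traceback failed")
            occupied.append((hit.p, hit.q))
            x = hit.p - 1
        return occupied

    # -- table fill --------------------------------------------------------
    def _fill(self) -> None:
        n = self.n
        Z0, mul, acc, wt = self.ZERO, self._mul, self._acc, self.wt
        mdl = self.model
        maxu = self.opts.max_interior_unpaired
        # tables indexed [i][j]; F[i][i-1] = ONE (empty exterior interval)
        self.F = [[Z0] * (n + 2) for _ in range(n + 3)]
        self.C = [[Z0] * (n + 2) for _ in range(n + 3)]
        self.M = [[Z0] * (n + 2) for _ in range(n + 3)]
        self.M1 = [[Z0] * (n + 2) for _ in range(n + 3)]
        self._site_cache: dict = {}
        self._site_vals: dict = {}
        for i in range(1, n + 3):
            if i - 1 <= n + 1:
                self.F[i][i - 1] = self.ONE
        F, C, M, M1 = self.F, self.C, self.M, self.M1
        allow = self.allow
        binding = self.binding

        for s in range(1, n + 1):
            for i in range(1, n - s + 2):
                j = i + s - 1
                # ---- C ----
                if allow[i, j]:
                    v = Z0
                    e = self.e_hairpin(i, j)
                    if e is not None:
                        if binding:
                            u = self.site_dp(i + 1, j - 1, _UC.HAIRPIN)
                            if u != Z0:
                                v = acc(v, mul(wt(e, 2), u))
                        else:
                            v = acc(v, wt(e, s))
                    # interior loops (incl. stacks); sides capped at maxu
                    for k in range(i + 1, j - 1):
                        u1 = k - i - 1
                        if u1 > maxu:
                            break
                        row = C[k]
                        lmin = max(k + 1, j - 1 - maxu)
                        for l in range(j - 1, lmin - 1, -1):
                            inner = row[l]
                            if inner == Z0 or not allow[k, l]:
                                continue
                            e = self.e_interior(i, j, k, l)
                            if e is None:
                                continue
                            if binding:
                                ua = self.site_dp(i + 1, k - 1, _UC.INTERIOR)
                                if ua == Z0:
                                    continue
                                ub = self.site_dp(l + 1, j - 1, _UC.INTERIOR)
                                if ub == Z0:
                                    continue
                                v = acc(v, mul(mul(mul(wt(e, 2), ua), ub), inner))
                            else:
                                v = acc(v, mul(wt(e, s - (l - k + 1)), inner))
                    # multibranch closing
                    for k in range(i + 2, j - 1):
                        m = M[i + 1][k - 1]
                        if m == Z0:
                            continue
                        m1 = M1[k][j - 1]
                        if m1 == Z0:
                            continue
                        e = self.e_multi_close(i, j, k)
                        if e is None:
                            continue
                        v = acc(v, mul(mul(wt(e, 2), m), m1))
                    C[i][j] = v

                # ---- M ----
                v = Z0
                if not binding:
                    e = self.e_ml_unpaired(i)
                    if e is not None and M[i + 1][j] != Z0:
                        v = acc(v, mul(wt(e, 1), M[i + 1][j]))
                    for k in range(i + 1, j + 1):
                        c = C[i][k]
                        if c == Z0:
                            continue
                        if k < j and self.degree_limit != 2:
                            eb = self.e_ml_branch(i, k, j, DecompStep.ML_SPLIT)
                            if eb is not None and M[k + 1][j] != Z0:
                                v = acc(v, mul(mul(wt(eb, 0), c), M[k + 1][j]))
                        er = self.e_ml_run(k + 1, j)
                        if er is not None:
                            eb = self.e_ml_branch(i, k, j, DecompStep.ML_STEM)
                            if eb is not None:
                                v = acc(v, mul(wt(eb + er, j - k), c))
                else:
                    # first branch (r, k) after a maximal leading run i..r-1
                    for r in range(i, j + 1):
                        lead = self.site_dp(i, r - 1, _UC.MULTI)
                        if lead == Z0:
                            continue
                        for k in range(r + 1, j + 1):
                            c = C[r][k]
                            if c == Z0:
                                continue
                            if k < j and self.degree_limit != 2:
                                eb = self.e_ml_branch(r, k, j, DecompStep.ML_SPLIT)
                                if eb is not None and M[k + 1][j] != Z0:
                                    v = acc(v, mul(mul(mul(wt(eb, 0), lead), c),
                                                   M[k + 1][j]))
                            trail = self.site_dp(k + 1, j, _UC.MULTI)
                            if trail == Z0:
                                continue
                            eb = self.e_ml_branch(r, k, j, DecompStep.ML_STEM)
                            if eb is not None:
                                v = acc(v, mul(mul(mul(wt(eb, 0), lead), c), trail))
                M[i][j] = v

                # ---- M1 ----
                v = Z0
                if not binding:
                    c = C[i][j]
                    if c != Z0:
                        e = self.e_m1_stem(i, j)
                        if e is not None:
                            v = acc(v, mul(wt(e, 0), c))
                    e = self.e_m1_unpaired(j)
                    if e is not None and M1[i][j - 1] != Z0:
                        v = acc(v, mul(wt(e, 1), M1[i][j - 1]))
                else:
                    for l in range(i + 1, j + 1):
                        c = C[i][l]
                        if c == Z0:
                            continue
                        trail = self.site_dp(l + 1, j, _UC.MULTI)
                        if trail == Z0:
                            continue
                        e = self.e_m1_stem(i, l)
                        if e is not None:
                            v = acc(v, mul(mul(wt(e, 0), c), trail))
                M1[i][j] = v

                # ---- F ----
                v = Z0
                e = self.e_ext_unpaired(i)
                if e is not None and F[i + 1][j] != Z0:
                    v = acc(v, mul(wt(e, 1), F[i + 1][j]))
                for k in range(i + 1, j + 1):
                    c = C[i][k]
                    if c == Z0:
                        continue
                    e = self.e_ext_stem(i, k)
                    if e is None:
                        continue
                    v = acc(v, mul(mul(wt(e, 0), c), F[k + 1][j]))
                F[i][j] = v

        if self.mode == "pf":
            z = self.F[1][n] if n else 1.0
            if not math.isfinite(z):
                raise FoldingError("partition function overflow despite rescaling")

    # -- results -----------------------------------------------------------
    @property
    def matrices(self) -> DPMatrices:
        return DPMatrices(self.F, self.C, self.M, self.M1, self.mode)

    def count(self) -> int:
        return self.F[1][self.n]

    def mfe_energy(self) -> float:
        return self.F[1][self.n]

    def log_Z(self) -> float:
        z = self.F[1][self.n]
        if z <= 0.0:
            raise NoAdmissibleStructureError("the constraints admit no structure")
        return math.log(z) - self.n * math.log(self.sigma)

    # -- MFE traceback ------------------------------------------------------
    def traceback(self):
        """Recover one optimal structure (deterministic tie-break: prefer
        the unpaired extension, then the smallest split point)."""
        if self.mode != "mfe":
            raise FoldingError("traceback requires mfe mode")
        n = self.n
        if self.F[1][n] == INF:
            raise NoAdmissibleStructureError("the constraints admit no structure")
        pairs: list[tuple[int, int]] = []
        occupied: list[tuple[int, int]] = []
        TOL = 1e-9
        stack: list[tuple[str, int, int]] = [("F", 1, n)]

        def run_sites(a, b, ctx):
            if self.binding and b >= a:
                occupied.extend(self._site_traceback(a, b, ctx))

        while stack:
            tab, i, j = stack.pop()
            if j < i:
                continue
            target = getattr(self, tab)[i][j]
            if tab == "F":
                e = self.e_ext_unpaired(i)
                if e is not None and abs(e + self.F[i + 1][j] - target) < TOL:
                    stack.append(("F", i + 1, j))
                    continue
                found = False
                for k in range(i + 1, j + 1):
                    c = self.C[i][k]
                    if c == INF:
                        continue
                    e = self.e_ext_stem(i, k)
                    if e is not None and abs(e + c + self.F[k + 1][j] - target) < TOL:
                        pairs.append((i, k))
                        stack.append(("C", i, k))
                        stack.append(("F", k + 1, j))
                        found = True
                        break
                if not found:
                    raise FoldingError(f"traceback failed in F[{i}][{j}]")
            elif tab == "C":
                e = self.e_hairpin(i, j)
                if e is not None:
                    if self.binding:
                        u = self.site_dp(i + 1, j - 1, _UC.HAIRPIN)
                        if u != INF and abs(e + u - target) < TOL:
                            run_sites(i + 1, j - 1, _UC.HAIRPIN)
                            continue
                    elif abs(e - target) < TOL:
                        continue
                found = False
                maxu = self.opts.max_interior_unpaired
                for k in range(i + 1, j - 1):
                    if k - i - 1 > maxu:
                        break
                    lmin = max(k + 1, j - 1 - maxu)
                    for l in range(j - 1, lmin - 1, -1):
                        inner = self.C[k][l]
                        if inner == INF or not self.allow[k, l]:
                            continue
                        e = self.e_interior(i, j, k, l)
                        if e is None:
                            continue
                        if self.binding:
                            ua = self.site_dp(i + 1, k - 1, _UC.INTERIOR)
                            ub = self.site_dp(l + 1, j - 1, _UC.INTERIOR)
                            if ua == INF or ub == INF:
                                continue
                            if abs(e + ua + ub + inner - target) < TOL:
                                run_sites(i + 1, k - 1, _UC.INTERIOR)
                                run_sites(l + 1, j - 1, _UC.INTERIOR)
                                pairs.append((k, l))
                                stack.append(("C", k, l))
                                found = True
                                break
                        elif abs(e + inner - target) < TOL:
                            pairs.append((k, l))
                            stack.append(("C", k, l))
                            found = True
                            break
                    if found:
                        break
                if found:
                    continue
                for k in range(i + 2, j - 1):
                    m = self.M[i + 1][k - 1]
                    m1 = self.M1[k][j - 1]
                    if m == INF or m1 == INF:
                        continue
                    e = self.e_multi_close(i, j, k)
                    if e is not None and abs(e + m + m1 - target) < TOL:
                        stack.append(("M", i + 1, k - 1))
                        stack.append(("M1", k, j - 1))
                        found = True
                        break
                if not found:
                    raise FoldingError(f"traceback failed in C[{i}][{j}]")
            elif tab == "M":
                if not self.binding:
                    e = self.e_ml_unpaired(i)
                    if e is not None and self.M[i + 1][j] != INF and \
                            abs(e + self.M[i + 1][j] - target) < TOL:
                        stack.append(("M", i + 1, j))
                        continue
                    found = False
                    for k in range(i + 1, j + 1):
                        c = self.C[i][k]
                        if c == INF:
                            continue
                        if k < j and self.degree_limit != 2:
                            eb = self.e_ml_branch(i, k, j, DecompStep.ML_SPLIT)
                            if eb is not None and self.M[k + 1][j] != INF and \
                                    abs(eb + c + self.M[k + 1][j] - target) < TOL:
                                pairs.append((i, k))
                                stack.append(("C", i, k))
                                stack.append(("M", k + 1, j))
                                found = True
                                break
                        er = self.e_ml_run(k + 1, j)
                        if er is not None:
                            eb = self.e_ml_branch(i, k, j, DecompStep.ML_STEM)
                            if eb is not None and abs(eb + er + c - target) < TOL:
                                pairs.append((i, k))
                                stack.append(("C", i, k))
                                found = True
                                break
                    if not found:
                        raise FoldingError(f"traceback failed in M[{i}][{j}]")
                else:
                    found = False
                    for r in range(i, j + 1):
                        lead = self.site_dp(i, r - 1, _UC.MULTI)
                        if lead == INF:
                            continue
                        for k in range(r + 1, j + 1):
                            c = self.C[r][k]
                            if c == INF:
                                continue
                            if k < j and self.degree_limit != 2:
                                eb = self.e_ml_branch(r, k, j, DecompStep.ML_SPLIT)
                                if eb is not None and self.M[k + 1][j] != INF and \
                                        abs(eb + lead + c + self.M[k + 1][j] - target) < TOL:
                                    run_sites(i, r - 1, _UC.MULTI)
                                    pairs.append((r, k))
                                    stack.append(("C", r, k))
                                    stack.append(("M", k + 1, j))
                                    found = True
                                    break
                            trail = self.site_dp(k + 1, j, _UC.MULTI)
                            if trail == INF:
                                continue
                            eb = self.e_ml_branch(r, k, j, DecompStep.ML_STEM)
                            if eb is not None and \
                                    abs(eb + lead + c + trail - target) < TOL:
                                run_sites(i, r - 1, _UC.MULTI)
                                run_sites(k + 1, j, _UC.MULTI)
                                pairs.append((r, k))
                                stack.append(("C", r, k))
                                found = True
                                break
                        if found:
                            break
                    if not found:
                        raise FoldingError(f"traceback failed in M[{i}][{j}]")
            else:  # M1
                if not self.binding:
                    c = self.C[i][j]
                    e = self.e_m1_stem(i, j)
                    if c != INF and e is not None and abs(e + c - target) < TOL:
                        pairs.append((i, j))
                        stack.append(("C", i, j))
                        continue
                    e = self.e_m1_unpaired(j)
                    if e is not None and self.M1[i][j - 1] != INF and \
                            abs(e + self.M1[i][j - 1] - target) < TOL:
                        stack.append(("M1", i, j - 1))
                        continue
                    raise FoldingError(f"traceback failed in M1[{i}][{j}]")
                else:
                    found = False
                    for l in range(i + 1, j + 1):
                        c = self.C[i][l]
                        if c == INF:
                            continue
                        trail = self.site_dp(l + 1, j, _UC.MULTI)
                        if trail == INF:
                            continue
                        e = self.e_m1_stem(i, l)
                        if e is not None and abs(e + c + trail - target) < TOL:
                            run_sites(l + 1, j, _UC.MULTI)
                            pairs.append((i, l))
                            stack.append(("C", i, l))
                            found = True
                            break
                    if not found:
                        raise FoldingError(f"traceback failed in M1[{i}][{j}]")
        return frozenset(pairs), tuple(sorted(occupied))

    # -- outside pass / base pair probabilities -----------------------------
    def outside(self) -> tuple[np.ndarray, np.ndarray]:
        """Outside recursion mirroring the inside terms; returns (bpp,
        unpaired probabilities)."""
        if self.mode != "pf":
            raise FoldingError("outside pass requires pf mode")
        if self.binding:
            raise FoldingError("use the enforce-pair identity in binding mode")
        n = self.n
        Z = self.F[1][n]
        if Z <= 0.0:
            raise NoAdmissibleStructureError("the constraints admit no structure")
        F, C, M, M1 = self.F, self.C, self.M, self.M1
        Cout = [[0.0] * (n + 2) for _ in range(n + 3)]
        Mout = [[0.0] * (n + 2) for _ in range(n + 3)]
        M1out = [[0.0] * (n + 2) for _ in range(n + 3)]
        wt = self.wt
        maxu = self.opts.max_interior_unpaired

        for s in range(n, 0, -1):
            for i in range(1, n - s + 2):
                j = i + s - 1
                # -- pushes from Mout[i][j] (final at this point) --
                mo = Mout[i][j]
                if mo != 0.0:
                    e = self.e_ml_unpaired(i)
                    if e is not None:
                        Mout[i + 1][j] += mo * wt(e, 1)
                    for k in range(i + 1, j + 1):
                        c = C[i][k]
                        if c == 0.0:
                            continue
                        if k < j and self.degree_limit != 2:
                            eb = self.e_ml_branch(i, k, j, DecompStep.ML_SPLIT)
                            if eb is not None and M[k + 1][j] != 0.0:
                                w = wt(eb, 0)
                                Cout[i][k] += mo * w * M[k + 1][j]
                                Mout[k + 1][j] += mo * w * c
                        er = self.e_ml_run(k + 1, j)
                        if er is not None:
                            eb = self.e_ml_branch(i, k, j, DecompStep.ML_STEM)
                            if eb is not None:
                                Cout[i][k] += mo * wt(eb + er, j - k)
                # -- pushes from M1out[i][j] --
                m1o = M1out[i][j]
                if m1o != 0.0:
                    if C[i][j] != 0.0:
                        e = self.e_m1_stem(i, j)
                        if e is not None:
                            Cout[i][j] += m1o * wt(e, 0)
                    e = self.e_m1_unpaired(j)
                    if e is not None and M1[i][j - 1] != 0.0:
                        M1out[i][j - 1] += m1o * wt(e, 1)
                # -- finalize Cout[i][j] with the exterior usage, then push --
                if C[i][j] != 0.0:
                    e = self.e_ext_stem(i, j)
                    if e is not None:
                        Cout[i][j] += F[1][i - 1] * wt(e, 0) * F[j + 1][n]
                    co = Cout[i][j]
                    if co != 0.0:
                        # interior loops: (i,j) closes, (k,l) enclosed
                        for k in range(i + 1, j - 1):
                            if k - i - 1 > maxu:
                                break
                            lmin = max(k + 1, j - 1 - maxu)
                            for l in range(j - 1, lmin - 1, -1):
                                if C[k][l] == 0.0 or not self.allow[k, l]:
                                    continue
                                e = self.e_interior(i, j, k, l)
                                if e is None:
                                    continue
                                Cout[k][l] += co * wt(e, s - (l - k + 1))
                        # multibranch closing
                        for k in range(i + 2, j - 1):
                            m = M[i + 1][k - 1]
                            m1 = M1[k][j - 1]
                            if m == 0.0 or m1 == 0.0:
                                continue
                            e = self.e_multi_close(i, j, k)
                            if e is None:
                                continue
                            w = wt(e, 2)
                            Mout[i + 1][k - 1] += co * w * m1
                            M1out[k][j - 1] += co * w * m

        bpp = np.zeros((n + 1, n + 1))
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if C[i][j] != 0.0 and Cout[i][j] != 0.0:
                    bpp[i, j] = C[i][j] * Cout[i][j] / Z
        unpaired = np.zeros(n + 1)
        for i in range(1, n + 1):
            unpaired[i] = 1.0 - float(bpp[i, :].sum() + bpp[:, i].sum())
        return bpp, unpaired

    # -- stochastic backtracking -------------------------------------------
    def sample(self, rng: np.random.Generator) -> frozenset[tuple[int, int]]:
        """Draw one structure from the Boltzmann distribution."""
        if self.mode != "pf":
            raise FoldingError("sampling requires pf mode")
        if self.binding:
            raise FoldingError("sampling is not supported with interval sites")
        n = self.n
        if self.F[1][n] <= 0.0:
            raise NoAdmissibleStructureError("the constraints admit no structure")
        F, C, M, M1 = self.F, self.C, self.M, self.M1
        wt = self.wt
        maxu = self.opts.max_interior_unpaired
        pairs: list[tuple[int, int]] = []
        stack: list[tuple[str, int, int]] = [("F", 1, n)]

        def choose(weights: list[float], total: float) -> int:
            r = rng.random() * total
            upto = 0.0
            for idx, w in enumerate(weights):
                upto += w
                if r <= upto:
                    return idx
            return len(weights) - 1

        while stack:
            tab, i, j = stack.pop()
            if j < i:
                continue
            if tab == "F":
                weights, actions = [], []
                e = self.e_ext_unpaired(i)
                if e is not None and F[i + 1][j] != 0.0:
                    weights.append(wt(e, 1) * F[i + 1][j])
                    actions.append(("F", i + 1, j, None))
                for k in range(i + 1, j + 1):
                    c = C[i][k]
                    if c == 0.0:
                        continue
                    e = self.e_ext_stem(i, k)
                    if e is None:
                        continue
                    weights.append(wt(e, 0) * c * F[k + 1][j])
                    actions.append(("FC", i, k, j))
                idx = choose(weights, F[i][j])
                act = actions[idx]
                if act[0] == "F":
                    stack.append(("F", act[1], act[2]))
                else:
                    _, a, k, jj = act
                    pairs.append((a, k))
                    stack.append(("C", a, k))
                    stack.append(("F", k + 1, jj))
            elif tab == "C":
                weights, actions = [], []
                e = self.e_hairpin(i, j)
                if e is not None:
                    weights.append(wt(e, j - i + 1))
                    actions.append(("H",))
                for k in range(i + 1, j - 1):
                    if k - i - 1 > maxu:
                        break
                    lmin = max(k + 1, j - 1 - maxu)
                    for l in range(j - 1, lmin - 1, -1):
                        if C[k][l] == 0.0 or not self.allow[k, l]:
                            continue
                        e = self.e_interior(i, j, k, l)
                        if e is None:
                            continue
                        weights.append(wt(e, (j - i + 1) - (l - k + 1)) * C[k][l])
                        actions.append(("I", k, l))
                for k in range(i + 2, j - 1):
                    m = M[i + 1][k - 1]
                    m1 = M1[k][j - 1]
                    if m == 0.0 or m1 == 0.0:
                        continue
                    e = self.e_multi_close(i, j, k)
                    if e is None:
                        continue
                    weights.append(wt(e, 2) * m * m1)
                    actions.append(("MB", k))
                idx = choose(weights, C[i][j])
                act = actions[idx]
                if act[0] == "I":
                    pairs.append((act[1], act[2]))
                    stack.append(("C", act[1], act[2]))
                elif act[0] == "MB":
                    stack.append(("M", i + 1, act[1] - 1))
                    stack.append(("M1", act[1], j - 1))
            elif tab == "M":
                weights, actions = [], []
                e = self.e_ml_unpaired(i)
                if e is not None and M[i + 1][j] != 0.0:
                    weights.append(wt(e, 1) * M[i + 1][j])
                    actions.append(("U",))
                for k in range(i + 1, j + 1):
                    c = C[i][k]
                    if c == 0.0:
                        continue
                    if k < j and self.degree_limit != 2:
                        eb = self.e_ml_branch(i, k, j, DecompStep.ML_SPLIT)
                        if eb is not None and M[k + 1][j] != 0.0:
                            weights.append(wt(eb, 0) * c * M[k + 1][j])
                            actions.append(("S", k))
                    er = self.e_ml_run(k + 1, j)
                    if er is not None:
                        eb = self.e_ml_branch(i, k, j, DecompStep.ML_STEM)
                        if eb is not None:
                            weights.append(wt(eb + er, j - k) * c)
                            actions.append(("L", k))
                idx = choose(weights, M[i][j])
                act = actions[idx]
                if act[0] == "U":
                    stack.append(("M", i + 1, j))
                elif act[0] == "S":
                    pairs.append((i, act[1]))
                    stack.append(("C", i, act[1]))
                    stack.append(("M", act[1] + 1, j))
                else:
                    pairs.append((i, act[1]))
                    stack.append(("C", i, act[1]))
            else:  # M1
                weights, actions = [], []
                c = C[i][j]
                e = self.e_m1_stem(i, j)
                if c != 0.0 and e is not None:
                    weights.append(wt(e, 0) * c)
                    actions.append(("P",))
                e = self.e_m1_unpaired(j)
                if e is not None and M1[i][j - 1] != 0.0:
                    weights.append(wt(e, 1) * M1[i][j - 1])
                    actions.append(("U",))
                idx = choose(weights, M1[i][j])
                if actions[idx][0] == "P":
                    pairs.append((i, j))
                    stack.append(("C", i, j))
                else:
                    stack.append(("M1", i, j - 1))
        return frozenset(pairs)


# --------------------------------------------------------------------------
# public API


def _defaults(seq, model, hard, soft, options):
    model = model or NearestNeighborModel.default()
    if hard is None:
        hard = HardConstraintMatrix.permissive(seq, model.min_hairpin_unpaired)
    soft = soft or SoftConstraintSet(len(seq))
    options = options or FoldOptions()
    return model, hard, soft, options


def count_structures(
    seq: Sequence,
    hard: HardConstraintMatrix | None = None,
    options: FoldOptions | None = None,
) -> int:
    """Exact number of structures satisfying all hard constraints."""
    model, hard, soft, options = _defaults(seq, None, hard, None, options)
    return _Fold(seq, model, hard, soft, options, "count").count()


def mfe_fold(
    seq: Sequence,
    model: NearestNeighborModel | None = None,
    hard: HardConstraintMatrix | None = None,
    soft: SoftConstraintSet | None = None,
    options: FoldOptions | None = None,
) -> FoldResult:
    """Minimum of E0(psi) + soft(psi) over the constrained ensemble."""
    model, hard, soft, options = _defaults(seq, model, hard, soft, options)
    fold = _Fold(seq, model, hard, soft, options, "mfe")
    total = fold.mfe_energy()
    if total == INF:
        raise NoAdmissibleStructureError("no admissible structure under these constraints")
    pairs, occupied = fold.traceback()
    standard = eval_structure(seq, pairs, model)
    return FoldResult(
        structure=pairs_to_dotbracket(len(seq), pairs),
        energy_total=total,
        energy_standard=standard,
        energy_soft=total - standard,
        pairs=pairs,
        occupied_sites=occupied,
    )


def partition_function(
    seq: Sequence,
    model: NearestNeighborModel | None = None,
    hard: HardConstraintMatrix | None = None,
    soft: SoftConstraintSet | None = None,
    options: FoldOptions | None = None,
) -> EnsembleResult:
    """Z = sum_psi exp(-E(psi)/RT) plus base-pair probabilities."""
    model, hard, soft, options = _defaults(seq, model, hard, soft, options)
    fold = _Fold(seq, model, hard, soft, options, "pf")
    log_z = fold.log_Z()
    rt = options.thermo.RT
    if fold.binding:
        bpp, unpaired = _binding_bpp(fold, seq, model, hard, soft, options)
    else:
        bpp, unpaired = fold.outside()
    z = math.exp(log_z) if log_z < 700 else INF
    return EnsembleResult(
        Z=z,
        log_Z=log_z,
        free_energy=-rt * log_z,
        bpp=bpp,
        unpaired_prob=unpaired,
        _state=fold,
    )


def _binding_bpp(fold, seq, model, hard, soft, options):
    """p_ij via the enforce-pair identity p_ij = Z[(i,j) enforced]/Z.

    The interval-site grammar has no outside pass here, so each admissible
    pair is enforced in a copy of the matrix and the constrained partition
    function recomputed (O(n^2) extra folds; intended for short RNAs)."""
    from .constraints import compile_constraints, enforce_pair, InconsistentConstraintError

    n = len(seq)
    log_z = fold.log_Z()
    bpp = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if not fold.allow[i, j]:
                continue
            m2 = hard.copy()
            try:
                _apply_enforce(m2, i, j)
            except InconsistentConstraintError:
                continue
            sub = _Fold(seq, model, m2, soft, options, "pf")
            if sub.F[1][n] <= 0.0:
                continue
            bpp[i, j] = math.exp(sub.log_Z() - log_z)
    unpaired = np.zeros(n + 1)
    for i in range(1, n + 1):
        unpaired[i] = 1.0 - float(bpp[i, :].sum() + bpp[:, i].sum())
    return bpp, unpaired


def _apply_enforce(m: HardConstraintMatrix, i: int, j: int) -> None:
    from .constraints import InconsistentConstraintError

    if not m.any_pair(i, j):
        raise InconsistentConstraintError(f"({i},{j})")
    m.clear_unpaired(i)
    m.clear_unpaired(j)
    m._clear_all_partners(i, keep=j)
    m._clear_all_partners(j, keep=i)
    for a in range(1, m.n + 1):
        for b in range(a + 1, m.n + 1):
            if (a < i < b < j) or (i < a < j < b):
                m.pair[a, b] = 0


def stochastic_backtrack(
    ensemble: EnsembleResult,
    n_samples: int,
    seed: int,
    prune_threshold: float | str | None = None,
) -> list[str]:
    """Draw i.i.d. Boltzmann samples from a computed ensemble.

    With pruning, base pairs whose probability falls below the threshold
    (default 1/(n * n_samples) when 'auto') are forbidden outright and the
    constrained partition function is recomputed before sampling; a
    hard-pruned pair therefore never appears in the sample, unlike the
    large-penalty emulation of hard constraints.
    """
    fold = ensemble._state
    if fold is None:
        raise FoldingError("ensemble lacks engine state; recompute partition_function")
    if prune_threshold is not None:
        n = fold.n
        thr = 1.0 / (n * n_samples) if prune_threshold == "auto" else float(prune_threshold)
        hard2 = fold.hard.copy()
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if fold.allow[i, j] and ensemble.bpp[i, j] < thr:
                    hard2.pair[i, j] = 0
        fold = _Fold(fold.seq, fold.model, hard2, fold.soft, fold.opts, "pf")
        if fold.F[1][n] <= 0.0:
            raise NoAdmissibleStructureError("pruning emptied the ensemble")
    rng = np.random.default_rng(seed)
    n = fold.n
    return [pairs_to_dotbracket(n, fold.sample(rng)) for _ in range(n_samples)]


def fold_with_binding_sites(
    seq: Sequence,
    model: NearestNeighborModel | None = None,
    hard: HardConstraintMatrix | None = None,
    soft: SoftConstraintSet | None = None,
    mode: str = "mfe",
    options: FoldOptions | None = None,
):
    """Fold with interval binding sites active (mfe or pf mode).

    Without sites this is identical to mfe_fold / partition_function."""
    if mode == "mfe":
        return mfe_fold(seq, model, hard, soft, options)
    if mode == "pf":
        return partition_function(seq, model, hard, soft, options)
    raise ValueError("mode must be 'mfe' or 'pf'")
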