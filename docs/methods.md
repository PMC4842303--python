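# Methods

This note documents the models, algorithms and numerical choices behind
`confold`, in the spirit of the methods documentation of mature folding and
simulation packages.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Search space and grammar

A secondary structure on x ∈ {A,C,G,U}ⁿ is a set of pairs (i, j), i < j,
from ℬ(x) = {GC, CG, AU, UA, GU, UG}, with no shared endpoints, no crossing
pairs, and j − i − 1 ≥ 3 for every pair (the hairpin geometric rule, applied
to all pairs as is conventional).  Structures are generated by the
unambiguous grammar

    F(i,j)  → ε | unpaired(i)·F(i+1,j) | C(i,k)·F(k+1,j)
    C(i,j)  → hairpin(i,j)
            | interior(i,j;k,l)·C(k,l)
            | close(i,j)·M(i+1,k−1)·M¹(k,j−1)      (k = start of last branch)
    M(i,j)  → unpaired(i)·M(i+1,j)
            | branch C(i,k)·M(k+1,j)               (more branches follow)
            | branch C(i,k)·run(k+1,j)             (last M branch)
    M¹(i,j) → C(i,j) | M¹(i,j−1)·unpaired(j)

Unambiguity matters: the counting mode sums 1 per derivation, so the grammar
must generate each structure exactly once.  The ten decomposition cases of
this grammar (exterior unpaired/stem; hairpin; interior; multibranch
closing; M unpaired/split/stem; M¹ stem/unpaired) are the domain of the
generic constraint callbacks.

Interior loops are capped at 30 unpaired nucleotides per side (the
customary sparsification of the O(n⁴) interior sum); at the oracle sizes
used in the tests (n ≤ 16) the cap is never active, so oracle comparisons
are exact.

## 2. Energy model

The embedded parameter set is compact by design:

| parameter | default | unit | role |
|---|---|---|---|
| stack_energies | 21 symmetric values, Turner-like | kcal/mol | all 36 ordered canonical stacks |
| hairpin_base | 5.6 | kcal/mol | hairpin of minimal size (3) |
| hairpin_log_coeff | 1.08 | kcal/mol | × ln(size/3) size dependence |
| interior_size_coeff | 0.5 | kcal/mol | × (u₁+u₂) for non-stack interior loops |
| interior_asymmetry_coeff | 0.5 | kcal/mol | × \|u₁−u₂\| |
| multiloop_closing / branch / unpaired | 3.4 / 0.4 / 0.0 | kcal/mol | linear multibranch decomposition a + b·(branches+1) + c·unpaired |
| min_hairpin_unpaired | 3 | nt | hairpin geometric rule |
| temperature | 310.15 K, R = 1.98717×10⁻³ kcal/(mol·K) | | RT ≈ 0.6163 kcal/mol |

There are no dangling ends, terminal mismatches, coaxial stacks or special
tri-/tetraloop tables.  This keeps the exhaustive enumeration oracle exact
(every loop energy is a closed form) and leaves the constraint layer — the
point of the package — fully exercised.  The stack table satisfies the
physical strand-flip symmetry E[(i,j),(k,l)] = E[(l,k),(j,i)] by
construction.  All parameters can be overridden via a flat key/value config
(`hairpin_base 4.2`, `stack_GC_GC -9.9`, ...); the engine never assumes the
defaults.

## 3. Hard constraints

Per-pair context masks (6 bits) and per-position unpaired masks (4 bits)
are stored in numpy uint8 arrays — one byte per matrix cell, n(n+1)/2 cells.
Compilation order: pairing-rule and hairpin-span bits are cleared first,
then directives apply in sequence.

* `force_unpaired(i)` clears all pairs involving i — O(n).
* `enforce_pair(i,j)` clears the unpaired bits of i and j, all alternative
  partners, and every pair crossing (i, j) — O(n²); since a structure holds
  fewer than n/2 pairs, any directive list compiles in O(n³).
* `enforce_interior_loop(u′,u″,v′,v″)` enforces both delimiting pairs,
  restricts (u′,u″) to the interior-closing context, and forces the loop
  positions unpaired.  Other decompositions of C(u′,u″) die automatically
  because v′/v″ may no longer be unpaired.
* `span_limit(L)` forbids pairs with span j − i + 1 > L (keeping local
  pairs; reading the limit the other way would forbid exactly the pairs the
  restriction is meant to keep).
* Forbidden interior loops are a sparse set of (i,j,k,l) tuples — never a
  dense O(n⁴) array.
* A multibranch degree limit of 2 is realised by skipping the M split term,
  so M holds exactly one branch.

Contradictions (a pair both enforced and forbidden, an enforced pair whose
bits are already cleared) raise at compile time, naming the pair.  The
per-position necessary condition — every position can be unpaired or has at
least one admissible partner — is checked separately; it is necessary but
not sufficient, which is documented behaviour, not a defect: full
satisfiability is equivalent to non-emptiness of the ensemble, which
`count_structures` decides exactly.

A per-context unpaired-run index (length of the admissible unpaired run
starting at each position) reduces per-loop constraint lookups to one or
two array accesses.

## 4. Soft constraints

Only the reduced parameters are stored.  The raw per-position bonuses
(bᵘᵢ for unpaired, bᵖᵢ for paired) collapse to δᵢ = bᵘᵢ − bᵖᵢ plus a
structure-independent constant E′ = Σᵢ bᵖᵢ, which shifts every structure
equally and therefore never influences the ensemble; analogously Δᵢⱼ for
pairs, charged exactly once at the closing evaluation of the loop the pair
closes.  `SoftConstraintSet.from_paired_unpaired` performs the reduction;
the shift-invariance tests verify both the reduction (engine vs raw-bonus
enumeration) and the invariance under a common shift of bᵘ and bᵖ.

Per-position terms are accumulated through prefix sums, so an unpaired run
costs O(1) regardless of length.  Loop-type-specific δᵗ/Δᵗ add per-context
arrays on top of the context-free ones.  Soft matrices are dense (the
~50 % memory overhead buys simple O(1) access).

Generic callbacks receive (step, i, j, k, l, payload) and return a bonus
energy (soft) or an allow/deny decision (hard).  Multiple soft callbacks
compose additively, hard ones conjunctively — matching the AND-only
expressivity of the constraint language; disjunctive or conditional
constraints ("one of these pairs") would require classified DP and are out
of scope.  An optional init hook receives (payload, sequence, model,
thermodynamics) before a fold.

**Span down-weighting.**  The multiplicative factor
γ(i,j) = α₁·(e^(−(j−i−1)/α₂) − 1) + 1 on loop energies is additive in
disguise: the callback returns (γ − 1)·E^L at each loop-closing step.  For
multibranch loops only the closing-step share (a + b) is reweighted — the
rest of the loop energy is distributed over M/M¹ steps whose spans are not
known at the closing step.  With α₁ = 0 the callback returns exactly 0.0,
so the unconstrained ensemble is reproduced bit for bit.

**Probing conversions.**  The linear-log conversion (slope 1.8, intercept
−0.6 by default) charges m·ln(r+1) + b per *paired* nucleotide; by the δ
reduction it is stored as δᵢ = −(m·ln(rᵢ+1) + b).  (The original
formulation penalises stacks; the compact model has no per-stack hook, so
the per-paired-nucleotide attachment is the documented deviation.)  The
log-odds conversion stores δᵢ = −RT·ln(pᵢ/(1−pᵢ)) from unpaired
probabilities, clamped to [10⁻⁶, 1−10⁻⁶] with a warning.  The ternary model
(distinct bonuses for unpaired, stem-interior and stem-terminal
nucleotides) attaches δᵘ to unpaired positions and δᵗ — via a generic
callback — to the nucleotides of loop-closing pairs and of enclosed pairs
that are not stacked pairs; the two cases coincide exactly for lonely
pairs, so the conversion refuses to run unless lonely pairs are disallowed.

**Lonely-pair exclusion** is the canonical heuristic: (i, j) is admissible
only if (i+1, j−1) or (i−1, j+1) is admissible.  This does not remove every
isolated pair from the ensemble (a stackable neighbour may still be
unpaired); the enumeration oracle applies the same per-pair predicate, so
the two routes agree exactly, and the heuristic is documented as such.

**Interval binding sites.**  A site [p, q] with bonus β can be occupied as
a unit inside hairpin, interior or multibranch loops (the loop types whose
recursions expose unpaired intervals; exterior sites are rejected).  With
sites active the M/M¹/loop recursions consume *maximal* unpaired runs as
units — splitting a run would count arrangements twice — and each run is
scored by a 1-D DP over non-overlapping, fully contained sites: min-plus
for MFE, sum-product for the partition function, arrangement counting in
the counting mode.  An occupied site contributes β and masks the
per-position soft terms of its interval; the standard multibranch
per-unpaired cost still applies to covered positions (they remain unpaired
in the secondary structure).  Base-pair probabilities in this mode use the
identity p₍ᵢⱼ₎ = Z[(i,j) enforced]/Z with one constrained fold per
admissible pair (O(n²) folds) instead of an outside pass through the
interval grammar — a deliberate simplicity/speed trade-off appropriate for
the short RNAs this mode targets.

## 5. Engine numerics

* **Counting** uses Python integers — exact at any size.
* **MFE traceback** re-derives each cell's optimal term with tolerance
  10⁻⁹, preferring the unpaired extension and then the smallest split
  point, so tracebacks are reproducible and documented.
* **Partition function**: per-nucleotide rescaling (each recursion term is
  multiplied by σ^consumed, consumed = nucleotides newly covered) activates
  for n > 200 with σ = exp(1.05·E_MFE/(n·RT)); log Z is always reported
  from the scaled tables, so the choice of σ is invisible in results.
  Overflow despite rescaling raises, never returns silent infinities.
* **Outside pass** mirrors the inside term structure exactly — including
  soft terms and callbacks — pushing outside weights from larger to smaller
  spans; p₍ᵢⱼ₎ = C·C_out/Z, and per-position unpaired probabilities complete
  each row to 1 within 10⁻⁹.
* **Stochastic backtracking** samples each cell's terms proportionally to
  their Boltzmann weights with one explicit seeded generator
  (`numpy.random.default_rng`) passed through all calls.  Pruning forbids
  pairs with p₍ᵢⱼ₎ below the threshold (default 1/(n·N) for N samples),
  recompiles the hard matrix and recomputes the partition function before
  sampling — a pruned pair therefore never appears, unlike the
  large-penalty emulation of hard constraints, which only makes forbidden
  structures exponentially rare.
* Empty ensembles (over-constrained inputs) raise a dedicated error in
  every mode.

## 6. Ensemble algebra

`compose_partition`, `bpp_complement` and `bpp_compose` implement the
hard↔soft composition identities.  The complement is the weighted
difference p − (Z[X]/Z)·p[X] normalized by the full Z (values below −10⁻⁹
raise a consistency error; round-off above that is clipped to 0); the
composition therefore assembles p′ = (Z/Z′)·p[¬X] + (Z[X]·e^(−E/RT)/Z′)·p[X],
which is algebraically identical to weighting the complement ensemble by
(Z−Z[X])/Z′ when the complement is normalized on its own ensemble.  The
composition route agrees with the direct soft-constrained fold to 10⁻⁹ for
single-pair features; for K overlapping features it provably does not —
pairwise composition misses the inclusion/exclusion cross terms (the 2^K
blow-up), and a regression test documents the inequality on a constructed
example.  The equivalent per-recursion soft constraints avoid the blow-up.

Ligand binding: ΔG = RT·ln(K_d/c), Z′ = Z + Z[X]·e^(−ΔG/RT).  The bundled
theophylline model abstracts the aptamer core to an interior-loop motif
(5′ GAUACCAG / 3′ CCCUUGGCAGC, K_d = 0.32 µM).  Motif placements are exact
string matches of both strands with canonical delimiting pairs, scanned in
a preprocessing step; each placement's ΔG + correction is applied by a
generic callback whenever the DP evaluates exactly that interior loop.
The intra-motif helix correction defaults to 0 and is user-settable (no
quantified default exists for the compact model).

## 7. Synthetic data and what the tests show

The oracle layer enumerates the complete constrained ensemble for n ≤ 20
(two independent enumerators — recursive interval decomposition and
non-crossing subset filtering — are cross-checked against each other, and
the unconstrained counts against an external exhaustive-suboptimal
enumerator).  Constraints are applied to enumerated structures
*declaratively* through the loop decomposition, and soft energies including
callbacks through the structure's unique grammar derivation, so oracle and
engine share no recursion code.

`random_instance` emulates study conditions: uniform or GC-biased random
sequences, directive densities of ~0.15 per nucleotide drawn from
forbid/force/enforce kinds and post-filtered for mutual consistency, soft
energies uniform in ±3 kcal/mol (the scale of realistic probing
pseudo-energies).  The modified-tRNA scenario plants a 63-nt cloverleaf
(GC-rich stems generated from the planted structure, A-runs elsewhere) and
marks stem-interior positions as unpairable "modified" bases —
demonstrating, not benchmarking, the sensitivity/PPV effect of modification
constraints.

What passing tests do and do not show: agreement with enumeration at
n ≤ 16 verifies the recursions, the constraint interleaving and the
probability algebra exactly, for every feature combination exercised; it
does not validate the compact energy parameters against measured RNA
thermodynamics (real-data accuracy needs the full nearest-neighbor tables,
which are out of scope), and oracle sizes cannot witness asymptotic
performance.  Problem sizes (200 counting instances at n ≤ 16, 100
thermodynamic instances at n ≤ 14, 50 composition instances, 10⁴ samples)
keep the whole suite in the seconds-to-minutes range while the instance
streams remain seeded and reproducible.

## 8. Known limitations

* Compact energy model — no dangling ends, mismatches, or special loops;
  predictions on real RNAs are qualitative.
* Conjunctive constraints only; conditional/disjunctive constraints would
  need classified DP.
* Binding-site mode computes p₍ᵢⱼ₎ by O(n²) constrained folds; fine for
  short RNAs, expensive beyond a few hundred nucleotides.
* The pure-Python recursions favour clarity over speed: quadratic-space
  tables, roughly cubic time with the interior cap — suitable for RNAs up
  to a few hundred nucleotides.
* No G-quadruplexes, no windowed/local folding, no comparative folding, no
  suboptimal enumeration beyond stochastic sampling.
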