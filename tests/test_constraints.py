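"""Constraint compilation, propagation, storage, parsing and conversion."""

import math

import numpy as np
import pytest

from confold import (
    PairContext,
    Sequence,
    SoftConstraintSet,
    SpanWeightParams,
    ThermoParams,
    UnpairedContext,
    check_consistency,
    compile_constraints,
    enforce_pair,
    forbid_pair,
    force_paired,
    force_unpaired,
    parse_constraint_file,
    parse_pseudo_dotbracket,
    shape_ternary_soft,
    shape_to_soft,
    span_weight_callback,
    unpaired_run_index,
)
from confold.constraints import ConstraintError, InconsistentConstraintError
from confold.grammar import DecompStep
from confold.oracle import enumerate_structures, random_instance


def pairs_with_bits(m):
    return {(i, j) for i in range(1, m.n + 1) for j in range(i + 1, m.n + 1)
            if m.any_pair(i, j)}


class TestCompile:
    def test_permissive_matrix_matches_pairing_rules(self):
        # brute force over B(x) with the hairpin span rule, seq GGAAACC
        m = compile_constraints(Sequence("GGAAACC"), [])
        assert pairs_with_bits(m) == {(1, 6), (1, 7), (2, 6), (2, 7)}

    def test_force_unpaired_clears_all_partners(self):
        m = compile_constraints(Sequence("GGAAACC"), [force_unpaired(1)])
        assert pairs_with_bits(m) == {(2, 6), (2, 7)}
        assert m.any_unpaired(1)

    def test_enforce_pair_clears_alternatives_and_crossings(self):
        m = compile_constraints(Sequence("GGAAACC"), [enforce_pair(1, 7)])
        assert not m.any_unpaired(1) and not m.any_unpaired(7)
        # (2,6) nests inside and survives; (2,7) and (1,6) are alternatives
        assert pairs_with_bits(m) == {(1, 7), (2, 6)}

    def test_contradiction_raises_naming_pair(self):
        with pytest.raises(InconsistentConstraintError, match=r"\(1,7\)"):
            compile_constraints(Sequence("GGAAACC"),
                                [forbid_pair(1, 7), enforce_pair(1, 7)])
        with pytest.raises(InconsistentConstraintError, match=r"\(1,7\)"):
            compile_constraints(Sequence("GGAAACC"),
                                [enforce_pair(1, 7), forbid_pair(1, 7)])

    def test_idempotent_recompilation(self):
        seq, dirs, _ = random_instance(n=14, seed=5)
        m1 = compile_constraints(seq, dirs)
        m2 = compile_constraints(seq, dirs + dirs)
        assert np.array_equal(m1.pair, m2.pair)
        assert np.array_equal(m1.unpaired, m2.unpaired)

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_restriction(self, seed):
        """Compilation never sets a bit the pairing rules had cleared."""
        seq, dirs, _ = random_instance(n=14, seed=seed)
        base = compile_constraints(seq, [])
        m = compile_constraints(seq, dirs)
        assert ((m.pair & ~base.pair) == 0).all()
        assert ((m.unpaired & ~base.unpaired) == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_compiled_ensemble_equals_declarative_filter(self, seed):
        """The ensemble under the compiled matrix equals the brute-force
        ensemble filtered by the directives' declarative meaning."""
        seq, dirs, _ = random_instance(n=12, seed=40 + seed, constraint_density=0.3)
        m = compile_constraints(seq, dirs)
        got = {ps for ps in enumerate_structures(seq, m).structures}

        must_unpaired = {d.pos[0] for d in dirs if d.kind == "force_unpaired"}
        banned = {d.pos for d in dirs if d.kind == "forbid_pair"}
        required = {d.pos for d in dirs if d.kind == "enforce_pair"}
        expected = set()
        for ps in enumerate_structures(seq).structures:
            paired = {x for p in ps for x in p}
            if paired & must_unpaired:
                continue
            if banned & ps:
                continue
            if not required <= ps:
                continue
            expected.add(ps)
        assert got == expected


class TestConsistency:
    def test_permissive_matrix_consistent(self):
        m = compile_constraints(Sequence("GGAAACC"), [])
        assert check_consistency(m) == []

    def test_unpaired_and_paired_conflict_detected(self):
        m = compile_constraints(Sequence("GGAAACC"),
                                [force_unpaired(1), force_paired(1)])
        assert check_consistency(m) == [1]

    def test_posthoc_clearing_detected(self):
        m = compile_constraints(Sequence("GGAAACC"), [enforce_pair(1, 7)])
        m.pair[1, 7] = 0  # clear the enforced pair behind the compiler's back
        assert check_consistency(m) == [1, 7]


class TestRunIndex:
    def test_all_unpaired(self):
        m = compile_constraints(Sequence("AAAAA"), [])
        assert unpaired_run_index(m).tolist() == [5, 4, 3, 2, 1]

    def test_forced_pair_breaks_run(self):
        m = compile_constraints(Sequence("AAAAA"), [])
        m.clear_unpaired(3)
        assert unpaired_run_index(m).tolist() == [2, 1, 0, 2, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_scan_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        m = compile_constraints(Sequence("A" * n), [])
        for trial in range(200):
            m.unpaired[1:] = rng.integers(0, 16, size=n, dtype=np.uint8)
            idx = unpaired_run_index(m)
            for i in range(1, n + 1):
                run = 0
                for u in range(i, n + 1):
                    if not m.any_unpaired(u):
                        break
                    run += 1
                assert idx[i - 1] == run


class TestPseudoDotBracket:
    def test_no_constraints(self):
        assert parse_pseudo_dotbracket(".......") == []

    def test_single_characters(self):
        kinds = {d.kind for d in parse_pseudo_dotbracket("x|<>...")}
        assert kinds == {"force_unpaired", "force_paired",
                         "force_paired_downstream", "force_paired_upstream"}

    def test_bracket_matching(self):
        dirs = parse_pseudo_dotbracket("((...))")
        assert [(d.kind, d.pos) for d in dirs] == [
            ("enforce_pair", (1, 7)), ("enforce_pair", (2, 6))]

    def test_unbalanced_reports_position(self):
        with pytest.raises(ConstraintError, match="position 5"):
            parse_pseudo_dotbracket("(...(..")
        with pytest.raises(ConstraintError, match="position 3"):
            parse_pseudo_dotbracket("..)....")


class TestConstraintFile:
    def test_records(self):
        dirs, soft = parse_constraint_file([
            "# comment", "", "P 3 0 2", "F 2 10 3", "E 5 0.5",
        ])
        assert [(d.kind, d.pos) for d in dirs] == [
            ("force_unpaired", (3,)), ("force_unpaired", (4,)),
            ("enforce_pair", (2, 10)), ("enforce_pair", (3, 9)),
            ("enforce_pair", (4, 8)),
        ]
        assert len(soft) == 1 and soft[0].pos == (5,) and soft[0].energy == 0.5

    def test_context_letters(self):
        dirs, _ = parse_constraint_file(["P 1 10 1 HM"])
        assert dirs[0].pair_context == (
            PairContext.HAIRPIN_CLOSING | PairContext.MULTI_CLOSING
            | PairContext.MULTI_ENCLOSED)

    def test_malformed_record_reports_line(self):
        with pytest.raises(ConstraintError, match="line 2"):
            parse_constraint_file(["P 1 10 1", "Q 1 2"])


class TestShapeConversion:
    def test_log_odds_half_is_zero(self, thermo):
        soft = shape_to_soft({3: 0.5}, 7, method="log_odds", thermo=thermo)
        assert soft.delta_unpaired[3] == pytest.approx(0.0)

    def test_log_odds_closed_form(self, thermo):
        p = math.e / (1 + math.e)
        soft = shape_to_soft({2: p}, 5, method="log_odds", thermo=thermo)
        assert soft.delta_unpaired[2] == pytest.approx(-thermo.RT)

    def test_log_odds_clamps_with_warning(self, thermo):
        with pytest.warns(UserWarning, match="clamped"):
            soft = shape_to_soft({1: 1.5}, 5, method="log_odds", thermo=thermo)
        assert math.isfinite(soft.delta_unpaired[1])

    def test_deigan_zero_reactivity_contributes_intercept(self):
        soft = shape_to_soft({4: 0.0}, 9, method="deigan", slope=1.8, intercept=-0.6)
        # paired-side contribution b = -0.6 stored as delta = +0.6 on unpaired
        assert soft.delta_unpaired[4] == pytest.approx(0.6)

    def test_missing_positions_contribute_nothing(self):
        soft = shape_to_soft({2: 1.0}, 6, method="deigan")
        assert soft.delta_unpaired[1] == 0.0 and soft.delta_unpaired[3] == 0.0


class TestTernaryModel:
    def test_requires_no_lonely_pairs(self):
        with pytest.raises(ConstraintError, match="lonely"):
            shape_ternary_soft({1: 0.2}, 5, lambda v: (v, v, v), no_lonely_pairs=False)

    def test_equal_bonuses_vanish(self):
        soft = shape_ternary_soft({i: 0.3 for i in range(1, 6)}, 5,
                                  lambda v: (1.1, 1.1, 1.1), no_lonely_pairs=True)
        assert not soft.delta_unpaired.any()
        cb = soft.callbacks[0]
        assert cb.function(DecompStep.HAIRPIN_LOOP, 1, 5, 0, 0, cb.payload) == 0.0

    def test_helix_energy_shift_matches_hand_count(self):
        """Helix (1,10),(2,9),(3,8) + hairpin: terminal pairs are (1,10)
        and (3,8); unpaired are 4..7; hand-computed shift = 2*(dt_i+dt_j)
        + sum du."""
        n = 10
        conv = lambda v: (0.5, 0.2, 0.0)   # du=0.5, dt=0.2 everywhere
        soft = shape_ternary_soft({i: 1.0 for i in range(1, n + 1)}, n, conv,
                                  no_lonely_pairs=True)
        from confold.structure import derivation_steps
        pairs = {(1, 10), (2, 9), (3, 8)}
        shift = sum(soft.callback_energy(*step) for step in derivation_steps(n, pairs))
        shift += sum(soft.delta_unpaired[u] for u in (4, 5, 6, 7))
        assert shift == pytest.approx(2 * (0.2 + 0.2) + 4 * 0.5)

    def test_uniform_stack_baseline_shift_leaves_deltas(self):
        """Shifting b^s uniformly changes only the dropped constant E'."""
        for kappa in (0.0, 2.5):
            conv = lambda v, k=kappa: (0.5 + k, 0.2 + k, 0.0 + k)
            soft = shape_ternary_soft({1: 1.0}, 5, conv, no_lonely_pairs=True)
            assert soft.delta_unpaired[1] == pytest.approx(0.5)
            assert soft.callbacks[0].payload["dt"][1] == pytest.approx(0.2)


class TestSpanWeight:
    def test_gamma_values(self):
        p = SpanWeightParams(0.5, 10.0)
        assert p.gamma(1, 2) == pytest.approx(1.0)          # span j-i-1 = 0
        assert SpanWeightParams(0.0, 7.0).gamma(1, 50) == pytest.approx(1.0)
        assert p.gamma(1, 10 ** 6) == pytest.approx(0.5)    # limit alpha1=0.5

    def test_callback_returns_gamma_minus_one_times_loop_energy(self, model):
        seq = Sequence("GAAAAAAAC")
        cb = span_weight_callback(SpanWeightParams(0.5, 5.0))
        cb.init(cb.payload, seq, model, ThermoParams())
        from confold.energy_model import eval_hairpin
        e_loop = eval_hairpin(seq, 1, 9, model)
        got = cb.function(DecompStep.HAIRPIN_LOOP, 1, 9, 0, 0, cb.payload)
        gamma = SpanWeightParams(0.5, 5.0).gamma(1, 9)
        assert got == pytest.approx((gamma - 1.0) * e_loop)

    def test_alpha2_must_be_positive(self):
        with pytest.raises(ValueError):
            SpanWeightParams(0.5, 0.0)


class TestSoftSet:
    def test_run_energy_matches_prefix_sums(self):
        soft = SoftConstraintSet(10)
        for i in range(1, 11):
            soft.add_unpaired(i, 0.1 * i)
        soft.add_unpaired(4, -1.0, UnpairedContext.MULTI)
        assert soft.run_energy(2, 5, UnpairedContext.HAIRPIN) == pytest.approx(
            0.2 + 0.3 + 0.4 + 0.5)
        assert soft.run_energy(2, 5, UnpairedContext.MULTI) == pytest.approx(
            0.2 + 0.3 + 0.4 + 0.5 - 1.0)
        assert soft.run_energy(5, 4, UnpairedContext.MULTI) == 0.0

    def test_pair_bonus_charged_once_at_closing(self):
        soft = SoftConstraintSet(10)
        soft.add_pair(2, 8, -1.5)
        assert soft.pair_energy(2, 8, PairContext.HAIRPIN_CLOSING) == -1.5
        assert soft.pair_energy(2, 8, PairContext.EXTERIOR) == 0.0

    def test_binding_sites_reject_exterior_context(self):
        soft = SoftConstraintSet(10)
        with pytest.raises(ConstraintError, match="hairpin, interior"):
            soft.binding_sites.add(2, 4, -3.0, UnpairedContext.EXTERIOR)
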