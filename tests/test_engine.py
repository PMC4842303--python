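"""Engine correctness: counting, MFE, partition function vs enumeration."""

import math

import numpy as np
import pytest

from confold import (
    FoldOptions,
    NoAdmissibleStructureError,
    Sequence,
    SoftConstraintSet,
    SpanWeightParams,
    compile_constraints,
    count_structures,
    forbid_pair,
    force_unpaired,
    mfe_fold,
    partition_function,
    span_limit,
    span_weight_callback,
)
from confold.oracle import (
    declarative_soft_energy,
    enumerate_structures,
    random_instance,
)
from confold.structure import dotbracket_to_pairs


class TestCounting:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAA", 1), ("GAAAC", 2), ("GGAAACC", 6),
    ])
    def test_known_counts(self, seq, expected):
        assert count_structures(Sequence(seq)) == expected

    def test_constrained_count_matches_enumeration(self):
        seq = Sequence("GGAAACC")
        hard = compile_constraints(seq, [force_unpaired(1)])
        assert count_structures(seq, hard) == enumerate_structures(seq, hard).count

    @pytest.mark.parametrize("seed", range(25))
    def test_random_instances_exact(self, seed):
        seq, dirs, _ = random_instance(n=8 + seed % 9, seed=seed)
        hard = compile_constraints(seq, dirs)
        assert count_structures(seq, hard) == enumerate_structures(seq, hard).count

    def test_diagonal_respects_unpaired_constraint(self):
        # a single position that must pair but has no partner: zero structures
        seq = Sequence("AAAA")
        hard = compile_constraints(seq, [])
        hard.clear_unpaired(2)
        assert count_structures(seq, hard) == 0


class TestMFE:
    def test_unpairable_sequence_open_chain(self, model):
        res = mfe_fold(Sequence("AAAA"), model)
        assert res.structure == "...." and res.energy_total == 0.0

    def test_all_pairs_forbidden_open_chain(self, model):
        seq = Sequence("GGGAAACCC")
        dirs = [forbid_pair(i, j) for i in range(1, 10) for j in range(i + 1, 10)
                if seq.pairable(i, j)]
        res = mfe_fold(seq, model, compile_constraints(seq, dirs))
        assert res.structure == "........." and res.energy_total == 0.0

    def test_overconstrained_raises(self, model):
        seq = Sequence("AAAA")
        hard = compile_constraints(seq, [])
        hard.clear_unpaired(2)
        with pytest.raises(NoAdmissibleStructureError):
            mfe_fold(seq, model, hard)

    @pytest.mark.parametrize("seed", range(15))
    def test_equals_enumerated_minimum(self, model, seed):
        seq, dirs, soft = random_instance(n=9 + seed % 8, seed=100 + seed,
                                          loop_type_soft=True)
        hard = compile_constraints(seq, dirs)
        ens = enumerate_structures(seq, hard)
        if not ens.count:
            return
        _, best = ens.mfe(model, soft)
        res = mfe_fold(seq, model, hard, soft)
        assert res.energy_total == pytest.approx(best, abs=1e-9)
        # traceback structure attains the energy and satisfies constraints
        assert res.pairs in set(ens.structures)
        from confold.energy_model import eval_structure
        re_eval = eval_structure(seq, res.pairs, model) + declarative_soft_energy(
            seq, res.pairs, soft)
        assert re_eval == pytest.approx(res.energy_total, abs=1e-9)
        assert res.energy_total == pytest.approx(
            res.energy_standard + res.energy_soft, abs=1e-9)

    def test_deterministic_traceback(self, model):
        seq, dirs, soft = random_instance(n=14, seed=7)
        hard = compile_constraints(seq, dirs)
        a = mfe_fold(seq, model, hard, soft)
        b = mfe_fold(seq, model, hard, soft)
        assert a.structure == b.structure


class TestPartitionFunction:
    def test_unpairable_sequence(self, model):
        res = partition_function(Sequence("AAAA"), model)
        assert res.Z == pytest.approx(1.0)
        assert not res.bpp.any()
        assert res.unpaired_prob[1:].tolist() == pytest.approx([1.0] * 4)

    def test_unpairable_with_soft_terms_closed_form(self, model, thermo):
        seq = Sequence("AAAA")
        soft = SoftConstraintSet(4)
        deltas = [0.3, -0.7, 1.1, 0.2]
        for i, d in enumerate(deltas, start=1):
            soft.add_unpaired(i, d)
        res = partition_function(seq, model, None, soft)
        assert res.Z == pytest.approx(math.exp(-sum(deltas) / thermo.RT), rel=1e-12)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_enumeration(self, model, thermo, seed):
        seq, dirs, soft = random_instance(n=9 + seed % 6, seed=200 + seed,
                                          loop_type_soft=True)
        hard = compile_constraints(seq, dirs)
        ens = enumerate_structures(seq, hard)
        if not ens.count:
            return
        Z, bpp, unp, _ = ens.boltzmann(model, soft, thermo)
        res = partition_function(seq, model, hard, soft)
        assert res.Z == pytest.approx(Z, rel=1e-10)
        assert np.abs(res.bpp - bpp).max() < 1e-10
        assert np.abs(res.unpaired_prob[1:] - unp[1:]).max() < 1e-10

    def test_probability_completeness(self, model):
        """unpaired_prob[i] + sum_j p_ij (both orientations) = 1."""
        seq, dirs, soft = random_instance(n=14, seed=11)
        res = partition_function(seq, model, compile_constraints(seq, dirs), soft)
        for i in range(1, 15):
            total = res.unpaired_prob[i] + res.bpp[i, :].sum() + res.bpp[:, i].sum()
            assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_hard_constraint_shrinks_Z(self, model, seed):
        """Z decreases weakly when any hard constraint is added."""
        seq, dirs, soft = random_instance(n=12, seed=300 + seed,
                                          constraint_density=0)
        z_free = partition_function(seq, model, None, soft).Z
        hard = compile_constraints(seq, [force_unpaired(1 + seed % 12)])
        z_con = partition_function(seq, model, hard, soft).Z
        assert z_con <= z_free * (1 + 1e-12)

    def test_rescaling_consistent_with_unscaled(self, model):
        seq, dirs, soft = random_instance(n=14, seed=17)
        a = partition_function(seq, model, None, soft)
        b = partition_function(seq, model, None, soft,
                               FoldOptions(pf_scale=0.7))
        assert b.log_Z == pytest.approx(a.log_Z, rel=1e-10)
        assert np.abs(a.bpp - b.bpp).max() < 1e-10


class TestShiftInvariance:
    @pytest.mark.parametrize("kappa", [0.0, 1.7, -4.0])
    def test_bpp_invariant_under_energy_scale_shift(self, model, thermo, kappa):
        """The ensemble depends on (b^u, b^p) only through delta = b^u-b^p:
        shifting both by kappa is absorbed into the constant E'."""
        rng = np.random.default_rng(5)
        n = 12
        seq, _, _ = random_instance(n=n, seed=55, constraint_density=0)
        b_u = rng.uniform(-2, 2, size=n)
        b_p = rng.uniform(-2, 2, size=n)
        ref = partition_function(
            seq, model, None,
            SoftConstraintSet.from_paired_unpaired(n, b_u, b_p))
        shifted = partition_function(
            seq, model, None,
            SoftConstraintSet.from_paired_unpaired(n, b_u + kappa, b_p + kappa))
        assert np.abs(ref.bpp - shifted.bpp).max() < 1e-9

    def test_delta_reduction_matches_raw_bonus_oracle(self, model, thermo):
        """Engine bpp from the delta reduction equals bpp computed from the
        raw (b^u, b^p) energies E = E0 + sum_p b^p + sum_u b^u."""
        rng = np.random.default_rng(6)
        n = 11
        seq, _, _ = random_instance(n=n, seed=56, constraint_density=0)
        b_u = rng.uniform(-2, 2, size=n)
        b_p = rng.uniform(-2, 2, size=n)
        from confold.energy_model import eval_structure
        ens = enumerate_structures(seq)
        ws, bpp = [], np.zeros((n + 1, n + 1))
        for ps in ens.structures:
            paired = {x for p in ps for x in p}
            e = eval_structure(seq, ps, model)
            e += sum(b_p[i - 1] if i in paired else b_u[i - 1]
                     for i in range(1, n + 1))
            ws.append((ps, math.exp(-e / thermo.RT)))
        Z = sum(w for _, w in ws)
        for ps, w in ws:
            for i, j in ps:
                bpp[i, j] += w / Z
        res = partition_function(
            seq, model, None, SoftConstraintSet.from_paired_unpaired(n, b_u, b_p))
        assert np.abs(res.bpp - bpp).max() < 1e-9


class TestSoftVsHard:
    def test_large_penalty_approaches_hard_constraint(self, model):
        """delta -> +20 kcal/mol drives the unpaired probability toward the
        hard-constrained value without reaching it exactly."""
        seq, _, _ = random_instance(n=12, seed=66, constraint_density=0)
        i = 3
        soft = SoftConstraintSet(12)
        soft.add_unpaired(i, 20.0)
        p_soft = partition_function(seq, model, None, soft).unpaired_prob[i]
        hard = compile_constraints(seq, [])
        hard.clear_unpaired(i)
        try:
            p_hard = partition_function(seq, model, hard).unpaired_prob[i]
        except NoAdmissibleStructureError:
            return
        assert abs(p_soft - p_hard) < 1e-8
        assert p_soft > p_hard or p_soft > 0.0


class TestSpanConstraints:
    def test_hard_span_limit_zeroes_long_range_bpp(self, model):
        seq, _, soft = random_instance(n=16, seed=70, constraint_density=0)
        L = 8
        hard = compile_constraints(seq, [span_limit(L)])
        res = partition_function(seq, model, hard, soft)
        for i in range(1, 17):
            for j in range(i + 1, 17):
                if j - i + 1 > L:
                    assert res.bpp[i, j] == 0.0

    def test_zero_alpha1_reproduces_unconstrained_bit_for_bit(self, model):
        seq, dirs, _ = random_instance(n=14, seed=71)
        hard = compile_constraints(seq, dirs)
        plain = partition_function(seq, model, hard)
        soft = SoftConstraintSet(14)
        soft.add_callback(span_weight_callback(SpanWeightParams(0.0, 12.0)))
        weighted = partition_function(seq, model, hard, soft)
        assert weighted.Z == plain.Z
        assert np.array_equal(weighted.bpp, plain.bpp)

    def test_downweighting_shifts_probability_to_short_range(self, model):
        seq, _, _ = random_instance(n=16, seed=72, constraint_density=0)
        soft = SoftConstraintSet(16)
        soft.add_callback(span_weight_callback(SpanWeightParams(0.9, 3.0)))
        plain = partition_function(seq, model)
        weighted = partition_function(seq, model, None, soft)
        # probabilities change but remain a valid distribution
        for i in range(1, 17):
            total = weighted.unpaired_prob[i] + weighted.bpp[i, :].sum() \
                + weighted.bpp[:, i].sum()
            assert total == pytest.approx(1.0, abs=1e-9)


class TestEngineOptions:
    @pytest.mark.parametrize("seed", range(6))
    def test_degree_limit_matches_declarative_filter(self, model, seed):
        seq, dirs, soft = random_instance(n=14, seed=400 + seed)
        hard = compile_constraints(seq, dirs)
        opts = FoldOptions(multiloop_degree_limit=2)
        ens = enumerate_structures(seq, hard, degree_limit=2)
        assert count_structures(seq, hard, opts) == ens.count
        if ens.count:
            Z, bpp, _, _ = ens.boltzmann(model, soft)
            res = partition_function(seq, model, hard, soft, opts)
            assert res.Z == pytest.approx(Z, rel=1e-10)
            assert np.abs(res.bpp - bpp).max() < 1e-10

    @pytest.mark.parametrize("seed", range(6))
    def test_lonely_pair_heuristic_matches_declarative_filter(self, model, seed):
        seq, dirs, soft = random_instance(n=13, seed=500 + seed)
        hard = compile_constraints(seq, dirs)
        opts = FoldOptions(no_lonely_pairs=True)
        ens = enumerate_structures(seq, hard, no_lonely_pairs=True)
        assert count_structures(seq, hard, opts) == ens.count
        if ens.count:
            Z, _, _, _ = ens.boltzmann(model, soft)
            res = partition_function(seq, model, hard, soft, opts)
            assert res.Z == pytest.approx(Z, rel=1e-10)
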