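"""Initialization, mutation operators, Metropolis acceptance, and the loop."""

import math

import numpy as np
import pytest

from ribodesign import (
    NucleotideSequence,
    OptimizerConfig,
    accept,
    homodimer_check,
    initialize,
    is_wc_pair,
    make_not_gate,
    mutate,
    run,
)
from ribodesign.gates import GateSpec, SpeciesSpec, TruthTableEntry
from ribodesign.objective import ObjectiveTerm
from ribodesign.optimizer import (
    effective_mask,
    exhaustive_search,
    partner_map,
    run_violation,
)
from ribodesign.validation import toy_yes_gate


@pytest.fixture()
def not_gate():
    return make_not_gate()


def max_run(residues):
    best = cur = 1
    for a, b in zip(residues, residues[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


class TestInitialize:
    def test_stems_complementary_and_motifs_placed(self, not_gate):
        for seed in range(5):
            seqs = initialize(not_gate, np.random.default_rng(seed))
            srna = seqs["sRNA"]
            sp = not_gate.species_by_name()["sRNA"]
            for i, j in sp.target_pairs():
                assert is_wc_pair(srna.residues[i], srna.residues[j])
            mrna = seqs["mRNA"].residues
            for m in not_gate.species_by_name()["mRNA"].motifs:
                assert mrna[m.start : m.end] == m.sequence

    def test_no_forbidden_runs(self, not_gate):
        for seed in range(10):
            seqs = initialize(not_gate, np.random.default_rng(seed))
            for s in seqs.values():
                assert max_run(s.residues) < 4

    def test_seeded_reproducibility(self, not_gate):
        a = initialize(not_gate, np.random.default_rng(7))
        b = initialize(not_gate, np.random.default_rng(7))
        assert {k: v.residues for k, v in a.items()} == \
            {k: v.residues for k, v in b.items()}


class TestMutate:
    def test_invariants_over_many_proposals(self, not_gate):
        """Lengths constant, fixed positions intact, no runs, stems paired."""
        rng = np.random.default_rng(1)
        cfg = OptimizerConfig()
        state = initialize(not_gate, rng, cfg)
        by_name = not_gate.species_by_name()
        masks = {n: effective_mask(sp) for n, sp in by_name.items()}
        for k in range(2000):
            word_len = (3, 2, 1)[k % 3]
            new_state, _ = mutate(state, not_gate, rng, word_len, cfg)
            for name, seq in new_state.items():
                old = state[name]
                assert len(seq) == len(old)
                for p, designable in enumerate(masks[name]):
                    if not designable:
                        assert seq.residues[p] == old.residues[p]
                for m in by_name[name].motifs:
                    assert seq.residues[m.start : m.end] == m.sequence
                assert max_run(seq.residues) < 4
                for i, j in by_name[name].target_pairs():
                    assert is_wc_pair(seq.residues[i], seq.residues[j])
            state = new_state

    def test_word_move_inserts_reverse_complement(self, not_gate):
        from ribodesign import reverse_complement

        rng = np.random.default_rng(3)
        cfg = OptimizerConfig(p_word=1.0)
        state = initialize(not_gate, rng, cfg)
        seen_word_move = False
        for _ in range(200):
            new_state, desc = mutate(state, not_gate, rng, 3, cfg)
            if desc.startswith("word3:"):
                src, rest = desc[6:].split("->")
                src_name, src_pos = src[:-1].split("[")
                tgt_name, tgt_pos = rest[:-1].split("[")
                s0, w0 = int(src_pos) - 1, int(tgt_pos) - 1
                word = state[src_name].residues[s0 : s0 + 3]
                inserted = new_state[tgt_name].residues[w0 : w0 + 3]
                # stem co-mutation may overwrite window positions afterwards;
                # require agreement wherever the window is loop-only
                pm = partner_map(not_gate.species_by_name()[tgt_name])
                expected = reverse_complement(word)
                for t in range(3):
                    if (w0 + t) not in pm:
                        assert inserted[t] == expected[t]
                seen_word_move = True
            state = new_state
        assert seen_word_move

    def test_point_move_changes_single_designable_position(self, not_gate):
        rng = np.random.default_rng(5)
        cfg = OptimizerConfig(p_word=0.0)
        state = initialize(not_gate, rng, cfg)
        new_state, desc = mutate(state, not_gate, rng, 1, cfg)
        assert desc.startswith("point:")
        changed = {
            name for name in state
            if state[name].residues != new_state[name].residues
        }
        assert len(changed) == 1


class TestAccept:
    def test_downhill_and_neutral_always_accepted(self, rng):
        assert accept(-1.0, 1.0, rng)
        assert accept(0.0, 1.0, rng)

    def test_infinite_and_nan_rejected(self, rng):
        assert not accept(math.inf, 1.0, rng)
        assert not accept(math.nan, 1.0, rng)

    def test_uphill_frequency_near_half_at_t_ln2(self):
        rng = np.random.default_rng(11)
        t = 2.0
        n = 20_000
        acc = sum(accept(t * math.log(2), t, rng) for _ in range(n))
        # binomial 4-sigma band around p = 0.5
        sigma = math.sqrt(0.25 / n)
        assert abs(acc / n - 0.5) < 4 * sigma


class TestHomodimerCheck:
    def test_non_self_complementary_kept(self, model):
        assert not homodimer_check(NucleotideSequence("s", "GGGGGG"), model)

    def test_palindrome_rejected(self, model):
        # GGGCCC self-duplex: -18 complex vs two -3 monomer folds -> dG = -12
        assert homodimer_check(NucleotideSequence("s", "GGGCCC"), model)

    def test_threshold_configurable(self, model):
        cfg = OptimizerConfig(homodimer_dg_threshold=-20.0)
        assert not homodimer_check(NucleotideSequence("s", "GGGCCC"), model,
                                   cfg)


class TestRunViolation:
    def test_runs_in_fixed_motifs_tolerated(self):
        mask = (False,) * 6 + (True,) * 2
        assert not run_violation("UUUUUUAC", mask, 4)

    def test_runs_touching_designable_rejected(self):
        mask = (False,) * 5 + (True,) * 3
        assert run_violation("UUUUUUAC", mask, 4)


class TestRun:
    def test_toy_inverse_fold_reaches_target(self, model):
        """Single-species inverse folding: final structure distance is 0."""
        # a lone structural species (no trans inputs, so one truth-table row)
        sp = SpeciesSpec(
            name="h", role="mRNA_5UTR", length=11,
            target_structure="((((...))))",
        )
        gate = GateSpec(
            "YES", [sp],
            [TruthTableEntry(frozenset(), "RBS_accessible")],
            [],
            [ObjectiveTerm("str", ("h",), target="((((...))))",
                           label="fold to target")],
        )
        res = run(gate, OptimizerConfig(iterations=300, rng_seed=0), model)
        assert res.objective == 0.0

    def test_deterministic_given_seed(self, model):
        gate = toy_yes_gate()
        cfg = OptimizerConfig(iterations=300, rng_seed=9)
        r1 = run(gate, cfg, model)
        r2 = run(gate, cfg, model)
        assert r1.objective == r2.objective
        assert {k: v.residues for k, v in r1.sequences.items()} == \
            {k: v.residues for k, v in r2.sequences.items()}
        assert [t.delta_f for t in r1.trajectory] == \
            [t.delta_f for t in r2.trajectory]

    def test_best_seen_is_trajectory_minimum(self, model):
        gate = toy_yes_gate()
        res = run(gate, OptimizerConfig(iterations=500, rng_seed=2), model)
        assert res.objective == pytest.approx(
            min(t.objective for t in res.trajectory)
        )

    def test_emitted_candidate_respects_constraints(self, model):
        gate = toy_yes_gate()
        res = run(gate, OptimizerConfig(iterations=400, rng_seed=4), model)
        for sp in gate.species:
            seq = res.sequences[sp.name].residues
            fixed = sp.fixed_sequence
            for p, designable in enumerate(effective_mask(sp)):
                if not designable:
                    assert seq[p] == fixed[p]


class TestExhaustiveSearch:
    def test_sa_matches_bruteforce_on_toy_gate(self, model):
        gate = toy_yes_gate()
        _, best_total = exhaustive_search(gate, model)
        hits = 0
        for seed in range(5):
            res = run(gate, OptimizerConfig(iterations=3000, rng_seed=seed,
                                            record_trajectory=False), model)
            hits += abs(res.objective - best_total) < 1e-9
        assert hits >= 4

    def test_free_position_count_guard(self, model):
        gate = make_not_gate()  # far more than 10 free positions
        with pytest.raises(Exception):
            exhaustive_search(gate, model, max_free=10)
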