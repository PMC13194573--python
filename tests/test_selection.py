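"""Marker screening, greedy/exhaustive minimal-set search, MLG grouping."""

import numpy as np
import pytest

from kaspfp import (
    ScreeningCriteria,
    SimulationConfig,
    exhaustive_min_set,
    greedy_min_set,
    matrix_summary,
    mlg_groups,
    pair_distinguished,
    screen_markers,
    simulate_genotypes,
)
from kaspfp.selection import InstanceTooLargeError
from .conftest import make_matrix


class TestScreening:
    def test_boundary_thresholds_inclusive(self):
        # a locus at exactly the maximum missing rate is retained
        matrix = make_matrix({"a": ["AA"], "b": ["AG"], "c": ["GG"], "d": ["AG"]})
        stats = matrix_summary(matrix)
        stats[0].missing_rate = 0.006
        kept = screen_markers(stats, None, ScreeningCriteria(max_missing_rate=0.006))
        assert kept == [stats[0].locus]

    def test_stability_flag_overrides_pic(self):
        matrix = make_matrix({"a": ["AG", "AA"], "b": ["AG", "AA"], "c": ["AA", "AG"]})
        stats = matrix_summary(matrix)
        qc = {stats[0].locus: False, stats[1].locus: True}
        kept = screen_markers(stats, qc, ScreeningCriteria())
        assert kept == [stats[1].locus]

    def test_unknown_qc_locus_rejected(self):
        matrix = make_matrix({"a": ["AG"], "b": ["AA"]})
        with pytest.raises(ValueError):
            screen_markers(matrix_summary(matrix), {"nope": True}, ScreeningCriteria())

    def test_matches_brute_force_predicates(self):
        config = SimulationConfig(n_accessions=40, n_loci=30, missing_rate=0.05,
                                  allele_freq_spectrum=(0.0, 0.5), seed=31)
        matrix, _ = simulate_genotypes(config)
        stats = matrix_summary(matrix)
        rng = np.random.default_rng(1)
        qc = {s.locus: bool(rng.random() > 0.2) for s in stats}
        criteria = ScreeningCriteria(max_missing_rate=0.05, min_maf=0.05, min_pic=0.1)
        kept = screen_markers(stats, qc, criteria)
        expected = [
            s.locus for s in stats
            if qc[s.locus] and s.missing_rate <= 0.05 and s.maf >= 0.05 and s.pic >= 0.1
        ]
        assert sorted(kept) == sorted(expected)
        # ordering: descending PIC, ties by locus ID
        pics = {s.locus: s.pic for s in stats}
        assert kept == sorted(kept, key=lambda l: (-pics[l], l))


class TestPairDistinguished:
    def test_differing_homozygote_vs_het(self):
        assert pair_distinguished(["AA"], ["AG"])

    def test_missing_call_never_discriminates(self):
        assert not pair_distinguished(["AA", "AA"], ["NN", "AA"])

    def test_heterozygote_orientation_ignored(self):
        assert not pair_distinguished(["AG", "TC"], ["GA", "CT"])


class TestGreedy:
    def test_single_fully_discriminating_locus(self):
        matrix = make_matrix({"a": ["AA", "AA"], "b": ["AG", "AA"], "c": ["GG", "AA"]})
        core = greedy_min_set(matrix, matrix.loci)
        assert core.loci == [matrix.loci[0]]
        assert core.unresolved_groups == []
        assert core.n_distinguished_accessions == 3

    def test_clone_pair_always_unresolved(self):
        config = SimulationConfig(n_accessions=20, n_loci=10, n_clone_pairs=1,
                                  missing_rate=0.0, seed=17)
        matrix, truth = simulate_genotypes(config)
        rng = np.random.default_rng(5)
        pair = sorted(truth.clone_pairs[0])
        for _ in range(5):
            k = rng.integers(2, 11)
            subset = [matrix.loci[i] for i in rng.choice(10, size=k, replace=False)]
            core = greedy_min_set(matrix, subset)
            assert any(set(pair) <= set(g) for g in core.unresolved_groups)

    def test_trace_gains_positive_and_distinguished_monotone(self, panel_77):
        matrix, _ = panel_77
        core = greedy_min_set(matrix, matrix.loci)
        assert all(step.new_pairs > 0 for step in core.trace)
        counts = [step.distinguished for step in core.trace]
        assert counts == sorted(counts)

    def test_minimality_after_pruning(self):
        # removing any single selected locus strictly decreases coverage
        for seed in range(6):
            config = SimulationConfig(n_accessions=10, n_loci=9, missing_rate=0.05,
                                      allele_freq_spectrum=(0.1, 0.5), seed=seed,
                                      ensure_unique=False)
            matrix, _ = simulate_genotypes(config)
            core = greedy_min_set(matrix, matrix.loci)
            full = core.distinguished_pairs
            for drop in core.loci:
                rest = [l for l in core.loci if l != drop]
                if not rest:
                    continue
                reduced = _coverage(matrix, rest)
                assert reduced < full

    def test_deterministic_with_tie_breaks(self, panel_77):
        matrix, _ = panel_77
        pic = {s.locus: s.pic for s in matrix_summary(matrix)}
        a = greedy_min_set(matrix, matrix.loci, pic)
        b = greedy_min_set(matrix, matrix.loci, pic)
        assert a.loci == b.loci and a.to_dict() == b.to_dict()

    def test_empty_candidates_rejected(self, panel_77):
        matrix, _ = panel_77
        with pytest.raises(ValueError):
            greedy_min_set(matrix, [])


def _coverage(matrix, loci) -> int:
    from itertools import combinations

    sub = matrix.subset_loci(list(loci))
    return sum(
        1
        for i, j in combinations(range(sub.n_accessions), 2)
        if pair_distinguished(sub.calls[i], sub.calls[j])
    )


class TestExhaustive:
    def test_complementary_loci_need_both(self):
        # locus 1 splits {a,b} from {c,d}; locus 2 splits within the halves
        matrix = make_matrix({
            "a": ["AA", "AA"],
            "b": ["AA", "GG"],
            "c": ["GG", "AA"],
            "d": ["GG", "GG"],
        })
        core = exhaustive_min_set(matrix, matrix.loci)
        assert sorted(core.loci) == sorted(matrix.loci)
        assert core.unresolved_groups == []

    def test_single_sufficient_locus_found_among_five(self):
        rows = {
            "a": ["AA", "AA", "AA", "AA", "AA"],
            "b": ["AG", "AA", "AA", "AA", "AA"],
            "c": ["GG", "AA", "AA", "AA", "AA"],
        }
        matrix = make_matrix(rows)
        core = exhaustive_min_set(matrix, matrix.loci)
        assert core.loci == [matrix.loci[0]]

    def test_greedy_within_one_of_optimal(self):
        agree = 0
        for seed in range(1, 13):
            n_acc = 8 + seed % 3
            n_loci = 8 + seed % 2
            config = SimulationConfig(n_accessions=n_acc, n_loci=n_loci,
                                      allele_freq_spectrum=(0.15, 0.5),
                                      missing_rate=0.02, seed=seed,
                                      ensure_unique=False)
            matrix, _ = simulate_genotypes(config)
            pic = {s.locus: s.pic for s in matrix_summary(matrix)}
            greedy = greedy_min_set(matrix, matrix.loci, pic)
            exact = exhaustive_min_set(matrix, matrix.loci, pic)
            assert greedy.distinguished_pairs == exact.distinguished_pairs
            assert len(greedy.loci) <= len(exact.loci) + 1
            agree += len(greedy.loci) == len(exact.loci)
        assert agree >= 9

    def test_large_instance_signalled(self, panel_77):
        matrix, _ = panel_77
        with pytest.raises(InstanceTooLargeError):
            exhaustive_min_set(matrix, matrix.loci, max_combinations=10)


class TestMlgGroups:
    def test_unique_rows_all_singletons(self):
        matrix = make_matrix({
            "a": ["AA", "AA"], "b": ["AG", "AA"], "c": ["GG", "GG"],
        })
        groups = mlg_groups(matrix, matrix.loci)
        assert all(len(g) == 1 for g in groups)

    def test_two_clone_pairs_two_classes(self):
        config = SimulationConfig(n_accessions=12, n_loci=8, n_clone_pairs=2,
                                  missing_rate=0.0, seed=29)
        matrix, truth = simulate_genotypes(config)
        groups = mlg_groups(matrix, matrix.loci)
        non_singletons = sorted(sorted(g) for g in groups if len(g) > 1)
        assert non_singletons == sorted(sorted(p) for p in truth.clone_pairs)

    def test_panel_matches_simulated_truth(self, panel_77):
        matrix, truth = panel_77
        groups = mlg_groups(matrix, matrix.loci)
        assert sum(1 for g in groups if len(g) == 1) == 73
        assert sorted(sorted(g) for g in groups if len(g) > 1) == sorted(
            sorted(p) for p in truth.clone_pairs
        )

    def test_transitive_closure_bridges_missing(self):
        # y matches both x and z through missing data although x and z differ
        matrix = make_matrix({
            "x": ["AA", "AA"],
            "y": ["NN", "AA"],
            "z": ["GG", "AA"],
        })
        groups = mlg_groups(matrix, matrix.loci)
        assert groups == [["x", "y", "z"]]

    def test_empty_locus_subset_rejected(self, panel_77):
        matrix, _ = panel_77
        with pytest.raises(ValueError):
            mlg_groups(matrix, [])


class TestMissingSemantics:
    def test_adding_missing_never_increases_coverage(self):
        rng = np.random.default_rng(99)
        for seed in range(5):
            config = SimulationConfig(n_accessions=10, n_loci=8, missing_rate=0.0,
                                      seed=seed, ensure_unique=False)
            matrix, _ = simulate_genotypes(config)
            before = _coverage(matrix, matrix.loci)
            degraded = matrix.calls.copy()
            holes = rng.random(degraded.shape) < 0.2
            degraded[holes] = "NN"
            from kaspfp import GenotypeMatrix

            noisy = GenotypeMatrix(matrix.accessions, matrix.loci, degraded)
            assert _coverage(noisy, noisy.loci) <= before
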