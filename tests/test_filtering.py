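"""The four-stage candidate filter cascade and its report."""

import numpy as np
import pytest

from kaspfp import (
    CandidateSNP,
    assess_kasp_feasibility,
    filter_flanking_conservation,
    filter_genotype_quality,
    filter_unique_mapping,
    run_filter_cascade,
    simulate_candidate_table,
)
from kaspfp.filtering import FilterReport, read_candidate_table, write_candidate_table


def candidate(pos=1000, chrom="chr1", flank="ACGT" * 15, **kwargs) -> CandidateSNP:
    return CandidateSNP(
        id=f"{chrom}_{pos}", chrom=chrom, pos=pos,
        ref_allele="A", alt_allele="G", flank5=flank, flank3=flank, **kwargs
    )


def with_calls(genotypes, depths=None, gqs=None, **kwargs) -> CandidateSNP:
    n = len(genotypes)
    return candidate(
        genotypes=np.array(genotypes, dtype="<U2"),
        depths=np.array(depths if depths is not None else [20] * n),
        gqs=np.array(gqs if gqs is not None else [40] * n),
        **kwargs,
    )


class TestFlankingConservation:
    @pytest.mark.parametrize("other, kept", [(1051, True), (1050, False), (950, False), (949, True)])
    def test_inclusive_50bp_window(self, other, kept):
        cand = candidate(pos=1000)
        positions = {"chr1": np.array(sorted([1000, other]))}
        retained = filter_flanking_conservation([cand], positions, window=50)
        assert (len(retained) == 1) is kept

    def test_own_position_not_counted(self):
        cand = candidate(pos=1000)
        assert filter_flanking_conservation([cand], {"chr1": np.array([1000])}) == [cand]

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            filter_flanking_conservation([candidate()], {"chr1": np.array([5, 2])})

    def test_planted_truth_recovered(self):
        cands, _, truth = simulate_candidate_table(100, secondary_poly_rate=0.4, seed=11)
        retained = filter_flanking_conservation(cands, truth.variant_positions)
        assert {c.id for c in retained} == {
            cid for cid, bad in truth.has_secondary.items() if not bad
        }


class TestGenotypeQuality:
    def test_direct_maf_count(self):
        cand = with_calls(["AA"] * 5 + ["AG"] * 5)
        retained = filter_genotype_quality([cand], min_maf=0.1)
        assert retained == [cand]
        assert cand.annotations["quality"]["maf"] == pytest.approx(0.25)

    def test_all_low_depth_becomes_fully_missing(self):
        cand = with_calls(["AA", "AG", "GG"], depths=[2, 3, 1])
        assert filter_genotype_quality([cand], min_depth=8) == []
        assert cand.annotations["quality"]["missing_rate"] == 1.0

    def test_low_gq_calls_masked_before_missing_rate(self):
        cand = with_calls(["AA"] * 8 + ["AG"] * 2, gqs=[40] * 8 + [5, 5])
        assert filter_genotype_quality([cand], max_missing=0.1) == []
        assert cand.annotations["quality"]["missing_rate"] == pytest.approx(0.2)

    def test_monomorphic_fails_biallelic(self):
        cand = with_calls(["AA"] * 10)
        assert filter_genotype_quality([cand], min_maf=0.0) == []
        assert "not_biallelic" in cand.annotations["quality"]["reasons"]

    def test_brute_force_oracle_on_simulated_loci(self):
        # noisy depth/GQ/MAF so every predicate fires somewhere
        cands, _, _ = simulate_candidate_table(
            500, seed=21, maf_range=(0.01, 0.5), depth_range=(6, 40), gq_range=(18, 60)
        )
        params = dict(min_depth=8, min_gq=20, max_missing=0.1, min_maf=0.05)
        retained = {c.id for c in filter_genotype_quality(cands, **params)}

        expected = set()
        for c in cands:
            calls = [
                "NN" if d < 8 or g < 20 else call
                for call, d, g in zip(c.genotypes, c.depths, c.gqs)
            ]
            present = [x for x in calls if x != "NN"]
            if len(present) < 0.9 * len(calls):
                continue
            counts: dict[str, int] = {}
            for x in present:
                for allele in x:
                    counts[allele] = counts.get(allele, 0) + 1
            total = sum(counts.values())
            freqs = [v / total for v in counts.values()]
            if len(freqs) == 2 and min(freqs) >= 0.05:
                expected.add(c.id)
        assert retained == expected
        assert 0 < len(expected) < 500  # both outcomes must actually occur


class TestUniqueMapping:
    def test_planted_duplicates_removed(self):
        cands, fasta, truth = simulate_candidate_table(100, duplicate_region_rate=0.2, seed=5)
        retained = filter_unique_mapping(cands, fasta)
        assert {c.id for c in retained} == {
            cid for cid, bad in truth.has_duplicate.items() if not bad
        }

    def test_reverse_complement_counts_as_hit(self):
        cands, fasta, _ = simulate_candidate_table(1, seed=8)
        from Bio.Seq import Seq
        from kaspfp.filtering import build_probe

        seq = "".join(fasta.splitlines()[1:])
        rc_copy = str(Seq(build_probe(cands[0])).reverse_complement())
        doubled = f">chr1\n{seq}{'T' * 80}{rc_copy}\n"
        assert filter_unique_mapping(cands, doubled) == []

    def test_probe_longer_than_flanks_rejected(self):
        cand = candidate(flank="ACGT" * 10)  # 40 bp per side
        with pytest.raises(ValueError):
            filter_unique_mapping([cand], ">chr1\nACGT\n", probe_len=100)


class TestKaspFeasibility:
    def test_alternating_sequence_feasible(self):
        cand = candidate(flank="AC" * 30)
        feasible, reasons = assess_kasp_feasibility(cand, (0.3, 0.7), 4)
        assert feasible and reasons == []

    def test_homopolymer_flagged(self):
        cand = candidate(flank="AC" * 22 + "AAAAAA" + "ACGTACGTAC")
        feasible, reasons = assess_kasp_feasibility(cand, max_homopolymer=4)
        assert not feasible and "homopolymer" in reasons

    def test_high_gc_flagged(self):
        cand = candidate(flank="GCGCGCGCAC" * 6)  # GC fraction 0.8
        feasible, reasons = assess_kasp_feasibility(cand, gc_range=(0.3, 0.7))
        assert not feasible and "gc_out_of_range" in reasons

    def test_ambiguous_base_flagged(self):
        cand = candidate(flank="AC" * 29 + "NA")
        feasible, reasons = assess_kasp_feasibility(cand)
        assert not feasible and "ambiguous_base" in reasons


class TestCascade:
    def test_defect_free_table_fully_retained(self):
        cands, fasta, truth = simulate_candidate_table(50, seed=1)
        retained, report = run_filter_cascade(
            cands, fasta, all_variant_positions=truth.variant_positions
        )
        assert len(retained) == 50
        assert all(s.n_retained == s.n_in for s in report.stages)

    def test_stage_order_and_monotone_counts(self):
        cands, fasta, truth = simulate_candidate_table(
            200, secondary_poly_rate=0.3, duplicate_region_rate=0.15, seed=13
        )
        _, report = run_filter_cascade(cands, fasta, all_variant_positions=truth.variant_positions)
        assert [s.name for s in report.stages] == [
            "flanking_conservation",
            "genotype_quality",
            "unique_mapping",
            "kasp_design_feasibility",
        ]
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert nxt.n_in == prev.n_retained
            assert nxt.n_retained <= nxt.n_in

    def test_mixed_defects_equal_truth_intersection(self):
        cands, fasta, truth = simulate_candidate_table(
            500, secondary_poly_rate=0.2, duplicate_region_rate=0.1, seed=13
        )
        retained, _ = run_filter_cascade(cands, fasta, all_variant_positions=truth.variant_positions)
        assert {c.id for c in retained} == truth.defect_free()

    def test_filters_idempotent(self):
        cands, fasta, truth = simulate_candidate_table(
            80, secondary_poly_rate=0.3, duplicate_region_rate=0.2, seed=17
        )
        once = filter_flanking_conservation(cands, truth.variant_positions)
        assert filter_flanking_conservation(once, truth.variant_positions) == once
        once = filter_genotype_quality(cands)
        assert filter_genotype_quality(once) == once
        once = filter_unique_mapping(cands, fasta)
        assert filter_unique_mapping(once, fasta) == once

    def test_report_chain_invariant_enforced(self):
        report = FilterReport()
        report.add("a", 100, 60, {})
        with pytest.raises(ValueError):
            report.add("b", 99, 50, {})  # input must equal previous retained
        with pytest.raises(ValueError):
            report.add("b", 60, 70, {})  # retained cannot exceed input


def test_candidate_table_round_trip(tmp_path):
    cands, _, _ = simulate_candidate_table(10, seed=6)
    path = tmp_path / "candidates.tsv"
    write_candidate_table(cands, path)
    back = read_candidate_table(path)
    assert [c.id for c in back] == [c.id for c in cands]
    assert all(a.flank5 == b.flank5 and a.flank3 == b.flank3 for a, b in zip(cands, back))


def test_candidate_id_must_match_coordinates():
    with pytest.raises(ValueError):
        CandidateSNP(id="chr1_5", chrom="chr1", pos=6, ref_allele="A", alt_allele="G")
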