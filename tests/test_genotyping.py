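"""Genotyping: candidate consolidation, likelihoods, posteriors, filters."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from clustersv.clustering import SignatureCluster
from clustersv.genotyping import (
    AlleleCall,
    AlignmentIndex,
    GenotypingParams,
    call_likelihoods,
    cluster_to_candidate,
    collect_allele_calls,
    genotype_candidate,
    genotype_posteriors,
    reclassify_duplications,
)
from clustersv.signatures import CompactAlignment
from conftest import make_sig


def make_cluster(sigs, sv_type="DEL"):
    return SignatureCluster(
        sv_type=sv_type, chrom="chr1", members=sigs, core_flags=[True] * len(sigs)
    )


def del_candidate(length=100, n=3, first=1000):
    sigs = [
        make_sig(first + i, first + i + length, length, read_id=f"r{i}", uid=i)
        for i in range(n)
    ]
    return cluster_to_candidate(make_cluster(sigs))


class TestClusterToCandidate:
    def test_mean_coordinates(self):
        sigs = [
            make_sig(100, 200, 100, read_id="a", uid=0),
            make_sig(102, 202, 100, read_id="b", uid=1),
            make_sig(104, 204, 100, read_id="c", uid=2),
        ]
        cand = cluster_to_candidate(make_cluster(sigs))
        assert (cand.first, cand.last, cand.length) == (102, 202, 100)

    def test_single_member_equals_signature(self):
        sig = make_sig(5000, 5120, 120, read_id="a", uid=0)
        cand = cluster_to_candidate(make_cluster([sig]))
        assert (cand.first, cand.last, cand.length) == (5000, 5120, 120)

    def test_insertion_length_is_mean_of_member_lengths(self):
        sigs = [
            make_sig(1000, 1000, l, sv_type="INS", read_id=f"r{l}", uid=i)
            for i, l in enumerate([80, 90, 85])
        ]
        cand = cluster_to_candidate(make_cluster(sigs, "INS"))
        assert cand.length == 85
        assert cand.last == cand.first

    def test_rounding_ties_toward_lower_coordinate(self):
        sigs = [
            make_sig(100, 200, 100, read_id="a", uid=0),
            make_sig(101, 201, 100, read_id="b", uid=1),
        ]
        cand = cluster_to_candidate(make_cluster(sigs))
        assert cand.first == 100  # mean 100.5 rounds down


class TestCollectAlleleCalls:
    def _setup(self, n_sv=4, n_ref=6):
        sigs = [make_sig(1000, 1100, 100, read_id=f"sv{i}", uid=i) for i in range(n_sv)]
        cand = cluster_to_candidate(make_cluster(sigs))
        alns = [
            CompactAlignment(f"sv{i}", "chr1", 500, 2000, signature_refs=[i])
            for i in range(n_sv)
        ] + [
            CompactAlignment(f"ref{i}", "chr1", 500, 2000, signature_refs=[])
            for i in range(n_ref)
        ]
        return cand, AlignmentIndex(alns)

    def test_no_spanning_alignments(self):
        cand, _ = self._setup()
        assert collect_allele_calls(cand, AlignmentIndex([])) == []

    def test_sv_and_ref_partition(self):
        cand, index = self._setup(4, 6)
        calls = collect_allele_calls(cand, index)
        assert sum(c.supports == "SV" for c in calls) == 4
        assert sum(c.supports == "REF" for c in calls) == 6
        assert all(c.observed_length == 100 for c in calls if c.supports == "SV")

    def test_foreign_cluster_signature_counts_as_ref(self):
        cand, _ = self._setup(2, 0)
        alns = [
            CompactAlignment("sv0", "chr1", 500, 2000, signature_refs=[0]),
            CompactAlignment("other", "chr1", 500, 2000, signature_refs=[999]),
        ]
        calls = collect_allele_calls(cand, AlignmentIndex(alns))
        by_read = {c.read_id: c.supports for c in calls}
        assert by_read == {"sv0": "SV", "other": "REF"}

    def test_non_spanning_alignment_excluded(self):
        cand, _ = self._setup(1, 0)
        alns = [CompactAlignment("half", "chr1", 1050, 2000, signature_refs=[])]
        assert collect_allele_calls(cand, AlignmentIndex(alns)) == []


class TestCallLikelihoods:
    def test_ref_call_constants(self):
        cand = del_candidate()
        lsv, lref = call_likelihoods(AlleleCall("r", "REF"), cand, GenotypingParams())
        assert lsv == pytest.approx(math.log10(0.001))
        assert lref == pytest.approx(math.log10(0.999))

    def test_sv_call_under_ref_allele_constant(self):
        cand = del_candidate()
        _, lref = call_likelihoods(
            AlleleCall("r", "SV", observed_length=100), cand, GenotypingParams()
        )
        assert lref == pytest.approx(math.log10(0.0001))

    def test_sv_call_length_model(self):
        """Observed 90 bp against an 85 bp cluster: Normal density, floored sd."""
        sigs = [make_sig(1000, 1000, 85, sv_type="INS", read_id=f"r{i}", uid=i) for i in range(5)]
        cand = cluster_to_candidate(make_cluster(sigs, "INS"))
        params = GenotypingParams(hts_factor=1.0)
        lsv, _ = call_likelihoods(AlleleCall("r", "SV", observed_length=90), cand, params)
        assert lsv == pytest.approx(math.log10(norm.pdf(90, loc=85, scale=5.0)))

    def test_density_floor_prevents_minus_infinity(self):
        cand = del_candidate(length=100)
        params = GenotypingParams()
        lsv, _ = call_likelihoods(AlleleCall("r", "SV", observed_length=10_000), cand, params)
        assert lsv == pytest.approx(math.log10(params.density_floor))

    def test_hts_factor_scales_density(self):
        cand = del_candidate(length=100)
        lsv_hifi, _ = call_likelihoods(
            AlleleCall("r", "SV", observed_length=100), cand, GenotypingParams(hts_factor=1.0)
        )
        lsv_ont, _ = call_likelihoods(
            AlleleCall("r", "SV", observed_length=100), cand, GenotypingParams(hts_factor=0.5)
        )
        assert lsv_ont == pytest.approx(lsv_hifi + math.log10(0.5))


def calls_mix(n_sv, n_ref, length=100):
    return [AlleleCall(f"s{i}", "SV", observed_length=length) for i in range(n_sv)] + [
        AlleleCall(f"n{i}", "REF") for i in range(n_ref)
    ]


class TestGenotypeCandidate:
    def test_all_sv_calls_homozygous(self):
        cand = del_candidate()
        sv = genotype_candidate(cand, calls_mix(10, 0), GenotypingParams())
        assert sv.genotype == "1/1"
        assert sv.n_sv_reads == 10 and sv.n_ref_reads == 0

    def test_balanced_mixture_heterozygous(self):
        cand = del_candidate()
        sv = genotype_candidate(cand, calls_mix(5, 5), GenotypingParams())
        assert sv.genotype == "0/1"

    def test_all_ref_filtered_out(self):
        cand = del_candidate()
        assert genotype_candidate(cand, calls_mix(0, 10), GenotypingParams()) is None

    def test_empty_calls_filtered_out(self):
        assert genotype_candidate(del_candidate(), [], GenotypingParams()) is None

    def test_quality_capped(self):
        cand = del_candidate()
        sv = genotype_candidate(cand, calls_mix(60, 0), GenotypingParams())
        assert 0 <= sv.quality <= 255

    @given(n_sv=st.integers(0, 20), n_ref=st.integers(0, 20), hts=st.floats(0.1, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_posterior_sums_to_one(self, n_sv, n_ref, hts):
        cand = del_candidate()
        post = genotype_posteriors(cand, calls_mix(n_sv, n_ref), GenotypingParams(hts_factor=hts))
        assert post.sum() == pytest.approx(1.0, abs=1e-9)
        assert (post >= 0).all()

    def test_monotonicity_in_sv_evidence(self):
        """More SV calls at fixed depth never move the genotype toward 0/0."""
        cand = del_candidate()
        params = GenotypingParams()
        rank = {"0/0": 0, "0/1": 1, "1/1": 2}
        for total in (4, 10, 20):
            prev = 0
            for n_sv in range(total + 1):
                post = genotype_posteriors(cand, calls_mix(n_sv, total - n_sv), params)
                best = ["0/0", "0/1", "1/1"][int(post.argmax())]
                assert rank[best] >= prev
                prev = rank[best]

    def test_limit_all_sv_evidence_posterior_to_one(self):
        """As P(SV call | REF allele) -> 0 with all-SV evidence, P(1/1) -> 1.

        In the diploid mixture the heterozygous likelihood retains a factor
        0.5 per call, so the exact limit with n calls is 2^n / (2^n + 1),
        which approaches 1 as evidence accumulates.
        """
        cand = del_candidate()
        prev = 0.0
        for p in (1e-4, 1e-8, 1e-12):
            params = GenotypingParams(p_sv_call_given_ref=p)
            post = genotype_posteriors(cand, calls_mix(10, 0), params)
            assert post[2] >= prev
            prev = post[2]
        assert prev == pytest.approx(2**10 / (2**10 + 1), abs=1e-6)
        post = genotype_posteriors(
            cand, calls_mix(30, 0), GenotypingParams(p_sv_call_given_ref=1e-12)
        )
        assert post[2] == pytest.approx(1.0, abs=1e-6)


def genotyped_ins(intra_firsts, length=100):
    from clustersv.genotyping import GenotypedSV

    return GenotypedSV(
        chrom="chr1", first=1000, last=1000, length=length, sv_type="INS",
        final_type="INS", genotype="0/1", quality=50.0, n_sv_reads=5, n_ref_reads=5,
        intra_firsts=list(intra_firsts),
    )


class TestDuplicationReclassification:
    def test_tight_insertion_stays_insertion(self):
        sv = genotyped_ins([1000, 1004, 1008])
        assert reclassify_duplications([sv])[0].final_type == "INS"

    def test_spread_insertion_becomes_duplication(self):
        sv = genotyped_ins([800, 1000, 1200], length=100)
        assert reclassify_duplications([sv])[0].final_type == "DUP"

    def test_deletions_unchanged(self):
        from clustersv.genotyping import GenotypedSV

        sv = GenotypedSV(
            chrom="chr1", first=1000, last=1400, length=400, sv_type="DEL",
            final_type="DEL", genotype="0/1", quality=50.0, n_sv_reads=5, n_ref_reads=5,
            intra_firsts=[500, 1500],
        )
        assert reclassify_duplications([sv])[0].final_type == "DEL"

    def test_threshold_uses_call_length_when_larger(self):
        # spread 400 exceeds epsilon 250 but not the 500 bp call length
        sv = genotyped_ins([800, 1200], length=500)
        assert reclassify_duplications([sv], epsilon=250)[0].final_type == "INS"
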