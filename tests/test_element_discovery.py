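"""Kmer dictionary, hypergeometric enrichment, BH-FDR, motif clustering and
TOD profiles, each checked against an independent brute-force oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from todcourse.element_discovery import (
    DICTIONARY_SIZE,
    KMAX,
    KMIN,
    ElementResult,
    _best_alignment,
    _linked,
    build_dictionary,
    cluster_kmers,
    enrich_kmers,
    promoter_kmer_set,
    run_element,
    schedule_phase_lists,
    tod_profile,
)
from todcourse.stats import bh_qvalues, hypergeom_pvalue
from todcourse.timecourse_io import PromoterSet


def naive_presence_counts(seqs):
    """Brute-force substring scan: promoter-presence count per kmer."""
    counts = {}
    for seq in seqs.values():
        seen = set()
        for k in range(KMIN, KMAX + 1):
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if "N" not in w:
                    seen.add(w)
        for w in seen:
            counts[w] = counts.get(w, 0) + 1
    return counts


class TestDictionary:
    def test_counts_match_naive_scan_on_tiny_promoters(self):
        seqs = {
            "g1": "ACGTACGTAC",
            "g2": "AAAAAAAAAA",
            "g3": "ACGTNACGTT",
            "g4": "TTTTACGTAC",
            "g5": "GCGCGCGCGC",
        }
        d = build_dictionary(PromoterSet(seqs))
        assert d.counts == naive_presence_counts(seqs)
        assert d.universe_size == 5

    def test_presence_not_occurrence(self):
        # "ACG" occurs twice in g1 but counts once
        d = build_dictionary(PromoterSet({"g1": "ACGTACGT"}))
        assert d.counts["ACG"] == 1

    def test_every_substring_is_in_the_dictionary(self, promoters):
        d = build_dictionary(promoters)
        gene = promoters.genes[0]
        seq = promoters[gene]
        for k in (3, 8):
            for i in range(0, len(seq) - k + 1, 37):
                assert d.counts[seq[i : i + k]] >= 1

    def test_analytic_size_bound(self, promoters):
        d = build_dictionary(promoters)
        assert len(d.counts) <= DICTIONARY_SIZE
        assert max(d.counts.values()) <= d.universe_size

    def test_reverse_complement_union(self):
        d = build_dictionary(PromoterSet({"g1": "AAACCCT"}), both_strands=True)
        assert d.counts.get("AGGGTTT") == 1  # revcomp of the full word


class TestHypergeometric:
    def test_worked_enumeration_example(self):
        # universe of 10, 4 carriers; draw 5, observe 4: C(4,4)C(6,1)/C(10,5)
        p = hypergeom_pvalue(4, 5, 4, 10)
        assert p == pytest.approx(6 / 252)

    def test_absent_kmer_has_p_one(self):
        assert hypergeom_pvalue(0, 5, 4, 10) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universes(self):
        """p equals exhaustive subset enumeration for every configuration
        with universe size <= 8 (spot grid; the acceptance suite sweeps
        up to 12)."""
        for M in range(1, 9):
            for K in range(M + 1):
                carriers = set(range(K))
                for n in range(M + 1):
                    hits = {}
                    total = 0
                    for subset in itertools.combinations(range(M), n):
                        total += 1
                        c = len(carriers.intersection(subset))
                        hits[c] = hits.get(c, 0) + 1
                    for k in range(min(K, n) + 1):
                        expect = sum(v for c, v in hits.items() if c >= k) / total
                        assert hypergeom_pvalue(k, n, K, M) == pytest.approx(
                            expect, abs=1e-12
                        )


class TestBH:
    def test_qvalues_match_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 60))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_qvalues(p), q_sm, atol=1e-12)

    def test_rejections_match_naive_step_up_with_family_padding(self):
        """With family size m > len(p), the q < alpha set equals the naive
        step-up on the p-vector padded with ones to length m."""
        rng = np.random.default_rng(2)
        alpha = 0.05
        for _ in range(25):
            k, m = 30, 200
            p = rng.beta(0.3, 5.0, size=k)  # enriched near zero
            q = bh_qvalues(p, m=m)
            padded = np.sort(np.concatenate([p, np.ones(m - k)]))
            thresh = 0.0
            for i, pv in enumerate(padded, start=1):
                if pv <= i * alpha / m:
                    thresh = pv
            naive_reject = p <= thresh
            np.testing.assert_array_equal(q < alpha, naive_reject)

    def test_q_monotone_in_p_and_at_least_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestEnrichment:
    def test_planted_kmer_significant_in_its_bin(self, study, promoters, callsets):
        """The Evening-Element-like word planted at 80% carriage in the
        phase-9 list reaches q < 0.05 against the promoter universe."""
        _, truth = study
        d = build_dictionary(promoters)
        bin_genes = list(truth.genes_in_phase_bin(9))
        df = enrich_kmers(d, bin_genes, promoters, alpha=0.05)
        row = df[df["kmer"] == "AAATATCT"]
        assert len(row) == 1 and bool(row["significant"].iloc[0])

    def test_empty_list_gives_empty_result(self, promoters):
        d = build_dictionary(promoters)
        assert enrich_kmers(d, [], promoters).empty

    def test_counts_are_consistent(self, promoters):
        d = build_dictionary(promoters)
        genes = list(promoters.genes[:20])
        df = enrich_kmers(d, genes, promoters)
        assert (df["foreground"] <= df["list_size"]).all()
        assert (df["foreground"] <= df["background"]).all()
        assert (df["q"] >= df["p"] - 1e-15).all()


class TestRunElement:
    def test_schedules_conditions_times_bins(self, callsets, promoters):
        schedule = schedule_phase_lists(callsets, bins=24)
        assert len(schedule) == len(callsets) * 24
        schedule23 = schedule_phase_lists(callsets, bins=23)
        assert len(schedule23) == len(callsets) * 23

    def test_planted_kmer_flagged_in_at_least_one_list(self, callsets, element_result):
        assert element_result.n_lists == len(callsets) * 24
        assert "AAATATCT" in element_result.significant_kmers()


class TestClustering:
    def test_substring_pair_forms_one_cluster(self):
        clusters = cluster_kmers({"AAATATCT", "AATATCT"})
        assert len(clusters) == 1
        assert clusters[0].members == {"AAATATCT": 0, "AATATCT": 1}

    def test_dissimilar_pair_stays_apart(self):
        a, b = "AAACCCT", "GGATCCG"
        # oracle: no ungapped offset reaches min(len)-1 = 6 matches
        best = max(
            _best_alignment(a, b, min_overlap=3)[0],
            _best_alignment(b, a, min_overlap=3)[0],
        )
        assert best < 6
        assert not _linked(a, b)
        assert len(cluster_kmers({a, b})) == 2

    def test_singleton_cluster_is_one_hot(self):
        (cl,) = cluster_kmers({"ACGTT"})
        assert cl.consensus() == "ACGTT"
        assert (cl.pfm.sum(axis=0) == 1).all()
        assert (cl.pfm.max(axis=0) == 1).all()

    def test_pfm_columns_sum_to_covering_members(self):
        (cl,) = cluster_kmers({"AAATATCT", "AATATCT", "ATATCT"})
        for pos in cl.pfm.columns:
            covering = sum(
                1 for k, off in cl.members.items() if off <= pos < off + len(k)
            )
            assert cl.pfm[pos].sum() == covering

    def test_every_significant_kmer_in_exactly_one_cluster(self, element_result):
        sig = element_result.significant_kmers()
        clusters = cluster_kmers(sig)
        seen = [k for cl in clusters for k in cl.kmers]
        assert sorted(seen) == sorted(sig)


class TestTODProfile:
    def _toy_result(self):
        rows = [
            {"condition": "c3", "phase_bin": 12, "kmer": "AAATT", "foreground": 5,
             "list_size": 6, "background": 8, "universe": 100, "p": 1e-6,
             "q": 1e-4, "significant": True},
            {"condition": "c1", "phase_bin": 3, "kmer": "AAATT", "foreground": 1,
             "list_size": 6, "background": 8, "universe": 100, "p": 0.4,
             "q": 0.9, "significant": False},
        ]
        return ElementResult(results=pd.DataFrame(rows), n_lists=48, alpha=0.05)

    def test_single_significant_cell(self):
        prof = tod_profile(self._toy_result(), "AAATT",
                           conditions=["c1", "c3"], bins=range(24))
        nz = prof.to_numpy().nonzero()
        assert prof.loc["c3", 12] == pytest.approx(4.0)
        assert len(nz[0]) == 1

    def test_never_significant_kmer_is_all_zero(self):
        prof = tod_profile(self._toy_result(), "GGGGG",
                           conditions=["c1", "c3"], bins=range(24))
        assert (prof.to_numpy() == 0).all()

    def test_planted_kmer_profile_peaks_at_target_bin_everywhere(
        self, element_result
    ):
        """The dusk-planted word's profile is maximal at its (drift-shifted)
        bin in every condition."""
        prof = tod_profile(element_result, "AAATATCT", bins=range(24))
        drifts = {"c1": 0, "c2": 2, "c3": 6}
        for cond, drift in drifts.items():
            expected_bin = (9 + drift) % 24
            row = prof.loc[cond]
            assert row.idxmax() == expected_bin
            assert row.max() > 0
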