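import itertools

import numpy as np
import pandas as pd
import pytest

from irlnc import enrichment as enr
from irlnc.errors import ConfigurationError, NoOverlapError


def ranked(scores, genes=None, lnc="l1", cancer=""):
    genes = genes or [f"g{i}" for i in range(1, len(scores) + 1)]
    return enr.RankedList(lnc, tuple(genes), np.asarray(scores, float), cancer)


def triples_frame(pairs):
    """pairs: list of (lncrna, mrna, H)."""
    return pd.DataFrame(pairs, columns=["lncrna_id", "mrna_id", "H"])


def exact_pvalue(scores, gene_set_size, observed_hits, weight=1.0):
    """Exhaustive enumeration oracle over all hit placements.

    Returns (observed ES, exact one-sided p on the observed sign) using the
    same sign convention as the permutation estimator but without add-one
    smoothing.
    """
    scores = np.asarray(scores, float)
    n = len(scores)
    obs_mask = np.zeros(n, bool)
    obs_mask[list(observed_hits)] = True
    obs_es = enr.enrichment_score(scores, obs_mask, weight)
    same, extreme = 0, 0
    for combo in itertools.combinations(range(n), gene_set_size):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        es = enr.enrichment_score(scores, mask, weight)
        if (es >= 0) == (obs_es >= 0):
            same += 1
            if abs(es) >= abs(obs_es):
                extreme += 1
    return obs_es, extreme / same, same / len(
        list(itertools.combinations(range(n), gene_set_size))
    )


class TestBuildRankedLists:
    def test_threshold_is_strict_and_sorted(self):
        table = triples_frame(
            [("l1", "m1", 0.9), ("l1", "m2", 0.4), ("l1", "m3", 0.6), ("l1", "m4", 0.5)]
        )
        lists = enr.build_ranked_lists(table, threshold=0.5)
        assert len(lists) == 1
        assert lists[0].genes == ("m1", "m3")  # 0.5 exactly is excluded

    def test_all_below_threshold_omitted(self):
        table = triples_frame([("l1", "m1", 0.5), ("l1", "m2", 0.2)])
        assert enr.build_ranked_lists(table) == []

    def test_tied_scores_break_lexicographically(self):
        table = triples_frame([("l1", "m2", 0.7), ("l1", "m1", 0.7), ("l1", "m3", 0.8)])
        lists = enr.build_ranked_lists(table)
        assert lists[0].genes == ("m3", "m1", "m2")


class TestEnrichmentScore:
    def test_top_gene_set_gives_unit_score(self):
        # running sum: +1 at the top gene, then -1/2 per miss: peak 1
        es = enr.enrichment_score([3, 2, 1], np.array([True, False, False]))
        assert es == pytest.approx(1.0)

    def test_bottom_gene_set_gives_negative_unit(self):
        # running sum: -1/2, -1, then back to 0: signed peak -1
        es = enr.enrichment_score([3, 2, 1], np.array([False, False, True]))
        assert es == pytest.approx(-1.0)

    def test_all_hits_is_one(self):
        assert enr.enrichment_score([3, 2, 1], np.ones(3, bool)) == 1.0

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            enr.enrichment_score([3, 2, 1], np.zeros(3, bool))

    def test_reversal_negates_es_at_weight_zero(self, rng):
        # structural symmetry of the unweighted running sum; the signed
        # result is only determined when the peak magnitude is unique, so
        # magnitude-tied arrangements are checked for |ES| equality only
        checked = 0
        while checked < 50:
            n = int(rng.integers(4, 12))
            scores = np.sort(rng.random(n))[::-1]
            n_hits = int(rng.integers(1, n))
            mask = np.zeros(n, bool)
            mask[rng.choice(n, n_hits, replace=False)] = True
            running = np.cumsum(mask / n_hits - (~mask) / (n - n_hits))
            es = enr.enrichment_score(scores, mask, weight=0.0)
            es_rev = enr.enrichment_score(scores[::-1], mask[::-1], weight=0.0)
            peak = np.abs(running).max()
            unique_peak = np.isclose(np.abs(running), peak).sum() == 1
            if unique_peak:
                assert es_rev == pytest.approx(-es, abs=1e-12)
                checked += 1
            else:
                assert abs(es_rev) == pytest.approx(abs(es), abs=1e-12)


class TestPermutationPvalue:
    def test_deterministic_given_seed(self):
        rl = ranked([0.9, 0.8, 0.7, 0.6, 0.55])
        a = enr.permutation_pvalue(rl, {"g1", "g2"}, n_perm=2000, seed=7)
        b = enr.permutation_pvalue(rl, {"g1", "g2"}, n_perm=2000, seed=7)
        assert a == b

    def test_small_n_perm_rejected(self):
        rl = ranked([0.9, 0.8])
        with pytest.raises(ConfigurationError):
            enr.permutation_pvalue(rl, {"g1"}, n_perm=50, seed=1)

    def test_all_hits_degenerates_to_p_one(self):
        rl = ranked([0.9, 0.8, 0.7])
        es, p, n_hits = enr.permutation_pvalue(rl, {"g1", "g2", "g3"}, seed=3)
        assert (es, p, n_hits) == (1.0, 1.0, 3)

    @pytest.mark.parametrize(
        "scores, set_size, hits",
        [
            ([5, 4, 3, 2, 1], 2, (0, 1)),  # C(5,2) = 10 placements
            ([5, 4, 3, 2, 1], 2, (3, 4)),
            ([0.9, 0.8, 0.7, 0.65, 0.6, 0.55, 0.52], 3, (0, 1, 2)),
            ([0.9, 0.8, 0.7, 0.65, 0.6, 0.55], 2, (2, 4)),
        ],
    )
    def test_agrees_with_exhaustive_enumeration(self, scores, set_size, hits):
        obs_es, p_exact, frac_same = exact_pvalue(scores, set_size, hits)
        genes = [f"g{i}" for i in range(len(scores))]
        rl = enr.RankedList("l1", tuple(genes), np.asarray(scores, float))
        gene_set = {genes[i] for i in hits}
        n_perm = 10_000
        es, p, _ = enr.permutation_pvalue(rl, gene_set, n_perm=n_perm, seed=11)
        assert es == pytest.approx(obs_es)
        k = n_perm * frac_same
        tol = 3 * np.sqrt(max(p_exact * (1 - p_exact), 1e-12) / k) + 2 / k
        assert abs(p - p_exact) <= tol


class TestAgainstReferenceImplementation:
    def test_es_matches_gseapy_prerank(self, rng):
        # independent reference for the weighted running-sum statistic
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        for rep in range(3):
            n = int(rng.integers(15, 40))
            scores = np.sort(rng.random(n))[::-1] + 0.1
            genes = [f"g{i}" for i in range(n)]
            n_hits = int(rng.integers(3, 8))
            hit_idx = sorted(rng.choice(n, n_hits, replace=False))
            gene_sets = {"s1": [genes[i] for i in hit_idx]}
            res = gseapy.prerank(
                rnk=pd.DataFrame({"gene": genes, "score": scores}),
                gene_sets=gene_sets,
                permutation_num=10,
                min_size=1,
                max_size=100,
                weight=1.0,
                seed=1,
                threads=1,
                no_plot=True,
                outdir=None,
            )
            reference_es = float(res.res2d["ES"].iloc[0])
            hits = np.array([g in set(gene_sets["s1"]) for g in genes])
            assert enr.enrichment_score(scores, hits, weight=1.0) == pytest.approx(
                reference_es, abs=1e-6
            )


class TestLncres:
    @pytest.mark.parametrize(
        "es, p, expected",
        [
            (0.5, 0.05, 0.9),
            (-0.5, 0.5, 0.0),
            (0.0, 0.2, 0.6),  # ES = 0 takes the non-negative branch
        ],
    )
    def test_examples(self, es, p, expected):
        assert enr.lncres(es, p) == pytest.approx(expected)

    def test_bounded_on_dense_p_grid(self):
        for p in np.linspace(1e-6, 1.0, 2000):
            assert abs(enr.lncres(0.7, p)) <= 1.0
            assert abs(enr.lncres(-0.7, p)) <= 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigurationError):
            enr.lncres(0.5, 0.0)


class TestRunEnrichment:
    def _lists(self):
        return [
            ranked([0.9, 0.8, 0.7, 0.6], ["m1", "m2", "m3", "m4"], "l1"),
            ranked([0.95, 0.85, 0.65], ["m2", "m3", "m5"], "l2"),
        ]

    def test_record_cardinality_bound(self):
        pathways = {"p1": frozenset({"m1", "m2"}), "p2": frozenset({"m3"})}
        records = enr.run_enrichment(self._lists(), pathways, n_perm=200, seed=1)
        assert len(records) <= len(self._lists()) * len(pathways)
        assert set(records.columns) == set(enr.RECORD_COLUMNS)

    def test_no_overlap_produces_no_record(self):
        pathways = {"p1": frozenset({"zz1", "zz2"})}
        records = enr.run_enrichment(self._lists(), pathways, n_perm=200, seed=1)
        assert records.empty

    def test_max_size_applies_to_raw_pathway(self):
        big = frozenset(f"x{i}" for i in range(40)) | {"m1"}
        records = enr.run_enrichment(
            self._lists(), {"pbig": big}, max_size=30, n_perm=200, seed=1
        )
        assert records.empty

    def test_fdr_is_bh_within_each_lncrna(self):
        pathways = {
            "p1": frozenset({"m1"}),
            "p2": frozenset({"m3"}),
            "p3": frozenset({"m2", "m4"}),
        }
        records = enr.run_enrichment(self._lists(), pathways, n_perm=500, seed=5)

        def bh(pvals):
            # independent step-up implementation
            order = np.argsort(pvals)
            m = len(pvals)
            adj = np.empty(m)
            prev = 1.0
            for rank_idx in range(m - 1, -1, -1):
                i = order[rank_idx]
                prev = min(prev, pvals[i] * m / (rank_idx + 1))
                adj[i] = prev
            return adj

        for _, grp in records.groupby("lncrna_id"):
            expected = bh(grp["nominal_p"].to_numpy())
            assert np.allclose(grp["fdr"].to_numpy(), expected)

    def test_results_invariant_to_list_order(self):
        pathways = {"p1": frozenset({"m1", "m3"}), "p2": frozenset({"m2"})}
        fwd = enr.run_enrichment(self._lists(), pathways, n_perm=500, seed=9)
        rev = enr.run_enrichment(self._lists()[::-1], pathways, n_perm=500, seed=9)
        pd.testing.assert_frame_equal(fwd, rev)


class TestExtractionAndUnion:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["lncrna_id", "pathway", "ES", "nominal_p", "fdr", "lncres"]
        )

    def test_thresholds_are_strict(self):
        records = self._records(
            [
                ("l1", "p1", 0.9, 0.002, 0.01, 0.996),  # kept
                ("l2", "p1", 0.9, 0.0025, 0.01, 0.995),  # lncres on threshold
                ("l3", "p1", -0.9, 0.0005, 0.2, -0.999),  # fdr fails
            ]
        )
        irset = enr.extract_irlncrnas(records, cancer_label="C1")
        assert irset.members == {("l1", "p1")}

    def test_extracted_pairs_imply_small_p(self):
        # |lncRES| > 0.995 is equivalent to p < 0.0025
        records = self._records(
            [
                ("l1", "p1", 0.9, 0.0024, 0.01, 1 - 2 * 0.0024),
                ("l2", "p1", -0.9, 0.001, 0.01, 2 * 0.001 - 1),
            ]
        )
        irset = enr.extract_irlncrnas(records)
        kept_p = records.set_index("lncrna_id").loc[
            [l for l, _ in irset.members], "nominal_p"
        ]
        assert (kept_p < 0.0025).all()
        assert len(irset.members) == 2

    def test_union_retains_per_cancer_pathways(self):
        sets = [
            enr.IrlncRNASet("C1", frozenset({("lA", "p1"), ("lB", "p2")})),
            enr.IrlncRNASet("C2", frozenset({("lA", "p1")})),
            enr.IrlncRNASet("C3", frozenset({("lA", "p1"), ("lA", "p2")})),
        ]
        union = enr.union_irlncrnas(sets)
        assert union.lncrnas == {"lA", "lB"}
        assert union.nc("lA", "p1") == 3
        assert union.nc("lA", "p2") == 1
        assert union.nc("lB", "p2") == 1
        counts = union.pair_counts(["p1", "p2", "p3"])
        assert counts.loc["lA", "p1"] == 3
        assert counts.loc["lB", "p3"] == 0

    def test_union_of_empty_is_empty(self):
        union = enr.union_irlncrnas([enr.IrlncRNASet("C1", frozenset())])
        assert union.lncrnas == frozenset()
        assert union.pair_counts(["p1"]).empty
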