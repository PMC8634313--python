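"""TPM, DE engine and classification tests with simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tevex import expression as ex
from tevex import sim
from tevex.chimera import ReadAlignment


def make_table(counts: pd.DataFrame, lengths=None, kinds=None, samples=None) -> ex.CountTable:
    n = len(counts)
    meta = pd.DataFrame(
        {
            "kind": kinds if kinds is not None else ["te_family"] * n,
            "length": lengths if lengths is not None else [1000] * n,
        },
        index=counts.index,
    )
    if samples is None:
        cond = ["mock" if c.startswith("mock") else "infected" for c in counts.columns]
        samples = pd.DataFrame({"condition": cond, "time_point": 0}, index=counts.columns)
    return ex.CountTable(counts=counts, meta=meta, samples=samples)


class TestCounting:
    def test_all_reads_one_family(self):
        alns = [(f"r{i}", "copy1") for i in range(10)]
        counts = ex.count_reads_per_family(alns, {"copy1": "F"})
        assert counts.to_dict() == {"F": 10}

    def test_multimapper_counted_once_deterministically(self):
        alns = [
            ReadAlignment("r1", "te", "copyB", (0, 50), (0, 50), "+"),
            ReadAlignment("r1", "te", "copyA", (0, 50), (10, 60), "+"),
        ]
        counts = ex.count_reads_per_family(alns, {"copyA": "FA", "copyB": "FB"})
        # equal alignment lengths: tie broken by sorted family name
        assert counts.to_dict() == {"FA": 1}

    def test_unknown_copy_skipped(self, caplog):
        counts = ex.count_reads_per_family([("r1", "mystery")], {"copy1": "F"})
        assert counts.empty

    def test_counts_match_provenance_on_synthetic_reads(self, infection_dataset, chimera_run):
        """With error-free reads, family counts from best TE alignments
        equal the per-family read tallies implied by provenance for reads
        that carry enough TE sequence to align."""
        ds = infection_dataset
        te_alns = [a for a in chimera_run.alignments if a.subject_kind == "te"]
        counts = ex.count_reads_per_family(te_alns, {f.name: f.name for f in ds.families})
        aligned_reads = {a.read_id for a in te_alns}
        prov = sim.provenance_frame(ds.provenance)
        expected = prov[prov.read_id.isin(aligned_reads)].family.value_counts()
        assert counts.sum() == len(aligned_reads)
        assert counts.to_dict() == expected.to_dict()


class TestTPM:
    def test_single_entity_gets_the_million(self):
        counts = pd.DataFrame({"mock_1": [7]}, index=["a"])
        tpm = ex.compute_tpm(make_table(counts))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_counts_and_lengths_split_evenly(self):
        counts = pd.DataFrame({"mock_1": [5, 5]}, index=["a", "b"])
        tpm = ex.compute_tpm(make_table(counts))
        assert tpm["mock_1"].tolist() == pytest.approx([5e5, 5e5])

    def test_length_normalization(self):
        counts = pd.DataFrame({"mock_1": [10, 10]}, index=["short", "long"])
        tpm = ex.compute_tpm(make_table(counts, lengths=[500, 2000]))
        assert tpm.loc["short", "mock_1"] / tpm.loc["long", "mock_1"] == pytest.approx(4.0)

    def test_columns_sum_to_a_million(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(20, 3)), columns=["mock_1", "mock_2", "infected_1"]
        )
        counts.index = [f"e{i}" for i in range(20)]
        tpm = ex.compute_tpm(make_table(counts, lengths=list(rng.integers(200, 5000, 20))))
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_replicate_flagged_nan(self):
        counts = pd.DataFrame({"mock_1": [0, 0], "mock_2": [1, 1]}, index=["a", "b"])
        tpm = ex.compute_tpm(make_table(counts))
        assert tpm["mock_1"].isna().all()
        assert tpm["mock_2"].sum() == pytest.approx(1e6)


class TestClassification:
    @pytest.mark.parametrize(
        "tpm,category",
        [
            (0.37, "not_expressed"),
            (3.999, "not_expressed"),
            (4.0, "expressed"),
            (49.9, "expressed"),
            (50.0, "highly_expressed"),
            (65.6, "highly_expressed"),
        ],
    )
    def test_category_boundaries(self, tpm, category):
        assert ex.classify_expression(tpm) == category

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            ex.classify_expression(-1.0)

    def test_series_version_agrees(self):
        vals = pd.Series([0.0, 0.37, 4.0, 50.0, 200.0])
        assert list(ex.classify_expression_series(vals)) == [ex.classify_expression(v) for v in vals]


class TestDEThresholds:
    def test_significant_but_small_fold_change_is_ns(self):
        res = pd.DataFrame({"log2fc": [1.9], "padj": [0.01]})
        assert ex.apply_de_thresholds(res)["de_flag"].iloc[0] == "ns"

    @pytest.mark.parametrize(
        "lfc,padj,flag",
        [(2.0, 0.049, "up"), (-2.0, 0.049, "down"), (2.5, 0.06, "ns"), (0.1, 0.001, "ns")],
    )
    def test_rule(self, lfc, padj, flag):
        res = pd.DataFrame({"log2fc": [lfc], "padj": [padj]})
        assert ex.apply_de_thresholds(res)["de_flag"].iloc[0] == flag

    def test_bh_matches_brute_force(self, rng):
        """padj from the engine equals a textbook BH computation."""
        pvals = rng.uniform(0, 1, 50)
        counts = pd.DataFrame(rng.poisson(100, size=(50, 6)),
                              columns=[f"mock_{i}" for i in range(3)] + [f"infected_{i}" for i in range(3)],
                              index=[f"e{i}" for i in range(50)])
        m = len(pvals)
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * m / rank)
            adj[i] = running
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(multipletests(pvals, method="fdr_bh")[1], adj)


class TestSizeFactors:
    def test_recovers_planted_library_scaling(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(500, size=(400, 1)).astype(float) + 1
        sf_true = np.array([1.0, 2.0, 0.5, 1.5])
        counts = pd.DataFrame(
            rng.poisson(base * sf_true), columns=["a", "b", "c", "d"]
        )
        sf = ex.size_factors(counts)
        ratios = sf.to_numpy() / sf_true
        np.testing.assert_allclose(ratios / ratios[0], 1.0, rtol=0.05)


class TestCallDE:
    def _planted_table(self, seed, n_null=40, lfc=4.0):
        truth = [sim.CountSimTruth(f"null_{i}", 0.0, 200.0, 0.05) for i in range(n_null)]
        truth += [
            sim.CountSimTruth("planted_up", lfc, 200.0, 0.05),
            sim.CountSimTruth("planted_down", -lfc, 200.0, 0.05),
        ]
        counts, samples = sim.simulate_count_table(truth, 3, seed=seed)
        samples["time_point"] = 0
        return make_table(counts, samples=samples)

    def test_planted_effects_flagged(self):
        table = self._planted_table(seed=42)
        res = ex.call_de(table, design="matched")
        flags = res.set_index("entity")["de_flag"]
        assert flags["planted_up"] == "up"
        assert flags["planted_down"] == "down"

    def test_estimated_lfc_tracks_planted(self):
        rng = np.random.default_rng(3)
        planted = rng.uniform(-4, 4, 300)
        truth = [sim.CountSimTruth(f"e{i}", float(l), 150.0, 0.05) for i, l in enumerate(planted)]
        counts, samples = sim.simulate_count_table(truth, 3, seed=13)
        samples["time_point"] = 0
        res = ex.call_de(make_table(counts, samples=samples), design="matched")
        rho = stats.spearmanr(res.set_index("entity").loc[[t.entity for t in truth], "log2fc"], planted)[0]
        assert rho >= 0.9

    def test_increasing_infected_counts_never_lowers_lfc(self):
        counts = pd.DataFrame(
            {
                "mock_1": [100, 500], "mock_2": [110, 480],
                "infected_1": [100, 510], "infected_2": [90, 505],
            },
            index=["target", "stable"],
        )
        sf = pd.Series(1.0, index=counts.columns)
        lfcs = []
        for extra in (0, 50, 200, 1000):
            bumped = counts.copy()
            bumped.loc["target", ["infected_1", "infected_2"]] += extra
            res = ex.nb_wald_test(bumped, ["mock_1", "mock_2"], ["infected_1", "infected_2"], sf)
            lfcs.append(res.loc["target", "log2fc"])
        assert all(b >= a for a, b in zip(lfcs, lfcs[1:]))

    def test_genes_used_for_normalization_but_not_reported(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.poisson(300, size=(30, 4)),
            columns=["mock_1", "mock_2", "infected_1", "infected_2"],
            index=[f"g{i}" for i in range(25)] + [f"te{i}" for i in range(5)],
        )
        kinds = ["gene"] * 25 + ["te_family"] * 5
        samples = pd.DataFrame(
            {"condition": ["mock", "mock", "infected", "infected"], "time_point": 0},
            index=counts.columns,
        )
        res = ex.call_de(make_table(counts, kinds=kinds, samples=samples))
        assert set(res["entity"]) <= {f"te{i}" for i in range(5)}

    def test_missing_matched_mock_timepoint_skipped(self, caplog):
        rng = np.random.default_rng(1)
        cols = ["mock_1", "mock_2", "inf0_1", "inf0_2", "inf6_1", "inf6_2"]
        counts = pd.DataFrame(rng.poisson(100, size=(10, 6)), columns=cols,
                              index=[f"e{i}" for i in range(10)])
        samples = pd.DataFrame(
            {
                "condition": ["mock", "mock", "infected", "infected", "infected", "infected"],
                "time_point": [0, 0, 0, 0, 6, 6],
            },
            index=cols,
        )
        res = ex.call_de(make_table(counts, samples=samples), design="matched")
        assert set(res["time_point"]) == {0}  # the 6-hpi contrast has no mock

    def test_baseline_design_contrasts_against_first_mock(self):
        rng = np.random.default_rng(2)
        cols = ["mock0_1", "mock0_2", "inf6_1", "inf6_2", "inf12_1", "inf12_2"]
        counts = pd.DataFrame(rng.poisson(200, size=(10, 6)), columns=cols,
                              index=[f"e{i}" for i in range(10)])
        samples = pd.DataFrame(
            {
                "condition": ["mock", "mock", "infected", "infected", "infected", "infected"],
                "time_point": [0, 0, 6, 6, 12, 12],
            },
            index=cols,
        )
        res = ex.call_de(make_table(counts, samples=samples), design="baseline")
        assert set(res["time_point"]) == {6, 12}


class TestAgainstIndependentEngine:
    def test_lfc_agrees_with_deseq2_implementation(self):
        """The built-in NB Wald engine's fold changes track those of an
        independent DESeq2 implementation on a strongly planted table."""
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(3)
        planted = rng.uniform(-4, 4, 80)
        truth = [sim.CountSimTruth(f"e{i}", float(l), 200.0, 0.05) for i, l in enumerate(planted)]
        counts, samples = sim.simulate_count_table(truth, 3, seed=17)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=counts.T, metadata=samples, design="~condition", quiet=True)
            dds.deseq2()
            ds_stats = DeseqStats(dds, contrast=["condition", "infected", "mock"], quiet=True)
            ds_stats.summary()
        ref = ds_stats.results_df["log2FoldChange"]
        mine = ex.nb_wald_test(
            counts,
            [c for c in counts if c.startswith("mock")],
            [c for c in counts if c.startswith("infected")],
            ex.size_factors(counts),
        )["log2fc"]
        r, _ = stats.pearsonr(ref, mine.loc[ref.index])
        assert r > 0.99
        # strongly induced/repressed entities agree in sign
        strong = planted[np.abs(planted) > 1]
        assert (np.sign(mine.to_numpy()[np.abs(planted) > 1]) == np.sign(strong)).all()


class TestInducedRepressed:
    def _frame(self, **cols):
        return pd.DataFrame(cols, index=["fam"])

    def test_induced(self):
        flags = self._frame(t0="ns", t72="up")
        out = ex.classify_induced_repressed(flags, self._frame(m=1.0), self._frame(t0=0.5, t72=63.0))
        assert bool(out.loc["fam", "induced"]) and not bool(out.loc["fam", "repressed"])

    def test_repressed(self):
        flags = self._frame(t72="down")
        out = ex.classify_induced_repressed(flags, self._frame(m=11.0), self._frame(t72=2.0))
        assert bool(out.loc["fam", "repressed"]) and not bool(out.loc["fam", "induced"])

    def test_already_expressed_not_induced(self):
        flags = self._frame(t72="up")
        out = ex.classify_induced_repressed(flags, self._frame(m=10.0), self._frame(t72=80.0))
        assert not bool(out.loc["fam", "induced"])

    def test_upregulation_required_for_induction(self):
        flags = self._frame(t72="ns")
        out = ex.classify_induced_repressed(flags, self._frame(m=1.0), self._frame(t72=30.0))
        assert not bool(out.loc["fam", "induced"])


class TestMeanTPM:
    def test_condition_and_timepoint_means(self):
        counts = pd.DataFrame(
            {"m0_1": [8, 0], "m0_2": [4, 0], "i0_1": [0, 6], "i6_1": [2, 2]},
            index=["a", "b"],
        )
        samples = pd.DataFrame(
            {
                "condition": ["mock", "mock", "infected", "infected"],
                "time_point": [0, 0, 0, 6],
            },
            index=counts.columns,
        )
        tpm = ex.compute_tpm(make_table(counts, samples=samples))
        by = ex.mean_tpm_by_condition(tpm, samples)
        assert by["mock"].loc["a", 0] == pytest.approx(1e6)
        assert by["infected"].loc["b", 0] == pytest.approx(1e6)
        assert by["infected"].loc["a", 6] == pytest.approx(5e5)


class TestCorrelations:
    def test_perfect_linear(self):
        x = pd.Series(np.arange(10.0), index=[f"f{i}" for i in range(10)])
        res = ex.correlate_factors(x, (2 * x).to_frame("copy_number"))
        assert res.loc["copy_number", "r"] == pytest.approx(1.0)

    def test_anti_proportional(self):
        x = pd.Series(np.arange(1.0, 11.0), index=[f"f{i}" for i in range(10)])
        res = ex.correlate_factors(x, (-3 * x).to_frame("age"))
        assert res.loc["age", "r"] == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self, rng):
        idx = [f"f{i}" for i in range(1000)]
        x = pd.Series(rng.normal(size=1000), index=idx)
        y = pd.DataFrame({"noise": rng.normal(size=1000)}, index=idx)
        res = ex.correlate_factors(x, y)
        assert abs(res.loc["noise", "r"]) < 0.1

    def test_zero_variance_flagged(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        res = ex.correlate_factors(x, pd.DataFrame({"flat": [5.0, 5.0, 5.0]}, index=list("abc")))
        assert np.isnan(res.loc["flat", "r"])
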