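"""DEG mapping, the per-probe Welch test (closed form, degenerate cases,
permutation oracle, shift invariance), signature calling and set overlaps."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

import amlsig as a
from amlsig.signature_enrichment import MappedSignatureInput

from conftest import run_pipeline_on_truth


def _mapped(probes):
    rows = [(f"Gene{i}", f"GENE{i}", p) for i, p in enumerate(probes)]
    return MappedSignatureInput(
        mapped=pd.DataFrame(rows, columns=["mouse_symbol", "human_symbol", "probe_id"]),
        unmapped_report=pd.DataFrame(columns=["mouse_symbol", "stage"]),
    )


def _diff(probe_rows, samples_prefix="s"):
    arr = np.asarray(probe_rows, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"PX{i}" for i in range(arr.shape[0])],
        columns=[f"{samples_prefix}{j}" for j in range(arr.shape[1])],
    )


class TestMapping:
    def test_one_to_many_probes(self):
        degs = a.DEGList(pd.DataFrame(
            {"gene": ["Cd48"], "direction": [1], "lfc": [2.0], "adj_p": [0.001]}
        ))
        orth = a.OrthologMap({"Cd48": frozenset({"CD48"})})
        annot = a.ProbeAnnotation({"probe_201": "CD48", "probe_202": "CD48"})
        mapped = a.map_degs_to_probes(degs, orth, annot, annot)
        assert len(mapped.mapped) == 2
        assert set(mapped.mapped["probe_id"]) == {"probe_201", "probe_202"}

    def test_no_ortholog_reported(self):
        degs = a.DEGList(pd.DataFrame(
            {"gene": ["Cd48", "Gm12345"], "direction": [1, 1],
             "lfc": [2.0, 2.0], "adj_p": [0.001, 0.001]}
        ))
        orth = a.OrthologMap({"Cd48": frozenset({"CD48"})})
        annot = a.ProbeAnnotation({"probe_201": "CD48"})
        mapped = a.map_degs_to_probes(degs, orth, annot, annot)
        assert list(mapped.unmapped_report["mouse_symbol"]) == ["Gm12345"]
        assert list(mapped.unmapped_report["stage"]) == ["no_ortholog"]

    def test_probe_must_be_shared_by_both_annotations(self):
        degs = a.DEGList(pd.DataFrame(
            {"gene": ["Cd48"], "direction": [1], "lfc": [2.0], "adj_p": [0.001]}
        ))
        orth = a.OrthologMap({"Cd48": frozenset({"CD48"})})
        annot_a = a.ProbeAnnotation({"p1": "CD48"})
        annot_b = a.ProbeAnnotation({"p2": "CD48"})
        with pytest.raises(a.PipelineError):
            a.map_degs_to_probes(degs, orth, annot_a, annot_b)

    def test_fully_mappable_synthetic_list_counts(self, small_sim):
        degs = a.simulate_deg_list(small_sim["truth"], n_decoys=0, seed=7)
        mapped = a.map_degs_to_probes(
            degs, small_sim["orthologs"], small_sim["annotation"],
            small_sim["annotation"]
        )
        ppg = small_sim["truth"].config.probes_per_gene
        assert len(mapped.mapped) == len(degs.entries) * ppg
        assert mapped.unmapped_report.empty


class TestEnrichmentTest:
    def test_welch_closed_form(self):
        table = a.enrichment_test(_diff([[2.0, 4.0]]), _diff([[1.0, 3.0]], "t"),
                                  _mapped(["PX0"]))
        row = table.iloc[0]
        assert row["t_stat"] == pytest.approx(0.7071, abs=1e-4)
        assert row["df"] == pytest.approx(2.0)
        assert row["delta"] == pytest.approx(1.0)

    def test_identical_cohorts_null(self):
        d = [[1.0, 2.0, 3.0]]
        row = a.enrichment_test(_diff(d), _diff(d, "t"), _mapped(["PX0"])).iloc[0]
        assert row["t_stat"] == 0.0
        assert row["p_value"] == 1.0
        assert row["enriched_in"] == "none"

    def test_degenerate_zero_variance(self):
        # equal constant cohorts -> t=0, p=1; unequal constants -> p=0 flagged
        t1 = a.enrichment_test(_diff([[2.0, 2.0]]), _diff([[2.0, 2.0]], "t"),
                               _mapped(["PX0"])).iloc[0]
        assert (t1["t_stat"], t1["p_value"]) == (0.0, 1.0)
        t2 = a.enrichment_test(_diff([[3.0, 3.0]]), _diff([[2.0, 2.0]], "t"),
                               _mapped(["PX0"])).iloc[0]
        assert t2["p_value"] == 0.0
        assert t2["flag"] == "degenerate"

    def test_single_sample_cohort_rejected(self):
        with pytest.raises(a.PipelineError):
            a.enrichment_test(_diff([[1.0]]), _diff([[1.0, 2.0]], "t"),
                              _mapped(["PX0"]))

    def test_bh_q_bounds_and_monotonicity(self, small_sim):
        table, _ = run_pipeline_on_truth(small_sim)
        t = table.sort_values("p_value")
        assert (t["q_value"] >= t["p_value"] - 1e-12).all()
        assert (t["q_value"].diff().dropna() >= -1e-12).all()

    def test_p_consistent_with_abs_t(self, small_sim):
        table, _ = run_pipeline_on_truth(small_sim)
        finite = table[np.isfinite(table["t_stat"])]
        # at (approximately) common df, larger |t| cannot give larger p
        sub = finite[np.abs(finite["df"] - finite["df"].median()) < 1.0]
        s = sub.sort_values("p_value")
        assert (s["t_stat"].abs().diff().dropna() <= 1e-9 + s["t_stat"].abs().max()).all()
        # direct check: p matches the survival function at its own t, df
        from scipy import stats
        expect = 2 * stats.t.sf(np.abs(finite["t_stat"]), finite["df"])
        np.testing.assert_allclose(finite["p_value"], expect, rtol=1e-10)

    def test_full_statistic_shift_invariant(self, small_sim):
        """Adding per-sample constants to the raw matrices changes nothing."""
        table1, _ = run_pipeline_on_truth(small_sim)
        ma, mb = small_sim["matrix_a"], small_sim["matrix_b"]
        rng = np.random.default_rng(11)
        shifted = dict(small_sim)
        shifted["matrix_a"] = ma.with_values(
            ma.values + pd.Series(rng.normal(0, 3, len(ma.sample_ids)),
                                  index=ma.values.columns)
        )
        shifted["matrix_b"] = mb.with_values(
            mb.values + pd.Series(rng.normal(0, 3, len(mb.sample_ids)),
                                  index=mb.values.columns)
        )
        table2, _ = run_pipeline_on_truth(shifted)
        # invariance is exact in real arithmetic (ranks are unchanged and the
        # per-sample reference absorbs the offset); IEEE rounding through the
        # recomputed reference leaves differences at machine resolution
        np.testing.assert_allclose(table1["t_stat"].to_numpy(),
                                   table2["t_stat"].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(table1["p_value"].to_numpy(),
                                   table2["p_value"].to_numpy(), atol=1e-12)

    def test_welch_p_agrees_with_permutation_oracle(self):
        """Welch p tracks the exhaustive label-permutation mid-p at n=4+4.

        The 70-point permutation null is discrete (granularity 1/35), so
        per-instance gaps above 0.05 are unavoidable for any continuous
        approximation; agreement is asserted on the average gap over the 20
        random instances.
        """
        rng = np.random.default_rng(2)

        def welch_abs_t(xa, xb):
            se2 = xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb)
            return abs(xa.mean() - xb.mean()) / np.sqrt(se2)

        deltas = []
        for _ in range(20):
            xa = rng.normal(0.5, 1.0, 4)
            xb = rng.normal(0.0, 1.0, 4)
            table = a.enrichment_test(_diff([xa]), _diff([xb], "t"), _mapped(["PX0"]))
            p_welch = table.iloc[0]["p_value"]
            pooled = np.concatenate([xa, xb])
            obs = welch_abs_t(xa, xb)
            stats_ = []
            for idx in combinations(range(8), 4):
                mask = np.zeros(8, bool)
                mask[list(idx)] = True
                stats_.append(welch_abs_t(pooled[mask], pooled[~mask]))
            stats_ = np.asarray(stats_)
            greater = (stats_ > obs + 1e-12).sum()
            ties = (np.abs(stats_ - obs) <= 1e-12).sum()
            p_perm = (greater + 0.5 * ties) / len(stats_)
            deltas.append(abs(p_welch - p_perm))
        assert np.mean(deltas) <= 0.05


class TestSignatureCall:
    def _table(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["probe_id", "human_symbol", "mouse_symbol", "delta",
                     "p_value", "q_value"],
        )
        df["enriched_in"] = np.where(
            (df["p_value"] < 0.05) & (df["delta"] > 0), "A",
            np.where((df["p_value"] < 0.05) & (df["delta"] < 0), "B", "none"),
        )
        for col in ["mean_diff_A", "mean_diff_B", "t_stat", "df"]:
            df[col] = 0.0
        df["flag"] = ""
        return df

    def test_any_probe_rule(self):
        table = self._table([
            ("p1", "G1", "g1", 1.0, 0.01, 0.02),
            ("p2", "G1", "g1", 1.0, 0.30, 0.40),
        ])
        sig = a.call_signature(table)
        assert sig.genes == ["G1"]

    def test_discordant_gene_excluded_and_flagged(self):
        table = self._table([
            ("p1", "G1", "g1", 1.0, 0.01, 0.02),
            ("p2", "G1", "g1", -1.0, 0.01, 0.02),
        ])
        sig = a.call_signature(table)
        assert sig.genes == []
        assert list(sig.summary["status"]) == ["discordant"]

    def test_sorted_by_best_probe_p(self):
        table = self._table([
            ("p1", "G1", "g1", 1.0, 0.04, 0.05),
            ("p2", "G2", "g2", 1.0, 0.001, 0.01),
        ])
        assert a.call_signature(table).genes == ["G2", "G1"]

    def test_recovery_on_planted_simulation(self, small_sim):
        _, sig = run_pipeline_on_truth(small_sim)
        planted = {m.replace("Gene", "GENE") for m in
                   small_sim["truth"].signature_genes}
        assert planted <= set(sig.genes)


class TestOverlapDegs:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [({"a", "b", "c"}, {"b", "c", "d"}, 2), ({"a"}, {"b"}, 0),
         (set("abcdefg"), set("efghijk"), 3)],
    )
    def test_counts(self, s1, s2, expected):
        res = a.overlap_degs(s1, s2)
        assert res["intersection_size"] == expected
        assert res["intersection_members"] == sorted(s1 & s2)

    def test_fraction_arithmetic(self):
        assert a.signature_fraction(19, 164) == 11.6
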