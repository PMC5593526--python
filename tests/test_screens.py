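"""Screen criteria: worked arithmetic, boundary strictness, brute-force
oracle agreement, invariance properties and planted-truth recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from p53screen.data_model import (
    ExpressionMatrix,
    GeneSet,
    OrthologMap,
    ProbeGeneMap,
    SampleDesign,
    ValidationError,
)
from p53screen.screens import (
    CohortScreenParams,
    MicroarrayScreenParams,
    RnaseqScreenParams,
    ScreenResult,
    intersect_candidates,
    screen_cohort,
    screen_microarray,
    screen_rnaseq,
    tissue_profile,
)
from p53screen.survival import CohortTable

MA_SAMPLES = ["MA_W0", "MA_W12", "MA_W24", "MA_W48", "MA_K0", "MA_K12", "MA_K24", "MA_K48"]


def _ma_design():
    return SampleDesign.from_records(
        [
            {
                "sample_id": f"MA_{arm}{t}",
                "genotype": "p53_wt" if arm == "W" else "p53_null",
                "treatment": "ADR" if t > 0 else "none",
                "timepoint": t,
                "tissue": None,
            }
            for arm in ("W", "K")
            for t in (0, 12, 24, 48)
        ]
    )


def _ma_matrix(rows: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame.from_dict(rows, orient="index", columns=MA_SAMPLES),
        feature_kind="probe",
    )


class TestMicroarrayScreen:
    def test_ratio_arithmetic_and_strict_boundary(self):
        # probe_a: A = median(10,10,10) = 10, B = min(30,...) = 30 -> 0.333
        # probe_b: A = 15, B = 30 -> exactly 0.5, excluded by strict inequality
        expr = _ma_matrix(
            {
                "a_p1": [30, 10, 10, 10, 31, 32, 33, 34],
                "b_p1": [30, 15, 15, 15, 31, 32, 33, 34],
            }
        )
        pmap = ProbeGeneMap(mapping={"a_p1": "A", "b_p1": "B"})
        res = screen_microarray(expr, _ma_design(), pmap)
        assert res.table.loc["A", "ratio"] == pytest.approx(1 / 3)
        assert res.table.loc["A", "candidate"]
        assert res.table.loc["B", "ratio"] == 0.5
        assert not res.table.loc["B", "candidate"]

    def test_zero_baseline_probe_excluded_not_fatal(self):
        expr = _ma_matrix(
            {
                "a_p1": [0, 10, 10, 10, 31, 32, 33, 34],  # B = 0: non-evaluable
                "a_p2": [30, 10, 10, 10, 31, 32, 33, 34],
            }
        )
        pmap = ProbeGeneMap(mapping={"a_p1": "A", "a_p2": "A"})
        res = screen_microarray(expr, _ma_design(), pmap)
        assert res.n_non_evaluable == 1
        assert res.table.loc["A", "candidate"]

    def test_any_probe_vs_median_probe_collapse(self):
        expr = _ma_matrix(
            {
                "a_p1": [30, 10, 10, 10, 31, 32, 33, 34],   # ratio 1/3
                "a_p2": [30, 30, 30, 30, 31, 32, 33, 34],   # ratio 1
                "a_p3": [30, 30, 30, 30, 31, 32, 33, 34],   # ratio 1
            }
        )
        pmap = ProbeGeneMap(mapping={f"a_p{i}": "A" for i in (1, 2, 3)})
        any_probe = screen_microarray(expr, _ma_design(), pmap)
        median_probe = screen_microarray(
            expr, _ma_design(), pmap, MicroarrayScreenParams(probe_collapse="median_probe")
        )
        assert any_probe.table.loc["A", "candidate"]
        assert not median_probe.table.loc["A", "candidate"]

    def test_scale_invariance(self, small_bundle):
        """Multiplying all samples of one probe by c > 0 leaves candidacy
        unchanged (the screen is pseudocount-free)."""
        expr, design, pmap = (
            small_bundle.microarray,
            small_bundle.microarray_design,
            small_bundle.probe_map,
        )
        base = screen_microarray(expr, design, pmap)
        scaled_values = expr.values.copy()
        scaled_values.iloc[::3] *= 37.5
        scaled = screen_microarray(
            ExpressionMatrix(values=scaled_values, feature_kind="probe"), design, pmap
        )
        pd.testing.assert_series_equal(base.table["candidate"], scaled.table["candidate"])

    def test_monotone_in_treated_values(self):
        """Decreasing a treated-condition value never turns a candidate into
        a non-candidate."""
        rng = np.random.default_rng(11)
        rows = {f"g{i}_p1": list(rng.uniform(5, 50, size=8)) for i in range(30)}
        expr = _ma_matrix(rows)
        pmap = ProbeGeneMap(mapping={p: p.split("_")[0] for p in rows})
        before = screen_microarray(expr, _ma_design(), pmap)
        lowered = expr.values.copy()
        lowered[["MA_W12", "MA_W24", "MA_W48"]] *= 0.5
        after = screen_microarray(
            ExpressionMatrix(values=lowered, feature_kind="probe"), _ma_design(), pmap
        )
        was = before.table["candidate"]
        now = after.table["candidate"]
        assert now[was].all()


def _rnaseq_fixture(mean_w, mean_wx, mean_kx, mean_k, n_rep=3):
    records, cols = [], {}
    for arm, mean, irr in (
        ("W", mean_w, False), ("WX", mean_wx, True), ("KX", mean_kx, True), ("K", mean_k, False)
    ):
        genotype = "p53_wt" if arm.startswith("W") else "p53_null"
        for rep in range(1, n_rep + 1):
            sid = f"mammary_gland_{arm}_{rep}"
            cols[sid] = [mean]
            records.append(
                {
                    "sample_id": sid,
                    "genotype": genotype,
                    "treatment": "irradiation" if irr else "none",
                    "timepoint": None,
                    "tissue": "mammary_gland",
                }
            )
    expr = ExpressionMatrix(
        values=pd.DataFrame(cols, index=["Gene1"]), feature_kind="gene"
    )
    return expr, SampleDesign.from_records(records)


class TestRnaseqScreen:
    def test_pseudocount_arithmetic(self):
        # pre-pseudocount means W=9, WX=1, KX=9, K=9 -> A=2, B=10, ratio 0.2
        expr, design = _rnaseq_fixture(9, 1, 9, 9)
        res = screen_rnaseq(expr, design)
        row = res.table.loc["Gene1"]
        assert row["A"] == pytest.approx(2.0)
        assert row["B"] == pytest.approx(10.0)
        assert row["ratio"] == pytest.approx(0.2)
        assert row["candidate"]

    def test_identical_replicates_mean_equals_value(self):
        expr, design = _rnaseq_fixture(5, 5, 5, 5)
        res = screen_rnaseq(expr, design)
        assert res.table.loc["Gene1", "A"] == pytest.approx(6.0)
        assert res.table.loc["Gene1", "ratio"] == pytest.approx(1.0)

    def test_missing_condition_group_raises(self):
        expr, design = _rnaseq_fixture(9, 1, 9, 9)
        with pytest.raises(ValidationError, match="no WX samples"):
            screen_rnaseq(expr, design, RnaseqScreenParams(screen_tissue="liver"))


def _cohort_from_genes(genes: dict[str, tuple[np.ndarray, np.ndarray]]) -> CohortTable:
    any_wt, any_mut = next(iter(genes.values()))
    n_wt, n_mut = len(any_wt), len(any_mut)
    table = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n_wt + n_mut)],
            "p53_status": ["wt"] * n_wt + ["mut"] * n_mut,
            "time_days": 100.0,
            "event": 0,
        }
    )
    expr = pd.DataFrame({g: np.concatenate([wt, mut]) for g, (wt, mut) in genes.items()})
    return CohortTable(table=pd.concat([table, expr], axis=1))


class TestCohortScreen:
    def test_direction_filter_and_identity(self):
        rng = np.random.default_rng(3)
        low = rng.normal(10, 1, 50)
        high = rng.normal(20, 1, 50)
        same = rng.normal(10, 1, 50)
        cohort = _cohort_from_genes(
            {
                "UP_IN_MUT": (low, high),    # candidate
                "DOWN_IN_MUT": (high, low),  # significant but wrong direction
                "FLAT": (same, same.copy()), # identical distributions
            }
        )
        res = screen_cohort(cohort)
        assert res.table.loc["UP_IN_MUT", "candidate"]
        assert res.table.loc["DOWN_IN_MUT", "p_value"] < 0.05
        assert not res.table.loc["DOWN_IN_MUT", "candidate"]
        assert not res.table.loc["FLAT", "candidate"]

    def test_degenerate_zero_variance(self):
        cohort = _cohort_from_genes(
            {
                "CONST_EQ": (np.full(10, 5.0), np.full(8, 5.0)),
                "CONST_NE": (np.full(10, 5.0), np.full(8, 9.0)),
            }
        )
        res = screen_cohort(cohort)
        assert res.table.loc["CONST_EQ", "p_value"] == 1.0
        assert not res.table.loc["CONST_EQ", "candidate"]
        assert res.table.loc["CONST_NE", "candidate"]

    def test_null_candidate_rate_matches_halved_alpha(self):
        """Two-sided test at alpha=0.05 plus the one-sided direction filter
        gives a type-I candidate rate of about 0.025."""
        rng = np.random.default_rng(42)
        n_genes = 4000
        genes = {
            f"G{i}": (rng.normal(0, 1, 60) + 10, rng.normal(0, 1, 40) + 10)
            for i in range(n_genes)
        }
        res = screen_cohort(_cohort_from_genes(genes))
        rate = res.table["candidate"].mean()
        sd = np.sqrt(0.025 * 0.975 / n_genes)
        assert abs(rate - 0.025) < 4 * sd


class TestIntersection:
    def _result(self, screen, genes, species="human"):
        table = pd.DataFrame({"candidate": True}, index=list(genes))
        return ScreenResult(
            screen=screen,
            table=table,
            candidates=GeneSet.from_iterable(screen, genes, species=species),
        )

    def test_worked_examples(self):
        omap = OrthologMap.identity(["A", "B", "C"])
        r = intersect_candidates(
            [self._result("microarray", ["A", "B", "C"]), self._result("cohort", ["B", "C"])],
            self._result("rnaseq", ["C"], species="mouse"),
            omap,
        )
        assert r.intersection.members == frozenset({"C"})
        assert r.pairwise_sizes["microarray&cohort"] == 2

        disjoint = intersect_candidates(
            [self._result("microarray", ["A"]), self._result("cohort", ["B"])],
            self._result("rnaseq", ["C"], species="mouse"),
            omap,
        )
        assert disjoint.intersection.members == frozenset()

    def test_unmapped_mouse_symbols_reported(self):
        omap = OrthologMap(pairs=[("A", "A")])
        r = intersect_candidates(
            [self._result("microarray", ["A"]), self._result("cohort", ["A"])],
            self._result("rnaseq", ["A", "Zz1"], species="mouse"),
            omap,
        )
        assert r.unmapped_mouse_symbols == ["Zz1"]
        assert r.intersection.members == frozenset({"A"})


@pytest.fixture(scope="module")
def fixture_bundle():
    from p53screen.synthetic_data import SimulationConfig, simulate_bundle

    return simulate_bundle(
        SimulationConfig(n_genes=20, n_true_repressed=6, n_prognostic=3,
                         cohort_n=(60, 30), seed=13)
    )


class TestBruteForceOracle:
    """Gene-for-gene agreement with direct reimplementations of each
    criterion on a 20-gene noisy fixture."""

    def test_microarray_oracle(self, fixture_bundle):
        b = fixture_bundle
        res = screen_microarray(b.microarray, b.microarray_design, b.probe_map)
        vals = b.microarray.values
        treated = [f"MA_W{t}" for t in (12, 24, 48)]
        baseline = ["MA_W0"] + [f"MA_K{t}" for t in (0, 12, 24, 48)]
        expected: dict[str, bool] = {}
        for probe in b.microarray.feature_ids:
            gene = b.probe_map.gene_of(probe)
            A = float(np.median([vals.loc[probe, s] for s in treated]))
            B = float(min(vals.loc[probe, s] for s in baseline))
            hit = B > 0 and A / B < 0.5
            expected[gene] = expected.get(gene, False) or hit
        assert dict(res.table["candidate"]) == expected

    def test_rnaseq_oracle(self, fixture_bundle):
        b = fixture_bundle
        res = screen_rnaseq(b.rnaseq, b.rnaseq_design)
        codes = b.rnaseq_design.codes
        tissue = b.rnaseq_design.table.set_index("sample_id")["tissue"]
        for gene in b.rnaseq.feature_ids:
            means = {}
            for code in ("W", "WX", "KX", "K"):
                samples = [
                    s for s in b.rnaseq.sample_ids
                    if codes[s] == code and tissue[s] == "mammary_gland"
                ]
                means[code] = float(
                    np.mean([b.rnaseq.values.loc[gene, s] + 1.0 for s in samples])
                )
            ratio = means["WX"] / min(means["W"], means["KX"], means["K"])
            assert res.table.loc[gene, "ratio"] == pytest.approx(ratio, rel=1e-12)
            assert res.table.loc[gene, "candidate"] == (ratio < 0.5)

    def test_cohort_oracle(self, fixture_bundle):
        from scipy import stats

        b = fixture_bundle
        res = screen_cohort(b.cohort)
        wt = b.cohort.table["p53_status"] == "wt"
        for gene in b.cohort.gene_columns:
            x = b.cohort.table.loc[wt, gene].to_numpy()
            y = b.cohort.table.loc[~wt, gene].to_numpy()
            f = np.var(x, ddof=1) / np.var(y, ddof=1)
            cdf = stats.f.cdf(f, len(x) - 1, len(y) - 1)
            equal_var = 2 * min(cdf, 1 - cdf) >= 0.05
            p = stats.ttest_ind(x, y, equal_var=equal_var).pvalue
            expected = (p < 0.05) and (np.mean(x) < np.mean(y))
            assert res.table.loc[gene, "candidate"] == expected

    def test_noise_free_planted_recovery(self, noisefree_bundle):
        b = noisefree_bundle
        planted = b.truth.true_repressed.members
        ma = screen_microarray(b.microarray, b.microarray_design, b.probe_map)
        assert ma.candidates.members == planted
        co = screen_cohort(b.cohort)
        assert co.candidates.members == planted
        rs = screen_rnaseq(b.rnaseq, b.rnaseq_design)
        mapped, unmapped = b.orthologs.to_human(rs.candidates.members)
        assert not unmapped
        assert mapped == planted


class TestTissueProfile:
    def test_log_ratios(self):
        expr, design = _rnaseq_fixture(5, 5, 5, 5)
        prof = tissue_profile(expr, design, GeneSet.from_iterable("g", ["Gene1"]))
        assert prof.loc["Gene1", "mammary_gland"] == pytest.approx(0.0)
        # irradiated mean at (2*mean + pseudocount) = half of control after shift
        expr2, design2 = _rnaseq_fixture(9, 4, 9, 9)
        prof2 = tissue_profile(expr2, design2, GeneSet.from_iterable("g", ["Gene1"]))
        assert prof2.loc["Gene1", "mammary_gland"] == pytest.approx(-1.0)

    def test_planted_module_suppressed_only_in_configured_tissues(self, noisefree_bundle):
        b = noisefree_bundle
        prof = tissue_profile(b.rnaseq, b.rnaseq_design, b.truth.true_repressed)
        fold_log2 = -np.log2(b.config.repression_fold)
        for tissue in prof.columns:
            expected = fold_log2 if tissue in b.truth.repressed_tissues else 0.0
            # pseudocount damps the planted log-fold; sign and magnitude order hold
            if expected < 0:
                assert (prof[tissue] < expected / 2).all()
            else:
                assert np.allclose(prof[tissue], 0.0, atol=1e-9)
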