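"""Comparative-Ct arithmetic, its invariances, and the three-stage module
classifier."""

import numpy as np
import pandas as pd
import pytest

from p53screen.data_model import GeneSet, ValidationError
from p53screen.qpcr import (
    CtTable,
    FoldChangeResult,
    ModuleCallParams,
    call_module,
    classify_adr_repressed,
    compute_ddct,
    run_module_call,
    validate_exogenous_p53,
    validate_knockdown,
)


def _ct_table(rows, reference="ACTB", statuses=None):
    return CtTable(
        records=pd.DataFrame(rows, columns=["gene", "cell_line", "condition", "replicate", "ct"]),
        reference_gene=reference,
        line_status=statuses or {},
    )


def _simple_table(ct_case_gene, ct_case_ref, ct_ctrl_gene, ct_ctrl_ref, n_rep=1):
    rows = []
    for rep in range(1, n_rep + 1):
        rows += [
            ("PLK1", "L1", "case", rep, ct_case_gene),
            ("ACTB", "L1", "case", rep, ct_case_ref),
            ("PLK1", "L1", "ctrl", rep, ct_ctrl_gene),
            ("ACTB", "L1", "ctrl", rep, ct_ctrl_ref),
        ]
    return _ct_table(rows)


class TestComputeDdct:
    def test_worked_arithmetic(self):
        # dCt case = 25-20 = 5; dCt control = 22-20 = 2; ddCt = 3
        fc = compute_ddct(_simple_table(25, 20, 22, 20), "PLK1", "L1", "case", "ctrl")
        assert fc.delta_delta_ct == pytest.approx(3.0)
        assert fc.log2fc == pytest.approx(-3.0)
        assert fc.fold == pytest.approx(0.125)

    def test_identity_on_equal_conditions(self):
        fc = compute_ddct(_simple_table(24, 20, 24, 20), "PLK1", "L1", "case", "ctrl")
        assert fc.log2fc == 0.0
        assert fc.fold == 1.0

    def test_single_replicate_has_no_sd_or_p(self):
        fc = compute_ddct(_simple_table(25, 20, 22, 20, n_rep=1), "PLK1", "L1", "case", "ctrl")
        assert fc.sd is None and fc.p_value is None
        fc3 = compute_ddct(_simple_table(25, 20, 22, 20, n_rep=3), "PLK1", "L1", "case", "ctrl")
        assert fc3.sd == 0.0 and fc3.p_value in (0.0, 1.0)

    def test_missing_reference_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="reference gene missing"):
            _ct_table(
                [("PLK1", "L1", "case", 1, 25.0), ("ACTB", "L1", "ctrl", 1, 20.0),
                 ("PLK1", "L1", "ctrl", 1, 22.0)]
            )

    def test_antisymmetry_and_offset_invariance(self):
        """Swapping case and control negates log2FC; adding a constant to all
        Ct values of one (line, condition, replicate) — reference included —
        leaves it unchanged."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            cts = rng.uniform(15, 32, size=4)
            base = _simple_table(*cts)
            fwd = compute_ddct(base, "PLK1", "L1", "case", "ctrl")
            rev = compute_ddct(base, "PLK1", "L1", "ctrl", "case")
            assert fwd.log2fc == pytest.approx(-rev.log2fc, abs=1e-12)

            offset = rng.uniform(-3, 3)
            shifted = base.records.copy()
            mask = shifted["condition"] == "case"
            shifted.loc[mask, "ct"] += offset
            shifted_table = _ct_table(shifted.to_records(index=False).tolist())
            after = compute_ddct(shifted_table, "PLK1", "L1", "case", "ctrl")
            assert after.log2fc == pytest.approx(fwd.log2fc, abs=1e-9)


def _fc(gene, line, log2fc):
    return FoldChangeResult(
        gene=gene, cell_line=line, case_condition="ADR", control_condition="untreated",
        delta_delta_ct=-log2fc, log2fc=log2fc, fold=2.0 ** log2fc,
        sd=0.1, p_value=0.01, n_case=3, n_control=3,
    )


class TestPanelClassifier:
    STATUSES = {"W1": "wt", "W2": "wt", "W3": "wt", "W4": "wt",
                "M1": "mut", "M2": "mut", "M3": "mut"}

    def _call(self, wt_fcs, mut_fcs):
        fcs = [_fc("G", f"W{i+1}", v) for i, v in enumerate(wt_fcs)]
        fcs += [_fc("G", f"M{i+1}", v) for i, v in enumerate(mut_fcs)]
        return classify_adr_repressed(fcs, self.STATUSES)

    def test_cutoff_is_inclusive(self):
        call = self._call([-2.0, -2.0, 0, 0], [0, 0, 0])
        assert call.n_wt_repressed == 2
        assert call.passed

    def test_mutant_repression_disqualifies(self):
        assert not self._call([-3, -3, 0, 0], [-2.5, 0, 0]).passed

    def test_all_wt_no_mut_passes(self):
        assert self._call([-3, -3, -3, -3], [0, 0, 0]).passed

    def test_one_wt_line_insufficient(self):
        assert not self._call([-3, -1, 0, 0], [0, 0, 0]).passed


class TestValidationStages:
    @pytest.mark.parametrize(
        "ctrl,si,expected,vacuous",
        [(-3.0, -0.2, True, False), (-3.0, -2.5, False, False), (-1.0, 0.0, False, True)],
    )
    def test_knockdown(self, ctrl, si, expected, vacuous):
        call = validate_knockdown(_fc("G", "L", ctrl), _fc("G", "L", si))
        assert call.dependent is expected
        assert call.suppressed_in_control is (not vacuous)

    @pytest.mark.parametrize(
        "adp53,adlacz,expected",
        [(-4.0, -0.3, True), (-4.0, -2.5, False), (-1.9, 0.0, False), (-2.0, 0.0, True)],
    )
    def test_exogenous(self, adp53, adlacz, expected):
        call = validate_exogenous_p53(_fc("G", "L", adp53), _fc("G", "L", adlacz))
        assert call.repressed_by_p53 is expected


class TestCallModule:
    def _calls(self, genes_cfg):
        """genes_cfg: gene -> (panel_pass, kd_dependent, exo_pass)."""
        from p53screen.qpcr import ExogenousCall, KnockdownCall, PanelCall

        panel, kd, exo = {}, {}, {}
        for g, (p, k, e) in genes_cfg.items():
            panel[g] = PanelCall(g, p, 2 if p else 0, 0, {})
            kd[g] = KnockdownCall(g, k, True, -3.0, 0.0 if k else -3.0)
            exo[g] = ExogenousCall(g, e, -3.0 if e else -1.0, 0.0)
        return panel, kd, exo

    def test_stagewise_exclusion_reasons(self):
        cfg = {
            "PASSES": (True, True, True),
            "FAILS_PANEL": (False, True, True),
            "FAILS_KD": (True, False, True),
            "FAILS_EXO": (True, True, False),
        }
        candidates = GeneSet.from_iterable("c", cfg)
        result = call_module(candidates, *self._calls(cfg))
        assert result.module.members == frozenset({"PASSES"})
        assert result.audit.loc["FAILS_PANEL", "excluded_at"] == "adr_panel"
        assert result.audit.loc["FAILS_KD", "excluded_at"] == "knockdown"
        assert result.audit.loc["FAILS_EXO", "excluded_at"] == "exogenous_p53"

    def test_validation_stages_can_be_disabled(self):
        cfg = {"FAILS_EXO": (True, True, False)}
        candidates = GeneSet.from_iterable("c", cfg)
        panel, kd, exo = self._calls(cfg)
        relaxed = ModuleCallParams(require_adp53_repression=False)
        result = call_module(candidates, panel, kd, None, relaxed)
        assert "FAILS_EXO" in result.module.members

    def test_missing_required_calls_raise(self):
        cfg = {"G": (True, True, True)}
        candidates = GeneSet.from_iterable("c", cfg)
        panel, kd, _ = self._calls(cfg)
        with pytest.raises(ValidationError):
            call_module(candidates, panel, kd, None)


class TestEndToEndModuleCall:
    def test_noise_free_planted_module_recovered(self, noisefree_bundle):
        b = noisefree_bundle
        planted = b.truth.true_repressed
        # candidates: the planted genes plus nulls that must all be rejected
        nulls = [g for g in b.cohort.gene_columns if g not in planted.members][:10]
        candidates = GeneSet.from_iterable("cand", sorted(planted.members) + nulls)
        result = run_module_call(
            candidates, b.qpcr["panel"], b.qpcr["knockdown"], b.qpcr["exogenous"]
        )
        assert result.module.members == planted.members
        assert (result.audit.loc[nulls, "excluded_at"] == "adr_panel").all()

    def test_module_grows_monotonically_with_looser_cutoff(self, small_bundle):
        b = small_bundle
        candidates = GeneSet.from_iterable("cand", list(b.cohort.gene_columns)[:30])
        strict = run_module_call(
            candidates, b.qpcr["panel"], b.qpcr["knockdown"], b.qpcr["exogenous"],
            ModuleCallParams(log2fc_cutoff=-2.5),
        )
        loose = run_module_call(
            candidates, b.qpcr["panel"], b.qpcr["knockdown"], b.qpcr["exogenous"],
            ModuleCallParams(log2fc_cutoff=-1.5),
        )
        assert strict.module.members <= loose.module.members
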