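"""Relative qPCR quantification (ddCt) and the three-stage module classifier.

Quantification follows the standard comparative-Ct scheme: per replicate the
target gene's cycle threshold is normalized to a reference gene
(dCt = Ct_gene - Ct_ref), conditions are contrasted on group means
(ddCt = mean dCt_case - mean dCt_control), and fold change = 2^-ddCt,
log2 fold change = -ddCt.  Replicates are not paired across conditions.

A gene joins the repressed module when it clears three stages:

1. **panel** — log2FC <= cutoff (default -2, inclusive) after genotoxic
   treatment in at least ``min_wt_lines`` p53 wild-type cell lines and at
   most ``max_mut_lines`` p53-mutant lines (defaults 2 of 4 / 0 of 3);
2. **knockdown** — the suppression seen under control siRNA is abrogated
   when p53 is silenced (log2FC back above the cutoff);
3. **exogenous p53** — ectopic wild-type p53 in a p53-mutant line reproduces
   the suppression while the control transduction does not.

Per-gene t-test p-values on dCt are reported for parity with significance
marks on figures but are not part of the membership criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneSet, ValidationError

REQUIRED_CT_COLUMNS = ("gene", "cell_line", "condition", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format cycle-threshold records plus panel metadata.

    ``records`` columns: gene, cell_line, condition, replicate, ct.
    ``line_status`` maps cell line -> p53 status in {"wt", "mut"}.
    The reference gene must be measured in every (cell_line, condition,
    replicate) in which any target gene is measured.
    """

    records: pd.DataFrame
    reference_gene: str
    line_status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(REQUIRED_CT_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
        if (self.records["ct"] <= 0).any() or self.records["ct"].isna().any():
            raise ValidationError("all Ct values must be positive")
        if self.reference_gene not in set(self.records["gene"]):
            raise ValidationError(f"reference gene {self.reference_gene!r} not measured")
        for status in self.line_status.values():
            if status not in ("wt", "mut"):
                raise ValidationError(f"p53 status must be wt|mut, got {status!r}")
        ref = self.records[self.records["gene"] == self.reference_gene]
        ref_keys = set(map(tuple, ref[["cell_line", "condition", "replicate"]].to_numpy()))
        tgt = self.records[self.records["gene"] != self.reference_gene]
        tgt_keys = set(map(tuple, tgt[["cell_line", "condition", "replicate"]].to_numpy()))
        if tgt_keys - ref_keys:
            example = sorted(tgt_keys - ref_keys)[0]
            raise ValidationError(
                f"reference gene missing for (cell_line, condition, replicate) {example}"
            )

    def genes(self) -> list[str]:
        return sorted(set(self.records["gene"]) - {self.reference_gene})

    def delta_ct(self, gene: str, cell_line: str, condition: str) -> np.ndarray:
        """Per-replicate dCt = Ct_gene - Ct_ref for one cell line/condition."""
        sub = self.records[
            (self.records["cell_line"] == cell_line)
            & (self.records["condition"] == condition)
        ]
        g = sub[sub["gene"] == gene].set_index("replicate")["ct"]
        r = sub[sub["gene"] == self.reference_gene].set_index("replicate")["ct"]
        if g.empty:
            raise ValidationError(
                f"no Ct for gene {gene!r} in {cell_line!r}/{condition!r}"
            )
        return (g - r.reindex(g.index)).to_numpy(dtype=float)


def read_ct_table(
    path: str | Path, reference_gene: str, line_status: Mapping[str, str] | None = None
) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    return CtTable(records=df, reference_gene=reference_gene,
                   line_status=dict(line_status or {}))


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ddCt
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeResult:
    gene: str
    cell_line: str
    case_condition: str
    control_condition: str
    delta_delta_ct: float
    log2fc: float
    fold: float
    sd: float | None          # SD of per-replicate case log2FC vs the control mean
    p_value: float | None     # two-tailed t-test on dCt, case vs control
    n_case: int
    n_control: int


def compute_ddct(
    ct: CtTable,
    gene: str,
    cell_line: str,
    case_condition: str,
    control_condition: str,
) -> FoldChangeResult:
    """Comparative-Ct contrast of one gene between two conditions of one
    cell line.  With a single replicate in either condition the point
    estimate is still computed but sd and p are unavailable (None)."""
    dct_case = ct.delta_ct(gene, cell_line, case_condition)
    dct_ctrl = ct.delta_ct(gene, cell_line, control_condition)
    ddct = float(np.mean(dct_case) - np.mean(dct_ctrl))
    log2fc = -ddct
    if len(dct_case) >= 2 and len(dct_ctrl) >= 2:
        per_rep_log2fc = -(dct_case - np.mean(dct_ctrl))
        sd = float(np.std(per_rep_log2fc, ddof=1))
        if np.var(dct_case, ddof=1) == 0 and np.var(dct_ctrl, ddof=1) == 0:
            p = 1.0 if ddct == 0 else 0.0
        else:
            p = float(stats.ttest_ind(dct_case, dct_ctrl, equal_var=True).pvalue)
    else:
        sd = None
        p = None
    return FoldChangeResult(
        gene=gene,
        cell_line=cell_line,
        case_condition=case_condition,
        control_condition=control_condition,
        delta_delta_ct=ddct,
        log2fc=log2fc,
        fold=float(2.0 ** log2fc),
        sd=sd,
        p_value=p,
        n_case=len(dct_case),
        n_control=len(dct_ctrl),
    )


# ---------------------------------------------------------------------------
# module-membership stages
# ---------------------------------------------------------------------------

@dataclass
class ModuleCallParams:
    log2fc_cutoff: float = -2.0
    min_wt_lines: int = 2
    max_mut_lines: int = 0
    require_knockdown_abrogation: bool = True
    require_adp53_repression: bool = True
    require_control_clean: bool = True  # the Ad-LacZ arm must stay above the cutoff

    def __post_init__(self) -> None:
        if self.log2fc_cutoff >= 0:
            raise ValidationError("log2fc_cutoff must be negative")
        if self.min_wt_lines < 1 or self.max_mut_lines < 0:
            raise ValidationError("line-count thresholds out of range")


@dataclass
class PanelCall:
    gene: str
    passed: bool
    n_wt_repressed: int
    n_mut_repressed: int
    log2fc_by_line: dict[str, float]


def classify_adr_repressed(
    fold_changes: Sequence[FoldChangeResult],
    line_status: Mapping[str, str],
    params: ModuleCallParams | None = None,
) -> PanelCall:
    """Stage 1: repressed (log2FC <= cutoff, inclusive) in enough wild-type
    lines and few enough mutant lines after genotoxic treatment."""
    params = params or ModuleCallParams()
    genes = {fc.gene for fc in fold_changes}
    if len(genes) != 1:
        raise ValidationError(f"one gene per panel call, got {sorted(genes)}")
    n_wt_total = sum(1 for s in line_status.values() if s == "wt")
    if n_wt_total < params.min_wt_lines:
        raise ValidationError(
            f"panel has {n_wt_total} wt lines, fewer than min_wt_lines={params.min_wt_lines}"
        )
    by_line = {fc.cell_line: fc.log2fc for fc in fold_changes}
    repressed = {line for line, fc in by_line.items() if fc <= params.log2fc_cutoff}
    n_wt = sum(1 for line in repressed if line_status[line] == "wt")
    n_mut = sum(1 for line in repressed if line_status[line] == "mut")
    return PanelCall(
        gene=genes.pop(),
        passed=(n_wt >= params.min_wt_lines) and (n_mut <= params.max_mut_lines),
        n_wt_repressed=n_wt,
        n_mut_repressed=n_mut,
        log2fc_by_line=by_line,
    )


@dataclass
class KnockdownCall:
    gene: str
    dependent: bool
    suppressed_in_control: bool   # vacuous-failure flag: never suppressed at all
    log2fc_control_si: float
    log2fc_p53_si: float


def validate_knockdown(
    fc_control_si: FoldChangeResult,
    fc_p53_si: FoldChangeResult,
    params: ModuleCallParams | None = None,
) -> KnockdownCall:
    """Stage 2: suppression under control siRNA + treatment must vanish when
    p53 is silenced.  A gene that was never suppressed under control siRNA
    fails, flagged as a vacuous case."""
    params = params or ModuleCallParams()
    if fc_control_si.gene != fc_p53_si.gene:
        raise ValidationError("knockdown contrasts refer to different genes")
    suppressed = fc_control_si.log2fc <= params.log2fc_cutoff
    abrogated = fc_p53_si.log2fc > params.log2fc_cutoff
    return KnockdownCall(
        gene=fc_control_si.gene,
        dependent=suppressed and abrogated,
        suppressed_in_control=suppressed,
        log2fc_control_si=fc_control_si.log2fc,
        log2fc_p53_si=fc_p53_si.log2fc,
    )


@dataclass
class ExogenousCall:
    gene: str
    repressed_by_p53: bool
    log2fc_adp53: float
    log2fc_adlacz: float


def validate_exogenous_p53(
    fc_adp53: FoldChangeResult,
    fc_adlacz: FoldChangeResult,
    params: ModuleCallParams | None = None,
) -> ExogenousCall:
    """Stage 3: ectopic wild-type p53 represses (log2FC <= cutoff) while the
    control transduction does not (strictly above the cutoff)."""
    params = params or ModuleCallParams()
    if fc_adp53.gene != fc_adlacz.gene:
        raise ValidationError("exogenous-p53 contrasts refer to different genes")
    repressed = fc_adp53.log2fc <= params.log2fc_cutoff
    control_clean = fc_adlacz.log2fc > params.log2fc_cutoff
    ok = repressed and (control_clean or not params.require_control_clean)
    return ExogenousCall(
        gene=fc_adp53.gene,
        repressed_by_p53=ok,
        log2fc_adp53=fc_adp53.log2fc,
        log2fc_adlacz=fc_adlacz.log2fc,
    )


@dataclass
class ModuleCallResult:
    module: GeneSet
    audit: pd.DataFrame  # per candidate: stage booleans + exclusion reason


def call_module(
    candidates: GeneSet,
    panel_calls: Mapping[str, PanelCall],
    knockdown_calls: Mapping[str, KnockdownCall] | None,
    exogenous_calls: Mapping[str, ExogenousCall] | None,
    params: ModuleCallParams | None = None,
) -> ModuleCallResult:
    """Combine the three stages into the final module with a per-gene audit
    trail recording the first stage that excluded each non-member."""
    params = params or ModuleCallParams()
    if params.require_knockdown_abrogation and knockdown_calls is None:
        raise ValidationError("knockdown validation required but no calls supplied")
    if params.require_adp53_repression and exogenous_calls is None:
        raise ValidationError("exogenous-p53 validation required but no calls supplied")

    rows = {}
    members = []
    for gene in sorted(candidates.members):
        panel = panel_calls.get(gene)
        row = {
            "panel_pass": bool(panel and panel.passed),
            "knockdown_pass": None,
            "exogenous_pass": None,
            "member": False,
            "excluded_at": None,
        }
        if panel is None or not panel.passed:
            row["excluded_at"] = "adr_panel"
        else:
            ok = True
            if params.require_knockdown_abrogation:
                kd = knockdown_calls.get(gene)
                row["knockdown_pass"] = bool(kd and kd.dependent)
                if not row["knockdown_pass"]:
                    row["excluded_at"] = "knockdown"
                    ok = False
            if ok and params.require_adp53_repression:
                ex = exogenous_calls.get(gene)
                row["exogenous_pass"] = bool(ex and ex.repressed_by_p53)
                if not row["exogenous_pass"]:
                    row["excluded_at"] = "exogenous_p53"
                    ok = False
            row["member"] = ok
            if ok:
                members.append(gene)
        rows[gene] = row
    audit = pd.DataFrame.from_dict(rows, orient="index")
    return ModuleCallResult(
        module=GeneSet(
            name="repressed_module",
            members=frozenset(members),
            provenance="panel + knockdown + exogenous p53 validation",
        ),
        audit=audit,
    )


# ---------------------------------------------------------------------------
# convenience driver over a generated/loaded Ct-table ensemble
# ---------------------------------------------------------------------------

PANEL_CASE, PANEL_CONTROL = "ADR", "untreated"
KD_BASELINE = "mock"
KD_CONTROL_SI, KD_P53_SI = "siEGFP_ADR", "sip53_ADR"
EXO_BASELINE, EXO_LACZ, EXO_P53 = "untransduced", "AdLacZ", "Adp53"


def run_module_call(
    candidates: GeneSet,
    panel: CtTable,
    knockdown: CtTable | None,
    exogenous: CtTable | None,
    params: ModuleCallParams | None = None,
) -> ModuleCallResult:
    """Full classifier over the standard three Ct tables (cell-line panel,
    siRNA knockdown, adenoviral transduction) using the canonical condition
    labels."""
    params = params or ModuleCallParams()
    panel_calls: dict[str, PanelCall] = {}
    kd_calls: dict[str, KnockdownCall] | None = None
    exo_calls: dict[str, ExogenousCall] | None = None

    for gene in sorted(candidates.members):
        fcs = [
            compute_ddct(panel, gene, line, PANEL_CASE, PANEL_CONTROL)
            for line in sorted(panel.line_status)
        ]
        panel_calls[gene] = classify_adr_repressed(fcs, panel.line_status, params)

    if knockdown is not None:
        kd_line = sorted(set(knockdown.records["cell_line"]))[0]
        kd_calls = {}
        for gene in sorted(candidates.members):
            fc_ctrl = compute_ddct(knockdown, gene, kd_line, KD_CONTROL_SI, KD_BASELINE)
            fc_p53 = compute_ddct(knockdown, gene, kd_line, KD_P53_SI, KD_BASELINE)
            kd_calls[gene] = validate_knockdown(fc_ctrl, fc_p53, params)

    if exogenous is not None:
        exo_line = sorted(set(exogenous.records["cell_line"]))[0]
        exo_calls = {}
        for gene in sorted(candidates.members):
            fc_p53 = compute_ddct(exogenous, gene, exo_line, EXO_P53, EXO_BASELINE)
            fc_lacz = compute_ddct(exogenous, gene, exo_line, EXO_LACZ, EXO_BASELINE)
            exo_calls[gene] = validate_exogenous_p53(fc_p53, fc_lacz, params)

    return call_module(candidates, panel_calls, kd_calls, exo_calls, params)
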