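"""The three candidate screens, their intersection, and the multi-tissue
expression profile.

Each screen extracts candidate repressed genes from one modality:

* **microarray** (probe level, ADR time course in p53 wild-type vs knockout
  mammary epithelial cells): per probe, A = median expression over the
  treated wild-type timepoints (W12, W24, W48) and B = minimum over the
  untreated wild-type baseline (W0) and all knockout samples (K0-K48);
  candidate iff A/B < 0.5 (strict).
* **RNA-seq** (gene level, FPKM, irradiated vs control mice): a pseudocount
  of 1 is added to every FPKM value first, then A = mean over irradiated
  wild-type (WX) and B = the minimum of the mean expressions of the other
  three arms (W, KX, K); candidate iff A/B < 0.5.
* **cohort** (tumor expression by somatic p53 status): per gene, an unpaired
  two-tailed t-test between wild-type and mutant tumors, with an F-test at
  alpha = 0.05 choosing the pooled or Welch variant; candidate iff p < 0.05
  and the wild-type mean is the lower one.  No multiple-testing correction.

Candidates from the mouse screen are translated through an ortholog map and
intersected with the two human screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    ExpressionMatrix,
    GeneSet,
    OrthologMap,
    ProbeGeneMap,
    SampleDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

MICROARRAY_TREATED_CODES = ("W12", "W24", "W48")
MICROARRAY_BASELINE_CODES = ("W0", "K0", "K12", "K24", "K48")


@dataclass
class MicroarrayScreenParams:
    ratio_threshold: float = 0.5
    probe_collapse: str = "any_probe"  # or "median_probe"

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValidationError("ratio_threshold must be positive")
        if self.probe_collapse not in ("any_probe", "median_probe"):
            raise ValidationError(f"unknown probe_collapse {self.probe_collapse!r}")


@dataclass
class RnaseqScreenParams:
    pseudocount: float = 1.0
    ratio_threshold: float = 0.5
    screen_tissue: str = "mammary_gland"

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")


@dataclass
class CohortScreenParams:
    alpha: float = 0.05
    variance_rule: str = "f_test_gate"  # or "welch_always"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.variance_rule not in ("f_test_gate", "welch_always"):
            raise ValidationError(f"unknown variance_rule {self.variance_rule!r}")


@dataclass
class ScreenResult:
    """Per-gene statistics and candidate calls for one screen.

    ``table`` is indexed by gene with at least the columns the screen's
    criterion used plus a boolean ``candidate``; ``probe_table`` (microarray
    only) keeps the probe-level detail behind the gene-level collapse.
    """

    screen: str
    table: pd.DataFrame
    candidates: GeneSet
    probe_table: pd.DataFrame | None = None
    n_non_evaluable: int = 0

    def __post_init__(self) -> None:
        if "candidate" not in self.table.columns:
            raise ValidationError("result table must carry a candidate column")


# ---------------------------------------------------------------------------
# microarray screen
# ---------------------------------------------------------------------------

def screen_microarray(
    expr: ExpressionMatrix,
    design: SampleDesign,
    probe_map: ProbeGeneMap,
    params: MicroarrayScreenParams | None = None,
) -> ScreenResult:
    """Probe-level ratio screen on the ADR time course.

    Probes with B = 0 cannot be evaluated (undefined ratio) and are excluded
    with a logged count rather than raising.  Gene candidacy collapses probe
    hits by ``params.probe_collapse``: ``any_probe`` (default) marks a gene
    if any of its probes passes; ``median_probe`` applies the threshold to
    the median probe ratio.
    """
    params = params or MicroarrayScreenParams()
    treated = design.samples_for(*MICROARRAY_TREATED_CODES)
    baseline = design.samples_for(*MICROARRAY_BASELINE_CODES)
    for codes, samples in ((MICROARRAY_TREATED_CODES, treated),
                           (MICROARRAY_BASELINE_CODES, baseline)):
        if not samples:
            raise ValidationError(f"no samples for condition codes {codes}")
    missing = set(MICROARRAY_TREATED_CODES + MICROARRAY_BASELINE_CODES) - set(
        design.table["condition_code"]
    )
    if missing:
        raise ValidationError(f"missing condition codes: {sorted(missing)}")

    A = expr.values[treated].median(axis=1)
    B = expr.values[baseline].min(axis=1)
    evaluable = B > 0
    n_bad = int((~evaluable).sum())
    if n_bad:
        logger.info("microarray screen: %d probes with zero baseline excluded", n_bad)
    ratio = A[evaluable] / B[evaluable]
    probe_hit = ratio < params.ratio_threshold

    probe_table = pd.DataFrame(
        {
            "gene": [probe_map.gene_of(p) for p in ratio.index],
            "A": A[evaluable],
            "B": B[evaluable],
            "ratio": ratio,
            "hit": probe_hit,
        }
    )
    if params.probe_collapse == "any_probe":
        gene_candidate = probe_table.groupby("gene")["hit"].any()
    else:
        gene_candidate = (
            probe_table.groupby("gene")["ratio"].median() < params.ratio_threshold
        )
    gene_table = pd.DataFrame(
        {
            "ratio": probe_table.groupby("gene")["ratio"].min(),
            "n_probes": probe_table.groupby("gene").size(),
            "candidate": gene_candidate,
        }
    )
    candidates = GeneSet.from_iterable(
        "microarray_candidates",
        gene_table.index[gene_table["candidate"]],
        provenance="ADR time-course ratio screen",
    )
    return ScreenResult(
        screen="microarray",
        table=gene_table,
        candidates=candidates,
        probe_table=probe_table,
        n_non_evaluable=n_bad,
    )


# ---------------------------------------------------------------------------
# RNA-seq screen
# ---------------------------------------------------------------------------

def screen_rnaseq(
    expr: ExpressionMatrix,
    design: SampleDesign,
    params: RnaseqScreenParams | None = None,
) -> ScreenResult:
    """Gene-level FPKM ratio screen on the irradiation design, restricted to
    one tissue (the screen tissue; other tissues only enter the profile in
    :func:`tissue_profile`)."""
    params = params or RnaseqScreenParams()
    groups = {}
    for code in ("WX", "W", "KX", "K"):
        samples = design.samples_for(code, tissue=params.screen_tissue)
        if not samples:
            raise ValidationError(
                f"no {code} samples for tissue {params.screen_tissue!r}"
            )
        groups[code] = samples

    # pseudocount added per sample value, before any averaging
    shifted = expr.values + params.pseudocount
    means = {code: shifted[samples].mean(axis=1) for code, samples in groups.items()}
    A = means["WX"]
    B = pd.concat([means["W"], means["KX"], means["K"]], axis=1).min(axis=1)
    ratio = A / B
    table = pd.DataFrame(
        {
            "A": A,
            "B": B,
            "mean_W": means["W"],
            "mean_KX": means["KX"],
            "mean_K": means["K"],
            "ratio": ratio,
            "candidate": ratio < params.ratio_threshold,
        }
    )
    candidates = GeneSet.from_iterable(
        "rnaseq_candidates",
        table.index[table["candidate"]],
        species="mouse",
        provenance=f"irradiation ratio screen, {params.screen_tissue}",
    )
    return ScreenResult(screen="rnaseq", table=table, candidates=candidates)


# ---------------------------------------------------------------------------
# cohort screen
# ---------------------------------------------------------------------------

def _gene_ttest(wt: np.ndarray, mut: np.ndarray, variance_rule: str) -> tuple[float, bool]:
    """Two-tailed two-sample t-test p-value and the equal-variance choice.

    Degenerate case: zero variance in both groups -> p = 1 if the means are
    equal, else p = 0 (the separation is infinite in units of the noise).
    """
    # constant groups: np.var on identical values returns rounding jitter
    # (~1e-27), so degeneracy is detected by element equality
    if np.all(wt == wt[0]) and np.all(mut == mut[0]):
        return (1.0, True) if wt[0] == mut[0] else (0.0, True)
    v_wt, v_mut = np.var(wt, ddof=1), np.var(mut, ddof=1)
    if variance_rule == "welch_always":
        equal_var = False
    else:
        # two-sided F-test on the variance ratio gates pooled vs Welch
        f = v_wt / v_mut if v_mut > 0 else np.inf
        if np.isinf(f):
            p_f = 0.0
        else:
            cdf = stats.f.cdf(f, len(wt) - 1, len(mut) - 1)
            p_f = 2 * min(cdf, 1 - cdf)
        equal_var = p_f >= 0.05
    p = stats.ttest_ind(wt, mut, equal_var=equal_var).pvalue
    return float(p), equal_var


def screen_cohort(
    cohort: "CohortTable",  # noqa: F821 - survival module type, duck-typed here
    params: CohortScreenParams | None = None,
) -> ScreenResult:
    """Per-gene t-test screen: candidate iff the wild-type-p53 tumors have
    significantly lower mean expression than the p53-mutant tumors."""
    params = params or CohortScreenParams()
    status = cohort.table["p53_status"]
    wt_idx = status == "wt"
    mut_idx = status == "mut"
    if not wt_idx.any() or not mut_idx.any():
        raise ValidationError("both p53 status groups must be non-empty")

    rows = {}
    for gene in cohort.gene_columns:
        wt = cohort.table.loc[wt_idx, gene].to_numpy(dtype=float)
        mut = cohort.table.loc[mut_idx, gene].to_numpy(dtype=float)
        p, equal_var = _gene_ttest(wt, mut, params.variance_rule)
        mean_wt, mean_mut = float(np.mean(wt)), float(np.mean(mut))
        rows[gene] = {
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "p_value": p,
            "pooled_variance": equal_var,
            "candidate": (p < params.alpha) and (mean_wt < mean_mut),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    candidates = GeneSet.from_iterable(
        "cohort_candidates",
        table.index[table["candidate"]],
        provenance="tumor cohort t-test screen",
    )
    return ScreenResult(screen="cohort", table=table, candidates=candidates)


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------

@dataclass
class IntersectionReport:
    intersection: GeneSet
    set_sizes: dict[str, int]
    pairwise_sizes: dict[str, int]
    unmapped_mouse_symbols: list[str] = field(default_factory=list)


def intersect_candidates(
    human_results: Sequence[ScreenResult],
    mouse_result: ScreenResult,
    orthologs: OrthologMap,
) -> IntersectionReport:
    """Intersect the human candidate sets with the ortholog-translated mouse
    set; reports all pairwise overlap sizes (the Venn counts) and any mouse
    symbols without an ortholog."""
    named: dict[str, set[str]] = {
        res.screen: set(res.candidates.members) for res in human_results
    }
    mouse_mapped, unmapped = orthologs.to_human(mouse_result.candidates.members)
    if unmapped:
        logger.warning("%d mouse candidates had no ortholog", len(unmapped))
    named[mouse_result.screen] = mouse_mapped

    names = list(named)
    common = set.intersection(*named.values()) if named else set()
    pairwise = {
        f"{x}&{y}": len(named[x] & named[y])
        for i, x in enumerate(names)
        for y in names[i + 1:]
    }
    return IntersectionReport(
        intersection=GeneSet(
            name="repressed_candidates",
            members=frozenset(common),
            provenance="intersection of " + "+".join(names),
        ),
        set_sizes={k: len(v) for k, v in named.items()},
        pairwise_sizes=pairwise,
        unmapped_mouse_symbols=unmapped,
    )


# ---------------------------------------------------------------------------
# multi-tissue profile
# ---------------------------------------------------------------------------

def tissue_profile(
    expr: ExpressionMatrix,
    design: SampleDesign,
    genes: GeneSet,
    genotype: str = "p53_wt",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 ratio of mean irradiated to mean non-irradiated expression per
    gene per tissue, for one genotype arm.

    The pseudocount is applied per sample value (same convention as the
    RNA-seq screen).  Tissues lacking either arm are omitted with a warning.
    """
    if genotype not in ("p53_wt", "p53_null"):
        raise ValidationError("genotype must be p53_wt or p53_null")
    irr_code = "WX" if genotype == "p53_wt" else "KX"
    ctl_code = "W" if genotype == "p53_wt" else "K"

    wanted = [g for g in expr.feature_ids if g.upper() in {m.upper() for m in genes.members}]
    shifted = expr.values.loc[wanted] + pseudocount
    tissues = sorted(set(design.table["tissue"].dropna()))
    cols = {}
    for tissue in tissues:
        irr = design.samples_for(irr_code, tissue=tissue)
        ctl = design.samples_for(ctl_code, tissue=tissue)
        if not irr or not ctl:
            logger.warning("tissue %r lacks one arm for %s; omitted", tissue, genotype)
            continue
        cols[tissue] = np.log2(shifted[irr].mean(axis=1) / shifted[ctl].mean(axis=1))
    if not cols:
        raise ValidationError("no tissue had both irradiated and control samples")
    return pd.DataFrame(cols)
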