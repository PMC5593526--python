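"""Synthetic dataset generators with a planted ground-truth repressed module.

Every input modality of the pipeline can be generated here with a shared
planted truth, so each stage — and the full pipeline — can be exercised and
scored without any external download:

* an ADR time-course probe-level microarray (wild-type vs p53-null cell
  lines, 0/12/24/48 h);
* a multi-tissue irradiation RNA-seq FPKM table (wild-type vs p53-null
  mice, repression planted only in a configurable subset of tissues);
* a tumor cohort with p53 status, expression, and exponential survival
  times whose hazard is driven by a latent risk factor loaded onto the
  planted prognostic genes;
* qPCR cycle-threshold tables for the cell-line panel, the siRNA knockdown
  and the adenoviral-transduction experiments, simulated at the Ct level so
  the comparative-Ct arithmetic is genuinely exercised;
* TSS annotations and ChIP-seq-like peak intervals with per-group promoter
  probabilities.

Expression noise is multiplicative lognormal (abundances are positive and
every screen criterion is scale-based); qPCR noise is additive on Ct.  All
generators are deterministic given the config seed: each one draws from its
own RNG stream derived from the master seed by a stable label, so adding a
generator never perturbs another's output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    GeneSet,
    OrthologMap,
    ProbeGeneMap,
    SampleDesign,
    ValidationError,
    normalize_symbol,
)
from .enrichment import PeakSet, TssAnnotation
from .qpcr import (
    EXO_BASELINE,
    EXO_LACZ,
    EXO_P53,
    KD_BASELINE,
    KD_CONTROL_SI,
    KD_P53_SI,
    PANEL_CASE,
    PANEL_CONTROL,
    CtTable,
)
from .survival import CohortTable

DEFAULT_TISSUES = (
    "mammary_gland",
    "uterus",
    "thymus",
    "liver",
    "lung",
    "spleen",
    "kidney",
    "colon",
)
DEFAULT_REPRESSED_TISSUES = ("mammary_gland", "uterus", "thymus")
# tissues sampled with two animals per arm instead of three
SMALL_N_TISSUES = ("mammary_gland", "ovary")

REFERENCE_GENE = "ACTB"
REFERENCE_CT = 20.0
BASELINE_MEDIAN_DAYS = 1825.0  # median survival of the low-risk group (~5 y)
CENSOR_HORIZON_DAYS = 3650.0


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the planted-truth simulation.

    The defaults mirror the emulated study designs: a 4 wild-type / 3
    p53-mutant cell-line panel, a 795/298 wild-type/mutant tumor cohort,
    promoter-peak probabilities matching the reported proportions for
    induced genes vs the repressed module (0.426 vs 0.037), a planted
    expression fold of 4 (screen ratio 0.25 against the 0.5 cutoff) and a
    planted qPCR effect of -3 log2 units against the -2 cutoff.
    """

    n_genes: int = 1000
    n_true_repressed: int = 50
    repression_fold: float = 4.0
    noise_sd_log: float = 0.2          # lognormal sigma on expression (natural log)
    ct_noise_sd: float = 0.15          # additive cycles on every Ct measurement
    qpcr_effect_log2: float = -3.0     # planted log2FC in responsive wt lines
    n_wt_lines: int = 4
    n_mut_lines: int = 3
    n_nonresponsive_wt: int = 1        # wt lines that never respond (SV40-like)
    peak_enrichment_prob: tuple[float, float] = (0.426, 0.037)
    cohort_n: tuple[int, int] = (795, 298)   # (wild-type p53, p53 mutant)
    hazard_ratio_high: float = 3.0
    n_prognostic: int = 9
    risk_loading: float = 0.8          # log-scale loading of the latent risk factor
    p21_dependent_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_true_repressed < 0:
            raise ValidationError("counts must be positive")
        if self.n_true_repressed > self.n_genes:
            raise ValidationError("n_true_repressed exceeds n_genes")
        if self.repression_fold <= 1:
            raise ValidationError("repression_fold must be > 1")
        if not all(0 <= p <= 1 for p in self.peak_enrichment_prob):
            raise ValidationError("peak probabilities must be in [0, 1]")
        if self.noise_sd_log < 0 or self.ct_noise_sd < 0:
            raise ValidationError("noise levels must be >= 0")
        if self.n_prognostic > self.n_true_repressed:
            raise ValidationError("n_prognostic exceeds n_true_repressed")
        if min(self.cohort_n) <= 0:
            raise ValidationError("cohort groups must be non-empty")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every dataset; pipeline stages never
    read it — it exists for recovery scoring only."""

    true_repressed: GeneSet
    prognostic: GeneSet
    p21_dependent: GeneSet
    repressed_tissues: tuple[str, ...]
    nonresponsive_wt_lines: tuple[str, ...]
    effects: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.true_repressed.members)
        return pd.DataFrame(
            {
                "gene": genes,
                "prognostic": [g in self.prognostic.members for g in genes],
                "p21_dependent": [g in self.p21_dependent.members for g in genes],
            }
        )


def _rng(config: SimulationConfig, label: str) -> np.random.Generator:
    """One independent, label-stable stream per generator."""
    return np.random.default_rng([config.seed, zlib.crc32(label.encode())])


def gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"GENE{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    genes = gene_ids(config)
    rng = _rng(config, "truth")
    planted = sorted(rng.choice(genes, size=config.n_true_repressed, replace=False))
    prognostic = planted[: config.n_prognostic]
    n_p21 = int(round(config.p21_dependent_fraction * len(planted)))
    p21_dep = sorted(rng.choice(planted, size=n_p21, replace=False))
    return GroundTruth(
        true_repressed=GeneSet.from_iterable("planted_repressed", planted,
                                             provenance="simulation"),
        prognostic=GeneSet.from_iterable("planted_prognostic", prognostic,
                                         provenance="simulation"),
        p21_dependent=GeneSet.from_iterable("planted_p21_dependent", p21_dep,
                                            provenance="simulation"),
        repressed_tissues=DEFAULT_REPRESSED_TISSUES,
        nonresponsive_wt_lines=tuple(
            f"WT{i}" for i in range(1, config.n_nonresponsive_wt + 1)
        ),
        effects={
            "repression_fold": config.repression_fold,
            "qpcr_effect_log2": config.qpcr_effect_log2,
            "hazard_ratio_high": config.hazard_ratio_high,
        },
    )


# ---------------------------------------------------------------------------
# microarray
# ---------------------------------------------------------------------------

def simulate_microarray(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, ProbeGeneMap, GroundTruth]:
    """ADR time-course microarray: one array per condition code (W0-W48,
    K0-K48), 1-3 probes per gene, planted genes reduced by the repression
    fold in the treated wild-type timepoints only."""
    truth = _ground_truth(config)
    rng = _rng(config, "microarray")
    genes = gene_ids(config)
    planted = truth.true_repressed.members

    conditions = [f"{arm}{t}" for arm in ("W", "K") for t in (0, 12, 24, 48)]
    samples = [f"MA_{c}" for c in conditions]
    treated = {"MA_W12", "MA_W24", "MA_W48"}

    probe_rows = []
    probe_ids = []
    mapping = {}
    n_probes = rng.integers(1, 4, size=len(genes))
    for gene, k in zip(genes, n_probes):
        base_gene = 100.0 * rng.lognormal(0.0, 1.0)
        for j in range(1, k + 1):
            probe = f"{gene}_p{j}"
            probe_ids.append(probe)
            mapping[probe] = gene
            base = base_gene * rng.lognormal(0.0, 0.3)
            row = []
            for sample in samples:
                level = base
                if gene in planted and sample in treated:
                    level /= config.repression_fold
                row.append(level * rng.lognormal(0.0, config.noise_sd_log))
            probe_rows.append(row)

    values = pd.DataFrame(probe_rows, index=probe_ids, columns=samples)
    expr = ExpressionMatrix(values=values, feature_kind="probe")
    design = SampleDesign.from_records(
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
    return expr, design, ProbeGeneMap(mapping=mapping), truth


# ---------------------------------------------------------------------------
# RNA-seq tissues
# ---------------------------------------------------------------------------

def simulate_rnaseq_tissues(
    config: SimulationConfig,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    repressed_tissues: Sequence[str] = DEFAULT_REPRESSED_TISSUES,
    unexpressed_fraction: float = 0.05,
) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth]:
    """Multi-tissue irradiation FPKM table (mouse gene symbols).

    Repression is planted only in irradiated wild-type samples of the
    configured tissues.  A fraction of non-planted genes is unexpressed
    (FPKM 0 everywhere) to exercise the pseudocount; planted-gene baselines
    are floored at 8 FPKM so the fold-4 effect is unambiguous against the
    +1 pseudocount.
    """
    truth = _ground_truth(config)
    rng = _rng(config, "rnaseq")
    genes_h = gene_ids(config)
    genes_m = [normalize_symbol(g, "mouse") for g in genes_h]
    planted_h = truth.true_repressed.members

    baselines = 30.0 * rng.lognormal(0.0, 1.0, size=len(genes_h))
    unexpressed = rng.random(len(genes_h)) < unexpressed_fraction
    for i, g in enumerate(genes_h):
        if g in planted_h:
            unexpressed[i] = False
            baselines[i] = max(baselines[i], 8.0)
    baselines[unexpressed] = 0.0

    records = []
    columns: dict[str, np.ndarray] = {}
    for tissue in tissues:
        n_rep = 2 if tissue in SMALL_N_TISSUES else 3
        for arm, irradiated in (("W", False), ("WX", True), ("K", False), ("KX", True)):
            genotype = "p53_wt" if arm.startswith("W") else "p53_null"
            for rep in range(1, n_rep + 1):
                sample = f"{tissue}_{arm}_{rep}"
                level = baselines.copy()
                if irradiated and genotype == "p53_wt" and tissue in repressed_tissues:
                    for i, g in enumerate(genes_h):
                        if g in planted_h:
                            level[i] /= config.repression_fold
                noise = rng.lognormal(0.0, config.noise_sd_log, size=len(genes_h))
                columns[sample] = level * noise
                records.append(
                    {
                        "sample_id": sample,
                        "genotype": genotype,
                        "treatment": "irradiation" if irradiated else "none",
                        "timepoint": None,
                        "tissue": tissue,
                    }
                )

    values = pd.DataFrame(columns, index=genes_m)
    expr = ExpressionMatrix(values=values, feature_kind="gene")
    design = SampleDesign.from_records(records)
    return expr, design, truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> tuple[CohortTable, GroundTruth]:
    """Tumor cohort with p53 status, expression and survival.

    Planted genes have their mean reduced by the repression fold in
    wild-type-p53 tumors.  A latent standard-normal risk factor u (independent
    of p53 status) multiplies the expression of the prognostic planted genes
    by exp(risk_loading * u); event times are exponential with the hazard
    multiplied by ``hazard_ratio_high`` for patients with u > 0, with
    independent uniform censoring.  High expression of a prognostic gene is
    therefore associated with worse survival through u.
    """
    truth = _ground_truth(config)
    rng = _rng(config, "cohort")
    genes = gene_ids(config)
    n_wt, n_mut = config.cohort_n
    n = n_wt + n_mut
    status = np.array(["wt"] * n_wt + ["mut"] * n_mut)
    is_wt = status == "wt"

    u = rng.normal(0.0, 1.0, size=n)
    baselines = 50.0 * rng.lognormal(0.0, 1.0, size=len(genes))
    planted = truth.true_repressed.members
    prognostic = truth.prognostic.members

    data = {}
    for i, gene in enumerate(genes):
        level = np.full(n, baselines[i])
        if gene in planted:
            level[is_wt] /= config.repression_fold
        if gene in prognostic:
            level = level * np.exp(config.risk_loading * u)
        noise = rng.lognormal(0.0, config.noise_sd_log, size=n)
        data[gene] = level * noise

    lam0 = np.log(2.0) / BASELINE_MEDIAN_DAYS
    hazard = lam0 * np.where(u > 0, config.hazard_ratio_high, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, CENSOR_HORIZON_DAYS, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "p53_status": status,
            "time_days": time,
            "event": event,
            **data,
        }
    )
    return CohortTable(table=table), truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def _ct_records(
    rng: np.random.Generator,
    genes: Sequence[str],
    delta_ct0: Mapping[tuple[str, str], float],
    cell_line: str,
    condition: str,
    shift_of: Mapping[str, float],
    ct_noise_sd: float,
    n_replicates: int = 3,
) -> list[dict]:
    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append(
            {
                "gene": REFERENCE_GENE,
                "cell_line": cell_line,
                "condition": condition,
                "replicate": rep,
                "ct": REFERENCE_CT + rng.normal(0.0, ct_noise_sd),
            }
        )
        for gene in genes:
            ct = (
                REFERENCE_CT
                + delta_ct0[(gene, cell_line)]
                + shift_of.get(gene, 0.0)
                + rng.normal(0.0, ct_noise_sd)
            )
            rows.append(
                {
                    "gene": gene,
                    "cell_line": cell_line,
                    "condition": condition,
                    "replicate": rep,
                    "ct": ct,
                }
            )
    return rows


def simulate_qpcr(
    config: SimulationConfig, genes: GeneSet
) -> tuple[dict[str, CtTable], GroundTruth]:
    """Cycle-threshold tables for the three validation experiments.

    Returns a dict with keys ``panel`` (every cell line x untreated/ADR),
    ``knockdown`` (one responsive wild-type line; mock baseline, control-
    siRNA + ADR, p53-siRNA + ADR, p21-siRNA + ADR) and ``exogenous`` (one
    p53-mutant line; untransduced, control and p53 adenovirus), all in
    triplicate.  Suppression (a Ct upshift of -qpcr_effect_log2 cycles)
    appears for planted genes under ADR in responsive wild-type lines only;
    p53 silencing cancels it, p21 silencing cancels it for the
    p21-dependent planted subset, and exogenous p53 reproduces it in the
    mutant line.
    """
    truth = _ground_truth(config)
    rng = _rng(config, "qpcr")
    target_genes = sorted(normalize_symbol(g) for g in genes.members)
    planted = truth.true_repressed.members
    p21_dep = truth.p21_dependent.members

    wt_lines = [f"WT{i}" for i in range(1, config.n_wt_lines + 1)]
    mut_lines = [f"MUT{i}" for i in range(1, config.n_mut_lines + 1)]
    statuses = {**{l: "wt" for l in wt_lines}, **{l: "mut" for l in mut_lines}}
    nonresponsive = set(truth.nonresponsive_wt_lines)
    responsive_wt = [l for l in wt_lines if l not in nonresponsive]
    if not responsive_wt:
        raise ValidationError("all wild-type lines configured non-responsive")

    shift = -config.qpcr_effect_log2  # repression: fewer transcripts -> later Ct
    delta_ct0 = {
        (g, line): rng.uniform(2.0, 8.0)
        for g in target_genes
        for line in wt_lines + mut_lines
    }

    panel_rows = []
    for line in wt_lines + mut_lines:
        responds = line in responsive_wt
        adr_shift = {
            g: shift for g in target_genes if g in planted and responds
        }
        panel_rows += _ct_records(rng, target_genes, delta_ct0, line,
                                  PANEL_CONTROL, {}, config.ct_noise_sd)
        panel_rows += _ct_records(rng, target_genes, delta_ct0, line,
                                  PANEL_CASE, adr_shift, config.ct_noise_sd)
    panel = CtTable(records=pd.DataFrame(panel_rows), reference_gene=REFERENCE_GENE,
                    line_status=statuses)

    kd_line = responsive_wt[0]
    kd_rows = []
    kd_conditions = {
        KD_BASELINE: {},
        KD_CONTROL_SI: {g: shift for g in target_genes if g in planted},
        KD_P53_SI: {},  # p53 silencing cancels the suppression entirely
        "sip21_ADR": {
            g: shift for g in target_genes if g in planted and g not in p21_dep
        },
    }
    for condition, shifts in kd_conditions.items():
        kd_rows += _ct_records(rng, target_genes, delta_ct0, kd_line, condition,
                               shifts, config.ct_noise_sd)
    knockdown = CtTable(records=pd.DataFrame(kd_rows), reference_gene=REFERENCE_GENE,
                        line_status={kd_line: "wt"})

    exo_line = mut_lines[0]
    exo_rows = []
    exo_conditions = {
        EXO_BASELINE: {},
        EXO_LACZ: {},
        EXO_P53: {g: shift for g in target_genes if g in planted},
    }
    for condition, shifts in exo_conditions.items():
        exo_rows += _ct_records(rng, target_genes, delta_ct0, exo_line, condition,
                                shifts, config.ct_noise_sd)
    exogenous = CtTable(records=pd.DataFrame(exo_rows), reference_gene=REFERENCE_GENE,
                        line_status={exo_line: "mut"})

    return {"panel": panel, "knockdown": knockdown, "exogenous": exogenous}, truth


# ---------------------------------------------------------------------------
# TSS annotation and peaks
# ---------------------------------------------------------------------------

def simulate_tss(genes: Sequence[str], seed: int = 0) -> TssAnnotation:
    """Deterministic TSS layout: genes spaced 1 Mb apart across chr1-chr22,
    alternating strand."""
    records = {}
    for i, gene in enumerate(sorted(normalize_symbol(g) for g in genes)):
        chrom = f"chr{(i % 22) + 1}"
        tss = 100_000 + (i // 22) * 1_000_000
        strand = "+" if i % 2 == 0 else "-"
        records[gene] = (chrom, tss, strand)
    return TssAnnotation.from_records(records)


def simulate_peaks(
    config: SimulationConfig,
    induced: GeneSet,
    module: GeneSet,
    tss: TssAnnotation,
    peak_width: int = 200,
    promoter_halfwidth: int = 2000,
) -> PeakSet:
    """One peak per annotated gene: inside the promoter window with the
    gene's group probability (induced vs module), otherwise placed more than
    10 kb downstream of the TSS so it misses both standard windows."""
    rng = _rng(config, "peaks")
    p_induced, p_module = config.peak_enrichment_prob
    triples = []
    for gene, row in tss.table.iterrows():
        if gene in induced.members:
            p = p_induced
        elif gene in module.members:
            p = p_module
        else:
            continue
        tss_pos = int(row.tss)
        if rng.random() < p:
            start = tss_pos + int(
                rng.integers(-promoter_halfwidth, promoter_halfwidth - peak_width + 2)
            )
        else:
            start = tss_pos + 10_001 + int(rng.integers(0, 50_000))
        triples.append((row.chrom, start, start + peak_width))
    return PeakSet.from_intervals(triples, source="simulated")


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    microarray: ExpressionMatrix
    microarray_design: SampleDesign
    probe_map: ProbeGeneMap
    rnaseq: ExpressionMatrix
    rnaseq_design: SampleDesign
    cohort: CohortTable
    qpcr: dict[str, CtTable]
    orthologs: OrthologMap
    truth: GroundTruth


def simulate_bundle(config: SimulationConfig) -> Bundle:
    """Generate the complete multi-modality dataset with one shared planted
    truth.  The qPCR tables cover every gene so any candidate set derived
    from the screens can be validated."""
    ma_expr, ma_design, probe_map, truth = simulate_microarray(config)
    rs_expr, rs_design, _ = simulate_rnaseq_tissues(config)
    cohort, _ = simulate_cohort(config)
    all_genes = GeneSet.from_iterable("universe", gene_ids(config))
    qpcr_tables, _ = simulate_qpcr(config, all_genes)
    return Bundle(
        config=config,
        microarray=ma_expr,
        microarray_design=ma_design,
        probe_map=probe_map,
        rnaseq=rs_expr,
        rnaseq_design=rs_design,
        cohort=cohort,
        qpcr=qpcr_tables,
        orthologs=OrthologMap.identity(gene_ids(config)),
        truth=truth,
    )


def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    """Write the bundle in the standard on-disk formats plus a ground-truth
    TSV."""
    from .data_model import write_expression_table, write_sample_design
    from .qpcr import write_ct_table
    from .survival import write_cohort_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_table(bundle.microarray, out / "microarray_expression.tsv")
    write_sample_design(bundle.microarray_design, out / "microarray_design.tsv")
    pd.Series(bundle.probe_map.mapping, name="gene").rename_axis("probe").to_csv(
        out / "probe_gene_map.tsv", sep="\t"
    )
    write_expression_table(bundle.rnaseq, out / "rnaseq_fpkm.tsv")
    write_sample_design(bundle.rnaseq_design, out / "rnaseq_design.tsv")
    write_cohort_table(bundle.cohort, out / "cohort.tsv")
    for name, table in bundle.qpcr.items():
        write_ct_table(table, out / f"qpcr_{name}.tsv")
    pd.DataFrame(bundle.orthologs.pairs, columns=["human", "mouse"]).to_csv(
        out / "orthologs.tsv", sep="\t", index=False
    )
    bundle.truth.to_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
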