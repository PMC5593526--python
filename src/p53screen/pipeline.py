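"""End-to-end orchestration: screens -> intersection -> qPCR module call ->
promoter enrichment -> prognosis, with a machine-readable report.

The pipeline can run fully from a synthetic bundle (``simulate: true`` in
the config) or from files on disk.  Every stage parameter is echoed into
the report so results are self-describing, and stage outputs are identical
whether a stage is run here or through its standalone API.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import enrichment, qpcr, screens, survival, synthetic_data
from .data_model import (
    GeneSet,
    OrthologMap,
    ProbeGeneMap,
    ValidationError,
    read_expression_table,
    read_gene_set,
    read_sample_design,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and stage parameters.

    With ``simulate`` set, inputs are generated from ``simulation`` instead
    of read from ``paths``.  Defaults are the study criteria: ratio cutoff
    0.5, pseudocount 1, alpha 0.05, log2FC cutoff -2 with the 2-of-4 /
    0-of-3 line rule, +/-2 kb and +/-10 kb TSS windows, median split.
    """

    simulate: bool = True
    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )
    paths: dict[str, str] = field(default_factory=dict)
    microarray: screens.MicroarrayScreenParams = field(
        default_factory=screens.MicroarrayScreenParams
    )
    rnaseq: screens.RnaseqScreenParams = field(default_factory=screens.RnaseqScreenParams)
    cohort: screens.CohortScreenParams = field(default_factory=screens.CohortScreenParams)
    module: qpcr.ModuleCallParams = field(default_factory=qpcr.ModuleCallParams)
    enrichment_windows: tuple[int, ...] = (2000, 10000)
    prognosis_alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for key in ("simulate", "paths", "prognosis_alpha", "seed", "output_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "enrichment_windows" in raw:
            kwargs["enrichment_windows"] = tuple(raw["enrichment_windows"])
        sim = dict(raw.get("simulation", {}))
        if "seed" not in sim and "seed" in raw:
            sim["seed"] = raw["seed"]
        kwargs["simulation"] = synthetic_data.SimulationConfig(**sim)
        kwargs["microarray"] = screens.MicroarrayScreenParams(**raw.get("microarray", {}))
        kwargs["rnaseq"] = screens.RnaseqScreenParams(**raw.get("rnaseq", {}))
        kwargs["cohort"] = screens.CohortScreenParams(**raw.get("cohort", {}))
        kwargs["module"] = qpcr.ModuleCallParams(**raw.get("module", {}))
        return cls(**kwargs)

    def validate(self) -> None:
        if not self.simulate:
            required = {
                "microarray_expression", "microarray_design", "probe_gene_map",
                "rnaseq_fpkm", "rnaseq_design", "cohort", "orthologs",
                "qpcr_panel", "induced_gene_set", "tss", "peaks",
            }
            if self.module.require_knockdown_abrogation:
                required.add("qpcr_knockdown")
            if self.module.require_adp53_repression:
                required.add("qpcr_exogenous")
            missing = required - set(self.paths)
            if missing:
                raise ValidationError(f"config missing input paths: {sorted(missing)}")
            absent = [p for p in self.paths.values() if not Path(p).exists()]
            if absent:
                raise ValidationError(f"input files not found: {absent}")


def _load_inputs(config: PipelineConfig) -> synthetic_data.Bundle:
    if config.simulate:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = synthetic_data.SimulationConfig(**{**asdict(sim), "seed": config.seed})
        return synthetic_data.simulate_bundle(sim)
    import pandas as pd

    from .qpcr import read_ct_table
    from .survival import read_cohort_table

    p = config.paths
    probe_df = pd.read_csv(p["probe_gene_map"], sep="\t", index_col=0)
    ortho_df = pd.read_csv(p["orthologs"], sep="\t")
    statuses = {}
    if "qpcr_line_status" in p:
        st = pd.read_csv(p["qpcr_line_status"], sep="\t")
        statuses = dict(zip(st["cell_line"], st["p53_status"]))
    qpcr_tables = {"panel": read_ct_table(p["qpcr_panel"], "ACTB", statuses)}
    if "qpcr_knockdown" in p:
        qpcr_tables["knockdown"] = read_ct_table(p["qpcr_knockdown"], "ACTB")
    if "qpcr_exogenous" in p:
        qpcr_tables["exogenous"] = read_ct_table(p["qpcr_exogenous"], "ACTB")
    return synthetic_data.Bundle(
        config=config.simulation,
        microarray=read_expression_table(p["microarray_expression"], "probe"),
        microarray_design=read_sample_design(p["microarray_design"]),
        probe_map=ProbeGeneMap(mapping=probe_df.iloc[:, 0].to_dict()),
        rnaseq=read_expression_table(p["rnaseq_fpkm"], "gene"),
        rnaseq_design=read_sample_design(p["rnaseq_design"]),
        cohort=read_cohort_table(p["cohort"]),
        qpcr=qpcr_tables,
        orthologs=OrthologMap(
            pairs=list(zip(ortho_df["human"], ortho_df["mouse"]))
        ),
        truth=None,  # real inputs carry no planted truth
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the JSON-serializable report.

    The report carries the schema version, all effective parameters, each
    intermediate gene set, per-stage statistics and timings, and (for
    simulated inputs) recovery scores against the planted truth.
    """
    config.validate()
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": {
            "microarray": asdict(config.microarray),
            "rnaseq": asdict(config.rnaseq),
            "cohort": asdict(config.cohort),
            "module": asdict(config.module),
            "enrichment_windows": list(config.enrichment_windows),
            "prognosis_alpha": config.prognosis_alpha,
        },
        "stages": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    raise StageError(name, str(exc)) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Timer()

    with stage("load_inputs"):
        bundle = _load_inputs(config)

    with stage("screen_microarray"):
        ma = screens.screen_microarray(
            bundle.microarray, bundle.microarray_design, bundle.probe_map,
            config.microarray,
        )
    with stage("screen_rnaseq"):
        rs = screens.screen_rnaseq(bundle.rnaseq, bundle.rnaseq_design, config.rnaseq)
    with stage("screen_cohort"):
        co = screens.screen_cohort(bundle.cohort, config.cohort)
    with stage("intersect"):
        inter = screens.intersect_candidates([ma, co], rs, bundle.orthologs)
    report["stages"]["screens"] = {
        "set_sizes": inter.set_sizes,
        "pairwise_sizes": inter.pairwise_sizes,
        "n_unmapped_mouse": len(inter.unmapped_mouse_symbols),
        "microarray_non_evaluable_probes": ma.n_non_evaluable,
        "candidates": sorted(inter.intersection.members),
    }

    with stage("qpcr_module_call"):
        call = qpcr.run_module_call(
            inter.intersection,
            bundle.qpcr["panel"],
            bundle.qpcr.get("knockdown"),
            bundle.qpcr.get("exogenous"),
            config.module,
        )
    report["stages"]["module"] = {
        "members": sorted(call.module.members),
        "n_members": len(call.module),
        "excluded": {
            g: row["excluded_at"]
            for g, row in call.audit.iterrows()
            if row["excluded_at"] is not None
        },
    }

    with stage("enrichment"):
        if config.simulate:
            universe = synthetic_data.gene_ids(bundle.config)
            induced = GeneSet.from_iterable(
                "induced_reference",
                [g for g in universe if g not in call.module.members][:183],
                provenance="simulated stand-in transactivated reference set",
            )
            tss = synthetic_data.simulate_tss(universe)
            peaks = synthetic_data.simulate_peaks(
                bundle.config, induced, call.module, tss
            )
        else:
            induced = read_gene_set(config.paths["induced_gene_set"], "induced")
            tss = enrichment.read_tss_table(config.paths["tss"])
            peaks = enrichment.read_bed(config.paths["peaks"])
        if len(call.module) and len(induced):
            enr = enrichment.enrichment_report(
                induced, call.module, tss, {"simulated": peaks},
                windows=config.enrichment_windows,
            )
            report["stages"]["enrichment"] = enr.to_dict(orient="records")
        else:
            report["stages"]["enrichment"] = []

    with stage("prognosis"):
        module_in_cohort = [
            g for g in call.module.members if g in bundle.cohort.gene_columns
        ]
        if module_in_cohort:
            prog = survival.prognosis_screen(
                bundle.cohort,
                GeneSet.from_iterable("module", module_in_cohort),
                alpha=config.prognosis_alpha,
            )
            report["stages"]["prognosis"] = {
                "n_significant": int(prog["significant"].sum()),
                "per_gene": prog.round(6).to_dict(orient="index"),
            }
        else:
            report["stages"]["prognosis"] = {"n_significant": 0, "per_gene": {}}

    if bundle.truth is not None:
        planted = bundle.truth.true_repressed.members
        called = call.module.members
        n_neg = bundle.config.n_genes - len(planted)
        report["recovery"] = {
            "sensitivity": len(called & planted) / len(planted) if planted else None,
            "specificity": 1.0 - len(called - planted) / n_neg if n_neg else None,
            "n_called": len(called),
            "n_planted": len(planted),
        }

    report["timings_s"] = timings

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        stable = {k: v for k, v in report.items() if k != "timings_s"}
        (out / "report.json").write_text(json.dumps(stable, indent=2, sort_keys=True))
        ma.table.to_csv(out / "screen_microarray.tsv", sep="\t")
        rs.table.to_csv(out / "screen_rnaseq.tsv", sep="\t")
        co.table.to_csv(out / "screen_cohort.tsv", sep="\t")
        call.audit.to_csv(out / "module_audit.tsv", sep="\t")
    return report
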