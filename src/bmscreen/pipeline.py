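"""End-to-end orchestration: simulate -> QC -> fit -> hits -> concordance.

The pipeline mirrors a combined molecular-profiling + in vitro screening
workflow: each culture's plates must pass QC before any hit calling
happens (a failed culture is excluded from analysis, it does not abort the
run); passing cultures are fitted, scored for selectivity against the
non-neoplastic controls, and funneled into hits; variant calls, when
provided, are matched tissue-vs-culture and used to flag hits whose target
family is genetically supported. Everything is written as plain TSV/JSON,
and identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import dose_response, plate_qc, selectivity_hits, synth_screen
from .screen_io import (
    ValidationError,
    WellMeasurement,
    read_plate_table,
    write_compound_library,
    write_plate_table,
    read_variant_table,
)
from .variant_concordance import (
    REFERENCE_PATIENTS,
    concordance_report,
    load_gene_to_family,
    load_reference_variants,
    split_by_patient,
)

__all__ = ["CultureSpec", "PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass(frozen=True)
class CultureSpec:
    """One screened culture: its ID (doubles as patient ID for variant
    linking) and an optional per-culture noise override for simulation."""

    culture_id: str
    noise_cv_percent: float | None = None
    inject_dmso_cv_percent: float | None = None  # force exact DMSO CV (corruption)
    plate_csv: str | None = None  # read this file instead of simulating


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; serializable to/from YAML."""

    seed: int = 0
    outdir: str = "bmscreen_out"
    # screen simulation (ignored for cultures that provide plate_csv)
    n_compounds: int = 60
    n_conc: int = 8
    noise_cv_percent: float = 10.0
    n_dmso_per_plate: int = 16
    frac_effective: float = 60 / 267
    frac_selective_given_effective: float = 29 / 60
    cultures: list[CultureSpec] = field(default_factory=lambda: [CultureSpec("BM-T1")])
    # thresholds
    cv_max: float = 15.0
    r2_min: float = 0.8
    auc_max: float = 0.75
    z_max: float = -2.0
    sd_floor: float = 0.05
    # variant integration: path to a TSV, or "reference" for the packaged table
    variants: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cv_max <= 0:
            raise ValidationError("cv_max must be positive")
        for name in ("r2_min", "auc_max", "z_max", "sd_floor"):
            if not isinstance(getattr(self, name), (int, float)):
                raise ValidationError(f"threshold {name} must be a number")
        self.cultures = [c if isinstance(c, CultureSpec) else CultureSpec(**c)
                         for c in self.cultures]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _culture_seed(base_seed: int, index: int) -> int:
    return (base_seed + 1000 * (index + 1)) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and write stage outputs plus ``summary.json``.

    Returns the summary dict. Any stage error removes the partial outputs
    of this run and raises :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    stage = "setup"
    try:
        # ---- stage: simulate / load -----------------------------------
        stage = "simulate"
        library = synth_screen.simulate_library(config.n_compounds)
        write_compound_library(library.values(), out("library.tsv"))
        culture_wells: dict[str, list[WellMeasurement]] = {}
        for i, spec in enumerate(config.cultures):
            if spec.plate_csv:
                wells = read_plate_table(spec.plate_csv)
            else:
                sim = synth_screen.SimConfig(
                    n_compounds=config.n_compounds,
                    n_conc=config.n_conc,
                    noise_cv_percent=(spec.noise_cv_percent
                                      if spec.noise_cv_percent is not None
                                      else config.noise_cv_percent),
                    n_dmso_per_plate=config.n_dmso_per_plate,
                    frac_effective=config.frac_effective,
                    frac_selective_given_effective=config.frac_selective_given_effective,
                    seed=_culture_seed(config.seed, i),
                    tumor_model_id=spec.culture_id,
                )
                wells, truths = synth_screen.simulate_screen(sim)
                if spec.inject_dmso_cv_percent is not None:
                    wells = synth_screen.inject_dmso_cv(
                        wells, spec.inject_dmso_cv_percent)
                write_plate_table(wells, out(f"plates_{spec.culture_id}.csv"))
                synth_screen.write_truth_table(truths, out(f"truth_{spec.culture_id}.tsv"))
            culture_wells[spec.culture_id] = wells
            logger.info("[simulate] culture %s: %d wells", spec.culture_id, len(wells))

        # ---- stage: qc -------------------------------------------------
        stage = "qc"
        qc_reports: dict[str, list[plate_qc.QCReport]] = {}
        screen_pass: dict[str, bool] = {}
        all_reports: list[plate_qc.QCReport] = []
        for culture_id, wells in culture_wells.items():
            by_plate: dict[str, list[WellMeasurement]] = {}
            for w in wells:
                by_plate.setdefault(w.plate_id, []).append(w)
            reports = [plate_qc.qc_plate(pw, cv_max=config.cv_max, r2_min=config.r2_min)
                       for _, pw in sorted(by_plate.items())]
            qc_reports[culture_id] = reports
            screen_pass[culture_id] = plate_qc.qc_screen(reports)
            all_reports.extend(reports)
            logger.info("[qc] culture %s: %s", culture_id,
                        "PASS" if screen_pass[culture_id] else "FAIL")
        plate_qc.write_qc_table(all_reports, out("qc_report.tsv"))
        analyzed = [c.culture_id for c in config.cultures if screen_pass[c.culture_id]]

        # ---- stage: fit + hits ----------------------------------------
        stage = "fit"
        gene_to_family = load_gene_to_family()
        if config.variants == "reference":
            variants = load_reference_variants()
        elif config.variants:
            variants = read_variant_table(config.variants)
        else:
            variants = []
        variants_by_patient = split_by_patient(variants)

        hits_rows: list[str] = []
        funnel_rows: list[str] = []
        family_rows: list[str] = []
        summary_cultures: dict[str, Any] = {}
        for culture_id in analyzed:
            fits = dose_response.fit_screen(culture_wells[culture_id])
            dose_response.write_fit_table(fits, out(f"drug_fits_{culture_id}.tsv"))

            stage = "hits"
            metrics = selectivity_hits.build_drug_metrics(
                fits, tumor_model_id=culture_id, library=library,
                sd_floor=config.sd_floor, exclude=synth_screen.POS_CTRL_COMPOUNDS)
            annotated, funnel = selectivity_hits.select_hits(
                metrics, r2_min=config.r2_min, auc_max=config.auc_max,
                z_max=config.z_max)
            patient_variants = []
            if culture_id in variants_by_patient:
                tissue, culture = variants_by_patient[culture_id]
                patient_variants = list(tissue) + list(culture)
            annotated = selectivity_hits.flag_genetic_support(
                annotated, patient_variants, library, gene_to_family)
            hits = [m for m in annotated if m.is_hit]
            for m in annotated:
                hits_rows.append("\t".join([
                    culture_id, m.compound_id, repr(m.auc_tumor), repr(m.auc_hfb),
                    repr(m.auc_pbc), repr(m.zprime), repr(m.r2_tumor),
                    str(int(m.pass_r2)), str(int(m.pass_auc)), str(int(m.pass_z)),
                    str(int(m.is_hit)), m.target_family, str(int(m.genetic_support)),
                ]))
            funnel_rows.append("\t".join([culture_id, str(funnel.n_screened),
                                          str(funnel.n_fit_pass), str(funnel.n_effective),
                                          str(funnel.n_selective)]))
            for fam, n, frac in selectivity_hits.summarize_target_families(hits, library):
                family_rows.append("\t".join([culture_id, fam, str(n), repr(frac)]))
            summary_cultures[culture_id] = {
                "funnel": asdict(funnel),
                "hits": sorted(m.compound_id for m in hits),
                "genetically_supported_hits": sorted(
                    m.compound_id for m in hits if m.genetic_support),
            }
            logger.info("[hits] culture %s: funnel %s", culture_id, asdict(funnel))

        header = ("culture_id\tcompound_id\tauc_tumor\tauc_hfb\tauc_pbc\tzprime\t"
                  "r2_tumor\tpass_r2\tpass_auc\tpass_z\tis_hit\ttarget_family\t"
                  "genetic_support")
        out("hits.tsv").write_text("\n".join([header, *hits_rows]) + "\n", encoding="utf-8")
        out("funnel.tsv").write_text(
            "\n".join(["culture_id\tn_screened\tn_fit_pass\tn_effective\tn_selective",
                       *funnel_rows]) + "\n", encoding="utf-8")
        out("family_summary.tsv").write_text(
            "\n".join(["culture_id\ttarget_family\tcount\tfraction", *family_rows]) + "\n",
            encoding="utf-8")

        # ---- stage: concordance ---------------------------------------
        stage = "concordance"
        concordance: dict[str, Any] = {}
        if variants:
            patients = {pid: pair for pid, pair in variants_by_patient.items()
                        if pid in REFERENCE_PATIENTS or config.variants != "reference"}
            report = concordance_report(patients)
            report.to_csv(out("concordance.tsv"), sep="\t", index=False)
            concordance = {
                row["patient_id"]: {
                    "n_matched": int(row["n_matched"]),
                    "concordance": float(row["concordance"]),
                }
                for _, row in report.iterrows()
            }

        # ---- stage: summary -------------------------------------------
        stage = "summary"
        summary = {
            "n_cultures": len(config.cultures),
            "n_cultures_analyzed": len(analyzed),
            "qc": {cid: {"screen_pass": screen_pass[cid],
                         "plates": {r.plate_id: {"cv_percent": r.cv_percent,
                                                 "plate_pass": r.plate_pass}
                                    for r in qc_reports[cid]}}
                   for cid in sorted(screen_pass)},
            "cultures": summary_cultures,
            "concordance": concordance,
            "thresholds": {"cv_max": config.cv_max, "r2_min": config.r2_min,
                           "auc_max": config.auc_max, "z_max": config.z_max,
                           "sd_floor": config.sd_floor},
            "seed": config.seed,
        }
        with out("summary.json").open("w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
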