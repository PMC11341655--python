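"""Synthetic 1536-well screen generator with known ground truth.

Emulates the layout of an ex vivo high-throughput viability screen: a
clinical compound library dosed as a geometric dilution series (default
half-log steps from 10 µM) plus a 0-µM vehicle anchor, DMSO control wells
and two broadly cytotoxic positive-control compounds on every plate, and
three cell models per screen — one patient-derived tumor culture and the
two non-neoplastic controls (human fibroblasts, peripheral blood cells).

Signals are baseline x 4PL(conc; truth) x multiplicative log-normal noise
whose coefficient of variation equals ``noise_cv_percent`` exactly.
Effectiveness and selectivity are assigned by deterministic quota so tests
can assert exact counts, and truth labels are semantically consistent with
the downstream decision rules:

* effective compounds have a true (noiseless) AUC < 0.7 over the default
  dose window — parameter draws are redrawn (same RNG stream) until this
  holds, so a "true effective" label always corresponds to a real effect;
* selective compounds are effective on the tumor model and flat on both
  controls; non-selective effective compounds share one curve across all
  three models; ineffective compounds are flat (bottom >= 0.9) everywhere.

Same seed => byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dose_response import compute_auc, FitResult, logistic4_conc
from .screen_io import (
    CellModel,
    ClinicalStatus,
    CompoundRecord,
    ModelClass,
    ValidationError,
    WellMeasurement,
    WellRole,
    format_well,
    N_COLS,
    N_ROWS,
)

__all__ = [
    "TruthParams",
    "SimConfig",
    "POS_CTRL_COMPOUNDS",
    "default_cell_models",
    "simulate_library",
    "simulate_screen",
    "inject_dmso_cv",
    "truth_hit_set",
    "write_truth_table",
    "read_truth_table",
]

# Positive-control compounds with broad cytotoxicity across cell types,
# emulating the pan-HDAC inhibitor panobinostat and the pan-kinase
# inhibitor staurosporine used as per-plate fit-quality controls.
POS_CTRL_COMPOUNDS = ("panobinostat", "staurosporine")
_POS_CTRL_TRUTH = dict(top=1.0, bottom=0.05, ic50_um=0.05, hill=1.5)

BASELINE_SIGNAL = 1.0e6  # per-plate luminescence baseline, arbitrary counts

HFB_MODEL_ID = "HFB"
PBC_MODEL_ID = "PBC"

# True-AUC ceiling for an "effective" label; keeps truth labels decisive
# relative to the AUC < 0.75 hit threshold.
_EFFECTIVE_AUC_CEILING = 0.7

_FAMILY_TARGETS = {
    "JAK": ("JAK1", "JAK2", "JAK3"),
    "HER2": ("ERBB2",),
    "FGFR": ("FGFR1", "FGFR2", "FGFR3"),
    "HDAC": ("HDAC1", "HDAC2", "HDAC6"),
    "HSP90": ("HSP90AA1",),
    "MEK": ("MAP2K1", "MAP2K2"),
    "ERK": ("MAPK1", "MAPK3"),
    "PI3K": ("PIK3CA",),
    "CDK": ("CDK4", "CDK6"),
    "BTK": ("BTK",),
}


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth 4PL parameters for one compound x cell model."""

    compound_id: str
    cell_model_id: str
    top: float
    bottom: float
    ic50_um: float
    hill: float
    is_effective_truth: bool
    is_selective_truth: bool

    def __post_init__(self) -> None:
        if self.bottom > self.top:
            raise ValidationError("truth bottom exceeds top")
        if self.ic50_um <= 0 or self.hill <= 0:
            raise ValidationError("ic50_um and hill must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of a simulated screen.

    Defaults mirror the screening setting this generator emulates: a
    267-compound clinical library, 8-point half-log dilutions up to 10 µM
    plus a vehicle anchor, 16 DMSO wells per plate, ~10% multiplicative
    noise, and effectiveness/selectivity rates matching a funnel in which
    roughly 60 of 267 compounds are truly effective and about half of
    those are tumor-selective.
    """

    n_compounds: int = 267
    n_conc: int = 8
    top_conc_um: float = 10.0
    dilution_factor: float = math.sqrt(10.0)
    n_dmso_per_plate: int = 16
    noise_cv_percent: float = 10.0
    frac_effective: float = 60 / 267
    frac_selective_given_effective: float = 29 / 60
    seed: int = 0
    tumor_model_id: str = "BM-T1"
    baseline_signal: float = BASELINE_SIGNAL

    def __post_init__(self) -> None:
        if not (2 <= self.n_conc <= 12):
            raise ValidationError(f"n_conc={self.n_conc} outside [2, 12]")
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be >= 1")
        if self.dilution_factor <= 1:
            raise ValidationError("dilution_factor must be > 1")
        if self.top_conc_um <= 0:
            raise ValidationError("top_conc_um must be positive")
        if self.n_dmso_per_plate < 2:
            raise ValidationError("need >= 2 DMSO wells per plate")
        if self.noise_cv_percent < 0:
            raise ValidationError("noise_cv_percent must be >= 0")
        for name in ("frac_effective", "frac_selective_given_effective"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValidationError(f"{name}={val} outside [0, 1]")

    @property
    def concentrations(self) -> tuple[float, ...]:
        """Tested doses: 0-µM vehicle anchor + geometric series up to the top."""
        series = [self.top_conc_um / self.dilution_factor**i for i in range(self.n_conc)]
        return (0.0, *sorted(series))


def default_cell_models(config: SimConfig) -> tuple[CellModel, CellModel, CellModel]:
    """The screen's cell-model trio: tumor culture + HFB + PBC controls."""
    return (
        CellModel(model_id=config.tumor_model_id, model_class=ModelClass.TUMOR,
                  patient_id=config.tumor_model_id, entity="SYNTH"),
        CellModel(model_id=HFB_MODEL_ID, model_class=ModelClass.HFB),
        CellModel(model_id=PBC_MODEL_ID, model_class=ModelClass.PBC),
    )


def simulate_library(n_compounds: int) -> dict[str, CompoundRecord]:
    """A deterministic compound-annotation table: compounds rotate through
    common target families; ~80% are labelled FDA-approved."""
    families = list(_FAMILY_TARGETS)
    library: dict[str, CompoundRecord] = {}
    for i in range(n_compounds):
        family = families[i % len(families)]
        cid = f"cmpd{i + 1:03d}"
        library[cid] = CompoundRecord(
            compound_id=cid,
            name=f"{family.lower()}-inhibitor-{i + 1}",
            target_genes=_FAMILY_TARGETS[family],
            target_family=family,
            clinical_status=(ClinicalStatus.CLINICAL_EVALUATION if i % 5 == 0
                             else ClinicalStatus.FDA_APPROVED),
        )
    return library


def _noiseless_auc(top: float, bottom: float, ic50_um: float, hill: float,
                   concentrations: Sequence[float]) -> float:
    pos = [c for c in concentrations if c > 0]
    fit = FitResult(top=top, bottom=bottom, log10_ic50=math.log10(ic50_um),
                    hill=hill, converged=True)
    return compute_auc(fit, math.log10(min(pos)), math.log10(max(pos)), n_grid=2001)


def _draw_effective(rng: np.random.Generator, concentrations: Sequence[float]
                    ) -> tuple[float, float, float, float]:
    """Effective-class parameters with a guaranteed true AUC < 0.7."""
    while True:
        top = 1.0
        bottom = float(rng.uniform(0.0, 0.3))
        ic50 = float(10.0 ** rng.uniform(-2.0, 0.0))
        hill = float(rng.uniform(0.8, 2.5))
        if _noiseless_auc(top, bottom, ic50, hill, concentrations) < _EFFECTIVE_AUC_CEILING:
            return top, bottom, ic50, hill


def _draw_flat(rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Ineffective-class parameters: essentially flat viability."""
    bottom = float(rng.uniform(0.9, 1.0))
    ic50 = float(10.0 ** rng.uniform(-2.0, 0.0))
    hill = float(rng.uniform(0.8, 2.5))
    return 1.0, bottom, ic50, hill


def _draw_truths(config: SimConfig, rng: np.random.Generator,
                 models: Sequence[CellModel]) -> list[TruthParams]:
    n = config.n_compounds
    n_eff = round(config.frac_effective * n)
    n_sel = round(config.frac_selective_given_effective * n_eff)
    order = rng.permutation(n)
    effective = set(order[:n_eff].tolist())
    selective = set(order[:n_sel].tolist())

    control_ids = [m.model_id for m in models if m.model_class is not ModelClass.TUMOR]
    tumor_id = next(m.model_id for m in models if m.model_class is ModelClass.TUMOR)

    truths: list[TruthParams] = []
    for i in range(n):
        cid = f"cmpd{i + 1:03d}"
        is_eff, is_sel = i in effective, i in selective
        if is_eff:
            shared = _draw_effective(rng, config.concentrations)
        for model_id in (tumor_id, *control_ids):
            if not is_eff:
                top, bottom, ic50, hill = _draw_flat(rng)
            elif is_sel and model_id != tumor_id:
                top, bottom, ic50, hill = _draw_flat(rng)
            else:
                # effective on this model; non-selective compounds share one
                # curve across models so they cannot look tumor-selective
                top, bottom, ic50, hill = shared
            truths.append(TruthParams(
                compound_id=cid, cell_model_id=model_id,
                top=top, bottom=bottom, ic50_um=ic50, hill=hill,
                is_effective_truth=is_eff, is_selective_truth=is_sel,
            ))
    return truths


def _noise_factors(rng: np.random.Generator, n: int, cv_percent: float) -> np.ndarray:
    """Unit-mean multiplicative log-normal factors with the requested CV."""
    if cv_percent == 0:
        return np.ones(n)
    cv = cv_percent / 100.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def simulate_screen(config: SimConfig) -> tuple[list[WellMeasurement], list[TruthParams]]:
    """Simulate one screen (tumor + HFB + PBC) and return wells with truth.

    Each cell model is screened on its own plate set; every plate carries
    ``n_dmso_per_plate`` DMSO wells and full dilution series of both
    positive-control compounds, then as many library-compound series as the
    1536-well geometry allows; extra plates are added as needed.
    """
    rng = np.random.default_rng(config.seed)
    models = default_cell_models(config)
    truths = _draw_truths(config, rng, models)
    truth_by_key = {(t.compound_id, t.cell_model_id): t for t in truths}
    concentrations = config.concentrations
    wells_per_series = len(concentrations)

    capacity = N_ROWS * N_COLS
    overhead = config.n_dmso_per_plate + len(POS_CTRL_COMPOUNDS) * wells_per_series
    per_plate = (capacity - overhead) // wells_per_series
    if per_plate < 1:
        raise ValidationError("plate cannot hold DMSO + positive controls + one series")

    compound_ids = [f"cmpd{i + 1:03d}" for i in range(config.n_compounds)]
    wells: list[WellMeasurement] = []
    for model in models:
        for plate_no, start in enumerate(range(0, len(compound_ids), per_plate), start=1):
            plate_id = f"{model.model_id}-P{plate_no}"
            chunk = compound_ids[start:start + per_plate]
            pos = iter(format_well(r, c) for r in range(1, N_ROWS + 1)
                       for c in range(1, N_COLS + 1))

            dmso_noise = _noise_factors(rng, config.n_dmso_per_plate, config.noise_cv_percent)
            for f in dmso_noise:
                wells.append(WellMeasurement(
                    plate_id=plate_id, well=next(pos), role=WellRole.DMSO,
                    compound_id="", conc_um=0.0, cell_model_id=model.model_id,
                    signal=config.baseline_signal * float(f)))

            def emit_series(cid: str, role: WellRole, top: float, bottom: float,
                            ic50: float, hill: float) -> None:
                noise = _noise_factors(rng, wells_per_series, config.noise_cv_percent)
                for conc, f in zip(concentrations, noise):
                    v = logistic4_conc(conc, top, bottom, ic50, hill)
                    wells.append(WellMeasurement(
                        plate_id=plate_id, well=next(pos), role=role,
                        compound_id=cid, conc_um=conc,
                        cell_model_id=model.model_id,
                        signal=config.baseline_signal * float(v) * float(f)))

            for ctrl in POS_CTRL_COMPOUNDS:
                emit_series(ctrl, WellRole.POS_CTRL,
                            _POS_CTRL_TRUTH["top"], _POS_CTRL_TRUTH["bottom"],
                            _POS_CTRL_TRUTH["ic50_um"], _POS_CTRL_TRUTH["hill"])
            for cid in chunk:
                t = truth_by_key[(cid, model.model_id)]
                emit_series(cid, WellRole.SAMPLE, t.top, t.bottom, t.ic50_um, t.hill)
    return wells, truths


def inject_dmso_cv(wells: Sequence[WellMeasurement], cv_percent: float,
                   ) -> list[WellMeasurement]:
    """Force each plate's DMSO wells to an exact sample CV (percent).

    Rescales the DMSO-signal deviations around their plate mean so the
    sample CV equals ``cv_percent`` exactly; used to corrupt a simulated
    screen deterministically for QC-gating tests. Non-DMSO wells are
    untouched.
    """
    from dataclasses import replace as _replace

    by_plate: dict[str, list[int]] = {}
    for i, w in enumerate(wells):
        if w.role is WellRole.DMSO:
            by_plate.setdefault(w.plate_id, []).append(i)
    out = list(wells)
    for plate_id, idx in by_plate.items():
        sig = np.array([wells[i].signal for i in idx])
        mean = sig.mean()
        sd = sig.std(ddof=1)
        target_sd = cv_percent / 100.0 * mean
        if sd > 0:
            new = mean + (sig - mean) * (target_sd / sd)
        else:  # degenerate zero-noise plate: alternate around the mean
            n = len(sig)
            signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(n)])
            signs -= signs.mean()
            new = mean + signs * target_sd / signs.std(ddof=1)
        for i, s in zip(idx, new):
            out[i] = _replace(wells[i], signal=float(s))
    return out


def truth_hit_set(truths: Iterable[TruthParams]) -> set[str]:
    """Compounds flagged tumor-selective in the ground truth."""
    return {t.compound_id for t in truths if t.is_selective_truth}


def write_truth_table(truths: Iterable[TruthParams], path) -> None:
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["compound_id", "cell_model_id", "top", "bottom",
                         "ic50_um", "hill", "is_effective_truth", "is_selective_truth"])
        for t in truths:
            writer.writerow([t.compound_id, t.cell_model_id, repr(t.top),
                             repr(t.bottom), repr(t.ic50_um), repr(t.hill),
                             int(t.is_effective_truth), int(t.is_selective_truth)])


def read_truth_table(path) -> list[TruthParams]:
    import csv
    from pathlib import Path

    truths: list[TruthParams] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            truths.append(TruthParams(
                compound_id=row["compound_id"], cell_model_id=row["cell_model_id"],
                top=float(row["top"]), bottom=float(row["bottom"]),
                ic50_um=float(row["ic50_um"]), hill=float(row["hill"]),
                is_effective_truth=bool(int(row["is_effective_truth"])),
                is_selective_truth=bool(int(row["is_selective_truth"])),
            ))
    return truths
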