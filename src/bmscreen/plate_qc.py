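"""Plate- and screen-level quality control.

Two gates, applied per plate:

* DMSO coefficient of variation (CV = 100 x sample SD / mean over the
  plate's DMSO control wells) must stay below ``cv_max`` (default 15%) —
  a check on luminescence detection and liquid handling;
* both positive-control compounds must fit the 4PL model with R² above
  ``r2_min`` (default 0.8) on the tumor culture's series. Plates holding
  only non-neoplastic control models are exempt from the R² gate.

A screen (one culture's plate set) passes only if every plate passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dose_response import fit_4pl, normalize_series
from .screen_io import ValidationError, WellMeasurement, WellRole

__all__ = ["QCReport", "compute_cv", "qc_plate", "qc_screen", "write_qc_table"]

logger = logging.getLogger(__name__)

CV_MAX_DEFAULT = 15.0
R2_MIN_DEFAULT = 0.8

# Cell-model IDs exempt from the positive-control R2 gate (non-neoplastic
# controls); the gate applies to the tumor culture's series.
CONTROL_MODEL_IDS = frozenset({"HFB", "PBC"})


@dataclass(frozen=True)
class QCReport:
    """QC verdict for one plate."""

    plate_id: str
    n_dmso: int
    cv_percent: float
    pos_ctrl_r2: dict[str, float]
    cv_pass: bool
    pos_ctrl_pass: bool

    @property
    def plate_pass(self) -> bool:
        return self.cv_pass and self.pos_ctrl_pass


def compute_cv(values: Sequence[float]) -> float:
    """Coefficient of variation as percent: 100 x sample SD / mean.

    Requires at least two strictly positive values. Invariant under
    positive rescaling.
    """
    if len(values) < 2:
        raise ValidationError(f"CV needs >= 2 values, got {len(values)}")
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("CV requires strictly positive values")
    return float(100.0 * arr.std(ddof=1) / arr.mean())


def qc_plate(wells: Iterable[WellMeasurement], *,
             cv_max: float = CV_MAX_DEFAULT,
             r2_min: float = R2_MIN_DEFAULT,
             control_model_ids: frozenset[str] = CONTROL_MODEL_IDS) -> QCReport:
    """QC one plate's wells: DMSO CV plus positive-control fit quality.

    All DMSO wells on the plate are pooled for the CV. Positive-control
    R² is evaluated on series of tumor cell models (any model not listed
    in ``control_model_ids``); a tumor plate with no positive-control
    series fails that gate with a warning.
    """
    wells = list(wells)
    if not wells:
        raise ValidationError("qc_plate needs at least one well")
    plate_ids = {w.plate_id for w in wells}
    if len(plate_ids) != 1:
        raise ValidationError(f"qc_plate expects one plate, got {sorted(plate_ids)}")
    (plate_id,) = plate_ids

    dmso = [w.signal for w in wells if w.role is WellRole.DMSO]
    if len(dmso) < 2:
        raise ValidationError(f"plate {plate_id} has {len(dmso)} DMSO wells; need >= 2")
    cv = compute_cv(dmso)

    is_tumor_plate = any(w.cell_model_id not in control_model_ids for w in wells)
    pos_r2: dict[str, float] = {}
    if is_tumor_plate:
        grouped: dict[str, list[tuple[float, float]]] = {}
        for w in wells:
            if w.role is WellRole.POS_CTRL and w.cell_model_id not in control_model_ids:
                grouped.setdefault(w.compound_id, []).append((w.conc_um, w.signal))
        for cid, pairs in sorted(grouped.items()):
            fit = fit_4pl(normalize_series(pairs, compound_id=cid))
            pos_r2[cid] = fit.r2 if fit.converged else float("nan")
        if grouped:
            pos_pass = all(r2 > r2_min for r2 in pos_r2.values())
        else:
            logger.warning("plate %s has no positive-control series", plate_id)
            pos_pass = False
    else:
        pos_pass = True  # control-model plate: R2 gate not applicable

    return QCReport(
        plate_id=plate_id, n_dmso=len(dmso), cv_percent=cv,
        pos_ctrl_r2=pos_r2, cv_pass=cv < cv_max, pos_ctrl_pass=pos_pass,
    )


def qc_screen(reports: Sequence[QCReport]) -> bool:
    """A screen meets the quality standard iff all of its plates pass."""
    if not reports:
        raise ValidationError("qc_screen needs at least one plate report")
    return all(r.plate_pass for r in reports)


def write_qc_table(reports: Iterable[QCReport], path) -> None:
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["plate_id", "n_dmso", "cv_percent", "pos_ctrl_r2",
                         "cv_pass", "pos_ctrl_pass", "plate_pass"])
        for r in reports:
            r2s = ";".join(f"{cid}={r2!r}" for cid, r2 in sorted(r.pos_ctrl_r2.items()))
            writer.writerow([r.plate_id, r.n_dmso, repr(r.cv_percent), r2s,
                             int(r.cv_pass), int(r.pos_ctrl_pass), int(r.plate_pass)])
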