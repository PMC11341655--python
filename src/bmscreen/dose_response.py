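"""Viability normalization, four-parameter logistic (4PL) fitting, and
normalized AUC scoring.

The dose-response model is the Hill / 4PL curve on log10 concentration:

    v(x) = bottom + (top - bottom) / (1 + 10**(hill * (x - log10_ic50)))

with x = log10(concentration in µM). ``top`` is the viability plateau at low
dose, ``bottom`` the residual viability at saturating dose, ``hill`` the
slope. Viability is normalized so that the anchor dose (the 0-µM vehicle
well when present, otherwise the lowest tested concentration) is exactly 1.

The drug-sensitivity score is the normalized area under the fitted curve
(AUC) over the tested positive-concentration window, clamped to [0, 1]:
AUC = 1 means no effect anywhere in the window, AUC = 0 complete kill.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import least_squares

from .screen_io import ValidationError, WellMeasurement, WellRole

__all__ = [
    "DoseResponseSeries",
    "FitResult",
    "logistic4",
    "logistic4_conc",
    "normalize_series",
    "fit_4pl",
    "compute_auc",
    "series_from_wells",
    "fit_screen",
]

logger = logging.getLogger(__name__)

# Default grid density for the AUC trapezoid; dense enough that the
# quadrature error is far below any decision threshold.
AUC_GRID_POINTS = 20001

# Fit bounds: (top, bottom, log10_ic50, hill). log10_ic50 bounds are set
# per-series to the tested window +/- 1 decade.
TOP_BOUNDS = (0.5, 1.5)
BOTTOM_BOUNDS = (-0.1, 1.1)
HILL_BOUNDS = (0.1, 20.0)


def logistic4(x: np.ndarray | float, top: float, bottom: float,
              log10_ic50: float, hill: float) -> np.ndarray | float:
    """4PL response at log10 concentration ``x``."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.asarray(x, dtype=float) - log10_ic50)))


def logistic4_conc(conc_um: np.ndarray | float, top: float, bottom: float,
                   ic50_um: float, hill: float) -> np.ndarray | float:
    """4PL response at concentration in µM; well-defined at 0 (returns top)."""
    c = np.asarray(conc_um, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50_um) ** hill)


@dataclass(frozen=True)
class DoseResponseSeries:
    """One compound x cell model dilution series, normalized and fit-ready."""

    compound_id: str
    cell_model_id: str
    conc_um: tuple[float, ...]   # strictly increasing, may start at 0 (vehicle)
    viability: tuple[float, ...]  # fraction of anchor signal; anchor == 1.0

    def __post_init__(self) -> None:
        if len(self.conc_um) != len(self.viability):
            raise ValidationError("concentration and viability lengths differ")
        if any(b <= a for a, b in zip(self.conc_um, self.conc_um[1:])):
            raise ValidationError("concentrations must be strictly increasing")

    @property
    def positive(self) -> tuple[np.ndarray, np.ndarray]:
        """(log10 conc, viability) over the positive-concentration points."""
        conc = np.asarray(self.conc_um)
        via = np.asarray(self.viability)
        mask = conc > 0
        return np.log10(conc[mask]), via[mask]


_SENTINEL = float("nan")


@dataclass(frozen=True)
class FitResult:
    """4PL fit of one series: parameters, convergence, R² and fitted AUC.

    ``r2`` and ``auc`` are NaN sentinels when not computable (non-converged
    fit, or flat data with zero total sum of squares); such a result cannot
    pass any downstream filter.
    """

    top: float
    bottom: float
    log10_ic50: float
    hill: float
    converged: bool
    r2: float = _SENTINEL
    auc: float = _SENTINEL


def normalize_series(raw: Iterable[tuple[float, float]], *, compound_id: str = "",
                     cell_model_id: str = "") -> DoseResponseSeries:
    """Normalize raw (concentration µM, signal) pairs to anchor viability 1.

    The anchor is the 0-µM vehicle point when present, else the lowest
    tested concentration. Duplicate concentrations are averaged (with a
    warning). Idempotent on already-normalized series.
    """
    by_conc: dict[float, list[float]] = {}
    for conc, signal in raw:
        by_conc.setdefault(float(conc), []).append(float(signal))
    if len(by_conc) < 4:
        raise ValidationError(
            f"need >= 4 distinct dose points, got {len(by_conc)} "
            f"({compound_id or 'series'})"
        )
    if any(len(v) > 1 for v in by_conc.values()):
        logger.warning("duplicate concentrations in %s/%s averaged",
                       compound_id or "series", cell_model_id or "model")
    conc = sorted(by_conc)
    signal = [float(np.mean(by_conc[c])) for c in conc]
    anchor = signal[0]  # lowest concentration; 0 µM sorts first when present
    if anchor <= 0:
        raise ValidationError(f"anchor signal must be positive, got {anchor}")
    viability = [s / anchor for s in signal]
    viability[0] = 1.0  # exact by construction
    return DoseResponseSeries(
        compound_id=compound_id,
        cell_model_id=cell_model_id,
        conc_um=tuple(conc),
        viability=tuple(viability),
    )


def fit_4pl(series: DoseResponseSeries, *, auc_grid_points: int = AUC_GRID_POINTS) -> FitResult:
    """Least-squares 4PL fit over the positive-concentration points.

    The 0-µM anchor is used for normalization only and excluded here
    (log 0 undefined). R² = 1 - SS_res/SS_tot on the fitted points; a flat
    series (SS_tot = 0) gets the NaN sentinel. The fitted normalized AUC
    over the tested window is attached when the fit converges. The fit is
    deterministic and invariant to input-point order (points are sorted by
    construction of the series).
    """
    x, y = series.positive
    if len(x) < 4:
        raise ValidationError(
            f"need >= 4 positive-concentration points to fit, got {len(x)}"
        )
    x_min, x_max = float(x[0]), float(x[-1])
    p0 = [
        min(max(float(y.max()), TOP_BOUNDS[0]), TOP_BOUNDS[1]),
        min(max(float(y.min()), BOTTOM_BOUNDS[0]), BOTTOM_BOUNDS[1]),
        0.5 * (x_min + x_max),
        1.0,
    ]
    bounds = (
        [TOP_BOUNDS[0], BOTTOM_BOUNDS[0], x_min - 1.0, HILL_BOUNDS[0]],
        [TOP_BOUNDS[1], BOTTOM_BOUNDS[1], x_max + 1.0, HILL_BOUNDS[1]],
    )
    ln10 = math.log(10.0)

    def residual(p: np.ndarray) -> np.ndarray:
        return logistic4(x, *p) - y

    def jacobian(p: np.ndarray) -> np.ndarray:
        top, bottom, log10_ic50, hill = p
        u = 10.0 ** (hill * (x - log10_ic50))
        s = 1.0 / (1.0 + u)
        jac = np.empty((x.size, 4))
        jac[:, 0] = s
        jac[:, 1] = 1.0 - s
        jac[:, 2] = (top - bottom) * s * s * u * ln10 * hill
        jac[:, 3] = -(top - bottom) * s * s * u * ln10 * (x - log10_ic50)
        return jac

    # Two-stage solve: a robust pass at moderate tolerance (flat, noisy
    # series are nearly unidentifiable in IC50/hill and crawl forever at
    # tight tolerances), then a tight polish kept only when it converges.
    result = least_squares(residual, p0, jac=jacobian, bounds=bounds,
                           xtol=1e-6, ftol=1e-6, gtol=1e-6, max_nfev=5000)
    if result.status <= 0:  # hit the evaluation cap without meeting tolerances
        return FitResult(top=_SENTINEL, bottom=_SENTINEL, log10_ic50=_SENTINEL,
                         hill=_SENTINEL, converged=False)
    polish = least_squares(residual, result.x, jac=jacobian, bounds=bounds,
                           xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300)
    if polish.status > 0:
        result = polish
    top, bottom, log10_ic50, hill = (float(p) for p in result.x)
    residuals = -result.fun
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else _SENTINEL
    fit = FitResult(top=top, bottom=bottom, log10_ic50=log10_ic50, hill=hill,
                    converged=True, r2=r2)
    auc = compute_auc(fit, x_min, x_max, n_grid=auc_grid_points)
    return replace(fit, auc=auc)


def compute_auc(fit: FitResult, x_min: float, x_max: float, *,
                n_grid: int = AUC_GRID_POINTS) -> float:
    """Normalized area under the fitted curve over [x_min, x_max] (log10 µM).

    The fitted viability is clamped to [0, 1] and integrated by the
    trapezoid rule on a dense uniform grid, then divided by the window
    width, so AUC lies in [0, 1]: 1 = no effect, 0 = complete kill.
    """
    if not fit.converged:
        raise ValidationError("cannot compute AUC of a non-converged fit")
    if not x_max > x_min:
        raise ValidationError(f"empty integration window [{x_min}, {x_max}]")
    grid = np.linspace(x_min, x_max, max(int(n_grid), 256))
    v = np.clip(logistic4(grid, fit.top, fit.bottom, fit.log10_ic50, fit.hill), 0.0, 1.0)
    return float(np.trapezoid(v, grid) / (x_max - x_min))


# ---------------------------------------------------------------------------
# Screen-level helpers
# ---------------------------------------------------------------------------


def series_from_wells(wells: Iterable[WellMeasurement],
                      roles: tuple[WellRole, ...] = (WellRole.SAMPLE, WellRole.POS_CTRL),
                      ) -> dict[tuple[str, str], DoseResponseSeries]:
    """Group wells by (compound, cell model) and normalize each series."""
    grouped: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for w in wells:
        if w.role in roles:
            grouped.setdefault((w.compound_id, w.cell_model_id), []).append(
                (w.conc_um, w.signal)
            )
    return {
        (cid, mid): normalize_series(pairs, compound_id=cid, cell_model_id=mid)
        for (cid, mid), pairs in grouped.items()
    }


def fit_screen(wells: Iterable[WellMeasurement],
               roles: tuple[WellRole, ...] = (WellRole.SAMPLE, WellRole.POS_CTRL),
               ) -> dict[tuple[str, str], FitResult]:
    """Normalize and fit every compound x cell model series in a well list."""
    return {
        key: fit_4pl(series)
        for key, series in series_from_wells(wells, roles).items()
    }


def write_fit_table(fits: Mapping[tuple[str, str], FitResult], path) -> None:
    """Write fits as a TSV (``drug_fits.tsv`` schema)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["compound_id", "cell_model_id", "top", "bottom",
                         "log10_ic50", "hill", "converged", "r2", "auc"])
        for (cid, mid), f in sorted(fits.items()):
            writer.writerow([cid, mid, repr(f.top), repr(f.bottom),
                             repr(f.log10_ic50), repr(f.hill),
                             int(f.converged), repr(f.r2), repr(f.auc)])


def read_fit_table(path) -> dict[tuple[str, str], FitResult]:
    import csv
    from pathlib import Path

    fits: dict[tuple[str, str], FitResult] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            fits[(row["compound_id"], row["cell_model_id"])] = FitResult(
                top=float(row["top"]), bottom=float(row["bottom"]),
                log10_ic50=float(row["log10_ic50"]), hill=float(row["hill"]),
                converged=bool(int(row["converged"])),
                r2=float(row["r2"]), auc=float(row["auc"]),
            )
    return fits
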