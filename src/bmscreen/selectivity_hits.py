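"""Tumor-vs-control selectivity scoring, staged hit selection, and
pharmacogenomic annotation of hits.

Selectivity here is a z-score on normalized AUCs: how many (floored)
standard deviations the tumor culture's AUC sits below the mean AUC of the
non-neoplastic controls (HFB, PBC). Scores below -2 mark a compound as
selectively antitumor. This decision rule is distinct from the classic
Zhang Z'-factor assay-quality statistic, which is provided separately as
:func:`compute_zprime_factor`.

Hit selection is a staged funnel over per-compound metrics:

  stage 1  fit quality      R² (tumor series) > r2_min   (default 0.8)
  stage 2  efficacy         AUC (tumor)       < auc_max  (default 0.75)
  stage 3  selectivity      Z' score          < z_max    (default -2)

The final hit set is the conjunction; stage ordering only shapes the
funnel counts.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .dose_response import FitResult
from .screen_io import CompoundRecord, ValidationError, VariantCall

__all__ = [
    "DrugMetrics",
    "FunnelCounts",
    "compute_zprime_selectivity",
    "compute_zprime_factor",
    "build_drug_metrics",
    "select_hits",
    "summarize_target_families",
    "flag_genetic_support",
]

logger = logging.getLogger(__name__)

R2_MIN_DEFAULT = 0.8
AUC_MAX_DEFAULT = 0.75
Z_MAX_DEFAULT = -2.0
SD_FLOOR_DEFAULT = 0.05


@dataclass(frozen=True)
class DrugMetrics:
    """Per-compound screen metrics and staged pass flags."""

    compound_id: str
    auc_tumor: float
    auc_hfb: float
    auc_pbc: float
    zprime: float
    r2_tumor: float
    converged: bool = True
    pass_r2: bool = False
    pass_auc: bool = False
    pass_z: bool = False
    is_hit: bool = False
    target_family: str = ""
    genetic_support: bool = False


@dataclass(frozen=True)
class FunnelCounts:
    """Compound counts surviving each selection stage."""

    n_screened: int
    n_fit_pass: int
    n_effective: int
    n_selective: int

    def __post_init__(self) -> None:
        if not (self.n_screened >= self.n_fit_pass >= self.n_effective
                >= self.n_selective >= 0):
            raise ValidationError(f"funnel counts not monotone: {self}")


def compute_zprime_selectivity(auc_tumor: float, auc_controls: Sequence[float],
                               sd_floor: float = SD_FLOOR_DEFAULT) -> float:
    """Tumor AUC in (floored) SD units relative to the control AUCs.

    Returns ``(auc_tumor - mean(controls)) / max(sample_sd(controls),
    sd_floor)``; negative when the tumor culture is more drug-sensitive
    than the non-neoplastic controls. The SD floor guards against
    division blow-ups with only two control models.
    """
    if len(auc_controls) < 2:
        raise ValidationError(f"need >= 2 control AUCs, got {len(auc_controls)}")
    if sd_floor <= 0:
        raise ValidationError("sd_floor must be positive")
    mean = statistics.fmean(auc_controls)
    sd = statistics.stdev(auc_controls)
    return (auc_tumor - mean) / max(sd, sd_floor)


def compute_zprime_factor(mu_p: float, sd_p: float, mu_n: float, sd_n: float) -> float:
    """The classic Z'-factor assay-quality statistic:
    ``1 - 3(sd_p + sd_n) / |mu_p - mu_n|``; at most 1."""
    if mu_p == mu_n:
        raise ValidationError("Z'-factor undefined for equal means")
    return 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)


def build_drug_metrics(fits: Mapping[tuple[str, str], FitResult],
                       tumor_model_id: str,
                       hfb_model_id: str = "HFB",
                       pbc_model_id: str = "PBC",
                       library: Mapping[str, CompoundRecord] | None = None,
                       sd_floor: float = SD_FLOOR_DEFAULT,
                       exclude: Sequence[str] = ()) -> list[DrugMetrics]:
    """Assemble per-compound metrics from per-(compound, model) fits.

    Compounds listed in ``exclude`` (e.g. the positive controls) are
    skipped. A compound missing a control-model fit, or whose control fit
    did not converge, gets a NaN Z' (it can never pass the selectivity
    stage).
    """
    compounds = sorted({cid for cid, mid in fits if mid == tumor_model_id
                        and cid not in set(exclude)})
    metrics: list[DrugMetrics] = []
    for cid in compounds:
        ft = fits[(cid, tumor_model_id)]
        fh = fits.get((cid, hfb_model_id))
        fp = fits.get((cid, pbc_model_id))
        auc_h = fh.auc if fh is not None and fh.converged else float("nan")
        auc_p = fp.auc if fp is not None and fp.converged else float("nan")
        if ft.converged and math.isfinite(auc_h) and math.isfinite(auc_p):
            z = compute_zprime_selectivity(ft.auc, [auc_h, auc_p], sd_floor)
        else:
            z = float("nan")
        family = library[cid].target_family if library and cid in library else ""
        metrics.append(DrugMetrics(
            compound_id=cid, auc_tumor=ft.auc, auc_hfb=auc_h, auc_pbc=auc_p,
            zprime=z, r2_tumor=ft.r2, converged=ft.converged,
            target_family=family,
        ))
    return metrics


def select_hits(metrics: Sequence[DrugMetrics], *,
                r2_min: float = R2_MIN_DEFAULT,
                auc_max: float = AUC_MAX_DEFAULT,
                z_max: float = Z_MAX_DEFAULT,
                ) -> tuple[list[DrugMetrics], FunnelCounts]:
    """Apply the staged R² -> AUC -> Z' funnel and annotate pass flags.

    Non-converged fits and NaN metrics fail their stage. Returns the
    annotated metrics (all compounds, not just hits) and the funnel
    counts.
    """
    annotated: list[DrugMetrics] = []
    n_fit = n_eff = n_sel = 0
    for m in metrics:
        p_r2 = bool(m.converged and math.isfinite(m.r2_tumor) and m.r2_tumor > r2_min)
        p_auc = bool(p_r2 and math.isfinite(m.auc_tumor) and m.auc_tumor < auc_max)
        p_z = bool(p_auc and math.isfinite(m.zprime) and m.zprime < z_max)
        n_fit += p_r2
        n_eff += p_auc
        n_sel += p_z
        annotated.append(replace(m, pass_r2=p_r2, pass_auc=p_auc, pass_z=p_z,
                                 is_hit=p_z))
    return annotated, FunnelCounts(len(metrics), n_fit, n_eff, n_sel)


def summarize_target_families(hits: Sequence[DrugMetrics],
                              library: Mapping[str, CompoundRecord],
                              ) -> list[tuple[str, int, float]]:
    """Distribution of hits over target families: (family, count, fraction).

    Fractions sum to 1 over families; sorted by descending count then
    family name. Raises if a hit is missing from the library.
    """
    counts: dict[str, int] = {}
    for h in hits:
        if h.compound_id not in library:
            raise ValidationError(f"hit {h.compound_id!r} missing from compound library")
        family = library[h.compound_id].target_family
        counts[family] = counts.get(family, 0) + 1
    total = sum(counts.values())
    return [(fam, n, n / total)
            for fam, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def flag_genetic_support(metrics: Sequence[DrugMetrics],
                         variants: Sequence[VariantCall],
                         library: Mapping[str, CompoundRecord],
                         gene_to_family: Mapping[str, Sequence[str]] | None = None,
                         ) -> list[DrugMetrics]:
    """Mark compounds whose target is supported by a detected variant.

    A compound is supported when some variant gene is one of its annotated
    target genes, or maps — via ``gene_to_family`` (direct targets and
    downstream-pathway links, e.g. STK11 -> ERK, TP53 -> HDAC/HSP90,
    ATM -> MEK) — to the compound's target family. Variant genes with no
    mapping are logged and ignored.
    """
    gene_to_family = gene_to_family or {}
    variant_genes = {v.gene for v in variants}
    supported_families: set[str] = set()
    for gene in sorted(variant_genes):
        families = gene_to_family.get(gene)
        if families:
            supported_families.update(families)
        else:
            logger.info("variant gene %s has no target-family mapping", gene)

    out: list[DrugMetrics] = []
    for m in metrics:
        rec = library.get(m.compound_id)
        direct = bool(rec and variant_genes.intersection(rec.target_genes))
        family = m.target_family or (rec.target_family if rec else "")
        via_family = bool(family and family in supported_families)
        out.append(replace(m, genetic_support=direct or via_family))
    return out
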