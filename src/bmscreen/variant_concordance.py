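"""Tissue-vs-culture variant matching and allele-fraction concordance.

Gene-panel calls from a resected tumor sample and its matched short-term
culture are paired on the exact (gene, cDNA HGVS) key — matching on the
cDNA notation because not every call carries a protein-level annotation.
Per-patient concordance is ``matched / max(n_tissue, n_culture)``; a fully
preserved mutational profile gives 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .screen_io import ValidationError, VariantCall, VariantSource, read_variant_table

__all__ = [
    "MatchedVariant",
    "match_variants",
    "patient_concordance",
    "concordance_report",
    "split_by_patient",
    "load_reference_variants",
    "load_gene_to_family",
]


@dataclass(frozen=True)
class MatchedVariant:
    """A variant seen in both tissue and matched culture, with its
    allele-fraction shift (culture minus tissue, percentage points)."""

    patient_id: str
    gene: str
    c_hgvs: str
    af_tissue: float
    af_culture: float

    @property
    def delta_af(self) -> float:
        return self.af_culture - self.af_tissue


def match_variants(tissue: Sequence[VariantCall], culture: Sequence[VariantCall],
                   ) -> tuple[list[MatchedVariant], list[VariantCall], list[VariantCall]]:
    """Pair tissue and culture calls on the exact (gene, cDNA HGVS) key.

    Returns (matches sorted by gene, unmatched tissue, unmatched culture).
    Each call participates in at most one match. All calls must share one
    patient (sample) ID.
    """
    patients = {v.sample_id for v in tissue} | {v.sample_id for v in culture}
    if len(patients) > 1:
        raise ValidationError(f"mixed patient IDs in one match: {sorted(patients)}")
    patient_id = next(iter(patients)) if patients else ""

    culture_by_key: dict[tuple[str, str], list[VariantCall]] = {}
    for v in culture:
        culture_by_key.setdefault(v.match_key, []).append(v)

    matches: list[MatchedVariant] = []
    unmatched_tissue: list[VariantCall] = []
    for t in tissue:
        pool = culture_by_key.get(t.match_key)
        if pool:
            c = pool.pop(0)
            matches.append(MatchedVariant(
                patient_id=patient_id, gene=t.gene, c_hgvs=t.c_hgvs,
                af_tissue=t.af_percent, af_culture=c.af_percent))
        else:
            unmatched_tissue.append(t)
    unmatched_culture = [c for pool in culture_by_key.values() for c in pool]
    matches.sort(key=lambda m: (m.gene, m.c_hgvs))
    return matches, unmatched_tissue, unmatched_culture


def patient_concordance(n_tissue: int, n_culture: int, n_matched: int) -> float:
    """Fraction of the larger call set that is shared: matched / max(n, m)."""
    denom = max(n_tissue, n_culture)
    return n_matched / denom if denom else float("nan")


def split_by_patient(calls: Iterable[VariantCall],
                     ) -> dict[str, tuple[list[VariantCall], list[VariantCall]]]:
    """Group a mixed-source call list into patient -> (tissue, culture)."""
    out: dict[str, tuple[list[VariantCall], list[VariantCall]]] = {}
    for v in calls:
        tissue, culture = out.setdefault(v.sample_id, ([], []))
        (tissue if v.source is VariantSource.TISSUE else culture).append(v)
    return out


def concordance_report(patients: Mapping[str, tuple[Sequence[VariantCall],
                                                    Sequence[VariantCall]]],
                       ) -> pd.DataFrame:
    """Per-patient concordance table with a pooled "ALL" row.

    Columns: patient_id, n_tissue, n_culture, n_matched, concordance,
    mean_abs_delta_af.
    """
    if not patients:
        raise ValidationError("concordance_report needs >= 1 patient")
    rows = []
    total_t = total_c = total_m = 0
    all_deltas: list[float] = []
    for patient_id in sorted(patients):
        tissue, culture = patients[patient_id]
        matches, _, _ = match_variants(list(tissue), list(culture))
        deltas = [abs(m.delta_af) for m in matches]
        rows.append({
            "patient_id": patient_id,
            "n_tissue": len(tissue),
            "n_culture": len(culture),
            "n_matched": len(matches),
            "concordance": patient_concordance(len(tissue), len(culture), len(matches)),
            "mean_abs_delta_af": (sum(deltas) / len(deltas)) if deltas else float("nan"),
        })
        total_t += len(tissue)
        total_c += len(culture)
        total_m += len(matches)
        all_deltas.extend(deltas)
    rows.append({
        "patient_id": "ALL",
        "n_tissue": total_t,
        "n_culture": total_c,
        "n_matched": total_m,
        "concordance": patient_concordance(total_t, total_c, total_m),
        "mean_abs_delta_af": (sum(all_deltas) / len(all_deltas)) if all_deltas else float("nan"),
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

# Patients with one tissue/culture pair each in the packaged reference set;
# the additional relapse-tissue sample carries the suffixed ID "BM36-2" and
# is excluded from the default five-patient report.
REFERENCE_PATIENTS = ("BM28", "BM31", "BM32", "BM35", "BM36")


def load_reference_variants() -> list[VariantCall]:
    """The packaged tissue/culture variant table for the five reference
    brain-metastasis patients (plus the BM36 relapse sample as BM36-2)."""
    path = resources.files("bmscreen.data") / "reference_variants.tsv"
    return read_variant_table(str(path))


def load_gene_to_family() -> dict[str, tuple[str, ...]]:
    """The packaged gene -> target-family map (direct targets plus
    downstream-pathway links used for genetic-support flagging)."""
    import csv

    path = resources.files("bmscreen.data") / "gene_to_family.tsv"
    mapping: dict[str, tuple[str, ...]] = {}
    with path.open() as fh:  # type: ignore[call-arg]
        for row in csv.DictReader(fh, delimiter="\t"):
            mapping[row["gene"].strip()] = tuple(
                f for f in row["families"].split(";") if f)
    return mapping
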