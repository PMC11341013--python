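"""Three-stage discovery of potentially pathogenic CH mutations in TII cells.

The cascade filters matched tumor/blood variant calls:

1. **Protein-altering** — keep missense, nonsense, indel and splice-site
   variants; drop intergenic, intronic, synonymous and UTR variants.
2. **CH-in-TII window** — keep variants seen in a patient's blood at a VAF
   strictly inside the clonal-hematopoiesis window (default 2%-25%, above the
   ctDNA range and below the germline band) *and* present in the same
   patient's tumor — the signature of a blood clone infiltrating the tumor.
3. **Pathogenicity** — keep variants that are frequent in the tumor cohort
   (> 5% of samples), essentially absent from the population reference
   (< 0.01%), expressed in at least one tumor-infiltrating immune cell type,
   and called damaging by both SIFT and PolyPhen.

All threshold comparisons are strict, exactly as stated; ties fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import CONSEQUENCES, IMMUNE_CELL_TYPES, PROTEIN_ALTERING


class MissingAnnotationError(KeyError):
    """A candidate variant lacks a required annotation (never silently false)."""


@dataclass(frozen=True)
class PanelConfig:
    """Thresholds of the discovery cascade (all comparisons strict)."""

    vaf_low: float = 0.02  # blood VAF must exceed this (CH definition)
    vaf_high: float = 0.25  # and stay below this (germline exclusion)
    tumor_vaf_min: float = 0.0  # tumor presence: any called VAF above this
    tumor_freq_min: float = 0.05  # fraction of tumor-cohort samples carrying it
    popfreq_max: float = 1e-4  # population reference frequency ceiling
    expression_min_fraction: float = 0.01  # detected-cell fraction per cell type
    immune_cell_types: tuple[str, ...] = IMMUNE_CELL_TYPES
    sift_max: float = 0.05  # SIFT "deleterious" below this
    polyphen_min: float = 0.446  # PolyPhen "possibly damaging" above this

    def __post_init__(self) -> None:
        if not 0 <= self.vaf_low < self.vaf_high <= 1:
            raise ValueError("require 0 <= vaf_low < vaf_high <= 1")


@dataclass(frozen=True)
class PanelMutation:
    """A candidate mutation with its four criterion values and pass flags."""

    variant_id: str
    gene: str
    tumor_cohort_freq: float
    population_freq: float
    expressed_in_tii: bool
    expressed_cell_types: tuple[str, ...]
    sift_damaging: bool
    polyphen_damaging: bool
    selected: bool


@dataclass
class PanelResult:
    """Outcome of the full cascade: selected panel, per-variant table, funnel."""

    panel: list[PanelMutation]
    table: pd.DataFrame  # one row per distinct input variant, with drop_reason
    funnel: dict[str, int]  # total -> protein_altering -> ch_tii -> selected

    @property
    def variant_ids(self) -> list[str]:
        return [m.variant_id for m in self.panel]


def is_protein_altering(consequence: str) -> bool:
    """True for missense, nonsense, frameshift/inframe indel and splice-site."""
    if consequence not in CONSEQUENCES:
        raise ValueError(f"unknown consequence: {consequence!r}")
    return consequence in PROTEIN_ALTERING


def select_ch_tii(
    calls: pd.DataFrame,
    vaf_low: float = 0.02,
    vaf_high: float = 0.25,
    tumor_vaf_min: float = 0.0,
) -> pd.DataFrame:
    """Keep calls whose blood VAF lies strictly inside the CH window and whose
    tumor shows the variant in the same patient.

    Returns the surviving (sample, variant) call rows.
    """
    if not 0 <= vaf_low < vaf_high <= 1:
        raise ValueError("require 0 <= vaf_low < vaf_high <= 1")
    if calls.empty:
        raise ValueError("calls table is empty")
    keep = (
        (calls["vaf_blood"] > vaf_low)
        & (calls["vaf_blood"] < vaf_high)
        & (calls["vaf_tumor"] > tumor_vaf_min)
    )
    return calls.loc[keep].reset_index(drop=True)


def tumor_cohort_frequency(
    variant_id: str,
    calls: pd.DataFrame,
    n_cohort_samples: int,
    tumor_vaf_min: float = 0.0,
) -> float:
    """Fraction of cohort samples whose tumor carries the variant.

    Duplicate calls for one sample count once (distinct-sample count).
    """
    if n_cohort_samples < 1:
        raise ValueError("n_cohort_samples must be >= 1")
    rows = calls[(calls["variant_id"] == variant_id) & (calls["vaf_tumor"] > tumor_vaf_min)]
    return rows["sample_id"].nunique() / n_cohort_samples


def _require(value, variant_id: str, name: str):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise MissingAnnotationError(
            f"variant {variant_id!r}: missing annotation {name!r}"
        )
    return value


def passes_pathogenicity(
    variant_id: str,
    gene: str,
    tumor_cohort_freq: float,
    population_freq: float,
    tii_expression: Mapping[str, float],
    sift_score: float,
    polyphen_score: float,
    config: PanelConfig | None = None,
) -> PanelMutation:
    """Evaluate the four pathogenicity criteria for one candidate.

    ``selected`` is true only when the mutation is frequent in the tumor
    cohort, rare in the population reference, expressed in at least one
    immune cell type, and damaging by both predictors. Each flag is recorded
    individually. Missing annotations raise, they are never treated as false.
    """
    cfg = config or PanelConfig()
    population_freq = _require(population_freq, variant_id, "population_freq")
    sift_score = _require(sift_score, variant_id, "sift_score")
    polyphen_score = _require(polyphen_score, variant_id, "polyphen_score")
    if tii_expression is None:
        raise MissingAnnotationError(
            f"variant {variant_id!r}: missing annotation 'tii_expression'"
        )
    expressed_types = tuple(
        ct
        for ct in cfg.immune_cell_types
        if _require(tii_expression.get(ct), variant_id, f"expr_{ct}")
        >= cfg.expression_min_fraction
    )
    sift_damaging = sift_score < cfg.sift_max
    polyphen_damaging = polyphen_score > cfg.polyphen_min
    selected = (
        tumor_cohort_freq > cfg.tumor_freq_min
        and population_freq < cfg.popfreq_max
        and len(expressed_types) > 0
        and sift_damaging
        and polyphen_damaging
    )
    return PanelMutation(
        variant_id=variant_id,
        gene=gene,
        tumor_cohort_freq=tumor_cohort_freq,
        population_freq=population_freq,
        expressed_in_tii=len(expressed_types) > 0,
        expressed_cell_types=expressed_types,
        sift_damaging=sift_damaging,
        polyphen_damaging=polyphen_damaging,
        selected=selected,
    )


def _annotation_lookup(annotations: pd.DataFrame) -> pd.DataFrame:
    required = {"variant_id", "population_freq", "sift_score", "polyphen_score"}
    missing = required - set(annotations.columns)
    if missing:
        raise MissingAnnotationError(
            f"annotation table lacks columns: {sorted(missing)}"
        )
    return annotations.set_index("variant_id")


def discover_panel(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    config: PanelConfig | None = None,
    n_cohort_samples: int | None = None,
) -> PanelResult:
    """Run the full three-stage cascade over a matched tumor/blood call table.

    ``annotations`` is keyed by variant_id with population_freq, sift_score,
    polyphen_score and per-cell-type ``expr_<type>`` columns. The tumor-cohort
    frequency denominator defaults to the number of distinct samples in
    ``calls``. Output panel is sorted by variant_id; the per-variant table
    records a machine-readable drop reason for every rejected variant.
    """
    cfg = config or PanelConfig()
    if calls.empty:
        raise ValueError("calls table is empty")
    n_cohort = n_cohort_samples or int(calls["sample_id"].nunique())
    ann = _annotation_lookup(annotations)

    variants = (
        calls[["variant_id", "gene", "consequence"]]
        .drop_duplicates("variant_id")
        .sort_values("variant_id")
        .reset_index(drop=True)
    )
    total = len(variants)

    pa_mask = variants["consequence"].map(is_protein_altering)
    pa_variants = set(variants.loc[pa_mask, "variant_id"])

    stage1_calls = calls[calls["variant_id"].isin(pa_variants)]
    if stage1_calls.empty:
        ch_variants: set[str] = set()
    else:
        kept = select_ch_tii(
            stage1_calls, cfg.vaf_low, cfg.vaf_high, cfg.tumor_vaf_min
        )
        ch_variants = set(kept["variant_id"])

    # distinct-tumor-sample carriage counts for every variant, any called VAF
    carrier_counts = (
        calls[calls["vaf_tumor"] > cfg.tumor_vaf_min]
        .groupby("variant_id")["sample_id"]
        .nunique()
    )

    records = []
    panel: list[PanelMutation] = []
    for row in variants.itertuples(index=False):
        vid, gene, consequence = row.variant_id, row.gene, row.consequence
        rec: dict = {
            "variant_id": vid,
            "gene": gene,
            "consequence": consequence,
            "protein_altering": vid in pa_variants,
            "ch_tii": vid in ch_variants,
            "tumor_cohort_freq": np.nan,
            "population_freq": np.nan,
            "expressed_in_tii": pd.NA,
            "sift_damaging": pd.NA,
            "polyphen_damaging": pd.NA,
            "selected": False,
            "drop_reason": "",
        }
        if vid not in pa_variants:
            rec["drop_reason"] = "not_protein_altering"
        elif vid not in ch_variants:
            rec["drop_reason"] = "outside_ch_tii_window"
        else:
            if vid not in ann.index:
                raise MissingAnnotationError(
                    f"variant {vid!r}: no row in annotation table"
                )
            a = ann.loc[vid]
            freq = carrier_counts.get(vid, 0) / n_cohort
            expr = {
                ct: a.get(f"expr_{ct}", None) for ct in cfg.immune_cell_types
            }
            mut = passes_pathogenicity(
                vid,
                gene,
                freq,
                a["population_freq"],
                expr,
                a["sift_score"],
                a["polyphen_score"],
                cfg,
            )
            rec.update(
                tumor_cohort_freq=mut.tumor_cohort_freq,
                population_freq=mut.population_freq,
                expressed_in_tii=mut.expressed_in_tii,
                sift_damaging=mut.sift_damaging,
                polyphen_damaging=mut.polyphen_damaging,
                selected=mut.selected,
            )
            if mut.selected:
                panel.append(mut)
            else:
                reasons = []
                if not mut.tumor_cohort_freq > cfg.tumor_freq_min:
                    reasons.append("tumor_freq_at_or_below_min")
                if not mut.population_freq < cfg.popfreq_max:
                    reasons.append("population_freq_too_high")
                if not mut.expressed_in_tii:
                    reasons.append("not_expressed_in_tii")
                if not (mut.sift_damaging and mut.polyphen_damaging):
                    reasons.append("not_damaging")
                rec["drop_reason"] = ";".join(reasons)
        records.append(rec)

    table = pd.DataFrame(records)
    funnel = {
        "total": total,
        "protein_altering": int(table["protein_altering"].sum()),
        "ch_tii": int(table["ch_tii"].sum()),
        "selected": int(table["selected"].sum()),
    }
    panel.sort(key=lambda m: m.variant_id)
    return PanelResult(panel=panel, table=table, funnel=funnel)


def panel_table(result: PanelResult) -> pd.DataFrame:
    """Selected panel as a flat table (one row per selected mutation)."""
    rows = [
        {
            "variant_id": m.variant_id,
            "gene": m.gene,
            "tumor_cohort_freq": m.tumor_cohort_freq,
            "population_freq": m.population_freq,
            "expressed_in_tii": m.expressed_in_tii,
            "expressed_cell_types": ",".join(m.expressed_cell_types),
            "sift_damaging": m.sift_damaging,
            "polyphen_damaging": m.polyphen_damaging,
        }
        for m in result.panel
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "gene", "tumor_cohort_freq", "population_freq",
            "expressed_in_tii", "expressed_cell_types", "sift_damaging",
            "polyphen_damaging",
        ],
    )
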