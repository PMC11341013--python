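"""Synthetic sequencing-cohort generator with planted ground truth.

This module stands in for the sequencing side of a clonal-hematopoiesis (CH)
screening study: a matched tumor/blood exome discovery cohort, per-variant
annotations (population frequency, deleteriousness scores, per-cell-type
expression in tumor-infiltrating immune cells), and multi-cohort blood
screening profiles whose cancer/non-cancer labels follow a known logistic
risk model over a planted mutation panel.

Every generator takes an explicit integer seed and is bit-reproducible for a
fixed seed. Variant classes emulate the biology the downstream filters key
on:

* ``germline_common`` — heterozygous germline variants, blood and tumor VAF
  near 0.5, common in the population reference.
* ``somatic_private`` — tumor-private somatic mutations; blood VAF in the
  circulating-tumor-DNA range (< 1%) when detected at all.
* ``ch_passenger`` — clonally expanded blood mutations (blood VAF in the
  2–25% CH window, present in tumor via infiltrating immune cells) that fail
  at least one pathogenicity criterion.
* ``ch_pathogenic`` — the planted panel: CH mutations satisfying all four
  selection criteria by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

CONSEQUENCES: tuple[str, ...] = (
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "splice_site",
    "synonymous",
    "intronic",
    "intergenic",
    "utr",
)

#: Consequence classes considered protein-altering in the discovery cascade.
PROTEIN_ALTERING: frozenset[str] = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "splice_site"}
)

IMMUNE_CELL_TYPES: tuple[str, ...] = ("B", "T", "NKT", "monocyte_macrophage")
CELL_TYPES: tuple[str, ...] = IMMUNE_CELL_TYPES + ("tumor", "other")

TRUE_CLASSES: tuple[str, ...] = (
    "germline_common",
    "somatic_private",
    "ch_passenger",
    "ch_pathogenic",
)

CANCER = "cancer"
NON_CANCER = "non_cancer"

#: Columns common to blood-profile tables, ahead of the per-variant VAF columns.
PROFILE_META_COLUMNS: tuple[str, ...] = ("sample_id", "cohort_id", "label")


@dataclass(frozen=True)
class CohortSpec:
    """One sequencing cohort: homogeneous label, mean exome read depth."""

    cohort_id: str
    size: int
    label: str  # "cancer" | "non_cancer"
    depth: int  # mean reads per locus
    development: bool  # True: split into train/val/test; False: wholly test


#: The 18-cohort topology used by the demo pipeline: cohort sizes, labels,
#: mean read depths and development/independent-test roles of the real study
#: cohorts (five cancer + five non-cancer development cohorts, eight
#: independent test cohorts; 1,992 samples in total).
TABLE1_COHORTS: tuple[CohortSpec, ...] = (
    CohortSpec("prjeb50602", 16, CANCER, 117, True),
    CohortSpec("prjna439205", 4, CANCER, 260, True),
    CohortSpec("prjna610493", 32, CANCER, 167, True),
    CohortSpec("prjna613408", 13, CANCER, 166, True),
    CohortSpec("tcga-luad", 440, CANCER, 177, True),
    CohortSpec("cptac-luad", 113, CANCER, 341, False),
    CohortSpec("cptac-lusc", 102, CANCER, 333, False),
    CohortSpec("prjeb47088", 22, CANCER, 36, False),
    CohortSpec("tcga-lusc", 214, CANCER, 173, False),
    CohortSpec("prjeb35045", 58, NON_CANCER, 95, True),
    CohortSpec("prjna167318", 163, NON_CANCER, 170, True),
    CohortSpec("prjna262923", 190, NON_CANCER, 195, True),
    CohortSpec("prjna342304", 46, NON_CANCER, 191, True),
    CohortSpec("prjna790003", 200, NON_CANCER, 166, True),
    CohortSpec("prjeb5736", 147, NON_CANCER, 68, False),
    CohortSpec("prjna421434", 91, NON_CANCER, 324, False),
    CohortSpec("prjna532465", 38, NON_CANCER, 457, False),
    CohortSpec("prjna59849", 103, NON_CANCER, 118, False),
)


@dataclass(frozen=True)
class VariantCatalogEntry:
    """A variant locus with its annotations and hidden generating class.

    ``carriage_prob`` is the per-patient probability that the variant is
    carried in the discovery (tumor) cohort; for panel mutations it equals
    the cancer-conditional prevalence and exceeds the 5% tumor-frequency
    criterion with margin.
    """

    variant_id: str
    gene: str
    consequence: str
    population_freq: float  # gnomAD-like population allele frequency
    sift_score: float  # lower = more damaging
    polyphen_score: float  # higher = more damaging
    tii_expression: Mapping[str, float]  # cell type -> detected-cell fraction
    true_class: str
    carriage_prob: float


@dataclass
class SimulationTruth:
    """Generating parameters: the planted panel and its logistic risk model."""

    panel: list[str]
    beta0_true: float
    beta_true: dict[str, float]
    prevalence_cancer: dict[str, float]
    prevalence_noncancer: dict[str, float]
    cohort_depths: dict[str, int]

    def __post_init__(self) -> None:
        for name in ("beta_true", "prevalence_cancer", "prevalence_noncancer"):
            m = getattr(self, name)
            if set(m) != set(self.panel):
                raise ValueError(f"{name} keys must equal the panel")
        if any(d <= 0 for d in self.cohort_depths.values()):
            raise ValueError("cohort depths must be positive")


@dataclass(frozen=True)
class VafParams:
    """VAF distribution settings for the matched discovery cohort.

    Germline VAF is truncated-normal around the heterozygous expectation 0.5;
    CH VAFs are uniform strictly inside the open (2%, 25%) window so that
    boundary comparisons are unambiguous; tumor-private somatic mutations show
    a ctDNA-range blood signal (< 1%) in a fraction of carriers.
    """

    germline_mean: float = 0.5
    germline_sd: float = 0.03
    germline_lo: float = 0.3
    germline_hi: float = 0.7
    ch_lo: float = 0.021
    ch_hi: float = 0.249
    somatic_tumor_lo: float = 0.05
    somatic_tumor_hi: float = 0.40
    ctdna_hi: float = 0.009
    somatic_blood_detect: float = 0.5
    depth: int = 180


# thresholds the planted panel must clear, mirrored from the discovery filters
_POPFREQ_MAX = 1e-4
_EXPRESSION_MIN = 0.01
_SIFT_MAX = 0.05
_POLYPHEN_MIN = 0.446
_TUMOR_FREQ_MIN = 0.05

_CRITERIA = ("tumor_freq", "population_freq", "expression", "damaging")


def _uniform_open(rng: np.random.Generator, lo: float, hi: float, size=None):
    """Uniform draw avoiding the exact endpoints."""
    u = rng.uniform(lo, hi, size)
    return u


def _expression_profile(
    rng: np.random.Generator, expressed_in_immune: bool
) -> dict[str, float]:
    prof: dict[str, float] = {}
    for ct in CELL_TYPES:
        prof[ct] = float(rng.uniform(0.0, 0.009))
    if expressed_in_immune:
        k = int(rng.integers(1, len(IMMUNE_CELL_TYPES) + 1))
        chosen = rng.choice(len(IMMUNE_CELL_TYPES), size=k, replace=False)
        for j in chosen:
            prof[IMMUNE_CELL_TYPES[j]] = float(rng.uniform(0.05, 0.6))
    prof["tumor"] = float(rng.uniform(0.0, 0.6))
    return prof


def expected_criterion_flags(entry: VariantCatalogEntry) -> dict[str, bool]:
    """Recompute the four pathogenicity-criterion predicates for an entry.

    The tumor-frequency criterion is evaluated on the generating carriage
    probability (the expected cohort frequency).
    """
    expressed = any(
        entry.tii_expression.get(ct, 0.0) >= _EXPRESSION_MIN
        for ct in IMMUNE_CELL_TYPES
    )
    return {
        "tumor_freq": entry.carriage_prob > _TUMOR_FREQ_MIN,
        "population_freq": entry.population_freq < _POPFREQ_MAX,
        "expression": expressed,
        "damaging": entry.sift_score < _SIFT_MAX
        and entry.polyphen_score > _POLYPHEN_MIN,
    }


def _panel_entry(rng: np.random.Generator, vid: str, gene: str):
    p_c = float(rng.uniform(0.12, 0.45))
    beta = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.5))
    p_n = float(expit(logit(p_c) - beta))
    entry = VariantCatalogEntry(
        variant_id=vid,
        gene=gene,
        consequence=str(rng.choice(sorted(PROTEIN_ALTERING))),
        population_freq=float(rng.uniform(0.0, 0.8e-4)),
        sift_score=float(rng.uniform(0.0, 0.045)),
        polyphen_score=float(rng.uniform(0.5, 0.99)),
        tii_expression=_expression_profile(rng, expressed_in_immune=True),
        true_class="ch_pathogenic",
        carriage_prob=p_c,
    )
    return entry, beta, p_c, p_n


def _passenger_entry(
    rng: np.random.Generator, vid: str, gene: str, fail: Sequence[str]
) -> VariantCatalogEntry:
    """A CH passenger failing exactly the criteria named in ``fail``."""
    carriage = float(rng.uniform(0.12, 0.45))
    popfreq = float(rng.uniform(0.0, 0.8e-4))
    sift = float(rng.uniform(0.0, 0.045))
    polyphen = float(rng.uniform(0.5, 0.99))
    expressed = True
    if "tumor_freq" in fail:
        carriage = float(rng.uniform(0.005, 0.02))
    if "population_freq" in fail:
        popfreq = float(rng.uniform(5e-4, 5e-2))
    if "expression" in fail:
        expressed = False
    if "damaging" in fail:
        # fail SIFT, PolyPhen, or both
        which = int(rng.integers(3))
        if which in (0, 2):
            sift = float(rng.uniform(0.1, 0.9))
        if which in (1, 2):
            polyphen = float(rng.uniform(0.0, 0.4))
    return VariantCatalogEntry(
        variant_id=vid,
        gene=gene,
        consequence=str(rng.choice(sorted(PROTEIN_ALTERING))),
        population_freq=popfreq,
        sift_score=sift,
        polyphen_score=polyphen,
        tii_expression=_expression_profile(rng, expressed_in_immune=expressed),
        true_class="ch_passenger",
        carriage_prob=carriage,
    )


def _germline_entry(rng: np.random.Generator, vid: str, gene: str):
    popfreq = float(rng.uniform(0.01, 0.5))
    return VariantCatalogEntry(
        variant_id=vid,
        gene=gene,
        consequence=str(rng.choice(CONSEQUENCES)),
        population_freq=popfreq,
        sift_score=float(rng.uniform(0.0, 1.0)),
        polyphen_score=float(rng.uniform(0.0, 1.0)),
        tii_expression=_expression_profile(rng, expressed_in_immune=bool(rng.integers(2))),
        true_class="germline_common",
        # Hardy-Weinberg carrier probability, capped
        carriage_prob=float(min(0.6, 2.0 * popfreq)),
    )


def _somatic_entry(rng: np.random.Generator, vid: str, gene: str):
    return VariantCatalogEntry(
        variant_id=vid,
        gene=gene,
        consequence=str(rng.choice(sorted(PROTEIN_ALTERING))),
        population_freq=float(rng.uniform(0.0, 0.8e-4)),
        sift_score=float(rng.uniform(0.0, 1.0)),
        polyphen_score=float(rng.uniform(0.0, 1.0)),
        tii_expression=_expression_profile(rng, expressed_in_immune=bool(rng.integers(2))),
        true_class="somatic_private",
        carriage_prob=float(rng.uniform(0.02, 0.2)),
    )


def make_variant_catalog(
    n_variants: int,
    panel_size: int,
    seed: int,
    cohort_depths: Mapping[str, int] | None = None,
) -> tuple[list[VariantCatalogEntry], SimulationTruth]:
    """Generate a variant catalog with ``panel_size`` planted panel mutations.

    Exactly ``panel_size`` entries have ``true_class == "ch_pathogenic"`` and
    satisfy all four pathogenicity criteria by construction; among the
    remaining entries at least one CH passenger fails each criterion
    individually, so every filter has a discriminating test case. Requires
    at least four non-panel slots (``panel_size <= n_variants - 4``).

    Returns the catalog (ordered by variant_id) and the generating truth:
    per-panel-mutation label-conditional carriage prevalences and the implied
    logistic risk model, whose coefficients are the per-mutation log
    odds-ratios ``logit(prevalence_cancer) - logit(prevalence_noncancer)``.
    """
    if n_variants < 10:
        raise ValueError("n_variants must be at least 10")
    if panel_size < 0:
        raise ValueError("panel_size must be non-negative")
    if panel_size > n_variants - 4:
        raise ValueError(
            "panel_size must leave at least 4 non-panel variants "
            f"(got panel_size={panel_size}, n_variants={n_variants})"
        )
    rng = np.random.default_rng(seed)

    width = max(4, len(str(n_variants - 1)))
    vids = [f"v{i:0{width}d}" for i in range(n_variants)]
    genes = [f"GENE{i:0{width}d}" for i in range(n_variants)]

    n_rest = n_variants - panel_size
    n_passenger = max(4, int(round(0.4 * n_rest)))
    n_germline = min(int(round(0.3 * n_rest)), n_rest - n_passenger)
    n_somatic = n_rest - n_passenger - n_germline

    # class layout shuffled over variant ids so id order carries no signal
    classes = (
        ["ch_pathogenic"] * panel_size
        + ["ch_passenger"] * n_passenger
        + ["germline_common"] * n_germline
        + ["somatic_private"] * n_somatic
    )
    order = rng.permutation(n_variants)
    assigned = [None] * n_variants
    for slot, cls in zip(order, classes):
        assigned[slot] = cls

    # the first four passengers (in id order) fail one criterion each
    passenger_rank = 0
    entries: list[VariantCatalogEntry] = []
    panel: list[str] = []
    beta_true: dict[str, float] = {}
    prev_c: dict[str, float] = {}
    prev_n: dict[str, float] = {}
    for i, cls in enumerate(assigned):
        vid, gene = vids[i], genes[i]
        if cls == "ch_pathogenic":
            entry, beta, p_c, p_n = _panel_entry(rng, vid, gene)
            panel.append(vid)
            beta_true[vid] = beta
            prev_c[vid] = p_c
            prev_n[vid] = p_n
        elif cls == "ch_passenger":
            if passenger_rank < len(_CRITERIA):
                fail: tuple[str, ...] = (_CRITERIA[passenger_rank],)
            else:
                k = int(rng.integers(1, len(_CRITERIA) + 1))
                idx = rng.choice(len(_CRITERIA), size=k, replace=False)
                fail = tuple(_CRITERIA[j] for j in sorted(idx))
            passenger_rank += 1
            entry = _passenger_entry(rng, vid, gene, fail)
        elif cls == "germline_common":
            entry = _germline_entry(rng, vid, gene)
        else:
            entry = _somatic_entry(rng, vid, gene)
        entries.append(entry)

    # Bayes-optimal intercept at equal class priors given class-conditional
    # independence of mutation carriage.
    beta0 = float(
        sum(np.log((1.0 - prev_c[v]) / (1.0 - prev_n[v])) for v in panel)
    )
    depths = dict(cohort_depths) if cohort_depths is not None else {
        c.cohort_id: c.depth for c in TABLE1_COHORTS
    }
    truth = SimulationTruth(
        panel=sorted(panel),
        beta0_true=beta0,
        beta_true=beta_true,
        prevalence_cancer=prev_c,
        prevalence_noncancer=prev_n,
        cohort_depths=depths,
    )
    return entries, truth


def catalog_annotations(catalog: Iterable[VariantCatalogEntry]) -> pd.DataFrame:
    """Flatten a catalog into the annotation table the discovery stage reads.

    Columns: variant_id, gene, consequence, population_freq, sift_score,
    polyphen_score, and one ``expr_<cell type>`` column per cell type.
    """
    rows = []
    for e in catalog:
        row = {
            "variant_id": e.variant_id,
            "gene": e.gene,
            "consequence": e.consequence,
            "population_freq": e.population_freq,
            "sift_score": e.sift_score,
            "polyphen_score": e.polyphen_score,
        }
        for ct in CELL_TYPES:
            row[f"expr_{ct}"] = e.tii_expression.get(ct, 0.0)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("variant_id").reset_index(drop=True)


def _truncnorm_vaf(rng, params: VafParams, size: int) -> np.ndarray:
    a = (params.germline_lo - params.germline_mean) / params.germline_sd
    b = (params.germline_hi - params.germline_mean) / params.germline_sd
    return stats.truncnorm.rvs(
        a, b, loc=params.germline_mean, scale=params.germline_sd,
        size=size, random_state=rng,
    )


def simulate_matched_discovery_cohort(
    catalog: Sequence[VariantCatalogEntry],
    n_patients: int,
    params: VafParams | None = None,
    seed: int = 0,
    cohort_id: str = "discovery",
) -> pd.DataFrame:
    """Simulate matched tumor/blood variant calls for a discovery cohort.

    One row per (patient, carried variant) with columns sample_id, cohort_id,
    variant_id, gene, consequence, vaf_tumor, vaf_blood, depth. Carriage is
    Bernoulli per patient with the catalog entry's carriage probability; VAFs
    follow the entry's class (germline near 0.5 in both tissues, CH inside
    the open 2-25% window in both, tumor-private somatic with ctDNA-range
    blood signal at most).
    """
    catalog = list(catalog)
    if not catalog:
        raise ValueError("catalog must not be empty")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    params = params or VafParams()
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_patients - 1)))
    sample_ids = np.array(
        [f"{cohort_id}-p{i:0{width}d}" for i in range(n_patients)]
    )

    frames = []
    for e in catalog:
        carried = rng.random(n_patients) < e.carriage_prob
        k = int(carried.sum())
        if k == 0:
            continue
        if e.true_class == "germline_common":
            vt = _truncnorm_vaf(rng, params, k)
            vb = _truncnorm_vaf(rng, params, k)
        elif e.true_class == "somatic_private":
            vt = _uniform_open(rng, params.somatic_tumor_lo, params.somatic_tumor_hi, k)
            detected = rng.random(k) < params.somatic_blood_detect
            vb = np.where(detected, rng.uniform(0.001, params.ctdna_hi, k), 0.0)
        else:  # ch_passenger / ch_pathogenic: CH clone visible in both tissues
            vt = _uniform_open(rng, params.ch_lo, params.ch_hi, k)
            vb = _uniform_open(rng, params.ch_lo, params.ch_hi, k)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids[carried],
                    "cohort_id": cohort_id,
                    "variant_id": e.variant_id,
                    "gene": e.gene,
                    "consequence": e.consequence,
                    "vaf_tumor": np.asarray(vt, dtype=float),
                    "vaf_blood": np.asarray(vb, dtype=float),
                    "depth": int(params.depth),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "sample_id", "cohort_id", "variant_id", "gene",
                "consequence", "vaf_tumor", "vaf_blood", "depth",
            ]
        )
    calls = pd.concat(frames, ignore_index=True)
    return calls.sort_values(["sample_id", "variant_id"], kind="mergesort").reset_index(
        drop=True
    )


def _normalize_label(label) -> str:
    if label in (CANCER, 1, True):
        return CANCER
    if label in (NON_CANCER, 0, False):
        return NON_CANCER
    raise ValueError(f"unknown cohort label: {label!r}")


def simulate_screening_cohorts(
    truth: SimulationTruth,
    cohort_spec: Iterable[CohortSpec | tuple],
    seed: int = 0,
    vaf_lo: float = 0.021,
    vaf_hi: float = 0.249,
) -> pd.DataFrame:
    """Simulate blood VAF profiles for label-pure screening cohorts.

    ``cohort_spec`` is an iterable of :class:`CohortSpec` or
    ``(cohort_id, size, label)`` tuples; every cohort is homogeneous in
    label (all cancer or all non-cancer). Per sample, carriage of each panel
    mutation is Bernoulli with the label-conditional prevalence, and carried
    mutations get a true blood VAF uniform inside the open CH window.
    Returns a wide table: sample_id, cohort_id, label (1 = cancer), then one
    column per panel variant holding the *true* (uncensored) VAF.
    """
    rng = np.random.default_rng(seed)
    panel = truth.panel
    frames = []
    for spec in cohort_spec:
        if isinstance(spec, CohortSpec):
            cid, size, label = spec.cohort_id, spec.size, spec.label
        else:
            cid, size, label = spec[0], spec[1], spec[2]
        label = _normalize_label(label)
        if size < 1:
            raise ValueError(f"cohort {cid!r} has non-positive size")
        prev = (
            truth.prevalence_cancer if label == CANCER else truth.prevalence_noncancer
        )
        block = {
            "sample_id": [f"{cid}-s{i:04d}" for i in range(size)],
            "cohort_id": cid,
            "label": 1 if label == CANCER else 0,
        }
        df = pd.DataFrame(block)
        for vid in panel:
            carried = rng.random(size) < prev[vid]
            vaf = np.where(carried, rng.uniform(vaf_lo, vaf_hi, size), 0.0)
            df[vid] = vaf
        frames.append(df)
    if not frames:
        raise ValueError("cohort_spec must not be empty")
    return pd.concat(frames, ignore_index=True)


def apply_depth_censoring(
    profiles: pd.DataFrame,
    cohort_depths: Mapping[str, int],
    min_alt_reads: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Censor true blood VAFs through finite read depth.

    For each carried mutation the alternate-read count is drawn
    ``Binomial(depth, true VAF)`` with the cohort's mean depth; the observed
    VAF is ``alt/depth`` when at least ``min_alt_reads`` alternate reads are
    seen, else 0. Mutations absent in truth stay absent. Adds a ``depth``
    column.
    """
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    rng = np.random.default_rng(seed)
    out = profiles.copy()
    variant_cols = [c for c in profiles.columns if c not in PROFILE_META_COLUMNS]
    out["depth"] = 0
    for cid in pd.unique(profiles["cohort_id"]):
        if cid not in cohort_depths:
            raise ValueError(f"no read depth for cohort {cid!r}")
        depth = int(cohort_depths[cid])
        if depth <= 0:
            raise ValueError(f"non-positive depth for cohort {cid!r}")
        mask = (profiles["cohort_id"] == cid).to_numpy()
        true_vaf = profiles.loc[mask, variant_cols].to_numpy(dtype=float)
        alt = rng.binomial(depth, true_vaf)
        observed = np.where(alt >= min_alt_reads, alt / depth, 0.0)
        out.loc[mask, variant_cols] = observed
        out.loc[mask, "depth"] = depth
    return out


def detection_probability(true_vaf: float, depth: int, min_alt_reads: int = 3) -> float:
    """Exact probability of detecting a mutation: P[Binom(depth, vaf) >= k]."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    return float(stats.binom.sf(min_alt_reads - 1, depth, true_vaf))
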