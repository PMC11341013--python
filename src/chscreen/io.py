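"""Readers and writers for the pipeline's text formats.

Canonical formats: MAF-like TSV for matched variant calls ('.' for missing),
CSV for blood VAF matrices and leaderboards, TSV for panel / coefficient /
split tables, JSON for truth, model and evaluation reports. Every writer's
output is re-readable by the matching reader. An optional VCF reader maps
records with AF/DP fields onto matched-call rows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .evaluation import EvalReport
from .model import FittedModel
from .panel import PanelResult, panel_table
from .simulate import CONSEQUENCES, SimulationTruth


class DataError(ValueError):
    """Malformed input data (file-level or row-level, with location)."""


CALL_COLUMNS = (
    "sample_id", "cohort_id", "variant_id", "gene", "consequence",
    "vaf_tumor", "vaf_blood", "depth",
)


def read_matched_calls(path) -> pd.DataFrame:
    """Read a MAF-like TSV of matched tumor/blood variant calls.

    Validates the header, consequence vocabulary and VAF ranges; '.' is
    parsed as missing. Errors name the offending line and field.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"sample_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise DataError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required columns: {sorted(missing)}")
    errors = []
    for col in ("vaf_tumor", "vaf_blood"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(vals < 0) | (vals > 1) | (df[col].notna() & vals.isna())]
        for i in bad[:10]:
            # +2: header line plus 1-based numbering
            errors.append(f"line {i + 2}: {col} out of [0,1]: {df.loc[i, col]!r}")
        df[col] = vals
    bad_cons = df.index[~df["consequence"].isin(CONSEQUENCES)]
    for i in bad_cons[:10]:
        errors.append(f"line {i + 2}: unknown consequence {df.loc[i, 'consequence']!r}")
    if errors:
        raise DataError(f"{path}: " + "; ".join(errors))
    return df


def write_matched_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, na_rep=".")


def read_profiles(path) -> pd.DataFrame:
    """Read a blood VAF matrix CSV (sample_id, cohort_id, label, variants...)."""
    df = pd.read_csv(path)
    for col in ("sample_id", "cohort_id"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    return df


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)


def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SimulationTruth(**d)


def write_model(model: FittedModel, path) -> None:
    payload = {
        "panel": model.panel,
        "beta0": model.beta0,
        "beta": model.beta.tolist(),
        "vaf_cutoff": model.vaf_cutoff,
        "class_weight": {str(k): v for k, v in model.class_weight.items()},
        "l2_strength": model.l2_strength,
        "converged": model.converged,
        "n_iter": model.n_iter,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model(path) -> FittedModel:
    with open(path) as fh:
        d = json.load(fh)
    return FittedModel(
        panel=d["panel"],
        beta0=d["beta0"],
        beta=np.asarray(d["beta"], dtype=float),
        vaf_cutoff=d["vaf_cutoff"],
        class_weight={int(k): v for k, v in d["class_weight"].items()},
        l2_strength=d["l2_strength"],
        converged=d["converged"],
        n_iter=d.get("n_iter", 0),
    )


def write_panel(result: PanelResult, path, funnel_path=None) -> None:
    panel_table(result).to_csv(path, sep="\t", index=False)
    if funnel_path is not None:
        with open(funnel_path, "w") as fh:
            json.dump(result.funnel, fh, indent=1, sort_keys=True)
            fh.write("\n")


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_split(split: pd.DataFrame, path) -> None:
    split.to_csv(path, sep="\t", index=False)


def read_split(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_eval_report(report: EvalReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_coefficients(stats_df: pd.DataFrame, path) -> None:
    stats_df.to_csv(path, sep="\t", index=True)


def read_coefficients(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant_id")


def read_vcf_calls(path, sample_id: str, cohort_id: str = "vcf") -> pd.DataFrame:
    """Map a (paired tumor/blood) VCF onto matched-call rows.

    Expects per-sample AF and DP FORMAT fields with two samples per record,
    tumor first then normal/blood; consequence is taken from a CSQ=/ANN=-free
    INFO key ``CONSEQUENCE`` when present, else ``missense`` is assumed.
    Requires :mod:`pysam` (optional dependency).
    """
    import pysam  # deferred: optional dependency

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) < 2:
            raise DataError(f"{path}: need tumor and blood sample columns")
        tumor, blood = samples[0], samples[1]
        for rec in vf:
            vid = f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alts[0] if rec.alts else '.'}"
            def _af(sample):
                af = rec.samples[sample].get("AF")
                if af is None:
                    return np.nan
                return float(af[0] if isinstance(af, tuple) else af)
            dp = rec.samples[blood].get("DP") or rec.info.get("DP", 0)
            cons = rec.info.get("CONSEQUENCE", "missense")
            if isinstance(cons, tuple):
                cons = cons[0]
            rows.append(
                {
                    "sample_id": sample_id,
                    "cohort_id": cohort_id,
                    "variant_id": vid,
                    "gene": rec.info.get("GENE", "."),
                    "consequence": cons,
                    "vaf_tumor": _af(tumor),
                    "vaf_blood": _af(blood),
                    "depth": int(dp),
                }
            )
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))
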