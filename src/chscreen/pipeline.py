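"""End-to-end pipeline: simulate, discover, split, select, refit, evaluate.

Stages run in a fixed order, each seeded from the run seed, and every
artifact lands in the output directory stamped with the configuration hash.
Two runs with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import io as cio
from . import model as mdl
from . import panel as pnl
from . import simulate as sim
from . import stats as st
from .config import RunConfig

log = logging.getLogger("chscreen")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _partition_matrix(profiles: pd.DataFrame, split: pd.DataFrame, panel, part):
    ids = split.loc[split["partition"] == part, "sample_id"]
    sub = profiles[profiles["sample_id"].isin(set(ids))]
    return mdl.build_vaf_matrix(sub, panel)


def run_pipeline(config: RunConfig, outdir, cohorts=None) -> dict:
    """Run the full study on synthetic cohorts and write all artifacts.

    ``cohorts`` defaults to the 18-cohort demo topology. Returns a summary
    dict (funnel counts, selected configuration, headline test metrics) that
    is also written to ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts = list(cohorts) if cohorts is not None else list(sim.TABLE1_COHORTS)
    seeds = _stage_seeds(config.seed)
    stage = "simulate"
    try:
        catalog, truth = sim.make_variant_catalog(
            config.n_variants, config.panel_size, seeds[0],
            cohort_depths={c.cohort_id: c.depth for c in cohorts},
        )
        calls = sim.simulate_matched_discovery_cohort(
            catalog, config.n_discovery_patients, seed=seeds[1]
        )
        annotations = sim.catalog_annotations(catalog)
        profiles_true = sim.simulate_screening_cohorts(truth, cohorts, seed=seeds[2])
        profiles = sim.apply_depth_censoring(
            profiles_true, truth.cohort_depths, config.min_alt_reads, seed=seeds[3]
        )
        cio.write_truth(truth, outdir / "truth.json")
        cio.write_matched_calls(calls, outdir / "discovery_calls.tsv")
        cio.write_profiles(profiles, outdir / "blood_profiles.csv")

        stage = "discover"
        pcfg = pnl.PanelConfig(
            vaf_low=config.vaf_low,
            vaf_high=config.vaf_high,
            tumor_freq_min=config.tumor_freq_min,
            popfreq_max=config.popfreq_max,
            expression_min_fraction=config.expression_min_fraction,
            sift_max=config.sift_max,
            polyphen_min=config.polyphen_min,
        )
        result = pnl.discover_panel(calls, annotations, pcfg)
        cio.write_panel(result, outdir / "panel.tsv", outdir / "funnel.json")
        panel = result.variant_ids
        if not panel:
            raise StageError("discover: empty panel, nothing to model")
        log.info("funnel: %s", result.funnel)

        stage = "split"
        by_cohort = {
            c.cohort_id: profiles.loc[
                profiles["cohort_id"] == c.cohort_id, "sample_id"
            ].tolist()
            for c in cohorts
        }
        development = [c.cohort_id for c in cohorts if c.development]
        split = ev.split_cohorts(
            by_cohort, development, config.test_frac, config.val_frac, seed=seeds[4]
        )
        cio.write_split(split, outdir / "split.tsv")

        stage = "grid"
        train_fm = _partition_matrix(profiles, split, panel, ev.TRAIN)
        val_fm = _partition_matrix(profiles, split, panel, ev.VALIDATION)
        test_fm = _partition_matrix(profiles, split, panel, ev.TEST)
        cutoffs = ev.default_cutoff_grid(
            config.cutoff_start, config.cutoff_stop, config.cutoff_step
        )
        hypers = [
            {"class_weight": cw, "l2_strength": l2, "tol": config.tol,
             "max_iter": config.max_iter}
            for cw in config.class_weight_options
            for l2 in config.l2_options
        ]
        if not cutoffs or not hypers:
            raise StageError("grid: empty grid")
        gs = ev.grid_search(train_fm, val_fm, cutoffs, hypers, cutpoint=config.cutpoint)
        gs.leaderboard.to_csv(outdir / "leaderboard.csv", index=False)
        log.info("grid: %d configs, best %s (batch mean %.4f)",
                 len(gs.leaderboard), gs.best_config, gs.best_score)

        stage = "refit"
        dev_ids = split.loc[split["partition"].isin([ev.TRAIN, ev.VALIDATION]), "sample_id"]
        dev_fm = mdl.build_vaf_matrix(
            profiles[profiles["sample_id"].isin(set(dev_ids))], panel
        )
        best = dict(gs.best_config)
        cutoff = best.pop("cutoff")
        final = mdl.fit_logistic(
            mdl.dichotomize(dev_fm, cutoff), vaf_cutoff=cutoff, **best
        )
        cio.write_model(final, outdir / "model.json")

        stage = "evaluate"
        report = ev.evaluate(final, test_fm, cutpoint=config.cutpoint)
        cio.write_eval_report(report, outdir / "eval_test.json")
        p_test = mdl.predict_matrix(final, test_fm)
        ev.roc_points(
            p_test.to_numpy(), test_fm.labels.loc[p_test.index].to_numpy()
        ).to_csv(outdir / "roc_test.csv", index=False)

        stage = "coefficients"
        boot = st.bootstrap_coefficients(
            mdl.dichotomize(dev_fm, cutoff),
            fit_config={"class_weight": final.class_weight,
                        "l2_strength": final.l2_strength,
                        "tol": config.tol, "max_iter": config.max_iter},
            B=config.bootstrap_B,
            seed=seeds[5],
        )
        report_df = st.coefficient_report(final, boot)
        cio.write_coefficients(report_df, outdir / "coefficients.tsv")

        summary = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "funnel": result.funnel,
            "panel_size": len(panel),
            "grid_size": int(len(gs.leaderboard)),
            "selected_config": {k: str(v) for k, v in gs.best_config.items()},
            "validation_batch_mean_accuracy": gs.best_score,
            "test": report.as_dict(),
            "coefficient_counts": report_df.attrs["counts"],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return summary
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"{stage}: {exc}") from exc
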