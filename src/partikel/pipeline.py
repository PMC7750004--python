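"""End-to-end orchestration: simulate -> cloze -> measures -> fits -> BFs -> report.

Every stochastic stage derives its seed deterministically from one master
seed, so a run with the same config produces byte-identical summary tables
(MCMC summaries reproduce to fixed seed and sampler version).  Stage outputs
are written as UTF-8 CSV under the configured output directory; a failure in
one stage halts the run with a stage-tagged error, leaving earlier artifacts
on disk.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cloze as cz
from . import decay
from . import eyemeasures as em
from . import synthetic as syn
from .bayesfactor import PRIOR_TIERS, bf_table_frame, compute_bf_table
from .models import (
    ContrastCoding,
    PriorSpec,
    fit_reading_model,
    write_posterior_table,
)

log = logging.getLogger("partikel")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class MCMCSettings:
    n_walkers: int = 32
    n_warmup: int = 600
    n_steps: int = 600


@dataclass
class PipelineConfig:
    """Round-trippable configuration of a full synthetic run."""

    master_seed: int = 1
    out_dir: str = "partikel_out"
    design: syn.ExperimentDesign = field(default_factory=syn.ExperimentDesign)
    spr_params: syn.GenerativeParams = field(
        default_factory=syn.GenerativeParams.spr_defaults
    )
    et_params: syn.GenerativeParams = field(
        default_factory=syn.GenerativeParams.et_defaults
    )
    cloze: syn.ClozeGenConfig = field(default_factory=syn.ClozeGenConfig)
    decay: decay.DecayConfig = field(default_factory=decay.DecayConfig)
    decay_n_small: int = 3
    decay_n_large: int = 18
    rt_min_ms: float = 100.0
    prior_tiers: dict = field(default_factory=lambda: dict(PRIOR_TIERS))
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    et_measures: tuple = ("ffd_ms",)
    run_bayes_factors: bool = True
    random_structure: str = "intercepts"

    def __post_init__(self) -> None:
        # every stage's seed is a fixed function of the master seed
        self.design = dataclasses.replace(self.design,
                                          seed=self.master_seed * 7 + 1)
        self.spr_params = dataclasses.replace(self.spr_params,
                                              seed=self.master_seed * 7 + 2)
        self.et_params = dataclasses.replace(self.et_params,
                                             seed=self.master_seed * 7 + 3)
        self.cloze = dataclasses.replace(self.cloze,
                                         seed=self.master_seed * 7 + 4)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["et_measures"] = list(self.et_measures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("design", syn.ExperimentDesign),
            ("spr_params", syn.GenerativeParams),
            ("et_params", syn.GenerativeParams),
            ("cloze", syn.ClozeGenConfig),
            ("decay", decay.DecayConfig),
            ("mcmc", MCMCSettings),
        ):
            if key in d and isinstance(d[key], dict):
                sub = d[key]
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                d[key] = typ(**sub)
        if "et_measures" in d:
            d["et_measures"] = tuple(d["et_measures"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ReportTables:
    condition_summaries: dict  # measure -> DataFrame
    median_split_summary: pd.DataFrame | None
    cloze_summary: pd.DataFrame | None
    posterior_tables: dict  # name -> DataFrame
    bf_tables: dict  # name -> DataFrame
    exclusion_log: pd.DataFrame
    seeds: dict


def bootstrap_condition_summary(
    trials: pd.DataFrame,
    value_column: str,
    group_columns: list[str],
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Condition mean with bootstrap 95% CI over by-participant means."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond, grp in trials.groupby(group_columns, sort=True):
        pm = grp.groupby("participant")[value_column].mean().to_numpy()
        mean = float(pm.mean())
        if len(pm) > 1:
            idx = rng.integers(0, len(pm), size=(n_boot, len(pm)))
            bm = pm[idx].mean(axis=1)
            lo, hi = np.percentile(bm, [2.5, 97.5])
        else:
            lo = hi = mean
        row = dict(zip(group_columns, cond if isinstance(cond, tuple) else (cond,)))
        row.update({"mean": mean, "ci_low": float(lo), "ci_high": float(hi),
                    "n_participants": len(pm)})
        rows.append(row)
    return pd.DataFrame(rows)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged and re-raised
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, out: Path):
    assignments = syn.build_latin_square(cfg.design)
    spr = syn.generate_spr_trials(cfg.design, cfg.spr_params)
    et, sequences = syn.generate_et_trials(cfg.design, cfg.et_params,
                                           emit_fixations=True)
    responses, targets = syn.generate_cloze_responses(cfg.cloze)
    syn.write_design_table(assignments, out / "design.csv")
    syn.write_spr_table(spr, out / "spr_trials.csv")
    et.to_csv(out / "et_trials.csv", index=False)
    syn.write_fixation_table(sequences, out / "fixations.csv")
    syn.write_cloze_table(responses, out / "cloze_responses.csv")
    return spr, et, sequences, responses, targets


@_stage("cloze")
def stage_cloze(cfg: PipelineConfig, out: Path, responses, targets):
    stats = [
        cz.compute_cloze_statistics(r, targets[r.item_id]) for r in responses
    ]
    summaries = [
        cz.summarize_condition(stats, lvl, seed=cfg.master_seed * 7 + 5)
        for lvl in ("small", "large", "short", "long")
    ]
    cz.write_summary_table(summaries, out / "cloze_summary.csv")
    selection = cz.select_items({
        item: [s for s in stats if s.item_id == item]
        for item in sorted({s.item_id for s in stats})
    })
    pd.DataFrame(
        [{"item": k, "outcome": v} for k, v in sorted(selection.reasons.items())]
    ).to_csv(out / "item_selection.csv", index=False)
    return stats, summaries, selection


@_stage("measures")
def stage_measures(cfg: PipelineConfig, out: Path, sequences):
    retained, exclusions = em.exclude_invalid_trials(sequences)
    region = em.particle_region(syn.PARTICLE_INDEX)
    measures = [em.compute_region_measures(s, region) for s in retained]
    em.write_measures(measures, out / "region_measures.csv")
    assert exclusions["retained"] + exclusions["blink/track loss"] == len(
        sequences
    ), "exclusion accounting failed"
    return measures, exclusions


@_stage("predictions")
def stage_predictions(cfg: PipelineConfig, out: Path):
    pred = decay.predict_design(cfg.decay, cfg.decay_n_small, cfg.decay_n_large)
    decay.write_prediction_table(pred, out / "decay_predictions.csv")
    return pred


@_stage("fit")
def stage_fit(cfg: PipelineConfig, out: Path, spr: pd.DataFrame,
              et: pd.DataFrame):
    coding = ContrastCoding()
    fits = {}
    mc = vars(cfg.mcmc)
    fits["spr_categorical"] = fit_reading_model(
        spr, coding, PriorSpec.self_paced_reading(), "reciprocal_speed",
        predictors="categorical", random_structure=cfg.random_structure,
        rt_min_ms=cfg.rt_min_ms, seed=cfg.master_seed * 7 + 6,
        n_walkers=mc["n_walkers"], n_warmup=mc["n_warmup"],
        n_steps=mc["n_steps"],
    )
    fits["spr_entropy"] = fit_reading_model(
        spr, coding, PriorSpec.self_paced_reading(), "reciprocal_speed",
        predictors="entropy", random_structure=cfg.random_structure,
        rt_min_ms=cfg.rt_min_ms, seed=cfg.master_seed * 7 + 7,
        n_walkers=mc["n_walkers"], n_warmup=mc["n_warmup"],
        n_steps=mc["n_steps"],
    )
    for col in cfg.et_measures:
        fits[f"et_{col[:-3]}"] = fit_reading_model(
            et, coding, PriorSpec.eye_tracking(), "log_ms",
            predictors="categorical", response_column=col,
            random_structure=cfg.random_structure,
            seed=cfg.master_seed * 7 + 8,
            n_walkers=mc["n_walkers"], n_warmup=mc["n_warmup"],
            n_steps=mc["n_steps"],
        )
    for name, fit in fits.items():
        write_posterior_table(fit, out / f"posterior_{name}.csv")
    return fits


@_stage("bf")
def stage_bf(cfg: PipelineConfig, out: Path, spr: pd.DataFrame):
    coding = ContrastCoding()
    mc = vars(cfg.mcmc)
    results = compute_bf_table(
        spr, coding, PriorSpec.self_paced_reading(), "reciprocal_speed",
        predictors="categorical", random_structure=cfg.random_structure,
        tiers=cfg.prior_tiers, seed=cfg.master_seed * 7 + 9,
        fit_kwargs=dict(rt_min_ms=cfg.rt_min_ms, n_walkers=mc["n_walkers"],
                        n_warmup=mc["n_warmup"], n_steps=mc["n_steps"]),
    )
    table = bf_table_frame(results)
    table.to_csv(out / "bf_spr_categorical.csv", index=False)
    return {"spr_categorical": table}


@_stage("report")
def stage_report(cfg: PipelineConfig, out: Path, spr, et, measures,
                 exclusions, fits, bf_tables) -> ReportTables:
    seed = cfg.master_seed * 7 + 10
    cond_cols = ["set_size", "distance"]
    summaries = {}
    clean_spr = spr[spr["rt_ms"] >= cfg.rt_min_ms]
    summaries["spr_rt_ms"] = bootstrap_condition_summary(
        clean_spr, "rt_ms", cond_cols, seed=seed
    )
    summaries["question_accuracy"] = bootstrap_condition_summary(
        spr.assign(acc=spr["question_correct"].astype(float) * 100),
        "acc", cond_cols, seed=seed + 1,
    )
    for col in ("ffd_ms", "fprt_ms", "tft_ms", "rpd_ms"):
        clean = et[~et["blink_or_trackloss"]]
        summaries[f"et_{col}"] = bootstrap_condition_summary(
            clean, col, cond_cols, seed=seed + 2
        )

    # entropy median split (descriptive only; entropy stays continuous in fits)
    labels = cz.median_split(
        dict(zip(clean_spr.index, clean_spr["entropy_bits"]))
    )
    split = clean_spr.assign(
        entropy_category=[labels[i] for i in clean_spr.index]
    )
    median_split_summary = bootstrap_condition_summary(
        split, "rt_ms", ["entropy_category", "distance"], seed=seed + 3
    )

    n_in = len(spr)
    n_fast = int((spr["rt_ms"] < cfg.rt_min_ms).sum())
    exclusion_rows = [
        {"stage": "self_paced", "reason": f"rt < {cfg.rt_min_ms:g} ms",
         "n_excluded": n_fast, "n_in": n_in, "n_retained": n_in - n_fast},
        {"stage": "eye_tracking", "reason": "blink/track loss",
         "n_excluded": exclusions["blink/track loss"],
         "n_in": exclusions["retained"] + exclusions["blink/track loss"],
         "n_retained": exclusions["retained"]},
    ]
    exclusion_log = pd.DataFrame(exclusion_rows)
    assert (exclusion_log["n_in"]
            == exclusion_log["n_retained"] + exclusion_log["n_excluded"]).all()

    tables = ReportTables(
        condition_summaries=summaries,
        median_split_summary=median_split_summary,
        cloze_summary=None,
        posterior_tables={k: v.params for k, v in fits.items()},
        bf_tables=bf_tables,
        exclusion_log=exclusion_log,
        seeds={"master_seed": cfg.master_seed},
    )
    write_report(tables, out)
    return tables


def write_report(tables: ReportTables, out_dir) -> list[Path]:
    """Write every report table as CSV plus a human-readable summary.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.condition_summaries.items():
        p = out / f"summary_{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if tables.median_split_summary is not None:
        p = out / "summary_median_split.csv"
        tables.median_split_summary.to_csv(p, index=False)
        written.append(p)
    p = out / "exclusions.csv"
    tables.exclusion_log.to_csv(p, index=False)
    written.append(p)

    lines = [f"seeds: {tables.seeds}"]
    if not tables.bf_tables:
        lines.append("bayes factors: not computed")
    for name, df in tables.bf_tables.items():
        lines.append(f"BF table {name} (per-measure, no family-wise "
                     f"error correction):")
        lines.append(df.to_string(index=False))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    written.append(out / "summary.txt")
    return written


def run_pipeline(cfg: PipelineConfig) -> ReportTables:
    """Run all stages in order; see module docstring for guarantees."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config.yaml")
    spr, et, sequences, responses, targets = stage_simulate(cfg, out)
    cloze_stats, cloze_summaries, _selection = stage_cloze(
        cfg, out, responses, targets
    )
    measures, exclusions = stage_measures(cfg, out, sequences)
    stage_predictions(cfg, out)
    fits = stage_fit(cfg, out, spr, et)
    bf_tables = stage_bf(cfg, out, spr) if cfg.run_bayes_factors else {}
    tables = stage_report(cfg, out, spr, et, measures, exclusions, fits,
                          bf_tables)
    tables.cloze_summary = pd.read_csv(out / "cloze_summary.csv")
    return tables
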