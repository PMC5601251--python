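"""End-to-end orchestration: simulate or load -> filter -> age curves -> decomposition -> report.

:func:`run_analysis` executes, per species x sex: the age-support filter,
the candidate age-function fits (null / linear / quadratic / single-threshold
scan, optionally double thresholds), AIC model averaging and the breakpoint
confidence interval, the early/late split at the best single threshold
(with per-species-sex overrides), and the within/among-individual
decomposition models.  Outputs are plain CSV tables plus a text run log
recording every filter's input/output counts, the seed, and per-fit
diagnostics.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import records as rec
from . import age_models as am
from . import decompose as dc
from .simulate import SimulationConfig, simulate_population, species_profile_defaults

__all__ = ["AnalysisConfig", "run_analysis", "summarize_population", "load_config"]

log = logging.getLogger("reproage")


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    Exactly one of ``input_path`` (a breeding-records CSV) or
    ``simulation`` (profile name or SimulationConfig mapping) must be set.
    """

    input_path: str | None = None
    simulation: dict | str | None = None
    species: list | None = None  # subset, default all present
    sexes: list | None = None
    min_age_count: int = 5
    study_end: int | None = None  # default: last observed season
    gap_rule: dict | None = None
    threshold_grid: dict = field(default_factory=dict)  # (species, sex) -> list of ages
    min_side: int = 25
    include_double_threshold: bool = False
    cutoff_overrides: dict = field(default_factory=dict)  # (species, sex) -> cutoff age
    robustness_terms: list = field(default_factory=list)
    out_dir: str = "reproage_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be given")


def load_config(path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from YAML (keys mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("threshold_grid", "cutoff_overrides"):
        if key in raw and raw[key]:
            raw[key] = {
                (k.split("/")[0], k.split("/")[1]): v for k, v in raw[key].items()
            }
    return AnalysisConfig(**raw)


def summarize_population(records: pd.DataFrame) -> dict:
    """Descriptive summaries: per-species mean annual success, failure stages,
    between-species correlations of annual success, within-pair age correlation.

    Mean annual breeding success is the mean of yearly success means, with
    an SE across years (the among-year variability is the relevant scale for
    comparing species).  Between-species Pearson correlations use the years
    both species were monitored (>= 3 shared years required).  If a
    ``failure_stage`` column is present (values ``incubation`` /
    ``chick_rearing`` on failures), the proportion of failures during
    incubation is reported.  When partner identities and ages are known,
    the within-pair mean-age correlation is computed across pairs.
    """
    out = {}
    yearly = (
        records.groupby(["species", "season"])["outcome"].mean().rename("success").reset_index()
    )
    rows = []
    for sp, sub in yearly.groupby("species"):
        rows.append(
            {
                "species": sp,
                "mean_annual_success": sub["success"].mean(),
                "se_annual_success": sub["success"].std(ddof=1) / np.sqrt(len(sub)),
                "n_years": len(sub),
            }
        )
    out["annual_success"] = pd.DataFrame(rows)

    if "failure_stage" in records.columns:
        fails = records[records["outcome"] == 0]
        rows = []
        for sp, sub in fails.groupby("species"):
            known = sub["failure_stage"].notna().sum()
            if known:
                rows.append(
                    {
                        "species": sp,
                        "prop_failures_incubation": (sub["failure_stage"] == "incubation").sum()
                        / known,
                        "n_failures": known,
                    }
                )
        out["failure_stages"] = pd.DataFrame(rows)

    species = sorted(yearly["species"].unique())
    rows = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            wa = yearly[yearly["species"] == a].set_index("season")["success"]
            wb = yearly[yearly["species"] == b].set_index("season")["success"]
            shared = wa.index.intersection(wb.index)
            if len(shared) < 3:
                raise ValueError(f"fewer than 3 shared years for {a} vs {b}")
            r = float(np.corrcoef(wa[shared], wb[shared])[0, 1])
            rows.append({"species_a": a, "species_b": b, "r": r, "n_years": len(shared)})
    if rows:
        out["between_species_correlation"] = pd.DataFrame(rows)

    if "partner_id" in records.columns:
        both = records.dropna(subset=["partner_id"])
        if not both.empty:
            key = both.apply(
                lambda r: tuple(sorted((r["individual_id"], r["partner_id"]))), axis=1
            )
            both = both.assign(pair_key=key)
            mean_age = both.groupby(["species", "pair_key", "sex"])["age"].mean().unstack("sex")
            rows = []
            for sp, sub in mean_age.groupby(level="species"):
                sub = sub.dropna()
                if len(sub) >= 3 and {"M", "F"} <= set(sub.columns):
                    rows.append(
                        {
                            "species": sp,
                            "r": float(np.corrcoef(sub["M"], sub["F"])[0, 1]),
                            "n_pairs": len(sub),
                        }
                    )
            if rows:
                out["within_pair_age_correlation"] = pd.DataFrame(rows)
    return out


def _stage(name, n_in, n_out):
    log.info("stage %-22s in=%-6d out=%-6d", name, n_in, n_out)


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline; returns the report bundle and writes CSVs.

    The bundle maps: ``records``, ``histories``, ``life_history`` (Table-1
    style), ``population`` (descriptives), and per species x sex:
    ``model_summary``, ``curve`` (age, fit, se, averaged_fit),
    ``threshold_ci``, ``decomposition`` (Table-2 style, early + late
    stacked).  Reruns with the same config and seed are byte-identical.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.input_path is not None:
        df = rec.read_records(config.input_path)
        log.info("loaded %d records from %s", len(df), config.input_path)
    else:
        sim = config.simulation
        if isinstance(sim, str):
            frames = []
            for prof in sim.split("+"):
                c = species_profile_defaults(prof.strip())
                c.seed = int(rng.integers(0, 2**31 - 1))
                frames.append(simulate_population(c)[0])
            df = pd.concat(frames, ignore_index=True)
        else:
            c = SimulationConfig(**dict(sim))
            if c.seed is None:
                c.seed = int(rng.integers(0, 2**31 - 1))
            df = simulate_population(c)[0]
        log.info("simulated %d records (seed %d)", len(df), config.seed)

    if config.species:
        n0 = len(df)
        df = df[df["species"].isin(config.species)].reset_index(drop=True)
        _stage("species subset", n0, len(df))
    if config.sexes:
        n0 = len(df)
        df = df[df["sex"].isin(config.sexes)].reset_index(drop=True)
        _stage("sex subset", n0, len(df))
    if df.empty:
        raise ValueError("no records left after subsetting")

    study_end = int(config.study_end if config.study_end is not None else df["season"].max())
    histories = rec.build_histories(df, study_end, gap_rule=config.gap_rule)
    annotated = rec.derive_covariates(df, histories)

    bundle = {
        "records": annotated,
        "histories": histories,
        "life_history": rec.summarize_life_history(histories),
        "population": summarize_population(annotated),
        "groups": {},
    }
    rec.write_records(annotated, out_dir / "records.csv")
    histories.to_csv(out_dir / "histories.csv", index=False)
    bundle["life_history"].to_csv(out_dir / "life_history.csv", index=False)
    for name, tab in bundle["population"].items():
        tab.to_csv(out_dir / f"population_{name}.csv", index=False)

    decomp_frames = []
    for (sp, sex), sub in annotated.groupby(["species", "sex"]):
        tag = f"{sp}_{sex}"
        try:
            n0 = len(sub)
            filtered = rec.filter_age_support(sub, min_count=config.min_age_count)
            _stage(f"age support {tag}", n0, len(filtered))
        except ValueError as e:
            raise ValueError(f"[age-support filter, {tag}] {e}") from e

        grid = config.threshold_grid.get((sp, sex))
        try:
            models, scan = am.fit_candidate_models(
                filtered, grid=grid, min_side=config.min_side,
                include_double=config.include_double_threshold,
            )
        except ValueError as e:
            raise ValueError(f"[age-model scan, {tag}] {e}") from e
        ages_pred = np.arange(filtered["age"].min(), filtered["age"].max() + 1)
        model_set = am.select_and_average(models, ages_pred)
        best_t = int(scan.best.thresholds[0])
        log.info("%s: best single threshold %d (95%% CI %d-%d), best model %s",
                 tag, best_t, scan.ci_low, scan.ci_high, model_set.best.spec.label)

        cutoff = int(config.cutoff_overrides.get((sp, sex), best_t))
        try:
            early, late = dc.split_at_threshold(filtered, cutoff)
            early_res = dc.fit_early_model(early, species=sp, sex=sex)
            late_res = dc.fit_late_model(
                late, robustness=config.robustness_terms, species=sp, sex=sex
            )
        except ValueError as e:
            raise ValueError(f"[decomposition, {tag}] {e}") from e
        _stage(f"early model {tag}", len(early), early_res.n_obs)
        _stage(f"late model {tag}", len(late), late_res.n_obs)

        group = {
            "model_summary": model_set.summary(),
            "curve": model_set.to_frame(),
            "threshold": {"best": best_t, "ci_low": scan.ci_low, "ci_high": scan.ci_high,
                          "cutoff_used": cutoff},
            "early": early_res,
            "late": late_res,
        }
        bundle["groups"][(sp, sex)] = group
        group["model_summary"].to_csv(out_dir / f"models_{tag}.csv", index=False)
        group["curve"].to_csv(out_dir / f"curve_{tag}.csv", index=False)
        decomp_frames.append(early_res.to_frame())
        decomp_frames.append(late_res.to_frame())

    decomp = pd.concat(decomp_frames, ignore_index=True)
    decomp.to_csv(out_dir / "decomposition.csv", index=False)
    bundle["decomposition"] = decomp
    with open(out_dir / "run_config.json", "w") as fh:
        json.dump({k: v for k, v in asdict(config).items()
                   if k not in ("threshold_grid", "cutoff_overrides")}, fh, indent=2, default=str)
    log.info("report written to %s", out_dir)
    return bundle
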