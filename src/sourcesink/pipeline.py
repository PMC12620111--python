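"""End-to-end orchestration: simulate -> fit -> select -> contribute.

Each stage is a plain function usable from Python; the click commands in
:mod:`sourcesink.cli` are thin wrappers.  A single :class:`RunConfig` holds
paths, seeds (independent named substreams of a master seed), candidate
model sets and simulation settings, and every tabular output carries a
metadata comment header (config hash, seeds) so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contributions import age_proportions, propagate
from .fecundity import (BreedingAttemptsSpec, fit_breeding_attempts,
                        fit_fledged, fit_nest_survival)
from .io import read_dataset, write_dataset
from .multistate import (MultistateSpec, encode_histories, estimability_screen,
                         fit_multistate)
from .schedule import InvasionSchedule
from .selection import ModelRanking, rank_models
from .simulate import CohortDesign, Dataset, simulate_dataset
from .truth import TruthSurface, VitalRateTable, default_schedule, default_truth, realize_truth

__all__ = ["RunConfig", "run_simulate", "run_fit", "run_contribute",
           "run_pipeline", "build_vital_rates", "summarize_contributions",
           "FitResults"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Substreams of ``seed`` drive simulation, optimiser jitter and the
    bootstrap independently, so stages can be rerun in isolation.
    """

    out_dir: Path = Path("run")
    seed: int = 1
    n_reps: int = 10_000
    cycle_length: int = 58
    k_max: int = 30
    clamp: bool = True
    #: candidate tsi forms per vital rate; trimmed sets speed up a run
    survival_forms: tuple[str, ...] = ("null", "linear", "quadratic", "log")
    movement_forms: tuple[str, ...] = ("null", "linear", "quadratic", "log")
    theta_forms: tuple[str, ...] = ("null", "linear", "quadratic", "log")
    attempts_forms: tuple[str, ...] = ("null", "linear", "quadratic", "log")
    nest_forms: tuple[str, ...] = ("null", "linear", "quadratic", "log")
    fledged_forms: tuple[str, ...] = ("null", "linear", "quadratic", "log")
    juv_interaction: bool = True
    detection: str = "constant"
    #: attempt-detection probability supplied externally (None = estimate it
    #: freely; annual counts alone cannot separate it from the attempt rate)
    attempt_detection: float | None = 0.8
    n_starts: int = 5
    gtol: float = 1e-8
    nest_random_effects: bool = True
    schedule: InvasionSchedule = field(default_factory=default_schedule)
    truth: TruthSurface = field(default_factory=default_truth)
    cohorts: CohortDesign = field(default_factory=CohortDesign)

    # -- derived seeds -----------------------------------------------------

    def _sub(self, name: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    @property
    def sim_seed(self) -> int:
        return self._sub("simulate")

    @property
    def fit_seed(self) -> int:
        return self._sub("fit")

    @property
    def boot_seed(self) -> int:
        return self._sub("bootstrap")

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir), "seed": self.seed,
            "n_reps": self.n_reps, "cycle_length": self.cycle_length,
            "k_max": self.k_max, "clamp": self.clamp,
            "survival_forms": list(self.survival_forms),
            "movement_forms": list(self.movement_forms),
            "theta_forms": list(self.theta_forms),
            "attempts_forms": list(self.attempts_forms),
            "nest_forms": list(self.nest_forms),
            "fledged_forms": list(self.fledged_forms),
            "juv_interaction": self.juv_interaction,
            "detection": self.detection,
            "attempt_detection": self.attempt_detection,
            "n_starts": self.n_starts,
            "gtol": self.gtol, "nest_random_effects": self.nest_random_effects,
            "schedule": self.schedule.to_dict(),
            "truth": self.truth.to_dict(),
            "cohorts": {"nestlings": self.cohorts.nestlings,
                        "adults": self.cohorts.adults},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        if "out_dir" in kw:
            kw["out_dir"] = Path(kw["out_dir"])
        if "schedule" in kw:
            kw["schedule"] = InvasionSchedule.from_dict(kw["schedule"])
        if "truth" in kw:
            kw["truth"] = TruthSurface.from_dict(kw["truth"])
        if "cohorts" in kw:
            kw["cohorts"] = CohortDesign(**kw["cohorts"])
        for key in ("survival_forms", "movement_forms", "theta_forms",
                    "attempts_forms", "nest_forms", "fledged_forms"):
            if key in kw:
                # a bare YAML `null` list entry means the null model
                kw[key] = tuple("null" if f is None else f for f in kw[key])
        unknown = set(kw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()} seed={config.seed} "
                 f"sim_seed={config.sim_seed} fit_seed={config.fit_seed} "
                 f"boot_seed={config.boot_seed}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# --------------------------------------------------------------------------
# stages


def run_simulate(config: RunConfig, force: bool = False) -> Dataset:
    """Simulate a dataset from the configured truth and write it out."""
    truth = realize_truth(config.schedule, config.truth)
    dataset = simulate_dataset(truth, config.schedule, config.cohorts,
                               seed=config.sim_seed)
    out = config.out_dir / "dataset"
    write_dataset(dataset, out, force=force)
    truth_table = truth.to_frame()
    _write_csv(truth_table, out / "truth_rates.csv", config)
    return dataset


@dataclass
class FitResults:
    """Fitted models, rankings and the assembled vital-rate table."""

    vital_rates: VitalRateTable
    rankings: dict[str, ModelRanking]
    multistate_fit: object
    breeding_fit: object
    nest_fit: object
    fledged_fit: object
    excluded: set[tuple[str, int]]

    def ranking_frame(self) -> pd.DataFrame:
        frames = []
        for vital, rk in self.rankings.items():
            tab = rk.table.copy()
            tab.insert(0, "vital_rate", vital)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)


def _rank_multistate(enc, schedule, config, vary: str, fixed_spec: MultistateSpec):
    fits = {}
    forms = config.survival_forms if vary == "survival" else config.movement_forms
    for form in forms:
        variants = [(form, False)]
        if (vary == "survival" and form != "null" and config.juv_interaction
                and form == "linear"):
            variants.append((form, True))
        for f, inter in variants:
            if vary == "survival":
                spec = MultistateSpec(
                    survival_tsi=f, survival_post_step=(f != "null"),
                    juv_tsi_interaction=inter,
                    movement_structure=fixed_spec.movement_structure,
                    movement_tsi=fixed_spec.movement_tsi,
                    movement_post_step=fixed_spec.movement_post_step,
                    detection=config.detection)
            else:
                spec = MultistateSpec(
                    survival_tsi=fixed_spec.survival_tsi,
                    survival_post_step=fixed_spec.survival_post_step,
                    juv_tsi_interaction=fixed_spec.juv_tsi_interaction,
                    movement_structure=fixed_spec.movement_structure,
                    movement_tsi=f, movement_post_step=(f != "null"),
                    detection=config.detection)
            label = f + ("+age" if inter else "")
            fits[label] = fit_multistate(enc, schedule, spec,
                                         n_starts=config.n_starts,
                                         seed=config.fit_seed,
                                         gtol=config.gtol)
    return fits


def run_fit(config: RunConfig, dataset: Dataset | None = None) -> FitResults:
    """Fit every vital-rate model, rank candidates by AICc, assemble rates.

    Candidate time-since-invasion forms are ranked per vital rate; estimates
    feeding the source-sink stage come from each top-ranked model.  The
    multistate candidates are ranked in two passes (survival forms first
    with null movement, then movement forms under the best survival form) to
    keep the candidate count linear in the number of forms.
    """
    if dataset is None:
        dataset = read_dataset(config.out_dir / "dataset")
    sched = dataset.schedule
    rankings: dict[str, ModelRanking] = {}

    if len(dataset.nests) == 0:
        raise ValueError("fecundity stage needs a non-empty nests table")

    enc = encode_histories(dataset.captures, sched)
    base = MultistateSpec(detection=config.detection)
    s_fits = _rank_multistate(enc, sched, config, "survival", base)
    rankings["survival"] = rank_models(s_fits)
    best_s = s_fits[rankings["survival"].best_label]
    m_fits = _rank_multistate(enc, sched, config, "movement", best_s.spec)
    rankings["movement"] = rank_models(m_fits)
    ms_fit = m_fits[rankings["movement"].best_label]

    b_fits = {}
    for form in config.theta_forms:
        spec = BreedingAttemptsSpec(theta_tsi=form, k_max=config.k_max,
                                    fix_p_det=config.attempt_detection)
        b_fits[form] = fit_breeding_attempts(dataset.breeders, sched, spec,
                                             seed=config.fit_seed)
    rankings["breeding"] = rank_models(b_fits)
    best_theta_form = rankings["breeding"].best_label
    a_fits = {}
    for form in config.attempts_forms:
        spec = BreedingAttemptsSpec(theta_tsi=best_theta_form,
                                    attempts_tsi=form, k_max=config.k_max,
                                    fix_p_det=config.attempt_detection)
        a_fits[form] = fit_breeding_attempts(dataset.breeders, sched, spec,
                                             seed=config.fit_seed)
    rankings["attempts"] = rank_models(a_fits)
    breeding_fit = a_fits[rankings["attempts"].best_label]

    n_fits = {form: fit_nest_survival(dataset.nests, sched, form,
                                      random_effects=config.nest_random_effects,
                                      cycle_length=config.cycle_length)
              for form in config.nest_forms}
    rankings["nest_success"] = rank_models(n_fits)
    nest_fit = n_fits[rankings["nest_success"].best_label]

    f_fits = {form: fit_fledged(dataset.nests, sched, form,
                                random_effects=config.nest_random_effects)
              for form in config.fledged_forms}
    rankings["fledged"] = rank_models(f_fits)
    fledged_fit = f_fits[rankings["fledged"].best_label]

    table = build_vital_rates(sched, breeding_fit, nest_fit, fledged_fit, ms_fit,
                              cycle_length=config.cycle_length)
    excluded = estimability_screen(dataset.captures, sched, ms_fit)

    results = FitResults(
        vital_rates=table, rankings=rankings, multistate_fit=ms_fit,
        breeding_fit=breeding_fit, nest_fit=nest_fit, fledged_fit=fledged_fit,
        excluded=excluded)
    _write_csv(table.to_frame(), config.out_dir / "vital_rates.csv", config)
    _write_csv(ms_fit.to_frame(), config.out_dir / "multistate_estimates.csv",
               config)
    _write_csv(results.ranking_frame(), config.out_dir / "model_ranking.csv",
               config)
    return results


def build_vital_rates(schedule, breeding_fit, nest_fit, fledged_fit,
                      multistate_fit, cycle_length: int = 58) -> VitalRateTable:
    """Assemble per-population-year estimates from the four fitted models."""
    R, T = len(schedule.populations), schedule.n_years
    theta = np.zeros((R, T, 3)); theta_se = np.zeros((R, T, 3))
    lam = np.ones((R, T)); lam_se = np.zeros((R, T))
    dsr = np.ones((R, T)); dsr_se = np.zeros((R, T))
    fled = np.zeros((R, T)); fled_se = np.zeros((R, T))
    for ri, r in enumerate(schedule.populations):
        for ti, t in enumerate(schedule.years):
            for a in (1, 2):
                th, th_se, la, la_se = breeding_fit.predict(r, t, a)
                theta[ri, ti, a], theta_se[ri, ti, a] = th, th_se
                lam[ri, ti], lam_se[ri, ti] = la, la_se
            dsr[ri, ti], dsr_se[ri, ti] = nest_fit.predict_daily_survival(r, t)
            fled[ri, ti], fled_se[ri, ti] = fledged_fit.predict_fledged(r, t)
    (S_g, psi, p), (S_g_se, psi_se, _) = multistate_fit.rates_with_se()
    S = np.zeros((R, T, 3)); S_se = np.zeros((R, T, 3))
    S[:, :, 0], S_se[:, :, 0] = S_g[:, :, 0], S_g_se[:, :, 0]
    for a in (1, 2):
        S[:, :, a], S_se[:, :, a] = S_g[:, :, 1], S_g_se[:, :, 1]
    return VitalRateTable(
        schedule=schedule, theta=theta, attempts_lambda=lam,
        daily_survival=dsr, fledged_mean=fled, survival=S, psi=psi,
        resight_p=p, cycle_length=cycle_length,
        theta_se=theta_se, attempts_lambda_se=lam_se,
        daily_survival_se=dsr_se, fledged_mean_se=fled_se,
        survival_se=S_se, psi_se=psi_se)


def run_contribute(config: RunConfig, results: FitResults | None = None,
                   dataset: Dataset | None = None) -> pd.DataFrame:
    """Propagate uncertainty into C/R/E, classify, write outputs."""
    if dataset is None:
        dataset = read_dataset(config.out_dir / "dataset")
    if results is None:
        results = run_fit(config, dataset)
    props = age_proportions(dataset.captures, dataset.schedule)
    contrib = propagate(results.vital_rates, props, n_reps=config.n_reps,
                        seed=config.boot_seed, exclude=results.excluded,
                        clamp=config.clamp)
    if len(contrib) == 0:
        raise ValueError("every population-year was excluded")
    _write_csv(contrib, config.out_dir / "contributions.csv", config)
    summary = summarize_contributions(contrib)
    with open(config.out_dir / "summary.txt", "w") as fh:
        for key, val in summary.items():
            fh.write(f"{key}: {val}\n")
    return contrib


def summarize_contributions(contrib: pd.DataFrame) -> dict:
    """Headline statistics of a contributions table.

    Fractions are over post-invasion population-years (tsi defined); the
    mean-tsi contrast compares population-years contributing at least one
    recruit per capita (C >= 1) with those below.
    """
    post = contrib[contrib["tsi"].notna()].copy()
    out: dict[str, object] = {
        "n_population_years": int(len(contrib)),
        "n_post_invasion": int(len(post)),
        "class_counts": contrib["class"].value_counts().to_dict(),
    }
    if len(post):
        ge1 = post[post["C"] >= 1.0]
        lt1 = post[post["C"] < 1.0]
        out["frac_C_ge_1"] = float(len(ge1) / len(post))
        out["mean_tsi_C_ge_1"] = float(ge1["tsi"].mean()) if len(ge1) else float("nan")
        out["mean_tsi_C_lt_1"] = float(lt1["tsi"].mean()) if len(lt1) else float("nan")
        gt1 = post[post["C"] > 1.0]
        if len(gt1):
            out["frac_dependent_among_C_gt_1"] = float(
                gt1["dependent_source"].mean())
        out["mean_R_when_C_ge_1"] = float(ge1["R"].mean()) if len(ge1) else float("nan")
        out["mean_R_when_C_lt_1"] = float(lt1["R"].mean()) if len(lt1) else float("nan")
        out["mean_E_when_C_ge_1"] = float(ge1["E"].mean()) if len(ge1) else float("nan")
        out["mean_E_when_C_lt_1"] = float(lt1["E"].mean()) if len(lt1) else float("nan")
    return out


def run_pipeline(config: RunConfig, force: bool = False) -> pd.DataFrame:
    """simulate -> fit -> contribute, writing a run manifest."""
    dataset = run_simulate(config, force=force)
    results = run_fit(config, dataset)
    contrib = run_contribute(config, results, dataset)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sim_seed": config.sim_seed,
        "fit_seed": config.fit_seed,
        "boot_seed": config.boot_seed,
        "config": config.to_dict(),
        "excluded_population_years": sorted(
            [list(x) for x in results.excluded]),
    }
    with open(config.out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return contrib
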