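"""End-to-end orchestration: ingestion -> screening -> CoDa -> models -> reallocation.

The pipeline either generates a synthetic study or reads the two input CSVs
(epoch-level MET records; participant covariate/outcome table), applies the
wear screens, forms wear-time compositions, fits the nested compositional
regression suite, and predicts the reallocation curve.  Artifacts are plain
TSV/CSV plus a deterministic run log recording the exclusion cascade, zero
replacements, and every configuration value, so a run is auditable and two
runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accelerometry as acc
from . import coda, reallocation, regression, synthetic


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    outdir: str = "timecoda_out"
    seed: int = 2017
    # ingestion: synthetic study, or paths to the two input CSVs
    synthetic: bool = True
    n_participants: int = 60
    days_per_participant: int = 7
    epochs_csv: str | None = None
    participants_csv: str | None = None
    # screening thresholds
    nonwear_run: int = acc.NONWEAR_RUN_MIN
    strict_nonwear: bool = True
    valid_day_minutes: int = acc.VALID_DAY_WEAR_MIN
    min_valid_days: int = acc.MIN_VALID_DAYS
    # CoDa conventions
    zero_strategy: str = "multiplicative"
    composition_method: str = "pooled"
    # model suite
    model_levels: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    include_ratio: bool = True
    # reallocation
    realloc_focal: str = "mvpa"
    realloc_rule: str = "equal"
    realloc_base: str = "arithmetic"  # or "geometric" (compositional mean)
    realloc_grid_pp: list[float] = field(default_factory=lambda: list(range(-3, 4)))

    def __post_init__(self) -> None:
        for name in ("nonwear_run", "valid_day_minutes", "min_valid_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.synthetic:
            for name in ("epochs_csv", "participants_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} must point to an existing file")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def write_descriptives(table: pd.DataFrame, path) -> pd.DataFrame:
    """Cohort descriptives TSV: n (%) for binaries, mean (SD) for continuous."""
    binaries = [
        ("Sex, male", "male"), ("BMI <18.5", "bmi_under"), ("BMI >=25.0", "bmi_over"),
        ("Education, >=13 years", "education"), ("Smoking status, smoker", "smoker"),
        ("Alcohol use, >=60 g/day", "alcohol"),
        ("Medication, hypertension", "med_hypertension"),
        ("Medication, dyslipidemia", "med_dyslipidemia"),
        ("Medication, diabetes", "med_diabetes"),
    ]
    continuous = [
        ("Age, years", "age"),
        ("Accelerometer wear time, min/day", "mean_wear"),
        ("Sedentary behavior, min/day", "mean_sb"),
        ("Light physical activity, min/day", "mean_lpa"),
        ("Moderate-to-vigorous physical activity, min/day", "mean_mvpa"),
        ("Intracranial volume, mm3", "icv"),
        ("Right hippocampal volume, mm3", "right_hv"),
        ("Left hippocampal volume, mm3", "left_hv"),
    ]
    n = len(table)
    rows = [{"characteristic": "Participants, n", "n": n, "pct": "", "mean": "", "sd": ""}]
    for label, col in binaries:
        if col not in table.columns:
            continue
        k = int(table[col].sum()) if n else 0
        rows.append({"characteristic": label, "n": k,
                     "pct": f"{100.0 * k / n:.1f}" if n else "", "mean": "", "sd": ""})
    for label, col in continuous:
        if col not in table.columns:
            continue
        if n == 0:
            rows.append({"characteristic": label, "n": "", "pct": "", "mean": "", "sd": ""})
            continue
        sd = table[col].std(ddof=1) if n > 1 else 0.0
        rows.append({"characteristic": label, "n": "", "pct": "",
                     "mean": f"{table[col].mean():.1f}", "sd": f"{sd:.1f}"})
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def _ingest(cfg: PipelineConfig, outdir: Path, log: list[str]):
    if cfg.synthetic:
        scfg = synthetic.CohortConfig(
            n_participants=cfg.n_participants, seed=cfg.seed,
            days_per_participant=cfg.days_per_participant,
        )
        covariates, outcomes, epochs, truth = synthetic.generate_study(scfg)
        participants = covariates.merge(outcomes, on="participant_id")
        epochs.to_csv(outdir / "epochs.csv", index=False)
        participants.to_csv(outdir / "participants.csv", index=False)
        truth.table.to_csv(outdir / "ground_truth.csv", index=False)
        log.append(f"ingestion: synthetic cohort n={cfg.n_participants} seed={cfg.seed}")
    else:
        epochs = acc.read_epochs_csv(cfg.epochs_csv)
        participants = pd.read_csv(cfg.participants_csv, dtype={"participant_id": str})
        log.append(f"ingestion: epochs={cfg.epochs_csv} participants={cfg.participants_csv}")
    return epochs, participants


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full chain; returns artifact paths and headline numbers.

    A cohort with no included participants (or too few to fit the largest
    model) stops after the descriptives with a logged reason instead of
    raising.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"timecoda pipeline, seed={cfg.seed}"]
    cfg.to_yaml(outdir / "config.yaml")
    result: dict = {"outdir": str(outdir)}

    epochs, participants = _ingest(cfg, outdir, log)

    # --- accelerometry screening ---------------------------------------
    days, screened = acc.process_epochs(
        epochs, nonwear_run=cfg.nonwear_run, strict_nonwear=cfg.strict_nonwear,
        valid_wear=cfg.valid_day_minutes, min_valid_days=cfg.min_valid_days,
    )
    days.to_csv(outdir / "days.tsv", sep="\t", index=False)
    screened.to_csv(outdir / "participants_screened.tsv", sep="\t", index=False)
    n_in = len(screened)
    included = screened[screened["included"]]
    log.append(
        f"screening: {n_in} participants with epoch data -> {len(included)} included, "
        f"{n_in - len(included)} excluded (insufficient_valid_days)"
    )
    no_epochs = set(participants["participant_id"]) - set(screened["participant_id"])
    if no_epochs:
        log.append(f"screening: {len(no_epochs)} participants had no epoch records")

    table = included.merge(participants, on="participant_id", how="inner")
    dropped_wear = len(included) - len(table)
    if dropped_wear:
        log.append(f"merge: {dropped_wear} screened participants lacked a covariate row")
    log.append(f"analysis set: n={len(table)}")
    result["n_analyzed"] = len(table)

    # --- compositions + zero handling -----------------------------------
    artifacts = {"config": outdir / "config.yaml", "days": outdir / "days.tsv",
                 "participants_screened": outdir / "participants_screened.tsv"}
    if len(table):
        comps = table[["t_sb", "t_lpa", "t_mvpa"]].to_numpy()
        n_zero = int((comps == 0).any(axis=1).sum())
        if n_zero:
            log.append(f"zero handling: {n_zero} compositions had a zero part "
                       f"(strategy={cfg.zero_strategy})")
            comps = coda.replace_zeros(comps, strategy=cfg.zero_strategy)
        else:
            log.append("zero handling: no zero parts observed")
    else:
        comps = np.empty((0, 3))

    desc = write_descriptives(table, outdir / "descriptives.tsv")
    artifacts["descriptives"] = outdir / "descriptives.tsv"
    result["descriptives_rows"] = len(desc)

    if len(table) < 2:
        log.append("aborting before models: fewer than 2 analyzable participants")
        _finish(outdir, log, artifacts, result)
        return result

    T = coda.variation_matrix(comps)
    coda.write_variation_tsv(T, outdir / "variation_matrix.tsv")
    artifacts["variation_matrix"] = outdir / "variation_matrix.tsv"
    center = coda.compositional_mean(comps)
    arith = coda.close(comps.mean(axis=0))
    log.append("variation matrix (SB-LPA, SB-MVPA, LPA-MVPA): "
               f"{T[0, 1]:.3f}, {T[0, 2]:.3f}, {T[1, 2]:.3f}")
    log.append(f"compositional mean (SB,LPA,MVPA): {np.round(center, 4).tolist()}")
    log.append(f"arithmetic mean composition:      {np.round(arith, 4).tolist()}")

    # --- model suite -----------------------------------------------------
    max_p = 3 + len(regression.MODEL_COVARIATES[max(cfg.model_levels)])
    if len(table) <= max_p:
        log.append(f"aborting before models: n={len(table)} <= p={max_p}")
        _finish(outdir, log, artifacts, result)
        return result
    constants = regression.constant_columns(
        table, regression.MODEL_COVARIATES[max(cfg.model_levels)]
    )
    if constants:
        log.append(f"models: dropping covariates constant in the analysis set: "
                   f"{sorted(constants)}")
    suite = regression.run_model_suite(
        comps, table, table, outcome_columns=("right_hv", "left_hv"),
        levels=tuple(cfg.model_levels), include_ratio=cfg.include_ratio,
        drop_constant=True,
    )
    suite.to_csv(outdir / "coefficients.tsv", sep="\t", index=False, float_format="%.6g")
    regression.format_coefficient_table(suite).to_csv(
        outdir / "coefficients_formatted.tsv", sep="\t", index=False
    )
    artifacts["coefficients"] = outdir / "coefficients.tsv"
    result["n_coefficient_rows"] = len(suite)

    # --- reallocation curve ---------------------------------------------
    top = regression.ModelSpec("right_hv", max(cfg.model_levels))
    fits, logcontrast = regression.fit_pivot_models(
        comps, table, table["right_hv"], top, frozenset(constants)
    )
    base = arith if cfg.realloc_base == "arithmetic" else center
    wear = float(table["mean_wear"].mean())
    curve = reallocation.reallocation_curve(
        logcontrast, base, cfg.realloc_focal,
        [d / 100.0 for d in cfg.realloc_grid_pp], wear, cfg.realloc_rule,
    )
    curve.to_csv(outdir / "reallocation_curve.csv", index=False, float_format="%.6g")
    artifacts["reallocation_curve"] = outdir / "reallocation_curve.csv"
    log.append(
        f"reallocation: focal={cfg.realloc_focal} rule={cfg.realloc_rule} "
        f"base={cfg.realloc_base} {np.round(base, 4).tolist()} "
        f"(alternative {'geometric' if cfg.realloc_base == 'arithmetic' else 'arithmetic'} "
        f"base {np.round(center if cfg.realloc_base == 'arithmetic' else arith, 4).tolist()}); "
        f"mean wear {wear:.1f} min/day"
    )
    result["beta_z1_mvpa_model_top"] = fits["mvpa"].beta_z1
    result["curve"] = curve

    _finish(outdir, log, artifacts, result)
    return result


def _finish(outdir: Path, log: list[str], artifacts: dict, result: dict) -> None:
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    artifacts["run_log"] = outdir / "run_log.txt"
    result["artifacts"] = {k: str(v) for k, v in artifacts.items()}
    result["log"] = log
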