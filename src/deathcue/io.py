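"""Readers, writers, configuration and the reproducible full-pipeline runner.

CSV dialects
------------
Trials:       trial_id, treatment, block, n_exposed_arm, n_control_arm,
              flies_loaded   (block may be empty)
Metabolites:  sample_id, genotype, exposure, then one column per metabolite;
              missing values as empty cells or ``NA``
Survival:     fly_id, exposure, genotype, event_time, event_observed — or the
              census long format vial, exposure, genotype, census_time,
              n_dead, n_censored, which is expanded to individuals

All randomness in a pipeline run flows from the single config seed through
deterministic per-stage substreams, so identical config + seed gives
byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metabolome as mb
from . import preference as pref
from .errors import ParameterError, StageError, ValidationError
from .survival import (
    SurvivalCohort,
    anova_interaction_age_at_death,
    cox_interaction,
    logrank_test,
)

__all__ = [
    "RunConfig",
    "stage_rng",
    "read_trials",
    "write_trials",
    "read_metabolite_matrix",
    "write_metabolite_matrix",
    "read_survival",
    "write_survival",
    "run_full_pipeline",
]

logger = logging.getLogger("deathcue")

TRIAL_COLUMNS = ["trial_id", "treatment", "block", "n_exposed_arm",
                 "n_control_arm", "flies_loaded"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, order-insensitive substream for a named pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


def stage_seed(seed: int, stage: str) -> int:
    """A plain integer seed derived for a named stage (for seeded APIs)."""
    return int(stage_rng(seed, stage).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Knobs for a full pipeline run; defaults follow the study protocol
    (100,000 randomizations for preference t/F statistics, 10,000 label
    permutations for PC separation, drop metabolites missing in more than
    5 of 32 samples, k = 10 imputation neighbours)."""

    seed: int = 0
    n_permutations_preference: int = 100_000
    n_permutations_pca: int = 10_000
    alpha: float = 0.05
    missingness_threshold: float = 5 / 32
    knn_k: int = 10
    target_pc: str | int = "auto"
    survival_interaction_method: str = "cox"
    trials_csv: str | None = None
    matrix_csv: str | None = None
    survival_csv: str | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_permutations_preference < 1 or self.n_permutations_pca < 1:
            raise ParameterError("permutation counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if not 0 <= self.missingness_threshold < 1:
            raise ParameterError("missingness_threshold must be in [0, 1)")
        if self.knn_k < 1:
            raise ParameterError("knn_k must be >= 1")
        if self.survival_interaction_method not in ("cox", "anova"):
            raise ParameterError("survival_interaction_method must be cox or anova")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def read_trials(path: str | Path) -> list[pref.ChoiceTrial]:
    """Read and validate a trial table; malformed rows are reported with
    their file line numbers (header is line 1)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"trial_id", "treatment", "n_exposed_arm", "n_control_arm"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    trials = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            n_e = int(row["n_exposed_arm"])
            n_c = int(row["n_control_arm"])
            loaded = int(row["flies_loaded"]) if row.get("flies_loaded", "") else 20
            block = row["block"] if row.get("block", "") else None
            trials.append(pref.ChoiceTrial(
                n_exposed=n_e, n_control=n_c, flies_loaded=loaded,
                treatment=row["treatment"], block=block,
            ))
        except (ValueError, ParameterError) as exc:
            raise ValidationError(f"{path}, line {line}: {exc}") from exc
    return trials


def write_trials(trials: list[pref.ChoiceTrial], path: str | Path) -> None:
    rows = [
        {
            "trial_id": f"t{i + 1:04d}",
            "treatment": t.treatment,
            "block": t.block if t.block is not None else "",
            "n_exposed_arm": t.n_exposed,
            "n_control_arm": t.n_control,
            "flies_loaded": t.flies_loaded,
        }
        for i, t in enumerate(trials)
    ]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metabolite matrix
# ---------------------------------------------------------------------------

def read_metabolite_matrix(
    path: str | Path, mode_path: str | Path | None = None, scale: str = "raw"
) -> mb.MetaboliteMatrix:
    """Read a samples x metabolites CSV; ``NA`` or empty cells become missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("sample_id", "genotype", "exposure"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample_id {dupes}")
    met_cols = [c for c in df.columns if c not in ("sample_id", "genotype", "exposure")]
    if len(set(met_cols)) != len(met_cols):
        raise ValidationError(f"{path}: duplicate metabolite columns")
    values = np.full((len(df), len(met_cols)), np.nan)
    for j, col in enumerate(met_cols):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "" or cell.upper() == "NA":
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-numeric abundance at row {i + 2}, "
                    f"column {col!r}: {cell!r}"
                ) from exc
    index = pd.Index(df["sample_id"], name="sample_id")
    data = pd.DataFrame(values, index=index, columns=met_cols)
    factors = pd.DataFrame(
        {"genotype": df["genotype"].to_numpy(), "exposure": df["exposure"].to_numpy()},
        index=index,
    )
    mode = None
    if mode_path is not None:
        md = pd.read_csv(mode_path)
        if not {"metabolite", "mode"} <= set(md.columns):
            raise ValidationError(f"{mode_path}: need columns metabolite, mode")
        mode = md.set_index("metabolite")["mode"].reindex(met_cols)
    return mb.MetaboliteMatrix(data=data, sample_factors=factors, scale=scale,
                               stage="raw", mode=mode)


def write_metabolite_matrix(m: mb.MetaboliteMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.insert(0, "exposure", m.sample_factors["exposure"].to_numpy())
    out.insert(0, "genotype", m.sample_factors["genotype"].to_numpy())
    out.to_csv(path, index=True, index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def read_survival(path: str | Path) -> SurvivalCohort:
    """Read an event-list CSV, or a census long format which is expanded."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "vial" in df.columns:
        required = {"vial", "census_time", "n_dead", "n_censored", "exposure"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: census format missing {sorted(missing)}")
        times, obs, expo, geno = [], [], [], []
        has_geno = "genotype" in df.columns
        for _, row in df.iterrows():
            for count, flag in ((int(row["n_dead"]), True),
                                (int(row["n_censored"]), False)):
                times.extend([float(row["census_time"])] * count)
                obs.extend([flag] * count)
                expo.extend([row["exposure"]] * count)
                if has_geno:
                    geno.extend([row["genotype"]] * count)
        return SurvivalCohort(
            event_time=np.array(times), event_observed=np.array(obs),
            exposure=np.array(expo),
            genotype=np.array(geno) if has_geno else None,
        )
    required = {"exposure", "event_time", "event_observed"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    try:
        return SurvivalCohort(
            event_time=df["event_time"].to_numpy(dtype=float),
            event_observed=df["event_observed"].to_numpy(dtype=float).astype(bool),
            exposure=df["exposure"].to_numpy(),
            genotype=df["genotype"].to_numpy() if "genotype" in df.columns else None,
        )
    except (ValueError, ParameterError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_survival(cohort: SurvivalCohort, path: str | Path) -> None:
    df = cohort.to_frame()
    df.insert(0, "fly_id", [f"fly{i + 1:05d}" for i in range(len(cohort))])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _round6(x: float) -> float:
    return float(np.round(float(x), 6))


def _preference_stage(config: RunConfig, out: Path) -> dict:
    trials = read_trials(config.trials_csv)
    by_treatment: dict[str, list] = {}
    for t in trials:
        by_treatment.setdefault(t.treatment, []).append(t)
    labels = sorted(by_treatment)
    seed = stage_seed(config.seed, "preference")
    rows, summary = [], {}
    summaries = {
        lab: pref.weighted_mean_pi(ts) for lab, ts in by_treatment.items()
    }
    summary["weighted_mean_pi"] = {
        lab: _round6(s.weighted_mean_pi) for lab, s in summaries.items()
    }
    if len(labels) == 2:
        res = pref.randomization_test_two_groups(
            by_treatment[labels[0]], by_treatment[labels[1]],
            n_permutations=config.n_permutations_preference, seed=seed)
        rows.append({"comparison": f"{labels[0]} vs {labels[1]}",
                     "statistic_kind": res.statistic_kind,
                     "observed_statistic": res.observed_statistic,
                     "p_value": res.p_value, "exhaustive": res.exhaustive})
    elif len(labels) >= 3:
        res = pref.randomization_anova(
            [by_treatment[lab] for lab in labels],
            n_permutations=config.n_permutations_preference, seed=seed)
        rows.append({"comparison": " vs ".join(labels),
                     "statistic_kind": res.statistic_kind,
                     "observed_statistic": res.observed_statistic,
                     "p_value": res.p_value, "exhaustive": res.exhaustive})
    pd.DataFrame(rows).to_csv(out / "preference_tests.csv", index=False)
    if rows:
        summary["test"] = {
            "comparison": rows[0]["comparison"],
            "p_value": _round6(rows[0]["p_value"]),
        }
    return summary


def _metabolome_stage(config: RunConfig, out: Path) -> dict:
    matrix = read_metabolite_matrix(config.matrix_csv)
    processed = mb.process_matrix(matrix,
                                  max_missing_fraction=config.missingness_threshold,
                                  k=config.knn_k)
    dec = mb.run_pca(processed)
    seed = stage_seed(config.seed, "pca_permutation")
    composite = mb.permutation_pc_test(
        processed, grouping_factor="composite",
        n_permutations=config.n_permutations_pca, seed=seed, decomposition=dec)
    # attribute significant components to a factor by within-stratum separation:
    # an effect confined to one genotype's exposed samples moves both marginal
    # means equally, so marginal tests cannot tell exposure from genotype
    strat = {
        "exposure": mb.stratified_pc_test(
            processed, "exposure", "genotype", config.n_permutations_pca,
            seed=seed, decomposition=dec),
        "genotype": mb.stratified_pc_test(
            processed, "genotype", "exposure", config.n_permutations_pca,
            seed=seed, decomposition=dec),
    }
    rows = [{"component": f"PC{z.component}",
             "z_composite": z.z_observed,
             "p_value": z.p_value,
             "p_familywise": z.p_familywise,
             "p_exposure_within_genotype": strat["exposure"][z.component - 1],
             "p_genotype_within_exposure": strat["genotype"][z.component - 1]}
            for z in composite]
    pd.DataFrame(rows).to_csv(out / "pc_separation.csv", index=False)

    sig_composite = [z.component for z in composite
                     if z.p_familywise < config.alpha]
    sig = {
        factor: [comp for comp in sig_composite
                 if strat[factor][comp - 1] < config.alpha]
        for factor in strat
    }
    if config.target_pc == "auto":
        # the exposure-separating component with the strongest within-stratum
        # evidence; fall back to the best composite separator
        if sig["exposure"]:
            target = min(sig["exposure"],
                         key=lambda comp: (strat["exposure"][comp - 1], comp))
        else:
            target = min(composite,
                         key=lambda z: (z.p_value, z.component)).component
    else:
        target = int(config.target_pc)

    top = mb.rank_loadings(dec, target, top_n=10)
    pd.DataFrame({
        "metabolite": top,
        "loading": [dec.loadings.iloc[:, target - 1][name] for name in top],
    }).to_csv(out / "top_loadings.csv", index=False)

    candidates = mb.screen_candidates(processed, alpha=config.alpha,
                                      decomposition=dec, component_index=target)
    pd.DataFrame([{
        "metabolite": c.name, "loading_on_target_pc": c.loading_on_target_pc,
        "direction": c.direction, "p_control": c.p_control,
        "p_mutant": c.p_mutant, "flagged": c.flagged,
    } for c in candidates]).to_csv(out / "candidates.csv", index=False)

    return {
        "n_metabolites_retained": processed.n_metabolites,
        "significant_pcs": {"composite": sig_composite, **sig},
        "target_pc": target,
        "top_loadings": top,
        "flagged_candidates": sorted(c.name for c in candidates if c.flagged),
    }


def _survival_stage(config: RunConfig, out: Path) -> dict:
    cohort = read_survival(config.survival_csv)
    rows, summary = [], {}
    expo_levels = sorted(set(map(str, cohort.exposure)))
    if len(expo_levels) == 2:
        a = cohort.subset(cohort.exposure.astype(str) == expo_levels[0])
        b = cohort.subset(cohort.exposure.astype(str) == expo_levels[1])
        stat, p = logrank_test(a, b)
        rows.append({"test": "logrank", "comparison": " vs ".join(expo_levels),
                     "statistic": stat, "p_value": p})
        summary["logrank"] = {"statistic": _round6(stat), "p_value": _round6(p)}
    if cohort.genotype is not None and len(set(map(str, cohort.genotype))) == 2:
        if config.survival_interaction_method == "cox":
            res = cox_interaction(cohort)
        else:
            res = anova_interaction_age_at_death(cohort)
        rows.append({"test": f"interaction_{res.method}",
                     "comparison": "exposure x genotype",
                     "statistic": res.interaction_estimate,
                     "p_value": res.p_value})
        summary["interaction"] = {
            "method": res.method,
            "estimate": _round6(res.interaction_estimate),
            "standard_error": _round6(res.standard_error),
            "p_value": _round6(res.p_value),
        }
    pd.DataFrame(rows).to_csv(out / "survival_tests.csv", index=False)
    return summary


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage with inputs from the config and write results.

    Writes per-stage CSVs, ``summary.json`` and ``run_log.txt`` into
    ``config.out_dir``; returns the summary dict.  Identical config + seed
    gives a byte-identical ``summary.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "parameters": {
        "n_permutations_preference": config.n_permutations_preference,
        "n_permutations_pca": config.n_permutations_pca,
        "alpha": config.alpha,
        "missingness_threshold": _round6(config.missingness_threshold),
        "knn_k": config.knn_k,
    }}
    stages = [
        ("preference", config.trials_csv, _preference_stage),
        ("metabolome", config.matrix_csv, _metabolome_stage),
        ("survival", config.survival_csv, _survival_stage),
    ]
    for name, inp, fn in stages:
        if inp is None:
            continue
        logger.info("running stage %s on %s", name, inp)
        try:
            summary[name] = fn(config, out)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    import deathcue

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"deathcue {deathcue.__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write(f"config: {json.dumps(asdict(config), sort_keys=True)}\n")
    return summary
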