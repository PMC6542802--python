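"""Synthetic data with the statistical structure the analyses assume.

Three generators:

* T-maze choice trials — per trial, the number of participating flies is
  binomial out of ``flies_loaded``, and each participant independently enters
  the exposed arm with probability ``p_exposed_arm``.
* A head-metabolome matrix — 4 * n_replicates samples (2 genotypes x 2
  exposures) by ~119 metabolites of log-normal abundances.  Latent structure
  is built on a random orthonormal basis with strictly decreasing direction
  variances; the exposure effect is a mean shift of ``effect_size`` standard
  deviations along the basis vector of the requested variance rank, applied
  to the exposed samples of the affected genotype only.  Missingness is
  completely at random, capped per metabolite so the default matrix survives
  the downstream missingness filter intact (it emulates a post-filter panel).
* Survival cohorts — event times from an exponential or Gompertz baseline
  hazard with multiplicative (proportional-hazards) exposure, genotype and
  interaction effects, with optional right-censoring at a fixed time.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .metabolome import MetaboliteMatrix, PlantedTruth
from .preference import ChoiceTrial
from .survival import SurvivalCohort

__all__ = [
    "TrialSimSpec",
    "MetabolomeSimSpec",
    "LogHazardEffects",
    "SurvivalSimSpec",
    "simulate_choice_trials",
    "simulate_metabolome",
    "simulate_cohorts",
]


# ---------------------------------------------------------------------------
# choice trials
# ---------------------------------------------------------------------------

@dataclass
class TrialSimSpec:
    """Parameters for simulated T-maze trials.

    ``p_exposed_arm`` is the probability that a participating fly enters the
    arm holding the treatment stimulus; 0.5 is the no-preference null.
    Participation below 1 models flies that never leave the loading arm.
    """

    n_trials: int
    flies_loaded: int = 20
    p_exposed_arm: float = 0.5
    participation_rate: float = 0.8
    treatment_label: str = "treated"
    block_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        if self.flies_loaded < 1:
            raise ParameterError("flies_loaded must be >= 1")
        if not 0.0 <= self.p_exposed_arm <= 1.0:
            raise ParameterError("p_exposed_arm must be in [0, 1]")
        if not 0.0 < self.participation_rate <= 1.0:
            raise ParameterError("participation_rate must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "TrialSimSpec":
        return cls(**d)


def simulate_choice_trials(spec: TrialSimSpec) -> list[ChoiceTrial]:
    """Draw trials: participants ~ Binomial(loaded, participation), then
    exposed-arm counts ~ Binomial(participants, p_exposed_arm)."""
    rng = np.random.default_rng(spec.seed)
    participants = rng.binomial(spec.flies_loaded, spec.participation_rate,
                                size=spec.n_trials)
    n_exposed = rng.binomial(participants, spec.p_exposed_arm)
    blocks: list[str | None]
    if spec.block_labels is None:
        blocks = [None] * spec.n_trials
    elif len(spec.block_labels) == spec.n_trials:
        blocks = list(spec.block_labels)
    else:  # round-robin assignment over the provided labels
        blocks = [spec.block_labels[i % len(spec.block_labels)]
                  for i in range(spec.n_trials)]
    return [
        ChoiceTrial(
            n_exposed=int(ne),
            n_control=int(pa - ne),
            flies_loaded=spec.flies_loaded,
            treatment=spec.treatment_label,
            block=blk,
        )
        for ne, pa, blk in zip(n_exposed, participants, blocks)
    ]


# ---------------------------------------------------------------------------
# metabolome matrix
# ---------------------------------------------------------------------------

@dataclass
class MetabolomeSimSpec:
    """Parameters for the synthetic head-metabolome matrix.

    The design is 2 genotypes x 2 exposures x ``n_replicates`` (default
    8 replicates -> 32 samples, 119 metabolites).  ``planted_pc_rank`` is the
    1-based variance rank of the latent direction carrying the exposure
    effect; ``effect_size`` is the exposed-vs-unexposed mean separation along
    it, in units of that direction's standard deviation, applied only to
    ``affected_genotype`` samples.  ``base_log_mean``/``base_log_sd`` set the
    log-normal abundance location and overall log-scale spread.
    """

    n_replicates: int = 8
    n_metabolites: int = 119
    missing_fraction: float = 0.03
    planted_pc_rank: int = 10
    effect_size: float = 3.0
    affected_genotype: str = "control"
    base_log_mean: float = 8.0
    base_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if self.n_metabolites < 2:
            raise ParameterError("n_metabolites must be >= 2")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ParameterError("missing_fraction must be in [0, 1)")
        n_samples = 4 * self.n_replicates
        m = min(n_samples - 1, self.n_metabolites)
        if not 1 <= self.planted_pc_rank <= m:
            raise ParameterError(
                f"planted_pc_rank must be in 1..{m} for this design"
            )
        if self.affected_genotype not in ("control", "mutant"):
            raise ParameterError("affected_genotype must be 'control' or 'mutant'")
        if self.base_log_sd <= 0:
            raise ParameterError("base_log_sd must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolomeSimSpec":
        return cls(**d)


def _direction_variances(m: int, rank: int, effect_size: float) -> np.ndarray:
    """Strictly decreasing variances with the planted rank spectrally isolated.

    The planted direction gets variance 24 relative to a gently decaying
    noise floor (0.97^i from 1.0) below it.  A mean shift of ``effect_size``
    SD on a quarter of the samples inflates the planted direction's variance
    by the factor 1 + 3 * effect_size^2 / 16; the ladder of directions above
    the planted rank is set 8x that inflated value (decaying 1.04x per step
    toward the planted slot) so that the planted eigenvector stays spectrally
    isolated from both sides after the shift (see docs/methods.md).
    """
    planted = 24.0
    inflated = planted * (1.0 + 3.0 * effect_size**2 / 16.0)
    lam = np.empty(m)
    for j in range(1, m + 1):
        if j < rank:
            lam[j - 1] = 8.0 * inflated * 1.04 ** (rank - 1 - j)
        elif j == rank:
            lam[j - 1] = planted
        else:
            lam[j - 1] = 0.97 ** (j - rank - 1)
    return lam


def _equalize_diagonal(F: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Rotate the factor F (p x m) so diag(F F^T) becomes constant.

    Bendel-Mickey-style Givens sweeps: each step mixes the rows with the
    smallest and largest squared norms so the smaller lands exactly on the
    target, preserving the eigenvalues of F F^T.  With a constant diagonal,
    every metabolite has the same population variance, so per-column
    standardization downstream is a near-scalar operation that does not
    distort the latent directions.
    """
    F = F.copy()
    p = F.shape[0]
    d = np.einsum("ij,ij->i", F, F)
    t = d.mean()
    for _ in range(4 * p):
        i = int(np.argmin(d))
        j = int(np.argmax(d))
        if d[j] - d[i] < tol * max(t, 1e-30):
            break
        a, g = d[i], d[j]
        b = float(F[i] @ F[j])
        x = (-b + math.sqrt(b * b - (a - t) * (g - t))) / (g - t)
        c = 1.0 / math.sqrt(1.0 + x * x)
        s = x * c
        fi = c * F[i] + s * F[j]
        fj = -s * F[i] + c * F[j]
        F[i], F[j] = fi, fj
        d[i] = F[i] @ F[i]
        d[j] = F[j] @ F[j]
    return F


def simulate_metabolome(spec: MetabolomeSimSpec) -> MetaboliteMatrix:
    """Generate a raw-scale (log-normal) abundance matrix with planted effect.

    The returned matrix is at pipeline stage ``raw`` with a ``truth``
    attribute recording the planted direction (unit vector in metabolite
    space), the realised per-sample scores along it (including the shift) and
    its assigned variance.
    """
    rng = np.random.default_rng(spec.seed)
    n = 4 * spec.n_replicates
    p = spec.n_metabolites
    rank = spec.planted_pc_rank
    # latent dimension: five minor directions below the planted rank suffice;
    # a larger residual space mostly dilutes the recoverable structure
    m = min(rank + 5, n - 1, p)

    # random orthonormal basis in metabolite space
    G = rng.standard_normal((p, m))
    V, R = np.linalg.qr(G)
    V *= np.sign(np.diag(R))  # deterministic sign convention

    lam = _direction_variances(m, rank, spec.effect_size)
    lam = lam * (spec.base_log_sd ** 2 * m / lam.sum())
    # rotate the basis so every metabolite has identical population variance
    V = _equalize_diagonal(V * np.sqrt(lam)) / np.sqrt(lam)
    S = rng.standard_normal((n, m)) * np.sqrt(lam)

    genotype = np.repeat(["control", "mutant"], 2 * spec.n_replicates)
    exposure = np.tile(np.repeat(["exposed", "unexposed"], spec.n_replicates), 2)
    shift_idx = (genotype == spec.affected_genotype) & (exposure == "exposed")
    S[shift_idx, rank - 1] += spec.effect_size * math.sqrt(lam[rank - 1])

    X_log = spec.base_log_mean + S @ V.T
    X = np.exp(X_log)

    # completely-at-random missingness, capped so the default panel passes
    # the downstream >5-of-32 missingness filter untouched
    mask = rng.random((n, p)) < spec.missing_fraction
    if spec.missing_fraction <= 5 / 32:
        cap = math.floor((5 / 32) * n)
        for j in range(p):
            idx = np.flatnonzero(mask[:, j])
            if idx.size > cap:
                drop = rng.choice(idx, size=idx.size - cap, replace=False)
                mask[drop, j] = False
    X = np.where(mask, np.nan, X)

    sample_ids = [
        f"{g[:3]}_{e[:5]}_{i % spec.n_replicates + 1:02d}"
        for i, (g, e) in enumerate(zip(genotype, exposure))
    ]
    names = [f"met{j + 1:03d}" for j in range(p)]
    data = pd.DataFrame(X, index=pd.Index(sample_ids, name="sample_id"),
                        columns=names)
    factors = pd.DataFrame(
        {"genotype": genotype, "exposure": exposure},
        index=data.index,
    )
    truth = PlantedTruth(direction=V[:, rank - 1].copy(),
                         scores=S[:, rank - 1].copy(),
                         variance=float(lam[rank - 1]),
                         rank=rank)
    return MetaboliteMatrix(data=data, sample_factors=factors, scale="raw",
                            stage="raw", truth=truth)


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class LogHazardEffects:
    """Additive effects on the log hazard (multiplicative on the hazard)."""

    exposure: float = 0.0
    genotype: float = 0.0
    interaction: float = 0.0


@dataclass
class SurvivalSimSpec:
    """Parameters for 2x2 (exposure x genotype) lifespan cohorts.

    The Gompertz baseline h(t) = a * exp(b t) is the classical model for
    adult fly mortality; defaults (a = 2e-4 /day, b = 0.12 /day) give a
    median lifespan near 50 days.  The exponential baseline is provided for
    quick analytic checks.  Effects act proportionally on the hazard.
    """

    n_per_arm: int = 150
    baseline_hazard_model: str = "gompertz"
    gompertz_a: float = 2e-4
    gompertz_b: float = 0.12
    exponential_rate: float = 0.02
    log_hazard_effects: LogHazardEffects = field(default_factory=LogHazardEffects)
    censoring_time: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ParameterError("n_per_arm must be >= 2")
        if self.baseline_hazard_model not in ("exponential", "gompertz"):
            raise ParameterError(
                "baseline_hazard_model must be 'exponential' or 'gompertz'"
            )
        if self.baseline_hazard_model == "exponential" and self.exponential_rate <= 0:
            raise ParameterError("exponential_rate must be positive")
        if self.baseline_hazard_model == "gompertz" and (
            self.gompertz_a <= 0 or self.gompertz_b <= 0
        ):
            raise ParameterError("Gompertz parameters must be positive")
        if self.censoring_time is not None and self.censoring_time <= 0:
            raise ParameterError("censoring_time must be positive")
        if isinstance(self.log_hazard_effects, dict):
            self.log_hazard_effects = LogHazardEffects(**self.log_hazard_effects)

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalSimSpec":
        return cls(**d)


def _draw_times(rng: np.random.Generator, spec: SurvivalSimSpec,
                hazard_multiplier: float, size: int) -> np.ndarray:
    u = rng.random(size)
    if spec.baseline_hazard_model == "exponential":
        lam = spec.exponential_rate * hazard_multiplier
        return -np.log(u) / lam
    a = spec.gompertz_a * hazard_multiplier
    b = spec.gompertz_b
    # inverse of the Gompertz cumulative hazard (a/b)(exp(bt) - 1)
    return np.log1p(-b * np.log(u) / a) / b


def simulate_cohorts(spec: SurvivalSimSpec) -> SurvivalCohort:
    """Draw a 2x2 cohort with ``n_per_arm`` individuals per cell."""
    rng = np.random.default_rng(spec.seed)
    eff = spec.log_hazard_effects
    times, observed, expo, geno = [], [], [], []
    for g_code, g in enumerate(["control", "mutant"]):
        for e_code, e in enumerate(["unexposed", "exposed"]):
            lp = (eff.exposure * e_code + eff.genotype * g_code
                  + eff.interaction * e_code * g_code)
            t = _draw_times(rng, spec, math.exp(lp), spec.n_per_arm)
            if spec.censoring_time is not None:
                obs = t <= spec.censoring_time
                t = np.minimum(t, spec.censoring_time)
            else:
                obs = np.ones_like(t, dtype=bool)
            times.append(t)
            observed.append(obs)
            expo.extend([e] * spec.n_per_arm)
            geno.extend([g] * spec.n_per_arm)
    return SurvivalCohort(
        event_time=np.concatenate(times),
        event_observed=np.concatenate(observed),
        exposure=np.array(expo),
        genotype=np.array(geno),
    )
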