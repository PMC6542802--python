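"""Preference-index statistics for two-choice (T-maze) trials.

A trial loads ``flies_loaded`` naive flies into a binary maze; ``n_exposed``
end up in the arm holding the treatment stimulus and ``n_control`` in the
opposite arm (the remainder never choose).  The preference index

    PI = (N_E - N_C) / (N_E + N_C)

ranges from -1 (complete avoidance) to +1 (complete attraction).  Replicate
trials are summarised by a chooser-weighted mean PI, and group differences are
tested by randomization: trial-level PIs (with their chooser weights attached)
are shuffled across group labels, a t-like or F-like statistic is recomputed
for each relabelling, and the p-value is the fraction of null statistics at
least as extreme as the observed one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BlockStructureError,
    InsufficientDataError,
    ParameterError,
    UndefinedPreferenceError,
)

__all__ = [
    "ChoiceTrial",
    "PreferenceSummary",
    "RandomizationResult",
    "preference_index",
    "participation_fraction",
    "weighted_mean_pi",
    "randomization_test_two_groups",
    "randomization_anova",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChoiceTrial:
    """One T-maze replicate: arm counts plus treatment and optional block label."""

    n_exposed: int
    n_control: int
    flies_loaded: int = 20
    treatment: str = ""
    block: str | None = None

    def __post_init__(self) -> None:
        if self.n_exposed < 0 or self.n_control < 0:
            raise ParameterError("arm counts must be non-negative")
        if self.flies_loaded < 1:
            raise ParameterError("flies_loaded must be a positive integer")
        if self.n_exposed + self.n_control > self.flies_loaded:
            raise ParameterError(
                f"choosers ({self.n_exposed + self.n_control}) exceed "
                f"flies_loaded ({self.flies_loaded})"
            )

    @property
    def n_choosers(self) -> int:
        return self.n_exposed + self.n_control


@dataclass(frozen=True)
class PreferenceSummary:
    """Chooser-weighted summary of replicate trials."""

    weighted_mean_pi: float
    total_choosers: int
    per_trial_pi: tuple[float, ...]
    participation_fractions: tuple[float, ...]
    n_excluded: int = 0


@dataclass
class RandomizationResult:
    """Outcome of a randomization test.

    ``p_value`` uses add-one smoothing, p = (1 + b) / (1 + m) with b the number
    of null statistics at least as extreme as the observed, except when the
    null was enumerated exhaustively, in which case it is the exact fraction.
    """

    observed_statistic: float
    null_sample: np.ndarray
    p_value: float
    n_permutations: int
    sidedness: str
    statistic_kind: str
    exhaustive: bool = False
    seed: int | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def preference_index(trial: ChoiceTrial) -> float:
    """(N_E - N_C) / (N_E + N_C); undefined when no fly chose."""
    if trial.n_choosers == 0:
        raise UndefinedPreferenceError(
            "preference index undefined: no fly entered either arm"
        )
    return (trial.n_exposed - trial.n_control) / trial.n_choosers


def participation_fraction(trial: ChoiceTrial) -> float:
    """Fraction of loaded flies that entered either arm."""
    return trial.n_choosers / trial.flies_loaded


def weighted_mean_pi(trials: list[ChoiceTrial]) -> PreferenceSummary:
    """Mean PI across replicates weighted by the number of choosing flies.

    Trials in which no fly chose carry no information about preference and are
    excluded (counted in ``n_excluded``) rather than imputed as zero.
    """
    kept = [t for t in trials if t.n_choosers > 0]
    n_excluded = len(trials) - len(kept)
    if not kept:
        raise UndefinedPreferenceError("all trials empty: weighted mean PI undefined")
    pis = [preference_index(t) for t in kept]
    weights = [t.n_choosers for t in kept]
    total = sum(weights)
    mean = sum(w * p for w, p in zip(weights, pis)) / total
    return PreferenceSummary(
        weighted_mean_pi=mean,
        total_choosers=total,
        per_trial_pi=tuple(pis),
        participation_fractions=tuple(participation_fraction(t) for t in kept),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# randomization statistics (vectorised over relabellings)
# ---------------------------------------------------------------------------

def _clean(trials: list[ChoiceTrial]) -> list[ChoiceTrial]:
    return [t for t in trials if t.n_choosers > 0]


def _weighted_t_matrix(pi: np.ndarray, w: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Chooser-weighted Welch-style t for each relabelling.

    ``in_a`` is a boolean (B, n) matrix assigning each trial to group A.  The
    per-group weighted mean is compared using standard errors based on the
    effective sample size n_eff = (sum w)^2 / (sum w^2).  A zero/zero ratio
    (identical constant PIs) is defined as t = 0 so that ties count as extreme.
    """
    in_b = ~in_a
    out = np.empty(in_a.shape[0])
    stats = []
    for mask in (in_a, in_b):
        sw = mask @ w
        swp = mask @ (w * pi)
        swp2 = mask @ (w * pi * pi)
        sw2 = mask @ (w * w)
        m = swp / sw
        # weighted variance about the weighted mean, unbiased via n_eff
        n_eff = sw * sw / sw2
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.maximum(swp2 / sw - m * m, 0.0)
            s2 = var * n_eff / (n_eff - 1.0)
            se2 = s2 / n_eff
        se2 = np.where(np.isfinite(se2), se2, np.inf)
        stats.append((m, se2))
    (ma, sa2), (mb, sb2) = stats
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ma - mb) / np.sqrt(sa2 + sb2)
    return np.nan_to_num(out, nan=0.0)


def _unweighted_t_matrix(pi: np.ndarray, w: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    return _weighted_t_matrix(pi, np.ones_like(w), in_a)


def _weighted_f(pi: np.ndarray, w: np.ndarray, group_slices: list[np.ndarray]) -> float:
    """Weighted one-way F for a single arrangement of PIs across groups."""
    n = pi.size
    g = len(group_slices)
    sw_tot = w.sum()
    grand = float((w * pi).sum() / sw_tot)
    ssb = 0.0
    ssw = 0.0
    for idx in group_slices:
        wg = w[idx]
        pg = pi[idx]
        swg = wg.sum()
        mg = float((wg * pg).sum() / swg)
        ssb += swg * (mg - grand) ** 2
        ssw += float((wg * (pg - mg) ** 2).sum())
    if ssw <= 0.0:
        return 0.0 if ssb <= 0.0 else math.inf
    return (ssb / (g - 1)) / (ssw / (n - g))


def _extreme_count(null: np.ndarray, observed: float, sidedness: str) -> int:
    if sidedness == "two_sided":
        return int(np.sum(np.abs(null) >= abs(observed)))
    if sidedness == "one_sided_greater":
        return int(np.sum(null >= observed))
    if sidedness == "one_sided_less":
        return int(np.sum(null <= observed))
    raise ParameterError(f"unknown sidedness: {sidedness!r}")


def _block_partition(
    group_a: list[ChoiceTrial], group_b: list[ChoiceTrial]
) -> list[tuple[np.ndarray, int]] | None:
    """Return per-block (trial indices into the pooled list, n from group A).

    Returns None when no trial carries a block label.  Raises when labels are
    inconsistent: every trial must be labelled if any is, and every block must
    contain trials from both groups (otherwise the within-block shuffle is
    vacuous and silently pools incomparable data).
    """
    pooled = group_a + group_b
    has_block = [t.block is not None for t in pooled]
    if not any(has_block):
        return None
    if not all(has_block):
        raise BlockStructureError("some trials have block labels and some do not")
    blocks_a = {t.block for t in group_a}
    blocks_b = {t.block for t in group_b}
    if blocks_a != blocks_b:
        raise BlockStructureError(
            f"block label sets differ between groups: {sorted(blocks_a)} vs "
            f"{sorted(blocks_b)}"
        )
    n_a = len(group_a)
    out = []
    for blk in sorted(blocks_a):
        idx = np.array([i for i, t in enumerate(pooled) if t.block == blk])
        a_in_block = int(sum(1 for t in group_a if t.block == blk))
        out.append((idx, a_in_block))
    return out


def _n_assignments(blocks: list[tuple[np.ndarray, int]]) -> int:
    total = 1
    for idx, n_a in blocks:
        total *= math.comb(len(idx), n_a)
    return total


def _enumerate_assignments(blocks: list[tuple[np.ndarray, int]], n: int) -> np.ndarray:
    """Boolean (B, n) matrix of every within-block assignment to group A."""
    per_block = []
    for idx, n_a in blocks:
        per_block.append([np.array(c) for c in itertools.combinations(idx, n_a)])
    rows = []
    for combo in itertools.product(*per_block):
        row = np.zeros(n, dtype=bool)
        for chosen in combo:
            row[chosen] = True
        rows.append(row)
    return np.array(rows)


def _sample_assignments(
    blocks: list[tuple[np.ndarray, int]], n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros((n_perm, n), dtype=bool)
    for idx, n_a in blocks:
        k = len(idx)
        # argpartition of uniforms gives a uniform random n_a-subset per row
        u = rng.random((n_perm, k))
        chosen = np.argpartition(u, n_a - 1, axis=1)[:, :n_a]
        out[np.arange(n_perm)[:, None], idx[chosen]] = True
    return out


def randomization_test_two_groups(
    group_a: list[ChoiceTrial],
    group_b: list[ChoiceTrial],
    n_permutations: int = 100_000,
    sidedness: str = "two_sided",
    seed: int | None = None,
    weighted: bool = True,
) -> RandomizationResult:
    """Randomization test comparing mean PI between two groups of trials.

    The observed statistic is a chooser-weighted Welch-style t on trial PIs
    (``weighted=False`` gives the unweighted Welch t).  The null is built by
    permuting trial-level PIs, with their weights attached, across the group
    labels — within blocks when block labels are present.  When the number of
    distinct assignments is at most ``n_permutations`` the null is enumerated
    exhaustively and the exact p-value is reported without smoothing.
    """
    group_a = _clean(group_a)
    group_b = _clean(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientDataError("each group needs at least 2 non-empty trials")
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")

    pooled = group_a + group_b
    pi = np.array([preference_index(t) for t in pooled])
    w = np.array([float(t.n_choosers) for t in pooled])
    n = len(pooled)
    n_a = len(group_a)

    blocks = _block_partition(group_a, group_b)
    if blocks is None:
        blocks = [(np.arange(n), n_a)]

    stat_fn = _weighted_t_matrix if weighted else _unweighted_t_matrix
    observed_assignment = np.zeros((1, n), dtype=bool)
    observed_assignment[0, :n_a] = True
    observed = float(stat_fn(pi, w, observed_assignment)[0])

    total = _n_assignments(blocks)
    if total <= n_permutations:
        assignments = _enumerate_assignments(blocks, n)
        null = stat_fn(pi, w, assignments)
        b = _extreme_count(null, observed, sidedness)
        p = b / total
        return RandomizationResult(observed, null, p, total, sidedness, "t_like",
                                   exhaustive=True, seed=seed)

    rng = np.random.default_rng(seed)
    assignments = _sample_assignments(blocks, n, n_permutations, rng)
    null = stat_fn(pi, w, assignments)
    b = _extreme_count(null, observed, sidedness)
    p = (1 + b) / (1 + n_permutations)
    return RandomizationResult(observed, null, p, n_permutations, sidedness,
                               "t_like", exhaustive=False, seed=seed)


def randomization_anova(
    groups: list[list[ChoiceTrial]],
    n_permutations: int = 100_000,
    seed: int | None = None,
    weighted: bool = True,
) -> RandomizationResult:
    """Randomization ANOVA across three or more groups of trials.

    The statistic is the chooser-weighted between-group mean square over the
    weighted within-group mean square of trial PIs; the null permutes PIs
    (weights attached) across all group labels; p is one-sided upper-tail.
    """
    if len(groups) < 3:
        raise InsufficientDataError(
            "randomization_anova needs >= 3 groups; use "
            "randomization_test_two_groups for two"
        )
    groups = [_clean(g) for g in groups]
    for g in groups:
        if len(g) < 2:
            raise InsufficientDataError("each group needs at least 2 non-empty trials")

    pooled = [t for g in groups for t in g]
    pi = np.array([preference_index(t) for t in pooled])
    w = np.array([float(t.n_choosers) for t in pooled]) if weighted else np.ones(len(pooled))
    sizes = [len(g) for g in groups]
    edges = np.cumsum([0] + sizes)
    slices = [np.arange(edges[i], edges[i + 1]) for i in range(len(groups))]

    observed = _weighted_f(pi, w, slices)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    n = len(pooled)
    for i in range(n_permutations):
        perm = rng.permutation(n)
        null[i] = _weighted_f(pi[perm], w[perm], slices)
    b = int(np.sum(null >= observed))
    p = (1 + b) / (1 + n_permutations)
    return RandomizationResult(observed, null, p, n_permutations,
                               "one_sided_greater", "F_like", exhaustive=False,
                               seed=seed)
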