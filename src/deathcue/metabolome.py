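"""Head-metabolome analysis pipeline.

Implements the targeted-metabolomics workflow end-to-end on a samples x
metabolites abundance matrix with a 2x2 (genotype x exposure) design:

    filter_missingness -> log_transform -> knn_impute -> standardize -> run_pca

followed by a permutation-calibrated Z-score test for principal components
that separate treatment groups, ranking of metabolite loadings on a component
of interest, and a two-criterion screen for candidate metabolites (exposure
effect present in the control genotype, absent in the sensory mutant).

The separation score for one component and one grouping factor is

    Z = between-group variance / within-group variance

with between = sum_k n_k (Mean_total - Mean_k)^2 over the sample projections,
and within the pooled within-group sum of squares (a mean-square variant is
available; the two differ by a constant factor for fixed group sizes, so
permutation p-values are identical).  The null distribution of Z is obtained
by shuffling sample labels; PCA of the unchanged matrix is unchanged by a
label shuffle, so projections are computed once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import (
    DegenerateDataError,
    DomainError,
    EmptyMatrixError,
    InsufficientDataError,
    ParameterError,
    PipelineOrderError,
)

__all__ = [
    "MetaboliteMatrix",
    "PCDecomposition",
    "ZSeparation",
    "CandidateMetabolite",
    "PIPELINE_STAGES",
    "filter_missingness",
    "log_transform",
    "knn_impute",
    "standardize",
    "process_matrix",
    "run_pca",
    "z_separation",
    "permutation_pc_test",
    "stratified_pc_test",
    "rank_loadings",
    "screen_candidates",
]

PIPELINE_STAGES = ("raw", "filtered", "logged", "imputed", "standardized")

GENOTYPE_LEVELS = ("control", "mutant")
EXPOSURE_LEVELS = ("exposed", "unexposed")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PlantedTruth:
    """Ground truth attached to synthetic matrices for recovery tests."""

    direction: np.ndarray       # unit vector in metabolite space
    scores: np.ndarray          # per-sample coordinates along it (incl. shift)
    variance: np.ndarray | float
    rank: int


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundances with factor labels and a missing mask.

    ``data`` holds abundances with NaN at missing entries; ``sample_factors``
    must carry ``genotype`` and ``exposure`` columns indexed like ``data``.
    ``scale`` tracks raw vs natural-log values and ``stage`` tracks progress
    through the enforced pipeline order.
    """

    data: pd.DataFrame
    sample_factors: pd.DataFrame
    scale: str = "raw"
    stage: str = "raw"
    mode: pd.Series | None = None
    truth: PlantedTruth | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ParameterError(f"duplicate metabolite names: {dupes}")
        if self.data.index.duplicated().any():
            raise ParameterError("duplicate sample ids")
        missing = self.data.index.difference(self.sample_factors.index)
        if len(missing) > 0:
            raise ParameterError(f"samples without factor labels: {list(missing)}")
        for col in ("genotype", "exposure"):
            if col not in self.sample_factors.columns:
                raise ParameterError(f"sample_factors missing column {col!r}")
        self.sample_factors = self.sample_factors.loc[self.data.index]
        if self.scale not in ("raw", "log"):
            raise ParameterError(f"unknown scale {self.scale!r}")
        if self.stage not in PIPELINE_STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.data.columns)


def _require_stage(m: MetaboliteMatrix, expected: str, op: str) -> None:
    if m.stage != expected:
        raise PipelineOrderError(
            f"{op} requires a matrix at stage {expected!r}, got {m.stage!r}; "
            f"pipeline order is {' -> '.join(PIPELINE_STAGES)}"
        )


@dataclass
class PCDecomposition:
    """PCA of the processed matrix: orthonormal loadings, sample scores,
    explained variances in non-increasing order (1-based component labels)."""

    loadings: pd.DataFrame        # metabolites x components
    projections: pd.DataFrame     # samples x components
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ZSeparation:
    """Observed Z separation for one component and one grouping factor,
    optionally with its permutation null.

    ``p_value`` is the per-component upper-tail permutation p; ``p_familywise``
    calibrates the same observed Z against the per-permutation maximum of Z
    across components, controlling the family-wise error over components.
    """

    component: int
    grouping_factor: str
    z_observed: float
    group_means: dict
    grand_mean: float
    group_sizes: dict
    n_groups: int
    null_z: np.ndarray | None = field(default=None, repr=False)
    p_value: float | None = None
    p_familywise: float | None = None


@dataclass
class CandidateMetabolite:
    """One metabolite through the two-criterion interaction screen."""

    name: str
    loading_on_target_pc: float
    p_control: float
    p_mutant: float
    direction: str
    flagged: bool


# ---------------------------------------------------------------------------
# processing steps
# ---------------------------------------------------------------------------

def filter_missingness(
    m: MetaboliteMatrix, max_missing_fraction: float = 5 / 32
) -> MetaboliteMatrix:
    """Drop metabolites missing in more than floor(f * n_samples) samples.

    With the default f = 5/32 on a 32-sample matrix, a metabolite missing in 6
    samples is dropped and one missing in 5 is retained.  Column order of the
    survivors is preserved.
    """
    _require_stage(m, "raw", "filter_missingness")
    if m.n_metabolites == 0:
        raise EmptyMatrixError("matrix has no metabolites")
    cutoff = math.floor(max_missing_fraction * m.n_samples)
    counts = m.missing_mask.sum(axis=0)
    keep = counts[counts <= cutoff].index
    if len(keep) == 0:
        raise EmptyMatrixError(
            f"all {m.n_metabolites} metabolites exceed the missingness cutoff"
        )
    data = m.data.loc[:, keep]
    mode = m.mode.loc[keep] if m.mode is not None else None
    return replace(m, data=data, mode=mode, stage="filtered")


def log_transform(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Natural-log transform of the observed abundances; mask unchanged."""
    _require_stage(m, "filtered", "log_transform")
    if m.scale == "log":
        raise DomainError("matrix is already on the log scale")
    values = m.data.to_numpy(dtype=float)
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise DomainError(
            f"non-positive abundance at sample {m.data.index[i]!r}, "
            f"metabolite {m.data.columns[j]!r}: {values[i, j]!r}"
        )
    data = pd.DataFrame(np.log(values), index=m.data.index, columns=m.data.columns)
    return replace(m, data=data, scale="log", stage="logged")


def knn_impute(m: MetaboliteMatrix, k: int = 10) -> MetaboliteMatrix:
    """Impute missing entries from the k nearest metabolites.

    Distance between two metabolites is the plain Euclidean distance over the
    samples in which both are observed.  A missing entry (sample i, metabolite
    j) becomes the mean of sample i's observed values for the k metabolites
    nearest to j.  When fewer than k usable neighbours exist, all available
    ones are used with a warning.  Deterministic; ties broken by smaller
    distance then column order.
    """
    _require_stage(m, "logged", "knn_impute")
    if k < 1:
        raise ParameterError("k must be >= 1")
    X = m.data.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if not (obs.any(axis=0)).all():
        empty = m.data.columns[~obs.any(axis=0)].tolist()
        raise DegenerateDataError(f"metabolites with no observed value: {empty}")
    if obs.all():
        return replace(m, stage="imputed")

    n, p = X.shape
    Xz = np.where(obs, X, 0.0)
    obs_f = obs.astype(float)
    # squared Euclidean over jointly observed samples, all metabolite pairs
    joint = obs_f.T @ obs_f                                  # p x p counts
    sq = Xz * Xz
    cross = Xz.T @ Xz
    a2 = sq.T @ obs_f                                        # sum x_j^2 over joint(j, l)
    d2 = a2 + a2.T - 2.0 * cross
    d2[joint == 0] = np.inf
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)

    out = X.copy()
    warned = False
    for j in range(p):
        rows = np.flatnonzero(~obs[:, j])
        if rows.size == 0:
            continue
        order = np.argsort(d2[j], kind="stable")
        for i in rows:
            usable = order[np.isfinite(d2[j][order]) & obs[i, order]]
            if usable.size == 0:
                raise DegenerateDataError(
                    f"no usable neighbour for sample {m.data.index[i]!r}, "
                    f"metabolite {m.data.columns[j]!r}"
                )
            if usable.size < k and not warned:
                warnings.warn(
                    f"fewer than k={k} neighbours available for "
                    f"{m.data.columns[j]!r}; using all {usable.size}",
                    stacklevel=2,
                )
                warned = True
            out[i, j] = X[i, usable[:k]].mean()
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return replace(m, data=data, stage="imputed")


def standardize(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Scale each metabolite to mean 0 and unit sample variance (ddof=1)."""
    _require_stage(m, "imputed", "standardize")
    X = m.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise PipelineOrderError("standardize requires a complete matrix")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateDataError(
            f"zero-variance metabolite(s): {m.data.columns[zero].tolist()}"
        )
    data = pd.DataFrame((X - mu) / sd, index=m.data.index, columns=m.data.columns)
    return replace(m, data=data, stage="standardized")


def process_matrix(
    m: MetaboliteMatrix,
    max_missing_fraction: float = 5 / 32,
    k: int = 10,
) -> MetaboliteMatrix:
    """Run filter -> log -> impute -> standardize in the enforced order."""
    m = filter_missingness(m, max_missing_fraction)
    if m.scale == "raw":
        m = log_transform(m)
    else:  # already log-scale input: keep values, advance the stage
        m = replace(m, stage="logged")
    m = knn_impute(m, k=k)
    return standardize(m)


# ---------------------------------------------------------------------------
# decomposition and separation testing
# ---------------------------------------------------------------------------

def run_pca(m: MetaboliteMatrix) -> PCDecomposition:
    """Covariance PCA of the processed matrix.

    Components are ordered by non-increasing explained variance (ddof = n-1);
    each loading vector's sign is fixed so its largest-magnitude entry is
    positive.  All min(n_samples - 1, n_metabolites) components are kept, so
    the explained variances sum to the total variance of the input.
    """
    _require_stage(m, "standardized", "run_pca")
    if m.n_samples < 3:
        raise InsufficientDataError("PCA needs at least 3 samples")
    X = m.data.to_numpy(dtype=float)
    n_comp = min(m.n_samples - 1, m.n_metabolites)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()              # p x c
    for c in range(n_comp):
        i = np.argmax(np.abs(loadings[:, c]))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    labels = [f"PC{i + 1}" for i in range(n_comp)]
    return PCDecomposition(
        loadings=pd.DataFrame(loadings, index=m.data.columns, columns=labels),
        projections=pd.DataFrame(scores, index=m.data.index, columns=labels),
        explained_variance=pca.explained_variance_.copy(),
    )


def _z_stat(x: np.ndarray, codes: np.ndarray, n_groups: int, within: str) -> float:
    grand = x.mean()
    between = 0.0
    ssw = 0.0
    n_minus_g = x.size - n_groups
    for g in range(n_groups):
        xg = x[codes == g]
        mg = xg.mean()
        between += xg.size * (grand - mg) ** 2
        ssw += ((xg - mg) ** 2).sum()
    if within == "mean_square":
        ssw = ssw / n_minus_g
    if ssw == 0.0:
        raise DegenerateDataError("within-group variance is zero")
    return between / ssw


def z_separation(
    projections_on_pc,
    groups,
    component: int = 0,
    grouping_factor: str = "",
    within: str = "ss",
) -> ZSeparation:
    """Observed Z = between-group variance / within-group variance.

    ``within='ss'`` (default) uses the pooled within-group sum of squared
    deviations; ``within='mean_square'`` divides that by sum(n_k - 1).  Both
    give identical permutation p-values for fixed group sizes.
    """
    if within not in ("ss", "mean_square"):
        raise ParameterError(f"unknown within-variance mode {within!r}")
    x = np.asarray(projections_on_pc, dtype=float)
    labels = np.asarray(groups)
    if x.shape != labels.shape:
        raise ParameterError("projections and group labels differ in length")
    levels, codes = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise InsufficientDataError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise InsufficientDataError("every group needs at least 2 samples")
    z = _z_stat(x, codes, len(levels), within)
    means = {lev: float(x[codes == g].mean()) for g, lev in enumerate(levels)}
    return ZSeparation(
        component=component,
        grouping_factor=grouping_factor,
        z_observed=z,
        group_means=means,
        grand_mean=float(x.mean()),
        group_sizes={lev: int(s) for lev, s in zip(levels, sizes)},
        n_groups=len(levels),
    )


def _grouping_labels(m: MetaboliteMatrix, grouping_factor: str) -> np.ndarray:
    if grouping_factor == "composite":
        f = m.sample_factors
        return (f["genotype"].astype(str) + ":" + f["exposure"].astype(str)).to_numpy()
    if grouping_factor not in m.sample_factors.columns:
        raise ParameterError(
            f"grouping factor {grouping_factor!r} not in sample factors "
            f"{list(m.sample_factors.columns)}"
        )
    return m.sample_factors[grouping_factor].to_numpy()


def _z_all_components(P: np.ndarray, codes: np.ndarray, n_groups: int,
                      within: str) -> np.ndarray:
    """Z for every component at once given integer group codes."""
    n, c = P.shape
    grand = P.mean(axis=0)
    between = np.zeros(c)
    ssw = np.zeros(c)
    for g in range(n_groups):
        Pg = P[codes == g]
        mg = Pg.mean(axis=0)
        between += Pg.shape[0] * (grand - mg) ** 2
        ssw += ((Pg - mg) ** 2).sum(axis=0)
    if within == "mean_square":
        ssw = ssw / (n - n_groups)
    return between / ssw


def permutation_pc_test(
    m: MetaboliteMatrix,
    grouping_factor: str = "composite",
    n_permutations: int = 10_000,
    seed: int | None = None,
    within: str = "ss",
    decomposition: PCDecomposition | None = None,
    keep_null: bool = False,
) -> list[ZSeparation]:
    """Permutation test of group separation on every principal component.

    Sample labels are shuffled jointly across the design (equivalently, rows
    of the factor table are permuted); PCA of the unchanged matrix is itself
    unchanged, so projections are computed once and Z is recomputed from the
    permuted labels.  The per-component p-value is upper-tail with add-one
    smoothing, p = (1 + #{null Z >= observed Z}) / (1 + n_permutations).  Each
    result also carries ``p_familywise``, calibrated against the maximum Z
    across components per permutation.

    ``grouping_factor`` is ``exposure``, ``genotype`` or ``composite`` (the
    four genotype x exposure cells).
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    labels = _grouping_labels(m, grouping_factor)
    dec = decomposition if decomposition is not None else run_pca(m)
    P = dec.projections.to_numpy()
    n, c = P.shape
    levels, codes = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ParameterError(f"grouping factor {grouping_factor!r} has one level")

    z_obs = _z_all_components(P, codes, len(levels), within)

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, c))
    for b in range(n_permutations):
        null[b] = _z_all_components(P, codes[rng.permutation(n)], len(levels), within)
    null_max = null.max(axis=1)

    results = []
    for j in range(c):
        count = int(np.sum(null[:, j] >= z_obs[j]))
        count_fw = int(np.sum(null_max >= z_obs[j]))
        x = P[:, j]
        means = {lev: float(x[codes == g].mean()) for g, lev in enumerate(levels)}
        sizes = np.bincount(codes)
        results.append(ZSeparation(
            component=j + 1,
            grouping_factor=grouping_factor,
            z_observed=float(z_obs[j]),
            group_means=means,
            grand_mean=float(x.mean()),
            group_sizes={lev: int(s) for lev, s in zip(levels, sizes)},
            n_groups=len(levels),
            null_z=null[:, j].copy() if keep_null else None,
            p_value=(1 + count) / (1 + n_permutations),
            p_familywise=(1 + count_fw) / (1 + n_permutations),
        ))
    return results


def stratified_pc_test(
    m: MetaboliteMatrix,
    test_factor: str = "exposure",
    stratify_by: str = "genotype",
    n_permutations: int = 10_000,
    seed: int | None = None,
    within: str = "ss",
    decomposition: PCDecomposition | None = None,
) -> list[float]:
    """Per-component evidence that ``test_factor`` separates samples within
    at least one stratum of ``stratify_by``.

    For each stratum, a permutation Z test of ``test_factor`` is run on the
    stratum's projections alone; the reported per-component p-value is the
    minimum across strata.  This attributes a component to a factor even when
    the effect is confined to one level of the other factor (an exposure
    response present in sighted controls but absent in blind mutants moves
    both marginal group means equally, so marginal tests cannot tell the two
    factors apart).  No multiplicity correction across strata is applied; the
    caller compares against its alpha.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    dec = decomposition if decomposition is not None else run_pca(m)
    P = dec.projections.to_numpy()
    strata = _grouping_labels(m, stratify_by)
    labels = _grouping_labels(m, test_factor)
    rng = np.random.default_rng(seed)
    c = P.shape[1]
    best_p = np.ones(c)
    for stratum in np.unique(strata):
        rows = strata == stratum
        Ps = P[rows]
        levels, codes = np.unique(labels[rows], return_inverse=True)
        if len(levels) < 2 or np.bincount(codes).min() < 2:
            continue
        ns = Ps.shape[0]
        z_obs = _z_all_components(Ps, codes, len(levels), within)
        count = np.zeros(c, dtype=int)
        for _ in range(n_permutations):
            z_null = _z_all_components(Ps, codes[rng.permutation(ns)],
                                       len(levels), within)
            count += z_null >= z_obs
        p = (1 + count) / (1 + n_permutations)
        best_p = np.minimum(best_p, p)
    return best_p.tolist()


def rank_loadings(
    d: PCDecomposition, component_index: int, top_n: int = 10
) -> list[str]:
    """Metabolites sorted by absolute loading on one component, descending.

    ``component_index`` is 1-based (PC10 is component_index=10).  Ties in
    absolute loading are broken lexicographically by metabolite name, so the
    ordering is deterministic and invariant to loading sign flips.
    """
    if not 1 <= component_index <= d.n_components:
        raise ParameterError(
            f"component_index {component_index} out of range 1..{d.n_components}"
        )
    col = d.loadings.iloc[:, component_index - 1]
    if top_n > len(col):
        warnings.warn(
            f"top_n={top_n} exceeds metabolite count {len(col)}; truncating",
            stacklevel=2,
        )
        top_n = len(col)
    order = sorted(col.index, key=lambda name: (-abs(col[name]), name))
    return order[:top_n]


# ---------------------------------------------------------------------------
# candidate screen
# ---------------------------------------------------------------------------

def screen_candidates(
    m: MetaboliteMatrix,
    candidates: list[str] | None = None,
    alpha: float = 0.05,
    decomposition: PCDecomposition | None = None,
    component_index: int | None = None,
) -> list[CandidateMetabolite]:
    """Two-criterion screen for perception-dependent metabolites.

    For each candidate, a one-sided Student's t test compares exposed vs
    unexposed samples within each genotype; the direction is set by the sign
    of the exposure effect in the control genotype.  A metabolite is flagged
    when the effect is significant in the control genotype (p_control < alpha)
    and not in the mutant (p_mutant >= alpha).
    """
    from scipy import stats

    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    f = m.sample_factors
    for col, levels in (("genotype", GENOTYPE_LEVELS), ("exposure", EXPOSURE_LEVELS)):
        present = set(f[col].astype(str))
        if not set(levels) <= present:
            raise InsufficientDataError(
                f"{col} must include levels {levels}; found {sorted(present)}"
            )
    if candidates is None:
        candidates = m.metabolite_names
    unknown = [c for c in candidates if c not in m.data.columns]
    if unknown:
        raise ParameterError(f"unknown candidate metabolites: {unknown}")

    cells = {}
    for geno in GENOTYPE_LEVELS:
        for expo in EXPOSURE_LEVELS:
            idx = (f["genotype"] == geno) & (f["exposure"] == expo)
            if idx.sum() < 2:
                raise InsufficientDataError(
                    f"cell genotype={geno}, exposure={expo} has "
                    f"{int(idx.sum())} samples; need >= 2"
                )
            cells[geno, expo] = idx.to_numpy()

    loading = None
    if decomposition is not None and component_index is not None:
        loading = decomposition.loadings.iloc[:, component_index - 1]

    out = []
    for name in candidates:
        x = m.data[name].to_numpy(dtype=float)
        ctrl_e = x[cells["control", "exposed"]]
        ctrl_u = x[cells["control", "unexposed"]]
        direction = "greater" if ctrl_e.mean() >= ctrl_u.mean() else "less"
        p_control = float(stats.ttest_ind(
            ctrl_e, ctrl_u, equal_var=True, alternative=direction).pvalue)
        mut_e = x[cells["mutant", "exposed"]]
        mut_u = x[cells["mutant", "unexposed"]]
        p_mutant = float(stats.ttest_ind(
            mut_e, mut_u, equal_var=True, alternative=direction).pvalue)
        out.append(CandidateMetabolite(
            name=name,
            loading_on_target_pc=float(loading[name]) if loading is not None else float("nan"),
            p_control=p_control,
            p_mutant=p_mutant,
            direction=direction,
            flagged=(p_control < alpha) and (p_mutant >= alpha),
        ))
    return out
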