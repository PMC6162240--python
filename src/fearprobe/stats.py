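"""Statistical machinery for group-level marker analysis.

Implements the classical tests used downstream of the evoked markers:
paired and Welch t-tests with Cohen's d effect sizes, Benjamini-Hochberg
FDR adjustment, nonparametric cluster-based permutation tests over the
sensor array (sign-flipping null, cluster-mass statistic), and
backward-elimination multiple regression with an overall F-test.
Distribution functions come from scipy; the procedures themselves are
implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from fearprobe.core import InvalidParameterError, SensorLayout

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "ClusterResult",
    "RegressionResult",
    "paired_t",
    "two_sample_t",
    "cohens_d",
    "fdr_adjust",
    "neighbor_graph",
    "cluster_permutation",
    "backward_elimination",
]


@dataclass
class TestResult:
    """t-test summary: the columns of a marker comparison table."""

    t: float
    p: float
    mean_difference: float
    se_difference: float
    cohens_d: float
    n: int
    alternative: str = "two-sided"


@dataclass
class Cluster:
    """A connected set of suprathreshold channels."""

    channels: list[int]
    mass: float  # sum of member t-values (signed)
    p: float  # Monte Carlo p-value


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    channel_t: np.ndarray
    n_permutations: int
    threshold_p: float
    seed: int | None = None

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]


@dataclass
class RegressionResult:
    """Final model of a backward-elimination regression."""

    selected: list[str]
    coefficients: dict[str, float]
    r2: float
    adjusted_r2: float
    f_statistic: float
    p_value: float
    n: int
    eliminated: list[str] = field(default_factory=list)


def _t_pvalue(t: float, df: float, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2 * sps.t.sf(abs(t), df))
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    raise InvalidParameterError(f"unknown alternative {alternative!r}")


def cohens_d(
    x: np.ndarray, y: np.ndarray, paired: bool = True, method: str = "diff_sd"
) -> float:
    """Cohen's d effect size.

    Paired default: mean difference divided by the standard deviation of
    the differences. ``method='pooled'`` uses the pooled within-group SD
    instead (also the definition used for unpaired comparisons). Scale
    invariant: d(ax, ay) = d(x, y) for a > 0.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if paired and method == "diff_sd":
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            return 0.0 if np.isclose(d.mean(), 0) else np.inf * np.sign(d.mean())
        return float(d.mean() / sd)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def paired_t(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided",
    d_method: str = "diff_sd",
) -> TestResult:
    """Classical paired t-test with n-1 degrees of freedom."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise InvalidParameterError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise InvalidParameterError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):  # identical samples: no effect, no evidence
            return TestResult(t=0.0, p=1.0, mean_difference=0.0, se_difference=0.0,
                              cohens_d=0.0, n=n, alternative=alternative)
        raise InvalidParameterError("zero variance of differences")
    se = sd / np.sqrt(n)
    t = float(d.mean() / se)
    return TestResult(
        t=t, p=_t_pvalue(t, n - 1, alternative),
        mean_difference=float(d.mean()), se_difference=float(se),
        cohens_d=cohens_d(x, y, paired=True, method=d_method), n=n,
        alternative=alternative,
    )


def two_sample_t(
    group_a: np.ndarray, group_b: np.ndarray, alternative: str = "two-sided"
) -> TestResult:
    """Welch two-sample t-test (unequal variances, unequal n allowed)."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InvalidParameterError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = np.sqrt(va / na + vb / nb)
    if se == 0:
        t, df = 0.0, na + nb - 2
    else:
        t = float((a.mean() - b.mean()) / se)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    return TestResult(
        t=t, p=_t_pvalue(t, df, alternative) if se > 0 else 1.0,
        mean_difference=float(a.mean() - b.mean()), se_difference=float(se),
        cohens_d=cohens_d(a, b, paired=False, method="pooled"), n=na + nb,
        alternative=alternative,
    )


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving with monotonicity enforcement:
    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted vector.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise InvalidParameterError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def neighbor_graph(layout: SensorLayout, scale: float = 1.5) -> list[list[int]]:
    """Adjacency lists: channels within a distance threshold are neighbours.

    The threshold is ``scale`` times the 10th percentile of all pairwise
    inter-channel distances, a density-adaptive default.
    """
    pos = layout.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    pair = d[np.triu_indices(len(pos), k=1)]
    thresh = scale * np.percentile(pair, 10)
    adj = (d <= thresh) & ~np.eye(len(pos), dtype=bool)
    return [[int(j) for j in np.flatnonzero(adj[i])] for i in range(len(pos))]


def _connected_clusters(members: np.ndarray, adjacency: list[list[int]]) -> list[list[int]]:
    """Connected components of the suprathreshold channel subgraph."""
    member_set = set(int(i) for i in members)
    seen: set[int] = set()
    clusters = []
    for start in members:
        start = int(start)
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in adjacency[node]:
                if nb in member_set and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        clusters.append(sorted(comp))
    return clusters


def _max_cluster_mass(t_vals: np.ndarray, t_crit: float, adjacency: list[list[int]]) -> float:
    """Largest |sum of t| over sign-separated suprathreshold clusters."""
    best = 0.0
    for sign in (1.0, -1.0):
        members = np.flatnonzero(sign * t_vals > t_crit)
        for comp in _connected_clusters(members, adjacency):
            best = max(best, abs(float(t_vals[comp].sum())))
    return best


def cluster_permutation(
    diffs: np.ndarray,
    layout: SensorLayout,
    n_perm: int = 1000,
    p_thresh: float = 0.05,
    seed: int | None = None,
    adjacency: list[list[int]] | None = None,
) -> ClusterResult:
    """Cluster-based permutation test on subject x channel difference maps.

    Per channel, a one-sample t-test of the T-NT differences against
    zero; channels with ``p < p_thresh`` (two-sided) form clusters of
    graph-connected neighbours, separately for positive and negative t.
    The cluster mass is the sum of member t-values. The null
    distribution flips the sign of whole subject difference maps
    ``n_perm`` times and records the maximum absolute cluster mass, so
    each observed cluster's Monte Carlo p-value
    ``(1 + #{null >= |mass|}) / (1 + n_perm)`` is corrected over the
    whole sensor array.
    """
    diffs = np.asarray(diffs, float)
    if diffs.ndim != 2:
        raise InvalidParameterError("diffs must be subjects x channels")
    n_sub, n_ch = diffs.shape
    if n_sub < 2:
        raise InvalidParameterError("need at least 2 subjects")
    if n_ch != layout.n_channels:
        raise InvalidParameterError("diffs columns must match layout channels")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; Monte Carlo p is coarse",
                      stacklevel=2)
    if adjacency is None:
        adjacency = neighbor_graph(layout)

    def t_stat(x: np.ndarray) -> np.ndarray:
        se = x.std(axis=0, ddof=1) / np.sqrt(n_sub)
        se = np.where(se == 0, np.inf, se)
        return x.mean(axis=0) / se

    t_obs = t_stat(diffs)
    t_crit = float(sps.t.isf(p_thresh / 2, n_sub - 1))

    observed = []
    for sign in (1.0, -1.0):
        members = np.flatnonzero(sign * t_obs > t_crit)
        for comp in _connected_clusters(members, adjacency):
            observed.append(Cluster(channels=comp, mass=float(t_obs[comp].sum()), p=1.0))

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    # vectorized channel t for all permutations: sign flips leave x^2 fixed
    sumsq = np.sum(diffs**2, axis=0)  # (n_ch,)
    means = flips @ diffs / n_sub  # (n_perm, n_ch)
    var = (sumsq[None, :] - n_sub * means**2) / (n_sub - 1)
    var = np.maximum(var, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / np.sqrt(var / n_sub)
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=0.0, neginf=0.0)

    null_max = np.array(
        [_max_cluster_mass(t_perm[i], t_crit, adjacency) for i in range(n_perm)]
    )
    for c in observed:
        c.p = float((1 + np.sum(null_max >= abs(c.mass))) / (1 + n_perm))
    observed.sort(key=lambda c: c.p)
    return ClusterResult(
        clusters=observed, channel_t=t_obs, n_permutations=n_perm,
        threshold_p=p_thresh, seed=seed,
    )


def backward_elimination(
    y: np.ndarray,
    X: pd.DataFrame,
    alpha_remove: float = 0.10,
    prescreen_alpha: float = 0.2,
) -> RegressionResult:
    """Backward-elimination OLS: drop the worst predictor until all pass.

    All candidates enter simultaneously when the sample size permits
    (n > k + 1); otherwise candidates are pre-screened by univariate
    p < ``prescreen_alpha`` first. At each step the predictor with the
    largest coefficient p-value is removed if it exceeds
    ``alpha_remove`` (the 10% level by default); iteration stops when
    every remaining predictor passes or none remain. The final model is
    summarized by r2, adjusted r2 and its F-test against the
    intercept-only model.
    """
    y = np.asarray(y, float)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float),
                         columns=[f"x{i + 1}" for i in range(np.asarray(X).shape[1])])
    n = len(y)
    if len(X) != n:
        raise InvalidParameterError("y and X must have equal length")

    candidates = list(X.columns)
    eliminated: list[str] = []
    if n <= len(candidates) + 1:
        kept = []
        for col in candidates:
            fit = sm.OLS(y, sm.add_constant(X[[col]])).fit()
            if fit.pvalues[col] < prescreen_alpha:
                kept.append(col)
        eliminated.extend(c for c in candidates if c not in kept)
        candidates = kept

    current = list(candidates)
    fit = None
    while current:
        design = sm.add_constant(X[current])
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            raise InvalidParameterError(
                f"rank-deficient design; collinear columns among {current}"
            )
        fit = sm.OLS(y, design).fit()
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] > alpha_remove:
            current.remove(worst)
            eliminated.append(worst)
            fit = None
        else:
            break

    if not current:
        return RegressionResult(
            selected=[], coefficients={}, r2=0.0, adjusted_r2=0.0,
            f_statistic=0.0, p_value=1.0, n=n, eliminated=eliminated,
        )
    fvalue = float(fit.fvalue)
    f_pvalue = float(fit.f_pvalue)
    if not np.isfinite(f_pvalue):  # perfect fit: F -> inf
        fvalue, f_pvalue = np.inf, 0.0
    return RegressionResult(
        selected=list(current),
        coefficients={"const": float(fit.params["const"]),
                      **{c: float(fit.params[c]) for c in current}},
        r2=float(fit.rsquared), adjusted_r2=float(fit.rsquared_adj),
        f_statistic=fvalue, p_value=f_pvalue, n=n, eliminated=eliminated,
    )
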