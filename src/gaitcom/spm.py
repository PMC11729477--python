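"""One-dimensional statistical parametric mapping over the gait cycle.

At each of the 101 cycle nodes a one-way repeated-measures ANOVA compares
the three measurement conditions (IMU, ML5, CoM); the resulting F field is
thresholded with 1-D random field theory (RFT) so the family-wise error
over the whole cycle is controlled at alpha.  Post-hoc paired-t fields use
a Bonferroni-corrected alpha (0.05 / 3 pairwise comparisons, i.e. 0.017).

The RFT pieces are the standard ones for smooth 1-D fields:

* field smoothness (FWHM) from the normalized residual gradients
  (Kiebel et al.): ``FWHM = sqrt(4 ln 2 / <|grad r~|^2>)``;
* resels = (field extent in nodes) / FWHM;
* the critical threshold solves ``E[EC](u) = alpha`` where the expected
  Euler characteristic combines the point exceedance probability with the
  Worsley (1994) 1-D EC density of the t or F field times the resel count;
* suprathreshold clusters are maximal runs of nodes above the threshold,
  with cluster p-values from the expected-cluster (Friston et al. 1994,
  D = 1) approximation.

A within-subject permutation oracle (condition-label permutation for F,
sign flips of paired differences for t) provides an independent check of
the RFT thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .errors import DataError, StatisticError

__all__ = [
    "SpmDesign",
    "Cluster",
    "SpmFieldResult",
    "PermutationResult",
    "rm_anova_field",
    "paired_t_field",
    "estimate_fwhm",
    "rft_threshold",
    "expected_euler_char",
    "find_clusters",
    "cluster_p_value",
    "spm_anova",
    "posthoc_paired_t",
    "permutation_oracle",
]

FOUR_LOG2 = 4.0 * math.log(2.0)
_EPS = 1e-12


@dataclass
class SpmDesign:
    """Balanced subject x condition x node data for one anatomical direction."""

    data: np.ndarray                      # (S, C, N)
    condition_names: tuple[str, ...] = ("IMU", "ML5", "CoM")
    alpha: float = 0.05
    alpha_posthoc: float | None = None    # default: alpha / n_pairwise

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataError("design data must be (subjects, conditions, nodes)")
        if self.data.shape[0] < 2:
            raise DataError("repeated-measures ANOVA needs >= 2 subjects")
        if self.data.shape[1] != len(self.condition_names):
            raise DataError("condition_names length must match the data")
        if np.isnan(self.data).any():
            raise DataError("design must be complete (no missing cells)")
        if not 0.0 < self.alpha < 1.0:
            raise DataError("alpha must lie in (0, 1)")
        if self.alpha_posthoc is None:
            k = self.data.shape[1]
            self.alpha_posthoc = self.alpha / (k * (k - 1) / 2)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[2]


@dataclass
class Cluster:
    start_node: int
    end_node: int          # inclusive
    start_pct: float
    end_pct: float
    peak: float
    p: float | None = None


@dataclass
class SpmFieldResult:
    stat: str                       # "F" | "t"
    field: np.ndarray               # (N,)
    dof: tuple[float, float]
    fwhm: float
    resels: float
    threshold: float
    clusters: list[Cluster]
    alpha: float
    two_tailed: bool = False
    label: str = ""
    degenerate: bool = False        # zero residual variance somewhere


# ---------------------------------------------------------------------------
# statistic fields

def rm_anova_field(data: np.ndarray):
    """Pointwise one-way repeated-measures F field.

    Returns ``(F, dof, residuals, degenerate)`` where ``residuals`` is the
    (S*C, N) interaction residual field used for smoothness estimation.
    At nodes with zero residual variance, F is 0 when there is also no
    condition effect and +inf otherwise; either case sets ``degenerate``.
    """
    data = np.asarray(data, dtype=float)
    S, C, N = data.shape
    if S < 2 or C < 2:
        raise DataError("need >= 2 subjects and >= 2 conditions")
    grand = data.mean(axis=(0, 1))
    subj = data.mean(axis=1)        # (S, N)
    cond = data.mean(axis=0)        # (C, N)
    ss_cond = S * ((cond - grand) ** 2).sum(axis=0)
    resid = data - subj[:, None, :] - cond[None, :, :] + grand
    ss_err = (resid ** 2).sum(axis=(0, 1))
    dof = (C - 1, (C - 1) * (S - 1))
    ms_cond = ss_cond / dof[0]
    ms_err = ss_err / dof[1]
    degenerate = bool(np.any(ms_err <= _EPS))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(
            ms_err > _EPS,
            ms_cond / np.where(ms_err > _EPS, ms_err, 1.0),
            np.where(ms_cond <= _EPS, 0.0, np.inf),
        )
    return F, dof, resid.reshape(S * C, N), degenerate


def paired_t_field(data_pair: np.ndarray):
    """Pointwise paired t field for an (S, 2, N) condition pair.

    Returns ``(t, dof, residuals, degenerate)``; residuals are the
    mean-centred within-pair differences.
    """
    data_pair = np.asarray(data_pair, dtype=float)
    S = data_pair.shape[0]
    if data_pair.ndim != 3 or data_pair.shape[1] != 2:
        raise DataError("paired t expects an (S, 2, N) array")
    if S < 2:
        raise DataError("paired t needs >= 2 subjects")
    d = data_pair[:, 0] - data_pair[:, 1]   # (S, N)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = bool(np.any(sd <= _EPS))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            sd > _EPS,
            mean / (np.where(sd > _EPS, sd, 1.0) / math.sqrt(S)),
            np.where(np.abs(mean) <= _EPS, 0.0, np.inf * np.sign(mean + _EPS)),
        )
    return t, (1.0, float(S - 1)), d - mean, degenerate


# ---------------------------------------------------------------------------
# random field theory

def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, in nodes) from normalized residual gradients.

    Residuals are normalized pointwise by the root sum of squares across
    curves; the mean squared gradient of the normalized field gives
    ``FWHM = sqrt(4 ln 2 / msg)``.  Constant residuals (zero gradient
    everywhere) return +inf (infinite smoothness).
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2 or R.shape[0] < 2:
        raise DataError("need >= 2 residual curves over >= 2 nodes")
    ssq = (R ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Rn = R / np.sqrt(ssq)
    grad = np.diff(Rn, axis=1)
    v = (grad ** 2).sum(axis=0)
    v = v[np.isfinite(v)]
    if v.size == 0 or np.all(v <= _EPS):
        return math.inf
    msg = float(v.mean())
    return math.sqrt(FOUR_LOG2 / msg)


def _ec1_density(u: float, stat: str, dof: tuple[float, float]) -> float:
    """Worsley (1994) 1-D Euler-characteristic density per resel."""
    if u <= 0 and stat == "F":
        return math.inf
    if stat == "t":
        v = dof[1]
        a = math.sqrt(FOUR_LOG2) / (2.0 * math.pi)
        return a * (1.0 + u * u / v) ** (-(v - 1.0) / 2.0)
    if stat == "F":
        k, v = dof
        a = math.sqrt(FOUR_LOG2 / (2.0 * math.pi))
        lognum = gammaln((v + k - 1.0) / 2.0) - gammaln(v / 2.0) - gammaln(k / 2.0)
        x = k * u / v
        return (
            a
            * math.exp(lognum)
            * math.sqrt(2.0)
            * x ** ((k - 1.0) / 2.0)
            * (1.0 + x) ** (-(v + k - 2.0) / 2.0)
        )
    raise ValueError(f"unknown statistic {stat!r}")


def _point_sf(u: float, stat: str, dof: tuple[float, float]) -> float:
    if stat == "t":
        return float(stats.t.sf(u, dof[1]))
    return float(stats.f.sf(u, dof[0], dof[1]))


def expected_euler_char(u: float, stat: str, dof: tuple[float, float], resels: float) -> float:
    """Expected Euler characteristic of the excursion set above ``u``.

    The point (boundary) term is the one-node exceedance probability; the
    extent term is the resel count times the 1-D EC density.
    """
    return _point_sf(u, stat, dof) + resels * _ec1_density(u, stat, dof)


def rft_threshold(
    alpha: float,
    dof: tuple[float, float],
    resels: float,
    stat: str = "F",
) -> float:
    """Critical value ``u*`` with ``E[EC](u*) = alpha``, solved to 1e-8.

    As ``resels -> 0`` the threshold tends to the ordinary single-comparison
    quantile of the t or F distribution.
    """
    if not 0.0 < alpha < 1.0:
        raise StatisticError("alpha must be in (0, 1)")
    if stat == "t" and dof[1] <= 1:
        # the t EC density with 1 dof does not decay; RFT is ill-posed
        raise StatisticError("RFT t-field threshold needs > 1 denominator dof (>= 3 subjects)")
    if resels < 0 or not np.isfinite(resels):
        resels = 0.0 if not np.isfinite(resels) else resels
    if resels < 0:
        raise StatisticError("resels must be >= 0")
    q0 = stats.t.isf(alpha, dof[1]) if stat == "t" else stats.f.isf(alpha, dof[0], dof[1])
    if resels == 0.0:
        return float(q0)
    g = lambda u: expected_euler_char(u, stat, dof, resels) - alpha
    lo = float(q0)
    hi = lo + 1.0
    for _ in range(200):
        if g(hi) < 0:
            break
        hi *= 2.0
    else:
        raise StatisticError("RFT threshold search failed to bracket a root")
    return float(optimize.brentq(g, lo, hi, xtol=1e-8))


def find_clusters(field: np.ndarray, threshold: float) -> list[Cluster]:
    """Maximal runs of consecutive nodes with ``field > threshold``."""
    f = np.asarray(field, dtype=float)
    above = f > threshold
    clusters: list[Cluster] = []
    n = f.size
    i = 0
    pct = 100.0 / (n - 1) if n > 1 else 0.0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            clusters.append(
                Cluster(
                    start_node=i,
                    end_node=j,
                    start_pct=i * pct,
                    end_pct=j * pct,
                    peak=float(f[i : j + 1].max()),
                )
            )
            i = j + 1
        else:
            i += 1
    return clusters


def cluster_p_value(
    extent_nodes: int,
    threshold: float,
    stat: str,
    dof: tuple[float, float],
    resels: float,
    n_nodes: int,
) -> float:
    """Cluster-level p from the expected-cluster approximation (1-D).

    Cluster extents above ``threshold`` are modelled as
    ``P(extent >= s) = exp(-beta s^2)`` (Friston et al. 1994 with D = 1),
    with ``beta`` fixed by the RFT expected cluster count and expected
    suprathreshold volume; the cluster p is
    ``1 - exp(-E[clusters] * P(extent >= s))``.
    """
    if resels <= 0 or n_nodes < 2:
        return float(_point_sf(threshold, stat, dof))
    resels_per_node = resels / (n_nodes - 1)
    s = extent_nodes * resels_per_node
    e_n = resels * _ec1_density(threshold, stat, dof)
    e_v = resels * _point_sf(threshold, stat, dof)
    if e_n <= 0:
        return 0.0
    e_s = max(e_v / e_n, _EPS)
    beta = (math.gamma(1.5) / e_s) ** 2
    p_ext = math.exp(-beta * s * s)
    return float(1.0 - math.exp(-e_n * p_ext))


# ---------------------------------------------------------------------------
# top-level SPM procedures

def _build_result(field_vals, stat, dof, residuals, alpha, two_tailed, label, degenerate):
    n = field_vals.size
    fwhm = estimate_fwhm(residuals) if not degenerate else math.inf
    resels = 0.0 if not np.isfinite(fwhm) else (n - 1) / fwhm
    solve_alpha = alpha / 2.0 if two_tailed else alpha
    threshold = rft_threshold(solve_alpha, dof, resels, stat=stat)
    test_field = np.abs(field_vals) if two_tailed else field_vals
    finite = np.where(np.isfinite(test_field), test_field, np.inf)
    clusters = find_clusters(finite, threshold)
    for c in clusters:
        c.p = cluster_p_value(c.end_node - c.start_node + 1, threshold, stat, dof, resels, n)
        if two_tailed:
            c.p = min(1.0, 2.0 * c.p)
    return SpmFieldResult(
        stat=stat, field=field_vals, dof=dof, fwhm=fwhm, resels=resels,
        threshold=threshold, clusters=clusters, alpha=alpha,
        two_tailed=two_tailed, label=label, degenerate=degenerate,
    )


def spm_anova(design: SpmDesign) -> SpmFieldResult:
    """Omnibus repeated-measures ANOVA field with RFT inference."""
    F, dof, resid, degenerate = rm_anova_field(design.data)
    if degenerate:
        warnings.warn("zero residual variance at some nodes; F field degenerate there",
                      stacklevel=2)
    return _build_result(F, "F", dof, resid, design.alpha, False, "omnibus", degenerate)


def posthoc_paired_t(design: SpmDesign, pair: tuple[str, str]) -> SpmFieldResult:
    """Two-tailed paired-t field for one condition pair at the Bonferroni alpha."""
    idx = tuple(design.condition_names.index(c) for c in pair)
    sub = design.data[:, idx, :]
    t, dof, resid, degenerate = paired_t_field(sub)
    label = f"{pair[0]} vs {pair[1]}"
    return _build_result(t, "t", dof, resid, design.alpha_posthoc, True, label, degenerate)


# ---------------------------------------------------------------------------
# permutation oracle

@dataclass
class PermutationResult:
    threshold: float
    max_distribution: np.ndarray
    n_perm: int
    alpha: float


def permutation_oracle(
    design: SpmDesign,
    n_perm: int = 1000,
    seed: int = 0,
    stat: str = "F",
    pair: tuple[str, str] | None = None,
) -> PermutationResult:
    """Permutation-based critical threshold for the field maximum.

    For the F field, condition labels are permuted independently within
    each subject; for the paired t field, the within-pair differences
    receive random sign flips.  The threshold is the ``1 - alpha`` quantile
    of the permuted field maxima (|t| maxima for the two-tailed t).
    """
    if n_perm < 100:
        raise StatisticError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    S, C, N = design.data.shape
    if stat == "F":
        alpha = design.alpha
        n_distinct = float(math.factorial(C)) ** S
        maxima = np.empty(n_perm)
        data = design.data
        for p in range(n_perm):
            perm = np.argsort(rng.random((S, C)), axis=1)
            shuffled = data[np.arange(S)[:, None], perm, :]
            F, _, _, _ = rm_anova_field(shuffled)
            maxima[p] = np.nanmax(np.where(np.isfinite(F), F, np.nan))
    elif stat == "t":
        if pair is None:
            raise StatisticError("paired-t permutation needs a condition pair")
        alpha = design.alpha_posthoc
        idx = tuple(design.condition_names.index(c) for c in pair)
        d = design.data[:, idx[0], :] - design.data[:, idx[1], :]
        n_distinct = 2.0 ** S
        maxima = np.empty(n_perm)
        for p in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=S)[:, None]
            ds = signs * d
            mean = ds.mean(axis=0)
            sd = ds.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.abs(mean) / (sd / math.sqrt(S))
            maxima[p] = np.nanmax(np.where(np.isfinite(t), t, np.nan))
    else:
        raise ValueError(f"unknown statistic {stat!r}")
    if n_distinct < 1.0 / alpha:
        warnings.warn(
            f"only ~{n_distinct:.0f} distinct permutations; alpha={alpha} not resolvable",
            stacklevel=2,
        )
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    return PermutationResult(threshold=threshold, max_distribution=maxima,
                             n_perm=n_perm, alpha=alpha)
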