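"""Hypothesis tests used to compare response amplitudes, from first principles.

Three families cover the pipeline's designs:

* :func:`friedman_with_dunn` — within-animal comparison of response
  amplitudes across stimuli (non-normal imaging amplitudes): Friedman
  rank test with tie correction, Dunn's rank post hoc versus a control
  stimulus.
* :func:`rm_anova_gg_dunnett` — repeated-measures one-way ANOVA with the
  Greenhouse–Geisser sphericity correction (normally distributed data,
  e.g. spike rates), Dunnett's many-to-one comparisons versus the solvent
  control.
* :func:`kruskal_wallis_dunn` — between-receptor comparisons on
  independent samples (e.g. per-animal EC50 values): tie-corrected
  Kruskal–Wallis H with Dunn's pairwise post hoc.

All statistics are computed directly from the rank / sums-of-squares
formulas rather than delegated, so every intermediate (ranks, tie terms,
epsilon, critical probabilities) is inspectable.  For tiny tables the rank
tests also offer exact permutation p-values by full enumeration.  Dunn
post-hoc p-values are Bonferroni-adjusted by default (Holm optional);
Dunnett probabilities come from a deterministic quadrature over the
equicorrelated multivariate-t distribution.

Test selection is the caller's: normality screening (e.g. Shapiro–Wilk)
can be reported via :func:`normality_report` but never switches the test
automatically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import roots_hermitenorm, roots_legendre

__all__ = [
    "TestResult",
    "friedman_with_dunn",
    "rm_anova_gg_dunnett",
    "kruskal_wallis_dunn",
    "dunnett_sf",
    "normality_report",
]

_EXACT_LIMIT = 500_000  # max permutations enumerated for exact p-values


@dataclass
class TestResult:
    """Omnibus statistic plus optional post-hoc comparison table."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    epsilon: float | None = None  # Greenhouse-Geisser, where applicable
    method: str = "asymptotic"
    comparisons: pd.DataFrame | None = field(default=None)
    # comparisons columns: comparison, statistic, p_raw, p_adj

    def to_frame(self, family: str = "") -> pd.DataFrame:
        """Tidy export: one row per comparison (or one omnibus row)."""
        if self.comparisons is None:
            return pd.DataFrame(
                [{"family": family, "comparison": "omnibus", "statistic": self.statistic,
                  "p_raw": self.p_value, "p_adj": self.p_value}]
            )
        out = self.comparisons.copy()
        out.insert(0, "family", family)
        return out


def _adjust(p_raw: np.ndarray, how: str) -> np.ndarray:
    p_raw = np.asarray(p_raw, dtype=float)
    m = p_raw.size
    if how == "none":
        return p_raw.copy()
    if how == "bonferroni":
        return np.minimum(p_raw * m, 1.0)
    if how == "holm":
        order = np.argsort(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {how!r}")


# ---------------------------------------------------------------------------
# Friedman


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-robust Friedman chi-square from within-row ranks.

    chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A - C) with A = sum of
    squared ranks and C = n k (k+1)^2 / 4; reduces to the classical
    12/(nk(k+1)) form without ties.
    """
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    a = float((ranks**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    if a <= c:  # all rows completely tied
        return 0.0
    return float((k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum() / (a - c))


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(c) for c in matrix.columns]
    arr = np.asarray(matrix, dtype=float)
    return arr, [f"condition{j + 1}" for j in range(arr.shape[1])]


def friedman_with_dunn(
    matrix,
    control: str | int | None = None,
    method: str = "asymptotic",
    adjust: str = "bonferroni",
) -> TestResult:
    """Friedman test across stimuli with Dunn's post hoc versus a control.

    ``matrix`` is animals × stimuli (complete — missing cells are an
    error, never imputed).  ``method="exact"`` enumerates all within-row
    rank permutations (feasible for small tables only).  Post-hoc z uses
    the classical variance k(k+1)/(6n) on mean ranks.
    """
    data, labels = _as_matrix(matrix)
    if np.isnan(data).any():
        raise ValueError("matrix has missing cells; repeated-measures tests need complete data")
    n, k = data.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 stimuli")
    if n < 2:
        raise ValueError("Friedman test needs at least 2 animals")
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    stat = _friedman_statistic(ranks)

    if method == "asymptotic":
        p = float(sps.chi2.sf(stat, k - 1))
    elif method == "exact":
        total = math.factorial(k) ** n
        if total > _EXACT_LIMIT:
            raise ValueError(
                f"exact Friedman enumeration needs {total} permutations (> {_EXACT_LIMIT})"
            )
        count = 0
        perms = list(itertools.permutations(range(k)))
        for combo in itertools.product(perms, repeat=n):
            permuted = np.array([ranks[i, list(pi)] for i, pi in enumerate(combo)])
            if _friedman_statistic(permuted) >= stat - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")

    comparisons = None
    if control is not None:
        ci = labels.index(control) if isinstance(control, str) else int(control)
        mean_ranks = ranks.mean(axis=0)
        se = math.sqrt(k * (k + 1) / (6.0 * n))
        rows = []
        for j in range(k):
            if j == ci:
                continue
            z = (mean_ranks[j] - mean_ranks[ci]) / se
            rows.append((f"{labels[j]} vs {labels[ci]}", z, 2.0 * sps.norm.sf(abs(z))))
        comp = pd.DataFrame(rows, columns=["comparison", "statistic", "p_raw"])
        comp["p_adj"] = _adjust(comp["p_raw"].to_numpy(), adjust)
        comparisons = comp
    return TestResult(
        test="friedman", statistic=stat, df=k - 1, p_value=p, method=method, comparisons=comparisons
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _kw_statistic(values: np.ndarray, group_sizes: list[int]) -> float:
    """Tie-robust H: (N−1)·between-group rank SS / total rank SS."""
    ranks = sps.rankdata(values)
    grand = ranks.mean()
    total = float(((ranks - grand) ** 2).sum())
    if total == 0:
        return 0.0
    between = 0.0
    start = 0
    for n_i in group_sizes:
        r_i = ranks[start : start + n_i].mean()
        between += n_i * (r_i - grand) ** 2
        start += n_i
    return float((len(values) - 1) * between / total)


def kruskal_wallis_dunn(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    method: str = "asymptotic",
    adjust: str = "bonferroni",
) -> TestResult:
    """Kruskal–Wallis H over independent groups with Dunn's pairwise post hoc.

    ``method="exact"`` enumerates every assignment of the pooled values to
    groups of the observed sizes (small samples only).  Dunn z statistics
    use the tie-corrected variance N(N+1)/12 − Σ(t³−t)/(12(N−1)).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has n = {g.size} < 2")
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    big_n = pooled.size
    stat = _kw_statistic(pooled, sizes)
    k = len(groups)

    if method == "asymptotic":
        p = float(sps.chi2.sf(stat, k - 1))
    elif method == "exact":
        total = math.factorial(big_n)
        for n_i in sizes:
            total //= math.factorial(n_i)
        if total > _EXACT_LIMIT:
            raise ValueError(f"exact KW enumeration needs {total} assignments (> {_EXACT_LIMIT})")
        idx = list(range(big_n))
        count = hits = 0
        for assignment in _group_assignments(idx, sizes):
            arranged = pooled[np.concatenate(assignment)]
            if _kw_statistic(arranged, sizes) >= stat - 1e-12:
                hits += 1
            count += 1
        p = hits / count
    else:
        raise ValueError(f"unknown method {method!r}")

    # Dunn pairwise z on pooled mean ranks, tie-corrected variance
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (12.0 * (big_n - 1))
    sigma2 = big_n * (big_n + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start : start + n_i].mean())
        start += n_i
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(sigma2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append((f"{labels[i]} vs {labels[j]}", z, 2.0 * sps.norm.sf(abs(z))))
    comp = pd.DataFrame(rows, columns=["comparison", "statistic", "p_raw"])
    comp["p_adj"] = _adjust(comp["p_raw"].to_numpy(), adjust)
    return TestResult(
        test="kruskal-wallis", statistic=stat, df=k - 1, p_value=p, method=method, comparisons=comp
    )


def _group_assignments(indices: list[int], sizes: list[int]):
    """Yield all partitions of ``indices`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield [np.array(indices)]
        return
    first, rest = sizes[0], sizes[1:]
    for chosen in itertools.combinations(indices, first):
        remaining = [i for i in indices if i not in chosen]
        for tail in _group_assignments(remaining, rest):
            yield [np.array(chosen)] + tail


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser and Dunnett


def rm_anova_gg_dunnett(
    matrix,
    control: str | int | None = None,
) -> TestResult:
    """One-way repeated-measures ANOVA with Greenhouse–Geisser correction.

    ``matrix`` is animals × conditions (complete).  The F statistic uses
    the condition and condition×animal (error) sums of squares; the
    sphericity correction scales both degrees of freedom by the
    Greenhouse–Geisser epsilon estimated from the double-centered sample
    covariance of conditions.  With ``control`` set, Dunnett's many-to-one
    t statistics (pooled RM error variance, equicorrelation ½) give
    familywise-adjusted p-values.
    """
    data, labels = _as_matrix(matrix)
    if np.isnan(data).any():
        raise ValueError("matrix has missing cells; repeated-measures tests need complete data")
    n, k = data.shape
    if k < 3:
        raise ValueError("need at least 3 conditions")
    if n < 2:
        raise ValueError("need at least 2 animals")

    grand = data.mean()
    col_means = data.mean(axis=0)
    row_means = data.mean(axis=1)
    ss_cond = n * float(((col_means - grand) ** 2).sum())
    resid = data - col_means[None, :] - row_means[:, None] + grand
    ss_err = float((resid**2).sum())
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_err <= 1e-30:
        raise ValueError("zero within-animal variance; RM-ANOVA degenerate")
    ms_err = ss_err / df2
    f_stat = (ss_cond / df1) / ms_err

    # Greenhouse-Geisser epsilon from the double-centered covariance
    cov = np.cov(data, rowvar=False, ddof=1)
    centered = cov - cov.mean(axis=0)[None, :] - cov.mean(axis=1)[:, None] + cov.mean()
    tr = float(np.trace(centered))
    frob = float((centered**2).sum())
    eps = 1.0 / df1 if frob <= 0 else min(tr**2 / (df1 * frob), 1.0)
    p = float(sps.f.sf(f_stat, eps * df1, eps * df2))

    comparisons = None
    if control is not None:
        ci = labels.index(control) if isinstance(control, str) else int(control)
        se = math.sqrt(2.0 * ms_err / n)
        rows = []
        for j in range(k):
            if j == ci:
                continue
            t = (col_means[j] - col_means[ci]) / se
            p_adj = dunnett_sf(abs(t), m=k - 1, df=df2)
            rows.append((f"{labels[j]} vs {labels[ci]}", t, 2.0 * sps.t.sf(abs(t), df2), p_adj))
        comparisons = pd.DataFrame(rows, columns=["comparison", "statistic", "p_raw", "p_adj"])
        # multivariate adjustment can numerically undercut raw p at the tail
        comparisons["p_adj"] = np.maximum(comparisons["p_adj"], comparisons["p_raw"])
    return TestResult(
        test="rm-anova-gg",
        statistic=float(f_stat),
        df=(eps * df1, eps * df2),
        p_value=p,
        epsilon=float(eps),
        comparisons=comparisons,
    )


def dunnett_sf(t: float, m: int, df: int, rho: float = 0.5) -> float:
    """Two-sided familywise tail probability of Dunnett's test statistic.

    P(max_j |T_j| > t) for m equicorrelated (correlation ``rho``) Student-t
    comparisons sharing ``df`` error degrees of freedom — the many-to-one
    structure where each treatment is compared to the same control gives
    rho = 1/2 for balanced designs.  Evaluated by Gauss–Legendre quadrature
    over the shared chi scale and Gauss–Hermite quadrature over the shared
    normal factor; deterministic, accurate to well below 1e-4.
    """
    if t <= 0:
        return 1.0
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    # z0 ~ N(0,1): probabilists' Hermite nodes integrate against exp(-x^2/2)
    z_nodes, z_weights = roots_hermitenorm(96)
    z_weights = z_weights / math.sqrt(2.0 * math.pi)
    # w = chi_df / sqrt(df), integrated via its quantile function
    u_nodes, u_weights = roots_legendre(96)
    u = 0.5 * (u_nodes + 1.0)
    u_weights = 0.5 * u_weights
    w = sps.chi.ppf(u, df) / math.sqrt(df)

    sr, s1r = math.sqrt(rho), math.sqrt(1.0 - rho)
    tw = t * w[:, None]  # (nw, 1)
    z = z_nodes[None, :]  # (1, nz)
    upper = (tw - sr * z) / s1r
    lower = (-tw - sr * z) / s1r
    inner = (sps.norm.cdf(upper) - sps.norm.cdf(lower)) ** m
    prob_all_below = float(u_weights @ inner @ z_weights)
    return min(max(1.0 - prob_all_below, 0.0), 1.0)


def normality_report(samples: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro–Wilk screening per sample — reported, never used to switch tests."""
    rows = []
    for name, x in samples.items():
        stat, p = sps.shapiro(np.asarray(x, dtype=float))
        rows.append({"sample": name, "W": stat, "p": p, "normal_at_alpha": p >= alpha})
    return pd.DataFrame(rows)
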