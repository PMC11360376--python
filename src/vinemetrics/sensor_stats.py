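"""Sensor-agreement and group-comparison statistics.

The battery mirrors common practice for comparing a set of measurement
tools against a reference on the same plants:

* descriptives (min, max, mean, sample SD, CV%);
* Pearson correlation with its two-sided t-test (equivalently the OLS
  F-test of overall significance);
* model-II regression (OLS, major axis, standardized major axis) with
  95% confidence intervals, since both variables carry measurement
  error;
* paired RMSE between estimate and reference;
* distributional checks: Lilliefors-corrected Kolmogorov-Smirnov and
  Shapiro-Wilk normality tests, Levene's test (center = mean) for
  homogeneity of variance;
* Welch's heteroscedastic one-way ANOVA;
* Games-Howell pairwise post-hoc comparisons (Welch SEs, studentized
  range), with BCa bootstrap confidence intervals of each mean
  difference (default 1000 resamples, 95%) and a compact letter display.

Plain KS with estimated mean/sd is anticonservative, hence the
Lilliefors correction; users comparing against a naive KS test will see
smaller p-values here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors


class DegenerateInputError(ValueError):
    """Raised for empty, constant, or mismatched statistical input."""


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    min: float
    max: float
    mean: float
    sd: float  # sample SD (n - 1)
    cv_percent: float  # 100 * sd / mean; NaN when mean == 0


def descriptive(values: np.ndarray) -> DescriptiveStats:
    v = np.asarray(values, float)
    if v.size == 0:
        raise DegenerateInputError("descriptive: empty input")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
    mean = float(v.mean())
    cv = 100.0 * sd / mean if mean != 0 and np.isfinite(sd) else float("nan")
    return DescriptiveStats(
        n=v.size, min=float(v.min()), max=float(v.max()),
        mean=mean, sd=sd, cv_percent=cv,
    )


# ---------------------------------------------------------------------------
# correlation / regression / error
# ---------------------------------------------------------------------------


def pearson_with_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p (t-test with n - 2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("pearson: need equal lengths >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("pearson: zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class Model2Fit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]


@dataclass(frozen=True)
class AgreementResult:
    n: int
    r: float
    r_squared: float
    p_value: float  # OLS F-test of overall significance
    rmse_paired: float
    ols: Model2Fit
    ma: Model2Fit
    sma: Model2Fit


def rmse_paired(estimates: np.ndarray, references: np.ndarray) -> float:
    """sqrt(mean squared difference) between paired estimates and references."""
    e = np.asarray(estimates, float)
    r = np.asarray(references, float)
    if e.size != r.size or e.size == 0:
        raise DegenerateInputError("rmse: need equal non-empty lengths")
    return float(np.sqrt(np.mean((e - r) ** 2)))


def rmse_residual(x: np.ndarray, y: np.ndarray) -> float:
    """Residual RMSE of the OLS fit of y on x (the regression-based variant)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope, intercept = np.polyfit(x, y, 1)
    return float(np.sqrt(np.mean((y - slope * x - intercept) ** 2)))


def model2_regression(x: np.ndarray, y: np.ndarray, conf: float = 0.95):
    """OLS, major-axis and standardized-major-axis fits with CIs.

    All three lines pass through the centroid. SMA slope magnitude is
    sd_y / sd_x with the sign of r; the MA slope follows the leading
    eigenvector of the covariance matrix. Slope CIs use the standard
    closed forms; the overall p is the OLS F-test (identical to the
    Pearson t-test p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n != y.size or n < 3:
        raise DegenerateInputError("model2: need equal lengths >= 3")
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise DegenerateInputError("model2: zero variance")
    mx, my = float(x.mean()), float(y.mean())
    r, p = pearson_with_test(x, y)
    r2 = r * r
    tcrit = stats.t.ppf(0.5 + conf / 2, n - 2)

    # OLS
    b_ols = r * sy / sx
    se_b = math.sqrt(max(0.0, (sy**2 / sx**2 - b_ols**2) / (n - 2))) if n > 2 else float("nan")
    ols = _fit_through_centroid(b_ols, mx, my, (b_ols - tcrit * se_b,
                                               b_ols + tcrit * se_b))

    # SMA: slope magnitude sd_y/sd_x with sign of r; CI per the standard
    # closed form B = t^2 (1 - r^2) / (n - 2)
    b_sma = math.copysign(sy / sx, r if r != 0 else 1.0)
    B = tcrit**2 * (1.0 - r2) / (n - 2)
    lo = b_sma * (math.sqrt(B + 1) - math.sqrt(B))
    hi = b_sma * (math.sqrt(B + 1) + math.sqrt(B))
    sma = _fit_through_centroid(b_sma, mx, my, tuple(sorted((lo, hi))))

    # MA: leading eigenvector of the covariance matrix; CI by rotating the
    # axis by +/- atan(A), A^2 = H / (1 - H), H = t^2 l1 l2 / ((n-2)(l1-l2)^2)
    cov = np.cov(x, y, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    b_ma = math.inf if v[0] == 0 else float(v[1] / v[0])
    l1, l2 = float(max(evals)), float(min(evals))
    if l1 == l2:
        ci_ma = (-math.inf, math.inf)
    else:
        H = tcrit**2 * l1 * l2 / ((n - 2) * (l1 - l2) ** 2)
        if H >= 1:
            ci_ma = (-math.inf, math.inf)
        else:
            A = math.sqrt(H / (1 - H))
            th = math.atan(b_ma) if math.isfinite(b_ma) else math.pi / 2
            ci_ma = tuple(sorted((math.tan(th - math.atan(A)),
                                  math.tan(th + math.atan(A)))))
    ma = _fit_through_centroid(b_ma, mx, my, ci_ma)

    rmse = rmse_paired(x, y) if n else float("nan")
    return AgreementResult(
        n=n, r=r, r_squared=r2, p_value=p, rmse_paired=rmse,
        ols=ols, ma=ma, sma=sma,
    )


def _fit_through_centroid(slope, mx, my, slope_ci) -> Model2Fit:
    if math.isfinite(slope):
        intercept = my - slope * mx
    else:
        intercept = float("nan")
    ic = tuple(
        my - s * mx if math.isfinite(s) else float("nan") for s in slope_ci[::-1]
    )
    if all(math.isfinite(v) for v in ic):
        ic = tuple(sorted(ic))
    return Model2Fit(slope=float(slope), intercept=float(intercept),
                     slope_ci=tuple(float(s) for s in slope_ci),
                     intercept_ci=ic)


# ---------------------------------------------------------------------------
# distributional checks
# ---------------------------------------------------------------------------


def normality_tests(values: np.ndarray) -> dict[str, float]:
    """Lilliefors-corrected KS and Shapiro-Wilk p-values."""
    v = np.asarray(values, float)
    if v.size < 3:
        raise DegenerateInputError("normality: need n >= 3")
    if np.std(v) == 0:
        raise DegenerateInputError("normality: constant input")
    if v.size >= 4:  # Lilliefors small-sample table starts at n = 4
        ks_stat, ks_p = lilliefors(v, dist="norm", pvalmethod="table")
    else:
        ks_stat, ks_p = float("nan"), float("nan")
    sw_stat, sw_p = stats.shapiro(v)
    return {"ks_stat": float(ks_stat), "ks_p": float(ks_p),
            "sw_stat": float(sw_stat), "sw_p": float(sw_p)}


def levene_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classic Levene test (center = mean); W and p."""
    if len(groups) < 2:
        raise DegenerateInputError("levene: need >= 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise DegenerateInputError("levene: each group needs n >= 2")
    # degenerate spread pattern: identical absolute deviations everywhere
    # (includes all-observations-equal) -> no variance heterogeneity signal
    dev = np.concatenate([np.abs(a - a.mean()) for a in arrays])
    if np.ptp(dev) == 0:
        return 0.0, 1.0
    w, p = stats.levene(*arrays, center="mean")
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Welch ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    p: float


def welch_anova(groups: list[np.ndarray]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way F with Satterthwaite-type df."""
    arrays = [np.asarray(g, float) for g in groups]
    k = len(arrays)
    if k < 2 or any(a.size < 2 for a in arrays):
        raise DegenerateInputError("welch_anova: >= 2 groups of n >= 2")
    n = np.array([a.size for a in arrays], float)
    m = np.array([a.mean() for a in arrays])
    s2 = np.array([a.var(ddof=1) for a in arrays])
    if np.all(s2 == 0):
        if np.ptp(m) == 0:
            return WelchAnovaResult(0.0, k - 1.0, float("inf"), 1.0)
        return WelchAnovaResult(float("inf"), k - 1.0, float("inf"), 0.0)
    w = n / s2
    W = w.sum()
    gm = (w * m).sum() / W
    A = (w * (m - gm) ** 2).sum() / (k - 1)
    h = ((1 - w / W) ** 2 / (n - 1)).sum()
    B = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * h
    F = A / B
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3.0 * h)
    p = float(stats.f.sf(F, df1, df2))
    return WelchAnovaResult(float(F), df1, float(df2), p)


# ---------------------------------------------------------------------------
# Games-Howell + BCa + compact letters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean(a) - mean(b)
    se: float
    t: float
    df: float
    p_adjusted: float
    ci_low: float  # BCa bootstrap CI of the difference
    ci_high: float


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    normality: dict[str, dict[str, float]]
    levene_w: float
    levene_p: float
    welch: WelchAnovaResult
    pairwise: tuple[PairwiseComparison, ...]
    letters: dict[str, str]


def bca_ci(
    data: tuple[np.ndarray, ...],
    statistic,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int | np.random.Generator | None = None,
):
    """BCa bootstrap CI of a (possibly multi-sample) statistic.

    Degenerate resampling distributions (e.g. both groups constant)
    collapse to the point estimate. The interval always contains the
    point estimate for the statistics used here.
    """
    arrays = tuple(np.asarray(d, float) for d in data)
    theta = statistic(*arrays)
    if all(np.ptp(a) == 0 for a in arrays):
        return float(theta), float(theta)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    res = stats.bootstrap(
        arrays, statistic, n_resamples=n_boot,
        confidence_level=conf, method="BCa", vectorized=False,
        rng=rng,
    )
    lo, hi = res.confidence_interval
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return float(theta), float(theta)
    return float(lo), float(hi)


def games_howell(
    groups: dict[str, np.ndarray],
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> GroupComparison:
    """Games-Howell pairwise comparisons with BCa intervals and letters.

    For each pair: Welch standard error and degrees of freedom, the
    studentized-range adjusted p ``q = |diff| / se * sqrt(2)`` referred
    to the range distribution with k groups, plus a BCa bootstrap CI of
    the mean difference. The compact letter display is built from the
    adjusted-p matrix at ``alpha`` (groups sharing a letter are not
    significantly different), letters assigned from the highest group
    mean down.
    """
    names = list(groups)
    arrays = {g: np.asarray(groups[g], float) for g in names}
    k = len(names)
    if k < 2 or any(a.size < 2 for a in arrays.values()):
        raise DegenerateInputError("games_howell: >= 2 groups of n >= 2")

    normality = {}
    for g in names:
        try:
            normality[g] = normality_tests(arrays[g])
        except DegenerateInputError:
            normality[g] = {"ks_stat": float("nan"), "ks_p": float("nan"),
                            "sw_stat": float("nan"), "sw_p": float("nan")}
    lev_w, lev_p = levene_test(list(arrays.values()))
    welch = welch_anova(list(arrays.values()))

    rng = np.random.default_rng(seed)
    rows = []
    sig: dict[tuple[str, str], bool] = {}
    for ga, gb in itertools.combinations(names, 2):
        a, b = arrays[ga], arrays[gb]
        na, nb = a.size, b.size
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = math.sqrt(va / na + vb / nb)
        diff = float(a.mean() - b.mean())
        if se == 0:
            t = 0.0 if diff == 0 else float("inf")
            df = float(na + nb - 2)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = abs(diff) / se
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
            p = float(stats.studentized_range.sf(t * math.sqrt(2.0), k, df))
            p = min(max(p, 0.0), 1.0)
        lo, hi = bca_ci(
            (a, b), lambda xa, xb: np.mean(xa) - np.mean(xb),
            n_boot=n_boot, conf=conf, seed=rng,
        )
        rows.append(PairwiseComparison(ga, gb, diff, float(se), float(t),
                                       float(df), p, lo, hi))
        sig[(ga, gb)] = sig[(gb, ga)] = p < alpha

    letters = compact_letter_display(
        {g: float(arrays[g].mean()) for g in names}, sig
    )
    return GroupComparison(
        groups=tuple(names), normality=normality,
        levene_w=lev_w, levene_p=lev_p, welch=welch,
        pairwise=tuple(rows), letters=letters,
    )


def compact_letter_display(
    means: dict[str, float], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insertion-style compact letter display.

    Groups sharing a letter are not significantly different. Letters are
    assigned scanning groups by mean descending, so the highest-mean
    cluster reads "a".
    """
    names = sorted(means, key=lambda g: -means[g])

    def differs(a: str, b: str) -> bool:
        return significant.get((a, b), False)

    sets: list[set[str]] = []
    for g in names:
        placed = False
        for s in sets:
            if not any(differs(g, other) for other in s):
                s.add(g)
                placed = True
        if not placed:
            sets.append({g})
    # ensure every non-significant pair shares a set
    for a, b in itertools.combinations(names, 2):
        if differs(a, b):
            continue
        if not any(a in s and b in s for s in sets):
            new = {a, b}
            for g in names:
                if g in (a, b):
                    continue
                if not any(differs(g, member) for member in new):
                    new.add(g)
            sets.append(new)
    # absorb subsets
    sets = [s for s in sets
            if not any(s < t for t in sets)]
    # deterministic letter order: by best (highest-mean) member
    sets.sort(key=lambda s: min(names.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {g: [] for g in names}
    for letter, s in zip(alphabet, sets):
        for g in names:
            if g in s:
                out[g].append(letter)
    return {g: ",".join(out[g]) for g in names}


# ---------------------------------------------------------------------------
# matrix helpers for report tables
# ---------------------------------------------------------------------------


def correlation_matrix(columns: dict[str, np.ndarray]):
    """Pairwise Pearson r (and p) among named, equally-long value vectors."""
    import pandas as pd

    names = list(columns)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names,
                     columns=names)
    for a, b in itertools.combinations(names, 2):
        xa, xb = np.asarray(columns[a], float), np.asarray(columns[b], float)
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() >= 3 and np.std(xa[ok]) > 0 and np.std(xb[ok]) > 0:
            rv, pv = pearson_with_test(xa[ok], xb[ok])
        else:
            rv, pv = float("nan"), float("nan")
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    return r, p
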