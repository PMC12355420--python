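"""Kinetics and supporting statistics.

Covers the cycloheximide-chase decay fit (single-exponential protein
degradation, half-life = ln 2 / k), the Mendelian segregation chi-square for
fetal genotype tallies, qPCR standard-curve relative quantification, and thin
wrappers over the standard two-group / multi-group tests used throughout the
study (Student/Welch t, Holm, ANOVA/Tukey, Kruskal-Wallis/Mann-Whitney).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import DecayCourse, GenotypeCounts, logger

__all__ = [
    "DecayFit",
    "ChiSquareResult",
    "normalize_pre",
    "fit_decay",
    "remaining_fraction",
    "mendelian_chisq",
    "exact_multinomial_test",
    "StandardCurve",
    "standard_curve_quant",
    "compare_groups",
    "anova_tukey",
    "kruskal_mannwhitney",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# cycloheximide-chase decay
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    """Single-exponential decay fit: value(t) = intercept * exp(-rate_k * t)."""

    rate_k: float  # per hour
    half_life_h: float  # ln2 / rate_k; inf when the series does not decay
    intercept: float  # % at t = 0
    residual_sd: float
    fitted: pd.DataFrame  # time_h, observed, fitted
    method: str = "loglinear"

    @property
    def decaying(self) -> bool:
        return self.rate_k > 0


def normalize_pre(course: DecayCourse) -> DecayCourse:
    """Scale each replicate so its pre-chase (t = 0) value is 100 %."""
    df = course.data.copy()
    for rep, sub in df.groupby("replicate"):
        pre = sub.loc[sub["time_h"] == 0, "value"]
        if len(pre) == 0:
            raise ValueError(f"replicate {rep}: missing pre (t=0) point")
        if len(pre) > 1:
            raise ValueError(f"replicate {rep}: expected exactly one pre point, got {len(pre)}")
        scale = 100.0 / float(pre.iloc[0])
        df.loc[sub.index, "value"] = sub["value"] * scale
    return DecayCourse(data=df, series_id=course.series_id)


def fit_decay(course: DecayCourse, method: str = "loglinear") -> DecayFit:
    """Estimate the degradation rate from a chase time course.

    ``loglinear`` regresses log(value) on time by ordinary least squares
    (closed form, robust default); ``nonlinear`` fits value = 100 * exp(-k t)
    by least squares with the intercept pinned at the normalized pre value.
    A non-decaying series (k <= 0) is returned with half-life flagged
    infinite rather than raising.
    """
    df = course.data
    t = df["time_h"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("decay fit requires >= 3 distinct timepoints")

    if method == "loglinear":
        if np.any(y <= 0):
            raise ValueError("loglinear fit requires strictly positive values")
        slope, intercept_log = np.polyfit(t, np.log(y), 1)
        k = -float(slope)
        intercept = float(np.exp(intercept_log))
        fitted_vals = intercept * np.exp(-k * t)
    elif method == "nonlinear":
        def model(tt, k):
            return 100.0 * np.exp(-k * tt)

        k0 = 0.03
        (k,), _ = optimize.curve_fit(model, t, y, p0=[k0], maxfev=10000)
        k = float(k)
        intercept = 100.0
        fitted_vals = model(t, k)
    else:
        raise ValueError(f"unknown decay method {method!r}")

    resid = y - fitted_vals
    residual_sd = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    half_life = LN2 / k if k > 0 else float("inf")
    if not k > 0:
        logger.warning("series %s does not decay (k=%.4g); half-life flagged infinite", course.series_id, k)
    return DecayFit(
        rate_k=k,
        half_life_h=half_life,
        intercept=intercept,
        residual_sd=residual_sd,
        fitted=pd.DataFrame({"time_h": t, "observed": y, "fitted": fitted_vals}),
        method=method,
    )


def remaining_fraction(fit: DecayFit, t: float) -> float:
    """Percent of protein remaining at time t hours: 100 * exp(-k t)."""
    return 100.0 * math.exp(-fit.rate_k * t)


# ---------------------------------------------------------------------------
# Mendelian segregation chi-square
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected_counts: tuple[float, float, float]


def mendelian_chisq(
    counts: GenotypeCounts, ratio: Sequence[float] = (1.0, 2.0, 1.0)
) -> ChiSquareResult:
    """Pearson goodness-of-fit of a genotype tally against a Mendelian ratio.

    Expected counts are total * ratio / sum(ratio); the statistic is
    sum((obs - exp)^2 / exp) on df = 2, no continuity correction.  At df 2
    the survival function has the closed form p = exp(-chi2 / 2).
    """
    r = np.asarray(ratio, dtype=float)
    if r.size != 3 or np.any(r <= 0):
        raise ValueError("ratio must be three positive numbers")
    obs = counts.as_array()
    expected = counts.total * r / r.sum()
    if np.any(expected == 0):
        raise ValueError("expected count of zero")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    return ChiSquareResult(chi2=chi2, df=2, p=p, expected_counts=tuple(expected))


def exact_multinomial_test(
    counts: GenotypeCounts, ratio: Sequence[float] = (1.0, 2.0, 1.0)
) -> float:
    """Exact multinomial goodness-of-fit p-value (sensitivity alternative).

    Enumerates all outcomes of n draws into 3 classes and sums the null
    probability of every outcome at least as extreme (by chi-square ordering)
    as the observed one.  Feasible for the litter-scale n used here.
    """
    r = np.asarray(ratio, dtype=float)
    probs = r / r.sum()
    n = counts.total
    obs_chi2 = mendelian_chisq(counts, ratio).chi2
    p_total = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            c = n - a - b
            exp = n * probs
            chi2 = ((a - exp[0]) ** 2 / exp[0] + (b - exp[1]) ** 2 / exp[1] + (c - exp[2]) ** 2 / exp[2])
            if chi2 >= obs_chi2 - 1e-12:
                p_total += math.exp(
                    stats.multinomial.logpmf([a, b, c], n=n, p=probs)
                )
    return min(1.0, p_total)


# ---------------------------------------------------------------------------
# qPCR standard-curve quantification
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    slope: float  # Ct per log10(quantity)
    intercept: float  # Ct at quantity 1
    efficiency: float  # 10^(-1/slope) - 1; 1.0 for a perfect 2x series
    r_squared: float

    def quantify(self, ct: float | Sequence[float]) -> np.ndarray | float:
        """Invert Ct through the fitted line to a relative quantity."""
        ct_arr = np.asarray(ct, dtype=float)
        q = 10.0 ** ((ct_arr - self.intercept) / self.slope)
        return float(q) if np.isscalar(ct) or ct_arr.ndim == 0 else q


def standard_curve_quant(
    standards: Sequence[tuple[float, float]],
    unknowns: Sequence[float] | None = None,
) -> tuple[StandardCurve, np.ndarray]:
    """Fit Ct on log10(relative quantity) and invert unknown Cts.

    ``standards`` are (relative quantity, Ct) pairs from a serial dilution of
    the reference sample; the amplification efficiency implied by the slope
    is reported (100 % corresponds to Ct increasing by log2(10) ~ 3.32 per
    10-fold dilution).  Non-monotone standards get a warning but are still
    fitted.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need >= 3 standard points")
    qty, ct = pts[:, 0], pts[:, 1]
    if len(np.unique(qty)) < 2:
        raise ValueError("standards must span >= 2 dilutions")
    order = np.argsort(qty)
    if not np.all(np.diff(ct[order]) <= 0):
        logger.warning("standard-curve Cts are not monotone in quantity; fitting anyway")
    logq = np.log10(qty)
    slope, intercept = np.polyfit(logq, ct, 1)
    pred = slope * logq + intercept
    ss_res = float(((ct - pred) ** 2).sum())
    ss_tot = float(((ct - ct.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    curve = StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        efficiency=float(10.0 ** (-1.0 / slope) - 1.0),
        r_squared=r2,
    )
    quants = curve.quantify(np.asarray(unknowns, dtype=float)) if unknowns is not None else np.array([])
    return curve, np.atleast_1d(quants)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "student",
    adjust: str = "none",
    families: Sequence[tuple[Sequence[float], Sequence[float]]] | None = None,
) -> dict:
    """Two-group comparison as used throughout the study.

    ``student`` / ``welch`` are two-sided; ``student_one_sided`` tests the
    alternative mean(a) > mean(b).  With ``adjust='holm'`` and a declared
    ``families`` list of additional (a, b) pairs, Holm-adjusted p-values are
    returned for the whole family (the queried pair first).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")

    def one(x, y):
        if np.array_equal(x, y) and np.ptp(x) == 0:
            return 0.0, 1.0  # degenerate equal-constant groups
        if test == "student":
            t, p = stats.ttest_ind(x, y, equal_var=True)
        elif test == "welch":
            t, p = stats.ttest_ind(x, y, equal_var=False)
        elif test == "student_one_sided":
            t, p = stats.ttest_ind(x, y, equal_var=True, alternative="greater")
        else:
            raise ValueError(f"unknown test {test!r}")
        return float(t), float(p)

    t_stat, p = one(a, b)
    result = {"t": t_stat, "p": p, "test": test}
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        pvals = [p] + [one(np.asarray(x, float), np.asarray(y, float))[1] for x, y in (families or [])]
        adj = multipletests(pvals, method="holm")[1]
        result["p_adjusted"] = float(adj[0])
        result["family_p_adjusted"] = [float(v) for v in adj]
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return result


def anova_tukey(groups: dict[str, Sequence[float]]) -> dict:
    """One-way ANOVA with Tukey HSD pairwise follow-up (pass-through)."""
    names = list(groups)
    arrays = [np.asarray(groups[n], float) for n in names]
    f_stat, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = {
        (names[i], names[j]): float(tukey.pvalue[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    return {"F": float(f_stat), "p": float(p), "tukey": pairwise}


def kruskal_mannwhitney(groups: dict[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis with Holm-adjusted pairwise Mann-Whitney follow-up."""
    from statsmodels.stats.multitest import multipletests

    names = list(groups)
    arrays = [np.asarray(groups[n], float) for n in names]
    h_stat, p = stats.kruskal(*arrays)
    pairs, pvals = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            _, pw = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            pairs.append((names[i], names[j]))
            pvals.append(pw)
    adj = multipletests(pvals, method="holm")[1] if pvals else []
    return {"H": float(h_stat), "p": float(p), "pairwise_holm": dict(zip(pairs, map(float, adj)))}
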