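"""Group statistics over delta-summary tables.

Mirrors a common two-track analysis of immunohistochemistry group data: the
(approximately normal) neuronal-loss signal is analysed with factorial ANOVA
followed by Bonferroni-corrected pairwise t-tests, while the skewed glial
signals and the tissue-reaction index use Kruskal–Wallis tests with Dunn
post-hocs.  The sampling unit throughout is the individual ROI image
(shank x region); ANOVA uses type-II sums of squares, appropriate for the
unbalanced main-effects designs that arise here, and rank tests always apply
the tie correction because downsampled intensities produce ties.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

CORTICAL_REGIONS = ("upper_cortex", "lower_cortex")


@dataclass
class TestResult:
    """One test statistic with raw and multiplicity-adjusted p values."""

    comparison: str
    statistic: str  # F | chi2 | t | z | beta | H
    value: float
    df: float | tuple | None
    n: int
    p_raw: float
    p_adj: float | None = None

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "statistic": self.statistic,
            "value": self.value,
            "df": self.df,
            "n": self.n,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
        }


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p value: min(1, p * m)."""
    return min(1.0, p * m)


def factorial_anova(
    table: pd.DataFrame,
    value: str = "delta_neun",
    factors: tuple[str, ...] = ("material", "tether", "width_um", "region"),
    interactions: tuple[tuple[str, str], ...] = (),
    typ: int = 2,
) -> list[TestResult]:
    """Between-factors ANOVA of one delta signal (type-II sums of squares).

    Factors with fewer than two observed levels are dropped with a warning;
    an interaction whose design cells are not all populated is dropped too.
    """
    df = table.dropna(subset=[value]).copy()
    degenerate = np.ptp(df[value].to_numpy(float)) == 0
    terms = []
    kept_factors = []
    for f in factors:
        if df[f].nunique() < 2:
            warnings.warn(f"factor {f!r} has <2 levels; dropped", stacklevel=2)
            continue
        kept_factors.append(f)
        terms.append(f"C(Q('{f}'))")
    if not terms:
        raise ValueError("no usable factors")
    for a, b in interactions:
        if a not in kept_factors or b not in kept_factors:
            continue
        cells = df.groupby([a, b], observed=True).size()
        full = df[a].nunique() * df[b].nunique()
        if len(cells) < full or (cells < 2).any():
            warnings.warn(f"empty/thin cells for {a}x{b}; interaction dropped", stacklevel=2)
            continue
        terms.append(f"C(Q('{a}')):C(Q('{b}'))")
    formula = f"Q('{value}') ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate all-equal data yields 0/0 F
        aov = anova_lm(model, typ=typ)
    out = []
    for term, row in aov.iterrows():
        if term == "Residual":
            continue
        label = (
            term.replace("C(Q('", "").replace("'))", "").replace(":", " x ")
        )
        fval = float(row["F"])
        p = float(row["PR(>F)"])
        if degenerate or not np.isfinite(fval):
            # a constant response carries no group information; the raw F is
            # rounding noise on zero sums of squares
            fval, p = 0.0, 1.0
        out.append(
            TestResult(
                comparison=label,
                statistic="F",
                value=fval,
                df=(float(row["df"]), float(aov.loc["Residual", "df"])),
                n=len(df),
                p_raw=p,
            )
        )
    return out


def posthoc_ttests(
    table: pd.DataFrame,
    value: str,
    factor: str,
    comparisons: list[tuple] | None = None,
    correction: str = "bonferroni",
) -> list[TestResult]:
    """Pairwise two-sample t-tests between factor levels, Bonferroni-corrected."""
    df = table.dropna(subset=[value])
    levels = sorted(df[factor].unique())
    if comparisons is None:
        comparisons = list(itertools.combinations(levels, 2))
    m = len(comparisons)
    out = []
    for a, b in comparisons:
        xa = df.loc[df[factor] == a, value].to_numpy(float)
        xb = df.loc[df[factor] == b, value].to_numpy(float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group {a!r} or {b!r} has fewer than 2 observations")
        if np.ptp(np.concatenate([xa, xb])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=True)
        out.append(
            TestResult(
                comparison=f"{a} vs {b}",
                statistic="t",
                value=float(t),
                df=len(xa) + len(xb) - 2,
                n=len(xa) + len(xb),
                p_raw=float(p),
                p_adj=bonferroni(float(p), m) if correction == "bonferroni" else float(p),
            )
        )
    return out


def paired_ttest(
    a: np.ndarray, b: np.ndarray, label: str = "top vs bottom half"
) -> TestResult:
    """Paired two-sided t-test, e.g. of per-image top vs bottom half-ROI means."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diff = a - b
    if np.ptp(diff) == 0:
        t, p = (0.0, 1.0) if diff[0] == 0 else (np.inf * np.sign(diff[0]), 0.0)
    else:
        t, p = sps.ttest_rel(a, b)
    return TestResult(label, "t", float(t), a.size - 1, a.size, float(p))


def kruskal_wallis(groups: list[np.ndarray], label: str = "group effect") -> TestResult:
    """Kruskal–Wallis H test (tie-corrected) against the chi-square reference."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    n = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all observations tied
        return TestResult(label, "H", 0.0, len(groups) - 1, n, 1.0)
    h, p = sps.kruskal(*groups)
    return TestResult(label, "H", float(h), len(groups) - 1, n, float(p))


def dunn_test(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    correction: str = "bonferroni",
) -> list[TestResult]:
    """Pairwise Dunn post-hoc tests on the pooled ranks of all groups.

    For groups i, j with mean pooled ranks Ri, Rj over N total observations::

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))
        T = sum(t^3 - t) / (12 (N - 1))   over tie groups of size t

    Two-sided normal p values, Bonferroni-adjusted over all pairs.  Singleton
    groups are allowed but flagged with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    if any(len(g) == 1 for g in groups):
        warnings.warn("singleton group in Dunn test", stacklevel=2)
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        out.append(
            TestResult(
                comparison=f"{labels[i]} vs {labels[j]}",
                statistic="z",
                value=float(z),
                df=None,
                n=sizes[i] + sizes[j],
                p_raw=float(p),
                p_adj=bonferroni(float(p), m) if correction == "bonferroni" else float(p),
            )
        )
    return out


def cross_section_regression(
    table: pd.DataFrame, value: str = "idx_tissue_reaction"
) -> tuple[list[TestResult], sm.regression.linear_model.RegressionResultsWrapper]:
    """OLS of the tissue-reaction index on material, tether, region and shank
    cross-section, restricted to the cortical ROIs (white matter excluded).

    Returns per-coefficient t tests plus the fitted statsmodels results.
    Perfectly aliased predictors are reported and dropped by the fit.
    """
    df = table[table["region"].isin(CORTICAL_REGIONS)].dropna(
        subset=[value, "cross_section_um2"]
    )
    formula = (
        f"Q('{value}') ~ C(material) + C(tether) + C(region) + cross_section_um2"
    )
    fit = smf.ols(formula, data=df).fit()
    out = []
    for name in fit.params.index:
        if name == "Intercept":
            continue
        out.append(
            TestResult(
                comparison=name,
                statistic="beta",
                value=float(fit.params[name]),
                df=float(fit.df_resid),
                n=int(fit.nobs),
                p_raw=float(fit.pvalues[name]),
            )
        )
    return out, fit


def useful_fraction_trend(
    weekly: pd.DataFrame,
    value: str = "pct_useful",
    group: str = "material",
) -> dict[str, TestResult]:
    """Per-material OLS slope of the percentage of useful electrodes on week.

    ``weekly`` needs columns [group, 'week', value] with >= 3 time points per
    group.  Returns the slope (percentage points per week) with its t test.
    """
    out: dict[str, TestResult] = {}
    for mat, sub in weekly.groupby(group):
        if sub["week"].nunique() < 3:
            raise ValueError(f"group {mat!r} has <3 time points")
        fit = smf.ols(f"Q('{value}') ~ week", data=sub).fit()
        out[mat] = TestResult(
            comparison=f"{mat}: {value} ~ week",
            statistic="beta",
            value=float(fit.params["week"]),
            df=float(fit.df_resid),
            n=int(fit.nobs),
            p_raw=float(fit.pvalues["week"]),
        )
    return out
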