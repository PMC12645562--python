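"""Group-comparison decision tree, robust outlier exclusion and qPCR quantification.

The procedure is a deterministic, auditable implementation of a common
experimental-biology testing protocol:

1. Univariate outlier exclusion by a simplified ROUT (robust location = median,
   robust scale = MAD-based, candidates flagged by false-discovery-rate control
   at Q on two-sided t-tail probabilities of the robust residuals).
2. Shapiro-Wilk normality per group (alpha 0.05). All normal -> parametric
   branch; otherwise natural-log transform and retest -> log-parametric branch;
   still non-normal (or non-positive values) -> nonparametric branch.
3. Within the parametric branches, Levene's test on medians (alpha 0.05)
   selects equal-variance (ANOVA + Tukey, or pooled Student t) versus
   unequal-variance machinery (Welch ANOVA + Dunnett T3-style pairwise Welch
   tests, or Welch t). The nonparametric branch uses Kruskal-Wallis + Dunn
   (or Mann-Whitney for two groups).

Every result carries a full audit trail: tests run, p-values, the path taken,
and the points excluded with reasons. The tree is a pure function of the data.

The qPCR helper implements relative quantification by 2^-ddCt against the
geometric mean of two housekeeping genes (on the expression scale the
geometric mean corresponds to the arithmetic mean of the Ct values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .isotope import DataError, ParameterError

ALPHA_NORMALITY = 0.05
ALPHA_VARIANCE = 0.05


@dataclass
class GroupComparisonResult:
    """Chosen test path, statistics and adjusted pairwise p-values for one endpoint."""

    endpoint: str
    path: str                       # parametric | log-parametric | nonparametric
    transformation: str             # none | log
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    posthoc_method: str
    pairwise: dict[tuple[str, str], float]
    excluded: list[tuple[str, float, str]]   # (group, value, reason)
    audit: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Simplified ROUT outlier exclusion
# ---------------------------------------------------------------------------

def rout_outliers(sample: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Flag univariate outliers by a simplified ROUT procedure at FDR Q = ``q``.

    Robust location is the median and robust scale the normal-consistent,
    finite-sample-corrected MAD (the RSDR). Each point's absolute robust
    residual is converted to a two-sided t-tail probability (at the MAD's
    equivalent degrees of freedom, ~0.37*(n-1), reflecting the scale
    estimate's own uncertainty) and the Benjamini-Hochberg step-up rule at Q
    flags the outliers. Samples with fewer than 3 points are never pruned.
    This is a stated approximation of the original robust-regression ROUT,
    reduced to the one-sample case.
    """
    if not 0 < q <= 0.1:
        raise ParameterError(f"q must lie in (0, 0.1], got {q}")
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise DataError("empty sample")
    flags = np.zeros(x.size, dtype=bool)
    if x.size < 3:
        return flags
    center = np.median(x)
    mad = np.median(np.abs(x - center))
    if mad == 0:
        # more than half the sample is identical; any distinct point is suspect
        # only if the sample is otherwise degenerate — leave unflagged
        return flags
    # finite-sample unbiasedness correction for the normal-consistent MAD
    # (Williams 2011); without it small samples over-flag
    n = x.size
    small_n_factor = {3: 1.196, 4: 1.363, 5: 1.206, 6: 1.200, 7: 1.140, 8: 1.129, 9: 1.107}
    b_n = small_n_factor.get(n, n / (n - 0.8))
    scale = 1.4826 * b_n * mad
    t = np.abs(x - center) / scale
    # the MAD scale estimate has ~37% asymptotic efficiency, so the robust
    # residual ratio is heavier-tailed than t(n-1); use the MAD's equivalent
    # degrees of freedom to keep the FDR honest on clean samples
    df = max(1.0, 0.37 * (n - 1))
    p = 2.0 * sps.t.sf(t, df=df)
    order = np.argsort(p)
    # Benjamini-Hochberg step-up on the ranked tail probabilities
    threshold_rank = -1
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / n:
            threshold_rank = rank
    if threshold_rank > 0:
        flags[order[:threshold_rank]] = True
    return flags


# ---------------------------------------------------------------------------
# Post hoc helpers
# ---------------------------------------------------------------------------

def _tukey(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    labels = list(groups)
    res = sps.tukey_hsd(*(groups[g] for g in labels))
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[(labels[i], labels[j])] = float(res.pvalue[i, j])
    return out


def _dunnett_t3(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunnett T3-style all-pairs comparison for unequal variances.

    Pairwise Welch t statistics with Sidak adjustment over the number of
    comparisons — a close approximation of the studentized-maximum-modulus
    criterion the exact T3 uses.
    """
    labels = list(groups)
    m = len(labels) * (len(labels) - 1) // 2
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            _, p = sps.ttest_ind(groups[labels[i]], groups[labels[j]], equal_var=False)
            out[(labels[i], labels[j])] = float(min(1.0, 1.0 - (1.0 - p) ** m))
    return out


def _dunn(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's test: pairwise mean-rank z statistics with Bonferroni adjustment."""
    labels = list(groups)
    values = np.concatenate([groups[g] for g in labels])
    which = np.concatenate([np.full(groups[g].size, i) for i, g in enumerate(labels)])
    ranks = sps.rankdata(values)
    n = values.size
    # tie correction for the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
    mean_ranks = [ranks[which == i].mean() for i in range(len(labels))]
    sizes = [int((which == i).sum()) for i in range(len(labels))]
    m = len(labels) * (len(labels) - 1) // 2
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(z)
            out[(labels[i], labels[j])] = float(min(1.0, p * m))
    return out


# ---------------------------------------------------------------------------
# The decision tree
# ---------------------------------------------------------------------------

def _all_normal(groups: dict[str, np.ndarray], audit: list[str], label: str) -> bool:
    normal = True
    for g, x in groups.items():
        _, p = sps.shapiro(x)
        audit.append(f"shapiro[{label}] {g}: p={p:.4g}")
        normal &= p > ALPHA_NORMALITY
    return normal


def select_and_compare(
    groups: dict[str, "np.ndarray | list[float]"],
    endpoint: str = "endpoint",
    q_outlier: float = 0.01,
    exclude_outliers: bool = True,
) -> GroupComparisonResult:
    """Run the full decision tree on ``groups`` (label -> values).

    Outlier exclusion (simplified ROUT at Q = ``q_outlier``) is applied per
    group before any testing; excluded points are listed in the result. The
    design (two-group versus one-way multi-group) follows from the number of
    groups. Groups with fewer than 3 retained points make the comparison
    refuse with a diagnostic rather than silently proceed.
    """
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    audit: list[str] = []
    excluded: list[tuple[str, float, str]] = []
    clean: dict[str, np.ndarray] = {}
    for g, values in groups.items():
        x = np.asarray(values, dtype=float)
        if exclude_outliers:
            flags = rout_outliers(x, q=q_outlier)
            for v in x[flags]:
                excluded.append((g, float(v), f"ROUT q={q_outlier}"))
            x = x[~flags]
        clean[g] = x
        if x.size < 3:
            raise DataError(
                f"group '{g}' has n={x.size} after exclusion; need >= 3 for the tree"
            )

    two_group = len(clean) == 2

    # --- branch selection -------------------------------------------------
    transformation = "none"
    if _all_normal(clean, audit, "raw"):
        path = "parametric"
        test_groups = clean
    else:
        positive = all(np.all(x > 0) for x in clean.values())
        if positive:
            logged = {g: np.log(x) for g, x in clean.items()}
            if _all_normal(logged, audit, "log"):
                path = "log-parametric"
                transformation = "log"
                test_groups = logged
            else:
                path = "nonparametric"
                test_groups = clean
        else:
            audit.append("log branch blocked: non-positive values present")
            path = "nonparametric"
            test_groups = clean

    # --- testing ----------------------------------------------------------
    labels = list(test_groups)
    if path in ("parametric", "log-parametric"):
        _, p_lev = sps.levene(*test_groups.values(), center="median")
        audit.append(f"levene(median): p={p_lev:.4g}")
        equal_var = p_lev > ALPHA_VARIANCE
        if two_group:
            stat, p = sps.ttest_ind(*test_groups.values(), equal_var=equal_var)
            omnibus = "student-t" if equal_var else "welch-t"
            posthoc = omnibus
            pairwise = {(labels[0], labels[1]): float(p)}
        elif equal_var:
            stat, p = sps.f_oneway(*test_groups.values())
            omnibus, posthoc = "one-way ANOVA", "Tukey"
            pairwise = _tukey(test_groups)
        else:
            import pingouin as pg

            long = pd.DataFrame({
                "value": np.concatenate(list(test_groups.values())),
                "group": np.concatenate(
                    [np.full(x.size, g) for g, x in test_groups.items()]
                ),
            })
            welch = pg.welch_anova(data=long, dv="value", between="group")
            p_col = "p_unc" if "p_unc" in welch.columns else "p-unc"
            stat, p = float(welch["F"].iloc[0]), float(welch[p_col].iloc[0])
            omnibus, posthoc = "Welch ANOVA", "Dunnett-T3"
            pairwise = _dunnett_t3(test_groups)
    else:
        if two_group:
            stat, p = sps.mannwhitneyu(*test_groups.values(), alternative="two-sided")
            omnibus = posthoc = "Mann-Whitney"
            pairwise = {(labels[0], labels[1]): float(p)}
        else:
            stat, p = sps.kruskal(*test_groups.values())
            omnibus, posthoc = "Kruskal-Wallis", "Dunn"
            pairwise = _dunn(test_groups)
    audit.append(f"path={path}, omnibus={omnibus}: stat={float(stat):.4g}, p={float(p):.4g}")

    return GroupComparisonResult(
        endpoint=endpoint,
        path=path,
        transformation=transformation,
        omnibus_test=omnibus,
        omnibus_statistic=float(stat),
        omnibus_p=float(p),
        posthoc_method=posthoc,
        pairwise=pairwise,
        excluded=excluded,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# Tolerance-curve comparison
# ---------------------------------------------------------------------------

def compare_curves(curves: list) -> GroupComparisonResult:
    """Two-way (group x time) ANOVA on tolerance curves with per-time Tukey contrasts.

    All curves must share a common time grid; group main effect and the
    group-by-time interaction come from an ordinary two-way ANOVA on the long
    table, and pairwise group contrasts are Tukey tests within each time
    point (reported as ``(group_i@t, group_j@t)``).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    by_group: dict[str, list] = {}
    for c in curves:
        by_group.setdefault(c.group, []).append(c)
    if len(by_group) < 2:
        raise ParameterError("need curves from at least 2 groups")
    grids = {tuple(c.times) for c in curves}
    if len(grids) != 1:
        raise DataError("curves do not share a common time grid")
    times = curves[0].times

    long = pd.DataFrame({
        "lactate": np.concatenate([c.lactate for c in curves]),
        "time": np.concatenate([c.times for c in curves]),
        "group": np.concatenate([np.full(c.times.size, c.group) for c in curves]),
    })
    model = smf.ols("lactate ~ C(group) * C(time)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    stat = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    audit = [
        f"two-way ANOVA group: F={stat:.4g}, p={p:.4g}",
        f"interaction group:time: p={float(table.loc['C(group):C(time)', 'PR(>F)']):.4g}",
    ]

    labels = sorted(by_group)
    pairwise: dict[tuple[str, str], float] = {}
    for t in times:
        at_t = {
            g: np.array([c.lactate[np.where(c.times == t)[0][0]] for c in by_group[g]])
            for g in labels
        }
        res = sps.tukey_hsd(*(at_t[g] for g in labels))
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                pairwise[(f"{labels[i]}@{t:g}", f"{labels[j]}@{t:g}")] = float(
                    res.pvalue[i, j]
                )

    return GroupComparisonResult(
        endpoint="lactate tolerance curve",
        path="parametric",
        transformation="none",
        omnibus_test="two-way ANOVA (group)",
        omnibus_statistic=stat,
        omnibus_p=p,
        posthoc_method="Tukey per time point",
        pairwise=pairwise,
        excluded=[],
        audit=audit,
    )


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def ddct(
    ct_target_treated: float,
    ct_target_control: float,
    ct_hk_treated: tuple[float, float],
    ct_hk_control: tuple[float, float],
) -> float:
    """Fold change by the 2^-ddCt method against two housekeeping genes.

    The reference Ct per condition is the arithmetic mean of the two
    housekeeping Cts — equivalent to normalizing to the geometric mean of the
    housekeeping expression levels, since expression is 2^-Ct.
    """
    cts = (ct_target_treated, ct_target_control, *ct_hk_treated, *ct_hk_control)
    if any(c is None or not np.isfinite(c) for c in cts):
        raise DataError("missing Ct value")
    if any(c <= 0 for c in cts):
        raise DataError("Ct values must be > 0")
    dct_treated = ct_target_treated - (ct_hk_treated[0] + ct_hk_treated[1]) / 2.0
    dct_control = ct_target_control - (ct_hk_control[0] + ct_hk_control[1]) / 2.0
    return float(2.0 ** (-(dct_treated - dct_control)))
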