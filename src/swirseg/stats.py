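"""Detection rates and group comparisons for the lesion-detection study.

The study design is paired: every proximal contact contributes two lesion
surfaces (the restored tooth and the opposing tooth), each examined by every
method.  This module aggregates the per-surface calls into detection rates,
compares rates against radiography with Fisher's exact test, and compares
lesion contrast / lesion depth across methods with a one-way
repeated-measures ANOVA (subject = contact-surface) after complete-case
removal, followed by Tukey-style pairwise comparisons on the repeated-
measures error term and a compact letter display (methods sharing a letter
are statistically similar at the chosen alpha).

A mixed-effects model (random intercept per subject), which tolerates
missing values, is available as an independent cross-check of the
repeated-measures results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Canonical method order (Table-style reporting).
METHODS = [
    "radiograph",
    "oct",
    "visual_before",
    "visual_after",
    "swir_r",
    "swir_ot",
    "swir_pt",
]
SURFACES = ["restored", "opposing"]
DEFAULT_ALPHA = 0.05

#: Long-format detection table columns.
TABLE_COLUMNS = ["contact_id", "surface", "method", "detected", "contrast", "depth_um"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.005 -> 0.01), as tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RateSummary:
    method: str
    group: str  # "all", "restored", or "opposing"
    n: int
    k_detected: int
    rate: float


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(["contact_id", "surface", "method", "detected"]) - set(table.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty detection table")
    return table


def detection_rates(table: pd.DataFrame) -> list[RateSummary]:
    """Per-method detection rates for all surfaces and per surface group.

    Missing calls are excluded from both numerator and denominator; rates
    are rounded half-up to two decimals for report parity.
    """
    table = _validate_table(table)
    out: list[RateSummary] = []
    groups = [("all", table)] + [
        (s, table[table["surface"] == s]) for s in SURFACES if (table["surface"] == s).any()
    ]
    methods = [m for m in METHODS if m in set(table["method"])]
    methods += [m for m in table["method"].unique() if m not in methods]
    for method in methods:
        for name, sub in groups:
            calls = sub.loc[sub["method"] == method, "detected"].dropna()
            n = int(len(calls))
            if n == 0:
                continue
            k = int(calls.astype(bool).sum())
            out.append(
                RateSummary(method, name, n, k, round_half_up(k / n, 2))
            )
    return out


def rates_frame(table: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in detection_rates(table)])


def fisher_exact(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for detection counts k1/n1 vs k2/n2.

    Two-sided in the standard conditional sense: the sum of probabilities of
    all 2x2 tables with the observed margins whose hypergeometric
    probability does not exceed that of the observed table.
    """
    for v in (k1, n1, k2, n2):
        if int(v) != v or v < 0:
            raise ValueError("counts must be non-negative integers")
    if k1 > n1 or k2 > n2:
        raise ValueError("detected count exceeds group size")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=int)
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def complete_cases(
    table: pd.DataFrame, measure: str, methods: Sequence[str]
) -> pd.DataFrame:
    """Wide subject-by-method matrix after complete-case removal.

    Subjects are (contact_id, surface) pairs; any subject missing ``measure``
    for any of ``methods`` is dropped entirely.
    """
    if measure not in ("contrast", "depth_um"):
        raise ValueError(f"unknown measure {measure!r}")
    sub = table[table["method"].isin(methods)]
    wide = sub.pivot_table(
        index=["contact_id", "surface"], columns="method", values=measure, aggfunc="first"
    )
    wide = wide.reindex(columns=list(methods)).dropna(axis=0, how="any")
    return wide


@dataclass
class RmAnovaResult:
    methods: list[str]
    n: int
    means: np.ndarray
    f_stat: float
    df_effect: int
    df_error: int
    p_value: float
    ms_error: float
    pairwise_p: Optional[pd.DataFrame]
    significant: pd.DataFrame
    letters: dict[str, str]
    alpha: float
    correction: str


def rm_anova(
    wide,
    alpha: float = DEFAULT_ALPHA,
    correction: str = "tukey",
    compute_p: bool = True,
    methods: Optional[Sequence[str]] = None,
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA from the sum-of-squares decomposition.

    ``wide`` is a complete subject-by-method matrix (DataFrame or 2-D
    array).  Total variation is split into subject, method and residual sums
    of squares; ``F = MS_method / MS_error`` with (k-1) and (n-1)(k-1)
    degrees of freedom.  Pairwise post-hoc comparisons use the studentized
    range on the repeated-measures error term (``correction='tukey'``,
    matching the usual repeated-measures multiple-comparisons default) or
    Bonferroni-adjusted paired t-tests (``correction='bonferroni'``).  With
    ``compute_p=False`` the Tukey path compares the q statistic against the
    cached critical value and reports significance only (fast path for large
    simulations).
    """
    if isinstance(wide, pd.DataFrame):
        cols = list(methods) if methods is not None else list(wide.columns)
        y = wide[cols].to_numpy(dtype=float)
    else:
        y = np.asarray(wide, dtype=float)
        cols = list(methods) if methods is not None else [f"m{i}" for i in range(y.shape[1])]
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 methods")
    if n < 3:
        raise ValueError("need at least 3 complete cases")
    if np.isnan(y).any():
        raise ValueError("rm_anova requires complete cases (no NaN)")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    meth_means = y.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_meth = n * ((meth_means - grand) ** 2).sum()
    resid = y - subj_means[:, None] - meth_means[None, :] + grand
    ss_err = (resid**2).sum()
    df_eff = k - 1
    df_err = (n - 1) * (k - 1)
    ms_meth = ss_meth / df_eff
    ms_err = ss_err / df_err
    if ms_err == 0:
        f_stat = np.inf if ms_meth > 0 else 0.0
        p_value = 0.0 if ms_meth > 0 else 1.0
    else:
        f_stat = ms_meth / ms_err
        p_value = float(sps.f.sf(f_stat, df_eff, df_err))

    pairs = list(itertools.combinations(range(k), 2))
    pmat = np.full((k, k), np.nan)
    np.fill_diagonal(pmat, 1.0)
    sig = np.zeros((k, k), dtype=bool)
    if correction == "tukey":
        se = np.sqrt(ms_err / n) if ms_err > 0 else 0.0
        diffs = np.array([abs(meth_means[i] - meth_means[j]) for i, j in pairs])
        if se > 0:
            qs = diffs / se
        else:  # zero residual variance: identical means tie, any gap separates
            qs = np.where(diffs == 0, 0.0, np.inf)
        if compute_p:
            ps = sps.studentized_range.sf(np.minimum(qs, 1e6), k, df_err)
            for (i, j), p in zip(pairs, ps):
                pmat[i, j] = pmat[j, i] = p
                sig[i, j] = sig[j, i] = p < alpha
        else:
            qcrit = _studentized_range_crit(alpha, k, df_err)
            for (i, j), q in zip(pairs, qs):
                s = q > qcrit
                sig[i, j] = sig[j, i] = s
    elif correction == "bonferroni":
        m = len(pairs)
        for i, j in pairs:
            d = y[:, i] - y[:, j]
            t, p = sps.ttest_rel(y[:, i], y[:, j])
            p_adj = min(1.0, p * m)
            pmat[i, j] = pmat[j, i] = p_adj
            sig[i, j] = sig[j, i] = p_adj < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")

    sig_df = pd.DataFrame(sig, index=cols, columns=cols)
    p_df = pd.DataFrame(pmat, index=cols, columns=cols) if compute_p or correction == "bonferroni" else None
    letters = dict(zip(cols, _letters_from_significance(sig)))
    return RmAnovaResult(
        methods=cols,
        n=n,
        means=meth_means,
        f_stat=float(f_stat),
        df_effect=df_eff,
        df_error=df_err,
        p_value=p_value,
        ms_error=float(ms_err),
        pairwise_p=p_df,
        significant=sig_df,
        letters=letters,
        alpha=alpha,
        correction=correction,
    )


_QCRIT_CACHE: dict[tuple[float, int, int], float] = {}


def _studentized_range_crit(alpha: float, k: int, df: int) -> float:
    key = (alpha, k, df)
    if key not in _QCRIT_CACHE:
        _QCRIT_CACHE[key] = float(sps.studentized_range.ppf(1 - alpha, k, df))
    return _QCRIT_CACHE[key]


def _letters_from_significance(sig: np.ndarray) -> list[str]:
    """Compact letter display by insert-and-absorb clique cover.

    Start with one group of all items; for every significantly different
    pair, split each group containing both into two subgroups excluding one
    item each; drop groups that are subsets of others.  Items end up sharing
    a letter iff no pair within the letter's group is significant.
    """
    k = sig.shape[0]
    groups: list[frozenset[int]] = [frozenset(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        new_groups: list[frozenset[int]] = []
        for g in groups:
            if i in g and j in g:
                new_groups.extend([g - {i}, g - {j}])
            else:
                new_groups.append(g)
        unique = []
        for g in new_groups:
            if g and g not in unique:
                unique.append(g)
        groups = [g for g in unique if not any(g < h for h in unique)]
    groups.sort(key=min)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for letter, g in zip(alphabet, groups):
        for item in sorted(g):
            letters[item] += letter
    return letters


def letter_groups(pairwise_p, alpha: float = DEFAULT_ALPHA) -> list[str]:
    """Compact letter display from a symmetric pairwise p-value matrix."""
    p = np.asarray(pairwise_p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("pairwise_p must be a square matrix")
    if not np.allclose(p, p.T, equal_nan=True):
        raise ValueError("pairwise_p must be symmetric")
    sig = p < alpha
    np.fill_diagonal(sig, False)
    return _letters_from_significance(sig)


def compare_measure(
    table: pd.DataFrame,
    measure: str,
    methods: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    correction: str = "tukey",
) -> RmAnovaResult:
    """Complete-case RM-ANOVA of ``measure`` over ``methods`` from the table."""
    wide = complete_cases(table, measure, methods)
    if len(wide) < 3:
        raise ValueError(
            f"fewer than 3 complete cases for {measure} over {list(methods)}"
        )
    return rm_anova(wide, alpha=alpha, correction=correction)


def mixed_effects_pairwise(
    table: pd.DataFrame, measure: str, methods: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Cross-check: random-intercept mixed model, Wald pairwise p-values.

    Unlike the repeated-measures ANOVA this tolerates missing values; it is a
    verification path, not the primary computation.
    """
    import statsmodels.formula.api as smf

    sub = table[table["method"].isin(methods)].dropna(subset=[measure]).copy()
    sub["subject"] = sub["contact_id"].astype(str) + "/" + sub["surface"].astype(str)
    sub = sub.rename(columns={measure: "y"})
    model = smf.mixedlm("y ~ C(method)", sub, groups=sub["subject"])
    try:
        fit = model.fit(reml=True)
    except np.linalg.LinAlgError:
        # near-zero subject variance can make the default path singular
        fit = model.fit(reml=True, method="powell")
    params = fit.params
    cov = fit.cov_params()
    names = list(params.index)
    level_term = {m: f"C(method)[T.{m}]" for m in methods}
    out: dict[tuple[str, str], float] = {}
    for m1, m2 in itertools.combinations(methods, 2):
        vec = pd.Series(0.0, index=names)
        for m, s in ((m1, 1.0), (m2, -1.0)):
            term = level_term[m]
            if term in vec.index:
                vec[term] = s
        est = float(vec @ params)
        var = float(vec @ cov @ vec)
        if var <= 0:
            out[(m1, m2)] = 1.0
            continue
        z = est / np.sqrt(var)
        out[(m1, m2)] = float(2 * sps.norm.sf(abs(z)))
    return out
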