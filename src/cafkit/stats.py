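"""Matched case-control statistics.

The statistical battery applied to the cohort: two-sided Fisher exact
tests on 2x2 contingency tables, Shapiro-gated two-sample comparisons
(Student t when both groups look normal, Wilcoxon rank-sum otherwise),
Spearman correlation, Kaplan-Meier curves with the log-rank test, Cox
proportional-hazards models with a p < 0.20 univariate entry rule for
the multivariate model, and greedy 1:1 nearest-neighbor matching of
controls to cases (exact on grade, calipers on age and Ki67).

Survival endpoint convention: the event is distant metastasis; local,
contralateral and axillary relapse and death without distant
metastasis censor. All tests are two-sided; no multiplicity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "FisherResult",
    "fisher_exact_2x2",
    "GroupComparison",
    "compare_groups",
    "spearman_corr",
    "KMResult",
    "km_logrank",
    "CoxResult",
    "cox_model",
    "MatchSpec",
    "match_controls",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with optional row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


class FisherResult(NamedTuple):
    pvalue: float
    odds_ratio: float


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums the hypergeometric probabilities, over all tables
    with the observed margins, that do not exceed the observed table's
    probability (with a 1 + 1e-7 relative slack for floating-point
    ties). The sample odds ratio (a*d)/(b*c) is reported, infinite when
    b*c = 0 with a*d > 0.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = sps.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(pvalue=p, odds_ratio=float(odds))


class GroupComparison(NamedTuple):
    test: str  # "t" | "wilcoxon"
    statistic: float
    pvalue: float
    shapiro_p: tuple[float, float]


def compare_groups(
    x: Sequence[float], y: Sequence[float], shapiro_alpha: float = 0.05
) -> GroupComparison:
    """Shapiro-gated two-sample comparison, two-sided.

    Each group is first tested for normality (Shapiro-Wilk); if both
    pass at ``shapiro_alpha`` a two-sample Student t test is used,
    otherwise the Wilcoxon rank-sum (Mann-Whitney) test with tie
    correction and normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    # Shapiro is undefined for constant samples; treat them as non-normal.
    px = sps.shapiro(x).pvalue if np.ptp(x) > 0 else 0.0
    py = sps.shapiro(y).pvalue if np.ptp(y) > 0 else 0.0
    if px > shapiro_alpha and py > shapiro_alpha:
        res = sps.ttest_ind(x, y)
        return GroupComparison("t", float(res.statistic), float(res.pvalue), (px, py))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        "wilcoxon", float(res.statistic), float(res.pvalue), (px, py)
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples of size >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class KMResult:
    """Per-group KM curves plus the log-rank test over all groups."""

    curves: dict  # group label -> DataFrame(time, survival)
    chi2: float
    pvalue: float
    medians: dict = field(default_factory=dict)


def km_logrank(groups: dict[str, pd.DataFrame]) -> KMResult:
    """Kaplan-Meier estimate per group + log-rank comparison.

    Each group frame needs ``time`` and ``event`` columns; times must be
    nonnegative and at least one event must be observed overall for the
    log-rank statistic to be defined.
    """
    if not groups:
        raise ValueError("at least one group is required")
    curves, medians = {}, {}
    frames = []
    for label, df in groups.items():
        if len(df) == 0:
            raise ValueError(f"group {label!r} is empty")
        t = np.asarray(df["time"], dtype=float)
        e = np.asarray(df["event"], dtype=bool)
        if np.any(t < 0):
            raise ValueError(f"group {label!r} has negative times")
        kmf = KaplanMeierFitter()
        kmf.fit(t, e)
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        medians[label] = float(kmf.median_survival_time_)
        frames.append(pd.DataFrame({"time": t, "event": e, "group": label}))
    pooled = pd.concat(frames, ignore_index=True)
    if not pooled["event"].any():
        raise ValueError("log-rank test undefined: no events observed")
    res = multivariate_logrank_test(
        pooled["time"], pooled["group"], pooled["event"]
    )
    return KMResult(
        curves=curves,
        chi2=float(res.test_statistic),
        pvalue=float(res.p_value),
        medians=medians,
    )


@dataclass(frozen=True)
class CoxResult:
    """Tidy Cox coefficient table with screening status."""

    table: pd.DataFrame  # covariate, hr, ci_low, ci_high, p, kept
    mode: str
    entry_p: float

    def row(self, covariate: str) -> pd.Series:
        return self.table.set_index("covariate").loc[covariate]


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cph = CoxPHFitter()
    cph.fit(
        df[["time", "event"] + covariates],
        duration_col="time",
        event_col="event",
    )
    s = cph.summary
    return pd.DataFrame(
        {
            "covariate": s.index,
            "coef": s["coef"].to_numpy(),
            "hr": s["exp(coef)"].to_numpy(),
            "ci_low": s["exp(coef) lower 95%"].to_numpy(),
            "ci_high": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)


def cox_model(
    records: pd.DataFrame,
    covariates: Sequence[str],
    mode: str = "univariate",
    entry_p: float = 0.20,
    scaling: dict[str, float] | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling, via lifelines).

    ``records`` needs ``time`` and ``event`` columns. ``univariate``
    mode fits each covariate alone; ``multivariate`` first screens
    univariately and keeps covariates with p < ``entry_p`` for a joint
    fit. ``scaling`` maps a covariate to a per-unit change on which its
    hazard ratio is reported (e.g. -50 for "per decrease of 50
    points"); the p-value is scale-invariant.
    """
    for col in ("time", "event"):
        if col not in records:
            raise ValueError(f"records must contain a {col!r} column")
    if int(records["event"].sum()) < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    covariates = list(covariates)
    for c in covariates:
        if np.ptp(np.asarray(records[c], dtype=float)) == 0:
            raise ValueError(f"covariate {c!r} is constant")
    scaling = scaling or {}

    uni_rows = []
    for c in covariates:
        row = _fit_cox(records, [c]).iloc[0]
        uni_rows.append(row)
    uni = pd.DataFrame(uni_rows).reset_index(drop=True)

    if mode == "univariate":
        out = uni.copy()
        out["kept"] = True
    elif mode == "multivariate":
        kept = uni.loc[uni["p"] < entry_p, "covariate"].tolist()
        if not kept:
            raise ValueError(
                f"no covariate passed the univariate p < {entry_p} screen"
            )
        multi = _fit_cox(records, kept)
        multi["kept"] = True
        dropped = uni[~uni["covariate"].isin(kept)].copy()
        dropped["kept"] = False
        out = pd.concat([multi, dropped], ignore_index=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # Rescale reported effect sizes (per k-unit change of the covariate).
    for c, k in scaling.items():
        m = out["covariate"] == c
        if not m.any():
            continue
        coef = out.loc[m, "coef"].to_numpy()
        lo = np.log(out.loc[m, "ci_low"].to_numpy())
        hi = np.log(out.loc[m, "ci_high"].to_numpy())
        b = np.exp(coef * k)
        bounds = np.sort(np.vstack([np.exp(lo * k), np.exp(hi * k)]), axis=0)
        out.loc[m, "hr"] = b
        out.loc[m, "ci_low"] = bounds[0]
        out.loc[m, "ci_high"] = bounds[1]
    return CoxResult(table=out.reset_index(drop=True), mode=mode, entry_p=entry_p)


@dataclass(frozen=True)
class MatchSpec:
    """1:1 matching rule: exact grade, calipers on age and Ki67."""

    age_caliper: float = 5.0
    ki67_caliper: float = 10.0
    exact: tuple[str, ...] = ("grade",)
    ratio: int = 1
    replacement: bool = False

    def __post_init__(self) -> None:
        if self.age_caliper <= 0 or self.ki67_caliper <= 0:
            raise ValueError("calipers must be positive")
        if self.ratio != 1 or self.replacement:
            raise ValueError("only 1:1 matching without replacement is supported")


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    spec: MatchSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Cases are visited in id order then seeded shuffle; each is matched
    to the unused pool member with the same grade, within both
    calipers, minimizing the caliper-normalized (age, Ki67) distance.
    Returns ``(pairs, unmatched_case_ids)``; pairs has columns
    ``case_id``, ``control_id``, ``distance``.
    """
    spec = spec or MatchSpec()
    if len(pool) == 0:
        raise ValueError("empty control pool")
    overlap = set(cases["id"]) & set(pool["id"])
    if overlap:
        raise ValueError(f"pool overlaps cases: {sorted(overlap)[:3]}...")
    rng = np.random.default_rng(seed)
    order = cases.sort_values("id").reset_index(drop=True)
    order = order.iloc[rng.permutation(len(order))]

    available = pool.set_index("id")
    used: set = set()
    pairs, unmatched = [], []
    for _, case in order.iterrows():
        cand = available[~available.index.isin(used)]
        for col in spec.exact:
            cand = cand[cand[col] == case[col]]
        da = (cand["age"] - case["age"]).abs() / spec.age_caliper
        dk = (cand["ki67"] - case["ki67"]).abs() / spec.ki67_caliper
        cand = cand[(da <= 1) & (dk <= 1)]
        if len(cand) == 0:
            unmatched.append(case["id"])
            continue
        dist = np.sqrt(
            ((cand["age"] - case["age"]) / spec.age_caliper) ** 2
            + ((cand["ki67"] - case["ki67"]) / spec.ki67_caliper) ** 2
        )
        best = dist.idxmin()
        used.add(best)
        pairs.append(
            {"case_id": case["id"], "control_id": best, "distance": float(dist[best])}
        )
    return pd.DataFrame(pairs, columns=["case_id", "control_id", "distance"]), unmatched
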