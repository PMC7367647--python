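"""Cohort-level evaluation of the screen: sensitivity/specificity with
exact counts, ROC/AUC with Youden-optimal cutoff, exact Fisher 2x2
statistics with conditional-MLE odds ratios, covariate cross-tabulations,
and OR-combination of two tests.

The conditional MLE odds ratio is the value maximizing the noncentral
hypergeometric likelihood of the observed 2x2 table given its margins —
the estimand reported by exact Fisher procedures — rather than the sample
cross-product ratio. The exact 95% CI inverts the one-sided tests at 2.5%
per side; tables with a zero cell yield open one-sided intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scoring import ScreeningCall, category_of

__all__ = [
    "LabeledCohort",
    "ConfusionRates",
    "RocCurve",
    "FisherResult",
    "confusion_rates",
    "positive_rate",
    "roc_auc",
    "optimal_cutoff",
    "fisher_exact_2x2",
    "crosstab_by_group",
    "combine_tests",
    "load_reported_cohorts",
]


@dataclass
class LabeledCohort:
    """Per-sample screening outcomes with cancer/control truth labels.

    ``statistic`` is the continuous quantity swept for the ROC — by default
    the max |panel segment Z| per sample.
    """

    sample_ids: list[str]
    labels: list[str]  # "cancer" | "control"
    screening: list[ScreeningCall]
    statistic: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(self.labels) != n or len(self.screening) != n:
            raise ValueError("cohort fields differ in length")
        bad = set(self.labels) - {"cancer", "control"}
        if bad:
            raise ValueError(f"labels must be cancer/control, got {bad}")
        if self.statistic is not None:
            self.statistic = np.asarray(self.statistic, dtype=float)
            if self.statistic.shape != (n,):
                raise ValueError("statistic length mismatch")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledCohort":
        calls = [
            ScreeningCall(sample_id=str(r.sample_id),
                          positive=bool(r.positive),
                          altered_count=int(r.altered_count),
                          cutoff_used=float(getattr(r, "cutoff", 2.702)))
            for r in df.itertuples(index=False)
        ]
        stat = df["statistic"].to_numpy(float) if "statistic" in df else None
        known = {"sample_id", "label", "positive", "altered_count",
                 "cutoff", "statistic"}
        cov_cols = [c for c in df.columns if c not in known]
        cov = df[["sample_id"] + cov_cols].set_index("sample_id") if cov_cols else None
        return cls(sample_ids=[str(s) for s in df["sample_id"]],
                   labels=[str(l) for l in df["label"]],
                   screening=calls, statistic=stat, covariates=cov)


@dataclass(frozen=True)
class ConfusionRates:
    sensitivity: Fraction
    specificity: Fraction
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * float(self.sensitivity)

    @property
    def specificity_pct(self) -> float:
        return 100.0 * float(self.specificity)


def confusion_rates(cohort: LabeledCohort) -> ConfusionRates:
    """Sensitivity/specificity of the screen, as exact integer ratios."""
    tp = fn = tn = fp = 0
    for label, call in zip(cohort.labels, cohort.screening):
        if label == "cancer":
            tp, fn = (tp + 1, fn) if call.positive else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if call.positive else (fp, tn + 1)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("cohort must contain both cancers and controls")
    return ConfusionRates(sensitivity=Fraction(tp, tp + fn),
                          specificity=Fraction(tn, tn + fp),
                          tp=tp, fn=fn, tn=tn, fp=fp)


def positive_rate(positives: int, total: int) -> Fraction:
    """Screen-positive fraction of a single-arm cohort, as an exact ratio."""
    if total <= 0 or not (0 <= positives <= total):
        raise ValueError("bad positive/total counts")
    return Fraction(positives, total)


@dataclass
class RocCurve:
    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(cohort: LabeledCohort) -> RocCurve:
    """ROC over the per-sample statistic (higher = more cancer-like).

    Thresholds sweep the observed statistic values (ties grouped); AUC is
    the trapezoid area, which equals the Mann-Whitney concordance
    probability.
    """
    if cohort.statistic is None:
        raise ValueError("cohort has no continuous statistic")
    y = np.array([1 if l == "cancer" else 0 for l in cohort.labels])
    x = cohort.statistic
    if np.all(x == x[0]):
        import warnings
        warnings.warn("constant statistic: ROC is degenerate, AUC = 0.5",
                      stacklevel=2)
        return RocCurve(cutoffs=np.array([x[0]]), tpr=np.array([1.0]),
                        fpr=np.array([1.0]), auc=0.5)
    from sklearn.metrics import roc_curve as _sk_roc

    fpr, tpr, thresh = _sk_roc(y, x)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(cutoffs=thresh, tpr=tpr, fpr=fpr, auc=auc)


def optimal_cutoff(curve: RocCurve) -> float:
    """Cutoff maximizing Youden's J = TPR - FPR; ties -> smaller cutoff."""
    finite = np.isfinite(curve.cutoffs)
    if finite.sum() < 1:
        raise ValueError("need at least one finite cutoff")
    j = curve.tpr[finite] - curve.fpr[finite]
    cuts = curve.cutoffs[finite]
    best = j.max()
    return float(cuts[np.isclose(j, best)].min())


@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    or_cmle: float
    ci95: tuple[float, float]


def _nchg(table, odds):
    (a, b), (c, d) = table
    return stats.nchypergeom_fisher(a + b + c + d, a + b, a + c, odds)


def fisher_exact_2x2(table) -> FisherResult:
    """Exact Fisher test of a 2x2 table with conditional-MLE odds ratio.

    Two-sided p sums noncentral-hypergeometric point probabilities not
    exceeding the observed one (at odds = 1); the OR solves the conditional
    score equation E_or[A] = a; the 95% CI inverts the exact one-sided
    tests at 2.5% each side (open at a boundary cell of zero).
    """
    (a, b), (c, d) = (int(table[0][0]), int(table[0][1])), \
                     (int(table[1][0]), int(table[1][1]))
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("2x2 table has an empty margin")
    tab = ((a, b), (c, d))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")

    lo_sup = max(0, (a + b) - (b + d))
    hi_sup = min(a + b, a + c)

    def mean_diff(log_or):
        return _nchg(tab, np.exp(log_or)).mean() - a

    if a == lo_sup:
        or_cmle = 0.0
    elif a == hi_sup:
        or_cmle = np.inf
    else:
        or_cmle = float(np.exp(optimize.brentq(mean_diff, -50, 50, xtol=1e-12)))

    # CI bounds: P(A >= a | or) = .025 (lower), P(A <= a | or) = .025 (upper)
    if a == lo_sup:
        lower = 0.0
    else:
        f = lambda log_or: _nchg(tab, np.exp(log_or)).sf(a - 1) - 0.025
        lower = float(np.exp(optimize.brentq(f, -50, 50, xtol=1e-10)))
    if a == hi_sup:
        upper = np.inf
    else:
        f = lambda log_or: _nchg(tab, np.exp(log_or)).cdf(a) - 0.025
        upper = float(np.exp(optimize.brentq(f, -50, 50, xtol=1e-10)))
    return FisherResult(table=tab, p_two_sided=float(p),
                        or_cmle=or_cmle, ci95=(lower, upper))


_CATEGORIES = [">=3", "2", "1", "0"]


def crosstab_by_group(
    cohort_df: pd.DataFrame,
    covariate: str,
    groups: Sequence[str] | None = None,
    test_groups: tuple[Sequence[str], Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate altered-segment categories by a covariate grouping.

    ``cohort_df`` needs columns ``altered_count`` and ``covariate``; rows
    with missing covariate are tabulated separately as "NA" and excluded
    from the test. When ``test_groups`` gives two disjoint sets of group
    labels, a collapsed 2x2 (group-set x screen-positivity) exact Fisher
    test is attached to the table attrs as ``fisher``.
    """
    df = cohort_df.copy()
    df["category"] = df["altered_count"].map(category_of)
    df["positive"] = df["altered_count"] >= 1
    df["_group"] = df[covariate].where(df[covariate].notna(), "NA").astype(str)
    if groups is None:
        groups = [g for g in df["_group"].unique() if g != "NA"]
    rows = []
    order = list(groups) + (["NA"] if (df["_group"] == "NA").any() else [])
    for g in order:
        sub = df[df["_group"] == g]
        row = {"group": g}
        for cat in _CATEGORIES:
            row[cat] = int((sub["category"] == cat).sum())
        row["n"] = len(sub)
        row["pct_positive"] = (100.0 * sub["positive"].mean()
                               if len(sub) else float("nan"))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("group")
    if test_groups is not None:
        ga, gb = (set(test_groups[0]), set(test_groups[1]))
        sub = df[df["_group"] != "NA"]
        in_a = sub["_group"].isin(ga)
        in_b = sub["_group"].isin(gb)
        tab = ((int((in_a & sub["positive"]).sum()),
                int((in_a & ~sub["positive"]).sum())),
               (int((in_b & sub["positive"]).sum()),
                int((in_b & ~sub["positive"]).sum())))
        out.attrs["fisher"] = fisher_exact_2x2(tab)
        out.attrs["fisher_groups"] = (sorted(ga), sorted(gb))
    return out


def combine_tests(call_a, call_b):
    """Combined positivity of two screening tests: logical OR.

    Accepts scalars or boolean arrays; cohort-level combined sensitivity
    follows by feeding the result back through confusion_rates.
    """
    return np.logical_or(call_a, call_b)


def calls_from_category_counts(counts: dict[str, int]) -> list[ScreeningCall]:
    """Expand a per-category altered-segment count table ('>=3'/'2'/'1'/'0')
    into per-sample screening calls via the positivity rule."""
    from .scoring import PanelScore, screen

    altered_by_cat = {"0": 0, "1": 1, "2": 2, ">=3": 3}
    calls = []
    k = 0
    for cat, n in counts.items():
        altered = altered_by_cat[cat]
        for _ in range(int(n)):
            score = PanelScore(sample_id=f"s{k}", segment_scores=[],
                               calls={}, altered_count=altered,
                               category=category_of(altered), cutoff=2.702,
                               direction_mode="absolute")
            calls.append(screen(score))
            k += 1
    return calls


def reported_screening_rates() -> dict[str, dict]:
    """Recompute every screening rate of the bundled published cohort
    summaries through the package's screening arithmetic.

    Returns a mapping of named rates, each with the exact ratio, the
    percentage, and the cohort size. The follow-up cohort uses the study's
    canonical 9/29 positives (its printed category row is internally
    inconsistent; see the data file note).
    """
    data = load_reported_cohorts()["cohorts"]

    def rate_of(calls):
        return sum(c.positive for c in calls), len(calls)

    disc_cancer = calls_from_category_counts(data["discovery_cancer"]["counts"])
    disc_ctrl = calls_from_category_counts(data["discovery_control"]["counts"])
    val_cancer = calls_from_category_counts(
        data["validation_presurgery"]["counts"])
    val_ctrl = calls_from_category_counts(data["validation_control"]["counts"])

    disc = LabeledCohort(
        sample_ids=[f"d{i}" for i in range(len(disc_cancer) + len(disc_ctrl))],
        labels=["cancer"] * len(disc_cancer) + ["control"] * len(disc_ctrl),
        screening=disc_cancer + disc_ctrl)
    val = LabeledCohort(
        sample_ids=[f"v{i}" for i in range(len(val_cancer) + len(val_ctrl))],
        labels=["cancer"] * len(val_cancer) + ["control"] * len(val_ctrl),
        screening=val_cancer + val_ctrl)
    disc_rates = confusion_rates(disc)
    val_rates = confusion_rates(val)

    hcc = rate_of(calls_from_category_counts(data["validation_hcc"]["counts"]))
    icc = rate_of(calls_from_category_counts(data["validation_icc"]["counts"]))
    multi = (sum(c.altered_count >= 2 for c in val_cancer), len(val_cancer))
    fu = data["followup_postsurgery"]
    followup = (int(fu["positives_reported"]), sum(fu["counts"].values()))
    # sanity: the rule is the same exact ratio positive_rate computes
    assert positive_rate(*followup) == Fraction(*followup)

    def entry(num: int, den: int) -> dict:
        return {"ratio": f"{num}/{den}", "pct": 100.0 * num / den, "n": den}

    return {
        "discovery_sensitivity": entry(disc_rates.tp,
                                       disc_rates.tp + disc_rates.fn),
        "discovery_specificity": entry(disc_rates.tn,
                                       disc_rates.tn + disc_rates.fp),
        "validation_sensitivity": entry(val_rates.tp,
                                        val_rates.tp + val_rates.fn),
        "validation_specificity": entry(val_rates.tn,
                                        val_rates.tn + val_rates.fp),
        "hcc_positive_rate": entry(*hcc),
        "icc_positive_rate": entry(*icc),
        "multi_segment_rate": entry(*multi),
        "postsurgery_positive_rate": entry(*followup),
    }


def reported_size_fisher() -> FisherResult:
    """Exact Fisher statistics of the published tumor-size cross-tabulation
    (>=5 cm vs <5 cm against screen positivity), reconstructed per-sample
    and collapsed through crosstab_by_group."""
    groups = load_reported_cohorts()["size_crosstab"]["groups"]
    altered_by_cat = {">=3": 3, "2": 2, "1": 1, "0": 0}
    rows = []
    k = 0
    for group, cats in groups.items():
        for cat, n in cats.items():
            for _ in range(int(n)):
                rows.append({"sample_id": f"sz{k}",
                             "size": None if group == "NA" else group,
                             "altered_count": altered_by_cat[cat]})
                k += 1
    df = pd.DataFrame(rows)
    tab = crosstab_by_group(df, "size", groups=[">=5cm", "3-5cm", "<3cm"],
                            test_groups=([">=5cm"], ["3-5cm", "<3cm"]))
    return tab.attrs["fisher"]


def load_reported_cohorts() -> dict:
    """Published per-category screening-count summaries bundled with the
    default panel (see the data file for provenance notes)."""
    import json
    from importlib import resources

    with resources.files("plasmacin.data").joinpath("cohort_counts.json").open() as fh:
        return json.load(fh)
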