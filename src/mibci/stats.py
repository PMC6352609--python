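"""Questionnaire scoring, subject grouping, and the inferential battery.

Imagery-questionnaire scores rescale the mean of the seven kinesthetic
(or visual) 1..7 Likert items to 0..100:

    score = (mean(items) - 1) / 6 * 100 .

Grouping rules: a score is "positive" when >= 70 (K+/V+ four-way
grouping); Perf+ subjects decode strictly above the cohort-mean
accuracy; Manual+ subjects practice manual activities weekly or daily.

Inference: Pearson / Spearman correlations, Welch's unequal-variance
t-test, Mann-Whitney U (exact for small untied samples), Shapiro-Wilk
normality, Glass's Delta effect size (control = larger group), and
Benjamini-Hochberg FDR control over declared test families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spst

from .containers import FREQUENCY_LEVELS, SubjectRecord
from .errors import ValidationError

#: Kinesthetic item subsets (1-based indices into K1..K7) for the
#: hand-specific (3 items) and arm-related (5 items) sub-scores. The
#: questionnaire's public form does not fix which items these are; the
#: defaults below are configuration, not a normative mapping.
DEFAULT_SUBSETS = {"hand": (2, 4, 6), "arm": (1, 2, 4, 6, 7)}

POSITIVE_SCORE_THRESHOLD = 70.0
MANUAL_POSITIVE_MIN_LEVEL = FREQUENCY_LEVELS.index("weekly")


@dataclass
class MIQScores:
    """0-100 imagery ability scores for one subject."""

    kmi_score: float
    vmi_score: float
    kmi_hand_score: float
    vmi_hand_score: float
    kmi_arm_score: float
    vmi_arm_score: float


@dataclass
class StatResult:
    """One statistical test outcome."""

    name: str
    estimate: float
    p_value: float
    n: tuple
    significant: bool | None = None
    adjusted_alpha: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def _rescale(items) -> float:
    return (float(np.mean(items)) - 1.0) / 6.0 * 100.0


def score_miq(record: SubjectRecord, subsets: dict | None = None) -> MIQScores:
    """Score the 14-item questionnaire: full and subset 0-100 scores."""
    subsets = dict(DEFAULT_SUBSETS, **(subsets or {}))
    k = record.kinesthetic_answers
    v = record.visual_answers
    if len(k) != 7 or len(v) != 7:
        raise ValidationError("need 7 kinesthetic and 7 visual answers")

    def sub(items, idx):
        return _rescale([items[i - 1] for i in idx])

    return MIQScores(
        kmi_score=_rescale(k),
        vmi_score=_rescale(v),
        kmi_hand_score=sub(k, subsets["hand"]),
        vmi_hand_score=sub(v, subsets["hand"]),
        kmi_arm_score=sub(k, subsets["arm"]),
        vmi_arm_score=sub(v, subsets["arm"]),
    )


def categorize_kv(kmi_score: float, vmi_score: float) -> str:
    """Four-way imagery-ability group; a score is positive when >= 70."""
    k = "+" if kmi_score >= POSITIVE_SCORE_THRESHOLD else "-"
    v = "+" if vmi_score >= POSITIVE_SCORE_THRESHOLD else "-"
    return f"K{k}V{v}"


def split_perf(accuracies) -> list[str]:
    """Perf+ iff accuracy strictly exceeds the cohort mean."""
    acc = np.asarray(accuracies, dtype=float)
    if len(acc) < 2:
        raise ValidationError("need at least 2 subjects to split on performance")
    mean = acc.mean()
    # strict ">" with a tolerance so exact ties (up to fp error) stay Perf-
    eps = 1e-12 * max(1.0, abs(mean))
    return ["Perf+" if a - mean > eps else "Perf-" for a in acc]


def split_manual(freq_manual) -> str:
    """Manual+ iff the declared frequency is weekly or daily.

    Accepts the ordinal level 0..5 or its name from
    ``FREQUENCY_LEVELS`` (never .. daily).
    """
    if isinstance(freq_manual, str):
        name = freq_manual.lower()
        if name not in FREQUENCY_LEVELS:
            raise ValidationError(
                f"unknown frequency level {freq_manual!r}; known: {list(FREQUENCY_LEVELS)}"
            )
        level = FREQUENCY_LEVELS.index(name)
    else:
        level = int(freq_manual)
        if not 0 <= level <= 5:
            raise ValidationError(f"frequency level {freq_manual} outside 0..5")
    return "Manual+" if level >= MANUAL_POSITIVE_MIN_LEVEL else "Manual-"


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("need n >= 3 for a correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in correlation input")
    for name, arr in (("x", x), ("y", y)):
        if np.ptp(arr) == 0:
            raise ValidationError(f"variable {name} is constant; correlation undefined")
    return x, y


def pearson_r(x, y) -> StatResult:
    """Pearson product-moment correlation with two-sided p-value."""
    x, y = _check_xy(x, y)
    res = spst.pearsonr(x, y)
    return StatResult("pearson_r", float(res.statistic), float(res.pvalue), (len(x),))


def spearman_rho(x, y) -> StatResult:
    """Spearman rank correlation (average ranks for ties), two-sided."""
    x, y = _check_xy(x, y)
    res = spst.spearmanr(x, y)
    return StatResult("spearman_rho", float(res.statistic), float(res.pvalue), (len(x),))


def welch_t(a, b) -> StatResult:
    """Welch's unequal-variance t-test (Satterthwaite df), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 observations")
    res = spst.ttest_ind(a, b, equal_var=False)
    return StatResult("welch_t", float(res.statistic), float(res.pvalue), (len(a), len(b)))


def mann_whitney_u(a, b) -> StatResult:
    """Mann-Whitney U, two-sided; exact when both n <= 8 and untied."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("empty group")
    tied = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not tied) else "asymptotic"
    res = spst.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult("mann_whitney_u", float(res.statistic), float(res.pvalue), (len(a), len(b)))


def shapiro_wilk(x) -> StatResult:
    """Shapiro-Wilk normality test."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValidationError("Shapiro-Wilk needs n >= 3")
    res = spst.shapiro(x)
    return StatResult("shapiro_wilk", float(res.statistic), float(res.pvalue), (len(x),))


def glass_delta(a, b) -> StatResult:
    """Glass's Delta: |mean difference| / SD of the control (larger) group.

    The control group is the larger sample (ties resolved toward the
    first argument); SD uses the n-1 denominator. No p-value is defined;
    the result's p_value is set to 1.0 as a placeholder.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    control = a if len(a) >= len(b) else b
    if len(control) < 2:
        raise ValidationError("control group needs >= 2 observations")
    sd = control.std(ddof=1)
    if sd == 0:
        raise ValidationError("control group has zero standard deviation")
    delta = abs(a.mean() - b.mean()) / sd
    return StatResult("glass_delta", float(delta), 1.0, (len(a), len(b)))


def bh_adjust(p_values, q: float = 0.20) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(rejected, threshold)``: boolean flags aligned with the
    input order, and the realized rejection threshold k*q/m (0.0 when
    nothing is rejected), where k is the largest rank with
    p_(k) <= k*q/m.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), 0.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    ok = np.nonzero(ranked <= crit)[0]
    if len(ok) == 0:
        return np.zeros(m, dtype=bool), 0.0
    k = ok[-1] + 1
    threshold = k * q / m
    rejected = p <= threshold
    return rejected, float(threshold)


#: Variables entering the correlation report, per subject record.
SCORE_VARS = ("kmi_score", "vmi_score", "kmi_hand_score", "vmi_hand_score")
FACTOR_VARS = (
    "age",
    "gender",
    "education_years",
    "freq_manual",
    "freq_sport",
    "freq_music",
    "freq_craft",
    "freq_gaming",
)


@dataclass
class StatReport:
    """Long-format correlation table plus per-family FDR thresholds."""

    table: pd.DataFrame
    families: dict[str, list[int]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def subject_variables(records: list[SubjectRecord]) -> pd.DataFrame:
    """Per-subject analysis variables: scores plus (numeric) personal factors."""
    rows = []
    for r in records:
        s = score_miq(r)
        rows.append(
            {
                "subject_id": r.subject_id,
                "kmi_score": s.kmi_score,
                "vmi_score": s.vmi_score,
                "kmi_hand_score": s.kmi_hand_score,
                "vmi_hand_score": s.vmi_hand_score,
                "age": r.age,
                "gender": 1.0 if r.gender == "F" else 0.0,
                "education_years": r.education_years,
                **{f: getattr(r, f) for f in SubjectRecord.FREQ_FIELDS},
            }
        )
    return pd.DataFrame(rows)


def run_correlation_table(
    records: list[SubjectRecord],
    accuracies: dict[str, np.ndarray],
    q: float = 0.20,
    families: dict[str, list[tuple[str, str]]] | None = None,
) -> StatReport:
    """Correlate every method's accuracy with scores and personal factors.

    ``accuracies`` maps method name -> per-subject accuracy array aligned
    with ``records``. For each (method, variable) pair both Pearson and
    Spearman coefficients are computed; Benjamini-Hochberg adjustment is
    applied within declared test families (default: one family of
    method x {KMI, VMI} score correlations, and one "primary hypothesis"
    family of best-method x personal-factor correlations, mirroring the
    reporting conventions of questionnaire-predictor studies).
    """
    varframe = subject_variables(records)
    n = len(varframe)
    for meth, acc in accuracies.items():
        if len(acc) != n:
            raise ValidationError(f"accuracies for {meth!r} misaligned with records")

    rows = []
    for meth, acc in accuracies.items():
        for var in SCORE_VARS + FACTOR_VARS:
            x = varframe[var].to_numpy(dtype=float)
            try:
                pr = pearson_r(x, acc)
                sr = spearman_rho(x, acc)
            except ValidationError:
                continue  # constant variable in a small cohort
            rows.append(
                {
                    "method": meth,
                    "variable": var,
                    "n": n,
                    "pearson_r": pr.estimate,
                    "pearson_p": pr.p_value,
                    "spearman_rho": sr.estimate,
                    "spearman_p": sr.p_value,
                }
            )
    table = pd.DataFrame(rows)

    if families is None:
        methods = list(accuracies)
        families = {
            "miq_scores": [(m, v) for m in methods for v in ("kmi_score", "vmi_score")],
        }
        best = methods[-1]
        families["personal_factors"] = [(best, v) for v in FACTOR_VARS]

    table["family"] = ""
    table["significant"] = False
    fam_rows: dict[str, list[int]] = {}
    thresholds: dict[str, float] = {}
    for fam, pairs in families.items():
        idx = [
            i
            for i, row in table.iterrows()
            if (row["method"], row["variable"]) in set(pairs)
        ]
        if not idx:
            thresholds[fam] = 0.0
            fam_rows[fam] = []
            continue
        rejected, thr = bh_adjust(table.loc[idx, "pearson_p"].to_numpy(), q=q)
        table.loc[idx, "family"] = fam
        table.loc[idx, "significant"] = rejected
        thresholds[fam] = thr
        fam_rows[fam] = idx
    return StatReport(table=table, families=fam_rows, thresholds=thresholds)


def score_table(report: StatReport, variables: tuple[str, str]) -> pd.DataFrame:
    """Wide per-classifier view of the correlation report.

    Rows are classification methods; columns are (r, p) for each of the
    two requested score variables — the layout used when reporting
    questionnaire-score vs accuracy correlations per classifier.
    """
    out = {}
    for var in variables:
        sub = report.table[report.table["variable"] == var].set_index("method")
        out[f"{var}_r"] = sub["pearson_r"]
        out[f"{var}_p"] = sub["pearson_p"]
    return pd.DataFrame(out)


def run_group_comparisons(
    records: list[SubjectRecord], accuracies: np.ndarray
) -> pd.DataFrame:
    """Between-group tests mirroring the subgroup analyses of the pipeline.

    Rows: Welch t / Mann-Whitney U / Glass's Delta for (a) accuracy
    between every pair of K/V groups with >= 2 members, (b) KMI and VMI
    scores between Perf+ and Perf-, and (c) accuracy between Manual+ and
    Manual-.
    """
    acc = np.asarray(accuracies, dtype=float)
    varframe = subject_variables(records)
    kv = [categorize_kv(k, v) for k, v in zip(varframe["kmi_score"], varframe["vmi_score"])]
    perf = split_perf(acc)
    manual = [split_manual(r.freq_manual) for r in records]

    rows = []

    def compare(tag, a, b, na, nb):
        if len(a) < 2 or len(b) < 2:
            return
        for fn in (welch_t, mann_whitney_u, glass_delta):
            res = fn(a, b)
            rows.append(
                {
                    "comparison": tag,
                    "test": res.name,
                    "estimate": res.estimate,
                    "p_value": res.p_value,
                    "n_a": na,
                    "n_b": nb,
                }
            )

    kv_arr = np.array(kv)
    groups = [g for g in ("K+V+", "K+V-", "K-V+", "K-V-") if np.sum(kv_arr == g) >= 2]
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            a, b = acc[kv_arr == g1], acc[kv_arr == g2]
            compare(f"accuracy {g1} vs {g2}", a, b, len(a), len(b))

    perf_arr = np.array(perf)
    for score in ("kmi_score", "vmi_score"):
        vals = varframe[score].to_numpy(dtype=float)
        a, b = vals[perf_arr == "Perf+"], vals[perf_arr == "Perf-"]
        compare(f"{score} Perf+ vs Perf-", a, b, len(a), len(b))

    man_arr = np.array(manual)
    a, b = acc[man_arr == "Manual+"], acc[man_arr == "Manual-"]
    compare("accuracy Manual+ vs Manual-", a, b, len(a), len(b))

    return pd.DataFrame(rows)
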