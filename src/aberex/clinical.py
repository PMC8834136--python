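"""Clinical endpoints and validation statistics.

Progression-free survival (PFS) is the interval from treatment to metastasis
or death from the disease; patients lost to follow-up, dead of another cause,
or dead without a reported cause are censored at last contact.  A 60-month
cutoff stratifies patients into early metastatic onset (event before 60
months), late onset (at risk at 60 months), or unclassifiable (censored
before the cutoff).

The module also provides the exact r x c Fisher test and Student t-test used
for stratified cohort comparison tables, Kaplan-Meier estimation with
Greenwood/log-log confidence bands, the Wilcoxon rank-sum test, qPCR
delta-Ct / delta-delta-Ct quantification against a reference transcript, and
the immunoreactive score (IRS) for immunohistochemistry.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

DEATH_CAUSES = ("UM", "other", "unknown", "alive")


@dataclass
class PatientRecord:
    """Minimal per-patient clinical record for PFS derivation."""

    patient_id: str
    followup_months: float | None = None
    metastasis: bool = False
    time_to_metastasis: float | None = None
    death_cause: str = "alive"  # UM | other | unknown | alive
    time_to_death: float | None = None
    ltd_mm: float | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in (self.followup_months, self.time_to_metastasis, self.time_to_death):
            if t is not None and t < 0:
                raise ValueError("times must be non-negative")
        if self.metastasis and self.time_to_metastasis is None:
            raise ValueError("metastasis=True requires time_to_metastasis")
        if self.death_cause not in DEATH_CAUSES:
            raise ValueError(f"unknown death cause {self.death_cause!r}")


@dataclass(frozen=True)
class SurvivalObservation:
    pfs_months: float
    event: int  # 1 = metastasis / disease death, 0 = censored

    def __post_init__(self) -> None:
        if self.pfs_months < 0:
            raise ValueError("pfs_months must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


EARLY, LATE, UNCLASSIFIABLE = "early", "late", "unclassifiable"


def derive_pfs(record: PatientRecord) -> SurvivalObservation:
    """Derive the PFS observation from a patient record.

    Event (=1) at the earliest of metastasis or disease-specific death;
    otherwise censored (=0) at last follow-up -- including death from another
    cause and death with unreported cause.
    """
    event_times = []
    if record.metastasis and record.time_to_metastasis is not None:
        event_times.append(record.time_to_metastasis)
    if record.death_cause == "UM" and record.time_to_death is not None:
        event_times.append(record.time_to_death)
    if event_times:
        return SurvivalObservation(min(event_times), 1)
    censor_times = [
        t for t in (record.followup_months, record.time_to_death) if t is not None
    ]
    if not censor_times:
        raise ValueError(f"patient {record.patient_id}: no usable time")
    return SurvivalObservation(max(censor_times), 0)


def stratify(obs: SurvivalObservation, cutoff: float = 60.0) -> str:
    """Early/late/unclassifiable stratum for one observation.

    Late includes every patient still at risk at the cutoff, with or without
    a later event; censoring before the cutoff is unclassifiable.
    """
    if obs.pfs_months >= cutoff:
        return LATE
    return EARLY if obs.event == 1 else UNCLASSIFIABLE


def stratify_cohort(
    observations, cutoff: float = 60.0
) -> pd.Series:
    return pd.Series({i: stratify(o, cutoff) for i, o in observations.items()})


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def kaplan_meier(observations, alpha: float = 0.05):
    """Product-limit estimate with Greenwood variance and log-log CI.

    Parameters
    ----------
    observations:
        Iterable of :class:`SurvivalObservation`.

    Returns
    -------
    dict with ``survival`` (DataFrame: timeline, estimate, CI bounds),
    ``median`` and ``median_ci`` (months; NaN when the curve never reaches
    0.5 or the CI bound never crosses it).
    """
    obs = list(observations)
    times = [o.pfs_months for o in obs]
    events = [o.event for o in obs]
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    ci = kmf.confidence_interval_survival_function_
    surv = pd.DataFrame(
        {
            "estimate": kmf.survival_function_["KM_estimate"],
            "ci_lower": ci.iloc[:, 0],
            "ci_upper": ci.iloc[:, 1],
        }
    )
    if sum(events) == 0:
        return {"survival": surv, "median": float("nan"),
                "median_ci": (float("nan"), float("nan"))}
    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
    return {"survival": surv, "median": median, "median_ci": (lo, hi)}


# ---------------------------------------------------------------------------
# Exact r x c Fisher test
# ---------------------------------------------------------------------------


def _log_fact(n: int) -> float:
    return math.lgamma(n + 1)


def fisher_exact_rxc(table, rel_tol: float = 1e-7) -> float:
    """Two-sided exact Fisher test for an r x c contingency table.

    Enumerates every non-negative integer table with the observed margins;
    the two-sided p-value is the total probability of tables whose
    (multivariate hypergeometric) probability does not exceed the observed
    table's, with a small relative tolerance for floating-point ties.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or (tab < 0).any():
        raise ValueError("table must be a non-negative 2-D integer array")
    # drop all-zero rows/columns: they carry no information
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.size == 0 or 1 in tab.shape:
        return 1.0
    row_m = tab.sum(axis=1)
    col_m = tab.sum(axis=0)
    n = int(tab.sum())
    log_const = (
        sum(_log_fact(r) for r in row_m)
        + sum(_log_fact(c) for c in col_m)
        - _log_fact(n)
    )

    def log_prob(t: np.ndarray) -> float:
        return log_const - sum(_log_fact(int(x)) for x in t.flat)

    lp_obs = log_prob(tab)
    cutoff = lp_obs + math.log1p(rel_tol)

    r, c = tab.shape
    p_total = 0.0
    # enumerate row by row over compositions with the fixed margins
    def rec(row_idx: int, col_rem: np.ndarray, acc_lp: float) -> None:
        nonlocal p_total
        if row_idx == r - 1:
            # last row forced by the column remainders
            lp = acc_lp - sum(_log_fact(int(x)) for x in col_rem)
            if lp <= cutoff:
                p_total += math.exp(lp)
            return
        target = int(row_m[row_idx])

        def fill(col_idx: int, rem: int, cells: list[int]) -> None:
            if col_idx == c - 1:
                if rem > col_rem[col_idx]:
                    return
                cells.append(rem)
                lp_row = -sum(_log_fact(x) for x in cells)
                new_rem = col_rem - np.array(cells)
                rec(row_idx + 1, new_rem, acc_lp + lp_row)
                cells.pop()
                return
            hi = min(rem, int(col_rem[col_idx]))
            for v in range(hi + 1):
                cells.append(v)
                fill(col_idx + 1, rem - v, cells)
                cells.pop()

        fill(0, target, [])

    rec(0, col_m.copy(), log_const)
    return min(p_total, 1.0)


def count_tables_with_margins(row_m, col_m) -> int:
    """Number of non-negative integer tables with the given margins
    (combinatorial companion of the Fisher enumeration, used as its
    correctness check)."""
    row_m = list(map(int, row_m))
    col_m = list(map(int, col_m))
    if sum(row_m) != sum(col_m):
        raise ValueError("margins disagree")

    total = 0
    c = len(col_m)

    def rec(rows_left, col_rem):
        nonlocal total
        if len(rows_left) == 1:
            total += 1 if sum(col_rem) == rows_left[0] else 0
            return
        target = rows_left[0]

        def fill(col_idx, rem, cells):
            if col_idx == c - 1:
                if rem <= col_rem[col_idx]:
                    rec(
                        rows_left[1:],
                        [cr - cl for cr, cl in zip(col_rem, cells + [rem])],
                    )
                return
            for v in range(min(rem, col_rem[col_idx]) + 1):
                fill(col_idx + 1, rem - v, cells + [v])

        fill(0, target, [])

    rec(row_m, col_m)
    return total


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

NOT_REPORTED = "Data not reported"


def student_t_from_stats(mean1, sd1, n1, mean2, sd2, n2, welch: bool = False):
    """Two-sided Student t-test from summary statistics (pooled variance by
    default; Welch by flag)."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "stratum",
    kind: str = "auto",
    welch: bool = False,
) -> dict:
    """Compare a clinical variable between the early and late strata.

    Continuous variables get a two-sided Student t-test (pooled variance);
    categorical variables get the exact r x c Fisher test.  Rows whose value
    or group is missing / "Data not reported" are excluded first.
    """
    sub = table[[group_col, variable]].copy()
    sub = sub[~sub[variable].isin([NOT_REPORTED])]
    sub = sub.dropna()
    sub = sub[sub[group_col].isin([EARLY, LATE])]
    groups = [g for _, g in sub.groupby(group_col)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        warnings.warn(f"{variable}: a group is empty after exclusions")
        return {"variable": variable, "test": "NA", "p": float("nan")}
    if kind == "auto":
        kind = (
            "continuous"
            if pd.api.types.is_numeric_dtype(sub[variable])
            else "categorical"
        )
    if kind == "continuous":
        a = sub.loc[sub[group_col] == EARLY, variable].astype(float)
        b = sub.loc[sub[group_col] == LATE, variable].astype(float)
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        return {"variable": variable, "test": "t", "statistic": float(t),
                "p": float(p)}
    ct = pd.crosstab(sub[variable], sub[group_col])
    p = fisher_exact_rxc(ct.values)
    return {"variable": variable, "test": "fisher", "p": p,
            "table": ct}


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact distribution for combined n <= 20 without ties; normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# qPCR delta-Ct
# ---------------------------------------------------------------------------


@dataclass
class QPCRMeasurement:
    """Replicate Ct values for one target gene and the reference gene."""

    sample_id: str
    target_gene: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]
    reference_gene: str = "CHMP2A"

    def __post_init__(self) -> None:
        if len(self.target_ct) < 2 or len(self.reference_ct) < 2:
            raise ValueError("need at least 2 replicates per gene")


def delta_ct(measurement: QPCRMeasurement) -> float:
    """delta-Ct = mean Ct(reference) - mean Ct(target).

    With this sign convention a target amplifying later (higher Ct) than the
    reference yields a negative delta-Ct, i.e. lower expression.
    """
    return float(
        np.mean(measurement.reference_ct) - np.mean(measurement.target_ct)
    )


def delta_delta_ct(sample: QPCRMeasurement, control: QPCRMeasurement):
    """delta-delta-Ct of a sample against the control sample and the implied
    fold change 2**ddCt."""
    ddct = delta_ct(sample) - delta_ct(control)
    return ddct, float(2.0**ddct)


# ---------------------------------------------------------------------------
# IHC immunoreactive score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IRSScore:
    intensity_score: int  # 0..3
    percentage_score: int  # 0..4

    def __post_init__(self) -> None:
        if self.intensity_score not in range(4):
            raise ValueError("intensity score must be 0..3")
        if self.percentage_score not in range(5):
            raise ValueError("percentage score must be 0..4")

    @property
    def irs(self) -> int:
        return self.intensity_score * self.percentage_score


def percentage_class(percent: float) -> int:
    """Map a raw percentage of stained cells to its score class:
    0% -> 0, <10% -> 1, 10-50% -> 2, 51-80% -> 3, >80% -> 4."""
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    if percent == 0:
        return 0
    if percent < 10:
        return 1
    if percent <= 50:
        return 2
    if percent <= 80:
        return 3
    return 4


def irs(intensity: int, percentage) -> IRSScore:
    """Immunoreactive score: intensity class (0-3) times percentage class
    (0-4).  ``percentage`` may be a class (integer 0-4) or a raw percent
    (any float, or an integer above 4)."""
    if isinstance(percentage, float) or percentage > 4:
        pclass = percentage_class(float(percentage))
    else:
        pclass = int(percentage)
    return IRSScore(int(intensity), pclass)
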