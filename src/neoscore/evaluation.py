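"""ROC analysis, DeLong comparison of correlated AUCs, operating-point
metrics, and the group-comparison statistics behind the cohort report.

AUC is computed as the Mann-Whitney pair statistic (ties count one half),
which equals the trapezoidal area under the empirical ROC curve. The DeLong
(1988) structural-component estimator provides the AUC variance and the
paired test for two scores on the same subjects. Group comparisons use
Fisher's exact test for categorical variables (two-sided by the
point-probability criterion) and the Mann-Whitney U-test for continuous
ones; r x c categorical tables use a seeded Monte-Carlo version of the
Freeman-Halton extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cohort import BOOLEAN_COVARIATES, Cohort, RACES
from .scoring import WeightTable, final_weights, score_injury


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    delong_variance: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class EvalMetrics:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    youden_j: float
    ppv: Optional[float]
    npv: Optional[float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    p_value: float


def _split(scores: Sequence[float], labels: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    return pos, neg


def _delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-subject structural components V10 (positives) and V01."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(v10.mean()), v10, v01


def auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """Empirical ROC with the Mann-Whitney AUC and its DeLong variance.

    The curve is built over all distinct observed cutpoints with the strict
    ``value > threshold`` positivity rule; it runs from (0, 0) to (1, 1).
    """
    pos, neg = _split(scores, labels)
    area, v10, v01 = _delong_components(pos, neg)
    m, n = len(pos), len(neg)
    if m > 1 and n > 1:
        variance = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    else:
        variance = float("nan")
    cuts = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr, fpr, thresholds = [0.0], [0.0], [np.inf]
    for cut in cuts:
        tpr.append(float((pos > cut).mean()))
        fpr.append(float((neg > cut).mean()))
        thresholds.append(float(cut))
    # a threshold below the minimum value classifies everything positive
    tpr.append(1.0)
    fpr.append(1.0)
    thresholds.append(-np.inf)
    return RocResult(
        fpr=np.asarray(fpr),
        tpr=np.asarray(tpr),
        thresholds=thresholds,
        auc=area,
        delong_variance=variance,
        n_pos=m,
        n_neg=n,
    )


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool]
) -> DelongResult:
    """Paired DeLong test for two correlated ROC curves on the same subjects.

    Returns the AUC difference (a minus b), its variance, and the two-sided
    p from the normal approximation. Identical scores give difference 0 and
    p exactly 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("both score vectors must cover the same subjects")
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    auc_a, v10_a, v01_a = _delong_components(pos_a, neg_a)
    auc_b, v10_b, v01_b = _delong_components(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    variance = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_a - auc_b
    if variance <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(variance)
        p = float(2 * stats.norm.sf(abs(z)))
    return DelongResult(auc_a=auc_a, auc_b=auc_b, difference=diff, variance=variance, p_value=p)


def operating_metrics(
    values: Sequence[float], labels: Sequence[bool], threshold: float
) -> EvalMetrics:
    """Confusion counts and derived rates at a strict ``value > threshold`` rule.

    PPV/NPV with a zero denominator are reported as ``None`` (absent), not 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = values > threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    tn = int((~pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both outcome classes must be present")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalMetrics(
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        youden_j=sens + spec - 1.0,
        ppv=tp / (tp + fp) if tp + fp > 0 else None,
        npv=tn / (tn + fn) if tn + fn > 0 else None,
    )


def _check_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if not np.all(table == np.floor(table)) or np.any(table < 0):
            raise ValueError("table entries must be non-negative integers")
        table = table.astype(int)
    return table


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (point-probability method:
    sum the probabilities of all tables no more likely than the observed)."""
    table = _check_table(np.asarray(table))
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def _log_table_prob(tables: np.ndarray, row_margins: np.ndarray, col_margins: np.ndarray) -> np.ndarray:
    """Log point probability of r x c tables under fixed margins."""
    total = row_margins.sum()
    const = (
        gammaln(row_margins + 1).sum()
        + gammaln(col_margins + 1).sum()
        - gammaln(total + 1)
    )
    return const - gammaln(tables + 1).sum(axis=(-2, -1))


def fisher_exact_rxc(
    table: Sequence[Sequence[int]], n_draws: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo Freeman-Halton test for an r x c table.

    Samples ``n_draws`` tables with the observed margins (Patefield
    algorithm) and applies the point-probability criterion; returns the
    add-one-corrected p estimate and its Monte-Carlo standard error. A 2x2
    input agrees with :func:`fisher_exact_2x2` up to MC error.
    """
    table = _check_table(np.asarray(table))
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    keep_r, keep_c = rows > 0, cols > 0
    table = table[keep_r][:, keep_c]
    rows, cols = rows[keep_r], cols[keep_c]
    if table.size == 0:
        raise ValueError("table has no positive margins")
    if min(table.shape) <= 1:
        return 1.0, 0.0  # a single row/column is fully determined by margins
    rng = np.random.default_rng(seed)
    sample = stats.random_table(rows, cols, seed=rng).rvs(n_draws)
    log_obs = _log_table_prob(table[None, :, :], rows, cols)[0]
    log_draws = _log_table_prob(sample, rows, cols)
    hits = int((log_draws <= log_obs + 1e-9).sum())
    p = (hits + 1) / (n_draws + 1)
    se = float(np.sqrt(p * (1 - p) / n_draws))
    return float(p), se


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (of ``x``) and two-sided p.

    Exact enumeration when the combined sample is small (n <= 12) with no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 12 and no_ties) else "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(result.statistic), float(min(result.pvalue, 1.0))


def _fmt_pct(count: int, total: int) -> str:
    return f"{count} ({round(100 * count / total)})"


def _binary_row(name: str, severe_vals: list, nonsevere_vals: list) -> dict:
    sev = [v for v in severe_vals if v is not None]
    non = [v for v in nonsevere_vals if v is not None]
    a, b = sum(non), len(non) - sum(non)
    c, d = sum(sev), len(sev) - sum(sev)
    p = fisher_exact_2x2([[a, b], [c, d]]) if min(a + b, c + d) > 0 else float("nan")
    return {
        "variable": name,
        "no_severe": _fmt_pct(a, len(non)),
        "severe": _fmt_pct(c, len(sev)),
        "p_value": p,
    }


def cohort_report(cohort: Cohort, weights: Optional[WeightTable] = None) -> pd.DataFrame:
    """Group-comparison table for severe vs. non-severe outcomes.

    One row per clinical and imaging characteristic: per-group n (%) for
    binaries and categories, mean (SD) or median (range) for continuous
    variables, a p-value (Fisher exact / Freeman-Halton MC / Mann-Whitney),
    and a significance star at p < 0.05.
    """
    labeled = cohort.labeled()
    severe = [r for r in labeled if r.severe]
    non = [r for r in labeled if not r.severe]
    if not severe or not non:
        raise ValueError("cohort report needs labeled records in both outcome groups")
    weights = weights or final_weights()

    rows: list[dict] = []

    def continuous(name: str, getter, kind: str) -> None:
        sev = [getter(r) for r in severe if getter(r) is not None]
        nsv = [getter(r) for r in non if getter(r) is not None]
        _, p = mann_whitney_u(sev, nsv)
        if kind == "mean":
            fmt = lambda v: f"{np.mean(v):.1f} ({np.std(v, ddof=1):.1f})"
        else:
            fmt = lambda v: f"{np.median(v):g} ({min(v):g}-{max(v):g})"
        rows.append(
            {"variable": name, "no_severe": fmt(nsv), "severe": fmt(sev), "p_value": p}
        )

    continuous("Gestational age, mean (SD), weeks", lambda r: r.covariates.gestational_age, "mean")
    continuous("Birth weight, mean (SD), grams", lambda r: r.covariates.birth_weight, "mean")

    binary_labels = {
        "sga": "SGA, n (%)",
        "male": "Male sex, n (%)",
        "preeclampsia": "Pre-eclampsia, n (%)",
        "chorioamnionitis": "Chorioamnionitis, n (%)",
        "vaginal_delivery": "Vaginal delivery, n (%)",
        "antenatal_steroids_any": "Any antenatal steroids, n (%)",
        "antenatal_steroids_complete": "Complete antenatal steroids, n (%)",
        "antenatal_magnesium": "Antenatal magnesium sulfate, n (%)",
        "postnatal_steroids": "Postnatal steroids, n (%)",
        "bpd": "BPD diagnosis, n (%)",
        "inotropes": "Inotropic medication administration, n (%)",
        "sepsis": "Culture-positive sepsis, n (%)",
        "nec": "Necrotizing enterocolitis, n (%)",
        "pda_ligation": "PDA ligation, n (%)",
        "seizures": "Clinically apparent seizures, n (%)",
        "severe_rop": "Severe ROP, n (%)",
    }
    for field in BOOLEAN_COVARIATES:
        rows.append(
            _binary_row(
                binary_labels[field],
                [getattr(r.covariates, field) for r in severe],
                [getattr(r.covariates, field) for r in non],
            )
        )

    # race: one r x c Monte-Carlo Freeman-Halton p across categories
    race_counts = np.array(
        [
            [sum(1 for r in grp if r.covariates.race == race) for race in RACES]
            for grp in (non, severe)
        ]
    )
    if race_counts.sum() > 0:
        p_race, _ = fisher_exact_rxc(race_counts[:, race_counts.sum(axis=0) > 0])
        for j, race in enumerate(RACES):
            rows.append(
                {
                    "variable": f"Race: {race}, n (%)",
                    "no_severe": _fmt_pct(int(race_counts[0, j]), len(non)),
                    "severe": _fmt_pct(int(race_counts[1, j]), len(severe)),
                    "p_value": p_race if j == 0 else float("nan"),
                }
            )

    continuous("5-min Apgar score, median (range)", lambda r: r.covariates.apgar5, "median")
    continuous("Ventilator days, median (range)", lambda r: r.covariates.ventilator_days, "median")
    for comp in ("cognitive", "motor", "language"):
        continuous(
            f"Bayley-III {comp} score, mean (SD)",
            lambda r, c=comp: getattr(r.bayley, c),
            "mean",
        )

    # imaging characteristics
    rows.append(
        _binary_row(
            "Any IVH, n (%)",
            [r.injury.ivh_category != "none" for r in severe],
            [r.injury.ivh_category != "none" for r in non],
        )
    )
    rows.append(
        _binary_row(
            "Grade III/IV IVH, n (%)",
            [r.injury.ivh_category == "high" for r in severe],
            [r.injury.ivh_category == "high" for r in non],
        )
    )
    rows.append(
        _binary_row(
            "Any cerebellar hemorrhage, n (%)",
            [r.injury.ch_size != "none" for r in severe],
            [r.injury.ch_size != "none" for r in non],
        )
    )
    rows.append(
        _binary_row(
            "Large cerebellar hemorrhage, n (%)",
            [r.injury.ch_size == "large" for r in severe],
            [r.injury.ch_size == "large" for r in non],
        )
    )
    rows.append(
        _binary_row(
            "Bilateral cerebellar hemorrhage, n (%)",
            [r.injury.ch_bilateral for r in severe],
            [r.injury.ch_bilateral for r in non],
        )
    )
    rows.append(
        _binary_row(
            "Multiple punctate or cystic WMI, n (%)",
            [r.injury.wmi_category == "multiple_or_cystic" for r in severe],
            [r.injury.wmi_category == "multiple_or_cystic" for r in non],
        )
    )
    rows.append(
        _binary_row(
            "Isolated punctate WMI, n (%)",
            [r.injury.wmi_category == "isolated_punctate" for r in severe],
            [r.injury.wmi_category == "isolated_punctate" for r in non],
        )
    )

    def any_injury(r) -> bool:
        return (
            r.injury.ivh_category != "none"
            or r.injury.ch_size != "none"
            or r.injury.wmi_category != "none"
        )

    rows.append(
        _binary_row(
            "Any brain injury, n (%)",
            [any_injury(r) for r in severe],
            [any_injury(r) for r in non],
        )
    )
    continuous(
        "MRI injury score, mean (SD)",
        lambda r: score_injury(r.injury, weights),
        "mean",
    )

    frame = pd.DataFrame(rows, columns=["variable", "no_severe", "severe", "p_value"])
    frame["significant"] = frame["p_value"].apply(
        lambda p: "*" if (not np.isnan(p)) and p < 0.05 else ""
    )
    return frame
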