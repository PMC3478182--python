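"""Dose-response statistics for fluorosis metrics.

The study pipeline this module reproduces: subjects are binned into five
cooking-water fluoride intervals; the per-subject severity is the higher
of the two central-incisor TF scores (and, analogously, the tooth with the
larger ΔQ supplies the subject-level metric triple); association with the
photographic TF score is measured by Spearman's rho; interval separation
by pairwise Mann-Whitney U tests with a simple Bonferroni correction (the
parametric ANOVA path is abandoned when median-centred Levene's test
rejects homogeneity of variances); repeatability by the intraclass
correlation coefficient (two-way random effects, absolute agreement,
single measure); and diagnostic performance by ROC analysis of ΔQ with the
TF <= 2 vs >= 3 case definition.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

METRIC_COLUMNS = (
    "area_ch",
    "delta_f_ch",
    "delta_q_ch",
    "area_blur",
    "delta_f_blur",
    "delta_q_blur",
)
N_INTERVALS = 5
N_PAIRS = N_INTERVALS * (N_INTERVALS - 1) // 2  # Bonferroni family: all 10 pairs


@dataclass(frozen=True)
class WaterIntervalScheme:
    """Cut points partitioning cooking-water fluoride (ppm) into 5 intervals.

    Lower-inclusive half-open intervals: [0, .20), [.20, .60), [.60, .90),
    [.90, 1.60), [1.60, inf); ppm values are rounded to 2 decimal places
    first, matching the precision of the published interval labels.
    """

    boundaries: tuple[float, ...] = (0.20, 0.60, 0.90, 1.60)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if len(b) != N_INTERVALS - 1 or (np.diff(b) <= 0).any():
            raise ValueError("boundaries must be 4 strictly increasing cut points")


def assign_interval(ppm: float, scheme: WaterIntervalScheme = WaterIntervalScheme()) -> int:
    """Map a water-fluoride concentration to its interval label 0-4."""
    if ppm < 0:
        raise ValueError("water fluoride concentration cannot be negative")
    rounded = round(float(ppm), 2)
    return int(np.searchsorted(scheme.boundaries, rounded, side="right"))


def subject_level(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-tooth rows to one subject-level row per capture.

    ``tf_subject`` is the higher of the two incisor TF scores.  For each
    method the subject-level metric triple comes from the tooth with the
    larger ΔQ (the max rule the study states for TF, applied analogously
    to the metrics so subject-level comparisons stay coherent).
    Rows flagged ``excluded`` are skipped.
    """
    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    out_rows = []
    keep_cols = [c for c in ("water_ppm", "water_interval") if c in df.columns]
    for (subject, capture), grp in df.groupby(["subject_id", "capture_index"], sort=True):
        row: dict = {"subject_id": subject, "capture_index": capture}
        for c in keep_cols:
            row[c] = grp[c].iloc[0]
        row["tf_subject"] = int(grp["tf"].max()) if "tf" in grp.columns else np.nan
        for method in ("ch", "blur"):
            dq = f"delta_q_{method}"
            if dq not in grp.columns:
                continue
            best = grp.loc[grp[dq].idxmax()]
            for stem in ("area", "delta_f", "delta_q"):
                row[f"{stem}_{method}"] = float(best[f"{stem}_{method}"])
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def spearman_table(
    records: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
    against: str = "tf_subject",
) -> pd.DataFrame:
    """Spearman's rho (average ranks for ties, t-approximation p) per metric."""
    rows = []
    y = records[against].to_numpy(dtype=float)
    for metric in metrics:
        if metric not in records.columns:
            continue
        x = records[metric].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"metric": metric, "rho": np.nan, "p": np.nan, "n": len(x)})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"metric": metric, "rho": float(rho), "p": float(p), "n": len(x)})
    return pd.DataFrame(rows)


def mann_whitney(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; returns (U of x, p).

    Tie-aware exact enumeration of all C(n1+n2, n1) rank splits when both
    samples have at most ``exact_max_n`` observations; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if n1 <= exact_max_n and n2 <= exact_max_n:
        ranks = stats.rankdata(np.concatenate([x, y]))
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        count = 0
        total = 0
        target = abs(u_obs - mu) - 1e-12
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            total += 1
            if abs(u - mu) >= target:
                count += 1
        return float(u_obs), count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def interval_separation(
    records: pd.DataFrame, metric: str, exact_max_n: int = 8
) -> dict:
    """Pairwise interval comparisons for one metric (the dose-response test).

    Runs median-centred Levene's test and one-way ANOVA to report which
    path the study's decision rule selects, then the 10 unordered pairwise
    Mann-Whitney U tests with a simple Bonferroni correction
    (adjusted p = min(1, 10 × p)).  Returns raw and adjusted 5×5 p-value
    tables (NaN on the diagonal and for non-computable pairs).
    """
    groups = {
        int(k): g[metric].dropna().to_numpy(dtype=float)
        for k, g in records.groupby("water_interval")
    }
    present = [k for k in range(N_INTERVALS) if len(groups.get(k, ())) >= 2]
    raw = np.full((N_INTERVALS, N_INTERVALS), np.nan)
    adj = np.full((N_INTERVALS, N_INTERVALS), np.nan)
    for i, j in itertools.combinations(range(N_INTERVALS), 2):
        if i not in present or j not in present:
            continue
        _, p = mann_whitney(groups[i], groups[j], exact_max_n)
        raw[i, j] = raw[j, i] = p
        adj[i, j] = adj[j, i] = min(1.0, N_PAIRS * p)
    levene_p = anova_p = np.nan
    if len(present) >= 2:
        samples = [groups[k] for k in present]
        try:
            levene_p = float(stats.levene(*samples, center="median").pvalue)
            anova_p = float(stats.f_oneway(*samples).pvalue)
        except Exception:
            pass
    path = "nonparametric" if (np.isnan(levene_p) or levene_p < 0.05) else "anova"
    idx = pd.Index(range(N_INTERVALS), name="water_interval")
    return {
        "metric": metric,
        "p_raw": pd.DataFrame(raw, index=idx, columns=idx),
        "p_adjusted": pd.DataFrame(adj, index=idx, columns=idx),
        "levene_p": levene_p,
        "anova_p": anova_p,
        "path": path,
    }


def icc_repeatability(
    records: pd.DataFrame, metrics: tuple[str, ...] = METRIC_COLUMNS
) -> pd.DataFrame:
    """ICC between capture 1 and capture 2 subject-level metrics.

    Reports the two-way random-effects, absolute-agreement, single-measure
    form ICC(2,1) as the headline, with the consistency form ICC(3,1)
    alongside.  Needs at least 5 complete pairs; undefined ICCs (zero
    between-subject variance) are reported as NaN.
    """
    rows = []
    for metric in metrics:
        if metric not in records.columns:
            continue
        wide = records.pivot_table(
            index="subject_id", columns="capture_index", values=metric
        )
        if not {1, 2}.issubset(wide.columns):
            rows.append({"metric": metric, "icc2_1": np.nan, "icc3_1": np.nan, "n_pairs": 0})
            continue
        pairs = wide[[1, 2]].dropna()
        n = len(pairs)
        if n < 5:
            rows.append({"metric": metric, "icc2_1": np.nan, "icc3_1": np.nan, "n_pairs": n})
            continue
        long = pairs.reset_index().melt(
            id_vars="subject_id", var_name="capture", value_name="value"
        )
        if np.ptp(pairs.to_numpy()) == 0 or pairs.mean(axis=1).std() == 0:
            rows.append({"metric": metric, "icc2_1": np.nan, "icc3_1": np.nan, "n_pairs": n})
            continue
        res = pg.intraclass_corr(
            data=long, targets="subject_id", raters="capture", ratings="value"
        ).set_index("Type")

        def _lookup(*labels: str) -> float:
            for lab in labels:  # pingouin label scheme differs by version
                if lab in res.index:
                    return float(res.loc[lab, "ICC"])
            raise KeyError(labels)

        rows.append(
            {
                "metric": metric,
                "icc2_1": _lookup("ICC2", "ICC(A,1)"),
                "icc3_1": _lookup("ICC3", "ICC(C,1)"),
                "n_pairs": n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RocResult:
    """ROC curve of a severity metric against the TF >= 3 case definition."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_point: tuple[float, float, float]  # (threshold, sens, spec)
    n_positive: int
    n_negative: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_analysis(
    records: pd.DataFrame, metric: str, tf_positive: int = 3
) -> RocResult:
    """ROC for classifying fluorosis (TF >= ``tf_positive``) from a metric.

    The curve sweeps every observed metric value as a "predict positive
    when metric >= threshold" rule; AUC by the trapezoid rule (which makes
    AUC equal the tie-adjusted Mann-Whitney U/(n1 n2)); the operating
    point maximizes Youden's J, ties resolved to the lower threshold.
    """
    values = records[metric].to_numpy(dtype=float)
    labels = records["tf_subject"].to_numpy(dtype=float) >= tf_positive
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    thresholds = np.concatenate([[np.inf], np.unique(values)[::-1]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for k, thr in enumerate(thresholds):
        pred = values >= thr
        sens[k] = (pred & labels).sum() / n_pos
        spec[k] = (~pred & ~labels).sum() / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    k = best[np.argmin(thresholds[best])]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        operating_point=(float(thresholds[k]), float(sens[k]), float(spec[k])),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def _tf_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """TF-score counts per interval, grouping scores of 4 or higher as 4+."""
    tf = records["tf_subject"].clip(upper=4)
    tab = (
        pd.crosstab(records["water_interval"], tf)
        .reindex(columns=range(5), fill_value=0)
    )
    tab.columns = ["0", "1", "2", "3", "4+"]
    return tab


def dose_response_report(
    records: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
    roc_metrics: tuple[str, ...] = ("delta_q_ch", "delta_q_blur"),
) -> dict:
    """Descriptives, interval separation, correlations, ICC and ROC.

    ``records`` is the long per-tooth table (both captures).  Returns a
    dict of DataFrames/objects; degenerate inputs degrade gracefully
    (single interval -> descriptives only, with a notice).
    """
    if records.empty:
        raise ValueError("empty input")
    subj = subject_level(records[records["capture_index"] == 1])
    present_metrics = tuple(m for m in metrics if m in subj.columns)
    notices: list[str] = []

    agg = subj.groupby("water_interval").agg(
        n=("subject_id", "count"),
        tf_mean=("tf_subject", "mean"),
        tf_sd=("tf_subject", "std"),
        **{
            f"{m}_{s}": (m, s)
            for m in present_metrics
            for s in ("mean", "std", "median", "min", "max")
        },
    )

    n_intervals = subj["water_interval"].nunique()
    separation = {}
    if n_intervals >= 2:
        for m in present_metrics:
            separation[m] = interval_separation(subj, m)
    else:
        notices.append("single interval: separation tests skipped")

    correlations = spearman_table(subj, present_metrics)

    both = subject_level(records)
    icc = icc_repeatability(both, present_metrics)

    roc: dict[str, RocResult] = {}
    for m in roc_metrics:
        if m not in subj.columns:
            continue
        try:
            roc[m] = roc_analysis(subj, m)
        except ValueError as exc:
            notices.append(f"ROC for {m} skipped: {exc}")

    return {
        "subject_table": subj,
        "descriptives": agg,
        "tf_distribution": _tf_distribution(subj),
        "separation": separation,
        "correlations": correlations,
        "icc": icc,
        "roc": roc,
        "notices": notices,
    }


def render_report_text(report: dict) -> str:
    """Human-readable summary of a dose-response report."""
    lines = ["Fluorosis dose-response report", "=" * 32, ""]
    lines.append("Per-interval descriptives (subject level):")
    lines.append(report["descriptives"].round(4).to_string())
    lines.append("")
    lines.append("TF-score distribution (4+ grouped):")
    lines.append(report["tf_distribution"].to_string())
    lines.append("")
    for metric, sep in report["separation"].items():
        lines.append(
            f"Pairwise Mann-Whitney (Bonferroni x{N_PAIRS}) for {metric} "
            f"[Levene p={sep['levene_p']:.4g} -> {sep['path']} path]:"
        )
        lines.append(sep["p_adjusted"].round(4).to_string())
        lines.append("")
    lines.append("Spearman correlations vs photographic TF score:")
    lines.append(report["correlations"].round(4).to_string(index=False))
    lines.append("")
    lines.append("Repeatability (ICC):")
    lines.append(report["icc"].round(4).to_string(index=False))
    lines.append("")
    for metric, roc in report["roc"].items():
        thr, sens, spec = roc.operating_point
        lines.append(
            f"ROC {metric}: AUC={roc.auc:.4f}, operating point thr={thr:.4g} "
            f"(sens={100 * sens:.2f}%, spec={100 * spec:.2f}%), "
            f"n+={roc.n_positive}, n-={roc.n_negative}"
        )
    for notice in report["notices"]:
        lines.append(f"NOTE: {notice}")
    return "\n".join(lines) + "\n"
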