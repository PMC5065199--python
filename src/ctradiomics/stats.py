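"""Variability quantification (coefficients of variation) and feature testing.

Variability of a radiomic feature is quantified per lesion as the coefficient
of variation, CV = sample SD / |mean| x 100%, over the repeated measurements
that define a variability source:

    intra_reader   — reader 1, sessions 1 vs 2, on FBP images
    inter_reader   — reader 1 vs reader 2, first session, on FBP images
    recon_FBP_S3 / recon_FBP_S5 / recon_S3_S5
                   — reader 1, first session, across the two named algorithms

Per-feature summary CV is the mean of per-lesion CVs (median via config), and
is categorized with closed upper bounds: very small (CV <= 5%), small
(5 < CV <= 10%), intermediate (10 < CV <= 20%), large (CV > 20%).

Feature differences across the three reconstruction algorithms are tested
with a normality-gated ladder: Shapiro-Wilk per algorithm, then
repeated-measures ANOVA with Tukey post-hoc if all groups look normal,
otherwise Friedman with pairwise Wilcoxon signed-rank, Bonferroni-adjusted
over the three pairs.  A feature that is bitwise identical across algorithms
for every lesion (the shape features under ROI propagation) yields an
explicit not-available sentinel rather than a p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import FEATURE_NAMES, MeasurementRecord

__all__ = [
    "CV_CATEGORIES",
    "VARIABILITY_SOURCES",
    "VariabilitySummary",
    "ComparisonResult",
    "coefficient_of_variation",
    "categorize_cv",
    "variability_summary",
    "variability_table",
    "rm_anova",
    "compare_feature_across_algorithms",
    "compare_variability_sources",
]

#: (upper bound %, category label), closed upper bounds as printed.
CV_CATEGORIES = ((5.0, "very_small"), (10.0, "small"), (20.0, "intermediate"))

VARIABILITY_SOURCES = (
    "intra_reader",
    "inter_reader",
    "recon_FBP_S3",
    "recon_FBP_S5",
    "recon_S3_S5",
)

NOT_AVAILABLE = "not_available"


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent: sample SD over |mean|.

    Returns NaN with a warning when the mean is zero (CV ill-posed).  The
    absolute mean keeps the CV finite and positive for sign-crossing features
    such as HU mean and skewness.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(f"need at least 2 values for a CV, got {values.size}")
    mean = values.mean()
    if mean == 0.0:
        warnings.warn("CV undefined for zero mean")
        return math.nan
    return float(values.std(ddof=1) / abs(mean) * 100.0)


def categorize_cv(cv: float) -> str:
    """Map a summary CV (%) to its robustness category (bounds closed)."""
    if math.isnan(cv):
        return NOT_AVAILABLE
    for bound, label in CV_CATEGORIES:
        if cv <= bound:
            return label
    return "large"


@dataclass
class VariabilitySummary:
    feature_name: str
    source: str
    per_lesion_cv: np.ndarray
    summary_cv: float
    category: str


@dataclass
class ComparisonResult:
    feature_name: str
    grouping: str
    test_used: str
    statistic: float
    p_value: float
    significant_after_correction: bool
    alpha_corrected: float


def _index_records(records: Iterable[MeasurementRecord]):
    idx: dict[tuple, MeasurementRecord] = {}
    for rec in records:
        if rec.key in idx:
            raise ValueError(f"duplicate measurement record {rec.key}")
        idx[rec.key] = rec
    return idx


def _source_keys(source: str, readers: list[str], sessions: list[int], baseline: str):
    """The (reader, session, algorithm) tuples whose feature values enter one CV."""
    r1 = readers[0]
    s1 = sessions[0]
    if source == "intra_reader":
        if len(sessions) < 2:
            raise ValueError("intra_reader variability needs two read sessions")
        return [(r1, s1, baseline), (r1, sessions[1], baseline)]
    if source == "inter_reader":
        if len(readers) < 2:
            raise ValueError("inter_reader variability needs two readers")
        return [(r1, s1, baseline), (readers[1], s1, baseline)]
    if source.startswith("recon_"):
        a, b = source[len("recon_"):].split("_")
        return [(r1, s1, a), (r1, s1, b)]
    raise ValueError(f"unknown variability source {source!r}")


def variability_summary(
    records: Iterable[MeasurementRecord],
    source: str,
    feature_name: str,
    aggregate: str = "mean",
    baseline_algorithm: str = "FBP",
) -> VariabilitySummary:
    """Per-lesion CVs and summary CV for one feature and variability source.

    Readers and sessions are ordered lexicographically; the first reader is
    the reference for intra-reader and reconstruction sources.  Raises,
    listing the lesions, if any lesion lacks the required measurement pair.
    """
    if feature_name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature_name!r}")
    recs = list(records)
    idx = _index_records(recs)
    lesions = sorted({r.lesion_id for r in recs})
    readers = sorted({r.reader_id for r in recs})
    sessions = sorted({r.session for r in recs})
    keys = _source_keys(source, readers, sessions, baseline_algorithm)
    missing = [
        lesion for lesion in lesions if any((lesion, *k) not in idx for k in keys)
    ]
    if missing:
        raise ValueError(f"missing records for source {source!r} on lesions: {missing}")
    per_lesion = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-mean CVs surface as NaN below
        for lesion in lesions:
            vals = [getattr(idx[(lesion, *k)].features, feature_name) for k in keys]
            per_lesion.append(
                math.nan if any(math.isnan(v) for v in vals)
                else coefficient_of_variation(vals)
            )
    per_lesion = np.asarray(per_lesion)
    finite = per_lesion[np.isfinite(per_lesion)]
    if finite.size == 0:
        summary = math.nan
    elif aggregate == "mean":
        summary = float(finite.mean())
    elif aggregate == "median":
        summary = float(np.median(finite))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return VariabilitySummary(
        feature_name=feature_name,
        source=source,
        per_lesion_cv=per_lesion,
        summary_cv=summary,
        category=categorize_cv(summary),
    )


def variability_table(
    records: Iterable[MeasurementRecord],
    sources: Sequence[str] = VARIABILITY_SOURCES,
    features: Sequence[str] = FEATURE_NAMES,
    aggregate: str = "mean",
) -> dict[tuple[str, str], VariabilitySummary]:
    """Variability summaries for every (feature, source) combination."""
    recs = list(records)
    return {
        (f, s): variability_summary(recs, s, f, aggregate=aggregate)
        for f in features
        for s in sources
    }


def rm_anova(data: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA F-test on an n x k within-subject table.

    Rows are subjects (lesions), columns are conditions (algorithms).
    Returns (F, p) with df = (k-1, (k-1)(n-1)).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError(f"need an n x k table with n, k >= 2, got shape {data.shape}")
    n, k = data.shape
    grand = data.mean()
    ss_treat = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_treat - ss_subj
    df_treat = k - 1
    df_err = (k - 1) * (n - 1)
    if ss_err <= 0:
        return math.inf, 0.0
    f_stat = (ss_treat / df_treat) / (ss_err / df_err)
    return float(f_stat), float(sps.f.sf(f_stat, df_treat, df_err))


def _na_result(feature_name: str, grouping: str, alpha: float) -> ComparisonResult:
    return ComparisonResult(
        feature_name=feature_name,
        grouping=grouping,
        test_used=NOT_AVAILABLE,
        statistic=math.nan,
        p_value=math.nan,
        significant_after_correction=False,
        alpha_corrected=alpha,
    )


def compare_feature_across_algorithms(
    values_by_algorithm: Mapping[str, Sequence[float]],
    feature_name: str = "",
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """Test one feature across the reconstruction algorithms, per lesion.

    ``values_by_algorithm`` maps each algorithm label to the per-lesion
    values, aligned across algorithms.  Shapiro-Wilk gates the ladder: all
    groups normal -> repeated-measures ANOVA + Tukey post-hoc; otherwise
    Friedman + pairwise Wilcoxon signed-rank with Bonferroni over the pairs.
    Returns the omnibus result plus one result per algorithm pair.
    """
    labels = list(values_by_algorithm)
    if len(labels) < 3:
        raise ValueError("need at least three algorithm groups")
    groups = [np.asarray(values_by_algorithm[lab], dtype=float) for lab in labels]
    n = groups[0].size
    if any(g.size != n for g in groups):
        raise ValueError("groups must be aligned per lesion (equal lengths)")
    if n < 3:
        raise ValueError(f"need at least 3 lesions, got {n}")
    grouping = " vs ".join(labels)
    table = np.column_stack(groups)
    if np.all(table.max(axis=1) == table.min(axis=1)):
        # identical across algorithms for every lesion — the shape-feature case
        return _na_result(feature_name, grouping, alpha), [
            _na_result(feature_name, f"{a} vs {b}", alpha)
            for a, b in _pairs(labels)
        ]

    normal = all(
        g.std() > 0 and sps.shapiro(g).pvalue > normality_alpha for g in groups
    )
    posthoc: list[ComparisonResult] = []
    if normal:
        f_stat, p = rm_anova(table)
        omnibus = ComparisonResult(
            feature_name, grouping, "rm_anova", f_stat, p, p < alpha, alpha
        )
        tk = sps.tukey_hsd(*groups)
        for (ia, a), (ib, b) in _pairs(list(enumerate(labels))):
            p_pair = float(tk.pvalue[ia, ib])
            stat_pair = float(tk.statistic[ia, ib])
            posthoc.append(
                ComparisonResult(
                    feature_name, f"{a} vs {b}", "tukey", stat_pair, p_pair,
                    p_pair < alpha, alpha,
                )
            )
    else:
        try:
            stat, p = sps.friedmanchisquare(*groups)
        except ValueError:
            return _na_result(feature_name, grouping, alpha), [
                _na_result(feature_name, f"{a} vs {b}", alpha)
                for a, b in _pairs(labels)
            ]
        omnibus = ComparisonResult(
            feature_name, grouping, "friedman", float(stat), float(p), p < alpha, alpha
        )
        n_pairs = len(list(_pairs(labels)))
        alpha_corr = alpha / n_pairs
        for a, b in _pairs(labels):
            ga = np.asarray(values_by_algorithm[a], dtype=float)
            gb = np.asarray(values_by_algorithm[b], dtype=float)
            if np.all(ga == gb):
                posthoc.append(_na_result(feature_name, f"{a} vs {b}", alpha_corr))
                continue
            stat_w, p_w = sps.wilcoxon(ga, gb)
            posthoc.append(
                ComparisonResult(
                    feature_name, f"{a} vs {b}", "wilcoxon_signed_rank",
                    float(stat_w), float(p_w), p_w < alpha_corr, alpha_corr,
                )
            )
    return omnibus, posthoc


def _pairs(items):
    return [(items[i], items[j]) for i in range(len(items)) for j in range(i + 1, len(items))]


def compare_variability_sources(
    per_lesion_cv_a: Sequence[float],
    per_lesion_cv_b: Sequence[float],
    feature_name: str = "",
    grouping: str = "",
    alpha: float = 0.05,
    family_size: int = 1,
) -> ComparisonResult:
    """Paired Wilcoxon signed-rank on per-lesion CVs from two sources.

    ``family_size`` applies a Bonferroni correction for the number of CV
    comparisons performed in one run (e.g. 4 gives the 0.05/4 ~ 0.013
    threshold).  All-zero differences return the not-available sentinel.
    """
    a = np.asarray(per_lesion_cv_a, dtype=float)
    b = np.asarray(per_lesion_cv_b, dtype=float)
    if a.size != b.size:
        raise ValueError("CV lists must be paired by lesion (equal lengths)")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    alpha_corr = alpha / family_size
    if a.size < 2 or np.all(a == b):
        return _na_result(feature_name, grouping, alpha_corr)
    stat, p = sps.wilcoxon(a, b)
    return ComparisonResult(
        feature_name, grouping, "wilcoxon_signed_rank", float(stat), float(p),
        p < alpha_corr, alpha_corr,
    )
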