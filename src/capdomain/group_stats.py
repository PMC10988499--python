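"""Univariate group statistics for supply indices and metabolomics.

* One-way ANOVA with Tukey HSD post hoc comparisons for structural and
  functional indices across stimulation groups.
* Fold change + equal-variance Student's t-test + Benjamini-Hochberg
  FDR adjustment ("volcano" table) for metabolite matrices.
* The compound-identification acceptance filter (accurate mass,
  retention time, isotope-pattern match).

Statistical significance is assigned at P <= 0.05 (boundary
inclusive) unless callers choose otherwise.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    AnovaResult,
    CompoundRecord,
    FeatureRecord,
    MetaboliteMatrix,
    ValidationError,
    VolcanoRow,
)

ALPHA_DEFAULT = 0.05

# compound-identification acceptance tolerances
MASS_TOL_PPM = 5.0
RT_TOL_S = 30.0
ISOTOPE_MIN_PCT = 90.0


def one_way_anova(
    groups: Sequence[np.ndarray], labels: Optional[Sequence[str]] = None
) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD on all group pairs.

    ``groups`` is a sequence of 1-D samples (each n >= 2). Tukey
    adjusted p-values come from the studentized-range distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs at least two observations")
    allv = np.concatenate(arrays)
    if np.var(allv) == 0:
        raise ValidationError("total variance is zero; ANOVA degenerate")
    within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if within == 0:
        raise ValidationError(
            "zero within-group variance; the F statistic is unbounded"
        )
    F, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = allv.size
    df = (k - 1, n - k)

    tuk = stats.tukey_hsd(*arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    pairs: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrays[i].mean() - arrays[j].mean())
            pairs[(labels[i], labels[j])] = (diff, float(tuk.pvalue[i, j]))
    return AnovaResult(F=float(F), df=df, p=float(p), tukey=pairs)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, in input order.

    Sort ascending, take adj_i = min_{j >= i} (p_j * m / j) capped at
    1, and return adjusted values aligned with the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def volcano_table(
    matrix: MetaboliteMatrix,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
    log_space_fold: bool = False,
) -> list[VolcanoRow]:
    """Per-compound fold change, t-test p and BH-FDR for two groups.

    Fold change is log2(mean_b / mean_a) on raw intensities by default
    (``log_space_fold`` switches to the difference of group means of
    log2 intensities). The t-test is the equal-variance Student's test
    unless ``equal_var=False`` selects Welch's variant. Compounds
    whose group mean is zero get an undefined (NaN) fold change and
    are flagged rather than dropped.
    """
    ma, mb = matrix.group_mask(group_a), matrix.group_mask(group_b)
    if ma.sum() < 2 or mb.sum() < 2:
        raise ValidationError("both groups need at least two samples")
    A = matrix.intensities[ma]  # (na, m)
    B = matrix.intensities[mb]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        if log_space_fold:
            la = np.where(A > 0, np.log2(A), np.nan)
            lb = np.where(B > 0, np.log2(B), np.nan)
            l2fc = np.nanmean(lb, axis=0) - np.nanmean(la, axis=0)
        else:
            l2fc = np.log2(mean_b / mean_a)
    flagged = (mean_a == 0) | (mean_b == 0)
    l2fc = np.where(flagged, np.nan, l2fc)

    tres = stats.ttest_ind(B, A, axis=0, equal_var=equal_var)
    p = np.asarray(tres.pvalue, dtype=float)
    # zero pooled variance gives p = 0 / NaN; report the smallest
    # representable positive p instead of dropping the row
    degenerate = ~np.isfinite(p) | (p == 0)
    diff_means = mean_a != mean_b
    p[degenerate & diff_means] = np.finfo(float).tiny
    p[degenerate & ~diff_means] = 1.0
    adj = bh_fdr(p)
    return [
        VolcanoRow(
            compound_id=matrix.compound_ids[j],
            log2_fold_change=float(l2fc[j]),
            raw_p=float(p[j]),
            fdr_adjusted_p=float(adj[j]),
            flagged=bool(flagged[j]),
        )
        for j in range(matrix.n_compounds)
    ]


def match_compound(
    feature: FeatureRecord,
    record: CompoundRecord,
    mass_tol_ppm: float = MASS_TOL_PPM,
    rt_tol_s: float = RT_TOL_S,
    isotope_min_pct: float = ISOTOPE_MIN_PCT,
) -> bool:
    """Compound-identification acceptance filter.

    Accept iff the measured/theoretical mass difference is below
    ``mass_tol_ppm`` (strict), the retention-time difference is below
    ``rt_tol_s`` (strict) and the isotope-pattern match exceeds
    ``isotope_min_pct`` (strict).
    """
    dmass_ppm = (
        abs(feature.measured_mass - record.theoretical_mass)
        / record.theoretical_mass
        * 1e6
    )
    drt = abs(feature.retention_time - record.retention_time)
    return (
        dmass_ppm < mass_tol_ppm
        and drt < rt_tol_s
        and feature.isotope_match > isotope_min_pct
    )


def group_zscore_table(matrix: MetaboliteMatrix) -> tuple[np.ndarray, list[str]]:
    """Group-mean z-score table (groups x compounds).

    Each compound's group means are standardised across groups
    (mean 0, SD 1); a plain-numbers substitute for a clustered
    heatmap. Returns (z, group_order).
    """
    groups = list(dict.fromkeys(matrix.sample_groups))  # stable order
    means = np.vstack(
        [matrix.intensities[matrix.group_mask(g)].mean(axis=0) for g in groups]
    )
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (means - mu) / sd
    return z, groups
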