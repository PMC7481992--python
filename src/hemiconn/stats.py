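"""Cohort statistics: normality, ANOVA/Tukey, cross-modal correlation, PLS.

Per ADHD subgroup the pipeline asks, for every (area, band) cell, how
strongly the fMRI connectome asymmetry and the EEG band-power asymmetry
covary across subjects: Pearson correlation with its two-sided t-based p,
and a one-latent-component partial-least-squares regression whose goodness
of fit R² is tested by permutation of the response.  With a single
predictor, one-component PLS coincides with simple least squares, so its R²
equals the squared Pearson correlation — that identity is used as a fast
path (and checked against scikit-learn in the test suite).  Raw p-values are
reported alongside Benjamini–Hochberg q-values; group differences per cell
are tested by one-way ANOVA with Tukey-HSD-corrected pairwise comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .asymmetry import NO_BAND, WHOLE, AsymmetryProfile
from .exceptions import StatsError
from .montage import AREAS

__all__ = [
    "shapiro_wilk",
    "cross_subject_correlation",
    "pls_fit",
    "anova_tukey",
    "AnovaResult",
    "CohortStats",
    "run_cohort_analysis",
]


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p for normality; degenerate input yields (nan, nan)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise StatsError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if not np.all(np.isfinite(x)):
        raise StatsError("Shapiro-Wilk input contains non-finite values")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: Shapiro-Wilk W undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def cross_subject_correlation(
    ai_a: Sequence[float], ai_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson r across subjects with the two-sided t-based p-value."""
    x = np.asarray(ai_a, dtype=float)
    y = np.asarray(ai_b, dtype=float)
    if x.size != y.size:
        raise StatsError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise StatsError(f"need at least 3 subjects, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("correlation input contains non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("zero-variance input to cross-subject correlation")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _pls1_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R² of a one-latent-component PLS regression of y on x.

    Scores are t = Xc w with w ∝ Xcᵀ yc; y is regressed on t.  For a single
    predictor this reduces to simple least squares (R² = r²).
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    w = xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        return 0.0
    t = xc @ (w / norm)
    tt = float(t @ t)
    if tt == 0:
        return 0.0
    resid = yc - t * (float(t @ yc) / tt)
    sstot = float(yc @ yc)
    return 1.0 - float(resid @ resid) / sstot


def pls_fit(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-component PLS R² with a permutation p-value.

    Parameters
    ----------
    x
        Predictors per subject: shape ``(n,)`` or ``(n, p)``.
    y
        Response per subject.
    n_perm
        Permutations of ``y`` for the p-value ((k+1)/(n+1) estimator);
        ``0`` skips the test and returns ``p = nan``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = y.size
    if x.shape[0] != n:
        raise StatsError(f"x has {x.shape[0]} rows but y has {n}")
    if n < 5:
        raise StatsError(f"PLS requires at least 5 subjects, got {n}")
    if y.std() == 0 or np.all(x.std(axis=0) == 0):
        raise StatsError("degenerate variance in PLS input")

    r2 = _pls1_r2(x, y)
    if n_perm <= 0:
        return r2, float("nan")
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if _pls1_r2(x, yp) >= r2:
            k += 1
    return r2, (k + 1) / (n_perm + 1)


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey-HSD-adjusted pairwise comparisons."""

    f: float
    p: float
    pairwise: dict[tuple[str, str], float]
    degenerate: bool = False


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA across groups plus Tukey HSD pairwise adjusted p-values."""
    if len(groups) < 2:
        raise StatsError("ANOVA requires at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise StatsError(f"group {name!r} has n={arr.size} < 2")
        if not np.all(np.isfinite(arr)):
            raise StatsError(f"group {name!r} contains non-finite values")

    pooled_within = np.concatenate([a - a.mean() for a in arrays.values()])
    if np.allclose(pooled_within, 0):
        pairs = {tuple(sorted(p)): float("nan") for p in combinations(arrays, 2)}
        return AnovaResult(float("nan"), float("nan"), pairs, degenerate=True)

    f, p = sps.f_oneway(*arrays.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * a.size for k, a in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    pairwise: dict[tuple[str, str], float] = {}
    uniq = [str(g) for g in tukey.groupsunique]
    for (g1, g2), padj in zip(combinations(uniq, 2), np.atleast_1d(tukey.pvalues)):
        pairwise[tuple(sorted((g1, g2)))] = float(padj)
    return AnovaResult(float(f), float(p), pairwise)


@dataclass
class CohortStats:
    """Tidy result tables of the cohort-level analysis."""

    correlations: pd.DataFrame  # group, metric_pair, band, area, r, p, q, pls_r2, pls_p
    anova: pd.DataFrame  # metric, band, area, F, p, pair columns
    shapiro: pd.DataFrame  # group, metric, band, area, W, p


def _bh_q(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    mask = np.isfinite(p)
    q = np.full_like(p, np.nan, dtype=float)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def _ai_matrix(
    profiles: Sequence[AsymmetryProfile], cell: tuple[str, str, str]
) -> np.ndarray:
    return np.array([p.entries[cell] for p in profiles])


def run_cohort_analysis(
    profiles: Sequence[AsymmetryProfile],
    groups: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    include_fc_eeg: bool = False,
    min_group_n: int = 3,
) -> CohortStats:
    """Full §-style cohort statistics over asymmetry profiles.

    Parameters
    ----------
    profiles
        One :class:`AsymmetryProfile` per subject.
    groups
        Map subject_id -> group label.
    n_perm
        Permutations for the PLS p-value (0 disables the permutation test).
    include_fc_eeg
        Also correlate FC-EEG area AI with power-EEG AI.
    min_group_n
        Groups smaller than this are skipped (with a warning) for the
        per-group correlation analysis.

    Per group (and for the pooled cohort under label ``"all"``), every
    (area, band) cell pairs the FC-fMRI area AI with the power-EEG AI of the
    matching area; Shapiro–Wilk normality, cross-subject Pearson r (with BH
    q-values per group) and one-component PLS R² with permutation p are
    reported.  ANOVA with Tukey HSD compares groups per cell when at least
    two groups are large enough.
    """
    by_group: dict[str, list[AsymmetryProfile]] = {}
    for prof in profiles:
        by_group.setdefault(groups.get(prof.subject_id, "all"), []).append(prof)

    bands = sorted({b for (_, b, _) in profiles[0].entries if b != NO_BAND})
    areas = [a for a in AREAS if ("FC-fMRI", NO_BAND, a) in profiles[0].entries]
    metric_pairs = [("FC-fMRI", "powerEEG")]
    if include_fc_eeg:
        metric_pairs.append(("FC-EEG", "powerEEG"))

    analysis_sets: dict[str, Sequence[AsymmetryProfile]] = dict(by_group)
    if len(by_group) > 1:
        analysis_sets["all"] = list(profiles)

    corr_rows = []
    shapiro_rows = []
    for gname, gprofiles in analysis_sets.items():
        if len(gprofiles) < min_group_n:
            warnings.warn(
                f"group {gname!r} has n={len(gprofiles)} < {min_group_n}; skipped",
                stacklevel=2,
            )
            continue
        for fc_metric, pw_metric in metric_pairs:
            for band in bands:
                for area in areas:
                    x = _ai_matrix(gprofiles, (fc_metric, NO_BAND, area))
                    y = _ai_matrix(gprofiles, (pw_metric, band, area))
                    try:
                        r, p = cross_subject_correlation(x, y)
                    except StatsError:
                        continue
                    if n_perm > 0 and len(gprofiles) >= 5:
                        pls_r2, pls_p = pls_fit(x, y, n_perm=n_perm, seed=seed)
                    else:
                        pls_r2, pls_p = r * r, float("nan")
                    corr_rows.append(
                        {
                            "group": gname,
                            "metric_pair": f"{fc_metric}~{pw_metric}",
                            "band": band,
                            "area": area,
                            "n": len(gprofiles),
                            "r": r,
                            "p": p,
                            "pls_r2": pls_r2,
                            "pls_p": pls_p,
                        }
                    )
        # normality of each AI variable within the group
        for cell in sorted(profiles[0].entries):
            vals = _ai_matrix(gprofiles, cell)
            if vals.size < 3 or np.ptp(vals) == 0:
                continue
            w, p = shapiro_wilk(vals)
            shapiro_rows.append(
                {
                    "group": gname,
                    "metric": cell[0],
                    "band": cell[1],
                    "area": cell[2],
                    "W": w,
                    "p": p,
                }
            )

    correlations = pd.DataFrame(corr_rows)
    if not correlations.empty:
        correlations["q"] = np.nan
        for gname in correlations["group"].unique():
            sel = correlations["group"] == gname
            correlations.loc[sel, "q"] = _bh_q(correlations.loc[sel, "p"].to_numpy())

    anova_rows = []
    eligible = {g: ps for g, ps in by_group.items() if len(ps) >= max(2, min_group_n)}
    if len(eligible) >= 2:
        for cell in sorted(profiles[0].entries):
            data = {g: _ai_matrix(ps, cell) for g, ps in eligible.items()}
            try:
                res = anova_tukey(data)
            except StatsError:
                continue
            row = {
                "metric": cell[0],
                "band": cell[1],
                "area": cell[2],
                "F": res.f,
                "p": res.p,
                "degenerate": res.degenerate,
            }
            for (g1, g2), padj in res.pairwise.items():
                row[f"tukey_{g1}_vs_{g2}"] = padj
            anova_rows.append(row)

    return CohortStats(
        correlations=correlations,
        anova=pd.DataFrame(anova_rows),
        shapiro=pd.DataFrame(shapiro_rows),
    )
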