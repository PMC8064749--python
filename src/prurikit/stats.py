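"""Statistical machinery shared by the electrophysiology and psychophysics stages.

Implements within-subject (repeated-measures) ANOVA for one or two within
factors with the Greenhouse–Geisser sphericity correction, Bonferroni
pairwise post hoc tests, a split-plot (mixed) ANOVA wrapper, and Scheffé
post hoc contrasts on mixed-design cell means.

The RM-ANOVA is computed directly from sums of squares with ε̂ estimated
from the sample covariance of orthonormalised within-subject contrasts —
the classic Greenhouse–Geisser estimator.  It is vectorised so that
simulation-based calibration (thousands of replicate fits) is cheap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "TestResult",
    "gg_epsilon",
    "rm_anova_gg",
    "rm_anova_gg_cube",
    "bonferroni_pairwise",
    "mixed_anova",
    "scheffe_posthoc",
    "paired_t",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class TestResult:
    """One inferential statistic with its provenance."""

    method: str
    statistic: float
    df: Tuple[float, ...]
    p_value: float
    effect: str = ""
    details: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _cell_matrix(
    data: pd.DataFrame, dv: str, subject: str, within: Sequence[str]
) -> Tuple[np.ndarray, List[Tuple], List]:
    """Pivot a long table to a complete subjects × cells matrix.

    Subjects missing any within-cell are dropped (listwise exclusion).
    Returns (matrix, cell index as tuples of factor levels, subject ids).
    """
    wide = data.pivot_table(
        index=subject, columns=list(within), values=dv, aggfunc="mean"
    )
    complete = wide.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("fewer than two subjects with complete within-subject cells")
    cells = [c if isinstance(c, tuple) else (c,) for c in complete.columns]
    return complete.to_numpy(dtype=float), cells, list(complete.index)


def gg_epsilon(y: np.ndarray, contrasts: Optional[np.ndarray] = None) -> float:
    """Greenhouse–Geisser ε̂ for a subjects × conditions score matrix.

    ``contrasts`` is a (k × m) orthonormal matrix whose rows span the
    effect subspace of the m conditions; by default the full (m−1)-dim
    within space (Helmert orthonormalisation).  ε̂ = tr(E)² / (k·tr(E²))
    with E the covariance of the contrast scores, clipped to [1/k, 1].
    """
    m = y.shape[1]
    if contrasts is None:
        contrasts = helmert(m, full=False)
    z = y @ contrasts.T
    e = np.cov(z, rowvar=False)
    e = np.atleast_2d(e)
    k = contrasts.shape[0]
    tr = float(np.trace(e))
    tr2 = float(np.sum(e * e.T))  # tr(E @ E), E symmetric
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (k * tr2)
    return float(np.clip(eps, 1.0 / k, 1.0))


def _one_way_f(y: np.ndarray) -> Tuple[float, float, float, float, float]:
    """F, df1, df2, MS_error and SS_effect for a one-way within design."""
    n, a = y.shape
    grand = y.mean()
    col = y.mean(axis=0)
    row = y.mean(axis=1)
    ss_a = n * float(np.sum((col - grand) ** 2))
    resid = y - col[None, :] - row[:, None] + grand
    ss_err = float(np.sum(resid**2))
    df1 = a - 1
    df2 = (n - 1) * (a - 1)
    ms_err = ss_err / df2
    f = (ss_a / df1) / ms_err if ms_err > 0 else np.inf if ss_a > 0 else 0.0
    return f, df1, df2, ms_err, ss_a


def rm_anova_gg(
    data: pd.DataFrame,
    dv: str,
    within: Union[str, Sequence[str]],
    subject: str,
) -> List[TestResult]:
    """Repeated-measures ANOVA with Greenhouse–Geisser correction.

    Supports one or two within-subject factors (all cells required per
    subject; incomplete subjects are excluded listwise).  For each effect
    the returned :class:`TestResult` carries the uncorrected F and df, the
    GG-corrected p-value as ``p_value``, and ``details`` with ``eps``,
    ``p_uncorrected`` and corrected dfs.  A two-level factor has ε = 1 by
    construction, so its corrected and uncorrected p coincide.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within_list) <= 2:
        raise ValueError("rm_anova_gg supports one or two within factors")
    y, cells, _ = _cell_matrix(data, dv, subject, within_list)

    results: List[TestResult] = []
    if len(within_list) == 1:
        f, df1, df2, _, _ = _one_way_f(y)
        eps = gg_epsilon(y)
        p_unc = float(sps.f.sf(f, df1, df2))
        p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
        results.append(
            TestResult(
                "rm_anova_gg",
                float(f),
                (float(df1), float(df2)),
                p_gg,
                effect=within_list[0],
                details={
                    "eps": eps,
                    "p_uncorrected": p_unc,
                    "df1_corr": eps * df1,
                    "df2_corr": eps * df2,
                },
            )
        )
        return results

    # two within factors: levels in pivot order (sorted), cube n × a × b
    a_levels = sorted({c[0] for c in cells})
    b_levels = sorted({c[1] for c in cells})
    a, b = len(a_levels), len(b_levels)
    if len(cells) != a * b:
        raise ValueError("within-factor design is not fully crossed")
    cube = y.reshape(y.shape[0], a, b)
    return rm_anova_gg_cube(cube, names=(within_list[0], within_list[1]))


def rm_anova_gg_cube(
    cube: np.ndarray, names: Tuple[str, str] = ("A", "B")
) -> List[TestResult]:
    """Two-way within RM-ANOVA (GG-corrected) on a subjects × A × B score cube.

    Low-overhead path used by :func:`rm_anova_gg` and by simulation-based
    calibration.
    """
    n, a, b = cube.shape
    y = cube.reshape(n, a * b)
    results: List[TestResult] = []
    within_list = list(names)

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)

    def _result(name, ss_eff, df_eff, ss_err, df_err, eps):
        ms_err = ss_err / df_err
        f = (ss_eff / df_eff) / ms_err if ms_err > 0 else (np.inf if ss_eff > 0 else 0.0)
        p_unc = float(sps.f.sf(f, df_eff, df_err))
        p_gg = float(sps.f.sf(f, eps * df_eff, eps * df_err))
        return TestResult(
            "rm_anova_gg",
            float(f),
            (float(df_eff), float(df_err)),
            p_gg,
            effect=name,
            details={
                "eps": eps,
                "p_uncorrected": p_unc,
                "df1_corr": eps * df_eff,
                "df2_corr": eps * df_err,
            },
        )

    # main effect A (error: subject × A)
    ss_a = n * b * float(np.sum((m_a - grand) ** 2))
    res_a = m_sa - m_s[:, None] - m_a[None, :] + grand
    ss_as = b * float(np.sum(res_a**2))
    eps_a = gg_epsilon(m_sa)
    results.append(_result(within_list[0], ss_a, a - 1, ss_as, (n - 1) * (a - 1), eps_a))

    # main effect B (error: subject × B)
    ss_b = n * a * float(np.sum((m_b - grand) ** 2))
    res_b = m_sb - m_s[:, None] - m_b[None, :] + grand
    ss_bs = a * float(np.sum(res_b**2))
    eps_b = gg_epsilon(m_sb)
    results.append(_result(within_list[1], ss_b, b - 1, ss_bs, (n - 1) * (b - 1), eps_b))

    # interaction A × B (error: subject × A × B)
    inter = m_ab - m_a[:, None] - m_b[None, :] + grand
    ss_ab = n * float(np.sum(inter**2))
    res_abs = (
        cube
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = float(np.sum(res_abs**2))
    c_ab = np.kron(helmert(a, full=False), helmert(b, full=False))
    eps_ab = gg_epsilon(y, c_ab)
    results.append(
        _result(
            f"{within_list[0]} * {within_list[1]}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_abs,
            (n - 1) * (a - 1) * (b - 1),
            eps_ab,
        )
    )
    return results


def bonferroni_pairwise(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    collapse: Optional[Sequence[str]] = None,
) -> List[TestResult]:
    """Bonferroni-corrected paired t-tests between all levels of a within factor.

    ``collapse`` names additional within factors to average over before
    comparing (the usual marginal-means post hoc).  The family is all
    pairwise comparisons within the factor.
    """
    cols = [within] + (list(collapse) if collapse else [])
    wide = data.pivot_table(index=subject, columns=cols, values=dv, aggfunc="mean")
    if collapse:
        wide = wide.T.groupby(level=0).mean().T
    wide = wide.dropna(axis=0)
    levels = list(wide.columns)
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    out: List[TestResult] = []
    for lo, hi in pairs:
        res = paired_t(wide[lo].to_numpy(), wide[hi].to_numpy())
        p_adj = min(1.0, res.p_value * m)
        out.append(
            TestResult(
                "paired_t_bonferroni",
                res.statistic,
                res.df,
                p_adj,
                effect=f"{lo} vs {hi}",
                details={"p_uncorrected": res.p_value, "n_comparisons": m},
            )
        )
    return out


def mixed_anova(
    data: pd.DataFrame, dv: str, within: str, between: str, subject: str
) -> List[TestResult]:
    """Split-plot ANOVA: one between-subjects and one within-subjects factor.

    Subjects missing a within-cell are excluded listwise.  With a 2-level
    within factor the sphericity correction factor is identically 1, so
    uncorrected p-values are exact.
    """
    import pingouin as pg

    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    keep = counts[counts == n_levels].index
    complete = data[data[subject].isin(keep)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 on degenerate data
        aov = pg.mixed_anova(
            data=complete, dv=dv, within=within, between=between, subject=subject
        )
    results = []
    for _, row in aov.iterrows():
        f = float(row["F"]) if "F" in row and np.isfinite(row.get("F", np.nan)) else np.nan
        if not np.isfinite(f) and float(row["SS"]) == 0.0:
            f, p = 0.0, 1.0  # degenerate all-equal data: no effect
        else:
            p = float(row["p_unc"])
        results.append(
            TestResult(
                "mixed_anova",
                f,
                (float(row["DF1"]), float(row["DF2"])),
                p,
                effect=str(row["Source"]),
                details={"ms": float(row.get("MS", np.nan))},
            )
        )
    return results


def _mixed_error_terms(
    data: pd.DataFrame, dv: str, within: str, between: str, subject: str
) -> Dict[str, float]:
    """Between- and within-subject error mean squares of a split-plot design."""
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    wide = wide.dropna(axis=0)
    groups = data.drop_duplicates(subject).set_index(subject)[between]
    groups = groups.loc[wide.index]
    w = wide.shape[1]
    y = wide.to_numpy(dtype=float)
    subj_mean = y.mean(axis=1)
    g_codes, g_levels = pd.factorize(groups, sort=True)
    n_g = len(g_levels)
    ss_bs = 0.0
    ss_ws = 0.0
    for gi in range(n_g):
        sel = g_codes == gi
        yg = y[sel]
        gm_cells = yg.mean(axis=0)
        gm = yg.mean()
        ss_bs += w * float(np.sum((subj_mean[sel] - gm) ** 2))
        resid = yg - yg.mean(axis=1)[:, None] - gm_cells[None, :] + gm
        ss_ws += float(np.sum(resid**2))
    n_total = y.shape[0]
    df_bs = n_total - n_g
    df_ws = (n_total - n_g) * (w - 1)
    return {
        "ms_bs": ss_bs / df_bs,
        "ms_ws": ss_ws / df_ws,
        "df_bs": df_bs,
        "df_ws": df_ws,
        "n_within": w,
        "n_cells": n_g * w,
    }


def scheffe_posthoc(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    comparisons: Optional[Sequence[Tuple[Tuple[str, str], Tuple[str, str]]]] = None,
) -> List[TestResult]:
    """Scheffé-adjusted pairwise contrasts among split-plot cell means.

    Cells are (between level, within level) pairs.  Within-group
    comparisons (same between level) use the within-subject error term;
    comparisons across groups use the pooled error
    (MS_bs + (w−1)·MS_ws)/w appropriate for cell means in a mixed design.
    Each contrast F is referred to the Scheffé criterion (k−1)·F with
    k = number of cells, i.e. p = sf(F/(k−1); k−1, df_error).

    ``comparisons`` defaults to all cell-mean pairs; each element is a
    pair of (between level, within level) tuples.
    """
    err = _mixed_error_terms(data, dv, within, between, subject)
    cell_means = data.groupby([between, within])[dv].mean()
    cell_ns = data.groupby([between, within])[dv].count()
    cells = list(cell_means.index)
    if comparisons is None:
        comparisons = list(itertools.combinations(cells, 2))
    k = err["n_cells"]
    w = err["n_within"]
    out: List[TestResult] = []
    for c1, c2 in comparisons:
        c1, c2 = tuple(c1), tuple(c2)
        if c1 not in cell_means.index or c2 not in cell_means.index:
            raise ValueError(f"unknown contrast {c1} vs {c2}")
        psi = float(cell_means[c1] - cell_means[c2])
        n1, n2 = int(cell_ns[c1]), int(cell_ns[c2])
        if c1[0] == c2[0]:  # same group: pure within contrast
            var = err["ms_ws"] * (1.0 / n1 + 1.0 / n2)
            df_err = err["df_ws"]
        else:
            ms_pooled = (err["ms_bs"] + (w - 1) * err["ms_ws"]) / w
            var = ms_pooled * (1.0 / n1 + 1.0 / n2)
            df_err = err["df_bs"] + err["df_ws"]
        if var > 0:
            f_psi = psi * psi / var
        else:
            f_psi = 0.0 if psi == 0 else np.inf
        p = float(sps.f.sf(f_psi / (k - 1), k - 1, df_err))
        out.append(
            TestResult(
                "scheffe",
                float(f_psi),
                (float(k - 1), float(df_err)),
                p,
                effect=f"{c1} vs {c2}",
                details={"mean_diff": psi},
            )
        )
    return out


def paired_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Classical paired t-test on per-fiber (or per-subject) response pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if x.size < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = x - y
    if np.allclose(d.var(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TestResult("paired_t", 0.0, (float(x.size - 1),), 1.0)
        raise ValueError("zero variance of differences: t undefined")
    t, p = sps.ttest_rel(x, y)
    return TestResult(
        "paired_t",
        float(t),
        (float(x.size - 1),),
        float(p),
        details={"mean_diff": float(d.mean()), "sem_diff": float(sps.sem(d))},
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson χ² of association on a 2×2 table, no continuity correction.

    Closed form χ² = n(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    Raises on a degenerate table (any zero margin).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("degenerate table: zero margin")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult("chi_square_2x2", float(chi2), (1.0,), p)
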