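"""Brain-wide nodal t-maps, their meta-analysis, and summary-stat tests.

Nodal analyses look beyond identified subnetworks: each region's strength
(mean streamline count over its backbone edges) is compared between groups
with covariate-adjusted t statistics, and the resulting whole-brain t-maps
are meta-analyzed — the hypo-/hyperconnectivity sign split across regions
via chi-square, and map-versus-map location via a paired t-test. Summary-
statistic utilities (chi-square on contingency counts, Welch t and one-way
ANOVA from printed group means/SDs) support demographic-table comparisons
when only aggregate numbers are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectomes import LOBES, Atlas
from .glm import DesignMatrix, contrast_t, fit_edges


@dataclass(frozen=True)
class NodalTMap:
    """Covariate-adjusted contrast t value per brain region."""

    label: str
    t: np.ndarray
    df: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.t)):
            raise ValueError("nodal t map contains non-finite values")


def nodal_t_map(
    strengths: np.ndarray,
    design: DesignMatrix,
    contrast: np.ndarray,
    label: str = "",
) -> NodalTMap:
    """Per-node contrast t from the same GLM machinery as the edge models.

    ``strengths`` is the subjects x nodes matrix of nodal strengths.
    """
    fit = fit_edges(strengths, design)
    stats = contrast_t(fit, design, contrast)
    return NodalTMap(label=label, t=stats.values, df=stats.df2)


class SignProportionResult(NamedTuple):
    counts: np.ndarray      # 2x2: rows = maps, cols = (t<0, t>=0)
    chi2: float
    df: int
    p: float
    n_zero: int             # t == 0 nodes counted as hyperconnectivity, flagged


def sign_proportion_test(
    tmap_a: NodalTMap | np.ndarray, tmap_b: NodalTMap | np.ndarray
) -> SignProportionResult:
    """Chi-square comparison of hypo- (t < 0) vs hyper- (t > 0) region counts.

    Exact zeros are counted on the hyperconnectivity side and reported in
    ``n_zero`` (they are measure-zero for continuous data).
    """
    ta = tmap_a.t if isinstance(tmap_a, NodalTMap) else np.asarray(tmap_a)
    tb = tmap_b.t if isinstance(tmap_b, NodalTMap) else np.asarray(tmap_b)
    if ta.shape != tb.shape:
        raise ValueError("t maps must cover the same regions")
    counts = np.array([
        [int(np.sum(ta < 0)), int(np.sum(ta >= 0))],
        [int(np.sum(tb < 0)), int(np.sum(tb >= 0))],
    ])
    chi2, df, p = chi_square_independence(counts)
    n_zero = int(np.sum(ta == 0) + np.sum(tb == 0))
    return SignProportionResult(counts=counts, chi2=chi2, df=df, p=p, n_zero=n_zero)


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float
    cohens_d: float


def paired_t_maps(
    tmap_a: NodalTMap | np.ndarray, tmap_b: NodalTMap | np.ndarray
) -> PairedTResult:
    """Paired t-test on node-wise differences between two t-maps.

    Cohen's d is the mean difference over the SD of the differences.
    """
    ta = tmap_a.t if isinstance(tmap_a, NodalTMap) else np.asarray(tmap_a, dtype=float)
    tb = tmap_b.t if isinstance(tmap_b, NodalTMap) else np.asarray(tmap_b, dtype=float)
    if ta.shape != tb.shape:
        raise ValueError("t maps must cover the same regions")
    n = len(ta)
    if n < 2:
        raise ValueError("need at least 2 regions for a paired t-test")
    diff = ta - tb
    sd = diff.std(ddof=1)
    if sd == 0:
        return PairedTResult(t=0.0, df=n - 1, p=1.0, cohens_d=0.0)
    res = sps.ttest_rel(ta, tb)
    return PairedTResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue),
        cohens_d=float(diff.mean() / sd),
    )


def paired_t_by_lobe(
    tmap_a: NodalTMap, tmap_b: NodalTMap, atlas: Atlas
) -> pd.DataFrame:
    """Whole-brain and lobe-stratified paired t comparisons of two maps."""
    rows = []
    res = paired_t_maps(tmap_a, tmap_b)
    rows.append({"stratum": "whole_brain", "n_regions": len(tmap_a.t),
                 "t": res.t, "df": res.df, "p": res.p, "cohens_d": res.cohens_d})
    lobe_arr = np.asarray(atlas.lobe)
    for lobe in LOBES:
        sel = lobe_arr == lobe
        if sel.sum() < 2:
            continue
        res = paired_t_maps(tmap_a.t[sel], tmap_b.t[sel])
        rows.append({"stratum": lobe, "n_regions": int(sel.sum()),
                     "t": res.t, "df": res.df, "p": res.p, "cohens_d": res.cohens_d})
    return pd.DataFrame(rows)


def chi_square_independence(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence on an r x c contingency table.

    No continuity correction; df = (r - 1)(c - 1). Zero row or column
    margins are an error.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or np.any(counts < 0):
        raise ValueError("counts must be a nonnegative 2-D table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def welch_t_from_summary(
    n1: int, m1: float, s1: float, n2: int, m2: float, s2: float
) -> tuple[float, float, float]:
    """Welch's two-sample t from group summaries (n, mean, SD).

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def anova_f_from_summary(
    groups: Sequence[tuple[int, float, float]]
) -> tuple[float, int, int, float]:
    """One-way ANOVA F from per-group summaries [(n, mean, SD), ...].

    Between and within sums of squares are reconstructed exactly from the
    summaries; returns (F, df1, df2, p).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for n, _, s in groups:
        if n < 2:
            raise ValueError("each group needs n >= 2")
        if s < 0:
            raise ValueError("group SDs must be nonnegative")
    N = sum(n for n, _, _ in groups)
    grand = sum(n * m for n, m, _ in groups) / N
    ssb = sum(n * (m - grand) ** 2 for n, m, _ in groups)
    ssw = sum((n - 1) * s**2 for n, _, s in groups)
    df1 = len(groups) - 1
    df2 = N - len(groups)
    if ssw == 0:
        raise ValueError("zero within-group variance")
    F = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), df1, df2, p
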