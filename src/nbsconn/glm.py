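"""Edge-wise general linear models with nuisance covariates.

Every edge (or node) is modelled by the same ordinary-least-squares design:
an intercept, the effect under test (group indicator columns with HC as the
reference level, or a centered continuous score), and nuisance covariates
(age, sex, scanner site, optionally age^2 and head motion). Group
comparisons use the omnibus F over the group columns or single-contrast t
statistics; permutation inference supports simple label permutation and the
Freedman-Lane scheme (permuting reduced-model residuals), which respects
exchangeability under nuisance covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectomes import GROUP_LEVELS

PERMUTATION_SCHEMES = ("label", "freedman_lane")


class DesignError(ValueError):
    """Raised for invalid or rank-deficient design matrices."""


@dataclass(frozen=True)
class DesignMatrix:
    """Fixed design shared by all edges.

    ``effect_columns`` indexes the columns under test (group indicators for
    the omnibus/contrast analyses, the score column for continuous models);
    all remaining columns, intercept included, are nuisance.
    """

    X: np.ndarray
    column_names: tuple[str, ...]
    effect_columns: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.column_names):
            raise DesignError("design shape does not match column names")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify offending columns via the QR diagonal
            _, R = np.linalg.qr(X)
            diag = np.abs(np.diag(R))
            bad = [self.column_names[k] for k in np.where(diag < 1e-8 * diag.max())[0]]
            raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")
        object.__setattr__(self, "X", X)
        object.__setattr__(
            self, "effect_columns", np.asarray(self.effect_columns, dtype=np.intp)
        )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return len(self.effect_columns)

    @property
    def nuisance_columns(self) -> np.ndarray:
        mask = np.ones(self.p, dtype=bool)
        mask[self.effect_columns] = False
        return np.where(mask)[0]

    def reduced(self) -> np.ndarray:
        """Design with the effect columns removed (the null model)."""
        return self.X[:, self.nuisance_columns]


def _encode_covariate(cohort: pd.DataFrame, name: str) -> tuple[list[np.ndarray], list[str]]:
    if name == "age2":
        age = cohort["age"].to_numpy(dtype=float)
        a = age - age.mean()
        col = a * a
        return [col - col.mean()], ["age2"]
    if name not in cohort.columns:
        raise DesignError(f"covariate {name!r} not in cohort table")
    series = cohort[name]
    if series.isna().any():
        raise DesignError(f"covariate {name!r} contains missing values")
    if series.dtype == object or str(series.dtype) == "category":
        levels = sorted(pd.unique(series.astype(str)))
        cols, names = [], []
        for lv in levels[1:]:  # first sorted level is the reference
            cols.append((series.astype(str) == lv).to_numpy(dtype=float))
            names.append(f"{name}_{lv}")
        return cols, names
    vals = series.to_numpy(dtype=float)
    return [vals - vals.mean()], [name]


def build_design(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "site"),
    effect: str = "group",
) -> DesignMatrix:
    """Build the shared design matrix from the cohort table.

    ``effect`` is either ``"group"`` (treatment-coded indicators for MDD and
    MDD_ANX with HC as reference — the omnibus / post-hoc contrast design)
    or ``"continuous:<column>"`` for a single mean-centered score such as
    ``continuous:stai_trait``. Categorical covariates are treatment-coded
    against their first sorted level; continuous covariates are centered.
    """
    cols: list[np.ndarray] = [np.ones(len(cohort))]
    names: list[str] = ["intercept"]
    effect_idx: list[int] = []

    if effect == "group":
        groups = cohort["group"].astype(str)
        bad = set(groups) - set(GROUP_LEVELS)
        if bad:
            raise DesignError(f"unknown group labels {sorted(bad)}")
        for lv in GROUP_LEVELS[1:]:
            effect_idx.append(len(cols))
            cols.append((groups == lv).to_numpy(dtype=float))
            names.append(f"group_{lv}")
    elif effect.startswith("continuous:"):
        var = effect.split(":", 1)[1]
        c, nm = _encode_covariate(cohort, var)
        if len(c) != 1:
            raise DesignError(f"continuous effect {var!r} must be numeric")
        if np.ptp(c[0]) == 0:
            raise DesignError(f"continuous effect {var!r} is constant")
        effect_idx.append(len(cols))
        cols.append(c[0])
        names.append(nm[0])
    else:
        raise DesignError(f"unknown effect specification {effect!r}")

    for cov in covariates:
        c, nm = _encode_covariate(cohort, cov)
        cols.extend(c)
        names.extend(nm)

    X = np.column_stack(cols)
    return DesignMatrix(X=X, column_names=tuple(names), effect_columns=np.array(effect_idx))


def group_contrast(design: DesignMatrix, group_a: str, group_b: str) -> np.ndarray:
    """Contrast vector for mean(group_a) - mean(group_b) on a group design."""
    c = np.zeros(design.p)
    for g, sign in ((group_a, 1.0), (group_b, -1.0)):
        if g == GROUP_LEVELS[0]:
            continue  # reference level: zero coefficient
        name = f"group_{g}"
        if name not in design.column_names:
            raise DesignError(f"design has no column for group {g!r}")
        c[design.column_names.index(name)] = sign
    return c


def effect_contrast(design: DesignMatrix) -> np.ndarray:
    """Unit contrast on a single-column effect (continuous designs)."""
    if design.q != 1:
        raise DesignError("effect_contrast requires exactly one effect column")
    c = np.zeros(design.p)
    c[design.effect_columns[0]] = 1.0
    return c


@dataclass(frozen=True)
class EdgeFit:
    """OLS fit of every edge against a common design."""

    coef: np.ndarray      # (p, E)
    resid: np.ndarray     # (n, E)
    rss: np.ndarray       # (E,)
    df_resid: int
    Y: np.ndarray         # reference to the fitted responses
    design: DesignMatrix


@dataclass(frozen=True)
class EdgeStats:
    """Per-edge statistic vector with its null degrees of freedom."""

    values: np.ndarray
    kind: str             # "F" | "t" | "conjunction"
    df1: int
    df2: int
    flags: np.ndarray | None = None  # e.g. zero-variance edges forced to 0


def fit_edges(Y: np.ndarray, design: DesignMatrix) -> EdgeFit:
    """Fit beta-hat = argmin ||y - X beta||^2 simultaneously for all edges."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not np.all(np.isfinite(Y)):
        bad = np.unique(np.where(~np.isfinite(Y))[1])
        raise DesignError(f"non-finite response values in edge columns {bad.tolist()}")
    if Y.shape[0] != design.n:
        raise DesignError("response row count does not match design")
    if design.n <= design.p:
        raise DesignError("need more subjects than design columns")
    coef, _, _, _ = np.linalg.lstsq(design.X, Y, rcond=None)
    resid = Y - design.X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    return EdgeFit(coef=coef, resid=resid, rss=rss,
                   df_resid=design.n - design.p, Y=Y, design=design)


def omnibus_F(fit: EdgeFit, design: DesignMatrix | None = None) -> EdgeStats:
    """Extra-sum-of-squares F test of the effect columns at every edge.

    F = [(RSS0 - RSS1) / q] / [RSS1 / (n - p)], with RSS0 from the reduced
    model that drops the effect columns. Degenerate zero-variance edges get
    F = 0 (flagged) rather than NaN.
    """
    design = design or fit.design
    Z = design.reduced()
    coef0, _, _, _ = np.linalg.lstsq(Z, fit.Y, rcond=None)
    resid0 = fit.Y - Z @ coef0
    rss0 = np.einsum("ij,ij->j", resid0, resid0)
    q, df2 = design.q, fit.df_resid
    denom = fit.rss / df2
    tot = np.einsum("ij,ij->j", fit.Y, fit.Y)
    flags = fit.rss <= 1e-12 * np.maximum(tot, 1.0)
    F = np.zeros_like(fit.rss)
    ok = ~flags
    F[ok] = ((rss0[ok] - fit.rss[ok]) / q) / denom[ok]
    F = np.maximum(F, 0.0)  # guard tiny negative round-off
    return EdgeStats(values=F, kind="F", df1=q, df2=df2, flags=flags)


def contrast_t(fit: EdgeFit, design: DesignMatrix | None, c: np.ndarray) -> EdgeStats:
    """t statistic of the contrast c'beta at every edge (df = n - p)."""
    design = design or fit.design
    c = np.asarray(c, dtype=float)
    if c.shape != (design.p,):
        raise DesignError(f"contrast length {c.shape} does not match p={design.p}")
    XtX = design.X.T @ design.X
    g = float(c @ np.linalg.solve(XtX, c))
    sigma2 = fit.rss / fit.df_resid
    denom = np.sqrt(sigma2 * g)
    tot = np.einsum("ij,ij->j", fit.Y, fit.Y)
    flags = (denom <= 0) | (fit.rss <= 1e-12 * np.maximum(tot, 1.0))
    t = np.zeros_like(fit.rss)
    ok = ~flags
    t[ok] = (c @ fit.coef)[ok] / denom[ok]
    return EdgeStats(values=t, kind="t", df1=1, df2=fit.df_resid, flags=flags)


@dataclass(frozen=True)
class PermutationRealization:
    """One permutation of the subject rows under a named scheme."""

    order: np.ndarray
    scheme: str


def permute_design(
    design: DesignMatrix,
    scheme: str = "freedman_lane",
    rng: np.random.Generator | int | None = None,
) -> PermutationRealization:
    """Draw one permutation realization (the same rows for every edge)."""
    if scheme not in PERMUTATION_SCHEMES:
        raise DesignError(f"unknown permutation scheme {scheme!r}; "
                          f"expected one of {PERMUTATION_SCHEMES}")
    rng = np.random.default_rng(rng)
    return PermutationRealization(order=rng.permutation(design.n), scheme=scheme)


def apply_permutation(
    Y: np.ndarray, design: DesignMatrix, realization: PermutationRealization
) -> tuple[np.ndarray, DesignMatrix]:
    """Materialize the permuted (Y*, X*) pair for one realization.

    ``label``: the effect columns' rows are permuted jointly while the
    covariates stay fixed. ``freedman_lane``: the reduced-model residuals
    are permuted and added back to the reduced-model fit; the design is
    unchanged. Computing the usual statistics on the returned pair yields
    the permuted statistics; the identity order reproduces the observed
    statistics exactly.
    """
    order = realization.order
    if realization.scheme == "label":
        Xp = design.X.copy()
        Xp[:, design.effect_columns] = Xp[order][:, design.effect_columns]
        design_p = DesignMatrix(X=Xp, column_names=design.column_names,
                                effect_columns=design.effect_columns)
        return np.asarray(Y, dtype=float), design_p
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Z = design.reduced()
    coef0, _, _, _ = np.linalg.lstsq(Z, Y, rcond=None)
    fitted0 = Z @ coef0
    resid0 = Y - fitted0
    return fitted0 + resid0[order], design
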