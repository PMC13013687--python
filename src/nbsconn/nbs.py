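"""Network-based statistic: component inference with permutation FWE control.

The NBS thresholds an edge-wise statistic map (F or t), extracts connected
components of the supra-threshold graph, and compares each observed
component's extent (edge count) with the permutation distribution of the
*maximal* null component extent, giving family-wise-error-corrected
p-values at the component level. Beyond the standard omnibus and one-sided
variants this module provides an ordered-pattern test — an edge-wise
conjunction of two one-sided contrasts, used to find subnetworks where one
group is shifted below and another above the reference on the same edges —
and a two-stage continuous (score association) analysis.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .connectomes import Atlas, ConnectomeError, EdgeSet
from .glm import (
    DesignMatrix,
    EdgeStats,
    contrast_t,
    effect_contrast,
    fit_edges,
    omnibus_F,
)

DIRECTIONS = ("two_sided_F", "greater", "less", "pattern")


# ---------------------------------------------------------------------------
# Connected components on the supra-threshold edge graph


def _components_from_mask(
    mask: np.ndarray, edges: np.ndarray, n_nodes: int
) -> list[np.ndarray]:
    """Group supra-threshold edge indices into connected components.

    Union-find over the kept edges. Components are returned sorted by
    extent descending; ties are broken by the smallest node index contained
    in the component (ascending), which makes the order deterministic.
    """
    idx = np.where(mask)[0]
    if idx.size == 0:
        return []
    parent = np.arange(n_nodes)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for i, j in edges[idx]:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    roots = np.array([find(i) for i in edges[idx, 0]])
    comps: dict[int, list[int]] = {}
    for e, r in zip(idx, roots):
        comps.setdefault(int(r), []).append(int(e))
    groups = [np.array(v, dtype=np.intp) for v in comps.values()]
    groups.sort(key=lambda g: (-len(g), int(edges[g].min())))
    return groups


def _supra_mask(
    values: np.ndarray | tuple[np.ndarray, np.ndarray],
    threshold: float,
    direction: str,
) -> np.ndarray:
    if direction == "two_sided_F":
        return np.asarray(values) > threshold
    if direction == "greater":
        return np.asarray(values) > threshold
    if direction == "less":
        return np.asarray(values) < -threshold
    if direction == "pattern":
        t_low, t_high = values
        return (np.asarray(t_low) < -threshold) & (np.asarray(t_high) > threshold)
    raise ValueError(f"unknown direction {direction!r}; expected one of {DIRECTIONS}")


def supra_threshold_components(
    stats: EdgeStats | np.ndarray,
    threshold: float,
    direction: str,
    backbone: EdgeSet,
) -> list[EdgeSet]:
    """Connected components of the supra-threshold graph, largest first."""
    if threshold <= 0:
        raise ValueError("primary threshold must be positive")
    values = stats.values if isinstance(stats, EdgeStats) else stats
    mask = _supra_mask(values, threshold, direction)
    groups = _components_from_mask(mask, backbone.edges, backbone.n_nodes)
    return [EdgeSet(backbone.edges[g], backbone.n_nodes) for g in groups]


# ---------------------------------------------------------------------------
# Fast permutation statistics

class _PermEngine:
    """Precomputed machinery to evaluate permuted edge statistics quickly.

    For the Freedman-Lane scheme the reduced-model fit and residuals are
    cached; a permutation only permutes residual rows and projects onto the
    cached orthonormal bases. For label permutation the effect columns are
    re-ordered and the design refactorized (cheap: p is small).
    """

    def __init__(
        self,
        Y: np.ndarray,
        design: DesignMatrix,
        scheme: str,
        contrasts: Sequence[np.ndarray] | None = None,
    ) -> None:
        self.Y = np.asarray(Y, dtype=float)
        self.design = design
        self.scheme = scheme
        self.contrasts = [np.asarray(c, dtype=float) for c in (contrasts or [])]
        X = design.X
        self.Qx, _ = np.linalg.qr(X)
        Z = design.reduced()
        self.Qz, _ = np.linalg.qr(Z)
        self.pinvX = np.linalg.pinv(X)
        XtXinv = np.linalg.inv(X.T @ X)
        self.gs = [float(c @ XtXinv @ c) for c in self.contrasts]
        self.df2 = design.n - design.p
        self.q = design.q
        if scheme == "freedman_lane":
            coef0 = np.linalg.lstsq(Z, self.Y, rcond=None)[0]
            self.fitted0 = Z @ coef0
            self.resid0 = self.Y - self.fitted0
        elif scheme != "label":
            raise ValueError(f"unknown permutation scheme {scheme!r}")

    def _ystar_and_design(self, order: np.ndarray):
        if self.scheme == "freedman_lane":
            return self.fitted0 + self.resid0[order], self.design.X, self.Qx, \
                self.Qz, self.pinvX, self.gs
        Xp = self.design.X.copy()
        Xp[:, self.design.effect_columns] = Xp[order][:, self.design.effect_columns]
        Qx, _ = np.linalg.qr(Xp)
        Z = Xp[:, self.design.nuisance_columns]
        Qz, _ = np.linalg.qr(Z)
        pinvX = np.linalg.pinv(Xp)
        XtXinv = np.linalg.inv(Xp.T @ Xp)
        gs = [float(c @ XtXinv @ c) for c in self.contrasts]
        return self.Y, Xp, Qx, Qz, pinvX, gs

    def f_stats(self, order: np.ndarray) -> np.ndarray:
        Ystar, _, Qx, Qz, _, _ = self._ystar_and_design(order)
        tot = np.einsum("ij,ij->j", Ystar, Ystar)
        px = Qx.T @ Ystar
        pz = Qz.T @ Ystar
        rss1 = tot - np.einsum("ij,ij->j", px, px)
        rss0 = tot - np.einsum("ij,ij->j", pz, pz)
        denom = rss1 / self.df2
        F = np.zeros_like(rss1)
        ok = denom > 0
        F[ok] = ((rss0[ok] - rss1[ok]) / self.q) / denom[ok]
        return np.maximum(F, 0.0)

    def t_stats(self, order: np.ndarray) -> list[np.ndarray]:
        Ystar, _, Qx, _, pinvX, gs = self._ystar_and_design(order)
        tot = np.einsum("ij,ij->j", Ystar, Ystar)
        px = Qx.T @ Ystar
        rss1 = np.maximum(tot - np.einsum("ij,ij->j", px, px), 0.0)
        sigma2 = rss1 / self.df2
        B = pinvX @ Ystar
        out = []
        for c, g in zip(self.contrasts, gs):
            denom = np.sqrt(sigma2 * g)
            t = np.zeros_like(denom)
            ok = denom > 0
            t[ok] = (c @ B)[ok] / denom[ok]
            out.append(t)
        return out


# ---------------------------------------------------------------------------
# Results


@dataclass
class NBSResult:
    """Outcome of one NBS analysis.

    ``components`` are the observed supra-threshold connected components in
    decreasing extent order; ``p_fwe[k]`` compares the k-th component's
    extent with the permutation null of the maximal extent using the
    (1 + b) / (1 + K) estimator (or the exhaustive proportion when every
    permutation was enumerated).
    """

    statistic_kind: str
    primary_threshold: float
    direction: str
    components: list[EdgeSet]
    p_fwe: np.ndarray
    observed_max_extent: int
    null_max_extents: np.ndarray
    n_perm: int
    seed: int | None
    edge_stats: EdgeStats | tuple[EdgeStats, EdgeStats]
    component_stat: str = "extent"
    exhaustive: bool = False
    effect_size: dict | None = None

    @property
    def significant(self) -> list[int]:
        return [k for k, p in enumerate(self.p_fwe) if p <= 0.05]

    def to_dict(self) -> dict:
        return {
            "statistic_kind": self.statistic_kind,
            "primary_threshold": self.primary_threshold,
            "direction": self.direction,
            "n_components": len(self.components),
            "component_extents": [len(c) for c in self.components],
            "p_fwe": [float(p) for p in self.p_fwe],
            "observed_max_extent": int(self.observed_max_extent),
            "n_perm": int(self.n_perm),
            "seed": self.seed,
            "component_stat": self.component_stat,
            "exhaustive": bool(self.exhaustive),
            "null_max_extents": np.asarray(self.null_max_extents).tolist(),
            "effect_size": self.effect_size,
        }

    def write(self, out_dir: str | Path, label: str, atlas: Atlas | None = None) -> None:
        """Serialize: JSON summary plus one TSV edge list per component."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / f"{label}.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        stats = self.edge_stats
        vals = stats[0].values if isinstance(stats, tuple) else stats.values
        for k, comp in enumerate(self.components):
            path = out_dir / f"{label}_component{k + 1}.tsv"
            with open(path, "w") as fh:
                fh.write("i\tj\tregion_i\tregion_j\tstatistic\n")
                # map component edges back to backbone columns via ordering
                for (i, j), v in zip(comp.edges, vals[self._edge_index(comp)]):
                    ni = atlas.region_names[i] if atlas else str(i)
                    nj = atlas.region_names[j] if atlas else str(j)
                    fh.write(f"{i}\t{j}\t{ni}\t{nj}\t{v:.6g}\n")

    def _edge_index(self, comp: EdgeSet) -> np.ndarray:
        return self._backbone.index_of(comp)

    _backbone: EdgeSet | None = None


def _component_stat_value(
    group: np.ndarray, values: np.ndarray, threshold: float, stat: str
) -> float:
    if stat == "extent":
        return float(len(group))
    if stat == "intensity":
        return float(np.sum(np.abs(values[group]) - threshold))
    raise ValueError(f"unknown component statistic {stat!r}")


def _max_component_stat(
    values, threshold: float, direction: str, edges: np.ndarray, n_nodes: int,
    stat: str,
) -> float:
    mask = _supra_mask(values, threshold, direction)
    groups = _components_from_mask(mask, edges, n_nodes)
    if not groups:
        return 0.0
    base = values[0] if isinstance(values, tuple) else values
    return max(_component_stat_value(g, np.asarray(base), threshold, stat) for g in groups)


def _permutation_orders(
    n: int, n_perm: int, seed: int | None, exhaustive: bool
):
    if exhaustive:
        return (np.array(p, dtype=np.intp) for p in itertools.permutations(range(n))), \
            math.factorial(n)
    rng = np.random.default_rng(seed)
    # counter-derived substreams: realization r is independent of evaluation order
    seeds = rng.integers(0, 2**31 - 1, size=n_perm)
    return (np.random.default_rng(int(s)).permutation(n) for s in seeds), n_perm


def _fwe_p(
    observed: Sequence[float], null_max: np.ndarray, exhaustive: bool,
    estimator: str = "plus_one",
) -> np.ndarray:
    null_max = np.asarray(null_max, dtype=float)
    K = len(null_max)
    out = np.empty(len(observed))
    for k, obs in enumerate(observed):
        b = int(np.sum(null_max >= obs))
        if exhaustive or estimator == "proportion":
            out[k] = b / K
        else:
            out[k] = (1 + b) / (1 + K)
    return out


def nbs_test(
    Y: np.ndarray,
    design: DesignMatrix,
    backbone: EdgeSet,
    threshold: float,
    direction: str = "two_sided_F",
    contrast: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int | None = None,
    scheme: str = "freedman_lane",
    component_stat: str = "extent",
    exhaustive: bool = False,
    estimator: str = "plus_one",
) -> NBSResult:
    """NBS inference for an omnibus F map or a one-sided contrast t map.

    Per permutation the edge statistics are recomputed under ``scheme`` and
    the maximal supra-threshold component statistic recorded;
    p_fwe(component) = (1 + #{null >= observed}) / (1 + K). With
    ``exhaustive=True`` all n! row permutations are enumerated (identity
    included) and the exact proportion is reported instead.
    """
    if len(backbone) == 0:
        raise ConnectomeError("backbone has no edges")
    if Y.shape[1] != len(backbone):
        raise ValueError("response columns do not match backbone edges")
    if not exhaustive and n_perm < 100:
        warnings.warn("n_perm < 100: reported FWE p-values are unreliable")

    fit = fit_edges(Y, design)
    if direction == "two_sided_F":
        observed_stats = omnibus_F(fit, design)
        engine = _PermEngine(Y, design, scheme)
        stat_fn: Callable = engine.f_stats
        wrap = lambda v: v  # noqa: E731
    elif direction in ("greater", "less"):
        if contrast is None:
            raise ValueError("a contrast vector is required for directed tests")
        observed_stats = contrast_t(fit, design, contrast)
        engine = _PermEngine(Y, design, scheme, contrasts=[contrast])
        stat_fn = lambda order: engine.t_stats(order)[0]  # noqa: E731
        wrap = lambda v: v  # noqa: E731
    else:
        raise ValueError(f"nbs_test does not handle direction {direction!r}")

    components = supra_threshold_components(observed_stats, threshold, direction, backbone)
    observed_vals = [
        _component_stat_value(backbone.index_of(c), observed_stats.values,
                              threshold, component_stat)
        for c in components
    ]
    orders, K = _permutation_orders(design.n, n_perm, seed, exhaustive)
    null_max = np.fromiter(
        (
            _max_component_stat(wrap(stat_fn(order)), threshold, direction,
                                backbone.edges, backbone.n_nodes, component_stat)
            for order in orders
        ),
        dtype=float, count=K,
    )
    p = _fwe_p(observed_vals, null_max, exhaustive, estimator)
    result = NBSResult(
        statistic_kind=observed_stats.kind,
        primary_threshold=threshold,
        direction=direction,
        components=components,
        p_fwe=p,
        observed_max_extent=len(components[0]) if components else 0,
        null_max_extents=null_max,
        n_perm=K,
        seed=seed,
        edge_stats=observed_stats,
        component_stat=component_stat,
        exhaustive=exhaustive,
    )
    result._backbone = backbone
    return result


def ordered_pattern_test(
    Y: np.ndarray,
    design: DesignMatrix,
    backbone: EdgeSet,
    contrast_low: np.ndarray,
    contrast_high: np.ndarray,
    threshold: float,
    n_perm: int = 5000,
    seed: int | None = None,
    scheme: str = "freedman_lane",
    component_stat: str = "extent",
    exhaustive: bool = False,
) -> NBSResult:
    """Directed test for an ordered three-group pattern on the same edges.

    An edge is kept iff t(contrast_low) < -threshold AND
    t(contrast_high) > +threshold — e.g. MDD below HC and MDD+ANX above HC
    simultaneously. The permutation null applies the identical conjunction
    rule, and FWE control again uses the maximal component statistic. Both
    t fields are retained in ``edge_stats`` for audit.
    """
    if len(backbone) == 0:
        raise ConnectomeError("backbone has no edges")
    if not exhaustive and n_perm < 100:
        warnings.warn("n_perm < 100: reported FWE p-values are unreliable")
    fit = fit_edges(Y, design)
    t_low = contrast_t(fit, design, contrast_low)
    t_high = contrast_t(fit, design, contrast_high)
    components = supra_threshold_components(
        (t_low.values, t_high.values), threshold, "pattern", backbone
    )

    engine = _PermEngine(Y, design, scheme, contrasts=[contrast_low, contrast_high])
    observed_vals = [float(len(c)) for c in components]
    if component_stat == "intensity":
        observed_vals = [
            _component_stat_value(
                backbone.index_of(c),
                np.minimum(-t_low.values, t_high.values), threshold, "intensity")
            for c in components
        ]
    orders, K = _permutation_orders(design.n, n_perm, seed, exhaustive)

    def null_stat(order):
        tl, th = engine.t_stats(order)
        vals = (tl, th) if component_stat == "extent" else np.minimum(-tl, th)
        if component_stat == "extent":
            return _max_component_stat(vals, threshold, "pattern",
                                       backbone.edges, backbone.n_nodes, "extent")
        mask = _supra_mask((tl, th), threshold, "pattern")
        groups = _components_from_mask(mask, backbone.edges, backbone.n_nodes)
        if not groups:
            return 0.0
        return max(_component_stat_value(g, vals, threshold, "intensity") for g in groups)

    null_max = np.fromiter((null_stat(o) for o in orders), dtype=float, count=K)
    p = _fwe_p(observed_vals, null_max, exhaustive)
    result = NBSResult(
        statistic_kind="conjunction",
        primary_threshold=threshold,
        direction="pattern",
        components=components,
        p_fwe=p,
        observed_max_extent=len(components[0]) if components else 0,
        null_max_extents=null_max,
        n_perm=K,
        seed=seed,
        edge_stats=(t_low, t_high),
        component_stat=component_stat,
        exhaustive=exhaustive,
    )
    result._backbone = backbone
    return result


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def component_effect_sizes(
    Y: np.ndarray,
    backbone: EdgeSet,
    component: EdgeSet,
    design: DesignMatrix,
    groups: Sequence[str] | np.ndarray,
    pair: tuple[str, str] | None = None,
) -> dict:
    """Effect sizes for a component's mean-connectivity score.

    Each subject is scored by the mean weight over the component's edges;
    the score is residualized on the nuisance covariates (intercept kept
    out of the residualization target's group structure — group membership
    is *not* regressed out). Returns Cohen's d for ``pair=(a, b)``
    (mean_a - mean_b over pooled SD) and, always, partial eta^2 from the
    omnibus F on the score: eta_p^2 = F q / (F q + df2).
    """
    if len(component) == 0:
        raise ValueError("component is empty")
    idx = backbone.index_of(component)
    score = np.asarray(Y, dtype=float)[:, idx].mean(axis=1)
    Z = design.reduced()
    coef0 = np.linalg.lstsq(Z, score, rcond=None)[0]
    resid = score - Z @ coef0

    out: dict = {}
    fit = fit_edges(score[:, None], design)
    F = float(omnibus_F(fit, design).values[0])
    q, df2 = design.q, fit.df_resid
    out["partial_eta2"] = (F * q) / (F * q + df2)
    out["omnibus_F"] = F

    if pair is not None:
        groups = np.asarray(groups)
        a, b = pair
        xa, xb = resid[groups == a], resid[groups == b]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group {a!r} or {b!r} has fewer than 2 subjects")
        na, nb = len(xa), len(xb)
        sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
        out["cohens_d"] = float((xa.mean() - xb.mean()) / np.sqrt(sp2)) if sp2 > 0 else 0.0
        out["pair"] = [a, b]
    return out


def continuous_nbs(
    Y: np.ndarray,
    design: DesignMatrix,
    backbone: EdgeSet,
    f_threshold: float,
    t_threshold: float,
    n_perm: int = 5000,
    seed: int | None = None,
    scheme: str = "freedman_lane",
    alpha: float = 0.05,
    run_directed: str = "auto",
) -> tuple[NBSResult, dict[str, NBSResult]]:
    """Two-stage association between connectivity and a continuous score.

    Stage 1: undirected F test on the score's coefficient (q = 1) with the
    usual component FWE. Stage 2 (run when stage 1 found a component with
    p_fwe <= alpha, or always when ``run_directed='always'``): one-sided t
    maps in each direction to identify the dominant sign of the
    association. The score must be the design's single effect column.
    """
    if design.q != 1:
        raise ValueError("continuous_nbs requires a single-column effect")
    stage1 = nbs_test(
        Y, design, backbone, f_threshold, "two_sided_F",
        n_perm=n_perm, seed=seed, scheme=scheme,
    )
    directed: dict[str, NBSResult] = {}
    go = run_directed == "always" or (
        run_directed == "auto" and any(p <= alpha for p in stage1.p_fwe)
    )
    if go:
        c = effect_contrast(design)
        for name, direction in (("positive", "greater"), ("negative", "less")):
            directed[name] = nbs_test(
                Y, design, backbone, t_threshold, direction, contrast=c,
                n_perm=n_perm, seed=None if seed is None else seed + 1,
                scheme=scheme,
            )
    return stage1, directed
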