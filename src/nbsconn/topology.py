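"""Topology characterization of an identified subnetwork.

Given a component found by the NBS, this module reports its hub nodes
(highest within-component degree), its lobe-pair composition against the
backbone background (goodness-of-fit and per-category chi-square), and a
permutation test of its mean total fiber length against random subnetworks
of identical size drawn from the backbone — the question being whether the
component preferentially involves long-range connections.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectomes import LOBES, Atlas, Connectome, ConnectomeError, EdgeSet

LOBE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations_with_replacement(LOBES, 2)
)  # 15 unordered categories


def subnetwork_degree(
    component: EdgeSet, atlas: Atlas | None = None, top_k: int = 6
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Within-component degree per node and the top_k hub list.

    Degree counts component edges incident to each node; hubs are the
    ``top_k`` highest-degree nodes, ties broken by the smaller node index.
    """
    if len(component) == 0:
        raise ValueError("component is empty")
    n = component.n_nodes
    deg = (
        np.bincount(component.edges[:, 0], minlength=n)
        + np.bincount(component.edges[:, 1], minlength=n)
    )
    order = np.lexsort((np.arange(n), -deg))
    hubs = [(int(i), int(deg[i])) for i in order[:top_k] if deg[i] > 0]
    return deg, hubs


def _pair_counts(edges: np.ndarray, lobe_idx: np.ndarray) -> np.ndarray:
    """Count edges per unordered lobe pair, in LOBE_PAIRS order."""
    li = lobe_idx[edges[:, 0]]
    lj = lobe_idx[edges[:, 1]]
    lo = np.minimum(li, lj)
    hi = np.maximum(li, lj)
    table = {pair: k for k, pair in enumerate(
        itertools.combinations_with_replacement(range(len(LOBES)), 2))}
    counts = np.zeros(len(LOBE_PAIRS), dtype=np.int64)
    for a, b in zip(lo, hi):
        counts[table[(int(a), int(b))]] += 1
    return counts


@dataclass
class LobeComposition:
    """Lobe-pair composition of a component versus the backbone background."""

    categories: list[str]
    component_counts: np.ndarray
    backbone_counts: np.ndarray
    component_proportions: np.ndarray
    backbone_proportions: np.ndarray
    chi2: float
    df: int
    p: float
    pooled_categories: list[str]       # after pooling expected < 1 into "other"
    per_category: pd.DataFrame         # one-vs-rest chi-square per lobe pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lobe_pair": self.categories,
            "component_count": self.component_counts,
            "component_proportion": self.component_proportions,
            "backbone_count": self.backbone_counts,
            "backbone_proportion": self.backbone_proportions,
        })


def lobe_pair_composition(
    component: EdgeSet, backbone: EdgeSet, atlas: Atlas
) -> LobeComposition:
    """Compare the component's lobe-pair mix with the whole-connectome mix.

    The goodness-of-fit chi-square tests the component's 15 unordered
    lobe-pair counts against expected = extent x backbone proportions;
    categories with expected < 1 are pooled into an "other" bin (counts are
    never dropped). A per-category one-vs-rest chi-square flags individual
    enrichments or depletions.
    """
    if len(backbone) == 0:
        raise ConnectomeError("backbone is empty")
    if len(component) == 0:
        raise ValueError("component is empty")
    lobe_idx = atlas.lobe_index()
    comp_counts = _pair_counts(component.edges, lobe_idx)
    back_counts = _pair_counts(backbone.edges, lobe_idx)
    extent = len(component)
    back_props = back_counts / len(backbone)
    expected = extent * back_props

    labels = [f"{a}-{b}" for a, b in LOBE_PAIRS]
    # pool empty-background / tiny-expectation categories
    keep = expected >= 1.0
    pooled_labels = [lab for lab, k in zip(labels, keep) if k]
    f_obs = list(comp_counts[keep].astype(float))
    f_exp = list(expected[keep])
    if np.any(~keep):
        pooled_labels.append("other")
        f_obs.append(float(comp_counts[~keep].sum()))
        f_exp.append(float(expected[~keep].sum()))
    f_obs_arr = np.array(f_obs)
    f_exp_arr = np.array(f_exp)
    nonzero = f_exp_arr > 0
    if np.any(~nonzero) and np.any(f_obs_arr[~nonzero] > 0):
        # component edges in categories absent from the backbone: impossible
        # by construction when component <= backbone, but guard anyway
        raise ConnectomeError("component contains edges outside the backbone support")
    f_obs_arr, f_exp_arr = f_obs_arr[nonzero], f_exp_arr[nonzero]
    # chisquare requires sums to match; they do by construction
    chi2, p = sps.chisquare(f_obs_arr, f_exp_arr)
    df = len(f_obs_arr) - 1

    rows = []
    for k, lab in enumerate(labels):
        table = np.array([
            [comp_counts[k], extent - comp_counts[k]],
            [back_counts[k], len(backbone) - back_counts[k]],
        ])
        if table[:, 0].sum() == 0 or np.any(table.sum(axis=1) == 0):
            c2, pv = 0.0, 1.0
        else:
            c2, pv, _, _ = sps.chi2_contingency(table, correction=False)
        rows.append({
            "lobe_pair": lab,
            "component_count": int(comp_counts[k]),
            "backbone_count": int(back_counts[k]),
            "chi2": float(c2),
            "p": float(pv),
            "enriched": bool(comp_counts[k] / max(extent, 1) > back_props[k]),
        })
    return LobeComposition(
        categories=labels,
        component_counts=comp_counts,
        backbone_counts=back_counts,
        component_proportions=comp_counts / extent,
        backbone_proportions=back_props,
        chi2=float(chi2),
        df=df,
        p=float(p),
        pooled_categories=pooled_labels,
        per_category=pd.DataFrame(rows),
    )


def mean_total_fiber_length(
    connectomes: Sequence[Connectome], component: EdgeSet
) -> float:
    """Mean over subjects of the summed fiber length across component edges.

    Each subject's total is the sum of that subject's fiber lengths over
    the component's edges; edges the subject lacks contribute zero.
    """
    if len(component) == 0:
        raise ValueError("component is empty")
    i, j = component.edges[:, 0], component.edges[:, 1]
    totals = []
    for c in connectomes:
        if c.lengths is None:
            raise ConnectomeError(f"{c.subject_id}: no fiber-length matrix")
        totals.append(float(c.lengths[i, j].sum()))
    return float(np.mean(totals))


def _double_edge_swap(
    edges_set: set[tuple[int, int]],
    backbone_keys: set[tuple[int, int]],
    target_swaps: int,
    rng: np.random.Generator,
    max_attempts: int,
) -> list[tuple[int, int]] | None:
    """Degree-preserving rewiring constrained to backbone membership."""
    edges = list(edges_set)
    current = set(edges_set)
    successes = 0
    attempts = 0
    m = len(edges)
    while successes < target_swaps and attempts < max_attempts:
        attempts += 1
        k1, k2 = rng.integers(0, m, size=2)
        if k1 == k2:
            continue
        a, b = edges[k1]
        c, d = edges[k2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        e1 = (min(a, d), max(a, d))
        e2 = (min(c, b), max(c, b))
        if a == d or c == b:
            continue
        if e1 in current or e2 in current:
            continue
        if e1 not in backbone_keys or e2 not in backbone_keys:
            continue
        current.discard(edges[k1])
        current.discard(edges[k2])
        current.add(e1)
        current.add(e2)
        edges[k1], edges[k2] = e1, e2
        successes += 1
    if successes < target_swaps:
        return None
    return edges


def random_subnetworks(
    backbone: EdgeSet,
    size: int,
    mode: str = "uniform_edges",
    R: int = 1000,
    seed: int | None = None,
    component: EdgeSet | None = None,
) -> list[EdgeSet]:
    """Draw R random subnetworks of ``size`` edges from the backbone.

    ``uniform_edges`` draws uniform random edge subsets — the simplest null
    of identical size. ``degree_matched`` starts from the observed
    component and applies double-edge swaps constrained to backbone
    membership (>= 10 x size successful swaps per draw), preserving the
    degree sequence exactly; when too few legal swaps exist it falls back
    to uniform draws with a warning.
    """
    if size > len(backbone):
        raise ValueError(f"size {size} exceeds backbone ({len(backbone)} edges)")
    if size < 1:
        raise ValueError("size must be at least 1")
    rng = np.random.default_rng(seed)
    m = len(backbone)
    if mode == "uniform_edges":
        out = []
        for _ in range(R):
            idx = rng.choice(m, size=size, replace=False)
            out.append(EdgeSet(backbone.edges[np.sort(idx)], backbone.n_nodes))
        return out
    if mode != "degree_matched":
        raise ValueError(f"unknown null mode {mode!r}")
    if component is None or len(component) != size:
        raise ValueError("degree_matched requires the observed component of that size")
    backbone_keys = {(int(i), int(j)) for i, j in backbone.edges}
    start = {(int(i), int(j)) for i, j in component.edges}
    target = 10 * size
    out = []
    fell_back = False
    for _ in range(R):
        swapped = _double_edge_swap(start, backbone_keys, target, rng,
                                    max_attempts=100 * target)
        if swapped is None:
            fell_back = True
            idx = rng.choice(m, size=size, replace=False)
            out.append(EdgeSet(backbone.edges[np.sort(idx)], backbone.n_nodes))
        else:
            out.append(EdgeSet.from_pairs(swapped, backbone.n_nodes))
    if fell_back:
        warnings.warn("degree_matched null infeasible for some draws; "
                      "fell back to uniform_edges")
    return out


@dataclass
class LengthTestResult:
    observed_mm: float
    null_mm: np.ndarray
    p_perm: float
    mode: str
    alternative: str


def fiber_length_permutation_test(
    connectomes: Sequence[Connectome],
    component: EdgeSet,
    backbone: EdgeSet,
    mode: str = "uniform_edges",
    R: int = 1000,
    alternative: str = "greater",
    seed: int | None = None,
) -> LengthTestResult:
    """Is the component's mean total fiber length extreme among size-matched
    random subnetworks of the backbone?

    p = (1 + #{null >= observed}) / (1 + R) for ``alternative='greater'``
    (ties counted against the observed network, which is conservative);
    ``less`` and ``two_sided`` are symmetric.
    """
    observed = mean_total_fiber_length(connectomes, component)
    # per-edge mean length across subjects: total-length sums are linear, so
    # the null statistic is a sum of these per-edge means over drawn edges
    i, j = backbone.edges[:, 0], backbone.edges[:, 1]
    per_edge = np.zeros(len(backbone))
    for c in connectomes:
        if c.lengths is None:
            raise ConnectomeError(f"{c.subject_id}: no fiber-length matrix")
        per_edge += c.lengths[i, j]
    per_edge /= len(connectomes)

    draws = random_subnetworks(backbone, len(component), mode=mode, R=R,
                               seed=seed, component=component)
    null = np.array([per_edge[backbone.index_of(d)].sum() for d in draws])
    b_ge = int(np.sum(null >= observed))
    b_le = int(np.sum(null <= observed))
    if alternative == "greater":
        p = (1 + b_ge) / (1 + R)
    elif alternative == "less":
        p = (1 + b_le) / (1 + R)
    elif alternative == "two_sided":
        p = min(1.0, 2 * min((1 + b_ge) / (1 + R), (1 + b_le) / (1 + R)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return LengthTestResult(observed_mm=float(observed), null_mm=null,
                            p_perm=float(p), mode=mode, alternative=alternative)


@dataclass
class SubnetworkReport:
    """Full characterization of one identified component."""

    degrees: np.ndarray
    hubs: list[tuple[int, int]]
    hub_names: list[str]
    composition: LobeComposition
    length_test: LengthTestResult | None
    length_test_degree_matched: LengthTestResult | None = None

    def to_dict(self) -> dict:
        out = {
            "hubs": [
                {"node": n, "name": nm, "degree": d}
                for (n, d), nm in zip(self.hubs, self.hub_names)
            ],
            "composition_chi2": self.composition.chi2,
            "composition_df": self.composition.df,
            "composition_p": self.composition.p,
            "lobe_pair_proportions": dict(zip(
                self.composition.categories,
                self.composition.component_proportions.tolist())),
            "mean_total_fiber_length_mm":
                None if self.length_test is None else self.length_test.observed_mm,
            "fiber_length_p_perm":
                None if self.length_test is None else self.length_test.p_perm,
        }
        if self.length_test_degree_matched is not None:
            out["fiber_length_p_perm_degree_matched"] = \
                self.length_test_degree_matched.p_perm
        return out

    def write(self, out_dir: str | Path, label: str) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / f"{label}_report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        self.composition.to_frame().to_csv(
            out_dir / f"{label}_lobe_pairs.tsv", sep="\t", index=False)


def characterize_subnetwork(
    component: EdgeSet,
    backbone: EdgeSet,
    atlas: Atlas,
    connectomes: Sequence[Connectome] | None = None,
    top_k: int = 6,
    null_mode: str = "uniform_edges",
    R: int = 1000,
    seed: int | None = None,
) -> SubnetworkReport:
    """Assemble the full topology report for one component.

    ``null_mode="both"`` runs the fiber-length test under the uniform null
    and again under the degree-matched null and reports both p-values.
    """
    deg, hubs = subnetwork_degree(component, atlas, top_k=top_k)
    comp = lobe_pair_composition(component, backbone, atlas)
    length_test = length_test_dm = None
    if connectomes is not None and connectomes[0].lengths is not None:
        first = "uniform_edges" if null_mode == "both" else null_mode
        length_test = fiber_length_permutation_test(
            connectomes, component, backbone, mode=first, R=R, seed=seed)
        if null_mode == "both":
            length_test_dm = fiber_length_permutation_test(
                connectomes, component, backbone, mode="degree_matched",
                R=R, seed=seed)
    return SubnetworkReport(
        degrees=deg,
        hubs=hubs,
        hub_names=[atlas.region_names[n] for n, _ in hubs],
        composition=comp,
        length_test=length_test,
        length_test_degree_matched=length_test_dm,
    )
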