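"""Containers and I/O for weighted structural connectomes.

A connectome is an undirected, weighted graph over the regions of a cortical
parcellation atlas. Edge weights are streamline counts from diffusion
tractography (nonnegative integers); an optional matched matrix carries the
mean fiber length of each connection in millimetres. Group analyses operate
on a *backbone*: the set of edges present in at least a given fraction of
the sample, which defines a common edge support across subjects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LOBES = ("frontal", "temporal", "parietal", "occipital", "insula")
HEMISPHERES = ("L", "R")
GROUP_LEVELS = ("HC", "MDD", "MDD_ANX")

_ASYMMETRY_TOL = 1e-6


class ConnectomeError(ValueError):
    """Raised when a connectome, atlas or cohort violates its invariants."""


@dataclass(frozen=True)
class Atlas:
    """Parcellation atlas: region names, lobe and hemisphere labels.

    Region ids are the 0-based positions in ``region_names``. Coordinates
    (mm) are optional and only used by the synthetic generator and for
    reporting.
    """

    region_names: tuple[str, ...]
    lobe: tuple[str, ...]
    hemisphere: tuple[str, ...]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.region_names)
        if len(self.lobe) != n or len(self.hemisphere) != n:
            raise ConnectomeError("atlas columns have inconsistent lengths")
        for row, lb in enumerate(self.lobe):
            if lb not in LOBES:
                raise ConnectomeError(
                    f"unknown lobe {lb!r} in atlas row {row} "
                    f"({self.region_names[row]}); expected one of {LOBES}"
                )
        for row, h in enumerate(self.hemisphere):
            if h not in HEMISPHERES:
                raise ConnectomeError(
                    f"unknown hemisphere {h!r} in atlas row {row}; expected L or R"
                )
        if self.coords is not None and np.asarray(self.coords).shape != (n, 3):
            raise ConnectomeError("atlas coords must have shape (n_regions, 3)")

    @property
    def n_nodes(self) -> int:
        return len(self.region_names)

    def lobe_index(self) -> np.ndarray:
        """Lobe of each region as an integer index into LOBES."""
        return np.array([LOBES.index(lb) for lb in self.lobe], dtype=np.intp)


@dataclass(frozen=True)
class Connectome:
    """One subject's weighted adjacency plus optional fiber-length matrix.

    ``weights`` is symmetric with a zero diagonal; ``lengths`` (mm) may carry
    a positive entry only where a connection exists.
    """

    subject_id: str
    weights: np.ndarray
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"{self.subject_id}: weights matrix is not square")
        if np.any(w < 0):
            raise ConnectomeError(f"{self.subject_id}: negative streamline count")
        if np.any(np.diag(w) != 0):
            raise ConnectomeError(f"{self.subject_id}: nonzero diagonal")
        if not np.array_equal(w, w.T):
            raise ConnectomeError(f"{self.subject_id}: weights not symmetric")
        if self.lengths is not None:
            ln = np.asarray(self.lengths, dtype=float)
            if ln.shape != w.shape:
                raise ConnectomeError(f"{self.subject_id}: lengths shape mismatch")
            if np.any(ln < 0):
                raise ConnectomeError(f"{self.subject_id}: negative fiber length")
            if np.any((ln > 0) & (w == 0)):
                raise ConnectomeError(
                    f"{self.subject_id}: fiber length present on absent edge"
                )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class EdgeSet:
    """A set of unordered node pairs (i < j) on a graph of ``n_nodes`` nodes.

    Edges are stored lexicographically sorted, which fixes the column order
    of stacked edge matrices and makes all downstream results deterministic.
    """

    edges: np.ndarray  # (m, 2) integer array, each row i < j
    n_nodes: int

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if e.size and (np.any(e[:, 0] >= e[:, 1]) or np.any(e < 0)
                       or np.any(e[:, 1] >= self.n_nodes)):
            raise ConnectomeError("edge indices must satisfy 0 <= i < j < n_nodes")
        keys = e[:, 0] * self.n_nodes + e[:, 1]
        if len(keys) > 1 and np.any(np.diff(keys) <= 0):
            raise ConnectomeError("edges must be lexicographically sorted and unique")
        object.__setattr__(self, "edges", e)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]], n_nodes: int) -> "EdgeSet":
        """Build from arbitrary (i, j) pairs; orients, sorts and deduplicates."""
        arr = np.asarray(list(pairs), dtype=np.intp).reshape(-1, 2)
        if arr.size:
            if np.any(arr[:, 0] == arr[:, 1]):
                raise ConnectomeError("self-pairs are not allowed")
            arr = np.sort(arr, axis=1)
            keys = arr[:, 0] * n_nodes + arr[:, 1]
            _, idx = np.unique(keys, return_index=True)
            arr = arr[np.sort(idx)]
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            arr = arr[order]
        return cls(arr, n_nodes)

    def __len__(self) -> int:
        return self.edges.shape[0]

    def keys(self) -> np.ndarray:
        """Encode each edge as i * n_nodes + j (strictly increasing)."""
        return self.edges[:, 0] * self.n_nodes + self.edges[:, 1]

    def index_of(self, other: "EdgeSet") -> np.ndarray:
        """Positions of ``other``'s edges within this edge set.

        Raises if any edge of ``other`` is absent here.
        """
        if other.n_nodes != self.n_nodes:
            raise ConnectomeError("edge sets are defined on different node counts")
        mine = self.keys()
        pos = np.searchsorted(mine, other.keys())
        bad = (pos >= len(mine)) | (mine[np.clip(pos, 0, len(mine) - 1)] != other.keys())
        if np.any(bad):
            raise ConnectomeError("edge set is not a subset of this backbone")
        return pos

    def node_set(self) -> np.ndarray:
        return np.unique(self.edges)


# ---------------------------------------------------------------------------
# Readers / writers


def read_atlas(path: str | Path) -> Atlas:
    """Read a TSV atlas with columns region_name, lobe, hemisphere [, x, y, z]."""
    df = pd.read_csv(path, sep="\t")
    for col in ("region_name", "lobe", "hemisphere"):
        if col not in df.columns:
            raise ConnectomeError(f"atlas file missing column {col!r}")
    coords = None
    if {"x", "y", "z"}.issubset(df.columns):
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return Atlas(
        region_names=tuple(df["region_name"].astype(str)),
        lobe=tuple(df["lobe"].astype(str)),
        hemisphere=tuple(df["hemisphere"].astype(str)),
        coords=coords,
    )


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    data = {
        "region_name": atlas.region_names,
        "lobe": atlas.lobe,
        "hemisphere": atlas.hemisphere,
    }
    df = pd.DataFrame(data)
    if atlas.coords is not None:
        df[["x", "y", "z"]] = np.asarray(atlas.coords)
    df.to_csv(path, sep="\t", index=False)


def _read_matrix(path: str | Path, index_base: int, n_hint: int | None) -> np.ndarray:
    """Read a dense no-header TSV matrix or an edge-list TSV (header i/j/...)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.split("\t")[0].strip() == "i":  # edge-list format
        df = pd.read_csv(path, sep="\t")
        if n_hint is None:
            raise ConnectomeError("edge-list connectome requires an atlas for its size")
        mat = np.zeros((n_hint, n_hint))
        i = df["i"].to_numpy(dtype=np.intp) - index_base
        j = df["j"].to_numpy(dtype=np.intp) - index_base
        val_col = "length_mm" if "length_mm" in df.columns and "weight" not in df.columns else "weight"
        v = df[val_col].to_numpy(dtype=float)
        if np.any(i < 0) or np.any(j < 0) or np.any(i >= n_hint) or np.any(j >= n_hint):
            raise ConnectomeError(f"{path.name}: edge index out of range")
        mat[i, j] = v
        mat[j, i] = v
        return mat
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ConnectomeError(f"{path.name}: matrix is not square {mat.shape}")
    return mat


def _repair(mat: np.ndarray, name: str, what: str) -> np.ndarray:
    """Symmetrize (element-wise max) and zero the diagonal, warning on repair."""
    asym = np.abs(mat - mat.T)
    scale = np.abs(mat).max() or 1.0
    if asym.max() > 0:
        if asym.max() / scale > _ASYMMETRY_TOL:
            warnings.warn(
                f"{name}: {what} matrix asymmetric (max rel {asym.max() / scale:.2e}); "
                "symmetrizing by element-wise max"
            )
        mat = np.maximum(mat, mat.T)
    if np.any(np.diag(mat) != 0):
        warnings.warn(f"{name}: nonzero diagonal in {what} matrix zeroed (no self-loops)")
        mat = mat.copy()
        np.fill_diagonal(mat, 0.0)
    return mat


def read_connectome(
    weights_path: str | Path,
    lengths_path: str | Path | None = None,
    atlas: Atlas | None = None,
    subject_id: str | None = None,
    index_base: int = 0,
) -> Connectome:
    """Read a subject connectome from dense-matrix or edge-list TSV files.

    The weight matrix is symmetrized by element-wise max and its diagonal
    forced to zero (with a warning when a repair was actually needed).
    Fiber-length entries on absent edges are dropped with a warning.
    """
    weights_path = Path(weights_path)
    sid = subject_id or weights_path.stem.replace("_weights", "")
    n_hint = atlas.n_nodes if atlas is not None else None
    w = _read_matrix(weights_path, index_base, n_hint)
    if np.any(w < 0):
        raise ConnectomeError(f"{sid}: negative streamline count in {weights_path.name}")
    if atlas is not None and w.shape[0] != atlas.n_nodes:
        raise ConnectomeError(
            f"{sid}: matrix size {w.shape[0]} does not match atlas ({atlas.n_nodes})"
        )
    w = _repair(w, sid, "weights")
    lengths = None
    if lengths_path is not None:
        ln = _read_matrix(lengths_path, index_base, w.shape[0] if n_hint is None else n_hint)
        if ln.shape != w.shape:
            raise ConnectomeError(f"{sid}: lengths matrix size mismatch")
        ln = _repair(ln, sid, "lengths")
        stray = (ln > 0) & (w == 0)
        if np.any(stray):
            warnings.warn(f"{sid}: {int(stray.sum())} fiber lengths on absent edges dropped")
            ln = np.where(stray, 0.0, ln)
        lengths = ln
    return Connectome(subject_id=sid, weights=w, lengths=lengths)


def write_connectome(
    connectome: Connectome,
    weights_path: str | Path,
    lengths_path: str | Path | None = None,
) -> None:
    """Write dense TSV matrices; integer counts round-trip bit-exactly."""
    w = connectome.weights
    if np.all(w == np.rint(w)):
        np.savetxt(weights_path, w, fmt="%d", delimiter="\t")
    else:
        np.savetxt(weights_path, w, fmt="%.10g", delimiter="\t")
    if lengths_path is not None:
        if connectome.lengths is None:
            raise ConnectomeError(f"{connectome.subject_id}: no lengths to write")
        np.savetxt(lengths_path, connectome.lengths, fmt="%.6g", delimiter="\t")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read the cohort CSV and validate the required columns.

    Required: subject_id, group (HC / MDD / MDD_ANX), age, sex, site; no
    missing values are allowed in these. Score columns (stai_state,
    stai_trait, bdi), remission and motion are optional.
    """
    df = pd.read_csv(path)
    required = ["subject_id", "group", "age", "sex", "site"]
    for col in required:
        if col not in df.columns:
            raise ConnectomeError(f"cohort file missing column {col!r}")
        if df[col].isna().any():
            raise ConnectomeError(f"cohort column {col!r} contains missing values")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ConnectomeError(f"duplicate subject_id {dup!r} in cohort")
    bad = set(df["group"]) - set(GROUP_LEVELS)
    if bad:
        raise ConnectomeError(f"unknown group labels {sorted(bad)}; expected {GROUP_LEVELS}")
    return df


# ---------------------------------------------------------------------------
# Backbone and per-subject summaries


def build_backbone(
    connectomes: Sequence[Connectome], prevalence: float = 0.05
) -> EdgeSet:
    """Edges present (weight > 0) in at least ``prevalence`` of the sample.

    The inclusion rule is count >= ceil(prevalence * n_subjects); with
    ``prevalence=0`` every possible pair is returned. Presence means any
    nonzero streamline count — no minimum count is imposed.
    """
    if len(connectomes) == 0:
        raise ConnectomeError("cannot build a backbone from an empty sample")
    n = connectomes[0].n_nodes
    counts = np.zeros((n, n), dtype=np.int64)
    for c in connectomes:
        if c.n_nodes != n:
            raise ConnectomeError(f"{c.subject_id}: node count {c.n_nodes} != {n}")
        counts += c.weights > 0
    min_count = math.ceil(prevalence * len(connectomes))
    iu = np.triu_indices(n, k=1)
    keep = counts[iu] >= min_count
    pairs = np.column_stack([iu[0][keep], iu[1][keep]])
    return EdgeSet(pairs, n)


def nodal_strength(
    connectome: Connectome,
    backbone: EdgeSet,
    partners: str = "backbone",
    warn_isolated: bool = True,
) -> np.ndarray:
    """Mean streamline count over each node's incident backbone edges.

    The denominator is the node's backbone degree (a fixed support shared by
    all subjects), so subject-absent edges contribute zeros to the mean.
    ``partners="all"`` divides by n_nodes - 1 instead. Nodes with no backbone
    edges get strength 0 (flagged with a warning).
    """
    if len(backbone) == 0:
        raise ConnectomeError("backbone is empty")
    n = connectome.n_nodes
    i, j = backbone.edges[:, 0], backbone.edges[:, 1]
    w = connectome.weights[i, j]
    sums = np.bincount(i, weights=w, minlength=n) + np.bincount(j, weights=w, minlength=n)
    deg = np.bincount(i, minlength=n) + np.bincount(j, minlength=n)
    if partners == "all":
        denom = np.full(n, n - 1, dtype=float)
    elif partners == "backbone":
        denom = deg.astype(float)
    else:
        raise ValueError(f"unknown partners mode {partners!r}")
    isolated = deg == 0
    if warn_isolated and np.any(isolated):
        warnings.warn(
            f"{connectome.subject_id}: {int(isolated.sum())} node(s) without backbone "
            "edges; strength set to 0"
        )
    out = np.zeros(n)
    ok = denom > 0
    out[ok] = sums[ok] / denom[ok]
    out[isolated] = 0.0
    return out


def stack_edges(
    connectomes: Sequence[Connectome], backbone: EdgeSet
) -> np.ndarray:
    """Stack backbone edge weights into a subjects x edges matrix.

    Rows follow the input subject order; columns follow the backbone's
    lexicographic (i, j) edge order, so column k corresponds to
    ``backbone.edges[k]`` and the mapping round-trips.
    """
    n = backbone.n_nodes
    i, j = backbone.edges[:, 0], backbone.edges[:, 1]
    Y = np.empty((len(connectomes), len(backbone)))
    for s, c in enumerate(connectomes):
        if c.n_nodes != n:
            raise ConnectomeError(f"{c.subject_id}: node count mismatch with backbone")
        Y[s] = c.weights[i, j]
    return Y


def stack_strengths(
    connectomes: Sequence[Connectome], backbone: EdgeSet, partners: str = "backbone"
) -> np.ndarray:
    """Stack nodal strengths into a subjects x nodes matrix."""
    rows = [
        nodal_strength(c, backbone, partners=partners, warn_isolated=(s == 0))
        for s, c in enumerate(connectomes)
    ]
    return np.vstack(rows)
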