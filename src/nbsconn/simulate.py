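"""Synthetic connectome cohorts with planted differential subnetworks.

The generator emulates the statistical structure a three-group structural
connectivity study assumes: unequal group sizes (healthy controls, a
depressed group, and a depressed group with comorbid anxiety), covariate
effects of age, sex and scanner site, a sparse distance-dependent weighted
connectome with a backbone shared across subjects plus per-subject edge
dropout, a connected *planted* subnetwork on which the MDD group is shifted
down and the MDD+ANX group shifted up relative to controls on the same
edges, and anxiety scores positively coupled to connectivity in a second
planted subnetwork. Every random quantity derives from one master seed and
the ground truth (planted edges, configured shifts, subject latents) is
returned for recovery testing.

Weight model. The expected weight of backbone edge (i, j) decays with
Euclidean distance, w0 = A exp(-lambda d). A subject's count is

    w = round( w0 * exp(c_s + s_g 1[planted] + sigma_lat u_s 1[planted]
               + gamma a_s 1[anxiety] + eps) )

with c_s the subject's covariate term, u_s and a_s standard-normal subject
latents, and eps independent edge noise. Planted edges split their total
log-noise variance sigma^2 into a shared subject component (fraction
``latent_share``) and an independent remainder, so component-level scores
do not average the noise away. The group log-shift s_g is calibrated in
closed form so that the *count-scale* standardized group difference per
planted edge equals the configured delta. Counts are nonnegative integers
with multiplicative right-skewed noise, matching streamline-count data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectomes import (
    GROUP_LEVELS,
    LOBES,
    Atlas,
    Connectome,
    ConnectomeError,
    EdgeSet,
    read_atlas,
    read_cohort,
    read_connectome,
    write_atlas,
    write_connectome,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the full cohort scale (906 / 532 / 249 subjects on a
    114-region atlas); tests and calibration runs scale the sizes down with
    :func:`dataclasses.replace`. Effect sizes ``delta_hypo`` and
    ``delta_hyper`` are per-edge standardized group differences (within-edge
    SD units) on the planted component; the defaults are chosen so that the
    component-level Cohen's d lands in the 0.45-0.8 range at full cohort
    size, the magnitude regime such studies report.
    """

    n_hc: int = 906
    n_mdd: int = 532
    n_mdd_anx: int = 249
    n_nodes: int = 114
    box_size_mm: float = 140.0
    base_density: float = 0.20
    decay_rate: float = 0.012        # per mm, distance decay of expected weight
    peak_weight: float = 400.0       # expected count at zero distance
    edge_noise_sd: float = 0.4       # total log-scale noise SD per edge
    latent_share: float = 0.5        # fraction of planted-edge noise variance shared per subject
    dropout: float = 0.02            # per subject-edge probability of a missing edge
    planted_size: int = 109          # edges in the group-difference component
    delta_hypo: float = -0.33        # per-edge standardized shift, MDD vs HC
    delta_hyper: float = 0.54        # per-edge standardized shift, MDD+ANX vs HC
    plant_length_bias: float = 0.0   # >0 biases the planted component to long edges
    age_slope: float = -0.004        # log-weight per year of age
    sex_effect: float = 0.05         # log-weight offset, male vs female
    site_effect: float = 0.06        # log-weight offset, site2 vs site1
    anxiety_size: int = 120          # edges in the anxiety-coupled component
    anxiety_coupling: float = 0.12   # log-weight per SD of the anxiety latent
    anxiety_score_scale: float = 4.0  # STAI points per SD of the anxiety latent
    age_mean: float = 35.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (18.0, 65.0)
    female_frac: tuple[float, float, float] = (0.636, 0.600, 0.731)
    stai_state_base: tuple[float, float, float] = (34.4, 48.5, 53.7)
    stai_state_sd: tuple[float, float, float] = (8.4, 12.9, 11.6)
    stai_trait_base: tuple[float, float, float] = (33.6, 51.2, 57.4)
    stai_trait_sd: tuple[float, float, float] = (8.3, 12.5, 10.6)
    bdi_base: tuple[float, float, float] = (4.1, 15.8, 20.9)
    bdi_sd: tuple[float, float, float] = (4.3, 10.8, 10.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_mdd, self.n_mdd_anx) < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not np.isfinite([self.delta_hypo, self.delta_hyper]).all():
            raise ValueError("effect sizes must be finite")
        if not (0.0 <= self.latent_share <= 1.0):
            raise ValueError("latent_share must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return self.n_hc + self.n_mdd + self.n_mdd_anx

    def group_sizes(self) -> dict[str, int]:
        return dict(zip(GROUP_LEVELS, (self.n_hc, self.n_mdd, self.n_mdd_anx)))


def calibrated_log_shift(delta: float, sigma: float) -> float:
    """Log-scale group shift giving a count-scale standardized diff of delta.

    For lognormal noise with log-SD sigma, a multiplicative shift e^s moves
    the mean by (e^s - 1) e^{sigma^2/2} w0 while the group variance scales
    with e^{2s}. Solving (e^s - 1) / sqrt((1 + e^{2s}) / 2) =
    delta sqrt(e^{sigma^2} - 1) for s gives the closed form below.
    """
    kappa = delta * np.sqrt(np.expm1(sigma**2))
    if abs(kappa) >= 2:
        raise ValueError("effect size too large for this noise level")
    x = (2.0 + kappa * np.sqrt(4.0 - kappa**2)) / (2.0 - kappa**2)
    return float(np.log(x))


@dataclass
class GroundTruth:
    """Planted structure of one generated dataset, for recovery testing."""

    planted: EdgeSet
    anxiety_edges: EdgeSet
    delta: dict[str, float]            # configured per-edge standardized shifts
    log_shift: dict[str, float]        # calibrated multiplicative shifts (log)
    planted_w0: np.ndarray             # expected weights of the planted edges
    covariate_coefficients: dict[str, float]
    anx_latent: np.ndarray             # per-subject anxiety latent (cohort order)
    config: GeneratorConfig

    def expected_component_d(self, group: str) -> float:
        """Closed-form component-level Cohen's d versus HC.

        The component score is the mean weight over the planted edges; its
        moments follow from the lognormal noise model (shared latent plus
        independent edge noise and edge dropout). Rounding to integer
        counts is ignored (negligible at these weight scales).
        """
        cfg = self.config
        s = self.log_shift[group]
        sigma2 = cfg.edge_noise_sd**2
        lat2 = cfg.latent_share * sigma2
        p = cfg.dropout
        w = self.planted_w0
        m = len(w)
        sw, sw2 = w.sum(), (w**2).sum()

        def moments(shift: float) -> tuple[float, float]:
            mean = (sw / m) * (1 - p) * np.exp(shift + sigma2 / 2)
            shared = (sw**2 - sw2) * (1 - p) ** 2 * np.exp(sigma2) * np.expm1(lat2)
            own = sw2 * (np.exp(2 * sigma2) * (1 - p) - np.exp(sigma2) * (1 - p) ** 2)
            var = np.exp(2 * shift) * (shared + own) / m**2
            return mean, var

        m1, v1 = moments(s)
        m0, v0 = moments(0.0)
        return float((m1 - m0) / np.sqrt((v1 + v0) / 2.0))

    def to_dict(self) -> dict:
        return {
            "planted_edges": self.planted.edges.tolist(),
            "anxiety_edges": self.anxiety_edges.edges.tolist(),
            "delta": self.delta,
            "log_shift": self.log_shift,
            "planted_w0": self.planted_w0.tolist(),
            "covariate_coefficients": self.covariate_coefficients,
            "anx_latent": self.anx_latent.tolist(),
            "n_nodes": self.planted.n_nodes,
        }


def generate_atlas(
    n_nodes: int, seed: int | None = None, box_size_mm: float = 140.0
) -> Atlas:
    """Random atlas: unit-box coordinates, lobes by spatial octant.

    The eight octants of the bounding box map cyclically onto the five
    lobes; if a lobe ends up unrepresented (possible at small n), nodes are
    deterministically reassigned from the largest lobe. Hemisphere is L/R
    by the x midline.
    """
    if n_nodes < 10:
        raise ValueError("need at least 10 regions")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box_size_mm, size=(n_nodes, 3))
    half = box_size_mm / 2.0
    octant = (
        (coords[:, 0] >= half).astype(int) * 4
        + (coords[:, 1] >= half).astype(int) * 2
        + (coords[:, 2] >= half).astype(int)
    )
    lobe_idx = octant % len(LOBES)
    for missing in range(len(LOBES)):
        if not np.any(lobe_idx == missing):
            counts = np.bincount(lobe_idx, minlength=len(LOBES))
            donor = int(np.argmax(counts))
            node = int(np.where(lobe_idx == donor)[0][-1])
            lobe_idx[node] = missing
    hemi = np.where(coords[:, 0] < half, "L", "R")
    return Atlas(
        region_names=tuple(f"region_{i:03d}" for i in range(n_nodes)),
        lobe=tuple(LOBES[k] for k in lobe_idx),
        hemisphere=tuple(hemi),
        coords=coords,
    )


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Cohort table with group labels, covariates and anxiety scores.

    Ages are truncated-normal within ``age_range``; sex and site are
    Bernoulli. State and trait anxiety share a per-subject latent ``a``
    (kept in column ``anx_latent``): score = group base +
    ``anxiety_score_scale`` * a + residual noise, so group means are ordered
    HC < MDD < MDD+ANX in expectation and scores are coupled to
    connectivity through the same latent.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    lo, hi = config.age_range
    a_lo = (lo - config.age_mean) / config.age_sd
    a_hi = (hi - config.age_mean) / config.age_sd
    idx = 0
    for g_i, (group, n_g) in enumerate(config.group_sizes().items()):
        ages = sps.truncnorm.rvs(a_lo, a_hi, loc=config.age_mean,
                                 scale=config.age_sd, size=n_g, random_state=rng)
        female = rng.random(n_g) < config.female_frac[g_i]
        site = rng.random(n_g) < 0.5
        latent = rng.standard_normal(n_g)
        motion = np.exp(rng.normal(-1.0, 0.3, size=n_g))

        def score(base, sd):
            resid = np.sqrt(max(sd[g_i] ** 2 - config.anxiety_score_scale**2, 1.0))
            return base[g_i] + config.anxiety_score_scale * latent \
                + rng.normal(0.0, resid, size=n_g)

        stai_s = score(config.stai_state_base, config.stai_state_sd)
        stai_t = score(config.stai_trait_base, config.stai_trait_sd)
        bdi = np.maximum(
            config.bdi_base[g_i] + rng.normal(0.0, config.bdi_sd[g_i], size=n_g), 0.0)
        if group == "HC":
            remission = [""] * n_g
        else:
            remission = rng.choice(
                ["acute", "partial", "full"], size=n_g,
                p=(0.42, 0.24, 0.34) if group == "MDD" else (0.49, 0.28, 0.23),
            ).tolist()
        for k in range(n_g):
            rows.append({
                "subject_id": f"sub-{idx:04d}",
                "group": group,
                "age": float(ages[k]),
                "sex": "female" if female[k] else "male",
                "site": "site2" if site[k] else "site1",
                "stai_state": float(stai_s[k]),
                "stai_trait": float(stai_t[k]),
                "bdi": float(bdi[k]),
                "remission": remission[k],
                "motion": float(motion[k]),
                "anx_latent": float(latent[k]),
            })
            idx += 1
    return pd.DataFrame(rows)


def plant_component(
    backbone: EdgeSet,
    size: int,
    seed: int | None = None,
    edge_lengths: np.ndarray | None = None,
    length_bias: float = 0.0,
    exclude: EdgeSet | None = None,
) -> EdgeSet:
    """Grow a connected edge set by randomized breadth-first edge accretion.

    Starting from one edge, frontier edges (backbone edges touching the
    current node set) are added one at a time; with ``length_bias > 0`` and
    ``edge_lengths`` given, selection probability scales with
    (length / mean length) ** bias, biasing the component to long-range
    connections. ``exclude`` removes edges from consideration.
    """
    rng = np.random.default_rng(seed)
    edges = backbone.edges
    avail = np.ones(len(backbone), dtype=bool)
    if exclude is not None and len(exclude):
        avail[backbone.index_of(exclude)] = False
    pool = np.where(avail)[0]
    if size < 1 or size > len(pool):
        raise ValueError(f"cannot plant {size} edges in {len(pool)} available")
    if edge_lengths is not None and length_bias != 0.0:
        weights = (np.asarray(edge_lengths, dtype=float) / np.mean(edge_lengths)) \
            ** length_bias
    else:
        weights = np.ones(len(backbone))

    # adjacency from node -> available edge indices
    n = backbone.n_nodes
    incident: list[list[int]] = [[] for _ in range(n)]
    for k in pool:
        i, j = edges[k]
        incident[i].append(int(k))
        incident[j].append(int(k))

    start = int(rng.choice(pool, p=weights[pool] / weights[pool].sum()))
    chosen = {start}
    nodes = set(map(int, edges[start]))
    frontier = {
        k for v in nodes for k in incident[v] if k not in chosen
    }
    while len(chosen) < size:
        if not frontier:
            raise ValueError("planted component infeasible: frontier exhausted")
        cand = np.fromiter(frontier, dtype=np.intp)
        w = weights[cand]
        k = int(rng.choice(cand, p=w / w.sum()))
        frontier.discard(k)
        chosen.add(k)
        for v in map(int, edges[k]):
            if v not in nodes:
                nodes.add(v)
                for e in incident[v]:
                    if e not in chosen:
                        frontier.add(e)
    return EdgeSet(edges[np.sort(np.fromiter(chosen, dtype=np.intp))], n)


def generate_connectomes(
    atlas: Atlas,
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    seed: int | None = None,
) -> tuple[list[Connectome], GroundTruth]:
    """Generate per-subject connectomes with planted group effects.

    Returns the connectome list (cohort row order) and the ground truth.
    See the module docstring for the weight model.
    """
    if atlas.coords is None:
        raise ConnectomeError("generator atlas needs coordinates")
    master = np.random.default_rng(config.seed if seed is None else seed)
    sub = [np.random.default_rng(s) for s in master.integers(0, 2**31 - 1, size=4)]
    rng_backbone, rng_plant, rng_anx, rng_noise = sub

    n = atlas.n_nodes
    coords = np.asarray(atlas.coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    d_pairs = dist[iu]
    n_pairs = len(d_pairs)
    m_target = int(round(config.base_density * n_pairs))
    probs = np.exp(-config.decay_rate * d_pairs)
    sel = rng_backbone.choice(n_pairs, size=m_target, replace=False,
                              p=probs / probs.sum())
    sel.sort()
    pairs = np.column_stack([iu[0][sel], iu[1][sel]])
    template = EdgeSet(pairs, n)
    d_edges = d_pairs[sel]
    w0 = config.peak_weight * np.exp(-config.decay_rate * d_edges)

    planted = plant_component(
        template, config.planted_size, seed=int(rng_plant.integers(2**31 - 1)),
        edge_lengths=d_edges, length_bias=config.plant_length_bias,
    )
    anx_edges = plant_component(
        template, config.anxiety_size, seed=int(rng_anx.integers(2**31 - 1)),
        exclude=planted,
    ) if config.anxiety_size > 0 else EdgeSet(np.empty((0, 2), dtype=np.intp), n)

    sigma = config.edge_noise_sd
    sigma_lat = sigma * np.sqrt(config.latent_share)
    sigma_ind = sigma * np.sqrt(1.0 - config.latent_share)
    log_shift = {
        "MDD": calibrated_log_shift(config.delta_hypo, sigma),
        "MDD_ANX": calibrated_log_shift(config.delta_hyper, sigma),
        "HC": 0.0,
    }

    S = len(cohort)
    m = len(template)
    planted_idx = template.index_of(planted)
    anx_idx = template.index_of(anx_edges) if len(anx_edges) else np.array([], dtype=np.intp)

    groups = cohort["group"].to_numpy()
    age = cohort["age"].to_numpy(dtype=float)
    male = (cohort["sex"].to_numpy() == "male").astype(float)
    site2 = (cohort["site"].to_numpy() == "site2").astype(float)
    if "anx_latent" in cohort.columns:
        a_lat = cohort["anx_latent"].to_numpy(dtype=float)
    else:
        a_lat = rng_noise.standard_normal(S)
    c_subj = (config.age_slope * (age - config.age_mean)
              + config.sex_effect * male + config.site_effect * site2)
    u_lat = rng_noise.standard_normal(S)

    col_sd = np.full(m, sigma)
    col_sd[planted_idx] = sigma_ind
    logw = np.log(w0)[None, :] + c_subj[:, None] \
        + rng_noise.standard_normal((S, m)) * col_sd[None, :]
    shift = np.array([log_shift[g] for g in groups])
    logw[:, planted_idx] += shift[:, None] + sigma_lat * u_lat[:, None]
    if len(anx_idx):
        logw[:, anx_idx] += config.anxiety_coupling * a_lat[:, None]
    weights_flat = np.rint(np.exp(logw))
    if config.dropout > 0:
        weights_flat[rng_noise.random((S, m)) < config.dropout] = 0.0
    lengths_flat = d_edges[None, :] * (1.0 + 0.03 * rng_noise.standard_normal((S, m)))
    lengths_flat = np.maximum(lengths_flat, 1.0)
    lengths_flat[weights_flat == 0] = 0.0

    i, j = template.edges[:, 0], template.edges[:, 1]
    connectomes = []
    sids = cohort["subject_id"].to_numpy()
    for s in range(S):
        W = np.zeros((n, n))
        W[i, j] = weights_flat[s]
        W[j, i] = weights_flat[s]
        L = np.zeros((n, n))
        L[i, j] = lengths_flat[s]
        L[j, i] = lengths_flat[s]
        connectomes.append(Connectome(subject_id=str(sids[s]), weights=W, lengths=L))

    truth = GroundTruth(
        planted=planted,
        anxiety_edges=anx_edges,
        delta={"MDD": config.delta_hypo, "MDD_ANX": config.delta_hyper},
        log_shift={k: v for k, v in log_shift.items() if k != "HC"},
        planted_w0=w0[planted_idx],
        covariate_coefficients={
            "age_slope": config.age_slope,
            "sex_effect": config.sex_effect,
            "site_effect": config.site_effect,
            "anxiety_coupling": config.anxiety_coupling,
        },
        anx_latent=a_lat,
        config=config,
    )
    return connectomes, truth


def generate_dataset(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[Atlas, pd.DataFrame, list[Connectome], GroundTruth]:
    """Atlas + cohort + connectomes + ground truth from one master seed."""
    seed = config.seed if seed is None else seed
    master = np.random.default_rng(seed)
    s_atlas, s_cohort, s_conn = (int(x) for x in master.integers(0, 2**31 - 1, size=3))
    atlas = generate_atlas(config.n_nodes, seed=s_atlas, box_size_mm=config.box_size_mm)
    cohort = generate_cohort(config, seed=s_cohort)
    connectomes, truth = generate_connectomes(atlas, cohort, config, seed=s_conn)
    return atlas, cohort, connectomes, truth


def write_dataset(
    out_dir: str | Path,
    atlas: Atlas,
    cohort: pd.DataFrame,
    connectomes: Sequence[Connectome],
    truth: GroundTruth | None = None,
) -> None:
    """Write a dataset as plain-text files that round-trip through the readers.

    Layout: atlas.tsv, cohort.csv, ground_truth.json, and per subject
    <subject_id>_weights.tsv and <subject_id>_lengths.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(atlas, out / "atlas.tsv")
    cohort.drop(columns=[c for c in ("anx_latent",) if c in cohort.columns]) \
        .to_csv(out / "cohort.csv", index=False)
    for c in connectomes:
        write_connectome(c, out / f"{c.subject_id}_weights.tsv",
                         out / f"{c.subject_id}_lengths.tsv" if c.lengths is not None else None)
    if truth is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh)


def read_dataset(
    data_dir: str | Path,
) -> tuple[Atlas, pd.DataFrame, list[Connectome]]:
    """Read a dataset written by :func:`write_dataset` (ground truth ignored)."""
    data_dir = Path(data_dir)
    atlas = read_atlas(data_dir / "atlas.tsv")
    cohort = read_cohort(data_dir / "cohort.csv")
    connectomes = []
    for sid in cohort["subject_id"]:
        wpath = data_dir / f"{sid}_weights.tsv"
        lpath = data_dir / f"{sid}_lengths.tsv"
        connectomes.append(read_connectome(
            wpath, lpath if lpath.exists() else None, atlas=atlas, subject_id=str(sid)))
    return atlas, cohort, connectomes
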