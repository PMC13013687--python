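"""End-to-end orchestration: group analysis, transdiagnostic analysis, and
a simulation calibration suite.

``run_group_analysis`` executes the full sequence on a dataset directory:
backbone construction, omnibus NBS, FDR-corrected post-hoc contrast NBS
(three group contrasts, each with its own permutation null), the
ordered-pattern conjunction test, topology characterization of the pattern
component, and the nodal brain-wide meta-analysis. Outputs are written as
JSON/TSV under a run directory together with a log that echoes the
configuration hash and master seed, so reruns are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectomes import build_backbone, stack_edges, stack_strengths
from .glm import build_design, group_contrast
from .nbs import (
    component_effect_sizes,
    continuous_nbs,
    fdr_adjust,
    nbs_test,
    ordered_pattern_test,
)
from .nodal import nodal_t_map, paired_t_by_lobe, sign_proportion_test
from .simulate import read_dataset
from .topology import characterize_subnetwork

logger = logging.getLogger("nbsconn")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    Default thresholds follow common NBS practice for large samples: a
    primary F threshold of 4.0 for the omnibus test, t = 1.962 (the
    two-sided 5% normal quantile) for directed tests, 5000 permutations,
    1000 random subnetworks for the fiber-length null, and a 5% edge
    prevalence backbone.
    """

    data_dir: str = "."
    out_dir: str = "nbsconn_run"
    covariates: tuple[str, ...] = ("age", "sex", "site")
    f_threshold: float = 4.0
    t_threshold: float = 1.962
    t_threshold_secondary: float = 1.9   # MDD+ANX vs MDD post-hoc contrast
    n_perm: int = 5000
    n_random_networks: int = 1000
    prevalence: float = 0.05
    seed: int = 0
    alpha: float = 0.05
    scheme: str = "freedman_lane"
    null_mode: str = "uniform_edges"
    weight_transform: str = "raw"        # raw | log1p
    subset_sex: str | None = None
    subset_site: str | None = None
    subset_remission: str | None = None
    zscore_exclude: float | None = None  # per-subject mean-connectivity |z| cut

    def __post_init__(self) -> None:
        if self.f_threshold <= 0 or self.t_threshold <= 0:
            raise ValueError("primary thresholds must be positive")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers
                       if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(out_dir / "log.txt", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def _load_and_filter(config: PipelineConfig):
    atlas, cohort, connectomes = read_dataset(config.data_dir)
    keep = np.ones(len(cohort), dtype=bool)
    if config.subset_sex:
        keep &= (cohort["sex"] == config.subset_sex).to_numpy()
    if config.subset_site:
        keep &= (cohort["site"] == config.subset_site).to_numpy()
    if config.subset_remission:
        rem = cohort.get("remission")
        keep &= ((cohort["group"] == "HC") |
                 (rem.fillna("") == config.subset_remission)).to_numpy()
    if config.zscore_exclude is not None:
        means = np.array([c.weights.sum() / 2 for c in connectomes])
        z = (means - means.mean()) / means.std(ddof=1)
        keep &= np.abs(z) <= config.zscore_exclude
        logger.info("outlier exclusion removed %d subjects", int((~keep).sum()))
    cohort = cohort.loc[keep].reset_index(drop=True)
    connectomes = [c for c, k in zip(connectomes, keep) if k]
    logger.info("cohort after filtering: %d subjects", len(cohort))
    return atlas, cohort, connectomes


def _prepare(config: PipelineConfig):
    atlas, cohort, connectomes = _load_and_filter(config)
    backbone = build_backbone(connectomes, prevalence=config.prevalence)
    logger.info("backbone: %d edges over %d nodes", len(backbone), backbone.n_nodes)
    Y = stack_edges(connectomes, backbone)
    if config.weight_transform == "log1p":
        Y = np.log1p(Y)
    elif config.weight_transform != "raw":
        raise ValueError(f"unknown weight transform {config.weight_transform!r}")
    return atlas, cohort, connectomes, backbone, Y


def run_group_analysis(config: PipelineConfig) -> dict:
    """Omnibus + post-hoc + ordered-pattern NBS with topology and nodal maps."""
    out_dir = Path(config.out_dir)
    _setup_logging(out_dir)
    t0 = time.time()
    logger.info("group analysis; config %s seed %d", config.digest(), config.seed)
    atlas, cohort, connectomes, backbone, Y = _prepare(config)
    design = build_design(cohort, covariates=config.covariates, effect="group")
    groups = cohort["group"].to_numpy()

    report: dict = {"config_digest": config.digest(), "seed": config.seed,
                    "n_subjects": len(cohort), "n_backbone_edges": len(backbone)}

    logger.info("stage: omnibus NBS (F > %.3g, %d perms)", config.f_threshold,
                config.n_perm)
    omnibus = nbs_test(Y, design, backbone, config.f_threshold, "two_sided_F",
                       n_perm=config.n_perm, seed=config.seed, scheme=config.scheme)
    omnibus.write(out_dir / "components", "omnibus", atlas)
    report["omnibus"] = omnibus.to_dict()
    if omnibus.components:
        report["omnibus"]["effect_size"] = component_effect_sizes(
            Y, backbone, omnibus.components[0], design, groups)

    posthoc = {}
    if any(p <= config.alpha for p in omnibus.p_fwe):
        logger.info("stage: post-hoc contrasts with FDR")
        specs = [
            ("MDD_vs_HC", "MDD", "HC", "less", config.t_threshold),
            ("MDD_ANX_vs_HC", "MDD_ANX", "HC", "greater", config.t_threshold),
            ("MDD_ANX_vs_MDD", "MDD_ANX", "MDD", "greater", config.t_threshold_secondary),
        ]
        raw_p = []
        for k, (name, a, b, direction, thr) in enumerate(specs):
            res = nbs_test(
                Y, design, backbone, thr, direction,
                contrast=group_contrast(design, a, b),
                n_perm=config.n_perm, seed=config.seed + 1 + k, scheme=config.scheme)
            res.write(out_dir / "components", name, atlas)
            entry = res.to_dict()
            if res.components:
                entry["effect_size"] = component_effect_sizes(
                    Y, backbone, res.components[0], design, groups, pair=(a, b))
            posthoc[name] = entry
            raw_p.append(res.p_fwe[0] if len(res.p_fwe) else 1.0)
        adj = fdr_adjust(raw_p)
        for (name, *_), pa in zip(specs, adj):
            posthoc[name]["p_fwe_fdr"] = float(pa)
    report["posthoc"] = posthoc

    logger.info("stage: ordered-pattern conjunction test")
    pattern = ordered_pattern_test(
        Y, design, backbone,
        group_contrast(design, "MDD", "HC"),
        group_contrast(design, "MDD_ANX", "HC"),
        config.t_threshold, n_perm=config.n_perm, seed=config.seed + 10,
        scheme=config.scheme)
    pattern.write(out_dir / "components", "pattern", atlas)
    report["pattern"] = pattern.to_dict()

    if pattern.components:
        logger.info("stage: topology characterization")
        sub = characterize_subnetwork(
            pattern.components[0], backbone, atlas, connectomes,
            null_mode=config.null_mode, R=config.n_random_networks,
            seed=config.seed + 20)
        sub.write(out_dir, "pattern")
        report["pattern_topology"] = sub.to_dict()

    logger.info("stage: nodal maps and meta-analysis")
    strengths = stack_strengths(connectomes, backbone)
    tmaps = {}
    for name, a, b in (("HC_vs_MDD", "MDD", "HC"), ("HC_vs_MDD_ANX", "MDD_ANX", "HC")):
        tmaps[name] = nodal_t_map(strengths, design,
                                  group_contrast(design, a, b), label=name)
    nodal_dir = out_dir / "nodal"
    nodal_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "region": atlas.region_names,
        "t_HC_vs_MDD": tmaps["HC_vs_MDD"].t,
        "t_HC_vs_MDD_ANX": tmaps["HC_vs_MDD_ANX"].t,
    }).to_csv(nodal_dir / "t_maps.tsv", sep="\t", index=False)
    sign = sign_proportion_test(tmaps["HC_vs_MDD"], tmaps["HC_vs_MDD_ANX"])
    paired = paired_t_by_lobe(tmaps["HC_vs_MDD"], tmaps["HC_vs_MDD_ANX"], atlas)
    paired.to_csv(nodal_dir / "paired_t.tsv", sep="\t", index=False)
    report["nodal"] = {
        "sign_counts": sign.counts.tolist(),
        "sign_chi2": sign.chi2, "sign_p": sign.p,
        "paired_t": float(paired.loc[0, "t"]),
        "paired_p": float(paired.loc[0, "p"]),
        "paired_d": float(paired.loc[0, "cohens_d"]),
    }

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("done in %.1fs", time.time() - t0)
    return report


def run_transdiagnostic(
    config: PipelineConfig, scores: tuple[str, ...] = ("stai_state", "stai_trait")
) -> dict:
    """Continuous anxiety-connectivity NBS; FDR applied jointly over scores."""
    out_dir = Path(config.out_dir)
    _setup_logging(out_dir)
    logger.info("transdiagnostic analysis; config %s seed %d",
                config.digest(), config.seed)
    atlas, cohort, connectomes, backbone, Y = _prepare(config)
    report: dict = {"config_digest": config.digest(), "seed": config.seed}
    stage1_p = []
    entries = {}
    for k, score in enumerate(scores):
        if score not in cohort.columns or cohort[score].isna().any():
            raise ValueError(f"score column {score!r} missing or incomplete")
        design = build_design(cohort, covariates=config.covariates,
                              effect=f"continuous:{score}")
        stage1, directed = continuous_nbs(
            Y, design, backbone, config.f_threshold, config.t_threshold,
            n_perm=config.n_perm, seed=config.seed + 100 * (k + 1),
            scheme=config.scheme, alpha=config.alpha)
        stage1.write(out_dir / "components", f"{score}_undirected", atlas)
        entry = {"undirected": stage1.to_dict()}
        for direction, res in directed.items():
            res.write(out_dir / "components", f"{score}_{direction}", atlas)
            entry[direction] = res.to_dict()
        entries[score] = entry
        stage1_p.append(stage1.p_fwe[0] if len(stage1.p_fwe) else 1.0)
    adj = fdr_adjust(stage1_p)
    for score, pa in zip(scores, adj):
        entries[score]["p_fwe_fdr"] = float(pa)
    report["scores"] = entries
    with open(out_dir / "report_transdiagnostic.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_simulation_suite(
    n_replicates: int = 50,
    deltas: tuple[float, ...] = (0.2, 0.5, 0.8),
    alphas: tuple[float, ...] = (0.01, 0.05),
    n_per_group: int = 40,
    n_nodes: int = 30,
    planted_size: int = 20,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Type-I and power calibration of the NBS over a seed grid.

    Each replicate generates a scaled synthetic cohort (null for type-I,
    planted effects for power) and runs the omnibus NBS; the table reports
    empirical rejection rates with binomial standard errors.
    """
    import dataclasses as dc

    from .simulate import GeneratorConfig, generate_dataset

    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    for delta in (0.0, *deltas):
        rejections = {a: 0 for a in alphas}
        for r in range(n_replicates):
            cfg = dc.replace(
                GeneratorConfig(), n_hc=n_per_group, n_mdd=n_per_group,
                n_mdd_anx=n_per_group, n_nodes=n_nodes,
                planted_size=planted_size, anxiety_size=0,
                delta_hypo=-delta, delta_hyper=delta,
                seed=seed + 1000 * r + int(delta * 100))
            atlas, cohort, conns, _ = generate_dataset(cfg)
            backbone = build_backbone(conns, prevalence=0.05)
            Y = stack_edges(conns, backbone)
            design = build_design(cohort)
            res = nbs_test(Y, design, backbone, 4.0, "two_sided_F",
                           n_perm=n_perm, seed=cfg.seed)
            p_min = min(res.p_fwe) if len(res.p_fwe) else 1.0
            for a in alphas:
                rejections[a] += p_min <= a
        for a in alphas:
            rate = rejections[a] / n_replicates
            rows.append({
                "delta": delta, "alpha": a, "rejection_rate": rate,
                "se": np.sqrt(rate * (1 - rate) / n_replicates),
                "n_replicates": n_replicates,
            })
    return pd.DataFrame(rows)
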