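"""End-to-end pipeline: simulate -> infer -> network -> statistics -> nulls.

A run is described by a :class:`RunConfig` (loadable from a flat YAML file
with one section per stage).  ``run_pipeline`` executes the enabled stages
in dependency order, writes every interface file, and returns a
:class:`RunReport` whose body is deterministic for a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io, network as net, nulls, saturation, stats
from .groups import build_group_matrix, infer_groups
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "RunReport", "run_pipeline", "assortativity_statistic"]

log = logging.getLogger("flocknet")

_TRAITS = ("sex", "age_class", "residency")


@dataclass
class RunConfig:
    """All pipeline parameters in one place."""

    out_dir: str = "flocknet_run"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "infer", "network", "stats", "nulls", "saturation"]
    )
    simulation: dict = field(default_factory=dict)
    detections_csv: str | None = None      # used instead of simulation when given
    phenotypes_csv: str | None = None
    k_max: int | None = None
    min_component_weight: float = 0.0
    node_iterations: int = 1000
    stream_iterations: int = 10_000
    sample_every: int = 100
    lag_bins: list[float] | None = None
    log_level: str = "INFO"

    _KNOWN = None  # filled below

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not isinstance(cfg.seed, int):
            raise ValueError("seed must be an integer")
        for p in (cfg.detections_csv, cfg.phenotypes_csv):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input file does not exist: {p}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage results plus a provenance block."""

    body: dict

    def to_json(self) -> str:
        return json.dumps(self.body, indent=2, sort_keys=True, default=_json_default)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, np.ndarray):
        return [_json_default(v) if isinstance(v, np.generic) else v for v in obj.tolist()]
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _clean(values: np.ndarray) -> list:
    return [None if not np.isfinite(v) else float(v) for v in np.asarray(values, float)]


def assortativity_statistic(trait: str):
    """Statistic closure: discrete assortativity of ``trait`` on the SRI network.

    The network is memoised on the matrix content, so label-only
    permutations (the node null) do not rebuild it.
    """
    cache: dict = {}

    def _network(matrix):
        key = (id(matrix), hash(matrix.incidence.tobytes()))
        if cache.get("key") != key:
            cache["key"] = key
            cache["net"] = net.build_network(matrix)
        return cache["net"]

    def fn(matrix, phenotypes):
        g = _network(matrix)
        labels = (
            phenotypes.set_index("individual_id")[trait]
            .reindex(g.node_ids)
            .fillna("unknown")
            .to_numpy()
        )
        try:
            return net.assortativity_discrete(g, labels)
        except net.UndefinedStatisticError:
            return np.nan

    return fn


def run_pipeline(config: RunConfig) -> RunReport:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = io.ensure_dir(config.out_dir)
    body: dict = {
        "provenance": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "flocknet_version": __version__,
            "stages": list(config.stages),
        }
    }
    stages = set(config.stages)
    detections = phenotypes = None
    matrix = None

    if "simulate" in stages:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
        log.info("simulate: %s", sim_cfg)
        phenotypes, layout, home_ranges, detections, truth = _simulate(sim_cfg)
        io.write_phenotypes(phenotypes, out / "phenotypes.csv")
        io.write_detections(detections, out / "detections.csv")
        truth.memberships.to_csv(out / "true_groups.csv", index=False)
        truth.group_meta.to_csv(out / "true_groups_meta.csv", index=False)
        body["simulate"] = {
            "n_individuals": len(phenotypes),
            "n_detections": len(detections),
            "n_true_groups": len(truth.group_meta),
            "planted_effects": truth.planted_effect_labels,
        }
    else:
        if config.detections_csv:
            detections = io.read_detections(config.detections_csv)
        if config.phenotypes_csv:
            phenotypes = io.read_phenotypes(config.phenotypes_csv)

    if "infer" in stages:
        if detections is None:
            raise RuntimeError("stage 'infer' needs detections (simulate or detections_csv)")
        gatherings = infer_groups(
            detections,
            k_max=config.k_max,
            min_component_weight=config.min_component_weight,
            seed=config.seed,
        )
        matrix = build_group_matrix(gatherings)
        io.write_groups(matrix, out / "groups.csv", out / "groups_meta.csv")
        log.info("infer: %d detections -> %d groups", len(detections), matrix.n_groups)
        body["infer"] = {"n_groups": matrix.n_groups, "n_individuals": matrix.n_individuals}

    if matrix is None and any(s in stages for s in ("network", "stats", "nulls", "saturation")):
        raise RuntimeError("downstream stages need the 'infer' stage (or pre-read groups)")

    if "network" in stages:
        g = net.build_network(matrix)
        net.write_graphml(g, out / "network.graphml")
        net.write_csv(g, out / "network.csv")
        body["network"] = {
            "n_nodes": g.n_nodes,
            "density": net.network_density(g) if g.n_nodes >= 2 else None,
        }

    if "stats" in stages:
        mean, mx, typical = stats.group_size_summaries(matrix)
        binning = stats.bin_group_sizes(matrix)
        edges = np.asarray(config.lag_bins) if config.lag_bins else stats.log_lag_bins()
        curve = stats.stability_curve(matrix, edges)
        body["stats"] = {
            "group_size": {"mean": mean, "max": mx, "typical": typical},
            "size_bins": binning.labels(),
            "stability": {
                "lag_bin_edges_s": _clean(curve.bin_edges),
                "s": _clean(curve.s_values),
                "pair_counts": _clean(curve.pair_counts),
            },
        }
        if phenotypes is not None:
            profiles = {}
            for trait, focal in (("sex", "male"), ("age_class", "juvenile"), ("residency", "immigrant")):
                prof = stats.class_proportion_profile(matrix, phenotypes, binning, trait, focal)
                profiles[trait] = {"focal_class": focal, "mean_proportion": _clean(prof.values)}
            body["stats"]["composition"] = profiles

    if "nulls" in stages:
        if phenotypes is None:
            raise RuntimeError("stage 'nulls' needs phenotypes")
        verdicts = {}
        stream_final = None
        for i, trait in enumerate(_TRAITS):
            fn = assortativity_statistic(trait)
            node = nulls.node_permutation_null(
                matrix,
                phenotypes,
                fn,
                n_iter=config.node_iterations,
                seed=config.seed + 1000 + i,
                statistic_name=f"assortativity[{trait}]",
            )
            stream = nulls.datastream_permutation_null(
                matrix,
                phenotypes,
                fn,
                n_iter=config.stream_iterations,
                sample_every=config.sample_every,
                seed=config.seed + 2000 + i,
                statistic_name=f"assortativity[{trait}]",
            )
            stream_final = stream.final_matrix
            cls = nulls.classify_effect(node.observed, node, stream, trait=trait)
            lo_n, hi_n = node.envelope
            lo_s, hi_s = stream.envelope
            verdicts[trait] = {
                "observed": float(node.observed),
                "verdict": cls.verdict,
                "node_envelope": [float(lo_n), float(hi_n)],
                "stream_envelope": [float(lo_s), float(hi_s)],
                "stream_skipped_swaps": stream.n_skipped,
            }
            log.info("nulls[%s]: observed=%.4f verdict=%s", trait, node.observed, cls.verdict)
        body["nulls"] = verdicts
        if "stats" in stages and stream_final is not None:
            # stability ratio against the final randomized matrix
            edges = np.asarray(config.lag_bins) if config.lag_bins else stats.log_lag_bins()
            obs_curve = stats.stability_curve(matrix, edges)
            perm_curve = stats.stability_curve(stream_final, edges)
            body["stats"]["stability"]["ratio_to_permuted"] = _clean(
                stats.stability_ratio(obs_curve, perm_curve)
            )

    if "saturation" in stages:
        body["saturation"] = {}
        for response in ("mean", "max"):
            try:
                res = saturation.SaturationModel.from_matrix(matrix, response).fit()
                body["saturation"][response] = res.to_dict()
            except ValueError as exc:
                body["saturation"][response] = {"error": str(exc)}

    report = RunReport(body)
    report.write(out / "run_report.json")
    return report


def _simulate(sim_cfg: SimulationConfig):
    population, layout, home_ranges, detections, truth = simulate_dataset(sim_cfg)
    return population, layout, home_ranges, detections, truth
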