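"""Synthetic detection streams with planted social and spatial structure.

Emulates a winter field design in which a grid of RFID-equipped feeding
stations logs visits of PIT-tagged birds over weekend sampling periods.
Foraging flocks ("gatherings") form at feeders; each member of a gathering
emits a burst of antenna reads around the gathering time.  The generator
plants three kinds of ground truth that downstream stages must recover:

* **social preferences** — multiplicative weights on phenotype similarity
  (same sex / same age / same residency) acting during sequential member
  sampling, producing within-group assortment or disassortment;
* **spatial segregation** — immigrants settle toward one edge of the grid,
  producing spatially (not socially) driven assortment by residency;
* **group-size saturation** — expected group size follows a logistic
  (saturating) function of the local pool size, with a known asymptote.

Every run is fully determined by ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthBundle",
    "make_feeder_grid",
    "generate_population",
    "assign_home_ranges",
    "simulate_gatherings",
    "simulate_dataset",
]

#: daylight window (seconds from local midnight) in which gatherings occur
DAY_START_S = 7 * 3600
DAY_END_S = 17 * 3600

# sex-specific morphometrics (mm): males larger in both wing and tarsus
_WING = {"male": (76.0, 1.9), "female": (73.5, 1.8)}
_TARSUS = {"male": (20.6, 0.6), "female": (19.9, 0.6)}
_WING_TARSUS_CORR = 0.4


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults give a desk-scale version of the field design: a grid of
    feeders sampled over consecutive two-day periods, bursty within-day
    visitation and flocks of mean size about five.
    """

    n_individuals: int = 100
    sex_ratio: float = 0.5            # proportion male
    juvenile_prop: float = 0.45
    immigrant_prop: float = 0.35
    n_feeders: int = 9                # laid out on a near-square grid
    n_periods: int = 4                # two days per sampling period
    gatherings_per_feeder_day: float = 6.0
    within_burst_sd: float = 30.0     # seconds
    detections_per_member: float = 3.0
    feeder_spacing: float = 250.0     # metres between adjacent feeders
    home_range_sd: float = 80.0       # availability-kernel scale, metres
    spatial_segregation_strength: float = 0.0   # immigrant displacement, metres
    social_preference: Mapping[str, float] = field(
        default_factory=lambda: {"same_sex": 1.0, "same_age": 1.0, "same_residency": 1.0}
    )
    group_size_asymptote: float = 8.0
    group_size_dispersion: float = 8.0   # negative-binomial shape
    seed: int = 0

    def validate(self) -> None:
        for name in ("sex_ratio", "juvenile_prop", "immigrant_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in (
            "gatherings_per_feeder_day",
            "within_burst_sd",
            "detections_per_member",
            "home_range_sd",
            "feeder_spacing",
            "group_size_asymptote",
            "group_size_dispersion",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_individuals < 0 or self.n_feeders < 1 or self.n_periods < 1:
            raise ConfigurationError("counts must be non-negative (feeders/periods >= 1)")
        if self.spatial_segregation_strength < 0:
            raise ConfigurationError("spatial_segregation_strength must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthBundle:
    """Planted ground truth: one row of ``memberships`` per (group, member)."""

    memberships: pd.DataFrame         # columns: group_id, individual_id
    group_meta: pd.DataFrame          # group_id, feeder_id, day, sampling_period, time_s
    planted_effect_labels: dict[str, str]   # trait -> {"social", "spatial", "none"}


def make_feeder_grid(n_feeders: int, spacing: float = 250.0) -> pd.DataFrame:
    """Stratified near-square grid of feeders: columns ``feeder_id, x, y``."""
    if n_feeders < 1:
        raise ConfigurationError("need at least one feeder")
    ncol = int(np.ceil(np.sqrt(n_feeders)))
    rows = np.arange(n_feeders) // ncol
    cols = np.arange(n_feeders) % ncol
    return pd.DataFrame(
        {
            "feeder_id": [f"F{i:02d}" for i in range(n_feeders)],
            "x": cols * spacing,
            "y": rows * spacing,
        }
    )


def generate_population(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a phenotype table.

    Sex, age class and residency are independent Bernoulli draws; wing and
    tarsus come from sex-specific bivariate normals with males larger in
    both measures.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals
    ids = [f"ID{i:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    age = np.where(rng.random(n) < config.juvenile_prop, "juvenile", "adult")
    res = np.where(rng.random(n) < config.immigrant_prop, "immigrant", "local")
    wing = np.empty(n)
    tarsus = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        k = int(m.sum())
        mw, sw = _WING[s]
        mt, st = _TARSUS[s]
        cov = np.array(
            [[sw**2, _WING_TARSUS_CORR * sw * st], [_WING_TARSUS_CORR * sw * st, st**2]]
        )
        draws = rng.multivariate_normal([mw, mt], cov, size=k) if k else np.empty((0, 2))
        wing[m], tarsus[m] = draws[:, 0], draws[:, 1]
    return pd.DataFrame(
        {
            "individual_id": ids,
            "sex": sex,
            "age_class": age,
            "residency": res,
            "wing_mm": np.round(wing, 2),
            "tarsus_mm": np.round(tarsus, 2),
        }
    )


def assign_home_ranges(
    population: pd.DataFrame,
    layout: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign each individual a home-range centre at one feeder.

    Locals pick a feeder uniformly.  Immigrants pick feeders with weight
    ``exp(strength * (x - x_max) / home_range_sd)``: at strength 0 this is
    uniform (immigrants fully mixed); as strength grows, immigrant centres
    concentrate monotonically toward the eastern (max-``x``) edge of the
    grid, emulating exclusion of immigrants from core areas.

    Returns a frame ``individual_id, home_feeder, home_x, home_y``.
    """
    if len(layout) == 0:
        raise ConfigurationError("feeder layout is empty")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    x = layout["x"].to_numpy(float)
    strength = config.spatial_segregation_strength
    w_imm = np.exp(strength * (x - x.max()) / config.home_range_sd)
    w_imm = w_imm / w_imm.sum()
    n_feed = len(layout)
    is_imm = (population["residency"] == "immigrant").to_numpy()
    choice = np.empty(len(population), dtype=int)
    choice[~is_imm] = rng.choice(n_feed, size=int((~is_imm).sum()))
    choice[is_imm] = rng.choice(n_feed, size=int(is_imm.sum()), p=w_imm)
    return pd.DataFrame(
        {
            "individual_id": population["individual_id"].to_numpy(),
            "home_feeder": layout["feeder_id"].to_numpy()[choice],
            "home_x": layout["x"].to_numpy()[choice],
            "home_y": layout["y"].to_numpy()[choice],
        }
    )


def _logistic_mean_size(pool: float, asymptote: float) -> float:
    # saturating map from local pool size to expected group size
    x0, s = asymptote, asymptote / 2.0
    return float(asymptote / (1.0 + np.exp(-(pool - x0) / s)))


def _draw_group_size(mean: float, dispersion: float, cap: int, rng: np.random.Generator) -> int:
    """Zero-truncated negative binomial with the given mean, capped at ``cap``."""
    mean = max(mean, 0.2)
    p = dispersion / (dispersion + mean)
    for _ in range(64):
        k = rng.negative_binomial(dispersion, p)
        if k >= 1:
            return int(min(k, cap))
    return 1


def _pair_feature_match(pop: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for feat, col in (("same_sex", "sex"), ("same_age", "age_class"), ("same_residency", "residency")):
        v = pop[col].to_numpy()
        out[feat] = v[:, None] == v[None, :]
    return out


def simulate_gatherings(
    population: pd.DataFrame,
    layout: pd.DataFrame,
    home_ranges: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate gatherings and the detection stream they emit.

    For each feeder and study day, gathering times are Poisson in number and
    uniform over daylight.  A gathering's members are drawn sequentially
    without replacement: the first by spatial availability alone (Gaussian
    kernel of distance from home-range centre to the feeder, scale
    ``home_range_sd``), each subsequent member by availability times the
    product of pairwise social-preference weights against current members.
    Each member emits at least one detection at times
    ``Normal(gathering time, within_burst_sd)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng

    n = len(population)
    n_days = 2 * config.n_periods
    det_rows: list[tuple] = []
    mem_rows: list[tuple] = []
    meta_rows: list[tuple] = []

    if n == 0:
        empty_det = pd.DataFrame(
            columns=["time_s", "day", "sampling_period", "feeder_id", "individual_id", "true_group_id"]
        )
        truth = TruthBundle(
            memberships=pd.DataFrame(columns=["group_id", "individual_id"]),
            group_meta=pd.DataFrame(
                columns=["group_id", "feeder_id", "day", "sampling_period", "time_s"]
            ),
            planted_effect_labels=_planted_labels(config),
        )
        return empty_det, truth

    ids = population["individual_id"].to_numpy()
    hr = home_ranges.set_index("individual_id").loc[ids]
    cx, cy = hr["home_x"].to_numpy(float), hr["home_y"].to_numpy(float)
    match = _pair_feature_match(population)
    pref = dict(config.social_preference)

    # pairwise social weight matrix: product over matching features
    social = np.ones((n, n))
    for feat, w in pref.items():
        if feat not in match:
            raise ConfigurationError(f"unknown social_preference feature: {feat}")
        social *= np.where(match[feat], float(w), 1.0)

    gid = 0
    for _, f in layout.iterrows():
        d2 = (cx - f["x"]) ** 2 + (cy - f["y"]) ** 2
        avail = np.exp(-d2 / (2.0 * config.home_range_sd**2))
        if avail.sum() <= 0:
            continue
        pool = float(avail.sum())
        for day in range(1, n_days + 1):
            period = (day - 1) // 2 + 1
            n_gath = rng.poisson(config.gatherings_per_feeder_day)
            times = np.sort(rng.uniform(DAY_START_S, DAY_END_S, size=n_gath))
            for t in times:
                size = _draw_group_size(
                    _logistic_mean_size(pool, config.group_size_asymptote),
                    config.group_size_dispersion,
                    cap=n,
                    rng=rng,
                )
                members = _sample_members(avail, social, size, rng)
                gid += 1
                gname = f"G{gid:06d}"
                meta_rows.append((gname, f["feeder_id"], day, period, float(t)))
                for m in members:
                    mem_rows.append((gname, ids[m]))
                    n_reads = max(1, rng.poisson(config.detections_per_member))
                    read_t = rng.normal(t, config.within_burst_sd, size=n_reads)
                    for rt in read_t:
                        det_rows.append((float(rt), day, period, f["feeder_id"], ids[m], gname))

    detections = pd.DataFrame(
        det_rows,
        columns=["time_s", "day", "sampling_period", "feeder_id", "individual_id", "true_group_id"],
    ).sort_values(["day", "feeder_id", "time_s"], kind="mergesort", ignore_index=True)
    truth = TruthBundle(
        memberships=pd.DataFrame(mem_rows, columns=["group_id", "individual_id"]),
        group_meta=pd.DataFrame(
            meta_rows, columns=["group_id", "feeder_id", "day", "sampling_period", "time_s"]
        ),
        planted_effect_labels=_planted_labels(config),
    )
    return detections, truth


def _sample_members(
    avail: np.ndarray, social: np.ndarray, size: int, rng: np.random.Generator
) -> list[int]:
    """Sequential weighted sampling without replacement."""
    n = len(avail)
    size = min(size, int((avail > 0).sum()))
    weights = avail.copy()
    members: list[int] = []
    for _ in range(size):
        total = weights.sum()
        if total <= 0:
            break
        pick = int(rng.choice(n, p=weights / total))
        members.append(pick)
        weights *= social[pick]
        weights[pick] = 0.0
    return members


def _planted_labels(config: SimulationConfig) -> dict[str, str]:
    pref = dict(config.social_preference)
    labels = {}
    for trait, feat in (("sex", "same_sex"), ("age_class", "same_age"), ("residency", "same_residency")):
        if abs(pref.get(feat, 1.0) - 1.0) > 1e-12:
            labels[trait] = "social"
        elif trait == "residency" and config.spatial_segregation_strength > 0:
            labels[trait] = "spatial"
        else:
            labels[trait] = "none"
    return labels


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: population, layout, home ranges, detections, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    population = generate_population(config, rng)
    layout = make_feeder_grid(config.n_feeders, config.feeder_spacing)
    home_ranges = assign_home_ranges(population, layout, config, rng)
    detections, truth = simulate_gatherings(population, layout, home_ranges, config, rng)
    return population, layout, home_ranges, detections, truth
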