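"""Synthetic CalCOFI-like dataset generator.

The generator writes down a small "true world" with the statistical structure
the analysis assumes, and persists every latent quantity so downstream stages
can be tested as parameter-recovery problems:

* a cross-shore station grid with known distances to the coast;
* per-cruise nitracline fields ``N(s, c) = a_c + b_c * dist(s) + eps`` whose
  slope ``b_c`` is steep in upwelling-favorable seasons and phases and flat in
  warm-anomaly phases;
* nitrate bottle profiles built piecewise-linearly so that 1 µM linear
  interpolation recovers the realized nitracline exactly;
* two Dirichlet endmember communities per taxonomic group (nearshore: fewer,
  less even ASVs; offshore: more, more even ASVs) mixed per sample with weight
  ``w = logistic(-k * (N - N0))``;
* multinomial read counts at log-normal sequencing depths straddling the
  17,000-read rarefaction cutoff.

All randomness flows from one master seed through named ``SeedSequence``
children spawned in a fixed order (region, endmembers, communities, reads), so
a run is reproducible end to end and each stage can be re-drawn independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from plankmap.core_data import AsvTable, Dataset, DEFAULT_PHASE_MAP, TaxonomyMap

SEASONS = ("winter", "spring", "summer", "fall")
#: multiplicative seasonal modulation of the cross-shore nitracline slope;
#: upwelling steepens the field in spring/summer.
SEASON_FACTOR = {"winter": -1.0, "spring": 1.0, "summer": 0.5, "fall": -0.5}
CRUISE_MONTHS = {"winter": 2, "spring": 5, "summer": 8, "fall": 11}

DEFAULT_GROUPS = (
    "heterotrophic_bacteria",
    "cyanobacteria",
    "archaea",
    "photosynthetic_protists",
    "heterotrophic_protists",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic world.

    Defaults emulate a six-year quarterly survey of ~40 stations spanning a
    coastal-upwelling to oligotrophic-offshore gradient, sampled at the
    surface (10 m) and deep chlorophyll maximum.
    """

    # sampling design
    n_stations: int = 40
    dist_min_km: float = 5.0
    dist_max_km: float = 350.0
    start_year: int = 2014
    n_years: int = 6
    cruises_per_year: int = 4          # quarterly cruises
    depth_classes: tuple[str, ...] = ("surface", "DCM")

    # nitracline field N(s,c) = a_c + b_c * dist + eps  [m]
    phase_intercept_m: Mapping[str, float] = field(
        default_factory=lambda: {"warm": 30.0, "cool": 14.0, "intermediate": 18.0})
    phase_slope_m_per_km: Mapping[str, float] = field(
        default_factory=lambda: {"warm": 0.05, "cool": 0.25, "intermediate": 0.15})
    season_slope_amplitude: float = 0.4    # b_c *= 1 + amp * SEASON_FACTOR[season]
    #: upwelling both steepens the cross-shore slope and shallows the
    #: nearshore intercept: a_c = phase intercept - amp * SEASON_FACTOR
    intercept_season_amp_m: float = 10.0
    slope_jitter_sd: float = 0.01          # per-cruise, m/km
    intercept_jitter_sd: float = 1.0       # per-cruise, m
    station_noise_sd_m: float = 3.0        # eps, truncated at +-2.5 sd
    min_nitracline_m: float = 2.0          # noisy field clipped here (outcropping)

    # bottle profiles
    profile_depths_m: tuple[float, ...] = tuple(float(z) for z in range(0, 210, 10))
    no3_gradient_uM_per_m: float = 0.05    # keeps the 1 µM crossing linear between bottles
    no3_background_uM: float = 0.05        # per-cast background drawn in [min, max]
    no3_background_max_uM: float = 0.45
    #: biological drawdown of nitrate above the nitracline: bottles strictly
    #: above the 1 µM bracketing pair are scaled by a per-cast factor drawn
    #: uniformly from this range (consumption decouples surface nitrate from
    #: the nitracline without touching the interpolated crossing)
    no3_drawdown_range: tuple[float, float] = (0.15, 1.0)
    env_noise_sd: float = 0.4              # per-cast noise on derived covariates
    #: station-persistent "site effect" noise on each covariate; does not
    #: average away across cruises, so covariates stay degraded copies of the
    #: nitracline field rather than converging onto it
    station_effect_sd: float = 1.0

    # community mixing w = logistic(-k (N - N0))
    mixing_steepness: float = 0.3          # k, 1/m
    mixing_midpoint_m: float = 25.0        # N0
    sample_logit_noise_sd: float = 0.5
    #: phases where cruise-level mixing decouples from that cruise's slope:
    #: samples mix on the station's long-term mean nitracline plus a shared
    #: per-cruise offset, so the spatial gradient persists but the
    #: slope-proportion relation breaks
    decoupled_phases: tuple[str, ...] = ("intermediate",)
    decoupled_cruise_offset_sd_m: float = 6.0

    # endmember communities
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_asvs_per_group: int = 40
    dirichlet_nearshore: float = 0.3       # sparse, uneven
    dirichlet_offshore: float = 2.0        # dense, even
    nearshore_support_fraction: float = 0.5

    # sequencing
    depth_median_reads: float = 50_000.0
    depth_log_sigma: float = 0.5           # ~1.5% of samples fall below 17,000 reads

    phase_map: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_PHASE_MAP))
    seed: int = 0

    def validate(self) -> None:
        if self.n_asvs_per_group < 2:
            raise ValueError("need at least 2 ASVs per group")
        for name in ("season_slope_amplitude", "slope_jitter_sd", "intercept_jitter_sd",
                     "station_noise_sd_m", "no3_gradient_uM_per_m", "env_noise_sd",
                     "sample_logit_noise_sd", "depth_median_reads", "depth_log_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        spacing = np.diff(self.profile_depths_m)
        if np.any(spacing <= 0):
            raise ValueError("profile depths must be strictly increasing")
        if not 0 < self.no3_background_uM <= self.no3_background_max_uM < 1.0:
            raise ValueError("need 0 < no3 background min <= max < 1 µM")
        # the 1 µM crossing must stay on a linear segment between bottles
        clip_span = (1.0 - self.no3_background_max_uM) / self.no3_gradient_uM_per_m
        if clip_span < spacing.max():
            raise ValueError(
                "no3 gradient too steep for the bottle spacing: interpolation "
                "would hit the background clip inside the bracketing interval")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_intercept_m"] = dict(self.phase_intercept_m)
        d["phase_slope_m_per_km"] = dict(self.phase_slope_m_per_km)
        d["phase_map"] = {int(k): v for k, v in dict(self.phase_map).items()}
        return d


@dataclass
class RegionSim:
    stations: pd.DataFrame       # station_id, lon, lat, distance_to_coast_km, is_cardinal
    profiles: pd.DataFrame       # long bottle table
    indices: pd.DataFrame        # date, cuti, beuti
    cruises: pd.DataFrame        # cruise_id, date, year, season, phase, true_slope, true_intercept
    station_cruise: pd.DataFrame  # station_id, cruise_id, true_nitracline_m


@dataclass
class CommunitySim:
    samples: pd.DataFrame            # sample metadata incl. phase
    compositions: np.ndarray         # (n_asvs_total, n_samples) expected proportions
    asv_groups: np.ndarray           # group label per ASV row
    sample_truths: pd.DataFrame      # sample_id, mixing_weight, true_label
    endmembers: dict[str, tuple[np.ndarray, np.ndarray]]  # group -> (near, off)


def default_group_config(config: SimConfig | None = None) -> list[dict]:
    """Group-mapping config that recovers the generating groups exactly."""
    groups = (config or SimConfig()).groups
    return [{"group_name": g, "rank": "clade", "match_patterns": [f"{g}*"]}
            for g in groups]


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("region", "endmembers", "communities", "reads")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _truncated_normal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Normal(0, sd) truncated at +-2.5 sd; keeps latent depths bounded."""
    if sd == 0:
        return np.zeros(size)
    return np.clip(rng.normal(0.0, sd, size), -2.5 * sd, 2.5 * sd)


def simulate_region(config: SimConfig, rng: np.random.Generator | None = None) -> RegionSim:
    """Draw the station grid, per-cruise nitracline fields and bottle profiles.

    Raises ``ValueError`` if the configuration produces a non-positive latent
    nitracline depth anywhere.
    """
    config.validate()
    rng = rng if rng is not None else _spawn_rngs(config.seed)["region"]

    # station grid: evenly spread offshore distances with mild jitter, laid
    # out southwest of a straight coastline for plausible lon/lat
    dist = np.linspace(config.dist_min_km, config.dist_max_km, config.n_stations)
    if config.n_stations > 1:
        jitter_span = 0.25 * (dist[1] - dist[0])
        dist = dist + rng.uniform(-jitter_span, jitter_span, config.n_stations)
    dist = np.maximum(dist, 0.5)
    lat = 34.0 - 0.004 * dist + rng.normal(0, 0.05, config.n_stations)
    lon = -117.5 - dist / (111.195 * np.cos(np.radians(lat)))
    stations = pd.DataFrame({
        "station_id": [f"st{i:02d}" for i in range(config.n_stations)],
        "lon": lon, "lat": lat,
        "distance_to_coast_km": dist,
        "is_cardinal": [i % 5 == 0 for i in range(config.n_stations)],
    })

    years = range(config.start_year, config.start_year + config.n_years)
    cruise_rows = []
    for year in years:
        phase = dict(config.phase_map)[year]
        for season in SEASONS[: config.cruises_per_year]:
            b = dict(config.phase_slope_m_per_km)[phase]
            b = b * (1.0 + config.season_slope_amplitude * SEASON_FACTOR[season])
            b = b + float(_truncated_normal(rng, config.slope_jitter_sd, ()))
            a = (dict(config.phase_intercept_m)[phase]
                 - config.intercept_season_amp_m * SEASON_FACTOR[season]
                 + float(_truncated_normal(rng, config.intercept_jitter_sd, ())))
            cruise_rows.append({
                "cruise_id": f"{year}-{season}",
                "date": pd.Timestamp(year=year, month=CRUISE_MONTHS[season], day=15),
                "year": year, "season": season, "phase": phase,
                "true_slope": b, "true_intercept": a,
            })
    cruises = pd.DataFrame(cruise_rows)

    depths = np.asarray(config.profile_depths_m)

    # station-persistent site effects: covariates are linear functions of the
    # nitracline depth plus per-cast noise plus these fixed offsets
    sd0 = config.station_effect_sd
    site = {
        "temp": rng.normal(0, 0.8 * sd0, config.n_stations),
        "sal": rng.normal(0, 0.05 * sd0, config.n_stations),
        "chl": rng.normal(0, 0.4 * sd0, config.n_stations),
        "po4": rng.normal(0, 0.15 * sd0, config.n_stations),
        "sio4": rng.normal(0, 1.5 * sd0, config.n_stations),
    }

    sc_rows, prof_rows = [], []
    for _, cr in cruises.iterrows():
        noiseless = cr["true_intercept"] + cr["true_slope"] * dist
        if np.any(noiseless <= 0):
            raise ValueError(
                f"config produces non-positive nitracline depth on {cr['cruise_id']}")
        eps = _truncated_normal(rng, config.station_noise_sd_m, config.n_stations)
        n_true = np.maximum(noiseless + eps, config.min_nitracline_m)
        if np.any(n_true >= depths[-1]):
            raise ValueError(
                f"latent nitracline deeper than the profile on {cr['cruise_id']}")
        for s in range(config.n_stations):
            N = float(n_true[s])
            sc_rows.append({"station_id": stations["station_id"][s],
                            "cruise_id": cr["cruise_id"],
                            "true_nitracline_m": N})
            sigma = config.env_noise_sd
            # per-cast background above the nitracline; the bound checked in
            # validate() keeps the 1 µM crossing on a linear bottle segment
            no3_bg = rng.uniform(config.no3_background_uM, config.no3_background_max_uM)
            no3 = np.maximum(no3_bg,
                             1.0 + config.no3_gradient_uM_per_m * (depths - N))
            # drawdown above the bracketing pair: scaling a non-decreasing
            # prefix keeps the profile monotone and the crossing exact
            bracket_lo = int(np.searchsorted(depths, N, side="left")) - 1
            if bracket_lo > 0:
                drawdown = rng.uniform(*config.no3_drawdown_range)
                no3 = no3.copy()
                no3[:bracket_lo] *= drawdown
            temp_surf = 12.0 + 0.08 * N + site["temp"][s] + rng.normal(0, sigma)
            sal_surf = (33.2 - 0.002 * N + site["sal"][s]
                        + rng.normal(0, 0.05 * sigma))
            po4_surf = max(0.05, 1.0 - 0.005 * N + site["po4"][s]
                           + rng.normal(0, 0.1 * sigma))
            sio4_surf = max(0.2, 12.0 - 0.06 * N + site["sio4"][s]
                            + rng.normal(0, sigma))
            chl_surf = max(0.02, 3.0 - 0.018 * N + site["chl"][s]
                           + rng.normal(0, 0.75 * sigma))
            dcm = float(np.clip(0.8 * N + 10.0, 15.0, 90.0))
            # vertical chl shape: DCM bump over a background fraction,
            # normalized so the 10 m bottle reads exactly chl_surf (the
            # stated linear-in-N quantity)
            bump = 0.25 + 0.75 * np.exp(-0.5 * ((depths - dcm) / 25.0) ** 2)
            bump = bump / (0.25 + 0.75 * np.exp(-0.5 * ((10.0 - dcm) / 25.0) ** 2))
            prof_rows.append(pd.DataFrame({
                "station_id": stations["station_id"][s],
                "cruise_id": cr["cruise_id"],
                "depth_m": depths,
                "no3": no3,
                "po4": po4_surf + 0.01 * depths,
                "sio4": sio4_surf + 0.05 * depths,
                "temperature": temp_surf - 0.05 * depths,
                "salinity": sal_surf + 0.003 * depths,
                "chl_a": chl_surf * bump,
            }))
    profiles = pd.concat(prof_rows, ignore_index=True)
    station_cruise = pd.DataFrame(sc_rows)

    # monthly upwelling indices: CUTI seasonal cycle, BEUTI depressed in the
    # warm phase (stratification decouples transport from nitrate flux)
    months = pd.date_range(f"{config.start_year}-01-15",
                           periods=12 * config.n_years, freq="MS") + pd.Timedelta(days=14)
    doy = months.month.to_numpy()
    cuti = 1.0 + 0.8 * np.sin(2 * np.pi * (doy - 2) / 12.0) + rng.normal(0, 0.1, len(months))
    phase_by_month = np.array([dict(config.phase_map)[y] for y in months.year])
    nitrate_avail = np.where(phase_by_month == "warm", 4.0,
                             np.where(phase_by_month == "cool", 9.0, 6.5))
    beuti = cuti * nitrate_avail + rng.normal(0, 0.5, len(months))
    indices = pd.DataFrame({"date": months, "cuti": cuti, "beuti": beuti})

    return RegionSim(stations=stations, profiles=profiles, indices=indices,
                     cruises=cruises, station_cruise=station_cruise)


def _logistic_weight(n_depth: np.ndarray, config: SimConfig) -> np.ndarray:
    k, n0 = config.mixing_steepness, config.mixing_midpoint_m
    delta = np.asarray(n_depth, dtype=float) - n0
    if np.isinf(k):  # hard-threshold limit
        return np.where(delta < 0, 1.0, np.where(delta > 0, 0.0, 0.5))
    return 1.0 / (1.0 + np.exp(k * delta))


def draw_endmembers(config: SimConfig,
                    rng: np.random.Generator) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """One (nearshore, offshore) endmember pair per group.

    The nearshore endmember concentrates on a subset of the group's ASVs with
    a sparse Dirichlet, the offshore endmember spreads evenly over all of
    them, so offshore Shannon entropy exceeds nearshore by construction of
    the concentration parameters.
    """
    if config.n_asvs_per_group < 2:
        raise ValueError("need at least 2 ASVs per group")
    endmembers = {}
    for group in config.groups:
        n = config.n_asvs_per_group
        support = max(2, int(round(config.nearshore_support_fraction * n)))
        near = np.zeros(n)
        near[:support] = rng.dirichlet(np.full(support, config.dirichlet_nearshore))
        off = rng.dirichlet(np.full(n, config.dirichlet_offshore))
        endmembers[group] = (near, off)
    return endmembers


def simulate_communities(config: SimConfig, region: RegionSim,
                         rng: np.random.Generator | None = None,
                         endmembers: dict | None = None,
                         rng_endmembers: np.random.Generator | None = None) -> CommunitySim:
    """Expected per-sample compositions from two-endmember mixing.

    Surface and DCM samples at a station share the station-level mixing
    weight up to independent per-sample logit noise.  In decoupled phases the
    weight is drawn from a phase-constant nitracline distribution instead of
    the station's own nitracline, severing the slope-community link.
    """
    config.validate()
    if rng is None or endmembers is None:
        rngs = _spawn_rngs(config.seed)
        rng = rng or rngs["communities"]
        if endmembers is None:
            endmembers = draw_endmembers(config, rng_endmembers or rngs["endmembers"])

    asv_groups = np.repeat(list(config.groups), config.n_asvs_per_group)
    near_full = np.concatenate([endmembers[g][0] for g in config.groups])
    off_full = np.concatenate([endmembers[g][1] for g in config.groups])
    n_groups = len(config.groups)

    sc = region.station_cruise.merge(
        region.cruises[["cruise_id", "date", "season", "phase"]], on="cruise_id")
    sc = sc.merge(region.stations[["station_id", "distance_to_coast_km"]], on="station_id")

    station_mean_n = region.station_cruise.groupby("station_id")[
        "true_nitracline_m"].mean()
    decoupled_offsets = {
        cr: float(rng.normal(0.0, config.decoupled_cruise_offset_sd_m))
        for cr in region.cruises.loc[
            region.cruises["phase"].isin(config.decoupled_phases), "cruise_id"]}

    sample_rows, truth_rows, comps = [], [], []
    counter = 0
    for _, row in sc.iterrows():
        if row["phase"] in config.decoupled_phases:
            n_eff = (station_mean_n[row["station_id"]]
                     + decoupled_offsets[row["cruise_id"]])
        else:
            n_eff = row["true_nitracline_m"]
        dcm_depth = float(np.clip(0.8 * row["true_nitracline_m"] + 10.0, 15.0, 90.0))
        for depth_class in config.depth_classes:
            logit_noise = rng.normal(0.0, config.sample_logit_noise_sd)
            w = float(_logistic_weight(np.array(n_eff + logit_noise / max(
                config.mixing_steepness, 1e-12), dtype=float), config))
            sample_id = f"s{counter:05d}"
            counter += 1
            sample_rows.append({
                "sample_id": sample_id,
                "station_id": row["station_id"],
                "cruise_id": row["cruise_id"],
                "date": row["date"],
                "depth_class": depth_class,
                "depth_m": 10.0 if depth_class == "surface" else dcm_depth,
                "phase": row["phase"],
            })
            comps.append((w * near_full + (1.0 - w) * off_full) / n_groups)
            truth_rows.append({
                "sample_id": sample_id,
                "mixing_weight": w,
                "true_label": "nearshore" if w > 0.5 else "offshore",
                "true_nitracline_m": row["true_nitracline_m"],
            })
    compositions = np.column_stack(comps)
    return CommunitySim(samples=pd.DataFrame(sample_rows),
                        compositions=compositions,
                        asv_groups=asv_groups,
                        sample_truths=pd.DataFrame(truth_rows),
                        endmembers=endmembers)


def simulate_reads(config: SimConfig, community: CommunitySim,
                   rng: np.random.Generator | None = None
                   ) -> tuple[AsvTable, TaxonomyMap]:
    """Multinomial read counts at log-normal library sizes.

    Taxonomy rank strings embed the generating group in the ``clade`` column
    so :func:`default_group_config` recovers group membership exactly.
    """
    rng = rng if rng is not None else _spawn_rngs(config.seed)["reads"]
    comp = community.compositions
    if not np.allclose(comp.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("compositions must sum to 1 per sample")
    n_asvs, n_samples = comp.shape
    depths = np.maximum(
        1, np.round(rng.lognormal(np.log(config.depth_median_reads),
                                  config.depth_log_sigma, n_samples))).astype(np.int64)
    counts = np.empty((n_asvs, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = comp[:, j] / comp[:, j].sum()
        counts[:, j] = rng.multinomial(depths[j], p)

    asv_ids = [f"ASV{i:05d}" for i in range(n_asvs)]
    domains = {"heterotrophic_bacteria": "Bacteria", "cyanobacteria": "Bacteria",
               "archaea": "Archaea", "photosynthetic_protists": "Eukaryota",
               "heterotrophic_protists": "Eukaryota"}
    ranks = pd.DataFrame({
        "domain": [domains.get(g, "Unknown") for g in community.asv_groups],
        "clade": [f"{g}_clade{i % 4}" for i, g in enumerate(community.asv_groups)],
        "species": [f"{g}_sp{i}" for i, g in enumerate(community.asv_groups)],
    }, index=pd.Index(asv_ids, name="asv_id"))
    taxonomy = TaxonomyMap.from_config(ranks, default_group_config(config))
    table = AsvTable(asv_ids, list(community.samples["sample_id"]), counts)
    return table, taxonomy


def simulate_dataset(config: SimConfig | None = None,
                     seed: int | None = None) -> Dataset:
    """Full synthetic dataset; ``seed`` overrides ``config.seed`` if given."""
    config = config or SimConfig()
    if seed is not None:
        config = SimConfig(**{**config.to_dict(), "seed": int(seed)})
        config.phase_map = {int(k): v for k, v in config.phase_map.items()}
    rngs = _spawn_rngs(config.seed)
    region = simulate_region(config, rngs["region"])
    endmembers = draw_endmembers(config, rngs["endmembers"])
    community = simulate_communities(config, region, rngs["communities"],
                                     endmembers=endmembers)
    table, taxonomy = simulate_reads(config, community, rngs["reads"])

    truths = community.sample_truths.merge(community.samples[
        ["sample_id", "station_id", "cruise_id", "depth_class"]], on="sample_id")
    truths = truths.merge(
        region.cruises[["cruise_id", "true_slope", "true_intercept", "season", "phase"]],
        on="cruise_id")
    return Dataset(asv=table, taxonomy=taxonomy, samples=community.samples,
                   stations=region.stations, profiles=region.profiles,
                   indices=region.indices, truths=truths)
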