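"""Shannon alpha/gamma diversity, Bray-Curtis similarity and phase comparison.

Shannon entropy is reported in nats (natural log) by default; the base is a
parameter because published values are sometimes base-2 or base-10.  Gamma
diversity pools all of a station's reads before applying the index, so on
equal-depth (rarefied) libraries gamma is never below the station's mean
alpha (concavity of entropy under equal-weight pooling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis_dissim
from scipy.stats import entropy as _entropy

from plankmap.core_data import AsvTable
from plankmap.preprocess import relative_abundance, subset_group


def shannon(vector: np.ndarray, base: float | None = None) -> float:
    """Shannon index ``H = -sum p_i log p_i`` of one sample's counts/proportions."""
    v = np.asarray(vector, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative abundances")
    if v.sum() == 0:
        raise ValueError("all-zero abundance vector")
    return float(_entropy(v, base=base))


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis similarity ``1 - sum|x-y| / sum(x+y)`` between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for an all-zero vector")
    return float(1.0 - _braycurtis_dissim(x, y))


def diversity_table(table: AsvTable, samples: pd.DataFrame,
                    group: str = "all", base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon H joined to station/cruise/depth-class metadata."""
    meta = samples.set_index("sample_id")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        if col.sum() == 0:
            continue
        m = meta.loc[sid]
        rows.append({"sample_id": sid, "station_id": m["station_id"],
                     "cruise_id": m["cruise_id"], "depth_class": m["depth_class"],
                     "group": group, "shannon_h": shannon(col, base=base)})
    return pd.DataFrame(rows)


def alpha_summary(diversity: pd.DataFrame, by: str = "station",
                  depth_class: str = "all") -> pd.DataFrame:
    """Mean per-sample alpha diversity per station or per cruise.

    ``depth_class`` restricts to ``"surface"`` or ``"DCM"`` samples;
    ``"all"`` pools both horizons.  Keys without samples are omitted.
    """
    if by not in ("station", "cruise"):
        raise ValueError("by must be 'station' or 'cruise'")
    key = f"{by}_id"
    df = diversity
    if depth_class != "all":
        df = df[df["depth_class"] == depth_class]
    out = (df.groupby(key)["shannon_h"].agg(["mean", "size"])
           .rename(columns={"mean": "mean_alpha", "size": "n_samples"})
           .reset_index())
    return out


def gamma_per_station(table: AsvTable, samples: pd.DataFrame,
                      depth_class: str = "all", base: float | None = None) -> pd.DataFrame:
    """Gamma diversity: reads pooled across all of a station's samples, then Shannon."""
    meta = samples.set_index("sample_id")
    pools: dict[str, np.ndarray] = {}
    for j, sid in enumerate(table.sample_ids):
        m = meta.loc[sid]
        if depth_class != "all" and m["depth_class"] != depth_class:
            continue
        st = m["station_id"]
        pools[st] = pools.get(st, 0) + table.counts[:, j]
    rows = [{"station_id": st, "gamma_h": shannon(pool, base=base)}
            for st, pool in pools.items() if np.sum(pool) > 0]
    return pd.DataFrame(rows)


def phase_similarity(table: AsvTable, samples: pd.DataFrame, taxonomy,
                     group: str = "all", phase_a: str = "warm", phase_b: str = "cool",
                     depth_class: str = "surface") -> tuple[pd.DataFrame, dict]:
    """Mean cross-phase Bray-Curtis similarity per station for one group.

    For each station with at least one usable sample in each phase at the
    chosen depth class, similarity is averaged over all phase-A x phase-B
    sample pairs on within-group relative abundances (renormalized after
    subsetting).  Stations lacking a phase and samples with zero group reads
    are omitted and reported.
    """
    if group == "all":
        sub, zero_samples = table, [s for s, t in zip(table.sample_ids, table.sample_sums())
                                    if t == 0]
    else:
        sub, zero_samples = subset_group(table, taxonomy, group)
    usable = [s for s in sub.sample_ids if s not in set(zero_samples)]
    sub = sub.select_samples(usable)
    props = relative_abundance(sub)

    meta = samples.set_index("sample_id")
    by_station: dict[str, dict[str, list[str]]] = {}
    for sid in sub.sample_ids:
        m = meta.loc[sid]
        if depth_class != "all" and m["depth_class"] != depth_class:
            continue
        if m["phase"] not in (phase_a, phase_b):
            continue
        by_station.setdefault(m["station_id"], {phase_a: [], phase_b: []})[
            m["phase"]].append(sid)

    rows, omitted = [], []
    for st, phases in sorted(by_station.items()):
        a_ids, b_ids = phases[phase_a], phases[phase_b]
        if not a_ids or not b_ids:
            omitted.append(st)
            continue
        sims = [bray_curtis(props[a].to_numpy(), props[b].to_numpy())
                for a in a_ids for b in b_ids]
        rows.append({"station_id": st, "group": group, "depth_class": depth_class,
                     "mean_similarity": float(np.mean(sims)),
                     "n_pairs": len(sims)})
    report = {"omitted_stations": omitted, "zero_count_samples": zero_samples}
    return pd.DataFrame(rows), report
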