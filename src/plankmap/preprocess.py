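"""Rarefaction, group subsetting, relative abundance and station summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plankmap.core_data import AsvTable, TaxonomyMap, PROFILE_VARIABLES
from plankmap.geo_env import nitracline_depth


@dataclass
class RarefactionReport:
    depth: int
    kept: list[str]
    dropped: list[str]
    input_sums: dict[str, int]


def rarefy(table: AsvTable, depth: int = 17_000,
           seed: int | np.random.Generator = 0) -> tuple[AsvTable, RarefactionReport]:
    """Subsample every library to ``depth`` reads without replacement.

    Samples whose library is smaller than ``depth`` are removed and reported,
    never silently dropped.  Each retained column is a uniform
    without-replacement draw (multivariate hypergeometric) from its reads, so
    column sums equal ``depth`` exactly and no cell exceeds its input.
    Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sums = table.sample_sums()
    keep_mask = sums >= depth
    if not keep_mask.any():
        raise ValueError(f"all {table.n_samples} samples fall below depth {depth}")
    kept = [s for s, k in zip(table.sample_ids, keep_mask) if k]
    dropped = [s for s, k in zip(table.sample_ids, keep_mask) if not k]

    out = np.empty((table.n_asvs, len(kept)), dtype=np.int64)
    j_out = 0
    for j, keep in enumerate(keep_mask):
        if not keep:
            continue
        col = table.counts[:, j]
        if col.sum() == depth:
            out[:, j_out] = col
        else:
            out[:, j_out] = rng.multivariate_hypergeometric(col, depth)
        j_out += 1
    report = RarefactionReport(
        depth=int(depth), kept=kept, dropped=dropped,
        input_sums={s: int(t) for s, t in zip(table.sample_ids, sums)})
    return AsvTable(list(table.asv_ids), kept, out), report


def subset_group(table: AsvTable, taxonomy: TaxonomyMap, group: str,
                 allow_empty: bool = False) -> tuple[AsvTable, list[str]]:
    """Restrict the table to one functional group's ASVs.

    Returns the restricted table and the ids of samples whose within-group
    total is zero (flagged; they carry no information about this group).
    """
    known = list(taxonomy.group_names) + ["unassigned"]
    if group not in known:
        raise KeyError(f"unknown group {group!r}; configured groups: {known}")
    asvs = [a for a in table.asv_ids if taxonomy.group_of(a) == group]
    if not asvs and not allow_empty:
        raise ValueError(f"group {group!r} matches no ASVs in the table")
    sub = table.select_asvs(asvs) if asvs else AsvTable([], list(table.sample_ids),
                                                        np.zeros((0, table.n_samples), dtype=np.int64))
    zero_samples = [s for s, t in zip(sub.sample_ids, sub.counts.sum(axis=0)) if t == 0]
    return sub, zero_samples


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Within-sample proportions; every column sums to 1."""
    sums = table.sample_sums().astype(float)
    if np.any(sums == 0):
        empty = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"samples with zero total counts: {empty}")
    props = table.counts / sums[np.newaxis, :]
    return pd.DataFrame(props, index=pd.Index(table.asv_ids, name="asv_id"),
                        columns=table.sample_ids)


def surface_values(profiles: pd.DataFrame, depth_m: float = 10.0) -> pd.DataFrame:
    """Bottle values at the sampled depth closest to ``depth_m`` per cast."""
    def _pick(grp: pd.DataFrame) -> pd.Series:
        idx = (grp["depth_m"] - depth_m).abs().idxmin()
        return grp.loc[idx, list(PROFILE_VARIABLES)]
    picked = (profiles.groupby(["station_id", "cruise_id"])[
        ["depth_m", *PROFILE_VARIABLES]].apply(_pick).reset_index())
    return picked


def station_summaries(profiles: pd.DataFrame,
                      nitracline_threshold_uM: float = 1.0,
                      surface_depth_m: float = 10.0) -> pd.DataFrame:
    """Per-station mean and coefficient of variation of the environmental field.

    For each station, near-surface temperature, salinity, NO3, PO4, SiO4 and
    chl-a plus the interpolated nitracline depth are collected across all
    cruises; the summary reports the arithmetic mean, the coefficient of
    variation CV = sample sd (ddof=1) / mean, and the observation count per
    variable.  Missing values are skipped; a single observation yields a mean
    but no CV; a zero mean with positive sd yields a missing CV with a
    warning.

    Returns a frame with columns ``station_id``, then ``{var}_mean``,
    ``{var}_cv``, ``{var}_n`` for each variable (nitracline depth as ``ncd``).
    """
    surf = surface_values(profiles, depth_m=surface_depth_m)
    ncd_rows = []
    for (st, cr), cast in profiles.groupby(["station_id", "cruise_id"]):
        depth, flag = nitracline_depth(cast["depth_m"].to_numpy(),
                                       cast["no3"].to_numpy(),
                                       threshold=nitracline_threshold_uM)
        ncd_rows.append({"station_id": st, "cruise_id": cr, "ncd": depth})
    surf = surf.merge(pd.DataFrame(ncd_rows), on=["station_id", "cruise_id"])

    variables = list(PROFILE_VARIABLES) + ["ncd"]
    rows = []
    for st, grp in surf.groupby("station_id"):
        row: dict = {"station_id": st}
        for var in variables:
            vals = grp[var].dropna().to_numpy(dtype=float)
            n = len(vals)
            row[f"{var}_n"] = n
            if n == 0:
                row[f"{var}_mean"] = np.nan
                row[f"{var}_cv"] = np.nan
                continue
            mean = float(np.mean(vals))
            row[f"{var}_mean"] = mean
            if n < 2:
                row[f"{var}_cv"] = np.nan
            else:
                sd = float(np.std(vals, ddof=1))
                if mean == 0.0:
                    if sd > 0:
                        warnings.warn(f"zero mean with positive sd for {var} at "
                                      f"station {st}; CV undefined", stacklevel=2)
                    row[f"{var}_cv"] = np.nan
                else:
                    row[f"{var}_cv"] = sd / mean
        rows.append(row)
    return pd.DataFrame(rows)
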