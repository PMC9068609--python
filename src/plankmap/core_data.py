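"""Domain containers and TSV readers/writers.

All tables are plain tab-separated text with one header row; missing numeric
cells are encoded ``NA``.  Sample, station and cruise identifiers are opaque
strings.  The containers are thin wrappers over numpy arrays and pandas
DataFrames; every cross-reference between tables is validated at ingestion and
nothing is silently dropped.
"""

from __future__ import annotations

import fnmatch
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: year -> phase used to stamp samples; warm anomaly, cool upwelling-typical,
#: and an intermediate period where nearshore/offshore forcing decoupled.
DEFAULT_PHASE_MAP: dict[int, str] = {
    2014: "warm",
    2015: "warm",
    2016: "warm",
    2017: "cool",
    2018: "cool",
    2019: "intermediate",
    2020: "intermediate",
}

PROFILE_VARIABLES = ("no3", "po4", "sio4", "temperature", "salinity", "chl_a")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AsvTable:
    """Integer ASV-by-sample count matrix; the unit of all community analysis."""

    asv_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_asvs, n_samples), non-negative integers

    def __post_init__(self) -> None:
        self.asv_ids = [str(a) for a in self.asv_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.asv_ids)} ASVs x {len(self.sample_ids)} samples"
            )
        for name, ids in (("ASV", self.asv_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {name} ids: {sorted(dupes)}")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts in ASV table")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("non-integer counts in ASV table")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AsvTable(list(self.asv_ids), list(sample_ids), self.counts[:, idx])

    def select_asvs(self, asv_ids: Sequence[str]) -> "AsvTable":
        pos = {a: i for i, a in enumerate(self.asv_ids)}
        idx = [pos[a] for a in asv_ids]
        return AsvTable(list(asv_ids), list(self.sample_ids), self.counts[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.asv_ids, name="asv_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AsvTable":
        return cls(list(frame.index.astype(str)), list(frame.columns.astype(str)),
                   frame.to_numpy())


@dataclass
class TaxonomyMap:
    """ASV -> rank strings plus an ASV -> functional-group assignment.

    Group membership is driven by a user-supplied config: an ordered list of
    ``{group_name, rank, match_patterns}`` entries, where ``match_patterns``
    are shell-style wildcards matched against the ASV's string at ``rank``.
    The first matching entry wins; unmatched ASVs get ``"unassigned"``.
    """

    ranks: pd.DataFrame  # index asv_id, columns = rank names
    groups: dict[str, str] = field(default_factory=dict)
    group_names: list[str] = field(default_factory=list)

    @classmethod
    def from_config(cls, ranks: pd.DataFrame, config: Sequence[Mapping]) -> "TaxonomyMap":
        names: list[str] = []
        groups: dict[str, str] = {}
        for entry in config:
            if entry["group_name"] not in names:
                names.append(entry["group_name"])
            if entry["rank"] not in ranks.columns:
                raise ValidationError(
                    f"group config rank {entry['rank']!r} not a taxonomy column "
                    f"(have {list(ranks.columns)})"
                )
        for asv_id, row in ranks.iterrows():
            label = "unassigned"
            for entry in config:
                value = str(row[entry["rank"]])
                if any(fnmatch.fnmatch(value, pat) for pat in entry["match_patterns"]):
                    label = entry["group_name"]
                    break
            groups[str(asv_id)] = label
        return cls(ranks=ranks, groups=groups, group_names=names)

    def group_of(self, asv_id: str) -> str:
        return self.groups.get(str(asv_id), "unassigned")

    def asvs_in_group(self, group: str) -> list[str]:
        return [a for a, g in self.groups.items() if g == group]


@dataclass
class Dataset:
    """Cross-validated bundle of all input tables."""

    asv: AsvTable
    taxonomy: TaxonomyMap
    samples: pd.DataFrame   # sample_id, station_id, cruise_id, date, depth_class, depth_m, phase
    stations: pd.DataFrame  # station_id, lon, lat, distance_to_coast_km, is_cardinal
    profiles: pd.DataFrame  # long: station_id, cruise_id, depth_m, no3, po4, sio4, temperature, salinity, chl_a
    indices: pd.DataFrame | None = None  # date, cuti, beuti [, ef_ratio, primary_production]
    truths: pd.DataFrame | None = None   # synthetic latent values, if simulated


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for i in ids:
        (dup if i in seen else seen).add(i)
    return dup


def derive_phase(dates: pd.Series, phase_map: Mapping[int, str] | None = None) -> pd.Series:
    """Map each sample's collection year to its climate phase label."""
    phase_map = dict(DEFAULT_PHASE_MAP if phase_map is None else phase_map)
    years = pd.to_datetime(dates).dt.year
    missing = sorted(set(years) - set(phase_map))
    if missing:
        raise ValidationError(f"years {missing} absent from phase map")
    return years.map(phase_map)


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True, **kw)
    except ValueError as exc:
        raise ValidationError(f"unparseable cell in {path}: {exc}") from exc


def read_tables(
    directory: str | Path,
    group_config: Sequence[Mapping] | str | Path | None = None,
    phase_map: Mapping[int, str] | None = None,
) -> Dataset:
    """Read and cross-validate the full TSV bundle from ``directory``.

    Expects ``counts.tsv`` (ASV rows x sample columns), ``taxonomy.tsv``,
    ``samples.tsv``, ``stations.tsv``, ``profiles.tsv`` and, optionally,
    ``indices.tsv`` and ``truths.tsv``; ``group_config`` is the group-mapping
    list or a path to its YAML file (``groups.yaml`` in the directory is used
    if present and none is given).

    Raises :class:`ValidationError` naming the offending ids when tables do
    not cross-reference.
    """
    directory = Path(directory)
    for required in ("counts.tsv", "taxonomy.tsv", "samples.tsv", "stations.tsv", "profiles.tsv"):
        if not (directory / required).exists():
            raise FileNotFoundError(directory / required)

    counts = _read_tsv(directory / "counts.tsv", index_col=0)
    asv = AsvTable.from_frame(counts)
    if np.any(asv.sample_sums() == 0):
        empty = [s for s, t in zip(asv.sample_ids, asv.sample_sums()) if t == 0]
        raise ValidationError(f"samples with zero total reads: {empty}")

    tax_frame = _read_tsv(directory / "taxonomy.tsv", index_col=0, dtype=str)
    missing_tax = sorted(set(asv.asv_ids) - set(tax_frame.index.astype(str)))
    if missing_tax:
        raise ValidationError(f"ASVs missing from taxonomy: {missing_tax[:10]}")

    if group_config is None and (directory / "groups.yaml").exists():
        group_config = directory / "groups.yaml"
    if isinstance(group_config, (str, Path)):
        with open(group_config) as fh:
            group_config = yaml.safe_load(fh)
    taxonomy = TaxonomyMap.from_config(tax_frame, group_config or [])

    samples = _read_tsv(directory / "samples.tsv", dtype={"sample_id": str,
                                                          "station_id": str,
                                                          "cruise_id": str})
    samples["date"] = pd.to_datetime(samples["date"])
    missing_meta = sorted(set(asv.sample_ids) - set(samples["sample_id"]))
    if missing_meta:
        raise ValidationError(f"samples in counts absent from metadata: {missing_meta}")
    samples = samples[samples["sample_id"].isin(asv.sample_ids)].reset_index(drop=True)
    if "phase" not in samples.columns:
        samples["phase"] = derive_phase(samples["date"], phase_map)

    stations = _read_tsv(directory / "stations.tsv", dtype={"station_id": str})
    if np.any(stations["distance_to_coast_km"].to_numpy() < 0):
        raise ValidationError("negative distance_to_coast_km")
    missing_station = sorted(set(samples["station_id"]) - set(stations["station_id"]))
    if missing_station:
        raise ValidationError(f"stations missing from station table: {missing_station}")

    profiles = _read_tsv(directory / "profiles.tsv",
                         dtype={"station_id": str, "cruise_id": str})
    profiles = profiles.sort_values(["station_id", "cruise_id", "depth_m"]).reset_index(drop=True)
    bad = profiles.groupby(["station_id", "cruise_id"])["depth_m"].apply(
        lambda d: not d.is_monotonic_increasing or d.duplicated().any())
    if bad.any():
        raise ValidationError(
            f"profiles with non-increasing depths: {list(bad[bad].index[:5])}")

    indices = None
    if (directory / "indices.tsv").exists():
        indices = _read_tsv(directory / "indices.tsv")
        indices["date"] = pd.to_datetime(indices["date"])
        if "ef_ratio" in indices.columns:
            ef = indices["ef_ratio"].dropna()
            if np.any((ef < 0) | (ef > 1)):
                raise ValidationError("ef_ratio outside [0, 1]")

    truths = None
    if (directory / "truths.tsv").exists():
        truths = _read_tsv(directory / "truths.tsv",
                           dtype={"station_id": str, "cruise_id": str})

    return Dataset(asv=asv, taxonomy=taxonomy, samples=samples, stations=stations,
                   profiles=profiles, indices=indices, truths=truths)


def write_tables(dataset: Dataset, directory: str | Path,
                 group_config: Sequence[Mapping] | None = None) -> None:
    """Write a :class:`Dataset` back to the TSV dialects :func:`read_tables` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.asv.to_frame().to_csv(directory / "counts.tsv", sep="\t", na_rep="NA")
    dataset.taxonomy.ranks.to_csv(directory / "taxonomy.tsv", sep="\t", na_rep="NA")
    samples = dataset.samples.copy()
    samples["date"] = pd.to_datetime(samples["date"]).dt.strftime("%Y-%m-%d")
    samples.to_csv(directory / "samples.tsv", sep="\t", index=False, na_rep="NA")
    dataset.stations.to_csv(directory / "stations.tsv", sep="\t", index=False, na_rep="NA")
    dataset.profiles.to_csv(directory / "profiles.tsv", sep="\t", index=False, na_rep="NA")
    if dataset.indices is not None:
        ind = dataset.indices.copy()
        ind["date"] = pd.to_datetime(ind["date"]).dt.strftime("%Y-%m-%d")
        ind.to_csv(directory / "indices.tsv", sep="\t", index=False, na_rep="NA")
    if dataset.truths is not None:
        dataset.truths.to_csv(directory / "truths.tsv", sep="\t", index=False, na_rep="NA")
    if group_config is not None:
        with open(directory / "groups.yaml", "w") as fh:
            yaml.safe_dump(list(group_config), fh, sort_keys=False)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(results: Mapping[str, pd.DataFrame], directory: str | Path,
                  seed: int | None = None, config: Mapping | None = None,
                  extra_manifest: Mapping | None = None) -> Path:
    """Write result tables as TSVs plus a JSON run manifest; returns manifest path.

    Floats are rendered with a fixed repr so equal runs yield byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame in results.items():
        path = directory / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
        written[name] = {"rows": int(len(frame)), "path": path.name}
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "tables": written,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest_path
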