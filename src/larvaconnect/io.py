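"""Readers/writers for the pipeline's interchange formats and run manifests.

Formats: sites table (CSV), gridded flow fields and density grids
(NetCDF, self-describing), trajectories (columnar parquet or CSV plus a
JSON metadata sidecar), connectivity matrices (CSV + sidecar), genotypes
(VCF with GT and "./." missing, or a dosage CSV) with a sample-metadata
CSV, community partitions (CSV), networks (GeoJSON LineStrings).  Every
write/read pair round-trips the in-memory object exactly, metadata
included.

All coordinates are WGS84 lon/lat degrees, timestamps UTC ISO-8601, grid
cells half-open [edge, next_edge).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .connectivity import ConnectivityMatrix, DensityGrid
from .domain import Domain
from .flow import FlowField
from .genotypes import MISSING, GenotypeMatrix
from .netcompare import CommunityPartition
from .tracking import Site, SimulationConfig, TrajectorySet

EPOCH = np.datetime64("1970-01-01T00:00:00", "s")


def _iso(t) -> str:
    return str(np.datetime64(t, "s"))


# ---------------------------------------------------------------- sites


def read_sites(path, domain: Domain | None = None) -> list[Site]:
    df = pd.read_csv(path)
    required = {"id", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sites CSV needs columns {sorted(required)}, has {list(df.columns)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate site ids {dupes}")
    sites = []
    for row_no, row in df.iterrows():
        lon, lat = float(row["lon"]), float(row["lat"])
        if not (-180 <= lon <= 360 and -90 <= lat <= 90):
            raise ValueError(f"{path} row {row_no}: coordinate out of range ({lon}, {lat})")
        if domain is not None and not domain.is_water(lon, lat):
            raise ValueError(f"{path}: site {row['id']!r} is not on a water cell")
        sites.append(Site(str(row["id"]), lon, lat, str(row.get("kind", "random"))))
    return sites


def write_sites(sites, path) -> None:
    pd.DataFrame(
        [{"id": s.id, "lon": s.lon, "lat": s.lat, "kind": s.kind} for s in sites]
    ).to_csv(path, index=False)


# ------------------------------------------------------------ flow field


def write_flowfield(ff: FlowField, path) -> None:
    dom = ff.domain
    hours = ((ff.times - EPOCH) / np.timedelta64(1, "h")).astype(float)
    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), ff.u, {"units": "m s-1", "long_name": "eastward velocity"}),
            "v": (("time", "lat", "lon"), ff.v, {"units": "m s-1", "long_name": "northward velocity"}),
            "land_mask": (("lat", "lon"), dom.land_mask.astype(np.int8), {"flag_meanings": "0=water 1=land"}),
        },
        coords={
            "time": ("time", hours, {"units": "hours since 1970-01-01 00:00:00"}),
            "lat": ("lat", dom.lat_centers),
            "lon": ("lon", dom.lon_centers),
        },
        attrs={
            "lon_min": dom.lon_min,
            "lon_max": dom.lon_max,
            "lat_min": dom.lat_min,
            "lat_max": dom.lat_max,
            "cell_size": dom.cell_size,
            "depth_m": ff.depth_m,
            "diffusivity_D": ff.diffusivity_D,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_flowfield(path) -> FlowField:
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        attrs = ds.attrs
        dom = Domain(
            attrs["lon_min"], attrs["lon_max"], attrs["lat_min"], attrs["lat_max"],
            attrs["cell_size"], ds["land_mask"].values.astype(bool),
        )
        times = EPOCH + (np.asarray(ds["time"].values, dtype=float) * 3600).astype("timedelta64[s]")
        return FlowField(
            dom, times, ds["u"].values.copy(), ds["v"].values.copy(),
            depth_m=float(attrs.get("depth_m", 6.0)),
            diffusivity_D=float(attrs.get("diffusivity_D", 0.0)),
        )


def write_density(dg: DensityGrid, path) -> None:
    dom = dg.domain
    ds = xr.Dataset(
        {
            "particle_hours": (("lat", "lon"), dg.particle_hours, {"units": "particle hour"}),
            "density": (("lat", "lon"), dg.density, {"units": "particles m-3"}),
            "land_mask": (("lat", "lon"), dom.land_mask.astype(np.int8)),
        },
        coords={"lat": dom.lat_centers, "lon": dom.lon_centers},
        attrs={
            "lon_min": dom.lon_min, "lon_max": dom.lon_max,
            "lat_min": dom.lat_min, "lat_max": dom.lat_max,
            "cell_size": dom.cell_size,
            "window_start": _iso(dg.window[0]), "window_end": _iso(dg.window[1]),
            "layer_thickness_m": dg.layer_thickness_m,
        },
    )
    ds.to_netcdf(path, engine="scipy")


# ----------------------------------------------------------- trajectories


def write_trajectories(traj: TrajectorySet, path) -> None:
    """Columnar records plus a ``<path>.meta.json`` sidecar holding the
    origin map, release times, config and window."""
    path = Path(path)
    df = traj.records.copy()
    if path.suffix == ".csv":
        df.to_csv(path, index=False)
    else:
        df.to_parquet(path, index=False)
    meta = {
        "sim_start": _iso(traj.sim_start),
        "sim_end": _iso(traj.sim_end),
        "config": asdict(traj.config),
        "origins": {str(k): v for k, v in traj.origins.items()},
        "release_times": {str(k): _iso(v) for k, v in traj.release_times.items()},
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_trajectories(path) -> TrajectorySet:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, parse_dates=["time"])
        df["time"] = df["time"].astype("datetime64[s]")
    else:
        df = pd.read_parquet(path)
        df["time"] = df["time"].astype("datetime64[s]")
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    origins = pd.Series(
        {int(k): v for k, v in meta["origins"].items()}, name="origin_site"
    ).sort_index()
    releases = pd.Series(
        {int(k): np.datetime64(v, "s") for k, v in meta["release_times"].items()},
        name="release_time",
    ).sort_index()
    return TrajectorySet(
        records=df,
        origins=origins,
        config=SimulationConfig(**meta["config"]),
        sim_start=np.datetime64(meta["sim_start"], "s"),
        sim_end=np.datetime64(meta["sim_end"], "s"),
        release_times=releases,
    )


# ----------------------------------------------------- connectivity matrix


def write_connectivity(C: ConnectivityMatrix, path) -> None:
    C.to_dataframe().to_csv(path)
    meta = {
        "window_start": _iso(C.window[0]),
        "window_end": _iso(C.window[1]),
        "settle_radius_m": C.settle_radius_m,
        "settle_window_days": C.settle_window_days,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_connectivity(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError(f"{path}: connectivity matrix must be square with matching ids")
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        window = (np.datetime64(meta["window_start"], "s"), np.datetime64(meta["window_end"], "s"))
        radius = meta["settle_radius_m"]
        days = meta["settle_window_days"]
    else:
        window = (EPOCH, EPOCH)
        radius, days = 2000.0, 7.0
    return ConnectivityMatrix(
        [str(c) for c in df.columns], df.to_numpy(dtype=np.int64), window, radius, days
    )


def write_network_geojson(C: ConnectivityMatrix, sites, path, min_count: int = 1) -> None:
    """Directed connectivity edges as GeoJSON LineStrings with a weight
    property, for map overlays."""
    pos = {s.id: (s.lon, s.lat) for s in sites}
    features = []
    for i, a in enumerate(C.site_ids):
        for j, b in enumerate(C.site_ids):
            w = int(C.counts[i, j])
            if i != j and w >= min_count:
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {"type": "LineString", "coordinates": [list(pos[a]), list(pos[b])]},
                        "properties": {"source": a, "target": b, "weight": w},
                    }
                )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


# -------------------------------------------------------------- genotypes


def write_sample_metadata(G: GenotypeMatrix, path) -> None:
    G.samples.rename_axis("sample").to_csv(path)


def read_sample_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample")


def write_dosage_csv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.dosages, index=G.samples.index, columns=G.locus_ids)
    df = df.where(df != MISSING, other=pd.NA)
    df.rename_axis("sample").to_csv(path)


def read_dosage_csv(path, samples: pd.DataFrame) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="sample")
    dos = df.fillna(MISSING).to_numpy(dtype=np.int8)
    return GenotypeMatrix(dos, samples.loc[df.index], list(df.columns))


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Minimal biallelic VCF 4.2 with GT only; loci placed at consecutive
    positions on a synthetic contig."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=larvaconnect",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.samples.index),
    ]
    for j, lid in enumerate(G.locus_ids):
        gts = "\t".join(_GT[int(g)] for g in G.dosages[:, j])
        lines.append(f"{chrom}\t{j + 1}\t{lid}\tA\tG\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, samples: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a biallelic VCF into dosages; a triallelic record is rejected
    with its locus id.  ``samples`` supplies site/stage metadata (defaults
    to a single unknown site)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    loci, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record {var.ID or var.POS!r}: ALT={var.ALT}")
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        dos = np.full(len(names), MISSING, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1] if a >= 0]
            if alleles:
                dos[i] = sum(alleles)
        rows.append(dos)
    vcf.close()
    dosages = np.stack(rows, axis=1) if rows else np.zeros((len(names), 0), dtype=np.int8)
    if samples is None:
        samples = pd.DataFrame({"site": "unknown", "stage": "adult"}, index=names)
    else:
        missing = set(names) - set(samples.index)
        if missing:
            raise ValueError(f"sample metadata missing for {sorted(missing)}")
        samples = samples.loc[names]
    return GenotypeMatrix(dosages, samples, loci)


# -------------------------------------------------- partitions, Fst, Q


def write_partition(p: CommunityPartition, path) -> None:
    pd.DataFrame({"node": p.nodes, "label": p.labels, "method": p.method}).to_csv(path, index=False)


def read_partition(path) -> CommunityPartition:
    df = pd.read_csv(path)
    return CommunityPartition(
        [str(n) for n in df["node"]], df["label"].to_numpy(), method=str(df["method"].iloc[0])
    )


def write_fst(result, matrix_path, table_path=None) -> None:
    result.fst.to_csv(matrix_path)
    if table_path:
        result.long_table().to_csv(table_path, index=False)


def write_q_matrix(res, path) -> None:
    """Q ordered by site then descending lead ancestry -- the order a
    structure-style bar plot wants."""
    q = res.Q.copy()
    q.columns = [f"cluster{k}" for k in range(res.K)]
    q.rename_axis("sample").to_csv(path)


# ---------------------------------------------------------------- manifest


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline stage: config snapshot,
    seeds, input checksums and outputs.  Written atomically."""

    stage: str
    config: dict
    seeds: dict
    inputs: dict = field(default_factory=dict)      # path -> sha256
    outputs: list = field(default_factory=list)
    wall_time_s: float = 0.0
    package_version: str = "0.1.0"

    def write(self, path) -> None:
        tmp = str(path) + f".tmp{os.getpid()}"
        Path(tmp).write_text(json.dumps(asdict(self), indent=1, default=str))
        os.replace(tmp, path)

    @staticmethod
    def read(path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))


class StageTimer:
    """Context manager building a manifest around a stage execution."""

    def __init__(self, stage: str, config: dict, seeds: dict, inputs=()):
        self.manifest = RunManifest(
            stage, config, seeds, inputs={str(p): sha256_file(p) for p in inputs}
        )

    def __enter__(self):
        self._t0 = time.monotonic()
        return self.manifest

    def __exit__(self, *exc):
        self.manifest.wall_time_s = time.monotonic() - self._t0
        return False
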