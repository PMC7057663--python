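"""Data ingestion, configuration and file writers.

Boundaries are read from GeoJSON (any planar metric CRS; geographic
coordinates are rejected).  Attribute tables arrive as CSV keyed by unit id.
Shapefile input is not supported — convert to GeoJSON first (e.g. with ogr2ogr
or QGIS).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape, mapping

from .geometry import AreaUnit, GeometryError, check_planar
from .model import MisalignedData

__all__ = [
    "RunConfig",
    "read_boundaries",
    "write_boundaries",
    "load_misaligned_data",
    "write_surface_csv",
    "read_surface_csv",
    "write_fit_report",
    "contour_lines",
    "write_contours_csv",
]


def read_boundaries(path: str | Path, partition: str, id_field: str = "id") -> list[AreaUnit]:
    """Read one partition's polygons from a GeoJSON FeatureCollection.

    The id is taken from ``properties[id_field]`` (case-insensitive match) or,
    failing that, the feature-level ``id``.  Duplicate ids and geographic
    (lon/lat) coordinates raise errors.
    """
    path = Path(path)
    if path.suffix.lower() in (".shp", ".shx", ".dbf"):
        raise GeometryError(
            "Shapefile input is not supported; convert the boundaries to "
            "GeoJSON (e.g. `ogr2ogr -f GeoJSON out.geojson in.shp`)"
        )
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features")
    if not feats:
        raise GeometryError(f"{path} contains no features")
    units: list[AreaUnit] = []
    for feat in feats:
        props = {str(k).lower(): v for k, v in (feat.get("properties") or {}).items()}
        uid = props.get(id_field.lower(), feat.get("id"))
        if uid is None:
            raise GeometryError(
                f"feature in {path} lacks id field {id_field!r}"
            )
        units.append(
            AreaUnit(id=str(uid), partition=partition, polygon=shape(feat["geometry"]))
        )
    ids = [u.id for u in units]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise GeometryError(f"duplicate ids in {path}: {dupes}")
    bounds = np.array([u.polygon.bounds for u in units])
    check_planar(
        (bounds[:, 0].min(), bounds[:, 1].min(), bounds[:, 2].max(), bounds[:, 3].max())
    )
    return units


def write_boundaries(units: list[AreaUnit], path: str | Path, id_field: str = "id") -> None:
    """Write units as a GeoJSON FeatureCollection (round-trips read_boundaries)."""
    feats = [
        {
            "type": "Feature",
            "properties": {id_field: u.id},
            "geometry": mapping(u.polygon),
        }
        for u in units
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class RunConfig:
    """Pipeline configuration (paths, field names, spacings, seeds)."""

    coarse_boundaries: str = ""
    fine_boundaries: str = ""
    outcome_csv: str = ""
    covariate_csv: str = ""
    coarse_id_field: str = "id"
    fine_id_field: str = "id"
    quadrature_spacing: float = 150.0
    prediction_spacing: float = 250.0
    threshold_group1: float = 79.2
    threshold_group2: float = 82.9
    seed: int = 0
    n_permutations: int = 1000
    coverage_B: int = 200
    output_dir: str = "arealgp_output"
    extra: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extra=extra)
        if not cfg.quadrature_spacing > 0 or not cfg.prediction_spacing > 0:
            raise ValueError("spacings must be positive")
        return cfg

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in every output."""
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _read_table(path: str | Path, id_field: str, value_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    idc = id_field.lower()
    missing = [c for c in [idc, *value_cols] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if df[idc].duplicated().any():
        dupes = df.loc[df[idc].duplicated(), idc].tolist()
        raise ValueError(f"{path}: duplicate ids {dupes}")
    if df[value_cols].isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    df[idc] = df[idc].astype(str)
    return df.set_index(idc)


def load_misaligned_data(
    config: RunConfig,
) -> tuple[MisalignedData, list[AreaUnit], list[AreaUnit]]:
    """Join boundary polygons to their attribute tables by id.

    Outcome CSV schema (case-insensitive): id, outcome_1, outcome_2.
    Covariate CSV schema: id, covariate.  Any id present on one side of a
    join but not the other is a hard error naming the ids.
    """
    for p in (
        config.coarse_boundaries,
        config.fine_boundaries,
        config.outcome_csv,
        config.covariate_csv,
    ):
        if not p or not Path(p).exists():
            raise FileNotFoundError(
                f"required input {p!r} does not exist; boundary polygons and "
                "attribute CSVs must be supplied by the user"
            )
    coarse = read_boundaries(config.coarse_boundaries, "coarse", config.coarse_id_field)
    fine = read_boundaries(config.fine_boundaries, "fine", config.fine_id_field)
    coarse = sorted(coarse, key=lambda u: u.id)
    fine = sorted(fine, key=lambda u: u.id)

    out = _read_table(config.outcome_csv, config.coarse_id_field, ["outcome_1", "outcome_2"])
    cov = _read_table(config.covariate_csv, config.fine_id_field, ["covariate"])

    for name, units, table in (
        ("outcome", coarse, out),
        ("covariate", fine, cov),
    ):
        poly_ids = {u.id for u in units}
        tab_ids = set(table.index)
        if poly_ids != tab_ids:
            only_poly = sorted(poly_ids - tab_ids)
            only_tab = sorted(tab_ids - poly_ids)
            raise ValueError(
                f"{name} join mismatch: polygons without rows {only_poly}, "
                f"rows without polygons {only_tab}"
            )
    outcome = out.loc[[u.id for u in coarse], ["outcome_1", "outcome_2"]].to_numpy()
    covariate = cov.loc[[u.id for u in fine], "covariate"].to_numpy()
    data = MisalignedData(
        coarse_units=coarse, fine_units=fine, outcome=outcome, covariate=covariate
    )
    return data, coarse, fine


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_surface_csv(field, neps: dict | None, path: str | Path) -> None:
    """Gridded surface export: x, y, mean/sd (and NEP if given) per group."""
    q = field.q
    df = pd.DataFrame(field.lattice.points, columns=["x", "y"])
    for g in (1, 2):
        s = field.group(g)
        df[f"mean{g}"] = field.mean[s]
        df[f"sd{g}"] = field.sd[s]
        if neps and g in neps:
            df[f"nep{g}"] = neps[g]
    df.to_csv(path, index=False)


def read_surface_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fit_report(table: pd.DataFrame, path: str | Path, header: str = "") -> None:
    """Plain-text fit report plus a CSV twin next to it."""
    path = Path(path)
    table.to_csv(path.with_suffix(".csv"), index=False)
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip() + "\n")
        fh.write(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        fh.write("\n")


def contour_lines(
    lattice_points: np.ndarray, values: np.ndarray, levels: list[float]
) -> dict[float, list[np.ndarray]]:
    """Iso-value contour polylines of a gridded surface.

    The points must form a (possibly partial) regular grid; the surface is
    re-gridded with NaN holes and contoured with matplotlib's contour engine.
    Returns, per level, a list of (k, 2) vertex arrays.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pts = np.asarray(lattice_points, dtype=float)
    xs = np.unique(pts[:, 0])
    ys = np.unique(pts[:, 1])
    Z = np.full((len(xs), len(ys)), np.nan)
    xi = np.searchsorted(xs, pts[:, 0])
    yi = np.searchsorted(ys, pts[:, 1])
    Z[xi, yi] = values
    fig, ax = plt.subplots()
    try:
        cs = ax.contour(xs, ys, Z.T, levels=sorted(levels))
        out: dict[float, list[np.ndarray]] = {}
        for lev, segs in zip(cs.levels, cs.allsegs):
            out[float(lev)] = [np.asarray(s) for s in segs]
    finally:
        plt.close(fig)
    return out


def write_contours_csv(contours: dict[float, list[np.ndarray]], path: str | Path) -> None:
    rows = []
    for lev, segs in contours.items():
        for si, seg in enumerate(segs):
            for x, y in seg:
                rows.append({"level": lev, "segment": si, "x": x, "y": y})
    pd.DataFrame(rows, columns=["level", "segment", "x", "y"]).to_csv(path, index=False)
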