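"""Self-contained synthetic fixtures: lattices, component tables, clusters.

Every other module is testable without downloads. The generator emulates
county-level composite-vulnerability data:

* :func:`make_lattice` builds an ``n_rows x n_cols`` rectangular polygon
  lattice in geographic coordinates (cells keyed ``R{r}C{c}``), standing in
  for county boundaries, with centroid anchors;
* :func:`pvi_example_model` loads the bundled 14-slice, 4-category model;
* :func:`simulate_components` draws each raw component as standard normal
  per record, with components inside a slice sharing a latent factor so
  their pairwise correlation is 0.5 (slices behave as coherent groups), and
  can plant a spatial cluster by adding a mean shift (in SD units) to every
  component of chosen slices for a subset of cells.

All randomness comes from ``numpy.random.default_rng`` (PCG64), so output
is fully deterministic given the seed across runs and platforms. The
frozen documentation fixture is the 14-slice model on a 10 x 10 lattice of
half-degree cells anchored at (-105E, 33N), seed 1234.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import model_io
from .errors import ValidationError
from .model_io import BoundaryLayer, SourceTable, ToxPiModel

#: Default lattice placement (southwestern CONUS corner of the grid).
DEFAULT_ORIGIN = (-105.0, 33.0)
FIXTURE_SEED = 1234

# components within a slice share a latent factor at loading sqrt(0.5),
# giving pairwise correlation 0.5 while keeping unit variance
_FACTOR_LOADING = math.sqrt(0.5)


@dataclass(frozen=True)
class LatticeSpec:
    """A rectangular lattice of square cells in geographic coordinates."""

    n_rows: int = 10
    n_cols: int = 10
    cell_size: float = 0.5  # degrees (county-scale spacing)
    origin: tuple[float, float] = DEFAULT_ORIGIN  # lon, lat of SW corner
    seed: int = FIXTURE_SEED

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("lattice needs at least one cell")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be > 0 degrees")


def make_lattice(spec: LatticeSpec = LatticeSpec()
                 ) -> tuple[BoundaryLayer, dict[str, tuple[float, float]]]:
    """Rectangular polygon lattice plus centroid anchors.

    Cells are keyed ``R{r}C{c}`` with row 0 at the southern edge; output is
    deterministic given *spec*.
    """
    lon0, lat0 = spec.origin
    keys, labels, geoms, anchors = [], [], [], {}
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            key = f"R{r}C{c}"
            x0 = lon0 + c * spec.cell_size
            y0 = lat0 + r * spec.cell_size
            keys.append(key)
            labels.append(f"Cell {key}")
            geoms.append(box(x0, y0, x0 + spec.cell_size, y0 + spec.cell_size))
            anchors[key] = (x0 + spec.cell_size / 2, y0 + spec.cell_size / 2)
    return BoundaryLayer(keys=keys, labels=labels, geometries=geoms,
                         crs=4326), anchors


def block_keys(spec: LatticeSpec, row0: int, col0: int,
               n_rows: int, n_cols: int) -> list[str]:
    """Keys of a contiguous block of lattice cells (for planted clusters)."""
    return [f"R{r}C{c}"
            for r in range(row0, min(row0 + n_rows, spec.n_rows))
            for c in range(col0, min(col0 + n_cols, spec.n_cols))]


def pvi_example_model() -> ToxPiModel:
    """The bundled 14-slice, 4-category model (synthetic stand-in weights)."""
    ref = resources.files("toxpimap.data") / "pvi_example.yaml"
    with resources.as_file(ref) as path:
        return model_io.parse_model_config(path)


def simulate_components(
    keys: list[str],
    model: ToxPiModel,
    seed: int,
    cluster: tuple[list[str], float] | None = None,
    cluster_slices: list[str] | None = None,
    anchors: dict[str, tuple[float, float]] | None = None,
) -> SourceTable:
    """Draw a raw component table for *keys* under *model*.

    Each component column is standard normal across records; components in
    the same slice share a latent factor (pairwise correlation 0.5).
    *cluster* = (subset of keys, shift) adds ``shift`` standard deviations
    to every component of *cluster_slices* (default: all slices) for the
    chosen records. With *anchors*, records carry lon/lat; otherwise they
    carry their key as a join key.
    """
    rng = np.random.default_rng(seed)
    n = len(keys)
    if len(set(keys)) != n:
        raise ValidationError("simulate_components: duplicate keys")
    shift_rows = np.zeros(n, dtype=bool)
    shift = 0.0
    if cluster is not None:
        cluster_keys, shift = cluster
        extra = set(cluster_keys) - set(keys)
        if extra:
            raise ValidationError(f"cluster keys not in lattice: {sorted(extra)[:5]}")
        member = set(cluster_keys)
        shift_rows = np.array([k in member for k in keys])
    shifted_slices = (set(cluster_slices) if cluster_slices is not None
                      else {s.name for s in model.slices})
    unknown = shifted_slices - {s.name for s in model.slices}
    if unknown:
        raise ValidationError(f"unknown cluster slices: {sorted(unknown)}")

    data = {}
    for slc in model.slices:
        factor = rng.standard_normal(n)
        for comp in slc.components:
            noise = rng.standard_normal(n)
            col = _FACTOR_LOADING * factor + _FACTOR_LOADING * noise
            if shift and slc.name in shifted_slices:
                # shift is in SD units; the sign respects the invert flag so
                # the cluster is always high-RISK after scaling
                col = col + (-shift if comp.invert else shift) * shift_rows
            data[comp.column] = col
    raw = pd.DataFrame(data, index=list(keys))

    if anchors is not None:
        missing = [k for k in keys if k not in anchors]
        if missing:
            raise ValidationError(f"keys without anchors: {missing[:5]}")
        lon = np.array([anchors[k][0] for k in keys])
        lat = np.array([anchors[k][1] for k in keys])
    else:
        lon = np.full(n, np.nan)
        lat = np.full(n, np.nan)
    return SourceTable(ids=list(keys), lon=lon, lat=lat,
                       join_key=list(keys), raw=raw)


def write_fixture(
    out_dir: str | os.PathLike,
    seed: int = FIXTURE_SEED,
    spec: LatticeSpec | None = None,
    cluster_block: tuple[int, int, int, int] | None = None,
    shift: float = 3.0,
) -> dict[str, str]:
    """Write the documentation fixture: model.yaml, data.csv, lattice.geojson.

    *cluster_block* = (row0, col0, n_rows, n_cols) optionally plants a
    high-risk cluster with the given SD shift. Returns the written paths.
    """
    from ._vecio import write_geojson

    spec = spec if spec is not None else LatticeSpec(seed=seed)
    os.makedirs(out_dir, exist_ok=True)
    model = pvi_example_model()
    boundaries, anchors = make_lattice(spec)
    cluster = None
    if cluster_block is not None:
        cluster = (block_keys(spec, *cluster_block), shift)
    table = simulate_components(boundaries.keys, model, seed=seed,
                                cluster=cluster, anchors=anchors)

    paths = {
        "model": os.path.join(out_dir, "model.yaml"),
        "data": os.path.join(out_dir, "data.csv"),
        "lattice": os.path.join(out_dir, "lattice.geojson"),
    }
    model_io.write_model_config(model, paths["model"])
    df = pd.DataFrame({"id": table.ids, "join_key": table.ids,
                       "lon": table.lon, "lat": table.lat})
    df = pd.concat([df, table.raw.reset_index(drop=True)], axis=1)
    df.to_csv(paths["data"], index=False)
    write_geojson(
        [(g, {"key": k, "label": lab})
         for k, lab, g in zip(boundaries.keys, boundaries.labels,
                              boundaries.geometries)],
        paths["lattice"])
    return paths
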