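"""HDF5 / JSON serialization of stimuli, rasters, models and recordings.

A :class:`~popfail.synthetic_data.SyntheticRecording` round-trips through a
single HDF5 bundle plus a small JSON manifest recording the seed, regime and
library versions, so any downstream stage can be replayed from the files
alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .glm import CosineBasis, GLMParams, GLMPopulation, SpikeRaster
from .stimuli import StimulusMovie
from .synthetic_data import Regime, SyntheticRecording

__all__ = [
    "save_movie",
    "load_movie",
    "save_raster",
    "load_raster",
    "save_population",
    "load_population",
    "save_recording",
    "load_recording",
    "write_manifest",
]


def _movie_to_group(g: h5py.Group, movie: StimulusMovie) -> None:
    g.create_dataset("values", data=movie.values, compression="gzip")
    g.attrs["pixel_size"] = movie.pixel_size
    g.attrs["refresh"] = movie.refresh


def _movie_from_group(g: h5py.Group) -> StimulusMovie:
    return StimulusMovie(
        values=g["values"][()],
        pixel_size=float(g.attrs["pixel_size"]),
        refresh=float(g.attrs["refresh"]),
    )


def _raster_to_group(g: h5py.Group, raster: SpikeRaster) -> None:
    g.create_dataset("counts", data=raster.counts, compression="gzip")
    g.attrs["dt"] = raster.dt
    g.attrs["trial_type"] = raster.trial_type
    if raster.cell_positions is not None:
        g.create_dataset("cell_positions", data=raster.cell_positions)


def _raster_from_group(g: h5py.Group) -> SpikeRaster:
    return SpikeRaster(
        counts=g["counts"][()],
        dt=float(g.attrs["dt"]),
        trial_type=str(g.attrs["trial_type"]),
        cell_positions=g["cell_positions"][()] if "cell_positions" in g else None,
    )


def _basis_to_group(g: h5py.Group, basis: CosineBasis) -> None:
    g.attrs["n_funcs"] = basis.n_funcs
    g.attrs["support"] = basis.support
    g.attrs["dt"] = basis.dt
    g.attrs["time_warp"] = basis.time_warp


def _basis_from_group(g: h5py.Group) -> CosineBasis:
    return CosineBasis(
        n_funcs=int(g.attrs["n_funcs"]),
        support=float(g.attrs["support"]),
        dt=float(g.attrs["dt"]),
        time_warp=float(g.attrs["time_warp"]),
    )


def _population_to_group(g: h5py.Group, pop: GLMPopulation) -> None:
    g.attrs["dt"] = pop.dt
    g.attrs["pixel_grid"] = pop.pixel_grid
    g.attrs["center_cell"] = pop.center_cell
    g.create_dataset("positions", data=pop.positions)
    for name in ("stim_basis", "hist_basis", "coup_basis"):
        _basis_to_group(g.create_group(name), getattr(pop, name))
    cells = g.create_group("cells")
    for i, c in enumerate(pop.cells):
        cg = cells.create_group(str(i))
        cg.create_dataset("spatial_filter", data=c.spatial_filter)
        cg.create_dataset("temporal_weights", data=c.temporal_weights)
        cg.create_dataset("history_weights", data=c.history_weights)
        cg.attrs["dc"] = c.dc
        cw = cg.create_group("coupling_weights")
        for j, w in c.coupling_weights.items():
            cw.create_dataset(str(j), data=w)
    ng = g.create_group("neighbor_graph")
    for i, nb in pop.neighbor_graph.items():
        ng.create_dataset(str(i), data=np.asarray(nb, dtype=int))


def _population_from_group(g: h5py.Group) -> GLMPopulation:
    cells_grp = g["cells"]
    cells = []
    for i in range(len(cells_grp)):
        cg = cells_grp[str(i)]
        cells.append(
            GLMParams(
                spatial_filter=cg["spatial_filter"][()],
                temporal_weights=cg["temporal_weights"][()],
                history_weights=cg["history_weights"][()],
                coupling_weights={
                    int(j): w[()] for j, w in cg["coupling_weights"].items()
                },
                dc=float(cg.attrs["dc"]),
            )
        )
    neighbor_graph = {
        int(i): [int(x) for x in ds[()]] for i, ds in g["neighbor_graph"].items()
    }
    return GLMPopulation(
        cells=cells,
        positions=g["positions"][()],
        dt=float(g.attrs["dt"]),
        stim_basis=_basis_from_group(g["stim_basis"]),
        hist_basis=_basis_from_group(g["hist_basis"]),
        coup_basis=_basis_from_group(g["coup_basis"]),
        neighbor_graph=neighbor_graph,
        pixel_grid=tuple(int(x) for x in g.attrs["pixel_grid"]),
        center_cell=int(g.attrs["center_cell"]),
    )


def save_movie(path, movie: StimulusMovie) -> None:
    with h5py.File(path, "w") as f:
        _movie_to_group(f.create_group("movie"), movie)


def load_movie(path) -> StimulusMovie:
    with h5py.File(path, "r") as f:
        return _movie_from_group(f["movie"])


def save_raster(path, raster: SpikeRaster) -> None:
    with h5py.File(path, "w") as f:
        _raster_to_group(f.create_group("raster"), raster)


def load_raster(path) -> SpikeRaster:
    with h5py.File(path, "r") as f:
        return _raster_from_group(f["raster"])


def save_population(path, pop: GLMPopulation) -> None:
    with h5py.File(path, "w") as f:
        _population_to_group(f.create_group("population"), pop)


def load_population(path) -> GLMPopulation:
    with h5py.File(path, "r") as f:
        return _population_from_group(f["population"])


def write_manifest(path, recording: SyntheticRecording, extra: dict | None = None) -> None:
    """JSON manifest: seed, regime, shapes and library versions."""
    import popfail

    manifest = {
        "seed": recording.seed,
        "regime": {
            "name": recording.regime.name,
            "coupling_gain": recording.regime.coupling_gain,
            "coupling_extent": recording.regime.coupling_extent,
            "temporal_scale": recording.regime.temporal_scale,
        },
        "n_cells": recording.truth.n_cells,
        "dt": recording.truth.dt,
        "refresh": recording.stimulus_fit.refresh,
        "versions": {"popfail": popfail.__version__, "numpy": np.__version__},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def save_recording(path, recording: SyntheticRecording, manifest_path=None) -> None:
    """One HDF5 bundle; optionally also a JSON manifest next to it."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = recording.seed
        f.attrs["regime_name"] = recording.regime.name
        f.attrs["regime_coupling_gain"] = recording.regime.coupling_gain
        f.attrs["regime_coupling_extent"] = recording.regime.coupling_extent
        f.attrs["regime_temporal_scale"] = recording.regime.temporal_scale
        for name in ("fit", "test", "decode"):
            _movie_to_group(
                f.create_group(f"stimulus_{name}"), getattr(recording, f"stimulus_{name}")
            )
            _raster_to_group(
                f.create_group(f"raster_{name}"), getattr(recording, f"raster_{name}")
            )
        _population_to_group(f.create_group("truth"), recording.truth)
    if manifest_path is not None:
        write_manifest(manifest_path, recording)


def load_recording(path) -> SyntheticRecording:
    with h5py.File(path, "r") as f:
        regime = Regime(
            name=str(f.attrs["regime_name"]),
            coupling_gain=float(f.attrs["regime_coupling_gain"]),
            coupling_extent=int(f.attrs["regime_coupling_extent"]),
            temporal_scale=float(f.attrs["regime_temporal_scale"]),
        )
        kwargs = {}
        for name in ("fit", "test", "decode"):
            kwargs[f"stimulus_{name}"] = _movie_from_group(f[f"stimulus_{name}"])
            kwargs[f"raster_{name}"] = _raster_from_group(f[f"raster_{name}"])
        return SyntheticRecording(
            truth=_population_from_group(f["truth"]),
            regime=regime,
            seed=int(f.attrs["seed"]),
            **kwargs,
        )
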