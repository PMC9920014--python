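"""Persistence for channel data, energy maps and phantom configs.

Channel data travel as HDF5 (datasets ``signals``; attrs ``dt``, antenna
coordinates, provenance) with a CSV-matrix + JSON-sidecar fallback; both
round-trip float64 bit-exactly (the CSV writer prints 17 significant
digits).  Energy maps are CSV grids with a JSON sidecar carrying the grid
origin, pitch, method and provenance.  Phantom configurations serialise to
YAML.  Phantoms export to HDF5 and a PNG tissue-map preview.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .beamform import EnergyMap, ImagingGrid
from .fdtd import ChannelData
from .phantom import ALNSpec, Phantom, PhantomConfig, SkinProfile

__all__ = [
    "save_channels_h5", "load_channels_h5",
    "save_channels_csv", "load_channels_csv",
    "save_map_csv", "load_map_csv",
    "save_phantom_h5",
    "config_to_yaml", "config_from_yaml",
    "render_map_png", "render_phantom_png",
]


# ---------------------------------------------------------------------------
# channel data
# ---------------------------------------------------------------------------

def save_channels_h5(channels: ChannelData, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=channels.signals)
        f.create_dataset("antenna_xy_mm", data=channels.antenna_xy_mm)
        f.attrs["dt"] = channels.dt
        f.attrs["meta"] = json.dumps(channels.meta)


def load_channels_h5(path) -> ChannelData:
    with h5py.File(path, "r") as f:
        return ChannelData(
            signals=f["signals"][()],
            dt=float(f.attrs["dt"]),
            antenna_xy_mm=f["antenna_xy_mm"][()],
            meta=json.loads(f.attrs["meta"]),
        )


def save_channels_csv(channels: ChannelData, path) -> None:
    """CSV matrix (one row per channel) plus a ``.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, channels.signals, delimiter=",", fmt="%.17e")
    sidecar = {
        "dt": channels.dt,
        "antenna_xy_mm": channels.antenna_xy_mm.tolist(),
        "meta": channels.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_channels_csv(path) -> ChannelData:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    signals = np.atleast_2d(np.loadtxt(path, delimiter=","))
    return ChannelData(
        signals=signals,
        dt=float(sidecar["dt"]),
        antenna_xy_mm=np.asarray(sidecar["antenna_xy_mm"], dtype=float),
        meta=sidecar["meta"],
    )


# ---------------------------------------------------------------------------
# energy maps
# ---------------------------------------------------------------------------

def save_map_csv(emap: EnergyMap, path) -> None:
    path = Path(path)
    np.savetxt(path, emap.values, delimiter=",", fmt="%.17e")
    g = emap.grid
    sidecar = {
        "x0_mm": g.x0_mm, "d0_mm": g.d0_mm, "pitch_mm": g.pitch_mm,
        "n_d": g.n_d, "n_x": g.n_x,
        "method": emap.method, "meta": emap.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_map_csv(path) -> EnergyMap:
    path = Path(path)
    sc = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = ImagingGrid(
        x0_mm=sc["x0_mm"], d0_mm=sc["d0_mm"], pitch_mm=sc["pitch_mm"],
        n_d=sc["n_d"], n_x=sc["n_x"],
    )
    values = np.atleast_2d(np.loadtxt(path, delimiter=","))
    return EnergyMap(values=values, grid=grid, method=sc["method"], meta=sc["meta"])


# ---------------------------------------------------------------------------
# phantom / configs
# ---------------------------------------------------------------------------

def save_phantom_h5(phantom: Phantom, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("tissue", "eps_inf", "delta_eps", "sigma_s", "tau"):
            f.create_dataset(name, data=getattr(phantom, name))
        f.create_dataset("antenna_xy_mm", data=phantom.antenna_xy_mm)
        f.create_dataset("antenna_cells", data=phantom.antenna_cells)
        f.attrs["dx_mm"] = phantom.dx_mm
        f.attrs["air_gap_mm"] = phantom.air_gap_mm
        truth = [
            {
                "center_mm": list(t.center_mm),
                "status": t.status,
                "long_axis_mm": t.long_axis_mm,
            }
            for t in phantom.truths
        ]
        f.attrs["truth"] = json.dumps(truth)
        for k, t in enumerate(phantom.truths):
            f.create_dataset(f"truth_mask_{k}", data=t.mask)


def config_to_yaml(config: PhantomConfig, path=None) -> str:
    d = dataclasses.asdict(config)
    d["skin"] = dataclasses.asdict(config.skin)
    d["alns"] = [dataclasses.asdict(a) for a in config.alns]
    text = yaml.safe_dump(d, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(src) -> PhantomConfig:
    """Load a PhantomConfig from YAML text or a file path."""
    p = Path(str(src))
    text = p.read_text() if p.exists() else str(src)
    d = yaml.safe_load(text)
    if "skin" in d:
        d["skin"] = SkinProfile(**d["skin"])
    if "alns" in d:
        d["alns"] = tuple(ALNSpec(**a) for a in d["alns"])
    return PhantomConfig(**d)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _extent(grid: ImagingGrid):
    return [
        grid.x0_mm, grid.x0_mm + grid.n_x * grid.pitch_mm,
        grid.d0_mm + grid.n_d * grid.pitch_mm, grid.d0_mm,
    ]


def render_map_png(emap: EnergyMap, path, truths=None, db_floor: float = -35.0) -> None:
    """Render an energy map (dB, normalised to peak) with truth outlines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = emap.values / max(emap.values.max(), np.finfo(float).tiny)
    db = 10.0 * np.log10(np.maximum(v, 10 ** (db_floor / 10.0)))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(db, extent=_extent(emap.grid), aspect="equal", cmap="jet",
                   vmin=db_floor, vmax=0.0)
    if truths:
        for t in truths:
            d, x = t.center_mm
            ax.plot(x, d, "wx", markersize=8, markeredgewidth=2)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("depth (mm)")
    ax.set_title(emap.method)
    fig.colorbar(im, ax=ax, label="energy (dB)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_phantom_png(phantom: Phantom, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    n_r, n_c = phantom.shape
    extent = [0, n_c * phantom.dx_mm,
              n_r * phantom.dx_mm - phantom.air_gap_mm, -phantom.air_gap_mm]
    ax.imshow(phantom.tissue, extent=extent, aspect="equal", cmap="viridis")
    ax.plot(phantom.antenna_xy_mm[:, 0], phantom.antenna_xy_mm[:, 1], "rv", markersize=4)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("depth (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
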