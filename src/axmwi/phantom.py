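"""2D numerical phantoms of the axillary region.

A phantom is a rectangular grid of square cells covering a small air gap, a
skin layer (uniform or sinusoidally undulating), optional subcutaneous
adipose and muscle bands, a heterogeneous healthy-tissue background and one
or more bean-shaped axillary lymph nodes (ALNs).  Each cell carries a tissue
label and the per-cell single-pole Debye parameters used by the FDTD solver.

Coordinate convention: the depth axis increases downward; depth 0 is the
nominal skin surface, so the air gap occupies negative depths.  Cells are
indexed 0-based with centres at ``(i + 1/2) * dx`` from the top of the grid.
Lateral position x runs from 0 at the left edge to ``width_mm`` at the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import Polygon

from .tissues import DEFAULT_TAU, DebyeMedium, tissue_library

__all__ = [
    "ALNSpec",
    "SkinProfile",
    "PhantomConfig",
    "Phantom",
    "TargetTruth",
    "BeanMask",
    "bean_mask",
    "bean_polygon",
    "build_phantom",
    "apply_heterogeneity",
    "antenna_positions",
    "TISSUE_CODES",
]

# integer labels of the tissue-index grid
TISSUE_CODES = {
    "air": 0,
    "skin": 1,
    "background_healthy": 2,
    "adipose": 3,
    "muscle": 4,
    "healthy_aln_surface": 5,
    "healthy_aln_cross": 6,
    "metastasized_aln_surface": 7,
    "metastasized_aln_cross": 8,
}

_CODE_TO_TISSUE = {v: k for k, v in TISSUE_CODES.items()}


@dataclass(frozen=True)
class ALNSpec:
    """Placement of one bean-shaped axillary lymph node."""

    depth_mm: float
    offset_mm: float = 0.0  # lateral offset of the centre from the domain centre
    long_axis_mm: float = 12.0
    orientation_rad: float = 0.0
    status: str = "metastasized"

    def __post_init__(self) -> None:
        if self.status not in ("healthy", "metastasized"):
            raise ValueError(f"unknown ALN status {self.status!r}")
        if self.long_axis_mm <= 0:
            raise ValueError("long_axis_mm must be > 0")


@dataclass(frozen=True)
class SkinProfile:
    """Skin surface shape: 'uniform' or 'sinusoidal' with given amplitude/period."""

    kind: str = "uniform"
    amplitude_mm: float = 1.0
    period_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "sinusoidal"):
            raise ValueError(f"unknown skin profile {self.kind!r}")
        if self.kind == "sinusoidal" and (self.amplitude_mm < 0 or self.period_mm <= 0):
            raise ValueError("sinusoidal profile needs amplitude >= 0 and period > 0")

    def surface_depth_mm(self, x_mm):
        """Depth of the skin surface at lateral position x (0 for uniform skin)."""
        x = np.asarray(x_mm, dtype=float)
        if self.kind == "uniform":
            s = np.zeros_like(x)
        else:
            s = 0.5 * self.amplitude_mm * (1.0 - np.cos(2.0 * np.pi * x / self.period_mm))
        return s if s.ndim else float(s)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and composition of an axillary phantom.

    ``depth_mm`` is the axillary region depth below the nominal skin surface
    (the 2-mm skin layer plus heterogeneous healthy tissue); an air gap of
    ``air_gap_mm`` sits above the surface so the antennas couple from air.
    """

    depth_mm: float = 100.0
    width_mm: float = 120.0
    dx_mm: float = 0.5
    skin_thickness_mm: float = 2.0
    skin: SkinProfile = field(default_factory=SkinProfile)
    adipose_mm: float = 0.0  # subcutaneous adipose band thickness (0 or 12)
    muscle: bool = False
    muscle_top_mm: float = 37.0
    muscle_thickness_mm: float = 25.0
    alns: tuple[ALNSpec, ...] = ()
    het_amplitude: float = 0.05
    het_tile_mm: float = 4.0
    het_seed: int = 0
    n_antennas: int = 16
    span_mm: float = 80.0
    air_gap_mm: float = 6.0
    aln_ring_mm: float = 1.0
    tau_s: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if min(self.depth_mm, self.width_mm, self.dx_mm, self.skin_thickness_mm) <= 0:
            raise ValueError("depth, width, dx and skin thickness must be > 0")
        if self.adipose_mm < 0:
            raise ValueError("adipose_mm must be >= 0")
        if not 0 <= self.het_amplitude < 1:
            raise ValueError("het_amplitude must be in [0, 1)")
        if self.het_tile_mm < self.dx_mm:
            raise ValueError("het_tile_mm must be >= dx_mm")
        if self.n_antennas >= 2 and self.span_mm > self.width_mm:
            raise ValueError("antenna span exceeds domain width")
        if isinstance(self.alns, list):
            object.__setattr__(self, "alns", tuple(self.alns))


@dataclass(frozen=True)
class TargetTruth:
    """Ground truth for one ALN: centre, full-grid mask, status and size.

    ``dx_mm``/``air_gap_mm`` describe the grid the mask lives on, so the
    truth can be resampled onto any imaging grid without the parent phantom.
    """

    center_mm: tuple[float, float]  # (depth, x)
    mask: np.ndarray  # boolean, phantom grid shape
    status: str
    long_axis_mm: float
    dx_mm: float = 0.5
    air_gap_mm: float = 0.0

    def mask_at(self, depth_mm, x_mm) -> np.ndarray:
        """Sample the truth mask at (depth, x) positions (mm), True inside."""
        d = np.asarray(depth_mm, dtype=float)
        x = np.asarray(x_mm, dtype=float)
        i = np.floor((d + self.air_gap_mm) / self.dx_mm).astype(int)
        j = np.floor(x / self.dx_mm).astype(int)
        ok = (i >= 0) & (i < self.mask.shape[0]) & (j >= 0) & (j < self.mask.shape[1])
        out = np.zeros(np.broadcast(i, j).shape, dtype=bool)
        ii = np.clip(i, 0, self.mask.shape[0] - 1)
        jj = np.clip(j, 0, self.mask.shape[1] - 1)
        out = np.where(ok, self.mask[ii, jj], False)
        return out


@dataclass
class Phantom:
    """Rasterised axillary model: tissue labels, Debye parameter grids, truth."""

    tissue: np.ndarray  # int8 (n_rows, n_cols)
    eps_inf: np.ndarray
    delta_eps: np.ndarray
    sigma_s: np.ndarray
    tau: np.ndarray
    dx_mm: float
    air_gap_mm: float
    antenna_xy_mm: np.ndarray  # (M, 2) columns (x_mm, surface_depth_mm)
    antenna_cells: np.ndarray  # (M, 2) columns (row, col) of the air feed cell
    truths: list[TargetTruth]
    config: PhantomConfig | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue.shape

    @property
    def width_mm(self) -> float:
        return self.tissue.shape[1] * self.dx_mm

    def depth_of_row(self, i):
        """Depth (mm, from the nominal skin surface) of cell-centre row i."""
        return (np.asarray(i) + 0.5) * self.dx_mm - self.air_gap_mm

    def x_of_col(self, j):
        return (np.asarray(j) + 0.5) * self.dx_mm

    def row_of_depth(self, depth_mm):
        return int(np.floor((depth_mm + self.air_gap_mm) / self.dx_mm))

    def col_of_x(self, x_mm):
        return int(np.floor(x_mm / self.dx_mm))

    def copy(self) -> "Phantom":
        return Phantom(
            tissue=self.tissue.copy(),
            eps_inf=self.eps_inf.copy(),
            delta_eps=self.delta_eps.copy(),
            sigma_s=self.sigma_s.copy(),
            tau=self.tau.copy(),
            dx_mm=self.dx_mm,
            air_gap_mm=self.air_gap_mm,
            antenna_xy_mm=self.antenna_xy_mm.copy(),
            antenna_cells=self.antenna_cells.copy(),
            truths=list(self.truths),
            config=self.config,
        )


# ---------------------------------------------------------------------------
# bean-shaped ALN mask
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _unit_bean() -> tuple[Polygon, float]:
    """Unit bean polygon, centred on its centroid with the longest chord on x.

    The bean curve r(theta) = sin^3(theta) + cos^3(theta) traces a closed,
    kidney-shaped lobe for theta in [-pi/4, 3*pi/4] (r >= 0 there, touching
    the origin at both ends).  Returns the normalised polygon and the length
    of its longest chord (before scaling).
    """
    theta = np.linspace(-np.pi / 4, 3 * np.pi / 4, 1441)
    r = np.sin(theta) ** 3 + np.cos(theta) ** 3
    r = np.clip(r, 0.0, None)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    poly = Polygon(pts).buffer(0)

    # longest chord by pairwise search on the boundary
    b = np.asarray(poly.exterior.coords)[::4]
    d2 = ((b[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    chord = float(np.sqrt(d2[i, j]))
    direction = b[j] - b[i]
    angle = np.arctan2(direction[1], direction[0])

    c = poly.centroid
    poly = shapely.affinity.translate(poly, -c.x, -c.y)
    poly = shapely.affinity.rotate(poly, -np.degrees(angle), origin=(0, 0))
    return poly, chord


def bean_polygon(center_xy_mm, long_axis_mm: float, orientation_rad: float = 0.0) -> Polygon:
    """Bean polygon in (x, depth) mm coordinates with the given longest chord."""
    poly, chord = _unit_bean()
    s = long_axis_mm / chord
    poly = shapely.affinity.scale(poly, s, s, origin=(0, 0))
    poly = shapely.affinity.rotate(poly, np.degrees(orientation_rad), origin=(0, 0))
    # recentre exactly on the centroid after rotation (rotation about the
    # centroid keeps it fixed, but buffer/scaling can move it slightly)
    c = poly.centroid
    poly = shapely.affinity.translate(poly, center_xy_mm[0] - c.x, center_xy_mm[1] - c.y)
    return poly


@dataclass(frozen=True)
class BeanMask:
    """Boolean raster of a bean curve plus the interior/ring split."""

    mask: np.ndarray       # full ALN footprint
    interior: np.ndarray   # cross-section cells (mask minus the outer ring)
    ring: np.ndarray       # outer ring, ``ring_mm`` thick
    polygon: Polygon


def bean_mask(
    center_mm,
    long_axis_mm: float,
    orientation_rad: float,
    dx_mm: float,
    shape: tuple[int, int],
    *,
    air_gap_mm: float = 0.0,
    ring_mm: float = 1.0,
) -> BeanMask:
    """Rasterise a bean-shaped ALN onto a phantom grid.

    ``center_mm`` is (depth, x) of the ALN centroid.  Cells whose centres fall
    inside the scaled/rotated bean polygon form the mask; a ``ring_mm``-thick
    outer ring (surface layer) is split from the interior (cross-section) so
    the two can carry different dielectric values.
    """
    if long_axis_mm <= 2 * dx_mm:
        raise ValueError("long_axis_mm must exceed two grid cells")
    depth_c, x_c = center_mm
    poly = bean_polygon((x_c, depth_c), long_axis_mm, orientation_rad)

    n_rows, n_cols = shape
    rows = (np.arange(n_rows) + 0.5) * dx_mm - air_gap_mm
    cols = (np.arange(n_cols) + 0.5) * dx_mm
    xx, dd = np.meshgrid(cols, rows)
    mask = shapely.contains_xy(poly, xx.ravel(), dd.ravel()).reshape(shape)
    if not mask.any():
        raise ValueError("bean mask is empty on this grid")

    inner = poly.buffer(-ring_mm)
    if inner.is_empty:
        interior = np.zeros_like(mask)
    else:
        interior = shapely.contains_xy(inner, xx.ravel(), dd.ravel()).reshape(shape)
        interior &= mask
    ring = mask & ~interior
    return BeanMask(mask=mask, interior=interior, ring=ring, polygon=poly)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def build_phantom(config: PhantomConfig, tissues: dict[str, DebyeMedium] | None = None) -> Phantom:
    """Build the rasterised phantom from a configuration and tissue library.

    Layer order from the top: air gap, skin (following the surface profile),
    optional subcutaneous adipose band, heterogeneous healthy background with
    an optional muscle band at ``[muscle_top_mm, muscle_top_mm +
    muscle_thickness_mm)``, and the ALNs (surface ring + cross-section
    interior) overriding the background.  ALNs may not overlap the muscle
    band, each other, or leave the tissue region.
    """
    if tissues is None:
        tissues = tissue_library(tau=config.tau_s)
    dx = config.dx_mm
    n_rows = int(round((config.air_gap_mm + config.depth_mm) / dx))
    n_cols = int(round(config.width_mm / dx))
    shape = (n_rows, n_cols)

    cols_x = (np.arange(n_cols) + 0.5) * dx
    rows_d = (np.arange(n_rows) + 0.5) * dx - config.air_gap_mm
    depth = rows_d[:, None] + np.zeros((1, n_cols))
    surf = np.asarray(config.skin.surface_depth_mm(cols_x))[None, :]

    if config.skin.kind == "sinusoidal" and config.skin.amplitude_mm > config.air_gap_mm:
        raise ValueError("air gap too small for the sinusoidal skin amplitude")

    tissue = np.full(shape, TISSUE_CODES["background_healthy"], dtype=np.int8)
    tissue[depth < surf] = TISSUE_CODES["air"]
    skin_band = (depth >= surf) & (depth < surf + config.skin_thickness_mm)
    tissue[skin_band] = TISSUE_CODES["skin"]
    if config.adipose_mm > 0:
        ad = (depth >= surf + config.skin_thickness_mm) & (
            depth < surf + config.skin_thickness_mm + config.adipose_mm
        )
        tissue[ad] = TISSUE_CODES["adipose"]
    if config.muscle:
        mus = (depth >= config.muscle_top_mm) & (
            depth < config.muscle_top_mm + config.muscle_thickness_mm
        )
        mus &= tissue == TISSUE_CODES["background_healthy"]
        tissue[mus] = TISSUE_CODES["muscle"]

    truths: list[TargetTruth] = []
    occupied = np.zeros(shape, dtype=bool)
    for aln in config.alns:
        center = (aln.depth_mm, config.width_mm / 2.0 + aln.offset_mm)
        bm = bean_mask(
            center,
            aln.long_axis_mm,
            aln.orientation_rad,
            dx,
            shape,
            air_gap_mm=config.air_gap_mm,
            ring_mm=config.aln_ring_mm,
        )
        minx, miny, maxx, maxy = bm.polygon.bounds
        if miny < config.skin_thickness_mm or maxy > config.depth_mm or minx < 0 or maxx > config.width_mm:
            raise ValueError(f"ALN at depth {aln.depth_mm} mm extends outside the tissue region")
        if (bm.mask & (tissue == TISSUE_CODES["muscle"])).any():
            raise ValueError(f"ALN at depth {aln.depth_mm} mm overlaps the muscle band")
        if (bm.mask & skin_band).any():
            raise ValueError(f"ALN at depth {aln.depth_mm} mm overlaps the skin")
        if (bm.mask & occupied).any():
            raise ValueError("ALNs overlap each other")
        occupied |= bm.mask
        pre = "healthy" if aln.status == "healthy" else "metastasized"
        tissue[bm.ring] = TISSUE_CODES[f"{pre}_aln_surface"]
        tissue[bm.interior] = TISSUE_CODES[f"{pre}_aln_cross"]
        truths.append(
            TargetTruth(
                center_mm=center,
                mask=bm.mask,
                status=aln.status,
                long_axis_mm=aln.long_axis_mm,
                dx_mm=dx,
                air_gap_mm=config.air_gap_mm,
            )
        )

    # per-cell Debye parameter grids (air: eps_inf = 1, lossless)
    eps_inf = np.ones(shape)
    delta_eps = np.zeros(shape)
    sigma_s = np.zeros(shape)
    tau = np.full(shape, config.tau_s)
    for name, code in TISSUE_CODES.items():
        if name == "air":
            continue
        med = tissues[name]
        sel = tissue == code
        eps_inf[sel] = med.eps_inf
        delta_eps[sel] = med.delta_eps
        sigma_s[sel] = med.sigma_s
        tau[sel] = med.tau

    ph = Phantom(
        tissue=tissue,
        eps_inf=eps_inf,
        delta_eps=delta_eps,
        sigma_s=sigma_s,
        tau=tau,
        dx_mm=dx,
        air_gap_mm=config.air_gap_mm,
        antenna_xy_mm=np.zeros((0, 2)),
        antenna_cells=np.zeros((0, 2), dtype=int),
        truths=truths,
        config=config,
    )
    xy, cells = antenna_positions(config.n_antennas, config.span_mm, ph)
    ph.antenna_xy_mm = xy
    ph.antenna_cells = cells

    if config.het_amplitude > 0:
        ph = apply_heterogeneity(ph, config.het_amplitude, config.het_tile_mm, config.het_seed)
    return ph


def apply_heterogeneity(phantom: Phantom, amplitude: float, tile_mm: float, seed: int) -> Phantom:
    """Tile the sub-skin region into squares and scale each tile's background
    Debye magnitudes (eps_inf, delta_eps, sigma_s) by one uniform random
    factor in [1 - amplitude, 1 + amplitude].

    Only background-healthy cells are touched: skin, adipose, muscle and ALN
    cells keep their nominal values, and the relaxation time is a time
    constant, not a magnitude, so it is never scaled.  Deterministic given
    ``seed``.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must be in [0, 1)")
    if tile_mm < phantom.dx_mm:
        raise ValueError("tile_mm must be >= dx")
    if amplitude == 0:
        return phantom.copy()

    out = phantom.copy()
    n_rows, n_cols = phantom.shape
    rows_d = phantom.depth_of_row(np.arange(n_rows))
    cols_x = phantom.x_of_col(np.arange(n_cols))
    # tiles anchored at the nominal surface (depth 0); the tile grid covers
    # the whole tissue region below it
    tr = np.floor(rows_d / tile_mm).astype(int)
    tc = np.floor(cols_x / tile_mm).astype(int)
    below = rows_d >= 0
    tr0 = tr[below].min()
    n_tr = tr[below].max() - tr0 + 1
    n_tc = tc.max() - tc.min() + 1
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - amplitude, 1.0 + amplitude, size=(n_tr, n_tc))

    fac = np.ones(phantom.shape)
    sel = (phantom.tissue == TISSUE_CODES["background_healthy"]) & below[:, None]
    rr, cc = np.nonzero(sel)
    fac[rr, cc] = factors[tr[rr] - tr0, tc[cc] - tc.min()]
    out.eps_inf *= fac
    out.delta_eps *= fac
    out.sigma_s *= fac
    return out


def antenna_positions(n: int, span_mm: float, phantom: Phantom) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced on-skin antenna positions centred over the domain.

    Returns ``(xy_mm, cells)``: per antenna the (x, surface depth) position on
    the skin surface, and the (row, col) of the feed cell — the air cell
    immediately above the local surface — used as the FDTD soft source and
    record point.
    """
    if n < 2:
        raise ValueError("need at least two antennas")
    if span_mm > phantom.width_mm:
        raise ValueError("antenna span exceeds domain width")
    cfg = phantom.config
    profile = cfg.skin if cfg is not None else SkinProfile()
    x = phantom.width_mm / 2.0 + np.linspace(-span_mm / 2.0, span_mm / 2.0, n)
    surf = np.asarray(profile.surface_depth_mm(x), dtype=float)
    xy = np.column_stack([x, surf])
    cols = np.clip((x / phantom.dx_mm).astype(int), 0, phantom.shape[1] - 1)
    rows = np.array(
        [int(np.floor((s + phantom.air_gap_mm) / phantom.dx_mm)) - 1 for s in surf]
    )
    # ensure the feed cell really is air (surface lands exactly on a cell edge
    # for uniform skin; walk up if rounding put us inside the skin)
    for k in range(n):
        while phantom.tissue[rows[k], cols[k]] != TISSUE_CODES["air"]:
            rows[k] -= 1
    cells = np.column_stack([rows, cols])
    return xy, cells
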