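"""Synthetic tracer-extravasation time-lapse generator.

A straight perfused capillary held at lumen concentration ``C0`` leaks tracer
through its wall at a rate set by the permeability ``P`` (a Robin / membrane
boundary condition), and the tracer diffuses into the surrounding hydrogel
with diffusivity ``D``.  Because a straight vessel is translation-invariant
along its axis, the field depends only on the wall-normal distance, so the
generator solves the 1D membrane-flux diffusion problem

    dC/dt = D d2C/dx2,   x in (0, x_max)
    -D dC/dx|_0 = P (C0 - C(0, t))        (flux through the wall)
    C(x_max, t) = 0                       (far sink)
    C(x, 0) = 0

with Crank-Nicolson time stepping, rasterizes the profile onto the imaging
grid, and renders noisy RGB frames (tracer in the red channel).  A small 2D
finite-volume solver with the same membrane condition is retained as an
independent oracle for tests.

The packaged reference configuration reproduces the study conditions of a
10 kDa Texas Red dextran assay: a 7 µm capillary through the centre of a
244.03 x 193.99 µm field of view at 1385 x 1101 px, imaged every 5 min for
180 min, with a planted permeability of 1.154e-7 cm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .analytic import wall_limited_parameter
from .io import TimeLapseStack
from .permeability import UM_MIN_TO_CM_S, FieldOfView

__all__ = [
    "VesselGeometry2D",
    "DiffusionScenario",
    "TimeGrid",
    "RenderParams",
    "AssayConfig",
    "WallFluxSolution",
    "Solution2D",
    "solve_wall_flux_1d",
    "wall_distance_map",
    "rasterize_field",
    "render_frames",
    "simulate_stack",
    "solve_2d_oracle",
    "reference_config",
]


@dataclass(frozen=True)
class VesselGeometry2D:
    """Straight vessel in the imaging plane.

    ``axis_point`` is a point on the vessel axis in physical FOV coordinates
    (µm, origin at the top-left pixel corner, x along image width);
    ``axis_angle`` is measured from the image x-axis in radians.
    """

    axis_point: tuple[float, float]
    axis_angle: float
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("vessel diameter must be positive")


@dataclass(frozen=True)
class DiffusionScenario:
    """Ground-truth physics of a synthetic extravasation movie.

    Parameters
    ----------
    D
        Tracer diffusivity in the hydrogel, µm²/min.
    P_true
        Planted transmural permeability, µm/min.
    C0
        Lumen tracer concentration, mM.
    h
        Optical section thickness, µm; the estimator's molar bookkeeping is
        per-section, so ``h`` appears in both generator and estimator.
    """

    D: float
    P_true: float
    C0: float
    h: float

    def __post_init__(self) -> None:
        if self.D <= 0 or self.C0 <= 0 or self.h <= 0:
            raise ValueError("D, C0 and h must be strictly positive")
        if self.P_true < 0:
            raise ValueError("P_true must be nonnegative")

    @property
    def P_true_cm_s(self) -> float:
        return self.P_true * UM_MIN_TO_CM_S

    def is_wall_limited(self, t_end: float, limit: float = 0.1) -> bool:
        """True when the membrane, not bulk diffusion, limits release."""
        return wall_limited_parameter(self.P_true, t_end, self.D) < limit


@dataclass(frozen=True)
class TimeGrid:
    """Frame times: 0, frame_interval, ..., duration (endpoints inclusive)."""

    frame_interval: float
    duration: float

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("frame_interval and duration must be positive")
        n = self.duration / self.frame_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be divisible by frame_interval")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_frames)


@dataclass(frozen=True)
class RenderParams:
    """Sensor model: linear gain, Gaussian background, integer quantization."""

    k: float = 2000.0  # counts per mM
    bg_mean: float = 100.0
    bg_sd: float = 5.0
    bit_depth: int = 16
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 0 or self.bg_sd < 0:
            raise ValueError("k and bg_sd must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


@dataclass(frozen=True)
class AssayConfig:
    """Complete recipe for one synthetic assay."""

    scenario: DiffusionScenario
    geometry: VesselGeometry2D
    grid: TimeGrid
    render: RenderParams
    fov: FieldOfView

    def with_seed(self, seed: int) -> "AssayConfig":
        return replace(self, render=replace(self.render, seed=seed))

    def to_dict(self) -> dict[str, Any]:
        return {
            "scenario": {
                "D_um2_min": self.scenario.D,
                "P_true_um_min": self.scenario.P_true,
                "P_true_cm_s": self.scenario.P_true_cm_s,
                "C0_mM": self.scenario.C0,
                "h_um": self.scenario.h,
            },
            "geometry": {
                "axis_point_um": list(self.geometry.axis_point),
                "axis_angle_rad": self.geometry.axis_angle,
                "diameter_um": self.geometry.diameter,
            },
            "grid": {
                "frame_interval_min": self.grid.frame_interval,
                "duration_min": self.grid.duration,
            },
            "render": {
                "k_counts_per_mM": self.render.k,
                "bg_mean": self.render.bg_mean,
                "bg_sd": self.render.bg_sd,
                "bit_depth": self.render.bit_depth,
            },
            "seed": self.render.seed,
        }


def reference_config(seed: int | None = None) -> AssayConfig:
    """The packaged reference assay: one 7 µm capillary, wall-limited leak.

    Planted permeability 1.154e-7 cm/s (0.069240 µm/min), lumen concentration
    10 mM, free-solution-order diffusivity 6000 µm²/min for a 10 kDa dextran,
    1 µm optical section; 244.03 x 193.99 µm FOV at 1385 x 1101 px, frames
    every 5 min for 180 min; 16-bit sensor at 2000 counts/mM over a 100 +/- 5
    count background.
    """
    fov = FieldOfView(width_um=244.03, height_um=193.99, nx=1385, ny=1101)
    return AssayConfig(
        scenario=DiffusionScenario(D=6000.0, P_true=1.154e-7 / UM_MIN_TO_CM_S,
                                   C0=10.0, h=1.0),
        geometry=VesselGeometry2D(
            axis_point=(fov.width_um / 2.0, fov.height_um / 2.0),
            axis_angle=0.0,
            diameter=7.0,
        ),
        grid=TimeGrid(frame_interval=5.0, duration=180.0),
        render=RenderParams(k=2000.0, bg_mean=100.0, bg_sd=5.0, bit_depth=16,
                            seed=seed),
        fov=fov,
    )


# ---------------------------------------------------------------------------
# 1D membrane-flux solver
# ---------------------------------------------------------------------------


@dataclass
class WallFluxSolution:
    """Wall-normal concentration profiles at the frame times.

    ``conc[f, i]`` is the concentration (mM) at distance ``x[i]`` from the
    vessel wall at frame time ``times[f]``.  ``mass`` is the extravascular
    mass per unit wall area (mM·µm), ``influx`` the time integral of the
    transmural flux, and ``outflux`` the integral of the leak through the
    far sink boundary; the scheme is conservative, so
    ``mass = influx - outflux`` to rounding error at every frame.
    """

    x: np.ndarray
    times: np.ndarray
    conc: np.ndarray
    mass: np.ndarray
    influx: np.ndarray
    outflux: np.ndarray
    truncated: bool = False

    def wall_concentration(self) -> np.ndarray:
        return self.conc[:, 0]

    def profile(self, t_index: int) -> tuple[np.ndarray, np.ndarray]:
        return self.x, self.conc[t_index]


def solve_wall_flux_1d(
    scenario: DiffusionScenario,
    grid: TimeGrid,
    dx: float = 1.0,
    x_max: float | None = None,
    dt: float = 0.05,
    allow_truncated: bool = False,
) -> WallFluxSolution:
    """Crank-Nicolson solution of the membrane-flux diffusion problem.

    The spatial discretization is a conservative finite-volume scheme on
    nodes ``x_i = i * dx`` with a half-width cell at the wall; the membrane
    flux ``P (C0 - C_wall)`` enters the wall cell, and the far node is held
    at zero (sink).  By default ``x_max`` is three diffusion lengths
    ``3 * sqrt(4 D T)``, far enough that no mass reaches the sink; a shorter
    domain must be acknowledged with ``allow_truncated=True``.
    """
    if dx <= 0 or dt <= 0:
        raise ValueError("dx and dt must be positive")
    L_diff = 3.0 * np.sqrt(4.0 * scenario.D * grid.duration)
    truncated = False
    if x_max is None:
        x_max = L_diff
    elif x_max < L_diff:
        if not allow_truncated:
            raise ValueError(
                f"x_max={x_max:.0f} µm is inside three diffusion lengths "
                f"({L_diff:.0f} µm); pass allow_truncated=True to accept the "
                "far-boundary error"
            )
        truncated = True
    steps_per_frame = grid.frame_interval / dt
    if abs(steps_per_frame - round(steps_per_frame)) > 1e-9:
        raise ValueError("frame_interval must be a multiple of dt")
    steps_per_frame = int(round(steps_per_frame))

    n = int(np.ceil(x_max / dx))  # nodes 0..n, node n is the Dirichlet sink
    x = np.arange(n + 1) * dx
    D, P, C0 = scenario.D, scenario.P_true, scenario.C0

    # finite-volume weights: half cell at the wall, full cells inside
    w = np.full(n, dx)
    w[0] = dx / 2.0

    # L c + b, unknowns c_0..c_{n-1}
    main = np.full(n, -2.0 * D / dx**2)
    off = np.full(n - 1, D / dx**2)
    main[0] = -(P + D / dx) / w[0]
    upper = off.copy()
    upper[0] = (D / dx) / w[0]
    L = sp.diags([off, main, upper], offsets=[-1, 0, 1], format="csc")
    b = np.zeros(n)
    b[0] = P * C0 / w[0]

    I = sp.identity(n, format="csc")
    A = splu((I - (dt / 2.0) * L).tocsc())
    B = (I + (dt / 2.0) * L).tocsr()

    c = np.zeros(n)
    frames = [np.zeros(n + 1)]
    mass = [0.0]
    influx = [0.0]
    outflux = [0.0]
    q_prev = P * C0  # flux at t=0 (wall concentration 0)
    qo_prev = 0.0  # leak into the far sink
    influx_acc = 0.0
    outflux_acc = 0.0
    for f in range(1, grid.n_frames):
        for _ in range(steps_per_frame):
            c = A.solve(B @ c + dt * b)
            q = P * (C0 - c[0])
            qo = D * c[-1] / dx
            influx_acc += dt * 0.5 * (q_prev + q)
            outflux_acc += dt * 0.5 * (qo_prev + qo)
            q_prev, qo_prev = q, qo
        if c.min() < -1e-9 * max(C0, 1.0):
            raise RuntimeError(
                f"negative concentration ({c.min():.3g}) at frame {f}; "
                f"reduce dt={dt} or dx={dx}"
            )
        full = np.concatenate([c, [0.0]])
        frames.append(full)
        mass.append(float(w @ c))
        influx.append(influx_acc)
        outflux.append(outflux_acc)

    return WallFluxSolution(
        x=x,
        times=grid.times,
        conc=np.clip(np.asarray(frames), 0.0, None),
        mass=np.asarray(mass),
        influx=np.asarray(influx),
        outflux=np.asarray(outflux),
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Rasterization and rendering
# ---------------------------------------------------------------------------


def wall_distance_map(geometry: VesselGeometry2D, fov: FieldOfView) -> np.ndarray:
    """Per-pixel distance (µm) from the pixel centre to the vessel axis."""
    px_w, px_h = fov.pixel_width_um, fov.pixel_height_um
    xs = (np.arange(fov.nx) + 0.5) * px_w
    ys = (np.arange(fov.ny) + 0.5) * px_h
    X, Y = np.meshgrid(xs, ys)
    ax, ay = geometry.axis_point
    # unit normal to the axis direction (cos a, sin a)
    nx_, ny_ = -np.sin(geometry.axis_angle), np.cos(geometry.axis_angle)
    dist = np.abs((X - ax) * nx_ + (Y - ay) * ny_)
    if dist.min() > geometry.diameter / 2.0:
        raise ValueError("vessel band does not intersect the field of view")
    return dist


def rasterize_field(
    solution: WallFluxSolution,
    geometry: VesselGeometry2D,
    fov: FieldOfView,
    t_index: int,
    C0: float,
    axis_distance: np.ndarray | None = None,
) -> np.ndarray:
    """Concentration image (mM) for one frame.

    Pixels whose centre lies within ``diameter / 2`` of the axis are lumen
    and get ``C0``; extravascular pixels get the wall-normal profile
    linearly interpolated at their distance to the nearest wall.
    """
    if axis_distance is None:
        axis_distance = wall_distance_map(geometry, fov)
    wall_dist = axis_distance - geometry.diameter / 2.0
    if wall_dist.max() > solution.x[-1]:
        raise ValueError(
            "profile does not cover all pixel-to-wall distances in the FOV"
        )
    x, c = solution.profile(t_index)
    img = np.interp(wall_dist, x, c)
    img[wall_dist <= 0.0] = C0
    return img


def render_frames(
    conc_images: np.ndarray,
    render: RenderParams,
    fov: FieldOfView,
    timestamps_min: np.ndarray,
    meta: dict[str, Any] | None = None,
) -> TimeLapseStack:
    """Render concentration images to a noisy integer RGB stack.

    Red carries ``k * C + bg``; green and blue carry background only, each
    with independent Gaussian noise of width ``bg_sd``.  Counts are rounded
    and clipped to the sensor's dynamic range.  The same seed produces a
    bit-identical stack.
    """
    conc_images = np.asarray(conc_images, dtype=np.float64)
    peak = render.k * np.nanmax(conc_images) + render.bg_mean
    if peak > render.max_count:
        warnings.warn(
            f"lumen signal ({peak:.0f} counts) saturates the "
            f"{render.bit_depth}-bit range; clipping",
            stacklevel=2,
        )
    rng = np.random.default_rng(render.seed)
    T = len(conc_images)
    ny, nx = conc_images.shape[1:]
    frames = np.empty((T, ny, nx, 3), dtype=render.dtype)
    for f in range(T):
        signal = render.k * conc_images[f] + render.bg_mean
        for ch in range(3):
            base = signal if ch == 0 else render.bg_mean
            noisy = base + rng.standard_normal((ny, nx)) * render.bg_sd
            np.clip(np.rint(noisy), 0, render.max_count, out=noisy)
            frames[f, :, :, ch] = noisy.astype(render.dtype)
    return TimeLapseStack(
        frames=frames,
        timestamps_min=np.asarray(timestamps_min, dtype=float),
        fov=fov,
        meta=dict(meta or {}),
    )


def simulate_stack(
    config: AssayConfig,
    dx: float = 1.0,
    solution: WallFluxSolution | None = None,
) -> TimeLapseStack:
    """Full generator: solve the wall-flux problem, rasterize, render.

    A precomputed ``solution`` may be supplied when rendering several noise
    realizations of the same physics.
    """
    sc, geom, grid = config.scenario, config.geometry, config.grid
    if not sc.is_wall_limited(grid.duration):
        warnings.warn(
            "scenario leaves the wall-limited regime; threshold calibration "
            "and the endpoint estimator assume membrane-limited release",
            stacklevel=2,
        )
    if solution is None:
        solution = solve_wall_flux_1d(sc, grid, dx=dx)
    dist = wall_distance_map(geom, config.fov)
    conc = np.empty((grid.n_frames, config.fov.ny, config.fov.nx),
                    dtype=np.float64)
    for f in range(grid.n_frames):
        conc[f] = rasterize_field(solution, geom, config.fov, f, sc.C0,
                                  axis_distance=dist)
    return render_frames(
        conc,
        config.render,
        config.fov,
        grid.times,
        meta={**config.to_dict()},
    )


# ---------------------------------------------------------------------------
# 2D oracle
# ---------------------------------------------------------------------------


@dataclass
class Solution2D:
    """Small 2D membrane-flux solution used as a cross-check in tests."""

    x: np.ndarray  # wall-normal coordinates, x=0 at the wall
    y: np.ndarray  # along-vessel coordinates
    times: np.ndarray
    conc: np.ndarray  # (T, ny, nx)
    mass: np.ndarray  # per unit wall length, averaged along the vessel
    influx: np.ndarray
    outflux: np.ndarray


def solve_2d_oracle(
    scenario: DiffusionScenario,
    geometry: VesselGeometry2D,
    grid: TimeGrid,
    nx: int = 200,
    ny: int = 17,
    dx: float = 3.0,
    dt: float = 0.5,
) -> Solution2D:
    """2D Crank-Nicolson membrane-flux solver on a small wall-attached box.

    The domain is the gel on one side of a straight vessel wall: x runs
    wall-normal from the wall (membrane flux) to a zero sink at
    ``(nx - 1) * dx``; y runs along the vessel with reflecting ends
    (translation invariance).  Intended purely as an independent oracle for
    the 1D generator on the same (possibly truncated) domain; the grid is
    capped at 200 x 200 nodes.
    """
    if nx > 200 or ny > 200:
        raise ValueError("oracle domain capped at 200 x 200 nodes")
    if abs(geometry.axis_angle % np.pi) > 1e-12:
        raise ValueError("2D oracle assumes a straight axis-aligned vessel")
    steps_per_frame = grid.frame_interval / dt
    if abs(steps_per_frame - round(steps_per_frame)) > 1e-9:
        raise ValueError("frame_interval must be a multiple of dt")
    steps_per_frame = int(round(steps_per_frame))

    D, P, C0 = scenario.D, scenario.P_true, scenario.C0
    n_un = nx - 1  # last x node is the Dirichlet sink
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx

    w = np.full(n_un, dx)
    w[0] = dx / 2.0

    # x-operator: identical FV scheme to the 1D solver
    main = np.full(n_un, -2.0 * D / dx**2)
    off = np.full(n_un - 1, D / dx**2)
    main[0] = -(P + D / dx) / w[0]
    upper = off.copy()
    upper[0] = (D / dx) / w[0]
    Lx = sp.diags([off, main, upper], offsets=[-1, 0, 1], format="csr")

    # y-operator: standard 1D Laplacian with reflecting (zero-flux) ends
    my = np.full(ny, -2.0 * D / dx**2)
    my[0] = my[-1] = -D / dx**2
    oy = np.full(ny - 1, D / dx**2)
    Ly = sp.diags([oy, my, oy], offsets=[-1, 0, 1], format="csr")

    Ix = sp.identity(n_un, format="csr")
    Iy = sp.identity(ny, format="csr")
    L = sp.kron(Iy, Lx) + sp.kron(Ly, Ix)

    b = np.zeros((ny, n_un))
    b[:, 0] = P * C0 / w[0]
    b = b.ravel()

    I = sp.identity(ny * n_un, format="csc")
    A = splu((I - (dt / 2.0) * L).tocsc())
    B = (I + (dt / 2.0) * L).tocsr()

    c = np.zeros(ny * n_un)
    full0 = np.zeros((ny, nx))
    frames = [full0]
    mass = [0.0]
    influx = [0.0]
    outflux = [0.0]
    q_prev = P * C0
    qo_prev = 0.0
    influx_acc = 0.0
    outflux_acc = 0.0
    for f in range(1, grid.n_frames):
        for _ in range(steps_per_frame):
            c = A.solve(B @ c + dt * b)
            sheet = c.reshape(ny, n_un)
            q = P * (C0 - sheet[:, 0].mean())
            qo = D * sheet[:, -1].mean() / dx
            influx_acc += dt * 0.5 * (q_prev + q)
            outflux_acc += dt * 0.5 * (qo_prev + qo)
            q_prev, qo_prev = q, qo
        grid2d = c.reshape(ny, n_un)
        if grid2d.min() < -1e-9 * max(C0, 1.0):
            raise RuntimeError(
                f"negative concentration in 2D oracle at frame {f}; "
                f"reduce dt={dt} or dx={dx}"
            )
        full = np.concatenate([grid2d, np.zeros((ny, 1))], axis=1)
        frames.append(full)
        mass.append(float((grid2d @ w).mean()))
        influx.append(influx_acc)
        outflux.append(outflux_acc)

    return Solution2D(
        x=x,
        y=y,
        times=grid.times,
        conc=np.clip(np.asarray(frames), 0.0, None),
        mass=np.asarray(mass),
        influx=np.asarray(influx),
        outflux=np.asarray(outflux),
    )
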