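"""Regular-grid reaction-diffusion microenvironment.

Each diffusible factor lives on the same rectilinear voxel grid and evolves
by ``d rho/dt = D * laplacian(rho) - lambda * rho`` plus per-cell secretion
and uptake applied in the voxel containing each cell.  Time stepping is a
locally one-dimensional (LOD) operator split: one implicit (backward-Euler)
tridiagonal solve per axis, then an implicit decay factor.  The scheme is
unconditionally stable, preserves nonnegativity, and with no-flux boundaries
and no decay conserves total mass to machine precision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = ["Boundary", "Domain", "SubstrateField", "Microenvironment"]


class Boundary(str, enum.Enum):
    DIRICHLET = "dirichlet"
    NO_FLUX = "no_flux"


@dataclass(frozen=True)
class Domain:
    """Rectangular simulation domain in micrometres (2-D by default)."""

    x_min: float = -500.0
    x_max: float = 500.0
    y_min: float = -500.0
    y_max: float = 500.0
    voxel_size: float = 20.0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("domain extents must be positive")

    @property
    def nx(self) -> int:
        return max(1, int(round((self.x_max - self.x_min) / self.voxel_size)))

    @property
    def ny(self) -> int:
        return max(1, int(round((self.y_max - self.y_min) / self.voxel_size)))

    @property
    def shape(self) -> tuple[int, int]:
        # row index = y, column index = x
        return (self.ny, self.nx)

    @property
    def voxel_volume(self) -> float:
        # 2-D simulations use a unit-thickness slab of one voxel depth
        return self.voxel_size ** 3

    def voxel_index(self, position) -> tuple[int, int]:
        x, y = float(position[0]), float(position[1])
        if not (self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max):
            raise ValueError(f"position {position} outside domain")
        i = min(int((y - self.y_min) / self.voxel_size), self.ny - 1)
        j = min(int((x - self.x_min) / self.voxel_size), self.nx - 1)
        return i, j

    def voxel_indices(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized voxel lookup with clamping at the boundary."""
        pos = np.asarray(positions, dtype=float)
        j = np.clip(((pos[:, 0] - self.x_min) / self.voxel_size).astype(int), 0, self.nx - 1)
        i = np.clip(((pos[:, 1] - self.y_min) / self.voxel_size).astype(int), 0, self.ny - 1)
        return i, j

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x_min + (np.arange(self.nx) + 0.5) * self.voxel_size
        ys = self.y_min + (np.arange(self.ny) + 0.5) * self.voxel_size
        return xs, ys

    def contains(self, position) -> bool:
        x, y = float(position[0]), float(position[1])
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


def _banded_factor(n: int, alpha: float, boundary: Boundary):
    """Banded matrix (ab form) for (I - alpha * L) with L the 1-D Laplacian
    stencil (in units of 1/dx^2 already folded into alpha)."""
    ab = np.zeros((3, n))
    ab[1, :] = 1.0 + 2.0 * alpha
    ab[0, 1:] = -alpha   # super-diagonal
    ab[2, :-1] = -alpha  # sub-diagonal
    if boundary is Boundary.NO_FLUX:
        # zero-flux: ghost node mirrors the edge node
        ab[1, 0] = 1.0 + alpha
        ab[1, -1] = 1.0 + alpha
    return ab


@dataclass
class SubstrateField:
    """One diffusing substrate on a shared domain grid."""

    name: str
    domain: Domain
    diffusion_coefficient: float = 0.0   # um^2/min
    decay_rate: float = 0.0              # 1/min
    initial_value: float = 0.0
    boundary: Boundary = Boundary.NO_FLUX
    boundary_value: float = 0.0          # used for dirichlet
    saturation_density: float = 1.0      # rho* targeted by secretion
    values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.boundary = Boundary(self.boundary)
        if self.values is None:
            self.values = np.full(self.domain.shape, float(self.initial_value))
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != self.domain.shape:
                raise ValueError("values shape does not match domain grid")
        self._solver_cache: dict[float, tuple] = {}

    # -- dynamics ---------------------------------------------------------

    def _solvers(self, dt: float):
        key = float(dt)
        if key not in self._solver_cache:
            dx = self.domain.voxel_size
            alpha = self.diffusion_coefficient * dt / (dx * dx)
            ny, nx = self.domain.shape
            self._solver_cache[key] = (
                _banded_factor(nx, alpha, self.boundary),
                _banded_factor(ny, alpha, self.boundary),
                alpha,
            )
        return self._solver_cache[key]

    def _apply_dirichlet(self):
        v = self.boundary_value
        self.values[0, :] = v
        self.values[-1, :] = v
        self.values[:, 0] = v
        self.values[:, -1] = v

    def step_diffusion(self, dt: float) -> None:
        """One operator-split implicit step of diffusion plus decay."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        if self.boundary is Boundary.DIRICHLET:
            self._apply_dirichlet()
        if self.diffusion_coefficient > 0:
            ab_x, ab_y, alpha = self._solvers(dt)
            if alpha > 0:
                # x sweep: each row is one tridiagonal system (shared matrix)
                rhs = self.values.T.copy()
                if self.boundary is Boundary.DIRICHLET:
                    rhs[0, :] = self.boundary_value
                    rhs[-1, :] = self.boundary_value
                    ab = ab_x.copy()
                    ab[1, 0] = ab[1, -1] = 1.0 + 2.0 * alpha
                    ab[0, 1] = ab[2, -2] = 0.0
                    # pin boundary rows to the boundary value
                    ab[1, 0] = 1.0
                    ab[1, -1] = 1.0
                    sol = solve_banded((1, 1), ab, rhs)
                else:
                    sol = solve_banded((1, 1), ab_x, rhs)
                self.values = sol.T
                # y sweep
                rhs = self.values.copy()
                if self.boundary is Boundary.DIRICHLET:
                    rhs[0, :] = self.boundary_value
                    rhs[-1, :] = self.boundary_value
                    ab = ab_y.copy()
                    ab[0, 1] = ab[2, -2] = 0.0
                    ab[1, 0] = 1.0
                    ab[1, -1] = 1.0
                    sol = solve_banded((1, 1), ab, rhs)
                else:
                    sol = solve_banded((1, 1), ab_y, rhs)
                self.values = sol
        if self.decay_rate > 0:
            self.values /= 1.0 + self.decay_rate * dt
        if self.boundary is Boundary.DIRICHLET:
            self._apply_dirichlet()
        np.maximum(self.values, 0.0, out=self.values)

    def apply_cell_exchange(self, positions, secretion, uptake, volumes, dt) -> None:
        """Implicit per-voxel secretion/uptake update for a batch of cells.

        For a cell of volume V in a voxel of volume Vv with secretion rate S
        (towards saturation density rho*) and uptake rate U::

            rho <- (rho + dt*(V/Vv)*S*rho*) / (1 + dt*(V/Vv)*(S+U))

        Secretion alone never drives the voxel above rho*; uptake alone only
        removes mass.  Cells sharing a voxel are applied sequentially in
        input order.
        """
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        secretion = np.broadcast_to(np.asarray(secretion, dtype=float), (len(positions),))
        uptake = np.broadcast_to(np.asarray(uptake, dtype=float), (len(positions),))
        volumes = np.broadcast_to(np.asarray(volumes, dtype=float), (len(positions),))
        for p in positions:
            if not self.domain.contains(p):
                raise ValueError(f"agent position {p} outside domain")
        ii, jj = self.domain.voxel_indices(positions)
        Vv = self.domain.voxel_volume
        rho_star = self.saturation_density
        for k in range(len(positions)):
            S, U, V = secretion[k], uptake[k], volumes[k]
            if S == 0.0 and U == 0.0:
                continue
            f = dt * (V / Vv)
            i, j = ii[k], jj[k]
            self.values[i, j] = (self.values[i, j] + f * S * rho_star) / (1.0 + f * (S + U))

    # -- sampling ---------------------------------------------------------

    def sample(self, position) -> float:
        i, j = self.domain.voxel_index(position)
        return float(self.values[i, j])

    def sample_many(self, positions) -> np.ndarray:
        i, j = self.domain.voxel_indices(positions)
        return self.values[i, j]

    def gradient(self, position) -> np.ndarray:
        i, j = self.domain.voxel_index(position)
        return self._gradient_at(np.array([i]), np.array([j]))[0]

    def gradient_many(self, positions) -> np.ndarray:
        i, j = self.domain.voxel_indices(positions)
        return self._gradient_at(i, j)

    def _gradient_at(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Central finite differences (one-sided at boundaries), units/um."""
        dx = self.domain.voxel_size
        ny, nx = self.domain.shape
        v = self.values
        jp = np.minimum(j + 1, nx - 1)
        jm = np.maximum(j - 1, 0)
        ip = np.minimum(i + 1, ny - 1)
        im = np.maximum(i - 1, 0)
        gx = (v[i, jp] - v[i, jm]) / ((jp - jm) * dx + np.where(jp == jm, 1.0, 0.0))
        gy = (v[ip, j] - v[im, j]) / ((ip - im) * dx + np.where(ip == im, 1.0, 0.0))
        return np.stack([gx, gy], axis=-1)

    def total_mass(self) -> float:
        return float(self.values.sum() * self.domain.voxel_volume)

    def to_csv(self) -> str:
        """(x, y, value) rows for small-grid export."""
        xs, ys = self.domain.voxel_centers()
        lines = ["x_um,y_um,value"]
        for i, y in enumerate(ys):
            for j, x in enumerate(xs):
                lines.append(f"{x:g},{y:g},{self.values[i, j]:.10g}")
        return "\n".join(lines) + "\n"


class Microenvironment:
    """A shared domain plus a named collection of substrate fields."""

    def __init__(self, domain: Domain):
        self.domain = domain
        self.fields: dict[str, SubstrateField] = {}

    def add_substrate(self, name: str, **kwargs) -> SubstrateField:
        f = SubstrateField(name=name, domain=self.domain, **kwargs)
        self.fields[name] = f
        return f

    def __getitem__(self, name: str) -> SubstrateField:
        return self.fields[name]

    def __contains__(self, name: str) -> bool:
        return name in self.fields

    def step(self, dt: float) -> None:
        for f in self.fields.values():
            f.step_diffusion(dt)

    def substrate_names(self) -> list[str]:
        return list(self.fields)
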