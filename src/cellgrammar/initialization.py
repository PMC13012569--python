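"""Initial agent populations: geometric seeding, position tables, affine
mapping of annotated spatial data, cohort composition, therapy transforms.

Positions are always in simulation micrometres.  Spatial tables (e.g. from
annotated spot-level transcriptomics) carry arbitrary source units and are
mapped into the domain by a similarity transform (uniform scale plus
translation) that centres the data bounding box and inscribes it maximally
while preserving the aspect ratio.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microenv import Domain

__all__ = [
    "SeedingSpec",
    "seed_disk",
    "seed_ring",
    "load_position_table",
    "map_spatial_table",
    "composition_from_counts",
    "apply_therapy_transform",
]


@dataclass
class SeedingSpec:
    """Declarative description of an initial population."""

    mode: str = "disk"  # disk | ring | positions_file | spatial_table
    counts: dict[str, int] = field(default_factory=dict)
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 400.0
    inner_radius: float = 0.0
    outer_radius: float = 0.0
    path: str | None = None

    def __post_init__(self):
        for t, c in self.counts.items():
            if int(c) != c or c < 0:
                raise ValueError(f"count for {t!r} must be a nonnegative integer")
        if self.mode == "ring" and self.inner_radius >= self.outer_radius:
            raise ValueError("ring needs inner_radius < outer_radius")

    def total(self) -> int:
        return int(sum(self.counts.values()))


def _disk_points(n: int, radius: float, center, rng) -> np.ndarray:
    """Area-uniform points in a disk: r = R*sqrt(u)."""
    u = rng.random(n)
    theta = rng.random(n) * 2.0 * np.pi
    r = radius * np.sqrt(u)
    return np.stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)], axis=1
    )


def seed_disk(n: int, radius: float, center=(0.0, 0.0), type_assignment=None, rng=None):
    """Seed ``n`` agents uniformly (by area) over a disk.

    ``type_assignment`` may be a single type name, a dict of proportions, or
    None (caller assigns).  Returns (positions, type_labels).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pts = _disk_points(int(n), radius, center, rng)
    labels = _assign_types(int(n), type_assignment, rng)
    return pts, labels


def seed_ring(counts_per_type: dict[str, int], inner: float, outer: float,
              center=(0.0, 0.0), rng=None):
    """Seed exact per-type counts area-uniformly in an annulus.

    Radii are drawn as r = sqrt(inner^2 + u*(outer^2 - inner^2)) so density
    is uniform over the annulus area; no rejection needed.
    """
    if inner >= outer:
        raise ValueError("ring needs inner < outer")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    all_pts, all_labels = [], []
    for name, count in counts_per_type.items():
        count = int(count)
        u = rng.random(count)
        theta = rng.random(count) * 2.0 * np.pi
        r = np.sqrt(inner ** 2 + u * (outer ** 2 - inner ** 2))
        pts = np.stack(
            [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)], axis=1
        )
        all_pts.append(pts)
        all_labels.extend([name] * count)
    positions = np.vstack(all_pts) if all_pts else np.zeros((0, 2))
    return positions, all_labels


def _assign_types(n: int, assignment, rng) -> list[str]:
    if assignment is None:
        return ["cell"] * n
    if isinstance(assignment, str):
        return [assignment] * n
    names = list(assignment)
    probs = np.array([assignment[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(names), size=n, p=probs)
    return [names[d] for d in draws]


def load_position_table(path_or_buffer) -> pd.DataFrame:
    """Read a position CSV with header (x, y[, z], cell_type[, ecm_density])."""
    df = pd.read_csv(path_or_buffer)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"x", "y", "cell_type"} - set(df.columns)
    if missing:
        raise ValueError(f"position table missing columns: {sorted(missing)}")
    return df


def map_spatial_table(table: pd.DataFrame, domain: Domain, margin: float = 0.0):
    """Map an annotated spot table into the domain by a similarity transform.

    The data bounding box is uniformly scaled (preserving aspect ratio) to be
    maximally inscribed in the domain and centred; relative pairwise
    distances are preserved up to the single scale factor.  Degenerate
    bounding boxes (single point or collinear along one axis) map to the
    domain centre with unit scale.  Returns (positions, labels, ecm) where
    ``ecm`` is the per-row ECM density column or None.
    """
    if len(table) == 0:
        raise ValueError("spatial table is empty")
    xy = table[["x", "y"]].to_numpy(dtype=float)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = hi - lo
    dom_w = (domain.x_max - domain.x_min) - 2 * margin
    dom_h = (domain.y_max - domain.y_min) - 2 * margin
    dom_c = np.array(
        [(domain.x_min + domain.x_max) / 2.0, (domain.y_min + domain.y_max) / 2.0]
    )
    if span.max() <= 0:
        positions = np.tile(dom_c, (len(xy), 1))
    else:
        scales = []
        if span[0] > 0:
            scales.append(dom_w / span[0])
        if span[1] > 0:
            scales.append(dom_h / span[1])
        scale = min(scales)
        data_c = (lo + hi) / 2.0
        positions = (xy - data_c) * scale + dom_c
    labels = [str(v) for v in table["cell_type"]]
    ecm = table["ecm_density"].to_numpy(dtype=float) if "ecm_density" in table else None
    return positions, labels, ecm


def rasterize_ecm(positions: np.ndarray, ecm: np.ndarray, domain: Domain) -> np.ndarray:
    """Average per-point ECM density into the domain's voxel grid."""
    total = np.zeros(domain.shape)
    count = np.zeros(domain.shape)
    i, j = domain.voxel_indices(positions)
    np.add.at(total, (i, j), ecm)
    np.add.at(count, (i, j), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1.0), 0.0)
    return out


def composition_from_counts(
    count_table: dict[str, int],
    tumor_total: int = 1000,
    pdl1_hi_fraction: float = 0.0,
    tumor_hi_type: str = "tumor PD-L1hi",
    tumor_lo_type: str = "tumor PD-L1lo",
) -> SeedingSpec:
    """Cohort composition: immune counts verbatim, tumor cells renormalized.

    The tumor compartment is set to exactly ``tumor_total`` agents split into
    PD-L1 hi/lo by ``pdl1_hi_fraction`` with largest-remainder rounding, so
    hi + lo == tumor_total for any fraction.
    """
    if tumor_total <= 0:
        raise ValueError("tumor_total must be positive")
    if not (0.0 <= pdl1_hi_fraction <= 1.0):
        raise ValueError("pdl1_hi_fraction must lie in [0, 1]")
    counts = {k: int(v) for k, v in count_table.items()}
    for k, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count for {k!r}")
    exact_hi = tumor_total * pdl1_hi_fraction
    hi = int(np.floor(exact_hi))
    lo = int(np.floor(tumor_total - exact_hi))
    leftover = tumor_total - hi - lo
    # largest remainder gets the leftover agent(s)
    if leftover > 0:
        if (exact_hi - hi) >= ((tumor_total - exact_hi) - lo):
            hi += leftover
        else:
            lo += leftover
    counts[tumor_hi_type] = hi
    counts[tumor_lo_type] = lo
    return SeedingSpec(mode="disk", counts=counts)


_T_CELL_MARKERS = ("CD8", "CD4")


def _is_t_cell(name: str) -> bool:
    return any(m in name for m in _T_CELL_MARKERS)


def apply_therapy_transform(spec: SeedingSpec, therapies) -> SeedingSpec:
    """Apply in-silico therapy edits to a cohort seeding spec.

    * ``gvax``      doubles every T-cell count;
    * ``nivolumab`` relabels PD-1hi T cells to PD-1lo and PD-L1hi tumor
      cells to PD-L1lo;
    * ``urelumab``  relabels CD137lo T cells to CD137hi.

    The relabelings commute, so therapy sets compose in any order.  Unknown
    type names raise a taxonomy error only when a relabeling needs them.
    """
    therapies = set(therapies)
    unknown = therapies - {"gvax", "nivolumab", "urelumab"}
    if unknown:
        raise ValueError(f"unknown therapies: {sorted(unknown)}")
    counts = dict(spec.counts)

    def relabel(frm: str, to: str):
        nonlocal counts
        out: dict[str, int] = {}
        for name, c in counts.items():
            new = name.replace(frm, to)
            out[new] = out.get(new, 0) + c
        counts = out

    if "gvax" in therapies:
        counts = {k: (2 * v if _is_t_cell(k) else v) for k, v in counts.items()}
    if "nivolumab" in therapies:
        relabel("PD-1hi", "PD-1lo")
        relabel("PD-L1hi", "PD-L1lo")
    if "urelumab" in therapies:
        relabel("CD137lo", "CD137hi")
    new_spec = SeedingSpec(
        mode=spec.mode,
        counts=counts,
        center=spec.center,
        radius=spec.radius,
        inner_radius=spec.inner_radius,
        outer_radius=spec.outer_radius,
        path=spec.path,
    )
    return new_spec
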