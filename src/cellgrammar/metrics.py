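"""Quantities of interest computed from simulation snapshots.

All metrics are pure functions of snapshot data: population curves and their
area under the curve (AUC), radial histograms and the 1-D Wasserstein
distance between them, the invasive-projection count of a simulated
spheroid, and cortical layer thicknesses with their residual sum of squares
against a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "PopulationSeries",
    "RadialDistribution",
    "population_auc",
    "radial_distribution",
    "wasserstein_1d",
    "invasive_projections",
    "layer_thickness",
    "layer_rss",
]


class MetricError(ValueError):
    pass


@dataclass
class PopulationSeries:
    """Counts over time per (cell type, state) combination."""

    times: np.ndarray
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_snapshots(cls, snapshots, live_only: bool = False) -> "PopulationSeries":
        times = np.array([s.time for s in snapshots])
        keys = set()
        for s in snapshots:
            keys.update(s.cell_types)
        counts = {}
        for key in sorted(keys):
            counts[key] = np.array([
                s.count(cell_type=key, state="live" if live_only else None)
                for s in snapshots
            ])
        return cls(times=times, counts=counts)


def population_auc(series: PopulationSeries, cell_type: str) -> float:
    """Trapezoidal integral of one population curve (cell*min)."""
    if len(series.times) < 2:
        raise MetricError("population AUC needs at least two time points")
    y = np.asarray(series.counts[cell_type], dtype=float)
    return float(np.trapezoid(y, series.times))


@dataclass
class RadialDistribution:
    """Normalized histogram of distances from a centre."""

    bin_edges: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != len(self.bin_edges) - 1:
            raise MetricError("frequencies must have one entry per bin")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_radius(self) -> float:
        return float(np.sum(self.bin_centers * self.frequencies))


def radial_distribution(positions, center, n_bins: int, r_max: float) -> RadialDistribution:
    """Histogram of Euclidean distances from ``center``, normalized to sum 1.

    Distances beyond ``r_max`` are assigned to the last bin.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) == 0:
        raise MetricError("radial distribution of an empty population")
    if n_bins < 1:
        raise MetricError("n_bins must be >= 1")
    d = np.linalg.norm(positions - np.asarray(center, dtype=float), axis=1)
    d = np.minimum(d, r_max * (1.0 - 1e-12))
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist, _ = np.histogram(d, bins=edges)
    freq = hist / hist.sum()
    return RadialDistribution(bin_edges=edges, frequencies=freq)


def wasserstein_1d(p: RadialDistribution, q: RadialDistribution) -> float:
    """W1 distance between two binned distributions with identical edges:
    sum over bins of |CDF_p - CDF_q| * bin width (micrometres)."""
    if len(p.bin_edges) != len(q.bin_edges) or not np.allclose(p.bin_edges, q.bin_edges):
        raise MetricError("distributions must share bin edges")
    widths = np.diff(p.bin_edges)
    cdf_p = np.cumsum(p.frequencies)
    cdf_q = np.cumsum(q.frequencies)
    return float(np.sum(np.abs(cdf_p - cdf_q) * widths))


# -- invasive projections -----------------------------------------------------


def _rasterize(positions, radii, extent, resolution, ecm_image=None):
    """Stamp each cell as a disk whose intensity falls linearly to 0 at the
    rim; optionally add a normalized ECM layer resampled onto the raster."""
    (x0, x1, y0, y1) = extent
    nx = max(int(np.ceil((x1 - x0) * resolution)), 2)
    ny = max(int(np.ceil((y1 - y0) * resolution)), 2)
    img = np.zeros((ny, nx))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(positions),))
    for (x, y), r in zip(positions, radii):
        rp = max(r * resolution, 1.0)
        cx = (x - x0) * resolution
        cy = (y - y0) * resolution
        jlo, jhi = int(np.floor(cx - rp)), int(np.ceil(cx + rp)) + 1
        ilo, ihi = int(np.floor(cy - rp)), int(np.ceil(cy + rp)) + 1
        jlo, jhi = max(jlo, 0), min(jhi, nx)
        ilo, ihi = max(ilo, 0), min(ihi, ny)
        if jlo >= jhi or ilo >= ihi:
            continue
        jj, ii = np.meshgrid(np.arange(jlo, jhi), np.arange(ilo, ihi))
        dist = np.sqrt((jj + 0.5 - cx) ** 2 + (ii + 0.5 - cy) ** 2)
        img[ilo:ihi, jlo:jhi] += np.maximum(1.0 - dist / rp, 0.0)
    if ecm_image is not None and np.max(ecm_image) > 0:
        from scipy.ndimage import zoom

        scale = (ny / ecm_image.shape[0], nx / ecm_image.shape[1])
        img += zoom(ecm_image / np.max(ecm_image), scale, order=1)[:ny, :nx]
    return img


def invasive_projections(
    positions,
    baseline_median_radius: float,
    radii=8.4,
    ecm_field=None,
    resolution: float = 0.4,
    min_arc_points: int = 3,
    margin: float = 0.05,
) -> int:
    """Count invasive projections of a simulated spheroid.

    Pipeline: rasterize cell positions as intensity disks with a radial
    gradient (default 0.4 px/um, i.e. 4 px per 10 um), add the ECM layer if
    given, binarize with an Otsu threshold, trace the outer contour of the
    mask, and count maximal contiguous contour arcs whose radial distance
    from the contour centroid exceeds the baseline median radius.  Arcs
    shorter than ``min_arc_points`` contour points are ignored, and the
    exceedance must clear a small relative ``margin`` so raster noise on a
    contour sitting exactly at the baseline radius does not register.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) == 0:
        raise MetricError("invasive projections of an empty snapshot")
    rmax = float(np.max(np.broadcast_to(np.asarray(radii, dtype=float), (len(positions),))))
    pad = 4.0 * rmax
    extent = (
        positions[:, 0].min() - pad,
        positions[:, 0].max() + pad,
        positions[:, 1].min() - pad,
        positions[:, 1].max() + pad,
    )
    img = _rasterize(positions, radii, extent, resolution, ecm_image=ecm_field)
    if img.max() <= 0:
        return 0
    thresh = threshold_otsu(img)
    mask = img > thresh
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return 0
    contour = max(contours, key=len)  # outer boundary of the main mass
    centroid = contour.mean(axis=0)
    radial = np.linalg.norm(contour - centroid, axis=1) / resolution
    # scale-free circular smoothing so raster noise on the rim does not
    # fragment one projection into several short arcs
    window = max(3, len(radial) // 50)
    kernel = np.ones(window) / window
    padded = np.concatenate([radial[-window:], radial, radial[:window]])
    radial = np.convolve(padded, kernel, mode="same")[window:-window]
    exceed = radial > baseline_median_radius * (1.0 + margin)
    return _count_arcs(exceed, min_arc_points)


def _count_arcs(exceed: np.ndarray, min_points: int) -> int:
    """Maximal contiguous True runs on a closed (wrap-around) contour."""
    n = len(exceed)
    if n == 0:
        return 0
    if exceed.all():
        return 1
    # rotate so the sequence starts on a False point: runs no longer wrap
    start = int(np.argmin(exceed))
    rolled = np.roll(exceed, -start)
    runs = 0
    length = 0
    for v in rolled:
        if v:
            length += 1
        else:
            if length >= min_points:
                runs += 1
            length = 0
    if length >= min_points:
        runs += 1
    return runs


# -- layer thickness ---------------------------------------------------------


def layer_thickness(
    positions, labels, layer_types, axis: int = 1,
    lo_pct: float = 2.5, hi_pct: float = 97.5,
) -> tuple[dict[str, float], list[str]]:
    """Per-layer spread of agent coordinates along ``axis``.

    Thickness is the 97.5th minus the 2.5th percentile of the coordinate for
    agents of each layer type — robust to stragglers.  Empty layers get
    thickness 0 and a warning record.  Returns (thicknesses, warnings).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    labels = np.asarray(labels)
    out: dict[str, float] = {}
    warnings: list[str] = []
    for layer in layer_types:
        coords = positions[labels == layer, axis]
        if len(coords) == 0:
            out[layer] = 0.0
            warnings.append(f"layer {layer!r} has no agents; thickness set to 0")
        else:
            out[layer] = float(np.percentile(coords, hi_pct) - np.percentile(coords, lo_pct))
    return out, warnings


def layer_rss(simulated: dict[str, float], reference: dict[str, float]) -> float:
    """Residual sum of squares of layer thicknesses over the reference's
    layers (um^2)."""
    return float(sum((simulated.get(k, 0.0) - v) ** 2 for k, v in reference.items()))
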