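"""Map- and distribution-level comparison metrics.

Histogram intersection quantifies the overlap between two sampled axon
radius distributions; the voxelwise coefficient of variation and the
coefficient of determination summarize posterior precision and model fit;
the callosal subregion utilities support anterior-to-posterior profile
analyses and scan-rescan comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Default radius histogram ranges: samples outside go to the end bins.
RADIUS_RANGE_M = (0.0, 25e-6)
SYNTHETIC_BIN_M = 0.25e-6   # synthetic (pooled-posterior) comparisons
WHOLE_STRUCTURE_BIN_M = 0.5e-6


@dataclass(frozen=True)
class DensityHistogram:
    """Density-normalized histogram on shared edges."""

    edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "density", d)
        if len(e) != len(d) + 1:
            raise ValueError("need one more edge than density value")
        total = np.sum(d * np.diff(e))
        if abs(total - 1.0) > 1e-6:
            raise ValueError("histogram is not density-normalized")

    @classmethod
    def from_samples(
        cls,
        samples,
        bin_width: float = SYNTHETIC_BIN_M,
        value_range: tuple[float, float] = RADIUS_RANGE_M,
    ) -> "DensityHistogram":
        """Histogram of samples; out-of-range values land in the end bins."""
        lo, hi = value_range
        n_bins = int(round((hi - lo) / bin_width))
        edges = lo + bin_width * np.arange(n_bins + 1)
        x = np.clip(np.asarray(samples, dtype=float), lo, np.nextafter(hi, lo))
        counts, _ = np.histogram(x, bins=edges)
        density = counts / (counts.sum() * bin_width)
        return cls(edges=edges, density=density)


def histogram_intersection(h1: DensityHistogram, h2: DensityHistogram) -> float:
    """H = sum_j min(h1j, h2j) / sum_j h1j, in [0, 1].

    The fraction of probability mass common to the two histograms; symmetric
    because the shared bins make the denominator the inverse bin width.
    """
    if h1.edges.shape != h2.edges.shape or not np.allclose(h1.edges, h2.edges):
        raise ValueError("histograms must share identical bin edges")
    return float(np.sum(np.minimum(h1.density, h2.density)) / np.sum(h1.density))


def voxelwise_cov(samples_per_voxel) -> tuple[np.ndarray, float]:
    """Percent coefficient of variation of R samples per voxel.

    Returns (per-voxel CoV array, mean over voxels).  Voxels with zero mean
    are undefined and returned as NaN (excluded from the map mean).
    """
    covs = []
    for s in samples_per_voxel:
        s = np.asarray(s, dtype=float)
        if len(s) < 2:
            raise ValueError("need at least 2 samples per voxel")
        m = s.mean()
        covs.append(np.nan if m == 0 else 100.0 * s.std(ddof=1) / m)
    covs = np.array(covs)
    return covs, float(np.nanmean(covs))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length vectors of at least 2 points")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


def subregion_partition(coords, n_regions: int = 5, axis: int = 1) -> np.ndarray:
    """Label voxels into equally spaced slabs along one axis.

    Cut planes are equally spaced between the minimal and maximal extent of
    the mask along ``axis`` (default: the anterior-posterior image axis);
    labels run 0 (anterior-most) to ``n_regions - 1``.  A voxel exactly on a
    plane joins the anterior side (left-closed convention).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("empty mask")
    x = coords[:, axis]
    planes = np.linspace(x.min(), x.max(), n_regions + 1)[1:-1]
    labels = np.zeros(len(x), dtype=int)
    for p in planes:
        labels += x > p
    return labels


def scan_rescan_rad(a: float, b: float) -> float:
    """Relative absolute difference |a - b| / (a + b)."""
    if a + b <= 0:
        raise ValueError("a + b must be positive")
    return abs(a - b) / (a + b)
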