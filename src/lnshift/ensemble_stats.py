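"""Trajectory ensemble statistics and the superposition-averaged structure.

Descriptive statistics use the population standard deviation (divide by n):
they summarize a complete trajectory, not a sample from one. Structure
averaging follows the usual Kabsch least-squares superposition of every frame
onto the first, then a per-atom coordinate mean; RMSF is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial.transform import Rotation

from .trajectory_io import Frame, Trajectory

__all__ = [
    "SeriesStats",
    "Histogram",
    "AverageStructure",
    "kabsch_rotation",
    "average_structure",
    "series_stats",
    "rmsd_values",
    "shift_histogram",
    "series_correlation",
]


@dataclass
class SeriesStats:
    min: float
    max: float
    mean: float
    std: float          # population (divide by n)
    range: float        # max − min
    n: int
    units: str = ""

    def to_dict(self) -> dict:
        return {
            "min": self.min,
            "max": self.max,
            "mean": self.mean,
            "std": self.std,
            "range": self.range,
            "n": self.n,
            "units": self.units,
        }


@dataclass
class Histogram:
    edges: np.ndarray
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class AverageStructure:
    reference_index: int
    elements: list[str]
    coords: np.ndarray   # per-atom mean, Å
    rmsf: np.ndarray     # per-atom positional spread, Å

    def to_frame(self) -> Frame:
        return Frame(index=0, elements=list(self.elements), coords=self.coords.copy())


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing ‖(R·p + t) − q‖.

    Reflections are excluded (det R = +1) even for chiral mismatches.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 3:
        raise ValueError("need matching N×3 coordinate sets with N ≥ 3")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    spread = min(np.linalg.svd(p0, compute_uv=False)[1], np.linalg.svd(q0, compute_uv=False)[1])
    if spread < 1e-10:
        raise ValueError("degenerate (collinear) point set: rotation underdetermined")
    rot, _ = Rotation.align_vectors(q0, p0)
    r = rot.as_matrix()
    t = qc - r @ pc
    return r, t


def align_frame(frame_coords: np.ndarray, ref_coords: np.ndarray) -> np.ndarray:
    r, t = kabsch_rotation(frame_coords, ref_coords)
    return frame_coords @ r.T + t


def average_structure(traj: Trajectory) -> AverageStructure:
    """Align every frame onto frame 0 (all atoms, unweighted), average the
    aligned coordinates per atom, and report the per-atom RMSF."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    ref = traj[0].coords
    aligned = np.empty((len(traj), *ref.shape))
    aligned[0] = ref
    for i, fr in enumerate(traj.frames[1:], start=1):
        aligned[i] = align_frame(fr.coords, ref)
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    return AverageStructure(
        reference_index=traj[0].index,
        elements=traj.elements,
        coords=mean,
        rmsf=rmsf,
    )


def series_stats(values, units: str = "") -> SeriesStats:
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty series")
    return SeriesStats(
        min=float(v.min()),
        max=float(v.max()),
        mean=float(v.mean()),
        std=float(v.std()),  # population
        range=float(v.max() - v.min()),
        n=int(v.size),
        units=units,
    )


def rmsd_values(a, b) -> float:
    """Root-mean-square deviation between two equal-length series."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size == 0:
        raise ValueError("series must have equal non-zero length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def shift_histogram(values, bin_width: float) -> Histogram:
    """Uniform-width histogram spanning [floor(min), ceil(max)] in units of
    the bin width; bins half-open [lo, hi) with the last bin closed."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty series")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    counts, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    return Histogram(edges=edges, counts=counts)


def series_correlation(a, b) -> float:
    """Pearson product-moment correlation of two series."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("series must have equal length ≥ 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(sps.pearsonr(a, b).statistic)
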