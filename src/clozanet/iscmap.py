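"""Inter-subject correlation (ISC) maps.

One subject's ISC map summarizes how similarly their brain responded to a
shared naturalistic stimulus compared with an independent reference group:
per voxel, the Pearson correlation between the subject's time course and
each reference subject's time course is Fisher z-transformed and averaged
over references.  Maps are kept in Fisher-z space (no back-transform).

Correlations are clamped to |r| <= 1 - CLAMP_EPS before arctanh so that
(near-)identical time courses cannot produce infinities, and zero-variance
time courses (e.g. masked-edge voxels) yield r = 0 rather than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ISCMap", "fisher_z", "compute_isc_map"]

logger = logging.getLogger(__name__)

#: correlations are clamped to +/- (1 - CLAMP_EPS) before the z-transform
CLAMP_EPS = 1e-7


@dataclass
class ISCMap:
    """Per-voxel mean Fisher-z correlation of one subject vs a reference group."""

    values: np.ndarray  # flat, one value per voxel
    subject_id: str
    n_reference: int
    grid_shape: tuple[int, ...]

    def volume(self) -> np.ndarray:
        """The map reshaped to its 3-D grid."""
        return self.values.reshape(self.grid_shape)


def fisher_z(r):
    """Fisher z-transform arctanh(r), the variance-stabilizing map for
    correlations; odd and strictly increasing on (-1, 1)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _standardize(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each voxel time course; flag zero-variance voxels.

    Returns (standardized T x V array with zero columns where degenerate,
    boolean V mask of degenerate voxels).
    """
    mu = ts.mean(axis=0)
    sd = ts.std(axis=0, ddof=0)
    # constant time courses: exact zeros plus rounding residue of a
    # constant level (sd ~ eps * |mean|)
    degenerate = sd <= 1e-12 * (np.abs(mu) + 1.0)
    sd_safe = np.where(degenerate, 1.0, sd)
    z = (ts - mu) / sd_safe
    z[:, degenerate] = 0.0
    return z, degenerate


def compute_isc_map(subject_ts: np.ndarray,
                    reference_ts,
                    subject_id: str = "subject",
                    grid_shape: tuple[int, ...] | None = None,
                    mask: np.ndarray | None = None) -> ISCMap:
    """Average Fisher-z correlation of one subject against each reference.

    Parameters
    ----------
    subject_ts : (T, V) array
        The subject's voxel time courses.
    reference_ts : sequence of (T, V) arrays or an (n, T, V) array
        Time courses of the independent reference group.  Only
        subject-vs-reference pairs are correlated, never reference pairs.
    grid_shape : optional
        Spatial shape recorded on the output map; defaults to ``(V,)``.
    mask : optional boolean array of V voxels
        Voxels outside the mask get value 0.
    """
    subject_ts = np.asarray(subject_ts, dtype=float)
    refs = np.asarray(reference_ts, dtype=float)
    if refs.ndim == 2:
        refs = refs[None]
    if refs.shape[0] < 1:
        raise ValueError("need at least one reference subject")
    if subject_ts.ndim != 2:
        raise ValueError("subject_ts must be a time-by-voxel matrix")
    T, V = subject_ts.shape
    if refs.shape[1:] != (T, V):
        raise ValueError(
            f"reference shape {refs.shape[1:]} does not match subject {(T, V)}")

    zs, deg_s = _standardize(subject_ts)
    zsum = np.zeros(V)
    n_degenerate = int(deg_s.sum())
    for j in range(refs.shape[0]):
        zr, deg_r = _standardize(refs[j])
        r = np.einsum("tv,tv->v", zs, zr) / T
        r[deg_s | deg_r] = 0.0  # no-signal voxels carry correlation 0
        n_degenerate += int(deg_r.sum())
        np.clip(r, -(1.0 - CLAMP_EPS), 1.0 - CLAMP_EPS, out=r)
        zsum += np.arctanh(r)
    if n_degenerate:
        logger.warning("zero-variance time courses at %d voxel instances; "
                       "their correlations were set to 0", n_degenerate)

    values = zsum / refs.shape[0]
    if mask is not None:
        values = np.where(np.asarray(mask, bool).ravel(), values, 0.0)
    return ISCMap(values=values, subject_id=subject_id,
                  n_reference=int(refs.shape[0]),
                  grid_shape=tuple(grid_shape) if grid_shape else (V,))


def cohort_isc_maps(subject_ts: np.ndarray, reference_ts: np.ndarray,
                    grid_shape: tuple[int, ...] | None = None) -> np.ndarray:
    """ISC maps for every subject of a cohort, stacked as (n_subjects, V)."""
    return np.stack([
        compute_isc_map(subject_ts[i], reference_ts, subject_id=f"sub-{i:03d}",
                        grid_shape=grid_shape).values
        for i in range(subject_ts.shape[0])
    ])
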