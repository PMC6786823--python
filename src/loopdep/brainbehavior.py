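"""Group-level brain-behavior statistics.

Correlates per-participant hippocampal activity differences (closed- minus
open-loop retrieval) with cortical reinstatement scores; compares dependent
correlations that share one variable with the Meng-Rosenthal-Rubin z test;
extracts face-connected suprathreshold clusters from voxelwise covariate
correlation maps; and splits a hippocampal mask into anterior and posterior
halves along its longitudinal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats


def roi_brain_behavior(values, covariate) -> dict:
    """Pearson correlation of ROI activity with a participant covariate.

    Returns r, R^2 and the two-tailed p value from the t distribution with
    n - 2 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and covariate must be aligned 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("correlation requires at least 4 participants")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "r2": float(r**2), "p": float(p), "n": n}


@dataclass
class CorrelationComparison:
    """Comparison of two correlations sharing one variable."""

    r_j1: float
    r_j2: float
    r_12: float
    n: int
    z: float
    p: float  # one-tailed, H1: rho_j1 > rho_j2


def compare_dependent_correlations(x_shared, y1, y2) -> CorrelationComparison:
    """Meng-Rosenthal-Rubin z test for correlations sharing one variable.

    Tests whether corr(x, y1) exceeds corr(x, y2) given the correlation
    between y1 and y2.  With Fisher transforms zhat of the two correlations:

        z = (zhat1 - zhat2) * sqrt((n - 3) / (2 * (1 - r_12) * h))
        h = (1 - f * rbar2) / (1 - rbar2),  rbar2 = (r_j1^2 + r_j2^2) / 2
        f = min(1, (1 - r_12) / (2 * (1 - rbar2)))

    One-tailed p = P(Z > z).  Swapping y1 and y2 negates z.
    """
    x = np.asarray(x_shared, dtype=float)
    a = np.asarray(y1, dtype=float)
    b = np.asarray(y2, dtype=float)
    if not (x.shape == a.shape == b.shape) or x.ndim != 1:
        raise ValueError("inputs must be aligned 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("comparison requires at least 4 participants")
    r_j1 = float(np.corrcoef(x, a)[0, 1])
    r_j2 = float(np.corrcoef(x, b)[0, 1])
    r_12 = float(np.corrcoef(a, b)[0, 1])
    for r in (r_j1, r_j2):
        if abs(r) >= 1.0 - 1e-12:
            raise ValueError("|r| = 1: Fisher transform undefined")
    rbar2 = (r_j1**2 + r_j2**2) / 2.0
    f = min(1.0, (1.0 - r_12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z1, z2 = np.arctanh(r_j1), np.arctanh(r_j2)
    if np.isclose(z1, z2):
        # identical correlations (e.g. y1 == y2): no evidence either way
        z = 0.0
    else:
        z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r_12) * h))
    return CorrelationComparison(
        r_j1=r_j1,
        r_j2=r_j2,
        r_12=r_12,
        n=n,
        z=float(z),
        p=float(stats.norm.sf(z)),
    )


@dataclass
class ClusterResult:
    """One face-connected suprathreshold cluster of a statistic map."""

    k: int
    peak: tuple
    peak_stat: float
    threshold_p: float


def group_covariate_map(
    volumes,
    covariate,
    threshold_p: float = 0.005,
    mask=None,
    min_cluster_size: int = 1,
) -> dict:
    """Voxelwise covariate correlation with cluster extraction.

    ``volumes`` is an (n_participants, nx, ny, nz) array of contrast values.
    Per voxel, activity is correlated with the covariate across participants
    and converted to a one-sided t test for a positive correlation; voxels
    with p below the cluster-defining threshold (restricted to ``mask`` if
    given) are grouped into face-connected components of at least
    ``min_cluster_size`` voxels.
    """
    vols = np.asarray(volumes, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if vols.ndim != 4 or vols.shape[0] != len(cov):
        raise ValueError("volumes must be (n_participants, nx, ny, nz) aligned to covariate")
    n = len(cov)
    if n < 4:
        raise ValueError("covariate map requires at least 4 participants")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vols.shape[1:]:
            raise ValueError("mask shape does not match the volumes")
        if not mask.any():
            raise ValueError("empty mask")

    flat = vols.reshape(n, -1)
    xc = cov - cov.mean()
    yc = flat - flat.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ yc) / denom, 0.0)
        r = np.clip(r, -0.999999, 0.999999)
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = stats.t.sf(t, n - 2)
    tmap = t.reshape(vols.shape[1:])
    pmap = p.reshape(vols.shape[1:])

    supra = pmap < threshold_p
    if mask is not None:
        supra &= mask
    structure = ndimage.generate_binary_structure(3, 1)  # face connectivity
    labels, n_labels = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n_labels + 1):
        voxels = np.argwhere(labels == lab)
        if len(voxels) < min_cluster_size:
            continue
        stats_in = tmap[tuple(voxels.T)]
        peak = voxels[int(np.argmax(stats_in))]
        clusters.append(
            ClusterResult(
                k=len(voxels),
                peak=tuple(int(i) for i in peak),
                peak_stat=float(stats_in.max()),
                threshold_p=threshold_p,
            )
        )
    clusters.sort(key=lambda c: c.k, reverse=True)
    return {"tmap": tmap, "pmap": pmap, "clusters": clusters}


def split_mask_longitudinal(mask, axis: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Split a binary mask at half its extent along the longitudinal axis.

    The occupied extent along ``axis`` is cut at half its length; the
    boundary slice is assigned to the posterior part.  Returns disjoint
    (anterior, posterior) masks partitioning the input.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 3:
        raise ValueError("mask must be 3-D")
    occupied = np.nonzero(m.any(axis=tuple(i for i in range(3) if i != axis)))[0]
    if occupied.size == 0:
        raise ValueError("empty mask")
    lo, hi = int(occupied[0]), int(occupied[-1])
    if lo == hi:
        raise ValueError("single-slice mask cannot be split")
    cut = lo + (hi - lo + 1) // 2
    idx = np.arange(m.shape[axis])
    shape = [1, 1, 1]
    shape[axis] = -1
    anterior = m & (idx.reshape(shape) < cut)
    posterior = m & (idx.reshape(shape) >= cut)
    return anterior, posterior
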