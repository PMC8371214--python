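"""PCA clustering of best-fit conformer sets and ensemble statistics.

Best-fit models are glycan-stripped, rigidly superposed on a chosen region
(usually the Fc), then decomposed by PCA of the flattened coordinates;
k-means on the first three components defines conformational groups, each
represented by its centroid model.  The Fab-tip separation statistic
summarizes how far apart the antigen-binding tips sit across an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .models import BeadModel


@dataclass
class PCAResult:
    projections: np.ndarray       # (n_models, n_components)
    eigenvalues: np.ndarray       # descending
    variance_captured_3: float    # percent for PC1-3
    groups: np.ndarray            # group label per model, 1..k
    centroids: dict               # group -> model index
    components: np.ndarray = None


def strip_glycans(model: BeadModel) -> BeadModel:
    """Remove all GLYCAN-tagged sites, preserving the order of the rest."""
    keep = model.region != "GLYCAN"
    return BeadModel(model.positions[keep], model.resnum[keep], model.chain[keep],
                     model.resname[keep], model.region[keep], model.f[keep],
                     model.mass[keep], dict(model.pivot_sets), model.provenance,
                     model.eu_offset)


def _check_topology(a: BeadModel, b: BeadModel, idx: np.ndarray) -> None:
    for i in idx:
        if (a.chain[i] != b.chain[i] or a.resnum[i] != b.resnum[i]
                or a.region[i] != b.region[i]):
            raise ValueError(
                f"site topology mismatch at index {i}: "
                f"{a.chain[i]}/{a.resnum[i]}/{a.region[i]} vs "
                f"{b.chain[i]}/{b.resnum[i]}/{b.region[i]}")


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping mobile onto target.

    Returns (R, t) with aligned = mobile @ R.T + t; proper rotation only
    (reflections are corrected by flipping the smallest singular vector).
    """
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - r @ cm
    return r, t


def superpose(models: list[BeadModel], reference: BeadModel,
              region: str) -> tuple[list[BeadModel], np.ndarray]:
    """Superpose every model onto the reference over one rigid region.

    Least-squares rigid transform (rotation + translation, no scaling) on
    the region's sites; returns the aligned models and the per-model RMSD
    over that region.
    """
    ref_idx = np.flatnonzero(reference.region == region)
    if len(ref_idx) < 3:
        raise ValueError(f"region {region} has fewer than 3 sites")
    target = reference.positions[ref_idx]
    aligned, rmsds = [], []
    for m in models:
        idx = np.flatnonzero(m.region == region)
        if len(idx) != len(ref_idx):
            raise ValueError(f"region {region} size differs from reference")
        _check_topology(m, reference, ref_idx)
        r, t = kabsch(m.positions[idx], target)
        new = m.with_positions(m.positions @ r.T + t)
        aligned.append(new)
        rmsds.append(float(np.sqrt(np.mean(
            np.sum((new.positions[idx] - target) ** 2, axis=1)))))
    return aligned, np.array(rmsds)


def pca_cluster(models: list[BeadModel], k: int, seed: int = 0,
                n_components: int = 3, full_space: bool = False) -> PCAResult:
    """PCA of flattened coordinates + k-means grouping with centroids.

    Models must be pre-superposed (and glycan-stripped when mixing
    glycosylated and deglycosylated sets).  Clustering runs on the first
    three principal components by default; the centroid of a group is the
    member minimizing the summed within-group distance in that space.
    """
    n = len(models)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of models ({n})")
    flat = np.array([m.positions.ravel() for m in models])
    mean = flat.mean(axis=0)
    x = flat - mean
    # SVD of the centered data; eigenvalues of the covariance are s^2/(n-1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s ** 2 / max(n - 1, 1)
    total = float(eig.sum())
    var3 = float(100.0 * eig[:3].sum() / total) if total > 0 else 0.0
    # sign convention: the largest-magnitude loading of each PC is positive
    for j in range(vt.shape[0]):
        lead = vt[j, np.argmax(np.abs(vt[j]))]
        if lead < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    proj = u * s
    space = proj if full_space else proj[:, :n_components]
    if total <= 1e-24:
        groups = np.ones(n, dtype=int)
        return PCAResult(proj, eig, var3, groups, {1: 0}, vt)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    groups = km.fit_predict(space) + 1
    centroids = {}
    for g in range(1, k + 1):
        members = np.flatnonzero(groups == g)
        sub = space[members]
        dsum = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1).sum(axis=1)
        centroids[g] = int(members[np.argmin(dsum)])
    return PCAResult(proj, eig, var3, groups, centroids, vt)


def fab_tip_separation(model: BeadModel, tip_selector=None) -> float:
    """Distance (nm) between the antigen-binding tips of the two Fabs.

    The default selector picks, for each Fab, the bead farthest from the
    hinge junction.  A custom ``tip_selector(model, region) -> site index``
    must return exactly one site per Fab.
    """
    tips = []
    for region in ("FAB1", "FAB2"):
        if tip_selector is None:
            idx = np.flatnonzero(model.region == region)
            if len(idx) == 0:
                raise ValueError(f"model has no {region} sites")
            j = model.positions[model.hinge_junction]
            d = np.linalg.norm(model.positions[idx] - j, axis=1)
            tips.append(model.positions[idx[np.argmax(d)]])
        else:
            i = tip_selector(model, region)
            i = np.atleast_1d(i)
            if len(i) != 1:
                raise ValueError(f"tip selector matched {len(i)} sites for {region}")
            tips.append(model.positions[int(i[0])])
    return float(np.linalg.norm(tips[0] - tips[1]))
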