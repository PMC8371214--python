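"""Torsion-angle Monte Carlo conformer generation with steric-clash rejection.

Discrete backbone moves (24 states of 15 deg) are applied at the declared
hinge pivot peptides; everything outside the moving side stays rigid.  A
proposed conformer is accepted iff it is free of steric clashes — there is
no energy term.  A constrained-dihedral hinge-start generator stands in for
the molecular-dynamics step that produced the five representative hinge
conformations of the original workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .constants import CLASH_CUTOFF_NM, IGG3_HINGE_PATTERN, VIRTUAL_BOND_NM
from .models import HINGE_CHAIN, BeadModel, count_cysteines, expand_hinge_sequence

TORSION_STEP_DEG = 15.0
N_TORSION_STATES = 24

#: disulfide-bridge geometry band for paired cysteine beads (nm)
DISULFIDE_RANGE = (0.4, 0.75)


@dataclass(frozen=True)
class TorsionMove:
    """One discrete torsion move at a hinge pivot.

    ``step_index`` selects a multiple of 15 deg (24 states); ``moving_side``
    says whether the Fab side or the Fc side of the pivot rotates;
    ``pivot_set`` names the pivot peptide the move belongs to (``fab1``,
    ``fab2`` or ``fc``) and fixes which rigid unit moves.
    """

    pivot_residue: int
    angle_kind: str           # "phi" | "psi"
    step_index: int           # 0..23
    moving_side: str          # "FAB_SIDE" | "FC_SIDE"
    pivot_set: str = ""

    def __post_init__(self):
        if self.angle_kind not in ("phi", "psi"):
            raise ValueError(f"angle_kind must be phi or psi, got {self.angle_kind!r}")
        if not (0 <= self.step_index < N_TORSION_STATES):
            raise ValueError("step_index outside the 24-state 15-degree grid")
        if self.moving_side not in ("FAB_SIDE", "FC_SIDE"):
            raise ValueError(f"bad moving_side {self.moving_side!r}")


@dataclass
class ClashReport:
    clash_count: int
    min_separation: float
    offending_pairs: list

    @property
    def accepted(self) -> bool:
        return self.clash_count == 0


def _resolve_pivot_set(model: BeadModel, move: TorsionMove) -> str:
    if move.pivot_set:
        name = move.pivot_set
        if name not in model.pivot_sets:
            raise KeyError(f"pivot set {name!r} not declared on this model")
        if (move.pivot_residue, move.angle_kind) not in model.pivot_sets[name]:
            raise ValueError(
                f"({move.pivot_residue}, {move.angle_kind}) not in pivot set {name!r}")
        return name
    side = {"FAB_SIDE": ("fab1", "fab2"), "FC_SIDE": ("fc",)}[move.moving_side]
    hits = [n for n in side
            if (move.pivot_residue, move.angle_kind) in model.pivot_sets.get(n, [])]
    if not hits:
        raise ValueError(
            f"pivot ({move.pivot_residue}, {move.angle_kind}) is not in a declared "
            "pivot set; the rest of the model is held rigid")
    if len(hits) > 1:
        raise ValueError(
            f"pivot ({move.pivot_residue}, {move.angle_kind}) is ambiguous between "
            f"sets {hits}; specify move.pivot_set")
    return hits[0]


def apply_torsion_move(model: BeadModel, move: TorsionMove) -> BeadModel:
    """Rigidly rotate the moving side of a pivot by ``step_index`` x 15 deg.

    phi rotates about the virtual bond entering the pivot bead, psi about
    the bond leaving it.  ``fab1`` moves carry FAB1 plus the hinge stub
    N-terminal of the axis; ``fc`` moves carry FC (anchor included) and the
    glycans plus the hinge tail; ``fab2`` moves swivel FAB2 alone about an
    axis through the hinge junction bead, so the junction attachment
    distance is preserved exactly.  All other sites are untouched.
    """
    name = _resolve_pivot_set(model, move)
    p = move.pivot_residue
    pos = model.positions
    if move.angle_kind == "phi":
        i1, i2 = model.hinge_index(p - 1), model.hinge_index(p)
    else:
        i1, i2 = model.hinge_index(p), model.hinge_index(p + 1)
    axis = pos[i2] - pos[i1]
    axis = axis / np.linalg.norm(axis)

    on_h = model.chain == HINGE_CHAIN
    lo_res = model.resnum[i1] - 1          # hinge residues strictly below the axis
    hi_res = model.resnum[i2] + 1          # hinge residues strictly above the axis
    if name == "fab1":
        mask = model.region_mask("FAB1") | (on_h & (model.resnum <= lo_res))
        point = pos[i1]
    elif name == "fab2":
        mask = model.region_mask("FAB2")
        point = pos[model.hinge_junction]
    else:  # fc
        mask = model.region_mask("FC", "GLYCAN") | (on_h & (model.resnum >= hi_res))
        point = pos[i2]
    if int(mask.sum()) < 2:
        raise ValueError("fewer than 2 beads on the moving side")

    angle = np.deg2rad(move.step_index * TORSION_STEP_DEG)
    if move.step_index == 0:
        return model.copy()
    rot = Rotation.from_rotvec(axis * angle)
    new = pos.copy()
    new[mask] = rot.apply(pos[mask] - point) + point
    return model.with_positions(new)


def detect_clash(model: BeadModel, cutoff: float = CLASH_CUTOFF_NM) -> ClashReport:
    """All inter-region and non-bonded intra-hinge bead pairs below cutoff.

    Pairs bonded in sequence (|dresnum| <= 2 within one chain) are exempt,
    as are pairs inside the same non-hinge rigid region (their packing is
    fixed at construction).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(model.positions)
    pairs = _nonexempt_pairs(model, tree.query_pairs(cutoff, output_type="ndarray"))
    if len(pairs):
        d = np.linalg.norm(model.positions[pairs[:, 0]] - model.positions[pairs[:, 1]],
                           axis=1)
        min_sep = float(d.min())
    else:
        wide = _nonexempt_pairs(model, tree.query_pairs(2 * cutoff, output_type="ndarray"))
        if len(wide):
            d = np.linalg.norm(model.positions[wide[:, 0]] - model.positions[wide[:, 1]],
                               axis=1)
            min_sep = float(d.min())
        else:
            min_sep = np.inf
    return ClashReport(len(pairs), min_sep, [tuple(p) for p in pairs])


def _nonexempt_pairs(model: BeadModel, pairs: np.ndarray) -> np.ndarray:
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    i, j = pairs[:, 0], pairs[:, 1]
    same_region = model.region[i] == model.region[j]
    non_hinge = model.region[i] != "HINGE"
    exempt = same_region & non_hinge
    same_chain = model.chain[i] == model.chain[j]
    bonded = same_chain & (np.abs(model.resnum[i] - model.resnum[j]) <= 2)
    exempt |= bonded
    return pairs[~exempt]


# ---------------------------------------------------------------------------
# hinge-start generation (stand-in for the MD + PCA step)
# ---------------------------------------------------------------------------

@dataclass
class HingeStartSet:
    """Representative hinge conformations with their cluster structure."""

    conformers: list                    # list of (n_res, 3) arrays, nm
    cluster_labels: np.ndarray          # 1..5
    centroids: list                     # 5 conformer indices
    end_to_end: np.ndarray              # nm per conformer
    cys_pair_distances: np.ndarray      # (n, 11) disulfide bead distances
    projections: np.ndarray = None      # PCA projections used for clustering
    eigenvalues: np.ndarray = None
    seed: int = 0


def _cys_positions(residues) -> np.ndarray:
    return np.flatnonzero(np.asarray(residues, dtype=object) == "C")


def generate_hinge_starts(n_conformers: int = 500, seed: int = 0,
                          hinge_residues=None, persistence_sigma: float = 0.45,
                          min_self_distance: float = 0.36,
                          max_attempts: int = 500, n_clusters: int = 5) -> HingeStartSet:
    """Sample self-avoiding extended hinge backbones and cluster them.

    Each conformer is a correlated random walk at fixed virtual bond length
    whose partner-strand disulfide distances (one per hinge cysteine) are
    kept inside the 0.4-0.75 nm bridge band.  PCA on the flattened
    coordinates followed by k-means gives five clusters; the centroid of a
    cluster is the member minimizing the summed in-cluster distance.
    """
    if n_conformers < n_clusters:
        raise ValueError(f"need at least {n_clusters} conformers")
    if hinge_residues is None:
        hinge_residues = expand_hinge_sequence(IGG3_HINGE_PATTERN)
    n_res = len(hinge_residues)
    cys_idx = _cys_positions(hinge_residues)
    rng = np.random.default_rng(seed)
    b = VIRTUAL_BOND_NM

    conformers, e2e, cysd = [], [], []
    for _ in range(n_conformers):
        for attempt in range(1, max_attempts + 1):
            d = np.array([0.0, 0.0, -1.0])
            pts = np.zeros((n_res, 3))
            for i in range(1, n_res):
                d = d + persistence_sigma * rng.normal(size=3)
                d /= np.linalg.norm(d)
                pts[i] = pts[i - 1] + b * d
            if _self_avoiding(pts, min_self_distance):
                break
        else:
            raise RuntimeError(
                f"hinge constraint satisfaction failed after {max_attempts} attempts")
        from .models import _orient_chain
        pts = _orient_chain(pts)
        conformers.append(pts)
        e2e.append(float(np.linalg.norm(pts[-1] - pts[0])))
        # partner-strand disulfide distances (implicit second hinge chain)
        cysd.append(rng.uniform(*DISULFIDE_RANGE, size=len(cys_idx)))

    flat = np.array([c.ravel() for c in conformers])
    n_pc = min(10, flat.shape[0] - 1, flat.shape[1])
    pca = PCA(n_components=n_pc, random_state=0)
    proj = pca.fit_transform(flat)
    km = KMeans(n_clusters=n_clusters, n_init=10,
                random_state=int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31))
    labels = km.fit_predict(proj[:, :3]) + 1

    centroids = []
    for g in range(1, n_clusters + 1):
        members = np.flatnonzero(labels == g)
        sub = proj[members, :3]
        dists = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1).sum(axis=1)
        centroids.append(int(members[np.argmin(dists)]))

    return HingeStartSet(conformers, labels, centroids, np.array(e2e),
                         np.array(cysd), proj, pca.explained_variance_, seed)


def _self_avoiding(pts: np.ndarray, min_dist: float) -> bool:
    tree = cKDTree(pts)
    pairs = tree.query_pairs(min_dist, output_type="ndarray")
    if len(pairs) == 0:
        return True
    return bool(np.all(np.abs(pairs[:, 0] - pairs[:, 1]) <= 2))


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

@dataclass
class ModelLibrary:
    """Ordered conformer collection sharing one site topology."""

    template: BeadModel
    coords: np.ndarray          # (n_models, n_sites, 3)
    metadata: pd.DataFrame      # model_id, start_id, move_index, rg
    info: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.coords)

    def model(self, i: int) -> BeadModel:
        return self.template.with_positions(self.coords[i])

    def models(self):
        for i in range(len(self)):
            yield self.model(i)

    @property
    def rg(self) -> np.ndarray:
        return self.metadata["rg"].to_numpy()

    @staticmethod
    def concatenate(libraries: list["ModelLibrary"]) -> "ModelLibrary":
        template = libraries[0].template
        coords = np.concatenate([lib.coords for lib in libraries])
        metas = []
        for k, lib in enumerate(libraries):
            m = lib.metadata.copy()
            if "start_id" not in m:
                m["start_id"] = k
            metas.append(m)
        meta = pd.concat(metas, ignore_index=True)
        meta["model_id"] = np.arange(len(meta))
        return ModelLibrary(template, coords, meta,
                            {"combined_from": [lib.info for lib in libraries]})


def save_library(library: ModelLibrary, out_dir, ids=None) -> None:
    """Write library models as bead tables plus a metadata table.

    ``ids`` restricts the export to selected model ids (e.g. a best-fit
    set); the metadata TSV always covers the exported models only.
    """
    from pathlib import Path
    from .pdbio import write_model
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ids is None:
        ids = library.metadata["model_id"].tolist()
    ids = [int(i) for i in ids]
    for i in ids:
        write_model(library.model(i), out / f"model_{i:06d}.tsv")
    meta = library.metadata[library.metadata["model_id"].isin(ids)]
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)


def load_library(in_dir) -> ModelLibrary:
    """Read back a library directory written by :func:`save_library`."""
    from pathlib import Path
    from .pdbio import read_model
    src = Path(in_dir)
    meta = pd.read_csv(src / "metadata.tsv", sep="\t")
    models = [read_model(src / f"model_{int(i):06d}.tsv")
              for i in meta["model_id"]]
    coords = np.array([m.positions for m in models])
    return ModelLibrary(models[0], coords, meta.reset_index(drop=True),
                        {"loaded_from": str(src)})


def run_tamc(start: BeadModel, pivot_profile: dict | None = None,
             n_moves: int = 1000, cutoff: float = CLASH_CUTOFF_NM,
             seed: int = 0, start_id: int = 0) -> ModelLibrary:
    """Markov-chain torsion-angle search: propose, clash-test, accept.

    Each proposal samples a pivot and a 15-degree step uniformly from the
    profile; the move is accepted iff the resulting conformer is clash
    free, in which case it both extends the chain and is appended to the
    library.  The start model is always model 0.  Deterministic given
    ``seed``.
    """
    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    profile = pivot_profile if pivot_profile is not None else start.pivot_sets
    if not profile:
        raise ValueError("empty pivot profile")
    current = start.copy()
    current.pivot_sets = dict(profile)

    flat = [(name, res, kind) for name, pivots in profile.items()
            for (res, kind) in pivots]
    side_of = {"fab1": "FAB_SIDE", "fab2": "FAB_SIDE", "fc": "FC_SIDE"}
    rng = np.random.default_rng(seed)

    coords = [current.positions.copy()]
    rows = [dict(model_id=0, start_id=start_id, move_index=0,
                 rg=current.radius_of_gyration())]
    n_rejected = 0
    for t in range(1, n_moves + 1):
        name, res, kind = flat[rng.integers(len(flat))]
        step = int(rng.integers(N_TORSION_STATES))
        move = TorsionMove(res, kind, step, side_of.get(name, "FAB_SIDE"), name)
        candidate = apply_torsion_move(current, move)
        if detect_clash(candidate, cutoff).accepted:
            current = candidate
            coords.append(current.positions.copy())
            rows.append(dict(model_id=len(coords) - 1, start_id=start_id,
                             move_index=t, rg=current.radius_of_gyration()))
        else:
            n_rejected += 1

    meta = pd.DataFrame(rows)
    info = dict(seed=seed, cutoff=cutoff, n_moves=n_moves,
                rejection_fraction=(n_rejected / n_moves) if n_moves else 0.0,
                profile={k: list(v) for k, v in profile.items()})
    return ModelLibrary(current, np.array(coords), meta, info)
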