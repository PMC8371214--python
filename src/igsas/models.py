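"""Domain types and construction of coarse-grained three-body antibody models.

The conformer unit of the whole pipeline is the :class:`BeadModel`: a
one-bead-per-residue (Calpha-like) coordinate set in nm, partitioned into
rigid regions FAB1 / FAB2 / FC / HINGE / GLYCAN.  The two Fab regions hang
off the N-terminal side of a long disulfide-rich hinge; the Fc region is
carried by a rigid 8-bead anchor segment at the hinge C-terminus.  All
observables consumed downstream (R_G, P(r), I(Q) at Q <= 1.5 nm^-1) are
shape-dominated at this resolution, so beads carry unit scattering length
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .constants import (
    AMINO_ACID_MASS,
    EU_OFFSET,
    GLYCAN_RESIDUE_MASS,
    GLYCAN_SYNONYMS,
    IGG3_HINGE_PATTERN,
    VIRTUAL_BOND_NM,
)

REGIONS = ("FAB1", "FAB2", "FC", "HINGE", "GLYCAN")

#: PDB-style glycan residue codes -> residue class
GLYCAN_CODE_CLASS = {"NAG": "HexNAc", "MAN": "Hex", "GAL": "Hex", "SIA": "NeuNAc", "FUC": "dHex"}

#: linear stand-in for the complex-type biantennary N-glycan
#: (Man3GlcNAc2 core plus two NeuNAc.Gal.GlcNAc antennae; 11 residues)
GLYCAN_CHAIN_CODES = ("NAG", "NAG", "MAN", "MAN", "NAG", "GAL", "SIA", "MAN", "NAG", "GAL", "SIA")

HINGE_CHAIN = "H"


class HingeSequenceError(ValueError):
    """Malformed hinge pattern (bad parentheses or a non-amino-acid letter)."""


class ConstructionError(ValueError):
    """Impossible three-body geometry at construction time."""


class BeadSite(NamedTuple):
    """Read-only view of one coarse-grained site."""

    index: int
    residue_name: str
    residue_number: int
    chain_id: str
    region: str
    position: np.ndarray  # (3,), nm
    scattering_length: float
    mass: float


@dataclass
class BeadModel:
    """Labelled coarse-grained coordinate set with rigid-region tags.

    Coordinates are in nm.  ``pivot_sets`` maps a pivot-set name
    (``fab1`` / ``fab2`` / ``fc``) to a list of ``(residue_number,
    angle_kind)`` pairs on the hinge chain; torsion moves are only legal at
    these pivots (the rest of the model is held rigid).
    """

    positions: np.ndarray          # (n, 3) nm
    resnum: np.ndarray             # (n,) int
    chain: np.ndarray              # (n,) str
    resname: np.ndarray            # (n,) str (1-letter for amino beads)
    region: np.ndarray             # (n,) str, one of REGIONS
    f: np.ndarray = None           # scattering lengths
    mass: np.ndarray = None        # Da
    pivot_sets: dict = field(default_factory=dict)
    provenance: str = ""
    eu_offset: int = EU_OFFSET

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.chain = np.asarray(self.chain, dtype=object)
        self.resname = np.asarray(self.resname, dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        n = len(self.positions)
        if self.f is None:
            self.f = np.ones(n)
        else:
            self.f = np.asarray(self.f, dtype=float)
        if self.mass is None:
            self.mass = np.array([_default_mass(rn) for rn in self.resname])
        else:
            self.mass = np.asarray(self.mass, dtype=float)

    # -- basic protocol ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def __len__(self) -> int:
        return self.n_sites

    def site(self, i: int) -> BeadSite:
        return BeadSite(i, self.resname[i], int(self.resnum[i]), self.chain[i],
                        self.region[i], self.positions[i], float(self.f[i]),
                        float(self.mass[i]))

    @property
    def rigid_regions(self) -> dict:
        """Map region name -> array of site indices (partitions all sites)."""
        return {r: np.flatnonzero(self.region == r) for r in REGIONS
                if np.any(self.region == r)}

    def region_mask(self, *names: str) -> np.ndarray:
        return np.isin(self.region, names)

    def hinge_index(self, residue_number: int) -> int:
        """Site index of a residue on the hinge chain (hinge or anchor bead)."""
        hits = np.flatnonzero((self.chain == HINGE_CHAIN) & (self.resnum == residue_number))
        if len(hits) != 1:
            raise KeyError(f"residue {residue_number} not unique on hinge chain")
        return int(hits[0])

    @property
    def hinge_junction(self) -> int:
        """Site index of the N-terminal hinge bead (Fab attachment point)."""
        mask = (self.chain == HINGE_CHAIN) & (self.region == "HINGE")
        idx = np.flatnonzero(mask)
        return int(idx[np.argmin(self.resnum[idx])])

    def to_eu(self, continuous_resnum: int) -> int:
        """Translate continuous numbering to EU numbering (hinge/Fc span)."""
        return continuous_resnum + self.eu_offset

    # -- derived observables ----------------------------------------------
    def radius_of_gyration(self) -> float:
        """f-weighted R_G (nm) from the bead coordinates."""
        w = self.f / self.f.sum()
        com = w @ self.positions
        return float(np.sqrt((w * ((self.positions - com) ** 2).sum(axis=1)).sum()))

    def total_mass(self) -> float:
        return float(self.mass.sum())

    def copy(self) -> "BeadModel":
        return BeadModel(self.positions.copy(), self.resnum.copy(), self.chain.copy(),
                         self.resname.copy(), self.region.copy(), self.f.copy(),
                         self.mass.copy(), dict(self.pivot_sets), self.provenance,
                         self.eu_offset)

    def with_positions(self, positions: np.ndarray) -> "BeadModel":
        m = self.copy()
        m.positions = np.asarray(positions, dtype=float).copy()
        return m

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        unknown = set(self.region) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region tags: {sorted(unknown)}")
        for c in np.unique(self.chain):
            rn = self.resnum[self.chain == c]
            if len(np.unique(rn)) != len(rn):
                raise ValueError(f"duplicate residue number in chain {c}")
            if np.any(np.diff(np.sort(rn)) < 1):
                raise ValueError(f"residue numbering not strictly increasing in chain {c}")
        hinge_chain_res = set(self.resnum[self.chain == HINGE_CHAIN].tolist())
        for name, pivots in self.pivot_sets.items():
            for res, kind in pivots:
                if kind not in ("phi", "psi"):
                    raise ValueError(f"bad angle kind {kind!r} in pivot set {name}")
                if res not in hinge_chain_res:
                    raise ValueError(f"pivot residue {res} not on the hinge chain")


def _default_mass(resname: str) -> float:
    if resname in AMINO_ACID_MASS:
        return AMINO_ACID_MASS[resname]
    if resname in GLYCAN_CODE_CLASS:
        return GLYCAN_RESIDUE_MASS[GLYCAN_CODE_CLASS[resname]]
    return 110.0


# ---------------------------------------------------------------------------
# sequence / composition bookkeeping
# ---------------------------------------------------------------------------

def _is_residue_letter(ch: str) -> bool:
    """Uppercase one-letter codes, including the extended/ambiguity codes."""
    return len(ch) == 1 and "A" <= ch <= "Z"


def expand_hinge_sequence(pattern: str) -> list[str]:
    """Expand a one-letter sequence with ``(...)n`` repeat groups.

    >>> expand_hinge_sequence("(AB)2C")
    ['A', 'B', 'A', 'B', 'C']
    """
    out: list[str] = []
    i = 0
    n = len(pattern)
    while i < n:
        ch = pattern[i]
        if ch == "(":
            close = pattern.find(")", i)
            if close < 0:
                raise HingeSequenceError(f"unmatched '(' at position {i}")
            group = pattern[i + 1:close]
            j = close + 1
            digits = ""
            while j < n and pattern[j].isdigit():
                digits += pattern[j]
                j += 1
            if not digits:
                raise HingeSequenceError(f"repeat group at position {i} lacks a count")
            for g in group:
                if not _is_residue_letter(g):
                    raise HingeSequenceError(f"non-amino-acid letter {g!r} in pattern")
            out.extend(list(group) * int(digits))
            i = j
        elif ch == ")":
            raise HingeSequenceError(f"unmatched ')' at position {i}")
        else:
            if not _is_residue_letter(ch):
                raise HingeSequenceError(f"non-amino-acid letter {ch!r} in pattern")
            out.append(ch)
            i += 1
    return out


def count_cysteines(residues: Sequence[str]) -> int:
    """Number of Cys residues in a one-letter residue list."""
    return sum(1 for r in residues if r == "C")


def glycan_mass_from_deconvolution(m_glyc: float, m_deglyc: float, n_sites: int) -> float:
    """Per-site glycan mass from deconvoluted intact masses.

    The glycan chain mass is the glycosylated minus the deglycosylated
    species mass shared over the ``n_sites`` occupied sites.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if m_glyc < m_deglyc:
        raise ValueError("glycosylated mass below deglycosylated mass")
    return (m_glyc - m_deglyc) / n_sites


def glycan_composition_mass(composition: dict) -> float:
    """Mass (Da) of a glycan given residue-class counts.

    Keys are residue classes (``Hex``, ``HexNAc``, ``NeuNAc``, ``dHex``) or
    common monosaccharide names (Gal, Man, GlcNAc, Fuc, ...).
    """
    total = 0.0
    for key, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for {key}")
        cls = GLYCAN_SYNONYMS.get(key, key)
        if cls not in GLYCAN_RESIDUE_MASS:
            raise KeyError(f"unknown glycan residue class {key!r}")
        total += count * GLYCAN_RESIDUE_MASS[cls]
    return total


# ---------------------------------------------------------------------------
# pivot profiles
# ---------------------------------------------------------------------------

def default_pivot_profile(hinge_resnums: Sequence[int], glycosylated: bool = True) -> dict:
    """Pivot peptides at the ends of the hinge, as lists of (residue, kind).

    ``fab1`` pivots move the first Fab together with the N-terminal hinge
    stub; ``fab2`` pivots swivel the second Fab about the hinge junction
    (the implicit second heavy chain); ``fc`` pivots move the Fc side.
    """
    start = int(min(hinge_resnums))
    last = int(max(hinge_resnums))

    def both(residues):
        return [(r, k) for r in residues for k in ("phi", "psi")]

    if glycosylated:
        profile = {
            "fab1": both(range(start + 1, start + 5)),       # 217-220
            "fab2": both(range(start + 1, start + 7)),       # 217-222
            "fc": both(range(last, last + 2)),               # 285-286
        }
    else:
        profile = {
            "fab1": both(range(start + 1, start + 4)),       # 217-219
            "fab2": both(range(start + 1, start + 5)),       # 217-220
            "fc": both(range(last - 2, last)),               # 283-284
        }
    return profile


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto ``direction`` (unit)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(z @ d)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def fill_ellipsoid(n: int, semi_axes: Sequence[float], rng: np.random.Generator,
                   min_spacing: float = 0.30, max_tries: int = 200000) -> np.ndarray:
    """Quasi-uniform bead fill of an ellipsoid with a minimum bead spacing."""
    a = np.asarray(semi_axes, float)
    pts = np.empty((n, 3))
    k = 0
    tries = 0
    while k < n:
        tries += 1
        if tries > max_tries:
            raise ConstructionError(f"could not place {n} beads with spacing {min_spacing}")
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = rng.random() ** (1 / 3)
        cand = a * u * r
        if k and np.min(np.sum((pts[:k] - cand) ** 2, axis=1)) < min_spacing ** 2:
            continue
        pts[k] = cand
        k += 1
    return pts


def lattice_ellipsoid(semi_axes: Sequence[float], spacing: float) -> np.ndarray:
    """Deterministic cubic-lattice bead fill of an ellipsoid.

    Useful for uniform-density reference bodies (spheres, rods) where
    random fills would leave sampling noise in the form factor.
    """
    a = np.asarray(semi_axes, float)
    grids = [np.arange(-ax, ax + spacing / 2, spacing) for ax in a]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    inside = ((pts / a) ** 2).sum(axis=1) <= 1.0
    return pts[inside]


def helical_hinge_path(n_residues: int, end_to_end: float,
                       bond: float = VIRTUAL_BOND_NM, turn_deg: float = 100.0) -> np.ndarray:
    """Deterministic compact helical path for the hinge backbone.

    The helix rise is set so the chain spans ``end_to_end`` nm along -z;
    the lateral radius follows from the fixed virtual bond length.
    """
    n_bonds = n_residues - 1
    dz = end_to_end / n_bonds
    if dz >= bond:
        raise ConstructionError("end_to_end longer than the fully extended chain")
    lateral = np.sqrt(bond ** 2 - dz ** 2)
    phi = np.deg2rad(turn_deg)
    rho = lateral / (2.0 * np.sin(phi / 2.0))
    i = np.arange(n_residues)
    pts = np.stack([rho * np.cos(i * phi), rho * np.sin(i * phi), -i * dz], axis=1)
    return pts - pts[0]


def _orient_chain(coords: np.ndarray) -> np.ndarray:
    """Start at origin, end-to-end vector along -z, azimuth fixed."""
    c = coords - coords[0]
    e = c[-1]
    n = np.linalg.norm(e)
    if n > 1e-9:
        r = _rotation_to(e / n)      # R maps +z to e/|e|
        c = c @ r                    # applies R^T to every row: e -> +z|e|
        c[:, 2] *= -1.0              # flip to -z
        c[:, 0] *= -1.0              # keep the frame right-handed
    # fix azimuth: bring the bead farthest from the z-axis into the +x half-plane
    d2 = c[:, 0] ** 2 + c[:, 1] ** 2
    k = int(np.argmax(d2))
    if d2[k] > 1e-12:
        ang = np.arctan2(c[k, 1], c[k, 0])
        ca, sa = np.cos(-ang), np.sin(-ang)
        rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
        c = c @ rz.T
    return c


# ---------------------------------------------------------------------------
# three-body construction
# ---------------------------------------------------------------------------

DEFAULT_GEOMETRY = dict(
    n_fab=200,
    n_fc=230,
    fab_semi_axes=(3.9, 1.9, 1.9),
    fc_semi_axes=(2.8, 2.2, 2.2),
    fab_separation=9.0,       # Fab-Fab centre distance, nm
    fab_center_height=3.2,    # z of Fab centres above the hinge junction, nm
    fab_tilt_deg=70.0,        # long-axis tilt away from +z
    hinge_end_to_end=9.8,     # used only for the canonical helical hinge
    fc_gap=1.3,               # gap between anchor tip and the Fc surface, nm
    n_anchor=8,
    fab_mass=47150.0,
    fc_mass=52000.0,
    min_region_separation=2.0,
)

_ANCHOR_SEQ = "SVFLFPPK"


def build_three_body_model(hinge_residues: Sequence[str] | None = None,
                           hinge_coords: np.ndarray | None = None,
                           glycans: bool = True,
                           seed: int = 0,
                           clash_cutoff: float | None = None,
                           **geometry) -> BeadModel:
    """Construct the coarse-grained Fab/Fab/Fc + long-hinge model.

    The hinge is one bead per residue (default: the expanded 70-mer);
    Fab and Fc regions are ellipsoidal bead clouds; the hinge C-terminus
    carries a rigid 8-bead anchor segment tagged FC which superposes the
    Fc.  Deterministic for a given seed.

    Parameters in ``geometry`` override :data:`DEFAULT_GEOMETRY`.
    """
    from .constants import CLASH_CUTOFF_NM
    geo = dict(DEFAULT_GEOMETRY)
    bad = set(geometry) - set(geo)
    if bad:
        raise TypeError(f"unknown geometry parameters: {sorted(bad)}")
    geo.update(geometry)
    if geo["n_fab"] < 1 or geo["n_fc"] < 1:
        raise ConstructionError("bead counts must be >= 1 per region")
    if clash_cutoff is None:
        clash_cutoff = CLASH_CUTOFF_NM

    if hinge_residues is None:
        hinge_residues = expand_hinge_sequence(IGG3_HINGE_PATTERN)
    hinge_residues = list(hinge_residues)
    n_h = len(hinge_residues)
    if n_h < 4:
        raise ConstructionError("hinge must have at least 4 residues")

    rng = np.random.default_rng(seed)
    b = VIRTUAL_BOND_NM

    # --- hinge chain ------------------------------------------------------
    if hinge_coords is None:
        hinge = helical_hinge_path(n_h, geo["hinge_end_to_end"])
    else:
        hinge = np.asarray(hinge_coords, float)
        if hinge.shape != (n_h, 3):
            raise ConstructionError("hinge_coords shape does not match hinge length")
    hinge = _orient_chain(hinge)
    hinge_start_res = 216
    hinge_resnum = np.arange(hinge_start_res, hinge_start_res + n_h)
    end = hinge[-1]

    # --- Fc anchor segment (rigid with FC) --------------------------------
    n_anchor = geo["n_anchor"]
    anchor = end + np.outer(np.arange(1, n_anchor + 1) * b, np.array([0, 0, -1.0]))
    anchor_resnum = np.arange(hinge_resnum[-1] + 1, hinge_resnum[-1] + 1 + n_anchor)

    # --- Fc body ----------------------------------------------------------
    fc_a, fc_b, fc_c = geo["fc_semi_axes"]
    fc_center = anchor[-1] + np.array([0, 0, -(geo["fc_gap"] + fc_a)])
    fc = fill_ellipsoid(geo["n_fc"], (fc_b, fc_c, fc_a), rng) + fc_center  # long axis z
    fc_resnum = np.arange(anchor_resnum[-1] + 1, anchor_resnum[-1] + 1 + geo["n_fc"])

    # --- Fab bodies -------------------------------------------------------
    tilt = np.deg2rad(geo["fab_tilt_deg"])
    half_sep = geo["fab_separation"] / 2.0
    fabs = []
    for sign in (+1.0, -1.0):
        direction = np.array([sign * np.sin(tilt), 0.0, np.cos(tilt)])
        rot = _rotation_to(direction)
        a, b, c = geo["fab_semi_axes"]
        local = fill_ellipsoid(geo["n_fab"], (b, c, a), rng)  # long axis along +z
        center = np.array([sign * half_sep, 0.0, geo["fab_center_height"]])
        fabs.append(local @ rot.T + center)

    # --- glycans ----------------------------------------------------------
    glycan_chains = []
    if glycans:
        for sign in (+1.0, -1.0):
            normal = np.array([0.0, sign, 0.0])
            surf = fc_center + np.array(geo["fc_semi_axes"]) * normal \
                + np.array([0, 0, 0.4 * fc_a])
            # curve the chain gently away from the Fc surface
            pts = [surf + 0.45 * normal]
            d = normal.copy()
            for _ in range(len(GLYCAN_CHAIN_CODES) - 1):
                d = d + np.array([0.15, 0.0, 0.1])
                d /= np.linalg.norm(d)
                pts.append(pts[-1] + 0.45 * d)
            glycan_chains.append(np.array(pts))

    # --- assemble ---------------------------------------------------------
    pos, resnum, chain, resname, region, mass = [], [], [], [], [], []

    def add(p, rn, ch, names, reg, m):
        pos.append(p)
        resnum.append(rn)
        chain.extend([ch] * len(p))
        resname.extend(names)
        region.extend([reg] * len(p))
        mass.extend(m)

    for k, fab in enumerate(fabs):
        reg = "FAB1" if k == 0 else "FAB2"
        ch = "A" if k == 0 else "B"
        n = geo["n_fab"]
        add(fab, np.arange(1, n + 1), ch, ["UNK"] * n, reg,
            [geo["fab_mass"] / n] * n)
    add(hinge, hinge_resnum, HINGE_CHAIN, hinge_residues, "HINGE",
        [AMINO_ACID_MASS[r] for r in hinge_residues])
    anchor_names = list(_ANCHOR_SEQ[:n_anchor])
    add(anchor, anchor_resnum, HINGE_CHAIN, anchor_names, "FC",
        [AMINO_ACID_MASS[r] for r in anchor_names])
    anchor_mass = sum(AMINO_ACID_MASS[r] for r in anchor_names)
    add(fc, fc_resnum, "F", ["UNK"] * geo["n_fc"], "FC",
        [(geo["fc_mass"] - anchor_mass) / geo["n_fc"]] * geo["n_fc"])
    for k, g in enumerate(glycan_chains):
        add(g, np.arange(1, len(g) + 1), "C" if k == 0 else "D",
            list(GLYCAN_CHAIN_CODES), "GLYCAN",
            [GLYCAN_RESIDUE_MASS[GLYCAN_CODE_CLASS[c]] for c in GLYCAN_CHAIN_CODES])

    model = BeadModel(
        positions=np.concatenate(pos),
        resnum=np.concatenate(resnum),
        chain=np.array(chain, dtype=object),
        resname=np.array(resname, dtype=object),
        region=np.array(region, dtype=object),
        mass=np.array(mass, dtype=float),
        pivot_sets=default_pivot_profile(hinge_resnum, glycosylated=glycans),
        provenance=f"build_three_body_model(seed={seed}, glycans={glycans})",
    )
    model.validate()

    # region centres must be cleanly separated at construction
    coms = {r: model.positions[idx].mean(axis=0)
            for r, idx in model.rigid_regions.items() if r != "GLYCAN"}
    names = list(coms)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = np.linalg.norm(coms[names[i]] - coms[names[j]])
            if d < geo["min_region_separation"]:
                raise ConstructionError(
                    f"regions {names[i]} and {names[j]} centres only {d:.2f} nm apart")

    from .mc import detect_clash
    report = detect_clash(model, clash_cutoff)
    if report.clash_count:
        raise ConstructionError(
            f"construction produced {report.clash_count} steric clashes "
            f"(min separation {report.min_separation:.3f} nm)")
    return model
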