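"""Ground-truth generator: antibody-like geometries and instrument-like curves.

Everything downstream of data reduction is testable against this module:
it builds three-body models with known geometry (an extended long-hinge
``igg3_like`` preset and a short-hinge ``compact_control``), simulates
X-ray-like (825-point, low-noise) and neutron-like (146-point, noisier,
flat 2%-of-I(0) background) curves on uniform Q grids over 0-1.5 nm^-1,
and emits a self-consistent fixture suite with a truth manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import IGG1_HINGE_PATTERN, IGG3_HINGE_PATTERN, VIRTUAL_BOND_NM
from .ensemble import fab_tip_separation, strip_glycans
from .mc import generate_hinge_starts
from .models import BeadModel, build_three_body_model, expand_hinge_sequence
from .pdbio import write_model
from .scattering import ScatteringCurve, debye_curve

QMAX = 1.5
N_POINTS = {"xray": 825, "neutron": 146}


@dataclass
class NoiseSpec:
    """Instrument-statistics emulation for one modality."""

    modality: str = "xray"
    relative_sigma0: float = 0.01
    sigma_growth: float = 2.0
    background_fraction: float = 0.0
    n_points: int = 825
    seed: int = 0

    def __post_init__(self):
        if self.relative_sigma0 < 0 or self.sigma_growth < 0 or self.background_fraction < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")


def xray_noise(relative_sigma0: float = 0.01, seed: int = 0) -> NoiseSpec:
    return NoiseSpec("xray", relative_sigma0, 2.0, 0.0, N_POINTS["xray"], seed)


def neutron_noise(relative_sigma0: float = 0.04, seed: int = 0) -> NoiseSpec:
    return NoiseSpec("neutron", relative_sigma0, 2.0, 0.02, N_POINTS["neutron"], seed)


@dataclass
class GroundTruth:
    """A synthetic model plus the geometric truths recorded at build time."""

    model: BeadModel
    true_rg: float
    true_dmax: float
    true_fab_fab: float
    true_fab_fc: tuple
    true_tip_separation: float
    seed: int = 0
    preset: str = "igg3_like"
    build_seed: int = 0       # rigid-body fill seed, reusable for trial models

    def self_consistent(self, rtol: float = 1e-9) -> bool:
        """Stored truths equal values recomputed from the coordinates."""
        vals = _truths_from_model(self.model)
        stored = (self.true_rg, self.true_dmax, self.true_fab_fab,
                  *self.true_fab_fc, self.true_tip_separation)
        return bool(np.allclose(stored, vals, rtol=rtol))


def _truths_from_model(model: BeadModel) -> tuple:
    from scipy.spatial.distance import pdist
    rg = model.radius_of_gyration()
    dmax = float(pdist(model.positions).max()) if model.n_sites > 1 else 0.0
    coms = {r: model.positions[i].mean(axis=0) for r, i in model.rigid_regions.items()}
    fab_fab = float(np.linalg.norm(coms["FAB1"] - coms["FAB2"]))
    fab_fc = (float(np.linalg.norm(coms["FAB1"] - coms["FC"])),
              float(np.linalg.norm(coms["FAB2"] - coms["FC"])))
    tip = fab_tip_separation(model)
    return (rg, dmax, fab_fab, *fab_fc, tip)


#: hinge end-to-end band of the extended antibody ground-truth ensemble
TRUTH_HINGE_E2E = (9.6, 10.8)


def _sample_hinge(rng: np.random.Generator, n_res: int,
                  e2e_range: tuple = TRUTH_HINGE_E2E, max_tries: int = 20) -> np.ndarray:
    """One self-avoiding hinge conformation with end-to-end in the band."""
    residues = ["A"] * n_res if n_res != 70 else None
    for _ in range(max_tries):
        starts = generate_hinge_starts(
            n_conformers=24, seed=int(rng.integers(2 ** 31)),
            hinge_residues=residues)
        ok = np.flatnonzero((starts.end_to_end >= e2e_range[0])
                            & (starts.end_to_end <= e2e_range[1]))
        if len(ok):
            return starts.conformers[int(rng.choice(ok))]
    raise RuntimeError("could not sample a hinge in the end-to-end band")


#: the extended hinge end-to-end band of the representative start structures
START_HINGE_E2E = (7.67, 10.80)


def build_tamc_starts(starts, seed: int = 0, glycans: bool = True,
                      body_seed: int | None = None,
                      e2e_range: tuple = START_HINGE_E2E, **geometry) -> list:
    """Full three-body start models from a hinge-start set's five centroids.

    Start hinges are restricted to the extended end-to-end band
    ``e2e_range`` (collapsed hinges are not plausible starts for an
    antibody whose hinge core is disulfide-locked); a centroid hinge
    outside the band or colliding with the rigid bodies is replaced by the
    next-closest member of its cluster.  With ``body_seed`` set, every
    start reuses that rigid-body fill — the usual study design, where all
    trial models share one set of domain structures.
    """
    from .models import ConstructionError
    rng = np.random.default_rng(seed)
    hinge_res = expand_hinge_sequence(IGG3_HINGE_PATTERN)
    models = []
    for g, ci in enumerate(starts.centroids, start=1):
        members = np.flatnonzero(starts.cluster_labels == g)
        in_band = members[(starts.end_to_end[members] >= e2e_range[0])
                          & (starts.end_to_end[members] <= e2e_range[1])]
        if len(in_band) == 0:
            # fall back to the whole set, nearest to the band
            in_band = np.flatnonzero(
                (starts.end_to_end >= e2e_range[0])
                & (starts.end_to_end <= e2e_range[1]))
        if len(in_band) == 0:
            in_band = members
        ref = starts.projections[ci, :3]
        order = in_band[np.argsort(np.linalg.norm(
            starts.projections[in_band, :3] - ref, axis=1))]
        # last resort: out-of-band cluster members rather than no start
        fallback = members[~np.isin(members, order)]
        order = np.concatenate([order, fallback])
        built = None
        for idx in order:
            fill_seed = body_seed if body_seed is not None \
                else int(rng.integers(2 ** 31))
            try:
                built = build_three_body_model(
                    hinge_residues=hinge_res, hinge_coords=starts.conformers[int(idx)],
                    glycans=glycans, seed=fill_seed, **geometry)
                break
            except ConstructionError:
                continue
        if built is None:
            raise ConstructionError(f"no clash-free start in cluster {g}")
        models.append(built)
    return models


def make_ground_truth(preset: str = "igg3_like", seed: int = 0,
                      glycans: bool | None = None, **geometry) -> GroundTruth:
    """Build a ground-truth model for a named study condition.

    ``igg3_like``: long (70-residue) hinge, well-separated Fab and Fc,
    maximum dimension in the 25-28 nm band and a triple-peaked P(r).
    ``compact_control``: short-hinge (IgG1-like) arrangement, maximum
    dimension below 18 nm and only two P(r) maxima.  ``custom`` requires
    explicit geometry parameters.
    """
    from .models import ConstructionError
    rng = np.random.default_rng(seed)
    if preset == "igg3_like":
        if glycans is None:
            glycans = True
        hinge_res = expand_hinge_sequence(IGG3_HINGE_PATTERN)
        model = None
        build_seed = 0
        for _ in range(30):   # resample hinges that collide with the bodies
            hinge = _sample_hinge(rng, len(hinge_res))
            build_seed = int(rng.integers(2 ** 31))
            try:
                model = build_three_body_model(
                    hinge_residues=hinge_res, hinge_coords=hinge, glycans=glycans,
                    seed=build_seed, **geometry)
                break
            except ConstructionError:
                continue
        if model is None:
            raise ConstructionError("no clash-free igg3_like build in 30 hinge samples")
    elif preset == "compact_control":
        if glycans is None:
            glycans = True
        hinge_res = expand_hinge_sequence(IGG1_HINGE_PATTERN)
        geo = dict(fab_separation=6.8, fab_center_height=1.6, fab_tilt_deg=65.0,
                   hinge_end_to_end=2.8, fc_gap=0.15, n_anchor=4,
                   fab_semi_axes=(3.3, 1.9, 1.9), fc_semi_axes=(2.4, 2.1, 2.1))
        geo.update(geometry)
        build_seed = int(rng.integers(2 ** 31))
        model = build_three_body_model(
            hinge_residues=hinge_res, glycans=glycans, seed=build_seed, **geo)
    elif preset == "custom":
        if not geometry:
            raise ValueError("custom preset requires explicit geometry parameters")
        if glycans is None:
            glycans = True
        build_seed = int(rng.integers(2 ** 31))
        model = build_three_body_model(glycans=glycans, seed=build_seed, **geometry)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    truths = _truths_from_model(model)
    return GroundTruth(model, truths[0], truths[1], truths[2],
                       (truths[3], truths[4]), truths[5], seed, preset, build_seed)


def simulate_curve(truth: GroundTruth, noise: NoiseSpec,
                   concentration: float = 1.0) -> ScatteringCurve:
    """Instrument-like curve: Debye forward model + multiplicative noise.

    sigma(Q) = relative_sigma0 (1 + (Q/Qmax)^growth) I(Q); neutron curves
    additionally carry a flat background of ``background_fraction`` x I(0).
    The intensity scales linearly with the pseudo-concentration.
    """
    q = np.linspace(0.0, QMAX, noise.n_points)
    base = debye_curve(truth.model, q, bin_width=0.02, modality=noise.modality)
    i = base.i * concentration
    i0 = float(i[0])
    if noise.background_fraction > 0:
        i = i + noise.background_fraction * i0
    sig = noise.relative_sigma0 * (1.0 + (q / QMAX) ** noise.sigma_growth) * i
    rng = np.random.default_rng(noise.seed)
    noisy = i + sig * rng.standard_normal(len(q))
    noisy = np.maximum(noisy, 1e-12 * i0)
    return ScatteringCurve(q, noisy, sig, noise.modality,
                           label=f"synthetic-{noise.modality}")


def write_curve(path, curve: ScatteringCurve) -> None:
    cols = [curve.q, curve.i] + ([curve.sigma] if curve.sigma is not None else [])
    np.savetxt(path, np.column_stack(cols),
               header="Q[1/nm] I(Q)" + (" sigma" if curve.sigma is not None else ""))


def read_curve(path, modality: str = "xray", label: str = "") -> ScatteringCurve:
    data = np.loadtxt(path)
    sigma = data[:, 2] if data.shape[1] > 2 else None
    return ScatteringCurve(data[:, 0], data[:, 1], sigma, modality, label)


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Emit the full synthetic study: models, curves, buffers, manifest.

    Two ground-truth models (a glycosylated igg3-like build and its
    glycan-stripped deglycosylated pair), four SAXS and four SANS curves at
    pseudo-concentrations realized as noise levels, buffer condition files
    for light and heavy water, and a manifest of all stored truths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    glyc = make_ground_truth("igg3_like", seed=int(rng.integers(2 ** 31)))
    deglyc_model = strip_glycans(glyc.model)
    t = _truths_from_model(deglyc_model)
    deglyc = GroundTruth(deglyc_model, t[0], t[1], t[2], (t[3], t[4]), t[5],
                         glyc.seed, "igg3_like_deglyc")

    write_model(glyc.model, out / "truth_glyc.pdb")
    write_model(deglyc.model, out / "truth_deglyc.pdb")

    manifest = {}
    for name, gt in (("glyc", glyc), ("deglyc", deglyc)):
        manifest[f"{name}.rg_nm"] = gt.true_rg
        manifest[f"{name}.dmax_nm"] = gt.true_dmax
        manifest[f"{name}.fab_fab_nm"] = gt.true_fab_fab
        manifest[f"{name}.fab1_fc_nm"] = gt.true_fab_fc[0]
        manifest[f"{name}.fab2_fc_nm"] = gt.true_fab_fc[1]
        manifest[f"{name}.tip_separation_nm"] = gt.true_tip_separation

    saxs_levels = [0.008, 0.010, 0.012, 0.015]
    sans_levels = [0.03, 0.04, 0.05, 0.06]
    for kind, levels, maker, truths in (
            ("saxs", saxs_levels, xray_noise, (glyc, glyc, deglyc, deglyc)),
            ("sans", sans_levels, neutron_noise, (glyc, glyc, deglyc, deglyc))):
        for j, (lvl, gt) in enumerate(zip(levels, truths), start=1):
            spec = maker(lvl, seed=int(rng.integers(2 ** 31)))
            curve = simulate_curve(gt, spec)
            write_curve(out / f"{kind}_{j}.dat", curve)
            manifest[f"{kind}_{j}.noise"] = lvl
            manifest[f"{kind}_{j}.n_points"] = spec.n_points

    (out / "buffer_light_water.txt").write_text(
        "temperature 20.0\ndensity 1.00578\nviscosity 0.010190\nvbar 0.776\n")
    (out / "buffer_heavy_water.txt").write_text(
        "temperature 20.0\ndensity 1.11106\nviscosity 0.01384\nvbar 0.780\n")

    with open(out / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k} {v}\n")
    return manifest
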