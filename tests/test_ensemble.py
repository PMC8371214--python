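"""Glycan stripping, superposition, PCA clustering, tip separation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import igsas
from igsas.ensemble import (
    fab_tip_separation,
    kabsch,
    pca_cluster,
    strip_glycans,
    superpose,
)
from tests.conftest import bare_model


class TestStripGlycans:
    def test_glycan_free_model_unchanged(self):
        m = igsas.build_three_body_model(glycans=False, seed=0)
        out = strip_glycans(m)
        assert out.n_sites == m.n_sites
        assert np.array_equal(out.positions, m.positions)

    def test_removes_exactly_the_glycan_beads(self, igg3_truth):
        m = igg3_truth.model
        out = strip_glycans(m)
        assert m.n_sites - out.n_sites == 22
        assert "GLYCAN" not in set(out.region)

    def test_site_order_preserved(self, igg3_truth):
        m = igg3_truth.model
        out = strip_glycans(m)
        keep = m.region != "GLYCAN"
        assert np.array_equal(out.resnum, m.resnum[keep])
        assert np.array_equal(out.chain, m.chain[keep])

    def test_stripped_pairs_match_deglycosylated_build(self):
        # a glycosylated build and its deglycosylated twin share the
        # protein topology once glycans are stripped
        glyc = igsas.build_three_body_model(glycans=True, seed=3)
        deglyc = igsas.build_three_body_model(glycans=False, seed=3)
        assert strip_glycans(glyc).n_sites == deglyc.n_sites


class TestSuperpose:
    def test_self_superposition_identity(self, igg3_truth):
        m = igg3_truth.model
        aligned, rmsd = superpose([m], m, "FC")
        assert rmsd[0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(aligned[0].positions, m.positions)

    def test_recovers_known_rigid_transform(self, igg3_truth):
        m = igg3_truth.model
        rot = Rotation.from_euler("xyz", [0.4, -0.9, 0.3]).as_matrix()
        moved = m.with_positions(m.positions @ rot.T + np.array([2.0, -1.0, 5.0]))
        aligned, rmsd = superpose([moved], m, "FC")
        assert rmsd[0] < 1e-6
        assert np.allclose(aligned[0].positions, m.positions, atol=1e-6)

    def test_matches_scipy_align_vectors_oracle(self):
        # independent closed-form implementation as the cross-check
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=(30, 3))
            b = rng.normal(size=(30, 3))
            r, t = kabsch(a, b)
            rmsd_ours = np.sqrt(np.mean(np.sum((a @ r.T + t - b) ** 2, axis=1)))
            rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            rmsd_scipy = np.sqrt(rssd ** 2 / len(a))
            assert rmsd_ours == pytest.approx(rmsd_scipy, abs=1e-9)

    def test_topology_mismatch_names_first_site(self, igg3_truth):
        m = igg3_truth.model
        other = m.copy()
        idx = np.flatnonzero(other.region == "FC")[0]
        other.resnum = other.resnum.copy()
        other.resnum[idx] = 9999
        with pytest.raises(ValueError, match="mismatch"):
            superpose([other], m, "FC")


class TestPcaCluster:
    def test_identical_models_zero_variance(self, compact_truth):
        models = [compact_truth.model.copy() for _ in range(50)]
        res = pca_cluster(models, k=5)
        assert np.allclose(res.eigenvalues, 0.0)
        assert len(set(res.groups.tolist())) == 1

    def test_two_well_separated_conformers(self, igg3_truth):
        base = strip_glycans(igg3_truth.model)
        mv = igsas.TorsionMove(218, "phi", 12, "FAB_SIDE", "fab2")
        other = strip_glycans(igsas.apply_torsion_move(igg3_truth.model, mv))
        rng = np.random.default_rng(0)
        models = [base.with_positions(base.positions
                                      + 0.05 * rng.standard_normal((base.n_sites, 3)))
                  for _ in range(50)]
        models += [other.with_positions(other.positions
                                        + 0.05 * rng.standard_normal((base.n_sites, 3)))
                   for _ in range(50)]
        res = pca_cluster(models, k=2, seed=0)
        first, second = res.groups[:50], res.groups[50:]
        agreement = (np.mean(first == np.bincount(first).argmax())
                     + np.mean(second == np.bincount(second).argmax())) / 2
        assert agreement >= 0.98

    def test_isotropic_noise_variance_share(self):
        # for isotropic noise the top-3 share approaches 3/d; the direct
        # eigen-spectrum of the same data is the oracle
        rng = np.random.default_rng(8)
        d_beads = 10
        flat = rng.standard_normal((4000, d_beads * 3))
        models = [bare_model(f.reshape(-1, 3)) for f in flat]
        res = pca_cluster(models, k=2, seed=0)
        direct = np.sort(np.linalg.eigvalsh(np.cov(flat.T)))[::-1]
        share_direct = 100.0 * direct[:3].sum() / direct.sum()
        assert res.variance_captured_3 == pytest.approx(share_direct, rel=1e-6)
        assert res.variance_captured_3 == pytest.approx(100.0 * 3 / (3 * d_beads),
                                                        rel=0.25)

    def test_trace_identity(self, compact_truth):
        rng = np.random.default_rng(2)
        base = compact_truth.model
        models = [base.with_positions(base.positions
                                      + 0.2 * rng.standard_normal((base.n_sites, 3)))
                  for _ in range(30)]
        res = pca_cluster(models, k=3, seed=1)
        flat = np.array([m.positions.ravel() for m in models])
        total = ((flat - flat.mean(0)) ** 2).sum() / (len(models) - 1)
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_centroid_minimizes_ingroup_distance(self, compact_truth):
        rng = np.random.default_rng(5)
        base = compact_truth.model
        models = [base.with_positions(base.positions
                                      + 0.3 * rng.standard_normal((base.n_sites, 3)))
                  for _ in range(40)]
        res = pca_cluster(models, k=4, seed=2)
        space = res.projections[:, :3]
        for g, c in res.centroids.items():
            members = np.flatnonzero(res.groups == g)
            sums = [np.linalg.norm(space[members] - space[m], axis=1).sum()
                    for m in members]
            assert space[c] in space[members]
            assert np.linalg.norm(space[members] - space[c], axis=1).sum() \
                == pytest.approx(min(sums))

    def test_projection_invariance_under_global_transform(self, compact_truth):
        rng = np.random.default_rng(9)
        base = compact_truth.model
        models = [base.with_positions(base.positions
                                      + 0.2 * rng.standard_normal((base.n_sites, 3)))
                  for _ in range(20)]
        res1 = pca_cluster(models, k=2, seed=0)
        rot = Rotation.from_euler("xyz", [0.2, 0.8, -0.5]).as_matrix()
        shifted = [m.with_positions(m.positions @ rot.T + np.array([3.0, 1.0, -2.0]))
                   for m in models]
        res2 = pca_cluster(shifted, k=2, seed=0)
        # eigenvalues are frame-independent; projections match up to sign
        assert np.allclose(res1.eigenvalues[:5], res2.eigenvalues[:5], rtol=1e-8)
        for j in range(3):
            dot = np.dot(res1.projections[:, j], res2.projections[:, j])
            norm = (np.linalg.norm(res1.projections[:, j])
                    * np.linalg.norm(res2.projections[:, j]))
            assert abs(dot) == pytest.approx(norm, rel=1e-6)

    def test_k_larger_than_set_rejected(self, compact_truth):
        with pytest.raises(ValueError):
            pca_cluster([compact_truth.model] * 3, k=5)


class TestFabTipSeparation:
    def test_constructed_tips(self):
        pts = np.array([[0.0, 0, 0], [8.0, 0, 0], [4.0, 0, -1.0], [4.0, 1, -1.0]])
        m = bare_model(pts)
        m.region = np.array(["FAB1", "FAB2", "HINGE", "HINGE"], dtype=object)
        m.chain = np.array(["A", "B", "H", "H"], dtype=object)
        m.resnum = np.array([1, 1, 216, 217])
        assert fab_tip_separation(m) == pytest.approx(8.0)

    def test_mirror_symmetry(self, igg3_truth):
        m = igg3_truth.model
        mirrored = m.with_positions(m.positions * np.array([-1.0, 1.0, 1.0]))
        # swap is irrelevant: the distance between the two tips is unchanged
        assert fab_tip_separation(mirrored) == pytest.approx(fab_tip_separation(m),
                                                             rel=1e-12)

    def test_selector_must_match_one_site(self, igg3_truth):
        def bad_selector(model, region):
            return np.flatnonzero(model.region == region)[:2]
        with pytest.raises(ValueError, match="2 sites"):
            fab_tip_separation(igg3_truth.model, bad_selector)
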