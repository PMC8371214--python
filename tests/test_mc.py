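"""Torsion moves, clash detection and library generation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import igsas
from igsas.mc import (
    DISULFIDE_RANGE,
    TorsionMove,
    apply_torsion_move,
    detect_clash,
    generate_hinge_starts,
    run_tamc,
)
from tests.conftest import bare_model


class TestTorsionMove:
    def test_zero_step_is_identity(self, igg3_truth):
        m = igg3_truth.model
        out = apply_torsion_move(m, TorsionMove(218, "phi", 0, "FAB_SIDE", "fab1"))
        assert np.array_equal(out.positions, m.positions)

    def test_full_turn_returns_to_start(self, igg3_truth):
        m = igg3_truth.model
        cur = m
        for _ in range(24):
            cur = apply_torsion_move(cur, TorsionMove(219, "psi", 1, "FAB_SIDE", "fab1"))
        assert np.abs(cur.positions - m.positions).max() < 1e-6

    @pytest.mark.parametrize("pivot,kind,setname", [
        (218, "phi", "fab1"), (220, "psi", "fab2"), (285, "phi", "fc")])
    def test_moving_region_distances_rigid(self, igg3_truth, pivot, kind, setname):
        # brute-force distance-matrix comparison within the moving rigid region
        m = igg3_truth.model
        side = "FC_SIDE" if setname == "fc" else "FAB_SIDE"
        out = apply_torsion_move(m, TorsionMove(pivot, kind, 7, side, setname))
        region = {"fab1": "FAB1", "fab2": "FAB2", "fc": "FC"}[setname]
        idx = np.flatnonzero(m.region == region)
        before = squareform(pdist(m.positions[idx]))
        after = squareform(pdist(out.positions[idx]))
        assert np.abs(before - after).max() < 1e-9

    def test_hinge_bond_lengths_preserved(self, igg3_truth):
        m = igg3_truth.model
        out = apply_torsion_move(m, TorsionMove(219, "phi", 11, "FAB_SIDE", "fab1"))
        sel = np.flatnonzero(m.chain == "H")
        b0 = np.linalg.norm(np.diff(m.positions[sel], axis=0), axis=1)
        b1 = np.linalg.norm(np.diff(out.positions[sel], axis=0), axis=1)
        assert np.abs(b0 - b1).max() < 1e-9

    def test_non_moving_sites_bit_identical(self, igg3_truth):
        m = igg3_truth.model
        out = apply_torsion_move(m, TorsionMove(218, "phi", 5, "FAB_SIDE", "fab1"))
        static = ~(out.region_mask("FAB1") | ((out.chain == "H") & (out.resnum <= 217)))
        assert np.array_equal(out.positions[static], m.positions[static])

    def test_undeclared_pivot_rejected(self, igg3_truth):
        with pytest.raises(ValueError, match="rigid"):
            apply_torsion_move(igg3_truth.model,
                               TorsionMove(250, "phi", 3, "FAB_SIDE"))

    def test_fab2_junction_attachment_preserved(self, igg3_truth):
        m = igg3_truth.model
        out = apply_torsion_move(m, TorsionMove(221, "psi", 9, "FAB_SIDE", "fab2"))
        j = m.positions[m.hinge_junction]
        d0 = np.linalg.norm(m.positions[m.region == "FAB2"] - j, axis=1)
        d1 = np.linalg.norm(out.positions[out.region == "FAB2"] - j, axis=1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_bad_step_index_rejected(self):
        with pytest.raises(ValueError):
            TorsionMove(218, "phi", 24, "FAB_SIDE")


class TestClashDetection:
    def test_two_close_beads_clash(self):
        m = bare_model(np.array([[0.0, 0, 0], [0.2, 0, 0]]))
        m.region = np.array(["FAB1", "FAB2"], dtype=object)
        m.chain = np.array(["A", "B"], dtype=object)
        rep = detect_clash(m, 0.35)
        assert rep.clash_count == 1
        assert rep.min_separation == pytest.approx(0.2)

    def test_construction_default_clash_free(self, igg3_truth):
        assert detect_clash(igg3_truth.model).accepted

    def test_bonded_neighbours_exempt(self):
        pts = np.array([[0, 0, 0], [0.3, 0, 0], [0.6, 0, 0.0]])
        m = bare_model(pts, region="HINGE")
        m.chain = np.array(["H", "H", "H"], dtype=object)
        assert detect_clash(m, 0.35).clash_count == 0

    def test_matches_brute_force_scan(self):
        # spatial-hash result vs an O(N^2) oracle on random two-region models
        rng = np.random.default_rng(11)
        cutoff = 0.5
        for _ in range(100):
            n = 50
            pts = rng.uniform(-2, 2, size=(n, 3))
            m = bare_model(pts)
            m.region = np.array(["FAB1"] * 20 + ["FAB2"] * 15 + ["HINGE"] * 15,
                                dtype=object)
            m.chain = np.array(["A"] * 20 + ["B"] * 15 + ["H"] * 15, dtype=object)
            m.resnum = np.concatenate([np.arange(1, 21), np.arange(1, 16),
                                       np.arange(1, 16)])
            expected = 0
            for i in range(n):
                for j in range(i + 1, n):
                    if m.region[i] == m.region[j] and m.region[i] != "HINGE":
                        continue
                    if m.chain[i] == m.chain[j] and abs(int(m.resnum[i]) - int(m.resnum[j])) <= 2:
                        continue
                    if np.linalg.norm(pts[i] - pts[j]) < cutoff:
                        expected += 1
            assert detect_clash(m, cutoff).clash_count == expected


@pytest.fixture(scope="module")
def starts():
    return generate_hinge_starts(200, seed=4)


class TestHingeStarts:
    def test_five_centroids_and_constraints(self, starts):
        assert len(starts.centroids) == 5
        lo, hi = DISULFIDE_RANGE
        assert np.all((starts.cys_pair_distances >= lo)
                      & (starts.cys_pair_distances <= hi))
        assert starts.cys_pair_distances.shape[1] == 11

    def test_self_avoidance(self, starts):
        for c in starts.conformers[:20]:
            d = squareform(pdist(c))
            n = len(c)
            far = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) > 2
            assert d[far].min() >= 0.36

    def test_centroid_lengths_overlap_extended_band(self, starts):
        # the five representative hinges span an extended range that
        # overlaps 7.67-10.80 nm
        e2e = starts.end_to_end[starts.centroids]
        assert e2e.max() > 7.67
        assert e2e.min() < 10.80

    def test_deterministic(self):
        a = generate_hinge_starts(30, seed=9)
        b = generate_hinge_starts(30, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.conformers, b.conformers))
        assert np.array_equal(a.cluster_labels, b.cluster_labels)
        assert a.centroids == b.centroids

    def test_unsatisfiable_constraints_report_attempts(self):
        with pytest.raises(RuntimeError, match="5 attempts"):
            generate_hinge_starts(6, seed=0, min_self_distance=5.0, max_attempts=5)


@pytest.fixture(scope="module")
def library(igg3_truth):
    return run_tamc(igg3_truth.model, n_moves=300, seed=8)


class TestLibraryGeneration:
    def test_zero_moves_returns_start_only(self, igg3_truth):
        lib = run_tamc(igg3_truth.model, n_moves=0, seed=0)
        assert len(lib) == 1
        assert np.array_equal(lib.coords[0], igg3_truth.model.positions)

    def test_absurd_cutoff_rejects_everything(self, igg3_truth):
        lib = run_tamc(igg3_truth.model, n_moves=50, cutoff=50.0, seed=0)
        assert len(lib) == 1
        assert lib.info["rejection_fraction"] == 1.0

    def test_deterministic(self, igg3_truth):
        a = run_tamc(igg3_truth.model, n_moves=100, seed=3)
        b = run_tamc(igg3_truth.model, n_moves=100, seed=3)
        assert np.array_equal(a.coords, b.coords)
        assert a.metadata.equals(b.metadata)

    def test_accepted_models_all_clash_free(self, library):
        for k in range(0, len(library), max(1, len(library) // 25)):
            assert detect_clash(library.model(k)).accepted

    def test_rigid_regions_invariant_across_library(self, library, igg3_truth):
        m0 = igg3_truth.model
        for region in ("FAB1", "FAB2", "FC"):
            idx = np.flatnonzero(m0.region == region)
            ref = pdist(m0.positions[idx])
            for k in range(0, len(library), max(1, len(library) // 10)):
                assert np.abs(pdist(library.coords[k][idx]) - ref).max() < 1e-9

    def test_rg_spread_exceeds_20_percent_of_mean(self, igg3_truth):
        lib = run_tamc(igg3_truth.model, n_moves=800, seed=12)
        rg = lib.rg
        assert (rg.max() - rg.min()) > 0.2 * rg.mean()

    def test_acceptance_monotone_in_cutoff(self, igg3_truth):
        sizes = [len(run_tamc(igg3_truth.model, n_moves=150, cutoff=c, seed=5))
                 for c in (0.2, 0.35, 0.6, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_library_directory_round_trip(self, library, tmp_path):
        from igsas.mc import load_library, save_library
        ids = library.metadata["model_id"].tolist()[:5]
        save_library(library, tmp_path / "lib", ids=ids)
        back = load_library(tmp_path / "lib")
        assert len(back) == 5
        assert np.allclose(back.coords, library.coords[:5], atol=1e-5)
        assert np.allclose(back.metadata["rg"], library.metadata["rg"][:5])

    def test_negative_moves_and_empty_profile_rejected(self, igg3_truth):
        with pytest.raises(ValueError):
            run_tamc(igg3_truth.model, n_moves=-1)
        with pytest.raises(ValueError, match="empty"):
            run_tamc(igg3_truth.model, pivot_profile={}, n_moves=10)
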