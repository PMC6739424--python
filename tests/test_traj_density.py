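"""Density-map pipeline: alignment, binning, grid rotation, averaging."""

import numpy as np
import pytest

import lipidscape as L
from lipidscape.traj_density import _bin_points
from lipidscape.trajectory import LipidTrajectory

from conftest import brute_force_angle, rotate


def make_trajectory(marker_xy_per_frame, backbone_xy_per_frame, box=(40.0, 40.0),
                    species="PI4P", leaflet="embedded"):
    """Small hand-built trajectory; one species, constant marker count."""
    F = len(marker_xy_per_frame)
    M = len(marker_xy_per_frame[0])
    xyz = np.zeros((F, M, 3))
    for f, pts in enumerate(marker_xy_per_frame):
        xyz[f, :, :2] = pts
        xyz[f, :, 2] = 18.0
    B = len(backbone_xy_per_frame[0])
    bb = np.zeros((F, B, 3))
    for f, pts in enumerate(backbone_xy_per_frame):
        bb[f, :, :2] = pts
    return LipidTrajectory(
        times=np.arange(F) * 250.0,
        box=box,
        ids=np.arange(M),
        species=np.array([species] * M, dtype=object),
        leaflet=np.array([leaflet] * M, dtype=object),
        xyz=xyz,
        backbone=bb,
    )


# ----------------------------------------------------------------- alignment

class TestInplaneAngle:
    def test_identity(self, rod_reference):
        assert L.fit_inplane_angle(rod_reference.xy, rod_reference) == pytest.approx(0.0)

    def test_known_rotation_vs_grid_search(self, rod_reference):
        theta = 0.5236  # 30 degrees
        frame = rotate(rod_reference.xy, theta)
        est = L.fit_inplane_angle(frame, rod_reference)
        assert est == pytest.approx(theta, abs=1e-9)
        oracle = brute_force_angle(frame, rod_reference.xy)
        assert abs(est - oracle) < 1e-4

    def test_noisy_rod_recovery(self, rod_reference):
        rng = np.random.default_rng(0)
        ref24 = L.ReferenceStructure(
            np.stack([np.linspace(-18.0, 18.0, 24), np.zeros(24)], axis=1)
        )
        frame = rotate(ref24.xy, 0.5236) + rng.normal(0, 0.1, ref24.xy.shape)
        est = L.fit_inplane_angle(frame, ref24)
        assert abs(est - 0.5236) < 0.02
        assert abs(est - brute_force_angle(frame, ref24.xy)) < 1e-4

    def test_matches_grid_search_on_random_configurations(self, rod_reference):
        """Estimator equals the brute-force RMSD minimizer on arbitrary
        (non-rod) point sets with noise, to grid resolution."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.normal(0, 5, (10, 2))
            pts -= pts.mean(axis=0)
            ref = L.ReferenceStructure(pts)
            theta = rng.uniform(-np.pi, np.pi)
            frame = rotate(pts, theta) + rng.normal(0, 0.05, pts.shape)
            est = L.fit_inplane_angle(frame, ref)
            assert abs(est - brute_force_angle(frame, pts)) < 1.5e-4

    def test_degenerate_geometry_raises(self, rod_reference):
        with pytest.raises(ValueError, match="degenerate"):
            L.fit_inplane_angle(np.zeros((25, 2)), rod_reference)

    def test_angle_range(self, rod_reference):
        for theta in (-3.0, 3.0, np.pi):
            est = L.fit_inplane_angle(rotate(rod_reference.xy, theta), rod_reference)
            assert -np.pi < est <= np.pi


class TestReferenceStructure:
    def test_from_backbone_centers_and_aligns(self):
        rng = np.random.default_rng(1)
        rod = np.stack([np.linspace(-10, 10, 15), np.zeros(15)], axis=1)
        shifted = rotate(rod, 1.1) + np.array([5.0, -3.0]) + rng.normal(0, 0.01, rod.shape)
        ref = L.ReferenceStructure.from_backbone(shifted)
        assert np.abs(ref.xy.mean(axis=0)).max() < 1e-9
        # principal axis along x: y spread much smaller than x spread
        assert ref.xy[:, 0].std() > 50 * ref.xy[:, 1].std()
        # chain direction pins the frame: first -> last runs along +x
        assert ref.xy[-1, 0] > ref.xy[0, 0]
        flipped = L.ReferenceStructure.from_backbone(shifted[::-1])
        assert np.allclose(flipped.xy, -ref.xy[::-1], atol=1e-9)

    def test_uncentered_rejected(self):
        with pytest.raises(ValueError):
            L.ReferenceStructure(np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]]))


# ------------------------------------------------------------------- binning

class TestBinning:
    def test_single_marker_central_bin(self, rod_reference):
        grid = L.GridSpec(bin_width=1.0, nx=21, ny=21)
        counts = _bin_points(np.array([[0.2, 0.3]]), grid)
        assert counts.sum() == 1
        assert counts[10, 10] == 1  # central bin covers [-0.5, 0.5)

    def test_periodic_wrap(self):
        # marker at x = Lx + 0.3 counts in the bin containing x = 0.3
        grid = L.GridSpec(bin_width=1.0, nx=20, ny=20)
        a = _bin_points(np.array([[20.0 + 0.3, 0.0]]), grid)
        b = _bin_points(np.array([[0.3, 0.0]]), grid)
        assert (a == b).all() and a.sum() == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-60, 60, (500, 2))
        grid = L.GridSpec(bin_width=1.0, nx=40, ny=40)
        assert _bin_points(pts, grid).sum() == 500

    def test_unknown_labels_raise(self, rod_reference):
        traj = make_trajectory([np.zeros((2, 2))], [rod_reference.xy])
        with pytest.raises(ValueError, match="species"):
            L.bin_leaflet_positions(traj, 0, "PIP2", "embedded", L.GridSpec(1.0, 40, 40))
        with pytest.raises(ValueError, match="leaflet"):
            L.bin_leaflet_positions(traj, 0, "PI4P", "upper", L.GridSpec(1.0, 40, 40))

    def test_grid_must_fit_box(self, rod_reference):
        traj = make_trajectory([np.zeros((2, 2))], [rod_reference.xy])
        with pytest.raises(ValueError, match="box"):
            L.bin_leaflet_positions(traj, 0, None, None, L.GridSpec(1.0, 100, 100))


# ------------------------------------------------------------- grid rotation

class TestRotateGrid:
    def test_zero_angle_identity(self):
        rng = np.random.default_rng(3)
        g = rng.random((30, 30))
        assert np.allclose(L.rotate_grid_pbc(g, 0.0), g, atol=1e-9)

    def test_quarter_turn_is_index_permutation(self):
        rng = np.random.default_rng(4)
        g = rng.random((24, 24))
        out = L.rotate_grid_pbc(g, np.pi / 2)
        # rotating the content by -90° must equal an exact lattice remap
        expected = L.rotate_grid_pbc(g, np.pi / 2, clip_negative=False)
        assert np.allclose(out, expected, atol=1e-9)
        # exactness at lattice nodes: rotating back recovers the input
        back = L.rotate_grid_pbc(out, -np.pi / 2)
        assert np.allclose(back, g, atol=1e-7)

    def test_mass_conserved_on_smooth_grid(self):
        rng = np.random.default_rng(5)
        from scipy.ndimage import gaussian_filter

        g = gaussian_filter(rng.random((50, 50)), 3.0, mode="wrap")
        out = L.rotate_grid_pbc(g, 0.6458)
        assert abs(out.sum() / g.sum() - 1) < 0.01

    def test_nonfinite_rejected(self):
        g = np.ones((10, 10))
        g[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            L.rotate_grid_pbc(g, 0.1)

    def test_delta_moves_to_rotated_position(self):
        # a bump at lab (6, 0); rotating the grid for a helix at +90°
        # must place it at helix-frame (0, -6)
        grid = np.zeros((41, 41))
        grid[20, 26] = 1.0  # (x=+6, y=0), centre at index 20
        out = L.rotate_grid_pbc(grid, np.pi / 2)
        iy, ix = np.unravel_index(np.argmax(out), out.shape)
        assert (iy, ix) == (14, 20)  # helix-frame (0, -6)


# ---------------------------------------------------------------- averaging

def fixed_marker_trajectory(rod_reference, n_frames=40, helix_xy=(6.0, 3.0)):
    """One marker rigidly co-rotating with the helix at helix-frame (6, 3)."""
    thetas = np.linspace(0, 1.8, n_frames)
    markers, backbones = [], []
    for th in thetas:
        markers.append(rotate(np.array([helix_xy]), th))
        backbones.append(rotate(rod_reference.xy, th))
    return make_trajectory(markers, backbones, box=(40.0, 40.0))


class TestAverageDensity:
    def test_zero_rotation_matches_oracle_exactly(self, rod_reference):
        rng = np.random.default_rng(6)
        markers = [rng.uniform(-20, 20, (30, 2)) for _ in range(10)]
        backbones = [rod_reference.xy] * 10
        traj = make_trajectory(markers, backbones)
        grid = L.GridSpec.for_box(traj.box)
        a = L.average_density(traj, "PI4P", "embedded", grid, skip_ns=0,
                              reference=rod_reference)
        o = L.oracle_density(traj, "PI4P", "embedded", grid, skip_ns=0,
                             reference=rod_reference)
        assert np.allclose(a.values, o.values, atol=1e-7)
        assert a.n_frames_used == 10

    def test_fixed_marker_collapses_to_delta(self, rod_reference):
        """A marker fixed in the rotating helix frame accumulates all its
        mass within the 3x3 neighbourhood of one bin, in both routes."""
        traj = fixed_marker_trajectory(rod_reference)
        grid = L.GridSpec.for_box(traj.box)
        # oracle route: exact delta tracking, no interpolation
        for fn, min_frac in ((L.oracle_density, 1.0 - 1e-12), (L.average_density, 0.9)):
            m = fn(traj, "PI4P", "embedded", grid, skip_ns=0, reference=rod_reference)
            iy, ix = np.unravel_index(np.argmax(m.values), m.values.shape)
            xc, yc = grid.bin_centers()
            assert abs(xc[ix] - 6.0) <= 1.0 and abs(yc[iy] - 3.0) <= 1.0
            neighborhood = m.values[iy - 1 : iy + 2, ix - 1 : ix + 2].sum()
            assert neighborhood / m.values.sum() >= min_frac

    def test_skip_and_sampling(self, rod_reference):
        markers = [np.zeros((1, 2))] * 20
        traj = make_trajectory(markers, [rod_reference.xy] * 20)
        # times are 0..4750 ps; skip 2 ns leaves times >= 2000 ps: 12 frames
        m = L.average_density(traj, None, None, skip_ns=2e-3 * 1000,
                              reference=rod_reference)
        assert m.n_frames_used == 12
        m2 = L.average_density(traj, None, None, skip_ns=0, sample_interval_ps=500,
                               reference=rod_reference)
        assert m2.n_frames_used == 10
        with pytest.raises(ValueError, match="skip"):
            L.average_density(traj, None, None, skip_ns=100, reference=rod_reference)

    def test_probability_normalization(self, rod_reference):
        traj = fixed_marker_trajectory(rod_reference)
        m = L.average_density(traj, None, None, skip_ns=0, reference=rod_reference,
                              normalization="probability")
        assert m.values.sum() == pytest.approx(1.0, abs=1e-6)
        assert (m.values >= 0).all()


@pytest.fixture(scope="module")
def site_trajectory():
    # PI4P-enriched patch: marker count raised for statistical power of
    # the map comparison (the signal, not the composition, is under test)
    params = L.TrajectoryParams(
        n_frames=700,
        species_counts={"POPC": 60, "PI4P": 60},
        enrichment_sites=[L.EnrichmentSite((6.0, 3.0), "PI4P")],
        seed=12,
    )
    return L.gen_membrane_trajectory(params)


class TestOracleEquivalence:
    def test_enrichment_peak_at_site(self, site_trajectory, rod_reference):
        grid = L.GridSpec.for_box(site_trajectory.box)
        m = L.average_density(site_trajectory, "PI4P", "embedded", grid,
                              skip_ns=25, reference=rod_reference)
        iy, ix = np.unravel_index(np.argmax(m.values), m.values.shape)
        xc, yc = grid.bin_centers()
        assert np.hypot(xc[ix] - 6.0, yc[iy] - 3.0) <= 2.0

    def test_routes_correlate(self, site_trajectory, rod_reference):
        grid = L.GridSpec.for_box(site_trajectory.box)
        a = L.average_density(site_trajectory, "PI4P", "embedded", grid,
                              skip_ns=25, reference=rod_reference)
        o = L.oracle_density(site_trajectory, "PI4P", "embedded", grid,
                             skip_ns=25, reference=rod_reference)
        assert L.map_correlation(a, o) > 0.95

    def test_opposing_leaflet_unenriched(self, site_trajectory, rod_reference):
        """Sites act on the embedded leaflet only: the opposing-leaflet PI4P
        map shows no excess near the site location."""
        grid = L.GridSpec.for_box(site_trajectory.box, 4.0)
        m = L.average_density(site_trajectory, "PI4P", "opposing", grid,
                              skip_ns=25, reference=rod_reference)
        xc, yc = grid.bin_centers()
        X, Y = np.meshgrid(xc, yc)
        near = np.hypot(X - 6.0, Y - 3.0) < 8.0
        enrichment = m.values[near].mean() / m.values.mean()
        assert enrichment < 1.3

    def test_convergence_with_bin_width(self, site_trajectory, rod_reference):
        """Mean absolute difference between the two routes shrinks
        monotonically as bins refine from 4 Å to 1 Å (probability maps)."""
        diffs = []
        for bw in (4.0, 2.0, 1.0):
            grid = L.GridSpec.for_box(site_trajectory.box, bw)
            a = L.average_density(site_trajectory, "PI4P", "embedded", grid,
                                  skip_ns=25, reference=rod_reference,
                                  normalization="probability")
            o = L.oracle_density(site_trajectory, "PI4P", "embedded", grid,
                                 skip_ns=25, reference=rod_reference,
                                 normalization="probability")
            diffs.append(np.abs(a.values - o.values).mean() * grid.bin_width ** 2)
        assert diffs[0] > diffs[1] > diffs[2]

    def test_global_rotation_invariance(self, rod_reference):
        """Rigidly rotating every frame (markers + backbone) leaves the
        helix-frame map unchanged up to interpolation error."""
        # wide well: the enrichment feature spans many bins, so spline
        # interpolation error stays small relative to the signal
        params = L.TrajectoryParams(
            n_frames=1200,
            species_counts={"PI4P": 240},
            enrichment_sites=[L.EnrichmentSite((6.0, 3.0), "PI4P", radius=6.0)],
            seed=13,
        )
        traj = L.gen_membrane_trajectory(params)
        phi = 0.9
        rot = traj.xyz.copy()
        rot[:, :, :2] = rotate(traj.xyz[:, :, :2].reshape(-1, 2), phi).reshape(
            rot.shape[0], rot.shape[1], 2
        )
        bb = traj.backbone.copy()
        bb[:, :, :2] = rotate(traj.backbone[:, :, :2].reshape(-1, 2), phi).reshape(
            bb.shape[0], bb.shape[1], 2
        )
        traj2 = LipidTrajectory(traj.times, traj.box, traj.ids, traj.species,
                                traj.leaflet, rot, bb)
        grid = L.GridSpec.for_box(traj.box)
        # point-rotation route: exactly invariant (same points, same bins)
        o1 = L.oracle_density(traj, "PI4P", "embedded", grid, skip_ns=25,
                              reference=rod_reference)
        o2 = L.oracle_density(traj2, "PI4P", "embedded", grid, skip_ns=25,
                              reference=rod_reference)
        assert np.allclose(o1.values, o2.values, atol=1e-9)
        # grid-rotation route: invariant within interpolation tolerance
        m1 = L.average_density(traj, "PI4P", "embedded", grid, skip_ns=25,
                               reference=rod_reference)
        m2 = L.average_density(traj2, "PI4P", "embedded", grid, skip_ns=25,
                               reference=rod_reference)
        assert L.map_correlation(m1, m2) > 0.99
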