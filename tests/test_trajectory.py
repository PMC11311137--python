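"""Radial distribution functions, coordination numbers, and ion-pairing
classification on constructed trajectories."""

import numpy as np
import pytest

from nucleokin.errors import DomainError, ValidationError
from nucleokin.synthetic import simulate_trajectory
from nucleokin.trajectory import (
    RDFResult,
    TrajectoryFrame,
    classify_ion_pairing,
    coordination_from_rdf,
    coordination_number,
    first_approach_distance,
    most_probable_distance,
    radial_distribution,
)


@pytest.fixture(scope="module")
def ideal_gas_frames():
    return simulate_trajectory("ideal_gas",
                               {"n": 500, "box": 25.0, "n_frames": 200}, seed=42)


@pytest.fixture(scope="module")
def ideal_gas_rdf(ideal_gas_frames):
    return radial_distribution(ideal_gas_frames, "X", "X", bin_width=0.25,
                               r_max=12.5)


class TestRadialDistribution:
    def test_fixed_pair_single_bin(self):
        frames = simulate_trajectory("fixed_pair", {"d": 5.0, "box": 20.0})
        rdf = radial_distribution(frames, "A", "B", bin_width=0.1)
        nonzero = np.nonzero(rdf.g)[0]
        assert nonzero.size == 1
        center = rdf.r_centers[nonzero[0]]
        # the occupied bin contains r = 5.0 (edge assignment goes upward)
        assert abs(center - 5.0) <= rdf.bin_width / 2 + 1e-9

    def test_like_species_self_pairs_excluded(self):
        pos = np.array([[5.0, 5.0, 5.0], [8.0, 5.0, 5.0]])
        frame = TrajectoryFrame(pos, ("A", "A"), (20.0, 20.0, 20.0))
        rdf = radial_distribution([frame], "A", "A", bin_width=0.1)
        # one unordered pair at 3.0 A; no spurious r=0 self-distance
        assert rdf.g[0] == 0.0
        nonzero = np.nonzero(rdf.g)[0]
        assert nonzero.size == 1
        assert abs(rdf.r_centers[nonzero[0]] - 3.0) <= 0.05

    def test_ideal_gas_flat(self, ideal_gas_rdf):
        """Uncorrelated particles give g(r) = 1 within +/- 0.05 past bin 0."""
        g = ideal_gas_rdf.g[1:]
        assert np.all(np.abs(g - 1.0) <= 0.05)

    def test_ideal_gas_long_range_normalization(self, ideal_gas_rdf):
        r = ideal_gas_rdf.r_centers
        tail = ideal_gas_rdf.g[(r >= 6.25) & (r <= 12.5)]
        assert 0.97 <= float(tail.mean()) <= 1.03

    def test_pair_count_conservation(self):
        # non-periodic cluster fully inside r_max: reconstructed histogram
        # counts every ordered pair exactly once
        rng = np.random.default_rng(9)
        pos = rng.uniform(4.0, 6.0, size=(12, 3))
        frame = TrajectoryFrame(pos, ("A",) * 12, (10.0, 10.0, 10.0),
                                periodic=False)
        rdf = radial_distribution([frame], "A", "A", bin_width=0.1, r_max=9.0)
        edges = np.arange(rdf.g.size + 1) * rdf.bin_width
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        counts = rdf.g * (12 * rdf.density_b * shell)
        assert float(counts.sum()) == pytest.approx(12 * 11, rel=1e-9)

    def test_translation_and_wrap_invariance(self):
        frames = simulate_trajectory("ideal_gas",
                                     {"n": 50, "box": 12.0, "n_frames": 5},
                                     seed=3)
        shifted = [
            TrajectoryFrame((f.positions + np.array([3.7, -1.2, 9.9])) % 12.0,
                            f.labels, f.box)
            for f in frames
        ]
        a = radial_distribution(frames, "X", "X", bin_width=0.2)
        b = radial_distribution(shifted, "X", "X", bin_width=0.2)
        assert np.allclose(a.g, b.g, rtol=1e-9, atol=1e-12)

    def test_r_max_beyond_half_box_rejected(self):
        frames = simulate_trajectory("ideal_gas", {"n": 10, "box": 10.0,
                                                   "n_frames": 1})
        with pytest.raises(ValidationError):
            radial_distribution(frames, "X", "X", r_max=8.0)

    def test_empty_selection_rejected(self):
        frames = simulate_trajectory("fixed_pair", {})
        with pytest.raises(ValidationError):
            radial_distribution(frames, "A", "Zr")

    def test_matches_mdanalysis_reference(self):
        """Cross-check against the established InterRDF implementation."""
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rdf import InterRDF
        from MDAnalysis.coordinates.memory import MemoryReader

        rng = np.random.default_rng(3)
        L, n_a, n_b, n_frames = 20.0, 25, 25, 20
        coords = rng.uniform(0, L, size=(n_frames, n_a + n_b, 3)).astype(np.float32)
        labels = ("A",) * n_a + ("B",) * n_b
        frames = [
            TrajectoryFrame(coords[i].astype(float), labels, (L, L, L))
            for i in range(n_frames)
        ]
        mine = radial_distribution(frames, "A", "B", bin_width=0.1, r_max=10.0)

        u = mda.Universe.empty(n_a + n_b, trajectory=True)
        u.add_TopologyAttr("names", ["A"] * n_a + ["B"] * n_b)
        dims = np.tile(np.array([L, L, L, 90.0, 90.0, 90.0], dtype=np.float32),
                       (n_frames, 1))
        u.load_new(coords, format=MemoryReader, dimensions=dims)
        ref = InterRDF(u.select_atoms("name A"), u.select_atoms("name B"),
                       nbins=100, range=(0.0, 10.0))
        ref.run()
        assert np.allclose(mine.g, ref.results.rdf, rtol=1e-6, atol=1e-6)


class TestCoordinationNumber:
    def test_fixed_pair_counts_one(self):
        frames = simulate_trajectory("fixed_pair", {"d": 4.0})
        assert coordination_number(frames, "A", "B", r_cut=5.0) == 1.0

    def test_ideal_gas_matches_analytic_volume(self, ideal_gas_frames):
        rho = 500 / 25.0**3
        r_cut = 6.0
        expected = 4.0 / 3.0 * np.pi * (500 - 1) / 25.0**3 * r_cut**3
        got = coordination_number(ideal_gas_frames[:50], "X", "X", r_cut=r_cut)
        assert got == pytest.approx(expected, rel=0.02)
        assert rho > 0  # density sanity for the analytic form above

    def test_direct_and_rdf_integral_agree(self):
        frames = simulate_trajectory(
            "two_shell",
            {"radii": (5.0, 9.0), "occupancies": (6, 3), "n_frames": 200},
            seed=1,
        )
        direct = coordination_number(frames, "S", "Ca", r_cut=7.0)
        via_rdf = coordination_number(frames, "S", "Ca", r_cut=7.0,
                                      method="rdf", bin_width=0.05)
        assert direct == pytest.approx(6.0, abs=0.05)
        assert via_rdf == pytest.approx(direct, rel=0.02)

    def test_hydration_shell_of_seven_waters(self):
        frames = simulate_trajectory("hydrated_ion",
                                     {"n_waters": 7, "shell_radius": 2.4},
                                     seed=0)
        assert coordination_number(frames, "Ca", "O_water", r_cut=3.0) == 7.0

    def test_nonpositive_cutoff_rejected(self):
        frames = simulate_trajectory("fixed_pair", {})
        with pytest.raises(DomainError):
            coordination_number(frames, "A", "B", r_cut=0.0)


class TestPeakMetrics:
    def test_fixed_pair_most_probable(self):
        frames = simulate_trajectory("fixed_pair", {"d": 5.0})
        rdf = radial_distribution(frames, "A", "B", bin_width=0.1)
        assert abs(most_probable_distance(rdf) - 5.0) <= 0.05 + 1e-9

    def test_two_shell_primary_population_wins(self):
        # taller shell at 5 A, weaker at 9 A -> most probable distance 5 A
        frames = simulate_trajectory(
            "two_shell",
            {"radii": (5.0, 9.0), "occupancies": (8, 2), "width": 0.3,
             "n_frames": 300},
            seed=4,
        )
        rdf = radial_distribution(frames, "S", "Ca", bin_width=0.1)
        assert most_probable_distance(rdf) == pytest.approx(5.0, abs=0.3)

    def test_tie_breaks_toward_smaller_r(self):
        rdf = RDFResult(
            r_centers=np.array([1.0, 2.0, 3.0, 4.0]),
            g=np.array([0.0, 2.0, 0.0, 2.0]),
            bin_width=1.0, density_b=0.01, n_frames=1,
        )
        assert most_probable_distance(rdf) == 2.0

    def test_all_zero_g_rejected(self):
        rdf = RDFResult(np.array([1.0, 2.0]), np.array([0.0, 0.0]), 1.0, 0.01, 1)
        with pytest.raises(DomainError):
            most_probable_distance(rdf)

    def test_first_approach_hard_core(self):
        # shells at 3.5 and 7.5 A: density first appears in the 3.5 A bin
        frames = simulate_trajectory(
            "two_shell",
            {"radii": (3.5, 7.5), "occupancies": (2, 8), "width": 0.0,
             "n_frames": 50},
            seed=2,
        )
        rdf = radial_distribution(frames, "S", "Ca", bin_width=0.1)
        assert first_approach_distance(rdf) == pytest.approx(3.5, abs=0.05)

    def test_first_approach_ideal_gas_first_bin(self, ideal_gas_rdf):
        assert first_approach_distance(ideal_gas_rdf) == ideal_gas_rdf.r_centers[0]


class TestIonPairingClassification:
    def test_contact_pair(self):
        frames = simulate_trajectory("fixed_pair", {"d": 2.4})
        rdf = radial_distribution(frames, "A", "B", bin_width=0.1)
        assert classify_ion_pairing(rdf).category == "contact"

    def test_solvent_separated_at_7_5(self):
        # broad cation population centred 7.5 A from the sulfate sulfur
        frames = simulate_trajectory(
            "two_shell",
            {"radii": (7.5,), "occupancies": (6,), "width": 0.4,
             "n_frames": 200, "box": 32.0},
            seed=6,
        )
        rdf = radial_distribution(frames, "S", "Ca", bin_width=0.1)
        result = classify_ion_pairing(rdf)
        assert result.category == "solvent-separated"
        assert result.first_peak_r == pytest.approx(7.5, abs=0.3)

    def test_boundary_assigned_to_lower_category(self):
        rdf = RDFResult(np.array([2.0, 3.2, 5.6]), np.array([0.0, 3.0, 1.0]),
                        0.4, 0.01, 1)
        assert classify_ion_pairing(rdf, contact_max=3.2,
                                    shared_max=5.6).category == "contact"
        rdf2 = RDFResult(np.array([2.0, 3.2, 5.6]), np.array([0.0, 1.0, 3.0]),
                         0.4, 0.01, 1)
        assert classify_ion_pairing(rdf2, contact_max=3.2,
                                    shared_max=5.6).category == "solvent-shared"

    def test_intermediate_is_solvent_shared(self):
        frames = simulate_trajectory("fixed_pair", {"d": 4.5})
        rdf = radial_distribution(frames, "A", "B", bin_width=0.1)
        assert classify_ion_pairing(rdf).category == "solvent-shared"
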