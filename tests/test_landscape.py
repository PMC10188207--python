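"""Reaction-coordinate, PMF and basin-analysis tests."""

import itertools

import numpy as np
import pytest

from foxptools import landscape, synthgen
from foxptools.landscape import (
    FrameCoords,
    ReactionCoordSeries,
    find_basins,
    helical_fraction,
    pmf2d,
    radius_of_gyration,
    select_representatives,
)
from foxptools.synthgen import GeneratorConfig, gen_reaction_coords


def _cube_frame():
    coords = np.array(list(itertools.product([-1.0, 1.0], repeat=3)))
    return FrameCoords(coords=coords, atom_names=["C"] * 8,
                       res_ids=np.arange(8))


def _random_frame(rng, n=40):
    return FrameCoords(
        coords=rng.normal(0, 5, size=(n, 3)),
        atom_names=["C"] * n,
        res_ids=np.arange(n),
        masses=rng.uniform(1, 16, size=n),
    )


class TestRadiusOfGyration:
    def test_point_mass_and_cube(self):
        frame = FrameCoords(
            coords=np.zeros((4, 3)), atom_names=["C"] * 4,
            res_ids=np.arange(4),
        )
        assert radius_of_gyration(frame) == 0.0
        assert radius_of_gyration(_cube_frame()) == pytest.approx(np.sqrt(3))

    def test_isometry_invariance(self, rng):
        frame = _random_frame(rng)
        base = radius_of_gyration(frame, mass_weighted=True)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = FrameCoords(
            coords=frame.coords @ rot.T + np.array([3.0, -2.0, 11.0]),
            atom_names=frame.atom_names,
            res_ids=frame.res_ids,
            masses=frame.masses,
        )
        assert radius_of_gyration(moved, mass_weighted=True) == pytest.approx(
            base, rel=1e-12
        )

    def test_atom_order_invariance(self, rng):
        frame = _random_frame(rng)
        perm = rng.permutation(frame.n_atoms)
        shuffled = FrameCoords(
            coords=frame.coords[perm],
            atom_names=[frame.atom_names[i] for i in perm],
            res_ids=frame.res_ids[perm],
            masses=frame.masses[perm],
        )
        assert radius_of_gyration(shuffled, mass_weighted=True) == (
            pytest.approx(radius_of_gyration(frame, mass_weighted=True))
        )

    def test_mass_weighted_matches_mdtraj(self, tmp_path):
        """Independent cross-check against the mdtraj Rg implementation."""
        import mdtraj as md

        frame = synthgen.build_peptide([-57.0] * 12, [-47.0] * 12)
        synthgen.write_pdb([frame], tmp_path / "f.pdb")
        traj = md.load(str(tmp_path / "f.pdb"))
        ours = radius_of_gyration(
            landscape.load_pdb(tmp_path / "f.pdb")[0], mass_weighted=True
        )
        assert ours == pytest.approx(float(md.compute_rg(traj)[0]) * 10.0,
                                     rel=1e-3)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(_cube_frame(), selection=np.array([], int))


class TestHelicalFraction:
    def test_ideal_helix_and_strand(self):
        helix = synthgen.build_peptide([-57.0] * 15, [-47.0] * 15)
        strand = synthgen.build_peptide([-120.0] * 15, [120.0] * 15)
        assert helical_fraction(helix) == 1.0
        assert helical_fraction(strand) == 0.0

    def test_alternating_blocks_give_half(self):
        mixed = synthgen.build_peptide(
            [-57.0] * 10 + [-120.0] * 10, [-47.0] * 10 + [120.0] * 10
        )
        assert helical_fraction(mixed) == pytest.approx(0.5)

    def test_short_runs_do_not_count(self):
        # helical dihedrals on 2 isolated residues only
        phi = [-120.0] * 4 + [-57.0] * 2 + [-120.0] * 4
        psi = [120.0] * 4 + [-47.0] * 2 + [120.0] * 4
        frame = synthgen.build_peptide(phi, psi)
        assert helical_fraction(frame) == 0.0

    def test_atom_order_invariance(self):
        frame = synthgen.build_peptide([-57.0] * 8, [-47.0] * 8)
        rng = np.random.default_rng(1)
        perm = rng.permutation(frame.n_atoms)
        shuffled = FrameCoords(
            coords=frame.coords[perm],
            atom_names=[frame.atom_names[i] for i in perm],
            res_ids=frame.res_ids[perm],
        )
        assert helical_fraction(shuffled) == helical_fraction(frame)

    def test_too_few_residues_rejected(self):
        frame = synthgen.build_peptide([-57.0] * 3, [-47.0] * 3)
        # only one interior residue has both dihedrals
        with pytest.raises(ValueError):
            helical_fraction(frame)


def _mixture_series(seed, weights=(0.8, 0.2), n=30000):
    cov = np.diag([0.3**2, 0.02**2])
    basins = [
        (weights[0], 12.0, 0.8, cov),
        (weights[1], 20.0, 0.2, cov),
    ]
    return gen_reaction_coords(basins, n, 0.5, GeneratorConfig(seed=seed))


class TestPMF2D:
    def test_uniform_occupancy_gives_zero_everywhere(self):
        rng = np.random.default_rng(0)
        series = ReactionCoordSeries(
            frame=np.arange(400),
            time_ns=np.arange(1, 401) * 0.5,
            rg_a=np.tile(np.repeat(np.arange(20.0), 20), 1),
            f_alpha=np.tile(np.linspace(0.025, 0.975, 20), 20),
        )
        surface = pmf2d(series, bins=20,
                        ranges=((-0.5, 19.5), (0.0, 1.0)))
        finite = np.isfinite(surface.pmf)
        np.testing.assert_allclose(surface.pmf[finite], 0.0, atol=1e-12)

    def test_duplicating_series_leaves_pmf_unchanged(self):
        series = _mixture_series(1, n=5000)
        surface = pmf2d(series, bins=30)
        doubled = ReactionCoordSeries(
            frame=np.arange(2 * len(series)),
            time_ns=np.arange(1, 2 * len(series) + 1) * 0.5,
            rg_a=np.concatenate([series.rg_a] * 2),
            f_alpha=np.concatenate([series.f_alpha] * 2),
        )
        surface2 = pmf2d(
            doubled, bins=30,
            ranges=((surface.rg_edges[0], surface.rg_edges[-1]),
                    (surface.fa_edges[0], surface.fa_edges[-1])),
        )
        np.testing.assert_allclose(surface2.pmf, surface.pmf, atol=1e-12)

    def test_minimum_is_zero(self):
        surface = pmf2d(_mixture_series(2), bins=40)
        assert np.nanmin(surface.pmf[np.isfinite(surface.pmf)]) == 0.0

    def test_kt_scale_at_300k(self):
        surface = pmf2d(_mixture_series(3), bins=40, temperature_k=300.0)
        assert surface.temperature_k == 300.0
        # kT at 300 K is 0.596 kcal/mol: a bin with half the max occupancy
        # sits near 0.596*ln 2
        counts = surface.counts
        target = counts.max() / 2
        idx = np.unravel_index(np.argmin(np.abs(counts - target)),
                               counts.shape)
        expected = -0.5961 * np.log(counts[idx] / counts.max())
        assert surface.pmf[idx] == pytest.approx(expected, rel=1e-3)

    def test_too_few_frames_rejected(self):
        series = _mixture_series(4, n=50)
        with pytest.raises(ValueError):
            pmf2d(series)


class TestFindBasins:
    def test_single_gaussian_single_basin(self):
        series = gen_reaction_coords(
            [(1.0, 12.0, 0.5, np.diag([0.3**2, 0.02**2]))],
            20000, 0.5, GeneratorConfig(seed=5),
        )
        surface = pmf2d(series, bins=30)
        assert len(find_basins(surface, depth_threshold=3.0)) == 1

    def test_three_separated_basins_found(self):
        cov = np.diag([0.25**2, 0.015**2])
        series = gen_reaction_coords(
            [(0.5, 11.0, 0.85, cov), (0.3, 15.0, 0.5, cov),
             (0.2, 22.0, 0.15, cov)],
            30000, 0.5, GeneratorConfig(seed=6),
        )
        surface = pmf2d(series, bins=40)
        basins = find_basins(surface, depth_threshold=3.0)
        assert len(basins) == 3

    def test_threshold_below_minimum_gives_none(self):
        surface = pmf2d(_mixture_series(7), bins=30)
        assert find_basins(surface, depth_threshold=-1.0) == []

    def test_basin_count_stable_over_seeds(self):
        """Well-separated 3-component mixtures resolve 3 basins in >= 95%
        of seeds."""
        cov = np.diag([0.25**2, 0.015**2])
        hits = 0
        for seed in range(100):
            series = gen_reaction_coords(
                [(0.5, 11.0, 0.85, cov), (0.3, 15.0, 0.5, cov),
                 (0.2, 22.0, 0.15, cov)],
                6000, 0.5, GeneratorConfig(seed=seed),
            )
            surface = pmf2d(series, bins=35)
            if len(find_basins(surface, depth_threshold=3.0)) == 3:
                hits += 1
        assert hits >= 95

    def test_weight_ratio_sets_minimum_gap(self):
        surface = pmf2d(_mixture_series(8, n=40000), bins=40,
                        temperature_k=300.0)
        basins = find_basins(surface, depth_threshold=3.0)
        gap = basins[1].min_pmf - basins[0].min_pmf
        assert gap == pytest.approx(0.596 * np.log(4), abs=0.15)


class TestSelectRepresentatives:
    def test_crafted_series_selects_windowed_frames(self):
        surface = pmf2d(_mixture_series(9), bins=30)
        basins = find_basins(surface, depth_threshold=3.0)
        series = ReactionCoordSeries(
            frame=np.arange(10),
            time_ns=np.arange(1, 11) * 1.0,
            rg_a=np.array([12.0, 12.1, 30.0, 11.9, 30.0, 30.0, 12.0, 30.0,
                           30.0, 30.0]),
            f_alpha=np.array([0.8, 0.81, 0.2, 0.79, 0.2, 0.2, 0.3, 0.2,
                              0.2, 0.2]),
        )
        basin = basins[0]  # mean near (12, 0.8)
        chosen = select_representatives(
            series, basin, rg_window=1.0, fa_window=0.05,
            min_separation_ns=0.0, min_history=1,
        )
        assert set(chosen) == {0, 1, 3}

    def test_thinning_by_time_separation(self):
        series = ReactionCoordSeries(
            frame=np.arange(100),
            time_ns=np.arange(1, 101) * 0.1,  # 0.1 ns apart
            rg_a=np.full(100, 12.0),
            f_alpha=np.full(100, 0.8),
        )
        basin = landscape.Basin("B1", {(0, 0)}, (0, 0), 0.0, 12.0, 0.8)
        chosen = select_representatives(
            series, basin, min_separation_ns=0.5, min_history=1
        )
        assert len(chosen) == 20
        assert np.all(np.diff(series.time_ns[chosen]) >= 0.5)

    def test_insufficient_history_warns_and_returns_empty(self):
        series = ReactionCoordSeries(
            frame=np.arange(5), time_ns=np.arange(1, 6) * 0.5,
            rg_a=np.full(5, 12.0), f_alpha=np.full(5, 0.8),
        )
        basin = landscape.Basin("B1", {(0, 0)}, (0, 0), 0.0, 12.0, 0.8)
        with pytest.warns(UserWarning, match="history"):
            chosen = select_representatives(series, basin, min_history=10_000)
        assert chosen.size == 0

    def test_zero_windows_select_exact_matches_only(self):
        series = ReactionCoordSeries(
            frame=np.arange(4), time_ns=np.arange(1, 5) * 1.0,
            rg_a=np.array([12.0, 12.0, 12.5, 12.0]),
            f_alpha=np.array([0.8, 0.8, 0.8, 0.81]),
        )
        basin = landscape.Basin("B1", {(0, 0)}, (0, 0), 0.0, 12.0, 0.8)
        chosen = select_representatives(
            series, basin, rg_window=0.0, fa_window=0.0,
            min_separation_ns=0.0, min_history=1,
        )
        assert set(chosen) == {0, 1}


class TestSeriesIO:
    def test_tsv_round_trip(self, tmp_path):
        series = _mixture_series(10, n=500)
        series.to_tsv(tmp_path / "rc.tsv")
        back = ReactionCoordSeries.from_tsv(tmp_path / "rc.tsv")
        np.testing.assert_array_equal(back.rg_a, series.rg_a)
        np.testing.assert_array_equal(back.f_alpha, series.f_alpha)
        assert back.temperature_k == series.temperature_k

    def test_xyz_reader(self, tmp_path):
        (tmp_path / "f.xyz").write_text(
            "3\ncomment\nC 0.0 0.0 0.0\nC 1.0 0.0 0.0\nC 0.0 1.0 0.0\n"
            "3\ncomment\nC 0.0 0.0 0.0\nC 2.0 0.0 0.0\nC 0.0 2.0 0.0\n"
        )
        frames = landscape.load_xyz(tmp_path / "f.xyz")
        assert len(frames) == 2
        assert frames[1].coords[1, 0] == 2.0
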