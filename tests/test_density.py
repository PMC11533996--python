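"""Structure factors, map synthesis, peak search and the water rules.

The independent oracles here are deliberately naive: direct complex
summation for structure factors, direct cosine summation for the Fourier
synthesis, and an exhaustive triple-loop scan for local maxima.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from solventaudit import density, synthetic_data
from solventaudit.density import MapGrid, Peak
from solventaudit.io_structures import AtomRecord, ReflectionSet, Structure

from conftest import periodic_distance


def atom(x, y, z, element="C", occ=1.0, b=10.0, water=False, serial=1, resid=1):
    return AtomRecord(
        serial=serial, name="O" if water else element, residue_name="HOH" if water else "ALA",
        chain="S" if water else "A", residue_id=resid, position=(x, y, z),
        occupancy=occ, adp=b, element=element, is_water=water,
        is_polymer_amino_acid=not water,
    )


CELL = (12.0, 12.0, 12.0, 90.0, 90.0, 90.0)


def brute_force_sf(structure, hkl):
    """Independent direct summation F(h) = sum_j f_j exp(2 pi i h.x)."""
    frac = structure.fractional_positions()
    recip = structure.frac_matrix
    out = []
    for h in hkl:
        svec = np.asarray(h, float) @ recip
        s2 = float(svec @ svec)
        f = 0j
        for a, x in zip(structure.atoms, frac):
            ff = density._electrons(a.element) * np.exp(-density._FORM_B * s2 / 4)
            f += ff * a.occupancy * np.exp(-a.adp * s2 / 4) * np.exp(2j * np.pi * np.dot(h, x))
        out.append(f)
    return np.array(out)


class TestStructureFactors:
    def test_single_atom_at_origin_all_phases_zero(self):
        st = Structure(atoms=[atom(0, 0, 0, b=15.0)], cell=CELL)
        refl = density.calc_structure_factors(st, d_min=2.0)
        assert np.allclose(refl.coeffs.imag, 0.0, atol=1e-10)
        assert np.all(refl.coeffs.real > 0)

    def test_f000_is_total_electron_count(self):
        st = Structure(
            atoms=[atom(1, 2, 3, "O", occ=0.5), atom(5, 5, 5, "C", occ=1.0)],
            cell=CELL,
        )
        refl = density.calc_structure_factors(st, d_min=2.0)
        assert refl.f000 == pytest.approx(8 * 0.5 + 6 * 1.0)
        assert not any((h == 0).all() for h in refl.hkl)  # (000) carried separately

    def test_half_cell_translation_extinguishes_odd_orders(self):
        st = Structure(
            atoms=[atom(2.0, 3.0, 4.0), atom(8.0, 3.0, 4.0)], cell=CELL
        )  # second atom at x + (1/2, 0, 0)
        refl = density.calc_structure_factors(st, d_min=2.0)
        odd_h = refl.hkl[:, 0] % 2 == 1
        assert np.allclose(np.abs(refl.coeffs[odd_h]), 0.0, atol=1e-9)
        oracle = brute_force_sf(st, refl.hkl)
        np.testing.assert_allclose(refl.coeffs, oracle, atol=1e-8)

    def test_matches_direct_summation_oracle(self, toy_crystal):
        st, _ = toy_crystal
        refl = density.calc_structure_factors(st, d_min=3.0)
        pick = np.random.default_rng(0).choice(len(refl.hkl), 25, replace=False)
        oracle = brute_force_sf(st, refl.hkl[pick])
        np.testing.assert_allclose(refl.coeffs[pick], oracle, rtol=1e-9, atol=1e-9)

    def test_identity_symmetry_expansion_changes_nothing(self, toy_crystal):
        st, _ = toy_crystal
        base = density.calc_structure_factors(st, d_min=2.5)
        doubled = Structure(
            atoms=st.atoms, cell=st.cell, symmetry_ops=["x,y,z"], metadata=st.metadata
        )
        again = density.calc_structure_factors(doubled, d_min=2.5)
        np.testing.assert_allclose(base.coeffs, again.coeffs, rtol=1e-12)

    def test_errors(self):
        st = Structure(atoms=[atom(0, 0, 0)], cell=CELL)
        with pytest.raises(ValueError):
            density.calc_structure_factors(st, d_min=-1.0)
        no_cell = Structure(atoms=[atom(0, 0, 0)])
        with pytest.raises(ValueError, match="cell"):
            density.calc_structure_factors(no_cell, d_min=2.0)


class TestMapSynthesis:
    def test_fft_equals_direct_summation(self):
        st = Structure(
            atoms=[atom(1.0, 2.0, 3.0, "O"), atom(6.0, 7.5, 2.0, "N")], cell=CELL
        )
        refl = density.calc_structure_factors(st, d_min=4.0)
        grid = density.synthesize_map(refl, "direct_coeffs", grid_spacing=2.0)
        nx, ny, nz = grid.dims
        vol = st.volume
        # direct summation over the same hemisphere + Friedel mates
        direct = np.zeros(grid.dims)
        for (h, k, l), f in zip(refl.hkl, refl.coeffs):
            for i in range(nx):
                for j in range(ny):
                    for kk in range(nz):
                        arg = 2 * np.pi * (h * i / nx + k * j / ny + l * kk / nz)
                        direct[i, j, kk] += 2 * (f.real * np.cos(arg) + f.imag * np.sin(arg))
        direct /= vol
        scale = np.abs(grid.values).max()
        np.testing.assert_allclose(grid.values / scale, direct / scale, atol=1e-8)

    def test_point_atom_maximum_at_site(self):
        st = Structure(atoms=[atom(3.0, 4.0, 5.0, "S", b=8.0)], cell=CELL)
        refl = density.calc_structure_factors(st, d_min=1.5)
        grid = density.synthesize_map(refl, "direct_coeffs")
        peak_idx = np.unravel_index(np.argmax(grid.values), grid.dims)
        frac = np.array(peak_idx) / np.array(grid.dims)
        pos = grid.orth_matrix @ frac
        spacing = max(CELL[0] / grid.dims[0], CELL[1] / grid.dims[1], CELL[2] / grid.dims[2])
        assert periodic_distance(st, pos, (3.0, 4.0, 5.0)) <= spacing / 2 * np.sqrt(3)

    def test_zero_coefficients_give_constant_zero_map(self):
        refl = ReflectionSet(
            hkl=np.array([[1, 0, 0], [0, 1, 0]]), cell=CELL,
            coeffs=np.zeros(2, dtype=complex), d_min=5.0,
        )
        grid = density.synthesize_map(refl, "direct_coeffs")
        assert np.allclose(grid.values, 0.0)
        assert grid.sigma == 0.0

    def test_missing_columns_error_names_them(self):
        refl = ReflectionSet(
            hkl=np.array([[1, 0, 0]]), cell=CELL, f_obs=np.array([10.0]), d_min=5.0
        )
        with pytest.raises(ValueError, match="coeffs"):
            density.synthesize_map(refl, "fo_fc")

    def test_heaviest_atom_hosts_global_maximum(self, toy_crystal):
        """Fourier consistency: calc -> synthesize peaks at the heavy atom."""
        st, _ = toy_crystal
        heavy = Structure(
            atoms=st.atoms + [atom(9.0, 2.0, 11.0, "SE", serial=999, resid=99)],
            cell=st.cell, metadata=st.metadata,
        )
        refl = density.calc_structure_factors(heavy, d_min=1.8)
        grid = density.synthesize_map(refl, "direct_coeffs")
        idx = np.unravel_index(np.argmax(grid.values), grid.dims)
        pos = grid.orth_matrix @ (np.array(idx) / np.array(grid.dims))
        spacing = max(c / d for c, d in zip(st.cell[:3], grid.dims))
        assert periodic_distance(st, pos, (9.0, 2.0, 11.0)) <= spacing


class TestSigmaScale:
    def test_scaling_normalizes_and_is_idempotent(self, toy_crystal):
        st, _ = toy_crystal
        refl = density.calc_structure_factors(st, d_min=2.5)
        grid = density.synthesize_map(refl, "direct_coeffs")
        scaled = density.sigma_scale(grid)
        assert abs(scaled.mean) < 1e-6
        assert scaled.sigma == pytest.approx(1.0, abs=1e-6)
        again = density.sigma_scale(scaled)
        np.testing.assert_allclose(again.values, scaled.values, atol=1e-12)
        assert scaled.orig_sigma == pytest.approx(grid.sigma)

    def test_hand_computed_eight_sample_grid(self):
        values = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float).reshape(2, 2, 2)
        grid = MapGrid(cell=CELL, values=values)
        assert grid.mean == pytest.approx(0.5)
        assert grid.sigma == pytest.approx(0.5)
        scaled = density.sigma_scale(grid)
        assert set(np.unique(scaled.values)) == {-1.0, 1.0}

    def test_constant_map_cannot_be_scaled(self):
        grid = MapGrid(cell=CELL, values=np.full((2, 2, 2), 7.0))
        with pytest.raises(ValueError, match="constant"):
            density.sigma_scale(grid)


def brute_force_peak_nodes(values, threshold, sign="positive"):
    """Exhaustive 26-neighbour strict local-extremum scan."""
    v = values if sign == "positive" else -values
    nx, ny, nz = v.shape
    nodes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = v[i, j, k]
                if c <= threshold:
                    continue
                ok = True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            if (di, dj, dk) == (0, 0, 0):
                                continue
                            if c <= v[(i + di) % nx, (j + dj) % ny, (k + dk) % nz]:
                                ok = False
                if ok:
                    nodes.append((i, j, k))
    return set(nodes)


class TestFindPeaks:
    def test_constant_map_has_no_peaks(self):
        grid = MapGrid(cell=CELL, values=np.zeros((4, 4, 4)))
        assert density.find_peaks(grid, 3.0) == []

    def test_single_spike(self):
        values = np.zeros((6, 6, 6))
        values[2, 3, 4] = 8.0
        grid = MapGrid(cell=CELL, values=values)
        peaks = density.find_peaks(grid, 5.0)
        assert len(peaks) == 1
        assert peaks[0].height_sigma == pytest.approx(8.0)
        np.testing.assert_allclose(peaks[0].position_frac, (2 / 6, 3 / 6, 4 / 6))

    def test_merge_radius_controls_blob_fusion(self):
        # two Gaussian blobs 6 A apart in a 12 A cell
        n = 24
        ax = np.arange(n) / n * 12.0
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")

        def blob(cx):
            d2 = (xx - cx) ** 2 + (yy - 6.0) ** 2 + (zz - 6.0) ** 2
            return np.exp(-d2 / 0.8)

        grid = density.sigma_scale(MapGrid(cell=CELL, values=blob(3.0) + blob(9.0)))
        two = density.find_peaks(grid, 1.0, merge_radius=2.0)
        one = density.find_peaks(grid, 1.0, merge_radius=8.0)
        assert len(two) == 2
        assert len(one) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("sign", ["positive", "negative"])
    def test_equals_exhaustive_scan(self, seed, sign):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 17, size=3))
        values = rng.normal(size=shape)
        grid = MapGrid(cell=CELL, values=values)
        threshold = 1.0
        expected = brute_force_peak_nodes(values, threshold, sign)
        peaks = density.find_peaks(grid, threshold, sign=sign, merge_radius=0.0)
        got = {
            tuple(int(round(f * d)) % d for f, d in zip(p.position_frac, shape))
            for p in peaks
        }
        assert got == expected

    def test_threshold_must_be_positive(self):
        grid = MapGrid(cell=CELL, values=np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            density.find_peaks(grid, 0.0)


class TestRFactor:
    def test_identity_and_scale_invariance(self):
        f = np.array([10.0, 25.0, 3.0])
        assert density.r_factor(f, f)["r"] == pytest.approx(0.0)
        out = density.r_factor(2 * f, f)
        assert out["scale_k"] == pytest.approx(2.0)
        assert out["r"] == pytest.approx(0.0)

    def test_three_term_hand_computation(self):
        # k = (10*10 + 20*20 + 30*60)/(10^2+20^2+60^2) = 2300/4100 = 23/41
        # R = (|10-230/41| + |20-460/41| + |30-1380/41|)/60 = 690/2460 = 23/82
        out = density.r_factor([10.0, 20.0, 30.0], [10.0, 20.0, 60.0])
        assert out["scale_k"] == pytest.approx(float(Fraction(23, 41)), rel=1e-12)
        assert out["r"] == pytest.approx(float(Fraction(23, 82)), rel=1e-12)

    def test_work_free_split_hand_computation(self):
        # k = 4600/7800 = 23/39; R_work = 960/2340 = 16/39; R_free = 280/1560 = 7/39
        f_obs = np.array([10.0, 20.0, 30.0, 40.0])
        f_calc = np.array([10.0, 20.0, 30.0, 80.0])
        out = density.r_factor(f_obs, f_calc, free_flag=np.array([0, 0, 0, 1]))
        assert out["scale_k"] == pytest.approx(float(Fraction(23, 39)), rel=1e-12)
        assert out["r_work"] == pytest.approx(float(Fraction(16, 39)), rel=1e-12)
        assert out["r_free"] == pytest.approx(float(Fraction(7, 39)), rel=1e-12)

    def test_removing_an_atom_strictly_increases_r(self):
        """Omitting any atom from the model raises R against full-model data."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            spec = synthetic_data.ToyCrystalSpec(
                n_protein_atoms=10, n_waters=2, seed=100 + trial,
                cell=(14.0, 14.0, 14.0, 90.0, 90.0, 90.0),
            )
            st, _ = synthetic_data.make_toy_crystal(spec)
            full = density.calc_structure_factors(st, d_min=2.5)
            f_obs = np.abs(full.coeffs)
            drop = int(rng.integers(len(st.atoms)))
            reduced = Structure(
                atoms=[a for i, a in enumerate(st.atoms) if i != drop],
                cell=st.cell, metadata=st.metadata,
            )
            part = density.calc_structure_factors(reduced, d_min=2.5)
            r = density.r_factor(f_obs, np.abs(part.coeffs))["r"]
            assert r > 0.0


def synthetic_peak(structure, pos, height):
    frac = (np.linalg.inv(structure.orth_matrix) @ np.asarray(pos)) % 1.0
    return Peak(position_frac=tuple(frac), position_orth=tuple(pos), height_sigma=height)


class TestCandidateWaters:
    def setup_method(self):
        self.structure = Structure(
            atoms=[atom(6.0, 6.0, 6.0, "O", serial=1)], cell=CELL
        )

    def test_peak_with_partner_in_range_accepted(self):
        peak = synthetic_peak(self.structure, (6.0, 6.0, 8.8), 4.0)  # O at 2.8 A
        cands = density.place_candidate_waters([peak], self.structure)
        assert len(cands) == 1
        assert cands[0].partner_distance == pytest.approx(2.8, abs=1e-6)

    def test_partner_beyond_range_rejected(self):
        peak = synthetic_peak(self.structure, (6.0, 6.0, 9.5), 4.0)  # 3.5 A
        assert density.place_candidate_waters([peak], self.structure) == []

    def test_low_peak_rejected_regardless_of_partner(self):
        peak = synthetic_peak(self.structure, (6.0, 6.0, 8.8), 3.0)
        assert density.place_candidate_waters([peak], self.structure) == []

    def test_clash_rejected(self):
        peak = synthetic_peak(self.structure, (6.0, 6.0, 6.8), 6.0)  # 0.8 A from O
        assert density.place_candidate_waters([peak], self.structure) == []

    def test_partner_found_through_periodic_image(self):
        # peak at z=2.2 and O at z=11.5: direct distance 9.3, image distance 2.7
        st = Structure(atoms=[atom(6.0, 6.0, 11.5, "O")], cell=CELL)
        peak = synthetic_peak(st, (6.0, 6.0, 2.2), 4.0)
        cands = density.place_candidate_waters([peak], st)
        assert len(cands) == 1
        assert cands[0].partner_distance == pytest.approx(2.7, abs=1e-6)

    def test_empty_input(self):
        assert density.place_candidate_waters([], self.structure) == []


class TestWaterRecovery:
    def test_noise_free_deletion_recovers_all_waters(self, noise_free_deletion):
        full, trunc, truth, refl = noise_free_deletion
        calc = density.calc_structure_factors(trunc, 1.8)
        refl.coeffs = calc.coeffs
        fofc = density.sigma_scale(density.synthesize_map(refl, "fo_fc"))
        peaks = density.find_peaks(fofc, 3.5)
        cands = density.place_candidate_waters(peaks, trunc)
        recovered = 0
        for t in truth.deleted_water_positions:
            d = min(periodic_distance(full, c.position, t) for c in cands)
            if d <= 0.5:
                recovered += 1
        assert recovered >= 9  # >= 90% of the 10 deleted waters
        for c in cands:
            d = min(periodic_distance(full, c.position, t) for t in truth.deleted_water_positions)
            assert d <= 3.2  # no spurious candidates far from truth

    def test_find_waters_2fofc_threshold_and_occupied_sites(self, noise_free_deletion):
        full, trunc, truth, refl = noise_free_deletion
        calc = density.calc_structure_factors(trunc, 1.8)
        refl.coeffs = calc.coeffs
        two = density.sigma_scale(density.synthesize_map(refl, "two_fo_fc"))
        cands = density.find_waters_2fofc(two, trunc, threshold_sigma=1.4)
        # deleted waters appear in the 2Fo-Fc map too; existing atoms are occupied
        assert len(cands) >= 8
        for c in cands:
            d = min(
                periodic_distance(full, c.position, a.position) for a in trunc.atoms
            )
            assert d >= 2.2


class TestFlagUnsupportedWaters:
    def _maps_with_value_at(self, structure, water_pos, diff_value, two_value):
        n = 12
        diff = np.zeros((n, n, n))
        two = np.full((n, n, n), 2.0)
        frac = (np.linalg.inv(structure.orth_matrix) @ np.asarray(water_pos)) % 1.0
        idx = tuple((np.round(frac * n).astype(int)) % n)
        diff[idx] = diff_value
        two[idx] = two_value
        return MapGrid(cell=structure.cell, values=diff), MapGrid(cell=structure.cell, values=two)

    def test_negative_density_flag(self):
        pos = (3.0, 3.0, 3.0)
        st = Structure(atoms=[atom(*pos, "O", water=True, serial=9, resid=101)], cell=CELL)
        fofc, two = self._maps_with_value_at(st, pos, -3.5, 2.0)
        flags = density.flag_unsupported_waters(st, fofc, two)
        assert flags[0].flags == {"negative_density"}
        assert flags[0].diff_value_sigma == pytest.approx(-3.5)

    def test_default_adp_flag(self):
        pos = (3.0, 3.0, 3.0)
        st = Structure(
            atoms=[atom(*pos, "O", water=True, b=30.00, serial=9, resid=101)], cell=CELL
        )
        fofc, two = self._maps_with_value_at(st, pos, 0.0, 2.0)
        flags = density.flag_unsupported_waters(st, fofc, two)
        assert flags[0].flags == {"default_adp"}

    def test_protein_overlap_flag(self):
        st = Structure(
            atoms=[
                atom(3.0, 3.0, 3.0, "N", serial=1),
                atom(3.0, 3.0, 4.0, "O", water=True, serial=2, resid=101),
            ],
            cell=CELL,
        )
        fofc, two = self._maps_with_value_at(st, (3.0, 3.0, 4.0), 0.0, 2.0)
        flags = density.flag_unsupported_waters(st, fofc, two)
        assert "protein_overlap" in flags[0].flags

    def test_zero_occupancy_with_refined_adp(self):
        pos = (3.0, 3.0, 3.0)
        st = Structure(
            atoms=[atom(*pos, "O", water=True, occ=0.0, b=47.2, serial=9, resid=101)],
            cell=CELL,
        )
        fofc, two = self._maps_with_value_at(st, pos, 0.0, 2.0)
        flags = density.flag_unsupported_waters(st, fofc, two)
        assert "zero_occupancy_with_refined_adp" in flags[0].flags

    def test_no_positive_support_flag(self):
        pos = (3.0, 3.0, 3.0)
        st = Structure(atoms=[atom(*pos, "O", water=True, serial=9, resid=101)], cell=CELL)
        fofc, two = self._maps_with_value_at(st, pos, 0.0, 0.2)
        flags = density.flag_unsupported_waters(st, fofc, two)
        assert "no_positive_support" in flags[0].flags

    def test_cell_mismatch_is_error(self):
        pos = (3.0, 3.0, 3.0)
        st = Structure(atoms=[atom(*pos, "O", water=True, serial=9, resid=101)], cell=CELL)
        fofc, two = self._maps_with_value_at(st, pos, 0.0, 2.0)
        other = MapGrid(cell=(15.0, 12.0, 12.0, 90.0, 90.0, 90.0), values=fofc.values)
        with pytest.raises(ValueError, match="cell"):
            density.flag_unsupported_waters(st, other, two)
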