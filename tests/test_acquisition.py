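"""k-space transforms, assembly schemes, correction factor, acquisition order."""

import numpy as np
import pytest

from dualtr import (
    acquisition_order,
    apply_correction,
    assemble_interleaved,
    assemble_reordered,
    assemble_single,
    assemble_zero_filled,
    estimate_correction_factor,
    forward_kspace,
    ghost_ratio_curve,
    make_uniform_flip_map,
    reconstruct,
    simulate_image_pair,
    steady_state_signals,
)


def _uniform_kspaces(params, theta=90.0, n=64):
    fm = make_uniform_flip_map(n=n, theta_deg=theta)
    pair = simulate_image_pair(fm, params)
    return fm, forward_kspace(pair.img_strong), forward_kspace(pair.img_weak)


class TestFourierTransforms:
    def test_constant_image_is_a_pure_dc_spike(self):
        k = forward_kspace(np.ones((16, 16)))
        dc = k.data[8, 8]
        assert dc == pytest.approx(16.0)
        off = k.data.copy()
        off[8, 8] = 0
        assert np.abs(off).max() < 1e-12

    def test_parseval_and_round_trip(self, rng):
        img = rng.random((32, 32))
        k = forward_kspace(img)
        assert np.sum(np.abs(k.data) ** 2) == pytest.approx(np.sum(img**2), rel=1e-12)
        np.testing.assert_allclose(reconstruct(k), np.abs(img), atol=1e-12)

    def test_matches_brute_force_centered_dft(self, rng):
        # O(N^4) direct evaluation of the centered unitary transform
        n = 8
        img = rng.random((n, n))
        k = forward_kspace(img)
        y, x = np.indices((n, n))
        oracle = np.empty((n, n), dtype=complex)
        for i in range(n):
            for j in range(n):
                phase = ((i - n // 2) * (y - n // 2) + (j - n // 2) * (x - n // 2)) / n
                oracle[i, j] = np.sum(img * np.exp(-2j * np.pi * phase)) / n
        np.testing.assert_allclose(k.data, oracle, atol=1e-10)

    def test_rejects_non_square_input(self):
        with pytest.raises(ValueError, match="square"):
            forward_kspace(np.ones((8, 12)))


class TestInterleavedAssembly:
    def test_identical_sources_reconstruct_the_strong_image(self, params):
        fm, ks, _ = _uniform_kspaces(params)
        a = assemble_interleaved(ks, ks)
        np.testing.assert_allclose(reconstruct(a.kspace),
                                   reconstruct(ks), atol=1e-13)

    def test_line_bookkeeping(self, params):
        _, ks, kw = _uniform_kspaces(params)
        a = assemble_interleaved(ks, kw)
        n = ks.n
        assert a.weak_lines.sum() == n // 2
        assert not a.weak_lines[n // 2]  # DC line keeps the strong signal
        ky = np.arange(n) - n // 2
        assert np.array_equal(a.weak_lines, ky % 2 != 0)

    def test_uniform_phantom_ghost_matches_the_closed_form(self, params):
        # interleaving two scaled copies of one image splits it into a main
        # lobe (S1+S2)/2 and a half-FOV ghost (S1-S2)/2
        fm, ks, kw = _uniform_kspaces(params, theta=90.0)
        img = reconstruct(assemble_interleaved(ks, kw).kspace)
        sp = steady_state_signals(90.0, params)
        expected = 100.0 * (sp.s_strong - sp.s_weak) / (sp.s_strong + sp.s_weak)
        curve = ghost_ratio_curve(img, fm)
        np.testing.assert_allclose(curve.value_pct, expected, rtol=1e-10)

    def test_every_row_comes_from_exactly_one_source(self, params):
        _, ks, kw = _uniform_kspaces(params)
        a = assemble_interleaved(ks, kw)
        for row in range(ks.n):
            source = kw if a.weak_lines[row] else ks
            np.testing.assert_array_equal(a.kspace.data[row], source.data[row])


class TestReorderedAssembly:
    def test_weak_lines_fill_the_outer_quarters_for_n64(self, params):
        _, ks, kw = _uniform_kspaces(params, n=64)
        a = assemble_reordered(ks, kw)
        weak_ky = set(np.flatnonzero(a.weak_lines) - 32)
        assert weak_ky == set(range(-32, -16)) | set(range(16, 32))
        assert not a.weak_lines[32]  # DC stays strong

    def test_inverted_reordering_swaps_the_roles(self, params):
        _, ks, kw = _uniform_kspaces(params, n=64)
        a = assemble_reordered(ks, kw)
        b = assemble_reordered(ks, kw, inverted=True)
        assert np.array_equal(b.weak_lines, ~a.weak_lines)

    def test_central_half_is_bitwise_the_strong_kspace(self, params):
        _, ks, kw = _uniform_kspaces(params)
        a = assemble_reordered(ks, kw)
        n = ks.n
        np.testing.assert_array_equal(a.kspace.data[n // 4:3 * n // 4],
                                      ks.data[n // 4:3 * n // 4])

    def test_identical_sources_reconstruct_identically_across_schemes(self, params):
        fm, ks, _ = _uniform_kspaces(params)
        ref = reconstruct(ks)
        for a in (assemble_interleaved(ks, ks), assemble_reordered(ks, ks),
                  assemble_reordered(ks, ks, inverted=True)):
            np.testing.assert_allclose(reconstruct(a.kspace), ref, atol=1e-13)


class TestZeroFilledAssembly:
    def test_energy_never_exceeds_the_source(self, params):
        _, ks, _ = _uniform_kspaces(params)
        a = assemble_zero_filled(ks)
        assert np.sum(np.abs(a.kspace.data) ** 2) <= np.sum(np.abs(ks.data) ** 2)

    def test_outer_rows_are_zero_and_center_is_preserved(self, params):
        _, ks, _ = _uniform_kspaces(params)
        a = assemble_zero_filled(ks)
        n = ks.n
        assert np.all(a.kspace.data[:n // 4] == 0)
        assert np.all(a.kspace.data[3 * n // 4:] == 0)
        np.testing.assert_array_equal(a.kspace.data[n // 4:3 * n // 4],
                                      ks.data[n // 4:3 * n // 4])


class TestCorrectionFactor:
    def test_identical_kspaces_give_unit_factor(self, params):
        _, ks, _ = _uniform_kspaces(params)
        for strategy in ("center_ratio", "l1_ratio", "masked_pointwise_mean"):
            assert estimate_correction_factor(ks, ks, strategy) == pytest.approx(1.0)

    def test_uniform_phantom_factor_is_the_signal_ratio(self, params):
        _, ks, kw = _uniform_kspaces(params, theta=60.0)
        sp = steady_state_signals(60.0, params)
        expected = sp.s_weak / sp.s_strong
        for strategy in ("center_ratio", "l1_ratio"):
            assert estimate_correction_factor(ks, kw, strategy) == pytest.approx(
                expected, rel=1e-10)

    def test_unit_factor_leaves_the_assembly_unchanged(self, params):
        _, ks, kw = _uniform_kspaces(params)
        a = assemble_interleaved(ks, kw)
        b = apply_correction(a, 1.0)
        np.testing.assert_array_equal(b.kspace.data, a.kspace.data)
        assert b.correction_applied == 1.0

    def test_exact_factor_nulls_the_uniform_phantom_ghost(self, params):
        fm, ks, kw = _uniform_kspaces(params, theta=90.0)
        factor = estimate_correction_factor(ks, kw)
        img = reconstruct(apply_correction(assemble_interleaved(ks, kw), factor).kspace)
        curve = ghost_ratio_curve(img, fm)
        assert curve.value_pct.max() < 1e-10

    def test_rejects_degenerate_inputs(self, params):
        _, ks, kw = _uniform_kspaces(params)
        with pytest.raises(ValueError, match="positive"):
            apply_correction(assemble_interleaved(ks, kw), 0.0)
        with pytest.raises(ValueError, match="weak lines"):
            apply_correction(assemble_single(ks, "strong"), 0.9)
        zero = forward_kspace(np.zeros((ks.n, ks.n)))
        with pytest.raises(ValueError, match="degenerate"):
            estimate_correction_factor(zero, kw)


class TestAcquisitionOrder:
    def test_n64_order_begins_as_published(self):
        assert acquisition_order(64)[:4] == [-32, -16, -31, -15]

    def test_is_a_permutation_of_all_phase_encode_indices(self):
        for n in (8, 64, 128):
            order = acquisition_order(n)
            assert sorted(order) == list(range(-n // 2, n // 2))

    def test_center_line_is_acquired_in_the_middle(self):
        for n in (8, 64, 128):
            assert acquisition_order(n).index(0) == n // 2

    def test_weak_and_strong_blocks_each_ascend(self):
        n = 64
        order = acquisition_order(n)
        weak = [ky for ky in order if ky < -n // 4 or ky >= n // 4]
        strong = [ky for ky in order if -n // 4 <= ky < n // 4]
        assert weak == sorted(weak) and strong == sorted(strong)

    def test_rejects_sizes_not_divisible_by_four(self):
        with pytest.raises(ValueError):
            acquisition_order(30)
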