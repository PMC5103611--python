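import numpy as np
import pytest

from radtrap.core import VolumeGrid
from radtrap import radiomics as R


def vol2d(slice2d, spacing=(1.0, 1.0, 3.0)):
    """Wrap a 2D array as a 2-slice volume (features are in-plane)."""
    arr = np.stack([np.asarray(slice2d, dtype=float)] * 2, axis=-1)
    return VolumeGrid(arr, spacing)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation paths)


def oracle_local_stats(sl, i, j, w):
    h = w // 2
    win = sl[max(0, i - h):i + h + 1, max(0, j - h):j + h + 1].ravel()
    return (win.mean(), win.std(), np.median(win), win.max() - win.min())


def oracle_glcm(sl, mask_pt, w, levels, offsets):
    """Per-voxel symmetric co-occurrence matrix by exhaustive pair listing."""
    i, j = mask_pt
    h = w // 2
    i0, i1 = max(0, i - h), min(sl.shape[0], i + h + 1)
    j0, j1 = max(0, j - h), min(sl.shape[1], j + h + 1)
    win = sl[i0:i1, j0:j1]
    lo, hi = win.min(), win.max()

    def q(v):
        if hi - lo <= 1e-12:
            return 0
        return min(int((v - lo) / (hi - lo) * levels), levels - 1)

    p = np.zeros((levels, levels))
    for a in range(i0, i1):
        for b in range(j0, j1):
            for da, db in offsets:
                a2, b2 = a + da, b + db
                if i0 <= a2 < i1 and j0 <= b2 < j1:
                    p[q(sl[a, b]), q(sl[a2, b2])] += 1
                    p[q(sl[a2, b2]), q(sl[a, b])] += 1
    if p.sum() == 0:
        return None
    return p / p.sum()


def oracle_haralick_stats(p):
    """The 13 statistics straight from their definitions."""
    g = p.shape[0]
    ii, jj = np.indices(p.shape)
    px, py = p.sum(1), p.sum(0)
    mx, my = (np.arange(g) * px).sum(), (np.arange(g) * py).sum()
    sx = np.sqrt(((np.arange(g) - mx) ** 2 * px).sum())
    sy = np.sqrt(((np.arange(g) - my) ** 2 * py).sum())
    nz = p > 1e-15
    ent = -(p[nz] * np.log(p[nz])).sum()
    psum = np.zeros(2 * g - 1)
    pdiff = np.zeros(g)
    for a in range(g):
        for b in range(g):
            psum[a + b] += p[a, b]
            pdiff[abs(a - b)] += p[a, b]
    sa = (np.arange(2 * g - 1) * psum).sum()
    se = -(psum[psum > 1e-15] * np.log(psum[psum > 1e-15])).sum()
    sv = ((np.arange(2 * g - 1) - sa) ** 2 * psum).sum()
    da = (np.arange(g) * pdiff).sum()
    de = -(pdiff[pdiff > 1e-15] * np.log(pdiff[pdiff > 1e-15])).sum()
    dv = ((np.arange(g) - da) ** 2 * pdiff).sum()
    corr = ((ii * jj * p).sum() - mx * my) / (sx * sy) if sx * sy > 1e-12 else 0.0
    hx = -(px[px > 1e-15] * np.log(px[px > 1e-15])).sum()
    hy = -(py[py > 1e-15] * np.log(py[py > 1e-15])).sum()
    pxy = np.outer(px, py)
    nzj = pxy > 1e-15
    hxy1 = -(p[nzj] * np.log(pxy[nzj])).sum()
    hxy2 = -(pxy[nzj] * np.log(pxy[nzj])).sum()
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 1e-12 else 0.0
    arg = 1 - np.exp(-2 * (hxy2 - ent))
    imc2 = np.sqrt(arg) if arg > 0 else 0.0
    return {
        "energy": (p ** 2).sum(), "contrast": ((ii - jj) ** 2 * p).sum(),
        "correlation": corr, "variance": ((ii - mx) ** 2 * p).sum(),
        "homogeneity": (p / (1 + (ii - jj) ** 2)).sum(),
        "sum_average": sa, "sum_variance": sv, "sum_entropy": se, "entropy": ent,
        "diff_variance": dv, "diff_entropy": de, "imc1": imc1, "imc2": imc2,
    }


def oracle_laws(sl, pair, w):
    kern = np.outer(R.LAWS_VECTORS[pair[:2]], R.LAWS_VECTORS[pair[2:]])
    h = 2
    padded = np.pad(sl, h, mode="symmetric")  # half-sample symmetric edges
    resp = np.zeros_like(sl)
    for i in range(sl.shape[0]):
        for j in range(sl.shape[1]):
            resp[i, j] = (padded[i:i + 5, j:j + 5] * kern).sum()
    resp = np.abs(resp)
    hw = w // 2
    out = np.zeros_like(sl)
    for i in range(sl.shape[0]):
        for j in range(sl.shape[1]):
            win = resp[max(0, i - hw):i + hw + 1, max(0, j - hw):j + hw + 1]
            out[i, j] = win.mean()
    return out


# ---------------------------------------------------------------------------


class TestRegistry:
    def test_bank_size(self):
        reg = R.default_registry()
        assert len(reg) == 308
        assert sum(d.sequence == "T2w" for d in reg) == 154
        assert sum(d.sequence == "ADC" for d in reg) == 154

    def test_selected_panel_names_present(self):
        names = [d.name for d in R.default_registry()]
        # the clinically reported panel: intensities, std, Sobel x, Haralick
        # correlation/energy/differential entropy, Laws R5E5/L5W5/W5L5
        assert "T2w.intensity" in names and "ADC.intensity" in names
        assert any(n.startswith("T2w.firstorder.std") for n in names)
        assert "T2w.sobel.gx" in names
        for stat in ("correlation", "energy", "diff_entropy"):
            assert any(f".haralick.{stat}." in n for n in names)
        for pair in ("R5E5", "L5W5", "W5L5"):
            assert any(f".laws.{pair}." in n for n in names), pair

    def test_names_unique_and_windows_odd(self):
        reg = R.default_registry()
        names = [d.name for d in reg]
        assert len(set(names)) == len(names)
        assert all(d.window % 2 == 1 for d in reg if d.window is not None)


class TestLocalStatistics:
    def test_constant_volume(self):
        vol = vol2d(np.full((10, 12), 3.5))
        maps = R.local_statistics(vol, None, 3)
        np.testing.assert_allclose(maps["mean"], 3.5)
        np.testing.assert_allclose(maps["std"], 0.0, atol=1e-12)
        np.testing.assert_allclose(maps["median"], 3.5)
        np.testing.assert_allclose(maps["range"], 0.0)

    def test_matches_bruteforce_window3(self, rng):
        sl = rng.normal(size=(12, 11))
        vol = vol2d(sl)
        maps = R.local_statistics(vol, None, 3)
        for i in range(12):
            for j in range(11):
                m, s, med, rg = oracle_local_stats(sl, i, j, 3)
                assert maps["mean"][i, j, 0] == pytest.approx(m, abs=1e-9)
                assert maps["std"][i, j, 0] == pytest.approx(s, abs=1e-9)
                assert maps["median"][i, j, 0] == pytest.approx(med, abs=1e-9)
                assert maps["range"][i, j, 0] == pytest.approx(rg, abs=1e-9)

    def test_parameter_errors(self, small_volume):
        with pytest.raises(ValueError):
            R.local_statistics(small_volume, None, 4)
        with pytest.raises(ValueError):
            R.local_statistics(small_volume, None, 99)


class TestSobel:
    def test_flat_field_is_zero(self):
        maps = R.sobel_gradients(vol2d(np.full((8, 8), 2.0)))
        for m in maps.values():
            np.testing.assert_allclose(m, 0.0, atol=1e-12)

    def test_ramp_gradient_is_8s(self):
        s = 2.5
        sl = s * np.arange(10)[:, None] * np.ones((10, 10))
        maps = R.sobel_gradients(vol2d(sl))
        interior = maps["gx"][1:-1, 1:-1, 0]
        np.testing.assert_allclose(interior, 8 * s, atol=1e-9)
        np.testing.assert_allclose(maps["gy"][1:-1, 1:-1, 0], 0.0, atol=1e-9)

    def test_rotation_swaps_axes(self, rng):
        sl = rng.normal(size=(9, 9))
        a = R.sobel_gradients(vol2d(sl))
        b = R.sobel_gradients(vol2d(np.rot90(sl)))
        # |gx| of the rotated image equals rotated |gy| of the original
        np.testing.assert_allclose(np.abs(b["gx"][..., 0]),
                                   np.rot90(np.abs(a["gy"][..., 0])), atol=1e-9)

    def test_too_small_slice_rejected(self):
        from radtrap.core import GeometryError

        with pytest.raises(GeometryError):
            R.sobel_gradients(VolumeGrid(np.zeros((2, 8, 4)), (1, 1, 1)))


class TestHaralick:
    def test_constant_window_degenerate_matrix(self):
        vol = vol2d(np.full((9, 9), 4.0))
        maps = R.haralick_features(vol, None, 5)
        c = (4, 4, 0)
        assert maps["energy"][c] == pytest.approx(1.0)
        assert maps["entropy"][c] == pytest.approx(0.0, abs=1e-12)
        assert maps["contrast"][c] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_contrast_matches_pair_counting(self):
        sl = np.indices((8, 8)).sum(0) % 2 * 10.0
        vol = vol2d(sl)
        offsets = [(1, 0)]
        maps = R.haralick_features(vol, None, 7, gray_levels=2, offsets=offsets)
        p = oracle_glcm(sl, (3, 3), 7, 2, offsets)
        exp = oracle_haralick_stats(p)
        assert maps["contrast"][3, 3, 0] == pytest.approx(exp["contrast"], abs=1e-9)
        assert maps["energy"][3, 3, 0] == pytest.approx(exp["energy"], abs=1e-9)

    def test_correlation_closed_form_on_coupled_pairs(self):
        # vertical stripes: every horizontal neighbour pair is (0,1) or (1,0)
        sl = (np.arange(8)[None, :] % 2 * 5.0) * np.ones((8, 1))
        vol = vol2d(sl)
        maps = R.haralick_features(vol, None, 5, gray_levels=2, offsets=[(0, 1)])
        # closed form: p = [[0, .5], [.5, 0]] -> corr = (E[ij]-mu^2)/var = -1
        assert maps["correlation"][4, 4, 0] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        sl = rng.integers(0, 50, size=(11, 10)).astype(float)
        vol = vol2d(sl)
        offsets = R.default_offsets(1)
        maps = R.haralick_features(vol, None, 5, gray_levels=8, offsets=offsets)
        for pt in [(2, 2), (5, 5), (8, 7), (0, 0)]:
            p = oracle_glcm(sl, pt, 5, 8, offsets)
            exp = oracle_haralick_stats(p)
            for stat in R.HARALICK_STATS:
                assert maps[stat][pt[0], pt[1], 0] == pytest.approx(exp[stat], abs=1e-9), stat

    def test_affine_intensity_remap_invariance(self, rng):
        sl = rng.normal(size=(10, 10))
        a = R.haralick_features(vol2d(sl), None, 5)
        b = R.haralick_features(vol2d(2.0 * sl + 10.0), None, 5)
        for stat in R.HARALICK_STATS:
            np.testing.assert_allclose(a[stat], b[stat], atol=1e-9)

    def test_parameter_errors(self, small_volume):
        with pytest.raises(ValueError):
            R.haralick_features(small_volume, None, 5, gray_levels=1)
        with pytest.raises(ValueError):
            R.haralick_features(small_volume, None, 4)


class TestGabor:
    def test_constant_slice_gives_zero_response(self):
        vol = vol2d(np.full((20, 20), 100.0))
        maps = R.gabor_bank(vol)
        for m in maps.values():
            assert np.abs(m).max() < 1e-6

    def test_grating_maximizes_matching_filter(self):
        theta, freq = 60, 0.18
        n = 48
        ii, jj = np.indices((n, n))
        phase = 2 * np.pi * freq * (ii * np.cos(np.deg2rad(theta)) + jj * np.sin(np.deg2rad(theta)))
        vol = vol2d(np.sin(phase))
        maps = R.gabor_bank(vol)
        center = (n // 2, n // 2, 0)
        best = max(maps, key=lambda k: maps[k][center])
        assert best == (theta, freq)

    def test_rotated_grating_moves_peak_orientation(self):
        freq = 0.18
        n = 48
        ii, jj = np.indices((n, n))

        def peak(theta):
            phase = 2 * np.pi * freq * (ii * np.cos(np.deg2rad(theta)) + jj * np.sin(np.deg2rad(theta)))
            maps = R.gabor_bank(vol2d(np.sin(phase)))
            return max(maps, key=lambda k: maps[k][n // 2, n // 2, 0])[0]

        assert peak(30) == 30
        assert peak(120) == 120

    def test_frequency_out_of_range_rejected(self, small_volume):
        with pytest.raises(ValueError):
            R.gabor_bank(small_volume, frequencies=(0.7,))


class TestLaws:
    def test_zero_sum_kernel_on_flat_field(self):
        vol = vol2d(np.full((12, 12), 9.0))
        for pair in ("E5L5", "S5S5", "R5E5", "W5L5"):
            np.testing.assert_allclose(R.laws_energy(vol, pair, 5), 0.0, atol=1e-9)

    def test_transpose_pair_relation(self, rng):
        sl = rng.normal(size=(14, 14)) + 3.0 * (np.arange(14)[None, :] % 3 == 0)
        a = R.laws_energy(vol2d(sl), "L5W5", 5)[..., 0]
        b = R.laws_energy(vol2d(sl.T), "W5L5", 5)[..., 0]
        assert not np.allclose(R.laws_energy(vol2d(sl), "W5L5", 5)[..., 0], a)
        np.testing.assert_allclose(b, a.T, atol=1e-9)

    def test_matches_bruteforce_convolution(self, rng):
        sl = rng.normal(size=(12, 13))
        for pair in ("R5E5", "L5W5", "E5S5"):
            got = R.laws_energy(vol2d(sl), pair, 5)[..., 0]
            np.testing.assert_allclose(got, oracle_laws(sl, pair, 5), atol=1e-9)

    def test_unknown_kernel_rejected(self, small_volume):
        with pytest.raises(ValueError):
            R.laws_energy(small_volume, "X5Y5", 5)


class TestExtractFeatures:
    @pytest.fixture(scope="class")
    def extraction(self, mpmri_case):
        t2w, adc, st = mpmri_case
        fm = R.extract_features(t2w, adc, st["pz"], labels=st["lesion"])
        return fm, t2w, adc, st

    def test_shape_and_columns(self, extraction):
        fm, t2w, _, st = extraction
        assert fm.values.shape == (st["pz"].sum(), 308)
        assert fm.columns == [d.name for d in R.default_registry()]
        assert fm.labels is not None and fm.labels.sum() == st["lesion"].sum()

    def test_intensity_column_is_identity(self, extraction):
        fm, t2w, adc, st = extraction
        np.testing.assert_array_equal(fm.column("T2w.intensity"), t2w.values[st["pz"]])
        np.testing.assert_array_equal(fm.column("ADC.intensity"), adc.values[st["pz"]])

    def test_columns_match_standalone_family_ops(self, extraction):
        fm, t2w, adc, st = extraction
        mask = st["pz"]
        idx = tuple(np.argwhere(mask).T)
        stats = R.local_statistics(t2w, mask, 5)
        np.testing.assert_allclose(fm.column("T2w.firstorder.std.w5"), stats["std"][idx])
        har = R.haralick_features(adc, mask, 7, offsets=R.default_offsets(2))
        np.testing.assert_allclose(fm.column("ADC.haralick.correlation.w7.d2"),
                                   har["correlation"][idx])
        laws = R.laws_energy(t2w, "R5E5", 5, mask)
        np.testing.assert_allclose(fm.column("T2w.laws.R5E5.w5"), laws[idx])

    def test_grid_mismatch_rejected(self, mpmri_case):
        from radtrap.core import GeometryError

        t2w, adc, st = mpmri_case
        bad = VolumeGrid(adc.values, adc.spacing, (5.0, 0.0, 0.0), "ADC")
        with pytest.raises(GeometryError):
            R.extract_features(t2w, bad, st["pz"])

    def test_translation_equivariance(self, rng):
        # interior mask: windows and the widest Gabor kernels must not touch
        # the slice edges, where reflection breaks shift equivariance
        vals = rng.normal(100, 10, size=(48, 48, 4))
        t2w = VolumeGrid(vals, (1, 1, 3))
        adc = VolumeGrid(vals * 2, (1, 1, 3), modality="ADC")
        mask = np.zeros(t2w.shape, bool)
        mask[22:26, 22:26, 1:3] = True
        fm = R.extract_features(t2w, adc, mask)
        shifted_mask = np.roll(mask, (2, 1), axis=(0, 1))
        fm2 = R.extract_features(t2w.with_values(np.roll(vals, (2, 1), axis=(0, 1))),
                                 adc.with_values(np.roll(vals * 2, (2, 1), axis=(0, 1))),
                                 shifted_mask)
        np.testing.assert_allclose(fm2.values, fm.values, atol=1e-6)

    def test_table_round_trip(self, extraction, tmp_path):
        fm = extraction[0]
        fm.write_table(tmp_path / "features.tsv")
        header = (tmp_path / "features.tsv").read_text().splitlines()[0].split("\t")
        assert header[:4] == ["i", "j", "k", "label"]
        assert len(header) == 4 + 308
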