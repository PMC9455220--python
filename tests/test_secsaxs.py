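import numpy as np
import pytest

from biosas import secsaxs as ss
from biosas import synthgen as sg
from biosas.sas_model import ScatteringCurve


@pytest.fixture(scope="module")
def sec_chrom(default_sec):
    partials, truth, info = default_sec
    return ss.assemble_chromatogram(partials), truth, info


@pytest.fixture(scope="module")
def sec_buffer(sec_chrom):
    chrom, truth, info = sec_chrom
    svd = ss.svd_rank(chrom)
    buf, ids = ss.select_buffer(chrom, svd.first_singular_vector, 0.30)
    return svd, buf, ids


def make_buffer_only(n_frames=500, seed=0, **kw):
    q = np.linspace(0.05, 4.0, 200)
    buf = ScatteringCurve(q, np.full_like(q, 50.0))
    partials, truth = sg.make_sec_run([], np.zeros((0, n_frames)), buf,
                                      n_frames, seed=seed, **kw)
    return ss.assemble_chromatogram(partials), truth


class TestAssemble:
    def test_full_run_is_1000_rows(self, sec_chrom):
        chrom, truth, _ = sec_chrom
        assert chrom.M.shape == (1000, 200)
        assert chrom.frame_mask.all()

    def test_missing_block_masked_not_dropped(self):
        partials, truth, _ = sg.default_sec_run(seed=7, missing_blocks=[3])
        assert len(partials) == 9
        chrom = ss.assemble_chromatogram(partials)
        assert chrom.n_frames == 1000
        assert not chrom.frame_mask[300:400].any()
        assert chrom.frame_mask[:300].all() and chrom.frame_mask[400:].all()

    def test_single_file_identity(self, default_sec):
        partials, *_ = default_sec
        chrom = ss.assemble_chromatogram([partials[0]])
        np.testing.assert_array_equal(chrom.M, partials[0].I)

    def test_inconsistent_grids_rejected(self, default_sec):
        partials, *_ = default_sec
        other = sg.PartialChromatogram(
            partials[1].frame_ids, partials[1].q * 1.01,
            partials[1].I, partials[1].sigma)
        with pytest.raises(ValueError):
            ss.assemble_chromatogram([partials[0], other])


class TestSvdRank:
    def test_rank_one_for_near_rank_one_matrix(self):
        rng = np.random.default_rng(0)
        profile = sg.gaussian_profile(300, 150, 40) + 0.5
        spectrum = sg.sphere_intensity(np.linspace(0.05, 4, 120), 3.0, 100.0) + 5
        M = np.outer(profile, spectrum)
        M += 1e-6 * M.max() * rng.standard_normal(M.shape)
        chrom = ss.Chromatogram(np.clip(M, 0, None), np.ones_like(M),
                                np.linspace(0.05, 4, 120), np.ones(300, bool))
        assert ss.svd_rank(chrom).rank == 1

    def test_default_run_rank_three(self, sec_buffer):
        svd, *_ = sec_buffer
        assert svd.rank == 3

    def test_noise_matrix_rank_at_most_one(self):
        # i.i.d. noise carries no retained structure beyond (at most) its mean
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            M = rng.standard_normal((200, 100))
            chrom = ss.Chromatogram(M, np.ones_like(M), np.linspace(0.1, 4, 100),
                                    np.ones(200, bool))
            counts.append(ss.svd_rank(chrom).rank)
        assert np.median(counts) <= 1

    def test_first_vector_sign_mean_positive(self, sec_buffer):
        svd, *_ = sec_buffer
        assert svd.first_singular_vector.mean() > 0

    def test_masked_rows_excluded(self):
        chrom, _ = make_buffer_only(200, seed=1)
        spiked = chrom.M.copy()
        spiked[50] *= 100.0      # huge outlier row ...
        mask = chrom.frame_mask.copy()
        mask[50] = False         # ... but masked away
        a = ss.svd_rank(ss.Chromatogram(spiked, chrom.sigma, chrom.q, mask))
        keep = mask.copy()
        expected = np.linalg.svd(chrom.M[keep], compute_uv=False)
        np.testing.assert_allclose(a.singular_values, expected)
        assert a.rank == 1


class TestNmf:
    def test_rank_one_exact_factorization(self):
        profile = sg.gaussian_profile(200, 100, 30) + 0.2
        spectrum = sg.sphere_intensity(np.linspace(0.05, 4, 80), 3.0, 100.0) + 5
        M = np.outer(profile, spectrum)
        chrom = ss.Chromatogram(M, np.ones_like(M), np.linspace(0.05, 4, 80),
                                np.ones(200, bool))
        r = ss.nmf_components(chrom, 1)
        recon = r.nmf_chromatograms @ r.nmf_spectra
        assert np.linalg.norm(recon - M) / np.linalg.norm(M) < 1e-6

    def test_component_spectra_recovered(self, sec_chrom):
        chrom, truth, _ = sec_chrom
        r = ss.nmf_components(chrom, 3)
        for spectrum in truth.extras["spectra"]:
            sims = [spectrum @ h / (np.linalg.norm(spectrum) * np.linalg.norm(h))
                    for h in r.nmf_spectra if np.linalg.norm(h) > 0]
            assert max(sims) > 0.98

    def test_deterministic(self, sec_chrom):
        chrom, *_ = sec_chrom
        a = ss.nmf_components(chrom, 2)
        b = ss.nmf_components(chrom, 2)
        np.testing.assert_array_equal(a.nmf_spectra, b.nmf_spectra)
        np.testing.assert_array_equal(a.nmf_chromatograms, b.nmf_chromatograms)

    def test_spectra_normalized_to_unit_max(self, sec_chrom):
        chrom, *_ = sec_chrom
        r = ss.nmf_components(chrom, 2)
        np.testing.assert_allclose(r.nmf_spectra.max(axis=1), 1.0)

    def test_invalid_k_rejected(self, sec_chrom):
        chrom, *_ = sec_chrom
        with pytest.raises(ValueError):
            ss.nmf_components(chrom, 0)
        with pytest.raises(ValueError):
            ss.nmf_components(chrom, 10**6)


class TestSelectBuffer:
    def test_exactly_thirty_percent_selected(self, sec_buffer):
        *_, ids = sec_buffer
        assert len(ids) == 300

    def test_no_peak_frames_selected(self, sec_chrom, sec_buffer):
        chrom, truth, info = sec_chrom
        *_, ids = sec_buffer
        prof = truth.extras["profiles"]
        peak_frames = np.flatnonzero((prof[0] > 0.1) | (prof[1] > 0.1))
        assert np.intersect1d(ids, peak_frames).size == 0

    def test_buffer_only_run_recovers_truth(self):
        chrom, truth = make_buffer_only(1000, seed=3)
        svd = ss.svd_rank(chrom)
        buf, ids = ss.select_buffer(chrom, svd.first_singular_vector, 0.30)
        chi2 = np.mean(((buf.I - 50.0) / buf.sigma) ** 2)
        assert chi2 <= 1.5

    def test_too_few_frames_rejected(self):
        chrom, _ = make_buffer_only(4, seed=0)
        with pytest.raises(ValueError):
            ss.select_buffer(chrom, chrom.M[0], 0.30)


class TestFindFractions:
    def _subtracted(self, chrom, buf):
        return ss.Chromatogram(
            chrom.M - buf.I[None, :],
            np.sqrt(chrom.sigma**2 + buf.sigma[None, :] ** 2),
            chrom.q, chrom.frame_mask)

    def test_single_peak_found_at_center(self):
        q = np.linspace(0.05, 4.0, 200)
        comp = ScatteringCurve(q, sg.sphere_intensity(q, 3.0, 100.0))
        buf = ScatteringCurve(q, np.full_like(q, 50.0))
        prof = sg.gaussian_profile(1000, 500, 30)[None, :]
        partials, _ = sg.make_sec_run([comp], prof, buf, 1000, seed=11)
        chrom = ss.assemble_chromatogram(partials)
        svd = ss.svd_rank(chrom)
        bufavg, _ = ss.select_buffer(chrom, svd.first_singular_vector, 0.30)
        regions = ss.find_fractions(self._subtracted(chrom, bufavg))
        assert len(regions) == 1
        lo, hi = regions[0]
        assert abs((lo + hi) / 2 - 500) <= 10

    def test_two_separated_peaks_disjoint(self, sec_chrom, sec_buffer):
        chrom, truth, info = sec_chrom
        _, buf, _ = sec_buffer
        regions = ss.find_fractions(self._subtracted(chrom, buf))
        assert len(regions) == 2
        assert regions[0][1] <= regions[1][0]

    def test_flat_noise_no_fractions(self):
        counts = []
        for seed in range(20):
            chrom, _ = make_buffer_only(500, seed=seed)
            svd = ss.svd_rank(chrom)
            buf, _ = ss.select_buffer(chrom, svd.first_singular_vector, 0.30)
            counts.append(len(ss.find_fractions(self._subtracted(chrom, buf))))
        assert np.median(counts) == 0


class TestAnalyzeFraction:
    def test_component_rg_recovered(self, sec_chrom, sec_buffer):
        chrom, truth, info = sec_chrom
        _, buf, _ = sec_buffer
        regions = ss.find_fractions(ss.Chromatogram(
            chrom.M - buf.I[None, :],
            np.sqrt(chrom.sigma**2 + buf.sigma[None, :] ** 2),
            chrom.q, chrom.frame_mask))
        assert len(regions) == len(info["components"])
        for region, comp in zip(regions, info["components"]):
            res = ss.analyze_fraction(chrom, region, buf)
            assert res.guinier is not None
            assert res.guinier.Rg == pytest.approx(comp["Rg"], rel=0.05)

    def test_pure_buffer_fraction_fails_gracefully(self):
        chrom, _ = make_buffer_only(300, seed=5)
        svd = ss.svd_rank(chrom)
        buf, _ = ss.select_buffer(chrom, svd.first_singular_vector, 0.30)
        res = ss.analyze_fraction(chrom, (100, 150), buf)
        assert res.guinier is None
        assert "error" in res.status

    def test_fully_masked_range(self):
        partials, truth, _ = sg.default_sec_run(seed=7, missing_blocks=[3])
        chrom = ss.assemble_chromatogram(partials)
        svd = ss.svd_rank(chrom)
        buf, _ = ss.select_buffer(chrom, svd.first_singular_vector, 0.30)
        res = ss.analyze_fraction(chrom, (300, 400), buf)
        assert "error" in res.status

    def test_out_of_bounds_rejected(self, sec_chrom, sec_buffer):
        chrom, *_ = sec_chrom
        _, buf, _ = sec_buffer
        with pytest.raises(ValueError):
            ss.analyze_fraction(chrom, (900, 1200), buf)
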