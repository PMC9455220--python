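import hashlib
import json

import h5py
import numpy as np
import pytest

from biosas import pipelines as pl
from biosas import synthgen as sg
from biosas.sas_model import (FrameStack, JobDescription, write_frames_h5)

TRUTH = sg.GroundTruth(model="sphere", Rg=np.sqrt(0.6) * 3, I0=100.0,
                       Dmax=6.0, buffer_level=50.0)
TRUTH_RG = np.sqrt(0.6) * 3


def flat_buffer(q):
    return np.full_like(q, 50.0)


@pytest.fixture(scope="module")
def geometry():
    return sg.default_geometry((128, 128))


def write_stack(path, stack):
    write_frames_h5(stack, path)
    return str(path)


class TestMultiframe:
    def test_identical_noiseless_frames_all_accepted(self, geometry, tmp_path):
        stack = sg.make_frames(TRUTH, geometry, 5, np.ones(5), noise=False)
        p = write_stack(tmp_path / "f.h5", stack)
        job = JobDescription(pipeline="multiframe", input_paths=[p],
                             output_path=str(tmp_path / "out.h5"))
        res = pl.run_multiframe(job)
        assert res.status == "success"
        assert res.payload["accepted"] == list(range(5))
        # final curve equals any per-frame curve (identical frames)
        with h5py.File(res.output_path) as h5:
            final = h5["entry/average_integration/curve/I"][()]
            frame0 = h5["entry/integration/curves/frame_0000/I"][()]
        np.testing.assert_allclose(final, frame0, rtol=1e-12)

    def test_damaged_tenth_frame_discarded(self, geometry, tmp_path):
        stack = sg.make_frames(TRUTH, geometry, 10, np.ones(10), seed=5)
        frames = np.array(stack.frames)
        rng = np.random.default_rng(99)
        qmap = geometry.q_map()
        model = 1.2 * (50.0 + sg.sphere_intensity(qmap, 3.0, 100.0))
        frames[9] = rng.poisson(model)
        damaged = FrameStack(frames.astype(np.int64), stack.monitor, geometry)
        p = write_stack(tmp_path / "d.h5", damaged)
        job = JobDescription(pipeline="multiframe", input_paths=[p],
                             output_path=str(tmp_path / "out.h5"))
        res = pl.run_multiframe(job)
        assert res.payload["accepted"] == list(range(9))

    def test_replay_is_bit_identical(self, geometry, tmp_path):
        stack = sg.make_frames(TRUTH, geometry, 4, np.ones(4), seed=8)
        p = write_stack(tmp_path / "f.h5", stack)
        out = tmp_path / "out.h5"
        job = JobDescription(pipeline="multiframe", input_paths=[p],
                             output_path=str(out))
        job_file = tmp_path / "job.json"
        job_file.write_text(job.to_json())
        hashes = []
        for _ in range(2):
            pl.replay_job(job_file)
            hashes.append(hashlib.sha256(out.read_bytes()).hexdigest())
        assert hashes[0] == hashes[1]

    def test_output_embeds_job_json(self, geometry, tmp_path):
        stack = sg.make_frames(TRUTH, geometry, 2, np.ones(2), seed=0)
        p = write_stack(tmp_path / "f.h5", stack)
        job = JobDescription(pipeline="multiframe", input_paths=[p],
                             output_path=str(tmp_path / "out.h5"))
        pl.run_multiframe(job)
        with h5py.File(job.output_path) as h5:
            stored = json.loads(h5["entry/provenance/job_json"][()])
        assert stored["pipeline"] == "multiframe"


class TestSubtract:
    def _run(self, tmp_path, geometry, buffer_scales=(1.0, 1.0), sample_level=None):
        mon = np.full(10, 5.0)
        sample_model = sample_level if sample_level is not None else (
            lambda q: 50.0 + sg.sphere_intensity(q, 3.0, 100.0))
        sample = sg.make_frames(TRUTH, geometry, 10, mon, seed=21,
                                model_intensity=sample_model)
        paths = [write_stack(tmp_path / "sample.h5", sample)]
        for i, scale in enumerate(buffer_scales):
            buf = sg.make_frames(
                TRUTH, geometry, 10, mon, seed=30 + i,
                model_intensity=lambda q, s=scale: s * flat_buffer(q))
            paths.append(write_stack(tmp_path / f"buf{i}.h5", buf))
        job = JobDescription(pipeline="subtract", input_paths=paths,
                             output_path=str(tmp_path / "sub.h5"))
        return pl.run_subtract(job)

    def test_recovers_rg_within_three_percent(self, geometry, tmp_path):
        res = self._run(tmp_path, geometry)
        assert res.status == "success"
        assert res.payload["guinier"].Rg == pytest.approx(TRUTH_RG, rel=0.03)
        assert res.payload["buffers_used"] == [0, 1]

    def test_inconsistent_buffer_excluded_with_warning(self, geometry, tmp_path):
        res = self._run(tmp_path, geometry, buffer_scales=(1.0, 1.3))
        assert len(res.payload["buffers_used"]) == 1
        with h5py.File(res.output_path) as h5:
            assert "warning" in h5["entry/buffer_comparison"].attrs

    def test_sample_equal_buffer_degrades_gracefully(self, geometry, tmp_path):
        res = self._run(tmp_path, geometry,
                        sample_level=lambda q: flat_buffer(q))
        assert res.status == "partial"
        stages = dict(res.stages)
        assert stages["integration"] == "ok"
        assert stages["guinier"].startswith("error")
        # subtracted curve consistent with zero
        curve = res.payload["curve"]
        z = curve.I / curve.sigma
        assert np.mean(z**2) < 2.0


@pytest.fixture(scope="module")
def partial_paths(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("hplc")
    partials, truth, info = sg.default_sec_run(seed=7)
    paths = []
    for i, part in enumerate(partials):
        p = tmp / f"partial_{i:03d}.h5"
        sg.write_partial_h5(part, p)
        paths.append(str(p))
    return paths, info


class TestHplc:
    def test_end_to_end_two_fractions(self, partial_paths, tmp_path):
        paths, info = partial_paths
        job = JobDescription(pipeline="hplc", input_paths=paths,
                             output_path=str(tmp_path / "run.h5"))
        res = pl.run_hplc(job)
        assert res.status == "success"
        assert res.payload["svd"].rank == 3
        assert len(res.payload["ranges"]) == 2
        for frac, comp in zip(res.payload["fractions"], info["components"]):
            assert frac.guinier.Rg == pytest.approx(comp["Rg"], rel=0.05)
        with h5py.File(res.output_path) as h5:
            assert "entry/fractions/fraction_000/guinier" in h5
            assert "entry/fractions/fraction_000/bift" in h5
            assert "entry/fractions/fraction_000/invariants" in h5
            assert "entry/fractions/fraction_000/kratky" in h5
            assert "entry/fractions/fraction_000/curve" in h5

    def test_missing_block_handled(self, tmp_path):
        partials, truth, info = sg.default_sec_run(seed=7, missing_blocks=[0])
        paths = []
        for i, part in enumerate(partials):
            p = tmp_path / f"p{i}.h5"
            sg.write_partial_h5(part, p)
            paths.append(str(p))
        job = JobDescription(pipeline="hplc", input_paths=paths,
                             parameters={"n_frames": 1000},
                             output_path=str(tmp_path / "run.h5"))
        res = pl.run_hplc(job)
        assert res.status == "success"
        with h5py.File(res.output_path) as h5:
            mask = h5["entry/chromatogram/frame_mask"][()]
        assert mask[:100].sum() == 0 and mask[100:].all()

    def test_single_partial_file(self, partial_paths, tmp_path):
        paths, _ = partial_paths
        job = JobDescription(pipeline="hplc", input_paths=paths[:1],
                             output_path=str(tmp_path / "one.h5"))
        res = pl.run_hplc(job)
        assert res.status == "success"

    def test_all_inputs_missing_fails(self, tmp_path):
        job = JobDescription(pipeline="hplc",
                             input_paths=[str(tmp_path / "nope.h5")],
                             output_path=str(tmp_path / "run.h5"))
        res = pl.run_hplc(job)
        assert res.status == "failed"


class TestDispatch:
    def test_unknown_pipeline_rejected(self):
        job = JobDescription(pipeline="teleport")
        with pytest.raises(ValueError, match="teleport"):
            pl.run_job(job)

    def test_schema_version_checked_on_replay(self, tmp_path):
        job = JobDescription(pipeline="multiframe")
        text = job.to_json().replace('"1.0"', '"0.1"')
        p = tmp_path / "job.json"
        p.write_text(text)
        with pytest.raises(ValueError, match="0.1"):
            pl.replay_job(p)

    def test_batch_preserves_order(self, tmp_path):
        geometry = sg.default_geometry((64, 64))
        results = []
        for k in range(3):
            stack = sg.make_frames(TRUTH, geometry, 2, np.ones(2), seed=k)
            fp = write_stack(tmp_path / f"f{k}.h5", stack)
            job = JobDescription(pipeline="multiframe", input_paths=[fp],
                                 output_path=str(tmp_path / f"o{k}.h5"))
            jp = tmp_path / f"j{k}.json"
            jp.write_text(job.to_json())
            results.append(pl.replay_job(jp))
        assert [r.status for r in results] == ["success"] * 3
        assert [r.output_path for r in results] == [
            str(tmp_path / f"o{k}.h5") for k in range(3)]
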