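"""The end-to-end transformer, its scikit-learn contract, and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from sklearn import clone
from sklearn.exceptions import NotFittedError

from ppgfid import Dataset, FiducialFeatureExtractor, extract_dataset, make_benchmark
from ppgfid.cli import main as cli_main
from ppgfid.features import FEATURE_COLUMNS
from ppgfid.signal_io import OUTPUT_FILENAMES


@pytest.fixture(scope="module")
def small_benchmark():
    return make_benchmark(8, seed=11)


class TestSklearnContract:
    def test_get_set_params_roundtrip(self):
        est = FiducialFeatureExtractor(fh=7.0)
        params = est.get_params()
        assert params["fh"] == 7.0
        est2 = clone(est)
        assert est2.get_params() == params

    def test_requires_fit_before_transform(self, small_benchmark):
        ds, _ = small_benchmark
        with pytest.raises(NotFittedError):
            FiducialFeatureExtractor().transform(ds.to_matrix())

    def test_transform_shape_and_dtype(self, small_benchmark):
        ds, _ = small_benchmark
        X = ds.to_matrix()
        out = FiducialFeatureExtractor().fit(X).transform(X)
        assert out.shape == (len(ds), 30)
        assert out.dtype == float

    def test_feature_matrix_matches_feature_table(self, small_benchmark):
        ds, _ = small_benchmark
        X = ds.to_matrix()
        est = FiducialFeatureExtractor().fit(X)
        res = est.extract(ds)
        np.testing.assert_array_equal(
            est.transform(X), res.feature_table.to_numpy(), strict=False
        )

    def test_invalid_filter_params_raise_on_fit(self):
        from ppgfid.errors import ParameterError

        with pytest.raises(ParameterError):
            FiducialFeatureExtractor(fl=8.0, fh=0.4).fit(np.zeros((2, 100)))


class TestPipeline:
    def test_successful_subjects_have_finite_core_features(self, small_benchmark):
        ds, _ = small_benchmark
        res = extract_dataset(ds)
        assert res.n_ok >= 6
        for r in res.results:
            if not r.ok:
                continue
            row = res.feature_table.loc[r.subject_id]
            for col in ("O", "S", "N", "D", "S_t", "a_t", "e_t"):
                assert np.isfinite(row[col])

    def test_failed_subject_keeps_nan_row(self):
        rng = np.random.default_rng(0)
        from ppgfid.signal_io import SubjectRecord

        flatline = SubjectRecord("FLAT", np.zeros(2100) + 1e-12 * rng.normal(size=2100))
        ds = Dataset(records=[flatline])
        res = extract_dataset(ds)
        assert not res.results[0].ok
        assert res.feature_table.loc["FLAT"].isna().all()

    def test_sqi_gating_excludes_low_quality(self, small_benchmark):
        ds, _ = small_benchmark
        sqi = {sid: (0.05 if i == 0 else 0.9) for i, sid in enumerate(ds.subject_ids)}
        res = extract_dataset(Dataset(records=ds.records, sqi=sqi))
        assert not res.results[0].ok
        assert "below threshold" in res.results[0].message

    def test_bundle_row_alignment_and_shapes(self, small_benchmark):
        ds, _ = small_benchmark
        res = extract_dataset(ds)
        bundle = res.to_bundle()
        bundle.validate()
        n = len(ds)
        assert bundle.ppg_segments.shape == (n, 1200)
        assert bundle.apg_segments.shape == (n, 1200)
        assert list(bundle.id_min1_min2["subject_id"]) == ds.subject_ids
        assert list(bundle.feature_table.index) == ds.subject_ids

    def test_segment_zero_padding_is_trailing(self, small_benchmark):
        ds, _ = small_benchmark
        res = extract_dataset(ds)
        bundle = res.to_bundle()
        for r, seg in zip(res.results, bundle.ppg_segments):
            if not r.ok:
                continue
            T = min(r.min2 - r.min1 + 1, 1200)
            assert np.all(seg[T:] == 0.0)
            assert np.any(seg[:T] != 0.0)


class TestCli:
    def _simulate(self, runner, tmp_path, n=6, seed=3):
        out = tmp_path / "sim"
        res = runner.invoke(
            cli_main,
            ["simulate", "-n", str(n), "--seed", str(seed), "--outdir", str(out)],
        )
        assert res.exit_code == 0, res.output
        return out

    def test_simulate_extract_evaluate_chain(self, tmp_path):
        runner = CliRunner()
        sim = self._simulate(runner, tmp_path)
        extdir = tmp_path / "ext"
        res = runner.invoke(
            cli_main,
            ["extract", str(sim / "ppg.csv"), "--sqi-csv", str(sim / "sqi.csv"),
             "--outdir", str(extdir)],
        )
        assert res.exit_code in (0, 1), res.output
        for name in OUTPUT_FILENAMES:
            assert (extdir / name).exists()
        feats = pd.read_csv(extdir / "PPG_features.csv")
        assert list(feats.columns) == ["subject_id"] + list(FEATURE_COLUMNS)
        res = runner.invoke(
            cli_main,
            ["evaluate", str(extdir), str(sim / "reference.csv"), "--tol", "0.01"],
        )
        assert res.exit_code == 0, res.output
        assert "pooled" in res.output

    def test_simulate_deterministic_across_runs(self, tmp_path):
        runner = CliRunner()
        a = self._simulate(runner, tmp_path / "a", seed=9)
        b = self._simulate(runner, tmp_path / "b", seed=9)
        for name in ("ppg.csv", "sqi.csv", "reference.csv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_bad_filter_band_exits_2(self, tmp_path):
        runner = CliRunner()
        sim = self._simulate(runner, tmp_path)
        res = runner.invoke(
            cli_main,
            ["extract", str(sim / "ppg.csv"), "--fl", "8", "--fh", "0.4",
             "--outdir", str(tmp_path / "x")],
        )
        assert res.exit_code == 2

    def test_bad_case_mix_exits_2(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", "-n", "3", "--case-mix", "0.9", "0.9", "0.1",
             "--outdir", str(tmp_path / "y")],
        )
        assert res.exit_code == 2

    def test_disjoint_ids_exit_2(self, tmp_path):
        runner = CliRunner()
        sim = self._simulate(runner, tmp_path, n=4)
        extdir = tmp_path / "ext"
        runner.invoke(cli_main, ["extract", str(sim / "ppg.csv"), "--outdir", str(extdir)])
        ref = pd.read_csv(sim / "reference.csv")
        ref["subject_id"] = ["Z%d" % i for i in range(len(ref))]
        badref = tmp_path / "badref.csv"
        ref.to_csv(badref, index=False)
        res = runner.invoke(cli_main, ["evaluate", str(extdir), str(badref)])
        assert res.exit_code == 2

    def test_manifest_written_and_stable(self, tmp_path):
        runner = CliRunner()
        sim = self._simulate(runner, tmp_path, seed=5)
        manifest = json.loads((sim / "run_manifest.json").read_text())
        assert manifest["command"] == "simulate"
        assert manifest["config"]["seed"] == 5
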