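"""Synthetic panel generation, file round-trips, and the command line."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from dnflogic import SynthConfig, evaluate_dnf, generate_panel
from dnflogic.cli import main
from dnflogic.io import (align_drug, load_feature_matrix, load_output_table,
                         write_panel)


class TestGenerator:
    def test_reproducible_under_seed(self):
        a = generate_panel(SynthConfig(seed=5))
        b = generate_panel(SynthConfig(seed=5))
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.z, b.z)

    def test_components_follow_planted_model_without_noise(self):
        cfg = SynthConfig(label_noise=0.0, seed=6)
        panel = generate_panel(cfg)
        np.testing.assert_array_equal(
            panel.components, evaluate_dnf(cfg.planted_model, panel.X))

    def test_component_separation_recoverable(self):
        # 4-sd separation: a midpoint cut misassigns ~2*Phi(-2) ~ 4.6%
        panel = generate_panel(SynthConfig(label_noise=0.0, seed=7))
        mid = 0.5 * (panel.config.mu_sensitive + panel.config.mu_resistant)
        assert ((panel.z < mid) == panel.components.astype(bool)).mean() > 0.9

    def test_missing_rate_masks_values(self):
        panel = generate_panel(SynthConfig(missing_rate=0.2, seed=8))
        missing = np.isnan(panel.z).mean()
        assert 0.1 < missing < 0.3
        assert len(panel.measured) == np.isfinite(panel.z).sum()
        ds = panel.to_dataset(b=1.0)
        assert ds.n == len(panel.measured)

    def test_null_config_ignores_features(self):
        cfg = SynthConfig(planted_model=None, sensitive_fraction=0.1, seed=9)
        panel = generate_panel(cfg)
        assert panel.ground_truth is None
        assert 0.03 < panel.components.mean() < 0.2

    def test_invalid_configs_rejected(self):
        from dnflogic import DNFModel, Literal
        with pytest.raises(ValueError, match="beyond n_features"):
            SynthConfig(n_features=2, planted_model=DNFModel([[Literal(5)]]))
        with pytest.raises(ValueError, match="below"):
            SynthConfig(mu_sensitive=5.0, mu_resistant=0.0)


class TestFileRoundTrip:
    def test_panel_written_and_reloaded_exactly(self, tmp_path):
        panel = generate_panel(SynthConfig(n_samples=40, missing_rate=0.1, seed=10))
        fpath, rpath = tmp_path / "feat.csv", tmp_path / "resp.csv"
        write_panel(panel, fpath, rpath, drug="drugA")
        X, ids, names = load_feature_matrix(fpath)
        np.testing.assert_array_equal(X, panel.X)
        assert ids == panel.sample_ids and names == panel.feature_names
        out = load_output_table(rpath, "drugA")
        Xs, z, lo, hi, kept = align_drug(X, ids, names, out, "drugA")
        assert len(kept) == len(panel.measured)
        np.testing.assert_allclose(z, panel.z[panel.measured])

    def test_non_binary_cell_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,g1,g2\ns1,0,1\ns2,2,0\n")
        with pytest.raises(ValueError, match="g1.*s2"):
            load_feature_matrix(p)

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("sample_id,g1\ns1,0\ns1,1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_feature_matrix(p)

    def test_unknown_drug_lists_available(self, tmp_path):
        p = tmp_path / "resp.csv"
        p.write_text("sample_id,drug,value\ns1,drugA,1.0\n")
        with pytest.raises(ValueError, match="available"):
            load_output_table(p, "drugB")


@pytest.fixture(scope="module")
def cli_panel(tmp_path_factory):
    """A small simulated panel written through the CLI itself."""
    d = tmp_path_factory.mktemp("cli")
    fpath, rpath = d / "features.csv", d / "response.csv"
    runner = CliRunner()
    res = runner.invoke(main, [
        "simulate", "--n-samples", "150", "--seed", "4",
        "--features-out", str(fpath), "--response-out", str(rpath)])
    assert res.exit_code == 0, res.output
    return d, fpath, rpath


class TestCli:
    def test_binarize_reports_threshold(self, cli_panel):
        d, fpath, rpath = cli_panel
        out = d / "thresholds.json"
        res = CliRunner().invoke(main, ["binarize", "--response", str(rpath),
                                        "--out", str(out)])
        assert res.exit_code == 0, res.output
        payload = json.loads(out.read_text())
        assert "synthetic_drug" in payload
        b = payload["synthetic_drug"]["b"]
        assert -1.0 < b < 3.0   # between the generator's component means

    def test_cv_deterministic_and_significant(self, cli_panel):
        d, fpath, rpath = cli_panel
        outs = []
        for i in (1, 2):
            out = d / f"cv{i}.json"
            res = CliRunner().invoke(main, [
                "cv", "--features", str(fpath), "--response", str(rpath),
                "--drug", "synthetic_drug", "--folds", "5",
                "--n-perm", "2000", "--seed", "0", "--out", str(out)])
            assert res.exit_code == 0, res.output
            outs.append(out.read_text())
        assert outs[0] == outs[1]
        payload = json.loads(outs[0])
        assert payload["significance"]["p"] < 0.01

    def test_infeasible_constrained_fit_exits_3(self, cli_panel):
        d, fpath, rpath = cli_panel
        out = d / "fit.json"
        res = CliRunner().invoke(main, [
            "fit", "--features", str(fpath), "--response", str(rpath),
            "--drug", "synthetic_drug", "-K", "1", "-M", "1",
            "--tpr-min", "1.0", "--tnr-min", "1.0", "--out", str(out)])
        assert res.exit_code == 3
        assert json.loads(out.read_text())["status"] == "infeasible"

    def test_missing_drug_exits_4(self, cli_panel):
        d, fpath, rpath = cli_panel
        res = CliRunner().invoke(main, [
            "fit", "--features", str(fpath), "--response", str(rpath),
            "--drug", "nope", "-K", "1", "-M", "1", "--out", str(d / "x.json")])
        assert res.exit_code == 4

    def test_bad_flags_exit_2(self):
        res = CliRunner().invoke(main, ["fit", "--bogus"])
        assert res.exit_code == 2
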