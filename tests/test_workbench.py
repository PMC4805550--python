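import json

import h5py
import numpy as np
import pytest
from click.testing import CliRunner

import gcmap
from gcmap.cli import main as cli_main
from gcmap.io import DEFAULT_CONFIG, config_hash, load_config
from gcmap.pipeline import analyze_bundle, run_pipeline, simulate_bundle

SMALL_CONFIG = {
    "population": {"n_cells": 8, "n_repeats": 1},
    "noise": {"sampling_khz": 5.0},
}


def small_config():
    cfg = load_config()
    cfg["population"].update(SMALL_CONFIG["population"])
    cfg["noise"].update(SMALL_CONFIG["noise"])
    cfg["analysis"]["n_clusters"] = 2
    return cfg


class TestBundleRoundTrip:
    def test_traces_roundtrip_losslessly(self, tmp_path):
        bundle = simulate_bundle(small_config(), seed=3)
        path = gcmap.write_bundle(bundle, tmp_path / "b.h5")
        back = gcmap.read_bundle(path)
        assert back.n_cells == bundle.n_cells
        for cid, rec in bundle.cells.items():
            np.testing.assert_array_equal(back.cells[cid].samples, rec.samples)
            assert back.cells[cid].dt_ms == rec.dt_ms
            np.testing.assert_array_equal(
                back.cells[cid].truth.counts, rec.truth.counts
            )

    def test_many_cell_count_roundtrip(self, tmp_path):
        cfg = small_config()
        cfg["population"]["n_cells"] = 49
        cfg["noise"]["duration_ms"] = 500.0
        cfg["noise"]["stim_onset_ms"] = 100.0
        cfg["noise"]["sampling_khz"] = 1.0
        bundle = simulate_bundle(cfg, seed=4)
        path = gcmap.write_bundle(bundle, tmp_path / "b49.h5")
        assert gcmap.read_bundle(path).n_cells == 49

    def test_missing_dt_attribute_names_it(self, tmp_path):
        bundle = simulate_bundle(small_config(), seed=5)
        path = gcmap.write_bundle(bundle, tmp_path / "bad.h5")
        with h5py.File(path, "a") as f:
            cid = next(iter(f["cells"]))
            del f[f"cells/{cid}/traces"].attrs["dt_ms"]
        with pytest.raises(gcmap.SchemaError, match="dt_ms"):
            gcmap.read_bundle(path)

    def test_unknown_schema_version_reported(self, tmp_path):
        bundle = simulate_bundle(small_config(), seed=6)
        path = gcmap.write_bundle(bundle, tmp_path / "v9.h5")
        with h5py.File(path, "a") as f:
            f.attrs["schema_version"] = "9"
        with pytest.raises(gcmap.SchemaError, match="found '9'"):
            gcmap.read_bundle(path)

    def test_derived_tables_roundtrip(self, tmp_path):
        bundle = run_pipeline(small_config(), seed=7)
        path = gcmap.write_bundle(bundle, tmp_path / "full.h5")
        back = gcmap.read_bundle(path)
        assert set(back.derived) == set(bundle.derived)
        for name, df in bundle.derived.items():
            got = back.derived[name]
            assert list(got.columns) == list(df.columns)
            assert len(got) == len(df)


class TestPipeline:
    def test_end_to_end_emits_all_products(self):
        bundle = run_pipeline(small_config(), seed=1)
        assert {"sites", "patterns", "groups", "correlation", "clusters"} <= set(
            bundle.derived
        )
        assert bundle.provenance["n_clusters"] >= 2
        assert bundle.provenance["config_hash"] == config_hash(small_config())

    def test_threshold_monotonicity(self):
        cfg = small_config()
        bundle = simulate_bundle(cfg, seed=2)
        n_sig = {}
        for thr in (3.09, 10.0):
            cfg["analysis"]["threshold"] = thr
            b = analyze_bundle(
                gcmap.ExperimentBundle(cells=bundle.cells), cfg
            )
            n_sig[thr] = (b.derived["sites"]["label"] == "significant").sum()
        assert n_sig[10.0] <= n_sig[3.09]

    def test_same_seed_byte_identical_products(self):
        a = run_pipeline(small_config(), seed=9)
        b = run_pipeline(small_config(), seed=9)
        for name in a.derived:
            assert a.derived[name].to_csv(index=False) == b.derived[name].to_csv(
                index=False
            )


class TestConfig:
    def test_defaults_carry_core_parameters(self):
        cfg = load_config()
        assert cfg["geometry"]["step_um"] == 41.5
        assert cfg["analysis"]["threshold"] == 3.09

    def test_yaml_override_deep_merges(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("analysis:\n  threshold: 5.0\n")
        cfg = load_config(p)
        assert cfg["analysis"]["threshold"] == 5.0
        assert cfg["analysis"]["kernel_halfwidth_um"] == 18.0

    def test_unknown_section_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("nonsense:\n  x: 1\n")
        with pytest.raises(ValueError, match="unknown config sections"):
            load_config(p)

    def test_config_hash_stable_and_sensitive(self):
        a = load_config()
        b = load_config()
        assert config_hash(a) == config_hash(b)
        b["analysis"]["threshold"] = 4.0
        assert config_hash(a) != config_hash(b)


class TestCli:
    def test_subcommands_compose_to_pipeline_result(self, tmp_path):
        cfg_path = tmp_path / "c.yaml"
        cfg_path.write_text(
            "population:\n  n_cells: 8\n  n_repeats: 1\n"
            "noise:\n  sampling_khz: 5.0\n"
            "analysis:\n  n_clusters: 2\n"
        )
        bundle_path = tmp_path / "b.h5"
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            [
                "simulate",
                "--config",
                str(cfg_path),
                "--seed",
                "11",
                "-o",
                str(bundle_path),
            ],
        )
        assert res.exit_code == 0, res.output
        for cmd in ("map", "correlate"):
            res = runner.invoke(cli_main, [cmd, str(bundle_path), "--config", str(cfg_path)])
            assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, ["cluster", str(bundle_path), "--k", "2"])
        assert res.exit_code == 0, res.output
        outdir = tmp_path / "out"
        res = runner.invoke(cli_main, ["report", str(bundle_path), "-o", str(outdir)])
        assert res.exit_code == 0, res.output

        direct = run_pipeline(small_config(), seed=11)
        stored = gcmap.read_bundle(bundle_path)
        for name in ("sites", "clusters"):
            assert (outdir / f"{name}.csv").exists()
            got = stored.derived[name]
            want = direct.derived[name]
            assert got.to_csv(index=False) == want.to_csv(index=False)

    def test_plasticity_command(self, tmp_path):
        cfg = small_config()
        pre = simulate_bundle(cfg, seed=13)
        post = simulate_bundle(cfg, seed=13)
        p1, p2 = tmp_path / "pre.h5", tmp_path / "post.h5"
        gcmap.write_bundle(pre, p1)
        gcmap.write_bundle(post, p2)
        out = tmp_path / "delta.csv"
        res = CliRunner().invoke(
            cli_main, ["plasticity", str(p1), str(p2), "-o", str(out)]
        )
        assert res.exit_code == 0, res.output
        assert out.exists()


class TestPlotting:
    def test_render_hooks_return_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        from gcmap.plotting import plot_correlation_matrix, plot_map, plot_pattern
        from gcmap.population import CorrelationMatrix

        bundle = run_pipeline(small_config(), seed=15)
        rec = next(iter(bundle.cells.values()))
        m = gcmap.ConnectivityMapper().fit(rec)
        assert plot_pattern(m.pattern_) is not None
        assert plot_map(m.map_) is not None
        long = bundle.derived["correlation"]
        centers = np.unique(long["center_i_um"])
        vals = long["r"].to_numpy().reshape(centers.size, centers.size)
        assert (
            plot_correlation_matrix(
                CorrelationMatrix(vals, centers),
                frame=gcmap.BandCoordinateFrame(),
            )
            is not None
        )
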