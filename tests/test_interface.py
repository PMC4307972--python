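"""I/O round trips, config validation, CLI behaviour, figure emission."""

import json

import numpy as np
import pytest

import spovmclust as s
from spovmclust.cli import cli_run
from spovmclust.io import (
    law_from_config,
    read_config,
    read_dataset,
    read_localization_curve,
    two_region_system_from_config,
    write_config,
    write_dataset,
    write_localization_curve,
)
from spovmclust.model import ConfigurationError
from spovmclust.plotting import plot_curves, plot_isotherms, plot_localization


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------

def test_dataset_round_trip(tmp_path, noiseless_radius_dataset):
    path = tmp_path / "data.csv"
    write_dataset(noiseless_radius_dataset, path)
    back = read_dataset(path)
    assert back == noiseless_radius_dataset


def test_missing_column_named_in_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("radius,concentration,adsorption\n1.0,1.0,0.5\n")
    with pytest.raises(ValueError, match="radius_um"):
        read_dataset(path)


def test_bad_rows_reported_with_line_numbers(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "radius_um,concentration,adsorption\n"
        "1.0,1.0,0.5\n"
        "-1.0,1.0,0.5\n"
    )
    with pytest.raises(ValueError, match=r"line\(s\) \[3\]"):
        read_dataset(path)
    path.write_text(
        "radius_um,concentration,adsorption\n"
        "1.0,1.0,abc\n"
    )
    with pytest.raises(ValueError, match="non-numeric"):
        read_dataset(path)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

def test_config_round_trip_json_and_yaml(tmp_path):
    cfg = {"law.kind": "tension", "law.c1": 0.7, "law.c2": 0.61, "A": 2.0}
    for name in ("c.json", "c.yaml"):
        path = tmp_path / name
        write_config(cfg, path)
        assert read_config(path, schema="simulate") == cfg
    law = law_from_config(cfg)
    assert law.kind == "tension" and law.c2 == 0.61


def test_unknown_config_key_rejected(tmp_path):
    path = tmp_path / "c.json"
    write_config({"law.kind": "tension", "bogus": 1}, path)
    with pytest.raises(ConfigurationError, match="bogus"):
        read_config(path, schema="simulate")


def test_nested_law_block_flattened(tmp_path):
    path = tmp_path / "c.yaml"
    path.write_text("law:\n  kind: curvature\n  c1: 2.67\n  c2: 1.1649\n")
    cfg = read_config(path, schema="simulate")
    assert law_from_config(cfg).c1 == 2.67


def test_localize_config_builds_system(tmp_path):
    path = tmp_path / "loc.json"
    write_config({"delta_b": 0.02, "e_r0": 0.2, "k_max": 10, "K_cap": 200,
                  "Cs_grid": [0.5, 1.0, 1.5]}, path)
    system, grid = two_region_system_from_config(read_config(path, "localize"))
    assert system.k_max == 10 and grid == [0.5, 1.0, 1.5]


def test_localization_curve_round_trip(tmp_path):
    sys_ = s.TwoRegionSystem(delta_b=0.02, e_r0=0.2, k_max=10, K_cap=200)
    curve = s.localization_curve(sys_, [0.5, 1.0, 1.5])
    path = tmp_path / "curve.csv"
    write_localization_curve(curve, path)
    df = read_localization_curve(path)
    np.testing.assert_allclose(df["fraction_1"], curve.fraction_1, rtol=1e-12)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_isotherm_prints_partition_sum(capsys):
    assert cli_run(["isotherm", "--er", "2", "--cs", "1"]) == 0
    assert capsys.readouterr().out.strip() == "1.278131"


def test_cli_isotherm_radius_law(capsys):
    code = cli_run(["isotherm", "--cs", "1", "--law", "tension",
                    "--c1", "0.7", "--c2", "0.61", "--radius", "0.75"])
    assert code == 0
    printed = float(capsys.readouterr().out)
    assert printed == pytest.approx(s.adsorption(1.0, 0.7 + 0.61 * 0.75), abs=1e-6)


def test_cli_clusters_table(capsys):
    assert cli_run(["clusters", "--er", "2", "--cs", "1", "--kmax", "3"]) == 0
    out = capsys.readouterr().out.splitlines()
    assert out[0] == "k,weight"
    assert len(out) == 5  # header + 3 rows + mean-size comment


def test_cli_divergence_is_reported_as_error(capsys):
    assert cli_run(["isotherm", "--er", "0", "--cs", "2"]) == 1
    assert "diverges" in capsys.readouterr().err


def test_cli_unknown_flag_is_usage_error():
    assert cli_run(["isotherm", "--er", "2", "--cs", "1", "--frobnicate"]) == 2


def test_cli_simulate_data_deterministic(tmp_path):
    out1, out2 = tmp_path / "a.csv", tmp_path / "b.csv"
    for out in (out1, out2):
        assert cli_run(["simulate-data", "--seed", "5", "--out", str(out)]) == 0
    assert out1.read_text() == out2.read_text()
    assert json.loads((tmp_path / "a.csv.spec.json").read_text())["seed"] == 5


def test_cli_fit_end_to_end(tmp_path):
    data = tmp_path / "d.csv"
    cfg = tmp_path / "gen.json"
    cfg.write_text(json.dumps({
        "law.kind": "tension", "law.c1": 0.7, "law.c2": 0.61,
        "radii": [0.75, 3.0], "noise_cv": 0.0,
    }))
    assert cli_run(["simulate-data", "--config", str(cfg), "--seed", "1",
                    "--out", str(data)]) == 0
    out = tmp_path / "fit.json"
    assert cli_run(["fit", "--law", "tension", "--data", str(data),
                    "--starts", "6", "--out", str(out)]) == 0
    result = json.loads(out.read_text())
    assert result["converged"] is True
    assert result["c1"] == pytest.approx(0.7, rel=1e-4)


def test_cli_localize(tmp_path):
    cfg = tmp_path / "loc.yaml"
    cfg.write_text(
        "delta_b: 0.02\ne_r0: 0.2\nk_max: 10\nK_cap: 200\n"
        "Cs_grid: [0.5, 1.0, 1.5]\n"
    )
    out = tmp_path / "curve.csv"
    assert cli_run(["localize", "--config", str(cfg), "--out", str(out)]) == 0
    assert len(read_localization_curve(out)) == 3


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def test_plot_isotherms_writes_figure(tmp_path):
    path = tmp_path / "iso.png"
    got = plot_isotherms([0.5, 1.0, 2.0], np.linspace(0.05, 1.5, 20), path)
    assert got is not None and path.exists() and path.stat().st_size > 0


def test_plot_empty_input_warns_and_skips(tmp_path):
    with pytest.warns(UserWarning, match="empty"):
        assert plot_isotherms([], [], tmp_path / "none.png") is None
    with pytest.warns(UserWarning, match="empty"):
        assert plot_localization(None, tmp_path / "none2.png") is None


def test_plot_curves_dispatch(tmp_path):
    sys_ = s.TwoRegionSystem(delta_b=0.0, e_r0=0.2, k_max=10, K_cap=100)
    curve = s.localization_curve(sys_, [0.5, 1.0])
    path = tmp_path / "loc.png"
    assert plot_curves({"curve": curve}, "localization", path) is not None
    with pytest.raises(ValueError, match="style"):
        plot_curves({}, "volcano", tmp_path / "x.png")
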