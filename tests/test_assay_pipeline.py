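"""File I/O round trips, group statistics and end-to-end pipeline runs."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from wormtherm import assay_pipeline as ap
from wormtherm import io as wio
from wormtherm import synthetic_worlds as sw


def small_assay(seed=5):
    cfg, _ = sw.preset("fed")
    cfg = sw.replace(cfg, n_worms=3, assay_duration=120.0, seed=seed)
    trajs, _ = sw.simulate_assay(cfg)
    return trajs


class TestTrajectoryIO:
    def test_round_trip_within_precision(self, tmp_path):
        trajs = small_assay()
        f = tmp_path / "t.csv"
        wio.write_trajectories(trajs, f)
        back = wio.read_trajectories(f)
        assert len(back) == len(trajs)
        for a, b in zip(trajs, back):
            assert a.worm_id == b.worm_id
            assert np.allclose(a.x, b.x, atol=1e-4)
            assert np.allclose(a.y, b.y, atol=1e-4)

    def test_missing_column_schema_error(self, tmp_path):
        trajs = small_assay()
        f = tmp_path / "t.csv"
        wio.write_trajectories(trajs, f)
        df = pd.read_csv(f).drop(columns=["x_mm"])
        f2 = tmp_path / "bad.csv"
        df.to_csv(f2, index=False)
        with pytest.raises(wio.SchemaError, match="x_mm"):
            wio.read_trajectories(f2)

    def test_shuffled_rows_resorted_with_warning(self, tmp_path):
        trajs = small_assay()
        f = tmp_path / "t.csv"
        wio.write_trajectories(trajs, f)
        df = pd.read_csv(f).sample(frac=1.0, random_state=0)
        f2 = tmp_path / "shuffled.csv"
        df.to_csv(f2, index=False)
        with pytest.warns(UserWarning, match="re-sorted"):
            back = wio.read_trajectories(f2)
        for a, b in zip(trajs, back):
            assert np.allclose(a.x, b.x, atol=1e-4)

    def test_duplicate_time_rejected(self, tmp_path):
        f = tmp_path / "t.csv"
        pd.DataFrame(
            {
                "worm_id": ["w"] * 3,
                "frame": [0, 1, 2],
                "time_s": [0.0, 0.0, 1.0],
                "x_mm": [0.0, 0.1, 0.2],
                "y_mm": [0.0, 0.0, 0.0],
            }
        ).to_csv(f, index=False)
        with pytest.raises(wio.SchemaError, match="non-monotone"):
            wio.read_trajectories(f)


class TestTraceIO:
    def test_round_trip(self, tmp_path, awc_ramp):
        params = sw.CalciumSimParams(event_rate_base=0.02, seed=3)
        trace, _ = sw.simulate_calcium(params, awc_ramp)
        f = tmp_path / "c.csv"
        wio.write_traces([trace], f)
        back = wio.read_traces(f)
        assert len(back) == 1
        assert np.allclose(back[0].fluorescence, trace.fluorescence, atol=1e-4)
        assert np.allclose(back[0].temperature, trace.temperature, atol=1e-4)


class TestGroupCompare:
    def make_table(self, groups):
        rows = []
        for gname, (state, values) in groups.items():
            for i, v in enumerate(values):
                rows.append(
                    {
                        "assay_id": f"{gname}_{i}",
                        "group": gname,
                        "feeding_state": state,
                        "statistic": "thermotaxis_bias",
                        "value": v,
                    }
                )
        return ap.make_assay_table(rows)

    def test_identical_groups_null_result(self):
        vals = [0.4, 0.5, 0.45, 0.55]
        t = self.make_table({"a": ("fed", vals), "b": ("fed", vals)})
        (c,) = ap.group_compare(t, "two_group_t")
        assert c.statistic == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == pytest.approx(1.0)

    def test_welch_power_for_unit_effect(self, rng):
        # N(0,1) vs N(1,1), n = 10: power at alpha 0.05 is ~0.56
        hits = 0
        reps = 2000
        for _ in range(reps):
            t = self.make_table(
                {"a": ("fed", rng.normal(0, 1, 10)), "b": ("fed", rng.normal(1, 1, 10))}
            )
            if ap.group_compare(t, "two_group_t")[0].p_value < 0.05:
                hits += 1
        assert 0.5 <= hits / reps <= 0.7

    def test_tukey_familywise_error_controlled(self, rng):
        fwer = 0
        reps = 1000
        for _ in range(reps):
            t = self.make_table(
                {
                    "a": ("fed", rng.normal(0, 1, 8)),
                    "b": ("fed", rng.normal(0, 1, 8)),
                    "c": ("fed", rng.normal(0, 1, 8)),
                }
            )
            results = ap.group_compare(t, "anova_tukey")
            pairwise = [c for c in results if c.kind == "tukey"]
            assert len(pairwise) == 3
            if any(c.p_value < 0.05 for c in pairwise):
                fwer += 1
        assert fwer / reps <= 0.07

    def test_small_group_rejected(self):
        t = self.make_table({"a": ("fed", [0.1]), "b": ("fed", [0.2, 0.3])})
        with pytest.raises(ValueError, match="< 2 assays"):
            ap.group_compare(t, "two_group_t")

    def test_bad_feeding_state_rejected(self):
        with pytest.raises(ValueError, match="feeding_state"):
            ap.make_assay_table(
                [
                    {
                        "assay_id": "x",
                        "group": "a",
                        "feeding_state": "hangry",
                        "statistic": "bias",
                        "value": 0.1,
                    }
                ]
            )


class TestFeedingStateContrast:
    def build(self, cell_means, noise_sd=0.0, n=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (g, s), m in cell_means.items():
            for i in range(n):
                rows.append(
                    {
                        "assay_id": f"{g}_{s}_{i}",
                        "group": g,
                        "feeding_state": s,
                        "statistic": "thermotaxis_bias",
                        "value": m + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                    }
                )
        return ap.make_assay_table(rows)

    def test_no_interaction_zero_effect(self):
        t = self.build(
            {("wt", "fed"): 0.5, ("wt", "starved"): 0.1,
             ("mut", "fed"): 0.7, ("mut", "starved"): 0.3},
            noise_sd=0.05, seed=1,
        )
        c = ap.feeding_state_contrast(t, "wt")
        assert abs(c.effect_size) < 0.15

    def test_cell_mean_arithmetic(self):
        # gaps: wt 0.5, mut 0.0 -> interaction effect magnitude 0.5
        t = self.build(
            {("wt", "fed"): 0.5, ("wt", "starved"): 0.0,
             ("mut", "fed"): 0.5, ("mut", "starved"): 0.5},
            noise_sd=0.01, seed=2,
        )
        c = ap.feeding_state_contrast(t, "wt")
        assert c.effect_size == pytest.approx(-0.5, abs=0.05)

    def test_f_equals_t_squared_in_2x2(self, rng):
        import statsmodels.formula.api as smf

        t = self.build(
            {("wt", "fed"): 0.5, ("wt", "starved"): 0.1,
             ("mut", "fed"): 0.4, ("mut", "starved"): 0.35},
            noise_sd=0.08, n=6, seed=3,
        )
        c = ap.feeding_state_contrast(t, "wt")
        m = smf.ols("value ~ C(group, Treatment('wt')) * C(feeding_state)", data=t).fit()
        tname = [n for n in m.params.index if ":" in n][0]
        assert c.statistic == pytest.approx(float(m.tvalues[tname]) ** 2, abs=1e-9)

    def test_shift_invariance_and_label_swap(self):
        t = self.build(
            {("wt", "fed"): 0.5, ("wt", "starved"): 0.0,
             ("mut", "fed"): 0.5, ("mut", "starved"): 0.45},
            noise_sd=0.05, n=5, seed=4,
        )
        c1 = ap.feeding_state_contrast(t, "wt")
        t2 = t.copy()
        t2["value"] = t2["value"] + 10.0
        c2 = ap.feeding_state_contrast(t2, "wt")
        assert c1.statistic == pytest.approx(c2.statistic, abs=1e-9)
        c3 = ap.feeding_state_contrast(t, "mut")
        assert c3.statistic == pytest.approx(c1.statistic, abs=1e-9)
        assert c3.effect_size == pytest.approx(-c1.effect_size, abs=1e-12)

    def test_missing_cell_rejected(self):
        t = self.build(
            {("wt", "fed"): 0.5, ("wt", "starved"): 0.0, ("mut", "fed"): 0.5}
        )
        with pytest.raises(ValueError):
            ap.feeding_state_contrast(t, "wt")


SMALL_CONFIG = {
    "seed": 9,
    "behavior": {
        "presets": ["fed", "starved"],
        "n_assays": 2,
        "n_worms": 4,
        "assay_duration_s": 420.0,
        "trim_start_s": 60.0,
    },
    "calcium": {"presets": ["awc_fed_like", "awc_starved_like"], "n_traces": 4},
}


def _hash_csvs(d: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(d.glob("*.csv")):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


class TestRunPipeline:
    def test_outputs_written(self, tmp_path):
        bundle = ap.run_pipeline(SMALL_CONFIG, out_dir=tmp_path)
        for name in (
            "behavior_assays.csv",
            "behavior_stats.csv",
            "calcium_neurons.csv",
            "calcium_bins.csv",
            "calcium_stats.csv",
            "report.txt",
        ):
            assert (tmp_path / name).exists()
        assert len(bundle["behavior_assays"]) == 4

    def test_rerun_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        ap.run_pipeline(SMALL_CONFIG, out_dir=d1)
        ap.run_pipeline(SMALL_CONFIG, out_dir=d2)
        assert _hash_csvs(d1) == _hash_csvs(d2)

    def test_seed_changes_output(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        ap.run_pipeline(SMALL_CONFIG, out_dir=d1)
        ap.run_pipeline({**SMALL_CONFIG, "seed": 10}, out_dir=d2)
        assert _hash_csvs(d1) != _hash_csvs(d2)


class TestCLI:
    def test_simulate_then_tracks(self, tmp_path):
        from click.testing import CliRunner

        from wormtherm.cli import main

        runner = CliRunner()
        r1 = runner.invoke(
            main,
            ["simulate", "--preset", "fed", "--seed", "3", "--out", str(tmp_path),
             "--n-worms", "3", "--duration", "180"],
        )
        assert r1.exit_code == 0, r1.output
        traj_csv = tmp_path / "trajectories_fed_00.csv"
        assert traj_csv.exists()
        out_csv = tmp_path / "res.csv"
        r2 = runner.invoke(
            main,
            ["tracks", str(traj_csv), "--trim-start", "0", "--out", str(out_csv)],
        )
        assert r2.exit_code == 0, r2.output
        df = pd.read_csv(out_csv)
        assert -1.0 <= df["bias"].item() <= 1.0

    def test_report_missing_config_fails_nonzero(self, tmp_path):
        from click.testing import CliRunner

        from wormtherm.cli import main

        runner = CliRunner()
        r = runner.invoke(main, ["report", "--config", str(tmp_path / "none.yaml")])
        assert r.exit_code != 0
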