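"""End-to-end orchestration and group-level statistics.

An :class:`AssayTable` (a tidy DataFrame with one row per assay and
statistic) is the unit on which group comparisons run — statistics never
see per-worm data, matching the convention that each dot in a behavioral
figure is one independent assay of ~15 animals.

Group comparisons: Welch's t-test between two groups (classic pooled
variance available via ``equal_var=True``) and one-way ANOVA with Tukey
HSD for more than two.  The feeding-state interaction contrast fits the
two-factor OLS model ``value ~ genotype * feeding_state`` and reports the
Wald F of the interaction term together with the difference of
(fed - starved) differences — the quantity asking "does this genotype
change the magnitude of the feeding-state effect?".

:func:`run_pipeline` drives simulate -> quantify -> compare from a flat
YAML-compatible config and writes deterministic CSV outputs (two runs from
one config are byte-identical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import calcium_quant as cq
from . import io as wio
from . import synthetic_worlds as sw
from . import track_quant as tq

__all__ = [
    "ContrastResult",
    "make_assay_table",
    "group_compare",
    "feeding_state_contrast",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

FEEDING_STATES = ("fed", "starved", "refed")
CSV_FLOAT_FORMAT = "%.6f"


@dataclass
class ContrastResult:
    """One tested effect: statistic, degrees of freedom, p, effect size."""

    name: str
    statistic: float
    df: Tuple[float, float]
    p_value: float
    effect_size: float
    kind: str = "t"

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def make_assay_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Build a tidy assay-level table.

    Each row needs assay_id, group (genotype/treatment), feeding_state,
    statistic, value; one value per (assay, statistic).
    """
    df = pd.DataFrame(rows, columns=["assay_id", "group", "feeding_state", "statistic", "value"])
    bad_states = set(df["feeding_state"]) - set(FEEDING_STATES)
    if bad_states:
        raise ValueError(
            f"feeding_state value(s) {sorted(bad_states)} not in {FEEDING_STATES}"
        )
    dup = df.duplicated(["assay_id", "statistic"])
    if dup.any():
        raise ValueError("duplicate (assay_id, statistic) rows in assay table")
    return df


def group_compare(
    table: pd.DataFrame,
    design: str = "two_group_t",
    statistic: Optional[str] = None,
    group_col: str = "group",
    equal_var: bool = False,
) -> List[ContrastResult]:
    """Compare a statistic across groups of assays.

    ``two_group_t`` runs a two-sided t-test (Welch by default) between
    exactly two groups; ``anova_tukey`` runs one-way ANOVA followed by
    Tukey HSD pairwise comparisons.  Every group must contain at least two
    assays.
    """
    df = table
    if statistic is not None:
        df = df[df["statistic"] == statistic]
    groups = {name: g["value"].to_numpy(dtype=float) for name, g in df.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    small = [name for name, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"group(s) with < 2 assays: {', '.join(map(str, small))}")

    names = sorted(groups)
    if design == "two_group_t":
        if len(groups) != 2:
            raise ValueError(f"two_group_t needs exactly 2 groups, got {len(groups)}")
        a, b = groups[names[0]], groups[names[1]]
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        return [
            ContrastResult(
                name=f"{names[0]} vs {names[1]}",
                statistic=float(res.statistic),
                df=(float(res.df), 0.0),
                p_value=float(res.pvalue),
                effect_size=float(np.mean(a) - np.mean(b)),
                kind="t",
            )
        ]
    if design == "anova_tukey":
        arrays = [groups[n] for n in names]
        f_res = stats.f_oneway(*arrays)
        n_total = sum(len(v) for v in arrays)
        out = [
            ContrastResult(
                name="one-way ANOVA",
                statistic=float(f_res.statistic),
                df=(float(len(names) - 1), float(n_total - len(names))),
                p_value=float(f_res.pvalue),
                effect_size=float(np.ptp([np.mean(v) for v in arrays])),
                kind="F",
            )
        ]
        tk = stats.tukey_hsd(*arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                out.append(
                    ContrastResult(
                        name=f"{names[i]} vs {names[j]} (Tukey)",
                        statistic=float(tk.statistic[i, j]),
                        df=(float(len(names)), float(n_total - len(names))),
                        p_value=float(tk.pvalue[i, j]),
                        effect_size=float(np.mean(arrays[i]) - np.mean(arrays[j])),
                        kind="tukey",
                    )
                )
        return out
    raise ValueError(f"unknown design {design!r}; use 'two_group_t' or 'anova_tukey'")


def feeding_state_contrast(
    table: pd.DataFrame,
    reference_group: str,
    statistic: Optional[str] = None,
) -> ContrastResult:
    """Wald F for the genotype x feeding-state interaction (2 x 2 design).

    Fits ``value ~ C(group) * C(feeding_state)`` by OLS and tests the
    interaction coefficient; in the 2 x 2 case the Wald F equals the
    squared t of that coefficient.  The effect size is the difference of
    (fed - starved) group means between the non-reference and reference
    genotype.
    """
    df = table
    if statistic is not None:
        df = df[df["statistic"] == statistic]
    df = df.copy()
    genotypes = sorted(df["group"].unique())
    states = sorted(df["feeding_state"].unique())
    if len(genotypes) != 2 or len(states) != 2:
        raise ValueError(
            f"interaction contrast needs a 2x2 design, got {len(genotypes)} "
            f"genotype(s) x {len(states)} feeding state(s)"
        )
    if reference_group not in genotypes:
        raise ValueError(f"reference group {reference_group!r} not in {genotypes}")
    missing = [
        (g, s)
        for g in genotypes
        for s in states
        if ((df["group"] == g) & (df["feeding_state"] == s)).sum() < 2
    ]
    if missing:
        raise ValueError(f"cells with < 2 assays: {missing}")

    model = smf.ols(
        f"value ~ C(group, Treatment('{reference_group}')) * C(feeding_state)",
        data=df,
    ).fit()
    inter_name = [n for n in model.params.index if ":" in n]
    assert len(inter_name) == 1
    wald = model.wald_test(inter_name[0], scalar=True)
    f_stat = float(wald.statistic)
    p = float(wald.pvalue)

    other = [g for g in genotypes if g != reference_group][0]
    means = df.groupby(["group", "feeding_state"])["value"].mean()
    gap_ref = means[(reference_group, "fed")] - means[(reference_group, "starved")]
    gap_other = means[(other, "fed")] - means[(other, "starved")]
    return ContrastResult(
        name=f"{other} x feeding interaction (vs {reference_group})",
        statistic=f_stat,
        df=(float(wald.df_num), float(wald.df_denom)),
        p_value=p,
        effect_size=float(gap_other - gap_ref),
        kind="F",
    )


# --- orchestration -------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "results",
    "behavior": {
        "presets": ["fed", "starved"],
        "n_assays": 8,
        "n_worms": 15,
        "assay_duration_s": 2100.0,
        "trim_start_s": 300.0,
        "write_trajectories": False,
    },
    "calcium": {
        "presets": ["awc_fed_like", "awc_starved_like"],
        "n_traces": 20,
        "ramp": "awc",
    },
}


def _merge_config(config: Optional[dict]) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _assay_seed(root: int, index: int) -> int:
    children = np.random.SeedSequence(root).spawn(index + 1)
    return int(children[index].generate_state(1)[0] & 0x7FFFFFFF)


def simulate_behavior_assays(
    presets: Sequence[str],
    n_assays: int,
    seed: int,
    n_worms: int = 15,
    assay_duration_s: float = 2100.0,
    trim_start_s: float = 300.0,
    collect_trajectories: bool = False,
) -> Tuple[pd.DataFrame, List[dict], Dict[str, List[tq.Trajectory]]]:
    """Simulate and quantify behavioral assays for the given presets.

    Returns the per-assay result table, tidy assay rows for statistics,
    and (optionally) the trajectories keyed by assay id.
    """
    gradient = sw.short_gradient()
    records = []
    tidy_rows = []
    stash: Dict[str, List[tq.Trajectory]] = {}
    idx = 0
    for name in presets:
        cfg, _ = sw.preset(name)
        feeding = "starved" if name.startswith("starved") else "fed"
        for a in range(n_assays):
            cfg_a = sw.replace(
                cfg,
                n_worms=n_worms,
                assay_duration=assay_duration_s,
                seed=_assay_seed(seed, idx),
            )
            idx += 1
            assay_id = f"{name}_{a:02d}"
            trajs, _truth = sw.simulate_assay(cfg_a, gradient)
            result = tq.quantify_assay(
                trajs,
                assay_id=assay_id,
                gradient_axis=gradient.warm_axis_deg,
                trim_start=trim_start_s,
            )
            if collect_trajectories:
                stash[assay_id] = trajs
            records.append(
                {
                    "assay_id": assay_id,
                    "preset": name,
                    "feeding_state": feeding,
                    "n_worms": result.n_worms,
                    "bias": result.thermotaxis_bias,
                    "mean_velocity_um_s": result.mean_velocity,
                    "reversal_rate_per_min": result.reversal_rate,
                }
            )
            tidy_rows.append(
                {
                    "assay_id": assay_id,
                    "group": name,
                    "feeding_state": feeding,
                    "statistic": "thermotaxis_bias",
                    "value": result.thermotaxis_bias,
                }
            )
    return pd.DataFrame(records), tidy_rows, stash


def simulate_calcium_group(
    preset_name: str,
    n_traces: int,
    seed: int,
    ramp: Optional[sw.TemperatureRamp] = None,
) -> Tuple[List[cq.NeuronSummary], List[Tuple[cq.DffTrace, List[cq.ResponseEvent]]]]:
    """Simulate and quantify a group of calcium traces for one preset."""
    _, params = sw.preset(preset_name)
    stim = ramp or sw.default_ramp("awc")
    summaries = []
    pairs = []
    for i in range(n_traces):
        p_i = sw.replace(params, seed=_assay_seed(seed, i))
        trace, _truth = sw.simulate_calcium(p_i, stim)
        d = cq.dff(trace)
        events = cq.detect_events(d)
        summaries.append(
            cq.summarize_neuron(f"{preset_name}_{i:03d}", events, ramp=stim)
        )
        pairs.append((d, events))
    return summaries, pairs


def run_pipeline(config: Optional[dict] = None, out_dir=None) -> Dict[str, object]:
    """Execute simulate -> quantify -> compare and write the report bundle.

    Writes behavior_assays.csv, behavior_stats.csv, calcium_neurons.csv,
    calcium_bins.csv, calcium_stats.csv and report.txt into the output
    directory.  All randomness flows from the single config seed; re-running
    with the same config reproduces every CSV byte for byte.
    """
    cfg = _merge_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report_lines = ["wormtherm pipeline report", "", f"config: {cfg!r}", ""]
    bundle: Dict[str, object] = {"config": cfg}

    bcfg = cfg.get("behavior")
    if bcfg:
        table, tidy_rows, stash = simulate_behavior_assays(
            presets=bcfg["presets"],
            n_assays=int(bcfg["n_assays"]),
            seed=seed,
            n_worms=int(bcfg["n_worms"]),
            assay_duration_s=float(bcfg["assay_duration_s"]),
            trim_start_s=float(bcfg["trim_start_s"]),
            collect_trajectories=bool(bcfg.get("write_trajectories")),
        )
        table.to_csv(out / "behavior_assays.csv", index=False, float_format=CSV_FLOAT_FORMAT)
        for assay_id, trajs in stash.items():
            wio.write_trajectories(trajs, out / f"trajectories_{assay_id}.csv")
        assay_table = make_assay_table(tidy_rows)
        stats_rows = []
        if len(set(bcfg["presets"])) >= 2:
            design = "two_group_t" if len(set(bcfg["presets"])) == 2 else "anova_tukey"
            for c in group_compare(assay_table, design=design, statistic="thermotaxis_bias"):
                stats_rows.append(
                    {
                        "contrast": c.name,
                        "kind": c.kind,
                        "statistic": c.statistic,
                        "p_value": c.p_value,
                        "effect_size": c.effect_size,
                    }
                )
        pd.DataFrame(stats_rows).to_csv(
            out / "behavior_stats.csv", index=False, float_format=CSV_FLOAT_FORMAT
        )
        for line in stats_rows:
            report_lines.append(
                f"behavior {line['contrast']}: {line['kind']}={line['statistic']:.4f}, "
                f"p={line['p_value']:.4g}, effect={line['effect_size']:.4f}"
            )
        mean_bias = table.groupby("preset")["bias"].mean()
        for name, value in mean_bias.items():
            report_lines.append(f"behavior mean bias [{name}]: {value:.4f}")
        bundle["behavior_assays"] = table
        bundle["behavior_stats"] = pd.DataFrame(stats_rows)

    ccfg = cfg.get("calcium")
    if ccfg:
        all_summaries = []
        bin_frames = []
        durations: Dict[str, List[float]] = {}
        for gi, name in enumerate(ccfg["presets"]):
            summaries, pairs = simulate_calcium_group(
                name,
                n_traces=int(ccfg["n_traces"]),
                seed=_assay_seed(seed, 1000 + gi),
                ramp=sw.default_ramp(ccfg.get("ramp", "awc")),
            )
            durations[name] = [s.total_response_duration for s in summaries]
            for s in summaries:
                all_summaries.append(
                    {
                        "neuron_id": s.neuron_id,
                        "group": name,
                        "n_events": s.n_events,
                        "total_duration_s": s.total_response_duration,
                        "mean_event_duration_s": s.mean_event_duration,
                        "t_star_C": np.nan if s.t_star is None else s.t_star,
                    }
                )
            bins = cq.bin_response_fraction(pairs)
            bins.insert(0, "group", name)
            bin_frames.append(bins)
        pd.DataFrame(all_summaries).to_csv(
            out / "calcium_neurons.csv", index=False, float_format=CSV_FLOAT_FORMAT
        )
        pd.concat(bin_frames, ignore_index=True).to_csv(
            out / "calcium_bins.csv", index=False, float_format=CSV_FLOAT_FORMAT
        )
        cstats = []
        names = list(durations)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                for test in ("ks", "mwu"):
                    r = cq.compare_distributions(durations[names[i]], durations[names[j]], test)
                    cstats.append(
                        {
                            "contrast": f"{names[i]} vs {names[j]}",
                            "test": test,
                            "statistic": r.statistic,
                            "p_value": r.p_value,
                        }
                    )
                    report_lines.append(
                        f"calcium {names[i]} vs {names[j]} [{test}]: "
                        f"stat={r.statistic:.4f}, p={r.p_value:.4g}"
                    )
        pd.DataFrame(cstats).to_csv(
            out / "calcium_stats.csv", index=False, float_format=CSV_FLOAT_FORMAT
        )
        bundle["calcium_neurons"] = pd.DataFrame(all_summaries)
        bundle["calcium_stats"] = pd.DataFrame(cstats)

    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    bundle["report"] = "\n".join(report_lines)
    logger.info("pipeline outputs written to %s", out)
    return bundle
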