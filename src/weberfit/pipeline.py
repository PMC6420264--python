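"""End-to-end experiment pipelines: simulate -> analyze -> report.

Three pipelines mirror the three experiment types:

* ``exp1_size``     — size reproduction by adjustment; SD-based JNDs and
  Weber fractions, bias correction, outlier screening, mixed ANOVA on
  the fractions with per-group linear trends.
* ``exp2_weight``   — weight discrimination by constant stimuli;
  psychometric fits per participant per standard, quartile JNDs, Weber
  fractions (JND/PSE and JND/standard), mixed ANOVA and trends.
* ``exp3_illusion`` — brightness-weight illusion; fits per brightness,
  susceptibility screening, PSE and JND trends over brightness.

All randomness flows from a single master seed; per-group streams are
spawned deterministically so results are bit-reproducible.  Every stage
logs counts in/out at each filter, and the summary JSON records a hash
of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adjustment, illusion, observers, psychometric
from .groupstats import linear_trend, mixed_anova

logger = logging.getLogger(__name__)

EXPERIMENTS = ("exp1_size", "exp2_weight", "exp3_illusion")


@dataclass
class GroupSpec:
    """One simulated participant group: size plus observer parameters."""

    n_participants: int
    observer: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Serializable description of a full simulate-and-analyze run."""

    experiment: str
    seed: int = 0
    design: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)  # name -> GroupSpec fields
    analysis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(experiment: str, seed: int = 0) -> PipelineConfig:
    """Reference configurations matching the three experiment designs.

    Group sizes and stimulus designs follow the reference experiments
    these pipelines emulate;
    observer noise regimes encode the two study conditions: a typical
    group obeying Weber's law (SD proportional to intensity) and a group
    with intensity-independent noise.
    """
    if experiment == "exp1_size":
        return PipelineConfig(
            experiment=experiment,
            seed=seed,
            design={"standards": [25.5, 35.5, 45.5, 55.5], "repetitions": 16},
            groups={
                "td": {
                    "n_participants": 20,
                    "observer": {
                        "regime": "weber",
                        "weber_fraction": 0.08,
                        "central_tendency": 0.3,
                    },
                },
                "asd": {
                    "n_participants": 26,
                    "observer": {
                        "regime": "constant",
                        "constant_sd": 3.2,
                        "central_tendency": 0.05,
                    },
                },
            },
            analysis={"outlier_threshold": 2.5, "fraction_denominator": "mean_estimate"},
        )
    if experiment == "exp2_weight":
        return PipelineConfig(
            experiment=experiment,
            seed=seed,
            design={
                "standards": [300, 350, 400, 450],
                "n_comparisons": 12,
                "step": 6,
                "repetitions": 12,
            },
            groups={
                "td": {
                    "n_participants": 12,
                    "observer": {"noise_law": "weber", "weber_fraction": 0.07},
                },
                "asd": {
                    "n_participants": 11,
                    "observer": {"noise_law": "constant", "constant_sd": 25.0},
                },
            },
            analysis={"fraction": "jnd_over_standard"},
        )
    if experiment == "exp3_illusion":
        shift = {"black": -6.0, "gray": 0.0, "white": 6.0}
        return PipelineConfig(
            experiment=experiment,
            seed=seed,
            design={
                "standard": 129,
                "brightness_levels": ["black", "gray", "white"],
                "n_comparisons": 11,
                "step": 7,
                "repetitions": 12,
            },
            groups={
                "td": {
                    "n_participants": 21,
                    "observer": {
                        "noise_law": "weber_perceived",
                        "weber_fraction": 0.1,
                        "brightness_shift": shift,
                    },
                },
                "asd": {
                    "n_participants": 18,
                    "observer": {
                        "noise_law": "constant",
                        "constant_sd": 13.0,
                        "brightness_shift": shift,
                    },
                },
            },
            analysis={"direction": "illusion"},
        )
    raise ValueError(f"unknown experiment {experiment!r}")


def _build_design(config: PipelineConfig) -> observers.StimulusDesign:
    d = config.design
    if config.experiment == "exp1_size":
        return observers.make_adjustment_design(d["standards"], d.get("repetitions", 16))
    if config.experiment == "exp2_weight":
        return observers.make_constant_stimuli_design(
            d["standards"], d["n_comparisons"], d["step"], d["repetitions"]
        )
    return observers.make_illusion_design(
        d.get("standard", 129),
        d.get("brightness_levels", ["black", "gray", "white"]),
        d.get("n_comparisons", 11),
        d.get("step", 7),
        d.get("repetitions", 12),
    )


def _group_seeds(seed: int, group_names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(group_names))
    return {g: int(c.generate_state(1)[0] % (2**31)) for g, c in zip(group_names, children)}


def simulate(config: PipelineConfig) -> pd.DataFrame:
    """Generate the trial table for every group in the configuration."""
    design = _build_design(config)
    names = sorted(config.groups)
    seeds = _group_seeds(config.seed, names)
    frames = []
    for gname in names:
        spec = config.groups[gname]
        n = spec["n_participants"]
        if config.experiment == "exp1_size":
            params = observers.AdjustmentObserverParams(**spec.get("observer", {}))
            frames.append(
                observers.simulate_adjustment(
                    params, design, n, seeds[gname], group=gname, participant_prefix=f"{gname}_"
                )
            )
        else:
            params = observers.ChoiceObserverParams(**spec.get("observer", {}))
            frames.append(
                observers.simulate_constant_stimuli(
                    params, design, n, seeds[gname], group=gname, participant_prefix=f"{gname}_"
                )
            )
    trials = pd.concat(frames, ignore_index=True)
    logger.info("simulated %d trials for groups %s", len(trials), names)
    return trials


def _round_sig(x: float, sig: int = 4) -> float:
    if not np.isfinite(x) or x == 0:
        return float(x)
    return float(np.format_float_positional(x, precision=sig, fractional=False, unique=True))


def _trend_dict(tc) -> dict:
    return {
        "estimate": tc.estimate,
        "F": tc.F,
        "df": list(tc.df),
        "p": tc.p,
        "partial_eta_sq": tc.partial_eta_sq,
        "degenerate": tc.degenerate,
    }


def _anova_dict(res) -> dict:
    t = res.table.set_index("effect")
    return {
        eff: {
            "F": float(t.loc[eff, "F"]),
            "df": [float(t.loc[eff, "df1"]), float(t.loc[eff, "df2"])],
            "p": float(t.loc[eff, "p"]),
            "partial_eta_sq": float(t.loc[eff, "partial_eta_sq"]),
        }
        for eff in t.index
    }


def analyze(config: PipelineConfig, trials: pd.DataFrame, outdir: Path | None = None) -> dict:
    """Run the analysis stages for the configured experiment on a trial
    table; write tidy CSVs when ``outdir`` is given; return the summary."""
    outdir = Path(outdir) if outdir is not None else None
    summary: dict = {
        "experiment": config.experiment,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    if config.experiment == "exp1_size":
        summaries, profiles, excluded = adjustment.analyze_adjustment(
            trials,
            outlier_threshold=config.analysis.get("outlier_threshold", 2.5),
            denominator=config.analysis.get("fraction_denominator", "mean_estimate"),
        )
        prof = adjustment.profiles_to_frame(profiles)
        long = prof.rename(columns={"intensity": "level", "fraction": "value"})
        res = mixed_anova(long, dv="value")
        summary["excluded"] = excluded
        summary["interaction"] = _anova_dict(res)["interaction"]
        summary["anova"] = _anova_dict(res)
        summary["groups"] = {}
        for gname, sub in long.groupby("group"):
            slopes = sub.drop_duplicates("participant")["slope"]
            tc = linear_trend(sub, within="level")
            summary["groups"][str(gname)] = {
                "mean_fraction_per_intensity": sub.groupby("level")["value"].mean().to_dict(),
                "fraction_slope": float(slopes.mean()),
                "linear_trend": _trend_dict(tc),
            }
        if outdir is not None:
            prof.to_csv(outdir / "weber_profiles.csv", index=False)
    elif config.experiment == "exp2_weight":
        fits = psychometric.fit_participants(trials)
        n_failed = int((~fits["converged"]).sum())
        logger.info("fitted %d functions (%d failed)", len(fits), n_failed)
        fraction = config.analysis.get("fraction", "jnd_over_standard")
        good = fits.dropna(subset=[fraction])
        long = good.rename(columns={"standard": "level", fraction: "value"})[
            ["participant", "group", "level", "value"]
        ]
        res = mixed_anova(long, dv="value")
        summary["n_failed_fits"] = n_failed
        summary["fraction_definition"] = fraction
        summary["interaction"] = _anova_dict(res)["interaction"]
        summary["anova"] = _anova_dict(res)
        summary["groups"] = {}
        for gname, sub in long.groupby("group"):
            slopes = (
                sub.groupby("participant")
                .apply(
                    lambda s: np.polyfit(s["level"], s["value"], 1)[0],
                    include_groups=False,
                )
                .astype(float)
            )
            tc = linear_trend(sub, within="level")
            summary["groups"][str(gname)] = {
                "mean_fraction_per_intensity": sub.groupby("level")["value"].mean().to_dict(),
                "fraction_slope": float(slopes.mean()),
                "linear_trend": _trend_dict(tc),
            }
        if outdir is not None:
            fits.to_csv(outdir / "psychometric_fits.csv", index=False)
    else:  # exp3_illusion
        fits = psychometric.fit_participants(trials)
        roster, trends = illusion.analyze_illusion(
            fits, direction=config.analysis.get("direction", "illusion")
        )
        counts = (
            roster.groupby(["group", "status"]).size().unstack(fill_value=0).to_dict("index")
        )
        summary["susceptibility"] = {g: dict(v) for g, v in counts.items()}
        summary["trends"] = {
            m: {g: _trend_dict(tc) for g, tc in per_group.items()}
            for m, per_group in trends.items()
        }
        if outdir is not None:
            fits.to_csv(outdir / "psychometric_fits.csv", index=False)
            roster.to_csv(outdir / "susceptibility.csv", index=False)
    return summary


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """simulate -> analyze -> report; deterministic given the seed.

    Writes ``trials.csv``, per-stage tidy CSVs, ``summary.json`` (full
    precision) and ``report.txt`` (4 significant digits) under
    ``outdir``; returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = simulate(config)
    trials.to_csv(outdir / "trials.csv", index=False)
    summary = analyze(config, trials, outdir=outdir)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "report.txt").write_text(_human_report(summary))
    config.to_yaml(outdir / "config.yaml")
    return summary


def _human_report(summary: dict, sig: int = 4) -> str:
    def fmt(obj):
        if isinstance(obj, dict):
            return {k: fmt(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [fmt(v) for v in obj]
        if isinstance(obj, float):
            return _round_sig(obj, sig)
        return obj

    return json.dumps(fmt(summary), indent=2, sort_keys=True)


def validate_trial_table(source, task: str | None = None) -> list[str]:
    """Schema-check a trial table; returns every violation found.

    Checks column presence, value ranges (binary responses, nonnegative
    magnitudes) and design balance (every participant holds the same set
    of standards with equal trial counts).  ``source`` is a path or a
    DataFrame; an unreadable path raises an OSError.
    """
    if isinstance(source, (str, Path)):
        table = pd.read_csv(source)
    else:
        table = source
    violations: list[str] = []
    if "participant" not in table.columns or "standard" not in table.columns:
        violations.append("missing required columns: participant and/or standard")
        return violations
    if task is None:
        task = str(table["task"].iloc[0]) if "task" in table.columns and len(table) else ""
    if task == "adjustment" or "estimate" in table.columns and table["estimate"].notna().any():
        if "estimate" not in table.columns:
            violations.append("adjustment table lacks 'estimate' column")
        else:
            bad = table.index[table["estimate"] < 0]
            for i in bad:
                violations.append(f"row {i}: negative estimate {table.loc[i, 'estimate']}")
    if task == "constant_stimuli" or "response" in table.columns and table["response"].notna().any():
        if "response" not in table.columns or "comparison" not in table.columns:
            violations.append("constant-stimuli table lacks 'response'/'comparison' columns")
        else:
            bad = table.index[~table["response"].isin([0, 1])]
            for i in bad:
                violations.append(f"row {i}: response {table.loc[i, 'response']!r} not in {{0, 1}}")
    # balance: identical standard sets and per-cell counts across participants
    cells = table.groupby(["participant", "standard"]).size().unstack()
    if cells.isna().to_numpy().any():
        for pid, row in cells.iterrows():
            miss = list(row.index[row.isna()])
            if miss:
                violations.append(f"participant {pid!r}: missing standard(s) {miss}")
    elif cells.nunique().gt(1).any():
        violations.append("unequal trial counts per (participant, standard) cell")
    return violations
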