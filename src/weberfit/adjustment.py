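"""Analysis of method-of-adjustment (magnitude reproduction) data.

The JND at each standard intensity is the within-participant SD of the
reproductions; the Weber fraction is that SD divided by the mean
reproduction (a coefficient of variation normalised to the perceived
magnitude).  Under Weber's law the fraction is constant across
intensities; intensity-independent noise instead produces fractions that
fall off as 1/I.

Perceptual bias is summarised per standard as (mean estimate − physical
size) and corrected for each participant's overall response shift by
subtracting their (perceived grand mean − physical grand mean); the
corrected biases sum to zero across standards by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRACTION_DEFINITIONS = ("sd_over_mean", "jnd_over_pse", "jnd_over_standard")


@dataclass(frozen=True)
class EstimationSummary:
    """Per-participant adjustment summary across standard intensities."""

    participant: str
    group: str
    standards: np.ndarray          # physical intensities, ascending
    mean_estimate: np.ndarray
    sd_estimate: np.ndarray        # within-participant SD = the JND
    n_trials: np.ndarray
    corrected_bias: np.ndarray | None = None

    @property
    def raw_bias(self) -> np.ndarray:
        return self.mean_estimate - self.standards

    @property
    def grand_perceived(self) -> float:
        return float(np.mean(self.mean_estimate))

    @property
    def grand_physical(self) -> float:
        return float(np.mean(self.standards))

    @property
    def mean_bias(self) -> float:
        """Participant's overall response shift (perceived − physical grand mean)."""
        return self.grand_perceived - self.grand_physical


@dataclass(frozen=True)
class WeberProfile:
    """Per-participant JNDs and Weber fractions along the intensity axis."""

    participant: str
    group: str
    intensities: np.ndarray
    jnd: np.ndarray
    fraction: np.ndarray
    fraction_definition: str
    slope: float  # least-squares slope of fraction on intensity

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant,
                "group": self.group,
                "intensity": self.intensities,
                "jnd": self.jnd,
                "fraction": self.fraction,
                "fraction_definition": self.fraction_definition,
                "slope": self.slope,
            }
        )


def summarize_estimates(trials: pd.DataFrame) -> list[EstimationSummary]:
    """Mean and unbiased (n−1) SD of estimates per participant per standard.

    Raises if any (participant, standard) cell holds fewer than two
    trials — a single reproduction has no defined spread.
    """
    required = {"participant", "standard", "estimate"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    summaries = []
    for pid, sub in trials.groupby("participant", sort=True):
        group = str(sub["group"].iloc[0]) if "group" in sub.columns else ""
        cells = sub.groupby("standard")["estimate"]
        counts = cells.count()
        thin = counts[counts < 2]
        if not thin.empty:
            cell = thin.index[0]
            raise ValueError(
                f"participant {pid!r}, standard {cell}: {int(thin.iloc[0])} trial(s); "
                "need >= 2 per cell"
            )
        summaries.append(
            EstimationSummary(
                participant=str(pid),
                group=group,
                standards=cells.mean().index.to_numpy(dtype=float),
                mean_estimate=cells.mean().to_numpy(dtype=float),
                sd_estimate=cells.std(ddof=1).to_numpy(dtype=float),
                n_trials=counts.to_numpy(dtype=int),
            )
        )
    return summaries


def bias_correct(summary: EstimationSummary) -> EstimationSummary:
    """Fill ``corrected_bias`` = raw bias minus the participant's grand-mean shift.

    corrected_bias(I) = (mean_estimate(I) − I) − (perceived grand mean −
    physical grand mean); its mean over standards is zero identically.
    """
    corrected = summary.raw_bias - summary.mean_bias
    return replace(summary, corrected_bias=corrected)


def flag_outliers(
    summaries: list[EstimationSummary],
    threshold: float = 2.5,
    two_sided: bool = False,
    leave_one_out: bool = True,
) -> list[str]:
    """Participants whose overall response shift is extreme within their group.

    The screening statistic is each participant's mean estimation bias
    (perceived grand mean − physical grand mean) — after the per-participant
    bias correction this is the only overall quantity left free.  A
    participant is flagged when their statistic falls below
    ``group mean − threshold·group SD`` (one-sided by default; symmetric
    with ``two_sided=True``).  With ``leave_one_out`` (default) each
    candidate is compared against the statistics of the *other* group
    members, so a single extreme value cannot inflate the SD and mask
    itself.  A group with zero spread yields no exclusions.
    """
    flagged: list[str] = []
    frame = pd.DataFrame(
        {
            "participant": [s.participant for s in summaries],
            "group": [s.group for s in summaries],
            "stat": [s.mean_bias for s in summaries],
        }
    )
    for gname, sub in frame.groupby("group", sort=True):
        if len(sub) < 3:
            raise ValueError(f"group {gname!r} has {len(sub)} participants; need >= 3")
        stats = sub["stat"].to_numpy()
        for i, (pid, x) in enumerate(zip(sub["participant"], stats)):
            ref = np.delete(stats, i) if leave_one_out else stats
            mu, sd = float(np.mean(ref)), float(np.std(ref, ddof=1))
            if sd == 0:
                logger.info("group %r has zero spread; no exclusions", gname)
                continue
            low = x < mu - threshold * sd
            high = two_sided and x > mu + threshold * sd
            if low or high:
                flagged.append(str(pid))
    return flagged


def weber_fractions_adjustment(
    summary: EstimationSummary, denominator: str = "mean_estimate"
) -> WeberProfile:
    """Weber fractions: within-participant SD over mean estimate per standard.

    ``denominator`` selects the normaliser: the raw mean estimation
    (default, the perceived magnitude) or the physical ``standard``.
    The profile's ``slope`` is the least-squares slope of fraction on the
    physical intensity; zero under exact Weber behaviour, negative when
    the JND fails to scale with intensity.
    """
    if denominator == "mean_estimate":
        denom = summary.mean_estimate
    elif denominator == "standard":
        denom = summary.standards
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if np.any(denom <= 0):
        raise ValueError(
            f"participant {summary.participant!r}: nonpositive denominator; "
            "cannot form Weber fraction"
        )
    fraction = summary.sd_estimate / denom
    slope = float(np.polyfit(summary.standards, fraction, 1)[0])
    return WeberProfile(
        participant=summary.participant,
        group=summary.group,
        intensities=summary.standards.copy(),
        jnd=summary.sd_estimate.copy(),
        fraction=fraction,
        fraction_definition="sd_over_mean",
        slope=slope,
    )


def analyze_adjustment(
    trials: pd.DataFrame,
    outlier_threshold: float | None = 2.5,
    denominator: str = "mean_estimate",
) -> tuple[list[EstimationSummary], list[WeberProfile], list[str]]:
    """Full adjustment pipeline: summarise, bias-correct, screen, profile.

    Returns (bias-corrected summaries, Weber profiles, excluded ids); the
    summaries/profiles exclude flagged participants.  ``outlier_threshold
    = None`` disables screening (sensitivity-analysis toggle).
    """
    summaries = [bias_correct(s) for s in summarize_estimates(trials)]
    excluded = (
        flag_outliers(summaries, threshold=outlier_threshold)
        if outlier_threshold is not None
        else []
    )
    if excluded:
        logger.info("excluding %d participant(s): %s", len(excluded), excluded)
    kept = [s for s in summaries if s.participant not in excluded]
    profiles = [weber_fractions_adjustment(s, denominator=denominator) for s in kept]
    return kept, profiles, excluded


def profiles_to_frame(profiles: list[WeberProfile]) -> pd.DataFrame:
    """Tidy long-format table of Weber profiles (one row per intensity)."""
    if not profiles:
        return pd.DataFrame(
            columns=[
                "participant",
                "group",
                "intensity",
                "jnd",
                "fraction",
                "fraction_definition",
                "slope",
            ]
        )
    return pd.concat([p.as_frame() for p in profiles], ignore_index=True)
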