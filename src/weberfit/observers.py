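"""Stimulus designs and synthetic observers for magnitude-judgement tasks.

Two task families are supported:

* **Method of adjustment** — the observer reproduces the magnitude of a
  standard stimulus (e.g. adjusts a circle's diameter to match a target).
  Precision is read from the spread of the reproductions.
* **Method of constant stimuli** — fixed comparison stimuli straddling a
  standard are presented repeatedly and the observer makes a binary
  "comparison greater?" judgement; choice proportions trace a psychometric
  function.

Observers can follow Weber's law (estimation noise proportional to stimulus
intensity, SD = c·I), violate it with intensity-independent noise
(SD = σ0), or mix both (affine, SD = σ0 + c·I).  Adjustment observers may
additionally exhibit a central-tendency bias pulling estimates toward the
mean of the presented range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: canonical column order for trial tables written by the simulators
TRIAL_COLUMNS = [
    "participant",
    "group",
    "task",
    "standard",
    "brightness",
    "comparison",
    "estimate",
    "response",
    "trial_index",
]

ADJUSTMENT_REGIMES = ("weber", "constant", "affine")
NOISE_LAWS = ("weber", "constant", "weber_perceived")


def visual_angle_deg(diameter: float, distance: float) -> float:
    """Visual angle (degrees) subtended by an object of given size.

    Uses the exact convention ``2*atan(diameter / (2*distance))`` rather
    than the small-angle approximation ``diameter/distance``; the two
    differ in the second decimal place already at ~2.4 degrees.

    Parameters
    ----------
    diameter : float
        Object extent, in the same length unit as `distance` (e.g. mm).
    distance : float
        Viewing distance; must be positive.
    """
    if distance <= 0:
        raise ValueError(f"viewing distance must be positive, got {distance!r}")
    if diameter < 0:
        raise ValueError(f"diameter must be nonnegative, got {diameter!r}")
    return math.degrees(2.0 * math.atan(diameter / (2.0 * distance)))


@dataclass(frozen=True)
class AdjustmentObserverParams:
    """Generative model of a method-of-adjustment observer.

    The estimate of a standard of intensity ``I`` is drawn from

    ``Normal(mean=(1-w)*I + w*anchor + additive_bias, sd=sd_at(I))``

    where ``sd_at`` depends on the noise regime:

    * ``weber``:    sd = c * I      (Weber's law, constant Weber fraction c)
    * ``constant``: sd = sigma0     (intensity-independent noise)
    * ``affine``:   sd = sigma0 + c * I

    ``w`` in [0, 1] is the central-tendency weight ("regression to the
    mean"): estimates are pulled toward `anchor`, by default the mean of
    the presented standards.
    """

    regime: str = "weber"
    weber_fraction: float = 0.08
    constant_sd: float = 0.0
    central_tendency: float = 0.0
    anchor: float | None = None
    additive_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.regime not in ADJUSTMENT_REGIMES:
            raise ValueError(
                f"regime must be one of {ADJUSTMENT_REGIMES}, got {self.regime!r}"
            )
        if self.weber_fraction < 0:
            raise ValueError("weber_fraction must be >= 0")
        if self.constant_sd < 0:
            raise ValueError("constant_sd must be >= 0")
        if not 0.0 <= self.central_tendency <= 1.0:
            raise ValueError("central_tendency must lie in [0, 1]")

    def sd_at(self, intensity: np.ndarray | float) -> np.ndarray | float:
        """Estimation SD at a given stimulus intensity."""
        intensity = np.asarray(intensity, dtype=float)
        if self.regime == "weber":
            sd = self.weber_fraction * intensity
        elif self.regime == "constant":
            sd = np.full_like(intensity, self.constant_sd)
        else:  # affine
            sd = self.constant_sd + self.weber_fraction * intensity
        if np.any(sd < 0):
            raise ValueError("noise configuration yields negative SD")
        return sd


@dataclass(frozen=True)
class ChoiceObserverParams:
    """Generative model of a 2AFC "which is heavier?" observer.

    The probability of judging a comparison of weight ``x`` heavier than a
    standard is

    ``P(heavier) = lapse/2 + (1 - lapse) * Phi((x - PSE) / sigma)``

    with ``PSE = standard + pse_offset + brightness_shift[brightness]``.
    The decision noise ``sigma`` follows one of three laws:

    * ``weber``:          sigma = c * standard   (physical intensity)
    * ``constant``:       sigma = sigma0
    * ``weber_perceived``: sigma = c * PSE       (noise scales with the
      *perceived* weight, including any illusory brightness shift)
    """

    pse_offset: float = 0.0
    noise_law: str = "weber"
    weber_fraction: float = 0.1
    constant_sd: float = 0.0
    lapse: float = 0.0
    brightness_shift: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_law not in NOISE_LAWS:
            raise ValueError(f"noise_law must be one of {NOISE_LAWS}, got {self.noise_law!r}")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")
        if self.weber_fraction < 0 or self.constant_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    def pse(self, standard: float, brightness: str | None = None) -> float:
        shift = 0.0
        if brightness is not None and self.brightness_shift is not None:
            shift = float(self.brightness_shift.get(brightness, 0.0))
        return standard + self.pse_offset + shift

    def sigma(self, standard: float, brightness: str | None = None) -> float:
        if self.noise_law == "weber":
            s = self.weber_fraction * standard
        elif self.noise_law == "constant":
            s = self.constant_sd
        else:  # weber_perceived
            s = self.weber_fraction * self.pse(standard, brightness)
        if s <= 0:
            raise ValueError(
                f"decision noise sigma={s} is not positive at standard={standard}"
            )
        return s

    def p_heavier(
        self, comparison: np.ndarray | float, standard: float, brightness: str | None = None
    ) -> np.ndarray | float:
        """Choice probability for given comparison weight(s)."""
        sigma = self.sigma(standard, brightness)
        pse = self.pse(standard, brightness)
        z = (np.asarray(comparison, dtype=float) - pse) / sigma
        return self.lapse / 2.0 + (1.0 - self.lapse) * norm.cdf(z)


@dataclass(frozen=True)
class StimulusDesign:
    """A stimulus design: standards, their comparisons, and repetitions.

    For constant-stimuli tasks, ``comparisons[i]`` are the comparison
    intensities paired with ``standards[i]``.  When ``brightness_levels``
    is given it is aligned element-wise with ``standards`` (the same
    physical standard may appear once per brightness).  ``meta`` carries
    inert presentation details (e.g. the start value of the adjustment
    cursor) that do not affect analysis.
    """

    task: str
    standards: tuple[float, ...]
    repetitions: int
    comparisons: tuple[tuple[float, ...], ...] = ()
    brightness_levels: tuple[str, ...] | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in ("adjustment", "constant_stimuli"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.task == "constant_stimuli" and len(self.comparisons) != len(self.standards):
            raise ValueError("need one comparison set per standard")
        if self.brightness_levels is not None and len(self.brightness_levels) != len(
            self.standards
        ):
            raise ValueError("brightness_levels must align with standards")

    @property
    def n_trials(self) -> int:
        """Total trials per participant."""
        if self.task == "adjustment":
            return len(self.standards) * self.repetitions
        return sum(len(c) for c in self.comparisons) * self.repetitions

    def trials_per_standard(self) -> dict[int, int]:
        """Trial count per standard slot (keyed by slot index)."""
        if self.task == "adjustment":
            return {i: self.repetitions for i in range(len(self.standards))}
        return {i: len(c) * self.repetitions for i, c in enumerate(self.comparisons)}


def make_adjustment_design(
    standards: Sequence[float], repetitions: int = 16, **meta: object
) -> StimulusDesign:
    """Method-of-adjustment design: each standard reproduced `repetitions` times."""
    return StimulusDesign(
        task="adjustment",
        standards=tuple(float(s) for s in standards),
        repetitions=int(repetitions),
        meta=dict(meta),
    )


def make_constant_stimuli_design(
    standards: Sequence[float],
    n_comparisons: int,
    step: float,
    repetitions: int,
    include_center: bool | None = None,
    brightness_levels: Sequence[str] | None = None,
) -> StimulusDesign:
    """Constant-stimuli design with uniformly spaced, symmetric comparisons.

    With an even ``n_comparisons`` the comparisons straddle the standard
    without including it: ``standard ± step*{1..n/2}``.  With an odd count
    the set is centered on the standard: ``standard ± step*{0..(n-1)/2}``.
    ``include_center`` can assert the intended parity explicitly; leave it
    ``None`` to infer from ``n_comparisons``.

    Total trials per participant = len(standards) * n_comparisons * repetitions.
    """
    if n_comparisons < 2:
        raise ValueError("n_comparisons must be >= 2")
    if step <= 0:
        raise ValueError("step must be positive")
    odd = n_comparisons % 2 == 1
    if include_center is not None and include_center != odd:
        raise ValueError(
            "include_center=%s inconsistent with n_comparisons=%d" % (include_center, n_comparisons)
        )
    if odd:
        half = (n_comparisons - 1) // 2
        offsets = np.arange(-half, half + 1) * step
    else:
        half = n_comparisons // 2
        offsets = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)]) * step
    comparisons = tuple(tuple(float(s) + offsets) for s in standards)
    return StimulusDesign(
        task="constant_stimuli",
        standards=tuple(float(s) for s in standards),
        repetitions=int(repetitions),
        comparisons=comparisons,
        brightness_levels=tuple(brightness_levels) if brightness_levels is not None else None,
    )


def make_illusion_design(
    standard: float = 129.0,
    brightness_levels: Sequence[str] = ("black", "gray", "white"),
    n_comparisons: int = 11,
    step: float = 7.0,
    repetitions: int = 12,
) -> StimulusDesign:
    """Brightness-weight illusion design: one physical standard shown at
    several brightness levels, gray comparisons in uniform steps."""
    return make_constant_stimuli_design(
        standards=[standard] * len(brightness_levels),
        n_comparisons=n_comparisons,
        step=step,
        repetitions=repetitions,
        brightness_levels=brightness_levels,
    )


def participant_rngs(seed: int, n_participants: int) -> list[np.random.Generator]:
    """Independent per-participant generators from a master seed.

    Substreams are spawned sequentially from ``np.random.SeedSequence(seed)``,
    so participant ``i`` always receives the same stream regardless of how
    many later participants are added.
    """
    children = np.random.SeedSequence(seed).spawn(n_participants)
    return [np.random.default_rng(c) for c in children]


def _finalize(table: pd.DataFrame) -> pd.DataFrame:
    for col in TRIAL_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table[TRIAL_COLUMNS]


def simulate_adjustment(
    params: AdjustmentObserverParams,
    design: StimulusDesign,
    n_participants: int,
    seed: int,
    group: str = "sim",
    participant_prefix: str = "p",
) -> pd.DataFrame:
    """Simulate method-of-adjustment trials; one row per reproduction.

    Estimates are Gaussian around ``(1-w)*I + w*anchor + additive_bias``
    with regime-dependent SD.  Negative draws (physically impossible
    sizes) are truncated at 0 and logged.
    """
    if design.task != "adjustment":
        raise ValueError("design.task must be 'adjustment'")
    anchor = params.anchor if params.anchor is not None else float(np.mean(design.standards))
    rngs = participant_rngs(seed, n_participants)
    standards = np.repeat(design.standards, design.repetitions)
    w = params.central_tendency
    means = (1.0 - w) * standards + w * anchor + params.additive_bias
    sds = np.asarray(params.sd_at(standards), dtype=float)

    frames = []
    n_truncated = 0
    for i, rng in enumerate(rngs):
        est = rng.normal(means, sds)
        neg = est < 0
        if neg.any():
            n_truncated += int(neg.sum())
            est = np.where(neg, 0.0, est)
        frames.append(
            pd.DataFrame(
                {
                    "participant": f"{participant_prefix}{i:03d}",
                    "group": group,
                    "task": "adjustment",
                    "standard": standards,
                    "estimate": est,
                    "trial_index": np.arange(standards.size),
                }
            )
        )
    if n_truncated:
        logger.warning("truncated %d negative simulated estimates at 0", n_truncated)
    return _finalize(pd.concat(frames, ignore_index=True))


def simulate_constant_stimuli(
    params: ChoiceObserverParams,
    design: StimulusDesign,
    n_participants: int,
    seed: int,
    group: str = "sim",
    participant_prefix: str = "p",
) -> pd.DataFrame:
    """Simulate 2AFC constant-stimuli trials; one row per judgement.

    Responses are Bernoulli draws from the observer's psychometric
    function; brightness-dependent PSE shifts apply when the design
    carries brightness levels.
    """
    if design.task != "constant_stimuli":
        raise ValueError("design.task must be 'constant_stimuli'")
    rngs = participant_rngs(seed, n_participants)

    std_col, bri_col, cmp_col, p_col = [], [], [], []
    for slot, (std, comps) in enumerate(zip(design.standards, design.comparisons)):
        bri = design.brightness_levels[slot] if design.brightness_levels is not None else None
        comps = np.asarray(comps, dtype=float)
        p = np.asarray(params.p_heavier(comps, std, bri), dtype=float)
        reps = design.repetitions
        std_col.append(np.full(comps.size * reps, std))
        bri_col.extend([bri] * (comps.size * reps))
        cmp_col.append(np.tile(comps, reps))
        p_col.append(np.tile(p, reps))
    standards = np.concatenate(std_col)
    comparisons = np.concatenate(cmp_col)
    probs = np.concatenate(p_col)

    frames = []
    for i, rng in enumerate(rngs):
        resp = (rng.random(probs.size) < probs).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "participant": f"{participant_prefix}{i:03d}",
                    "group": group,
                    "task": "constant_stimuli",
                    "standard": standards,
                    "brightness": bri_col,
                    "comparison": comparisons,
                    "response": resp,
                    "trial_index": np.arange(probs.size),
                }
            )
        )
    return _finalize(pd.concat(frames, ignore_index=True))
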