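"""Brightness-weight illusion analysis.

Identical weights that differ only in surface brightness are perceived as
differing in heaviness; when lifted (rather than merely observed) the
usual direction reverses, with brighter objects judged heavier.  The
measurable signature is a shift of the point of subjective equality:
PSE(black) < PSE(gray) < PSE(white).

The analysis screens participants for susceptibility to the illusion
(the PSE shift in the illusion-consistent direction), then asks whether
JNDs scale with the *perceived* weight — the participant's own PSE per
brightness — which Weber's law predicts for typical observers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groupstats import TrendContrast, linear_trend

logger = logging.getLogger(__name__)

BRIGHTNESS_ORDER = ("black", "gray", "white")


@dataclass(frozen=True)
class IllusionRecord:
    """Per-participant PSEs and JNDs at the three brightness levels.

    ``pse``/``jnd`` map brightness -> value; a brightness whose fit
    failed is absent (or NaN), making the susceptibility status
    undetermined rather than false.
    """

    participant: str
    group: str
    pse: dict
    jnd: dict
    converged: dict

    def complete(self) -> bool:
        return all(
            b in self.pse and np.isfinite(self.pse[b]) and self.converged.get(b, False)
            for b in BRIGHTNESS_ORDER
        )


def screen_susceptibility(record: IllusionRecord, direction: str = "illusion") -> bool | None:
    """Susceptibility to the brightness-weight illusion from PSE ordering.

    ``direction="illusion"`` (default) requires the lifted-illusion
    pattern with strict inequalities: PSE(black) < PSE(gray) and
    PSE(white) > PSE(gray).  ``direction="any"`` accepts a monotone
    shift in either direction (black and white displaced from gray with
    opposite signs).  Returns ``None`` (undetermined, logged) when any
    of the three fits is missing or unconverged.
    """
    if not record.complete():
        logger.warning(
            "participant %r: susceptibility undetermined (missing/failed fit)",
            record.participant,
        )
        return None
    b, g, w = (record.pse[k] for k in BRIGHTNESS_ORDER)
    if direction == "illusion":
        return bool(b < g and w > g)
    if direction == "any":
        return bool((b - g) * (w - g) < 0)
    raise ValueError(f"unknown direction {direction!r}")


def records_from_fits(fits: pd.DataFrame) -> list[IllusionRecord]:
    """Build illusion records from the tidy per-fit table
    (columns participant, group, brightness, pse, jnd, converged)."""
    records = []
    for (pid, grp), sub in fits.groupby(["participant", "group"], sort=True):
        sub = sub.set_index("brightness")
        records.append(
            IllusionRecord(
                participant=str(pid),
                group=str(grp),
                pse=sub["pse"].to_dict(),
                jnd=sub["jnd"].to_dict(),
                converged=sub["converged"].to_dict(),
            )
        )
    return records


def susceptibility_roster(
    records: list[IllusionRecord], direction: str = "illusion"
) -> pd.DataFrame:
    """One row per participant with status susceptible / non_susceptible /
    undetermined; the three statuses partition the input exactly."""
    rows = []
    for r in records:
        s = screen_susceptibility(r, direction)
        status = "undetermined" if s is None else ("susceptible" if s else "non_susceptible")
        rows.append({"participant": r.participant, "group": r.group, "status": status})
    return pd.DataFrame(rows)


def brightness_trend(
    records: list[IllusionRecord],
    measure: str = "pse",
    direction: str = "illusion",
    susceptible_only: bool = True,
) -> dict[str, TrendContrast]:
    """Linear trend of PSE or JND over brightness (black < gray < white),
    per group, on susceptible participants by default.

    Brightness is an ordered factor with equally spaced linear contrast
    weights (−1, 0, +1).  Degenerate (zero within-subject error) patterns
    are flagged on the returned contrast, not raised.
    """
    if measure not in ("pse", "jnd"):
        raise ValueError(f"measure must be 'pse' or 'jnd', got {measure!r}")
    rows = []
    for r in records:
        if susceptible_only and screen_susceptibility(r, direction) is not True:
            continue
        vals = r.pse if measure == "pse" else r.jnd
        for i, b in enumerate(BRIGHTNESS_ORDER):
            rows.append(
                {
                    "participant": r.participant,
                    "group": r.group,
                    "brightness_index": i,
                    "value": vals[b],
                }
            )
    if not rows:
        raise ValueError("no susceptible participants with complete fits")
    table = pd.DataFrame(rows)
    out = {}
    for gname, sub in table.groupby("group", sort=True):
        if sub["participant"].nunique() < 2:
            raise ValueError(f"group {gname!r}: need >= 2 susceptible participants")
        out[str(gname)] = linear_trend(sub, within="brightness_index")
    return out


def analyze_illusion(
    fits: pd.DataFrame, direction: str = "illusion"
) -> tuple[pd.DataFrame, dict[str, dict[str, TrendContrast]]]:
    """Screen susceptibility and compute per-group brightness trends.

    Returns the roster and ``{measure: {group: TrendContrast}}`` for PSE
    (the illusion's strength) and JND (Weber scaling with perceived
    weight).
    """
    records = records_from_fits(fits)
    roster = susceptibility_roster(records, direction)
    counts = roster.groupby(["group", "status"]).size()
    logger.info("susceptibility counts:\n%s", counts.to_string())
    trends = {
        m: brightness_trend(records, measure=m, direction=direction) for m in ("pse", "jnd")
    }
    return roster, trends
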