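"""Region-based reading measures from ordered fixation sequences.

Computes the four standard measures for a target region (here the verb particle
merged with the word to its left, since two-to-three-letter particles are often
skipped):

FFD   first fixation duration — duration of the first first-pass fixation in
      the region.
FPRT  first-pass reading time (gaze duration) — summed fixations from first
      entering the region until first leaving it in either direction.
TFT   total fixation time — all fixations in the region across the trial.
RPD   regression path duration (go-past time) — summed fixations from first
      entering the region until the first fixation strictly to its right,
      including regressive fixations to earlier regions.

First-pass convention: if material to the right of the region is fixated before
the region is ever entered, the region counts as skipped in first pass (FFD,
FPRT and RPD are missing; TFT may still be positive).  If no fixation ever
lands right of the region, RPD runs to the end of the trial and the result is
flagged unterminated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import pandas as pd


class FixationError(ValueError):
    """Malformed fixation sequence."""


@dataclass
class FixationSequence:
    """Ordered fixations for one trial: (region_index >= 1, duration_ms > 0)."""

    trial_id: str
    fixations: list[tuple[int, float]]
    blink_or_trackloss: bool = False

    def __post_init__(self) -> None:
        for i, (region, dur) in enumerate(self.fixations):
            if region < 1 or int(region) != region:
                raise FixationError(
                    f"trial {self.trial_id}, fixation {i}: region index must "
                    f"be a positive integer, got {region}"
                )
            if not (dur > 0) or not math.isfinite(dur):
                raise FixationError(
                    f"trial {self.trial_id}, fixation {i}: duration must be "
                    f"positive and finite, got {dur}"
                )


@dataclass
class RegionMeasures:
    trial_id: str
    region: tuple[int, int]  # inclusive span (lo, hi)
    ffd_ms: float | None
    fprt_ms: float | None
    tft_ms: float | None
    rpd_ms: float | None
    skipped_first_pass: bool
    rpd_unterminated: bool = False

    def as_dict(self) -> dict:
        return {
            "trial": self.trial_id,
            "region_lo": self.region[0],
            "region_hi": self.region[1],
            "ffd_ms": self.ffd_ms,
            "fprt_ms": self.fprt_ms,
            "tft_ms": self.tft_ms,
            "rpd_ms": self.rpd_ms,
            "skipped_first_pass": self.skipped_first_pass,
            "rpd_unterminated": self.rpd_unterminated,
        }


def particle_region(particle_index: int) -> tuple[int, int]:
    """Merged target span: the particle and the word immediately before it."""
    if particle_index < 2:
        raise FixationError("particle must have a preceding word (index >= 2)")
    return (particle_index - 1, particle_index)


def compute_region_measures(
    seq: FixationSequence,
    region: tuple[int, int] | int,
) -> RegionMeasures:
    """Apply the four measure definitions to one trial.

    ``region`` is an inclusive (lo, hi) span of 1-based region indices, or a
    single index.
    """
    if isinstance(region, int):
        region = (region, region)
    lo, hi = region
    if lo > hi or lo < 1:
        raise FixationError(f"invalid region span {region}")

    fixes = seq.fixations
    in_region = [lo <= r <= hi for r, _ in fixes]
    right_of = [r > hi for r, _ in fixes]

    tft = sum(d for (r, d), inside in zip(fixes, in_region) if inside)
    ever_fixated = any(in_region)

    # first first-pass entry: the first region fixation occurring before any
    # fixation to the right of the region
    first_right = next((i for i, flag in enumerate(right_of) if flag), None)
    first_entry = next((i for i, flag in enumerate(in_region) if flag), None)
    skipped = first_entry is None or (
        first_right is not None and first_right < first_entry
    )

    if not ever_fixated:
        return RegionMeasures(seq.trial_id, region, None, None, None, None,
                              skipped_first_pass=True)
    if skipped:
        return RegionMeasures(seq.trial_id, region, None, None, tft, None,
                              skipped_first_pass=True)

    ffd = fixes[first_entry][1]

    # first pass: sum durations from first_entry until the first fixation
    # outside the region in either direction
    fprt = 0.0
    for (r, d) in fixes[first_entry:]:
        if lo <= r <= hi:
            fprt += d
        else:
            break

    # go-past: sum from first_entry (inclusive) up to, but excluding, the
    # first fixation strictly right of the region
    rpd = 0.0
    unterminated = True
    for (r, d) in fixes[first_entry:]:
        if r > hi:
            unterminated = False
            break
        rpd += d

    return RegionMeasures(
        seq.trial_id,
        region,
        ffd_ms=ffd,
        fprt_ms=fprt,
        tft_ms=tft,
        rpd_ms=rpd,
        skipped_first_pass=False,
        rpd_unterminated=unterminated,
    )


def exclude_invalid_trials(
    trials: Iterable[FixationSequence],
) -> tuple[list[FixationSequence], dict[str, int]]:
    """Drop trials flagged for blinks/track loss; return retained + counts."""
    retained: list[FixationSequence] = []
    log = {"blink/track loss": 0, "retained": 0}
    for t in trials:
        if t.blink_or_trackloss:
            log["blink/track loss"] += 1
        else:
            retained.append(t)
            log["retained"] += 1
    return retained, log


# ---------------------------------------------------------------------------
# Delimited I/O


def read_fixation_table(path) -> list[FixationSequence]:
    """Read a fixation CSV: trial, order, region, duration_ms, blink_flag."""
    df = pd.read_csv(path)
    required = {"trial", "order", "region", "duration_ms", "blink_flag"}
    if not required.issubset(df.columns):
        raise FixationError(
            f"fixation table must have columns {sorted(required)}"
        )
    out = []
    for trial, grp in df.groupby("trial", sort=True):
        grp = grp.sort_values("order")
        out.append(
            FixationSequence(
                trial_id=str(trial),
                fixations=[
                    (int(r), float(d))
                    for r, d in zip(grp["region"], grp["duration_ms"])
                ],
                blink_or_trackloss=bool(grp["blink_flag"].any()),
            )
        )
    return out


def measures_frame(measures: Sequence[RegionMeasures]) -> pd.DataFrame:
    """Tidy table of region measures, one row per trial x region."""
    return pd.DataFrame([m.as_dict() for m in measures])


def write_measures(measures: Sequence[RegionMeasures], path) -> None:
    measures_frame(measures).to_csv(path, index=False)
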