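"""Cloze-test statistics for verb-particle predictability.

A cloze test truncates each stimulus sentence just before the verb particle and
asks respondents to complete it.  The distribution of completions quantifies how
predictable the particle is: the *cloze probability* of a completion is the
proportion of respondents who produced it, and the Shannon entropy of the
completion distribution (in bits) measures overall uncertainty about the
particle's identity.  High entropy means many plausible particles, i.e. low
predictability.

This module turns raw completion tables into per-item/condition cloze
probabilities, target cloze, and entropy; summarizes them by condition (Beta
method-of-moments for cloze, bootstrap for entropy); performs median splits for
descriptive tables; and applies the item-selection rules used to screen stimuli
(a particle must always be elicited, and the large-set condition must elicit
more particle types than the small-set condition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SET_SIZES = ("small", "large")
DISTANCES = ("short", "long")
CONDITIONS = tuple((s, d) for s in SET_SIZES for d in DISTANCES)


class ClozeError(ValueError):
    """Invalid cloze input (empty response set, negative counts, bad values)."""


def normalize_completion(raw: str) -> str:
    """Canonicalize a completion string: strip, lowercase, first token only."""
    tokens = str(raw).strip().lower().split()
    return tokens[0] if tokens else ""


@dataclass
class ClozeResponseSet:
    """Completion counts for one item in one condition.

    ``completions`` maps completion string -> respondent count; ``is_particle``
    flags which completions are verb particles (an input judgement, not
    something this package infers from German morphology).
    """

    item_id: str
    set_size: str
    distance: str
    completions: Mapping[str, int]
    is_particle: Mapping[str, bool]
    n_respondents: int

    def __post_init__(self) -> None:
        if not self.completions:
            raise ClozeError(f"item {self.item_id}: empty response set")
        if self.set_size not in SET_SIZES or self.distance not in DISTANCES:
            raise ClozeError(
                f"item {self.item_id}: unknown condition "
                f"({self.set_size}, {self.distance})"
            )
        for comp, count in self.completions.items():
            if count < 1 or int(count) != count:
                raise ClozeError(
                    f"item {self.item_id}: count for {comp!r} must be a "
                    f"positive integer, got {count}"
                )
        total = sum(self.completions.values())
        if total > self.n_respondents:
            raise ClozeError(
                f"item {self.item_id}: counts sum to {total} > "
                f"n_respondents {self.n_respondents}"
            )


@dataclass
class ClozeStatistics:
    """Cloze probabilities, target cloze, and entropy for one item/condition."""

    item_id: str
    set_size: str
    distance: str
    probabilities: dict[str, float]
    target_particle: str
    target_cloze: float
    entropy_bits: float
    n_particle_types: int

    @property
    def condition(self) -> tuple[str, str]:
        return (self.set_size, self.distance)


def shannon_entropy_bits(probabilities: Iterable[float]) -> float:
    """H = -sum p_i log2 p_i, with 0 * log 0 taken as 0."""
    p = np.asarray(list(probabilities), dtype=float)
    if p.size == 0:
        return 0.0
    if np.any(p < 0):
        raise ClozeError("probabilities must be non-negative")
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def compute_cloze_statistics(
    responses: ClozeResponseSet,
    target: str,
    particle_only: bool = True,
) -> ClozeStatistics:
    """Normalize completion counts and compute target cloze and entropy.

    When ``particle_only`` is true (the default), the probability universe is
    restricted to completions flagged as particles; non-particle completions
    are dropped before normalization.  Entropy is in bits.  A target absent
    from the universe gets cloze 0.
    """
    target = normalize_completion(target)
    universe = {
        normalize_completion(comp): int(count)
        for comp, count in responses.completions.items()
        if not particle_only or responses.is_particle.get(comp, False)
    }
    universe = {c: n for c, n in universe.items() if n > 0}
    if not universe:
        raise ClozeError(
            f"item {responses.item_id}: no completions left in the chosen "
            f"universe (particle_only={particle_only})"
        )
    total = sum(universe.values())
    probs = {c: n / total for c, n in universe.items()}
    n_particle_types = sum(
        1
        for comp in responses.completions
        if responses.is_particle.get(comp, False)
    )
    return ClozeStatistics(
        item_id=responses.item_id,
        set_size=responses.set_size,
        distance=responses.distance,
        probabilities=probs,
        target_particle=target,
        target_cloze=probs.get(target, 0.0),
        entropy_bits=shannon_entropy_bits(probs.values()),
        n_particle_types=n_particle_types,
    )


@dataclass
class ConditionSummary:
    """Mean and 95% interval for cloze and entropy at one factor level."""

    level: str
    n_items: int
    cloze_mean: float
    cloze_ci: tuple[float, float]
    cloze_beta_shapes: tuple[float, float] | None
    entropy_mean: float
    entropy_ci: tuple[float, float]
    warnings: list[str] = field(default_factory=list)


def beta_method_of_moments(values: Sequence[float]) -> tuple[float, float]:
    """Fit Beta(a, b) to values in [0, 1] by matching mean and variance.

    With mean m and variance v, nu = m(1-m)/v - 1, a = m*nu, b = (1-m)*nu.
    Degenerate (zero-variance) input raises ClozeError; callers fall back to a
    point interval.
    """
    x = np.asarray(values, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ClozeError("cloze values must lie in [0, 1]")
    m = float(np.mean(x))
    v = float(np.var(x, ddof=0))
    if v <= 0 or m <= 0 or m >= 1:
        raise ClozeError("degenerate values: cannot fit a Beta distribution")
    nu = m * (1 - m) / v - 1
    if nu <= 0:
        raise ClozeError("variance too large for a Beta fit at this mean")
    return (m * nu, (1 - m) * nu)


def summarize_condition(
    stats_collection: Iterable[ClozeStatistics],
    level: str,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> ConditionSummary:
    """Summarize target cloze and entropy across items at one factor level.

    ``level`` is one of small/large/short/long.  Cloze: a Beta distribution is
    fitted to the per-item target-cloze values by method of moments and its
    mean and 2.5%/97.5% quantiles reported.  Entropy: the mean of per-item
    entropies with a nonparametric bootstrap 95% percentile interval.
    """
    if level in SET_SIZES:
        items = [s for s in stats_collection if s.set_size == level]
    elif level in DISTANCES:
        items = [s for s in stats_collection if s.distance == level]
    else:
        raise ClozeError(f"unknown factor level {level!r}")
    if len(items) < 2:
        raise ClozeError(f"need >= 2 items at level {level!r}, got {len(items)}")

    cloze = np.array([s.target_cloze for s in items])
    entropy = np.array([s.entropy_bits for s in items])
    warns: list[str] = []

    shapes: tuple[float, float] | None
    try:
        shapes = beta_method_of_moments(cloze)
        dist = stats.beta(*shapes)
        cloze_ci = (float(dist.ppf(0.025)), float(dist.ppf(0.975)))
    except ClozeError:
        shapes = None
        cloze_ci = (float(np.mean(cloze)), float(np.mean(cloze)))
        warns.append("cloze values degenerate; CI collapsed to the mean")
        warnings.warn(warns[-1], stacklevel=2)

    if np.ptp(entropy) == 0:
        entropy_ci = (float(entropy[0]), float(entropy[0]))
        warns.append("entropy values degenerate; CI collapsed to the mean")
        warnings.warn(warns[-1], stacklevel=2)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(entropy), size=(n_boot, len(entropy)))
        boot_means = entropy[idx].mean(axis=1)
        entropy_ci = (
            float(np.percentile(boot_means, 2.5)),
            float(np.percentile(boot_means, 97.5)),
        )

    return ConditionSummary(
        level=level,
        n_items=len(items),
        cloze_mean=float(np.mean(cloze)),
        cloze_ci=cloze_ci,
        cloze_beta_shapes=shapes,
        entropy_mean=float(np.mean(entropy)),
        entropy_ci=entropy_ci,
        warnings=warns,
    )


def median_split(values: Mapping[object, float]) -> dict[object, str]:
    """Label values strictly below the median "low", strictly above "high".

    Ties at the median are assigned "low" (deterministic convention).  With an
    even number of distinct values the split is exactly half/half.
    """
    if not values:
        raise ClozeError("median_split: empty input")
    vals = np.array(list(values.values()), dtype=float)
    med = float(np.median(vals))
    if np.ptp(vals) == 0:
        warnings.warn("median_split: all values tied; everything labelled low",
                      stacklevel=2)
    return {k: ("high" if v > med else "low") for k, v in values.items()}


@dataclass
class ItemSelectionResult:
    retained: list[str]
    reasons: dict[str, str]  # item_id -> "retained" or rejection reason


def select_items(
    stats_by_item: Mapping[str, Sequence[ClozeStatistics]],
) -> ItemSelectionResult:
    """Apply the stimulus screening rules across the four conditions.

    An item is retained iff (a) every condition elicited at least one particle
    completion and (b) within each distance level, the large-set condition
    elicited strictly more particle types than the small-set condition.  Items
    missing a condition are skipped with a logged reason.
    """
    retained: list[str] = []
    reasons: dict[str, str] = {}
    for item_id, stats_list in stats_by_item.items():
        by_cond = {s.condition: s for s in stats_list}
        missing = [c for c in CONDITIONS if c not in by_cond]
        if missing:
            reasons[item_id] = f"missing condition(s): {missing}"
            continue
        if any(s.n_particle_types < 1 for s in by_cond.values()):
            reasons[item_id] = "no particle elicited in at least one condition"
            continue
        ok = all(
            by_cond[("large", d)].n_particle_types
            > by_cond[("small", d)].n_particle_types
            for d in DISTANCES
        )
        if not ok:
            reasons[item_id] = (
                "large set did not elicit more particle types than small set"
            )
            continue
        retained.append(item_id)
        reasons[item_id] = "retained"
    return ItemSelectionResult(retained=retained, reasons=reasons)


# ---------------------------------------------------------------------------
# Delimited I/O


def read_cloze_table(path) -> list[ClozeResponseSet]:
    """Read a UTF-8 CSV of raw cloze responses.

    Columns: item, set_size, distance, respondent, completion, is_particle.
    One row per respondent; rows are aggregated into counts per
    item x condition.
    """
    df = pd.read_csv(path, dtype={"item": str, "completion": str})
    required = {"item", "set_size", "distance", "respondent", "completion",
                "is_particle"}
    if not required.issubset(df.columns):
        raise ClozeError(f"cloze table must have columns {sorted(required)}")
    out: list[ClozeResponseSet] = []
    for (item, ss, dist), grp in df.groupby(["item", "set_size", "distance"],
                                            sort=True):
        comps = grp["completion"].map(normalize_completion)
        counts = comps.value_counts().to_dict()
        flags = dict(zip(comps, grp["is_particle"].astype(bool)))
        out.append(
            ClozeResponseSet(
                item_id=str(item),
                set_size=str(ss),
                distance=str(dist),
                completions=counts,
                is_particle=flags,
                n_respondents=int(grp["respondent"].nunique()),
            )
        )
    return out


def write_summary_table(summaries: Sequence[ConditionSummary], path) -> None:
    """Write condition summaries as CSV (one row per factor level)."""
    rows = [
        {
            "condition": s.level,
            "n_items": s.n_items,
            "cloze_mean": s.cloze_mean,
            "cloze_ci_low": s.cloze_ci[0],
            "cloze_ci_high": s.cloze_ci[1],
            "entropy_mean": s.entropy_mean,
            "entropy_ci_low": s.entropy_ci[0],
            "entropy_ci_high": s.entropy_ci[1],
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
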