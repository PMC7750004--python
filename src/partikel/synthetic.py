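"""Synthetic experiment generator.

Emulates the statistical structure of a 2x2 (particle set size x verb-particle
distance) Latin-square reading experiment: 60 participants x 24 items (6 trials
per condition per participant) with 72 fillers; a cloze-norming study (48
items, 63 fillers, 111 sentences per list); reciprocal-normal self-paced
reading times with crossed participant/item random effects; compositional
lognormal eye-tracking measures that obey the containment relations
FFD <= FPRT <= TFT and FPRT <= RPD by construction; multinomial cloze
completions over small (<= 6) vs large (>= 10) particle inventories; and
~92-97% comprehension accuracy.

Per-item entropy is drawn from two overlapping components (small-set mean 1.10
bits, large-set mean 1.20 bits) so that both set-size categories contain high-
and low-entropy items — the configuration that motivates re-analysing entropy
as a continuous predictor rather than relying on the categorical set-size
proxy.

Everything is driven by one seeded ``numpy`` generator; defaults are the study
conditions, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cloze import ClozeResponseSet
from .eyemeasures import FixationSequence

CONDITION_ORDER = [
    ("small", "short"),
    ("small", "long"),
    ("large", "short"),
    ("large", "long"),
]

#: 1-based index of the particle in the abstract 9-word sentence emitted by the
#: fixation-sequence generator; the analysis region is the span (5, 6).
PARTICLE_INDEX = 6


class DesignError(ValueError):
    """Invalid design or generative configuration."""


@dataclass
class ExperimentDesign:
    n_participants: int = 60
    n_items: int = 24
    n_fillers: int = 72
    n_lists: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items % len(CONDITION_ORDER) != 0:
            raise DesignError(
                f"n_items ({self.n_items}) must be divisible by the "
                f"{len(CONDITION_ORDER)} conditions"
            )


def build_latin_square(design: ExperimentDesign) -> pd.DataFrame:
    """Assign items to conditions in four counterbalanced lists.

    Item i in list l receives condition (i + l) mod 4, so across the four
    lists every item appears in all four conditions and within a list each
    condition occurs n_items/4 times.  Participants rotate through lists.
    Filler rows are interleaved at seeded random positions per participant.

    Returns a tidy frame: participant, list, trial_index, item, set_size,
    distance, is_filler.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for p in range(design.n_participants):
        lst = p % design.n_lists
        trials = []
        for i in range(design.n_items):
            ss, dist = CONDITION_ORDER[(i + lst) % len(CONDITION_ORDER)]
            trials.append((f"i{i + 1:02d}", ss, dist, False))
        for f in range(design.n_fillers):
            trials.append((f"f{f + 1:02d}", "", "", True))
        order = rng.permutation(len(trials))
        for pos, idx in enumerate(order):
            item, ss, dist, filler = trials[idx]
            rows.append(
                {
                    "participant": f"p{p + 1:02d}",
                    "list": lst + 1,
                    "trial_index": pos + 1,
                    "item": item,
                    "set_size": ss,
                    "distance": dist,
                    "is_filler": filler,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GenerativeParams:
    """Generating parameters on the transformed (analysis) scale.

    ``scale`` selects the response family: ``reciprocal_speed`` generates
    self-paced reading times as rt = 1000/speed with speed Gaussian on the
    words-per-second scale; ``log_ms`` generates eye-tracking first fixation
    durations as lognormal and builds the remaining measures compositionally.

    Fixed-effect defaults mirror the magnitudes the experiments were designed
    around (speed intercept 2.5 words/s; log-duration intercept 5.66 ~ 287 ms;
    small +-0.5-coded condition effects).  Random-effect SDs are given per
    coefficient (intercept, set size, distance, interaction) for participants
    and items; correlations between random effects are zero in the generator.
    """

    scale: Literal["reciprocal_speed", "log_ms"] = "reciprocal_speed"
    intercept: float = 2.5
    effect_set_size: float = 0.07
    effect_distance: float = -0.02
    effect_interaction: float = 0.02
    entropy_slope: float = 0.0
    entropy_as_predictor: bool = False
    participant_sds: tuple[float, float, float, float] = (0.3, 0.05, 0.05, 0.05)
    item_sds: tuple[float, float, float, float] = (0.1, 0.03, 0.03, 0.03)
    residual_sd: float = 0.5
    # per-item entropy mixture (bits), overlapping across set-size categories
    entropy_small_mean: float = 1.10
    entropy_large_mean: float = 1.20
    entropy_sd: float = 0.35
    accuracy: float = 0.94
    question_rt_log_mean: float = 7.6  # ~2000 ms
    question_rt_log_sd: float = 0.25
    # self-paced reading only: fraction of trials replaced by <100 ms presses
    sub100_fraction: float = 0.01
    # eye tracking only: probabilities and lognormal(log mean, sd) increments
    p_refix: float = 0.15
    refix_log_mean: float = 5.08  # ~160 ms
    refix_log_sd: float = 0.4
    p_reread: float = 0.25
    reread_log_mean: float = 5.19  # ~180 ms
    reread_log_sd: float = 0.5
    p_regress: float = 0.20
    regress_log_mean: float = 5.19
    regress_log_sd: float = 0.5
    blink_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_refix", "p_reread", "p_regress", "blink_rate",
                     "accuracy", "sub100_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise DesignError(f"{name} must be in [0, 1], got {v}")
        if self.residual_sd <= 0:
            raise DesignError("residual_sd must be positive")
        if any(s < 0 for s in self.participant_sds + self.item_sds):
            raise DesignError("random-effect SDs must be non-negative")

    @classmethod
    def spr_defaults(cls, **overrides) -> "GenerativeParams":
        return cls(scale="reciprocal_speed", **overrides)

    @classmethod
    def et_defaults(cls, **overrides) -> "GenerativeParams":
        base = dict(
            scale="log_ms",
            intercept=5.66,
            effect_set_size=0.02,
            effect_distance=0.01,
            effect_interaction=0.01,
            participant_sds=(0.15, 0.02, 0.02, 0.02),
            item_sds=(0.08, 0.02, 0.02, 0.02),
            residual_sd=0.25,
            sub100_fraction=0.0,
        )
        base.update(overrides)
        return cls(**base)


def _contrast(level: str, positive: str) -> float:
    return 0.5 if level == positive else -0.5


def draw_item_entropies(
    design: ExperimentDesign, params: GenerativeParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per item x set-size entropy values from two overlapping components."""
    rows = []
    for i in range(design.n_items):
        for ss, mu in (("small", params.entropy_small_mean),
                       ("large", params.entropy_large_mean)):
            h = -1.0
            while h < 0:
                h = rng.normal(mu, params.entropy_sd)
            rows.append({"item": f"i{i + 1:02d}", "set_size": ss,
                         "entropy_bits": h})
    return pd.DataFrame(rows)


def _linear_predictor(
    df: pd.DataFrame, params: GenerativeParams, rng: np.random.Generator
) -> np.ndarray:
    """Transformed-scale mean per trial: fixed effects + crossed random effects."""
    c_ss = df["set_size"].map(lambda s: _contrast(s, "large")).to_numpy()
    c_d = df["distance"].map(lambda s: _contrast(s, "long")).to_numpy()
    if params.entropy_as_predictor:
        h = df["entropy_bits"].to_numpy()
        x1 = h - h.mean()
        slope1 = params.entropy_slope
    else:
        x1 = c_ss
        slope1 = params.effect_set_size
    design_cols = np.column_stack(
        [np.ones(len(df)), x1, c_d, x1 * c_d]
    )
    beta = np.array([params.intercept, slope1, params.effect_distance,
                     params.effect_interaction])

    participants = pd.Categorical(df["participant"])
    items = pd.Categorical(df["item"])
    u = rng.normal(0.0, params.participant_sds,
                   size=(len(participants.categories), 4))
    w = rng.normal(0.0, params.item_sds, size=(len(items.categories), 4))
    re_part = np.einsum("nj,nj->n", design_cols, u[participants.codes])
    re_item = np.einsum("nj,nj->n", design_cols, w[items.codes])
    return design_cols @ beta + re_part + re_item


def _target_trials(design: ExperimentDesign, params: GenerativeParams,
                   rng: np.random.Generator) -> pd.DataFrame:
    assignments = build_latin_square(
        replace(design, seed=int(rng.integers(2**31)))
    )
    df = assignments[~assignments["is_filler"]].copy()
    entropies = draw_item_entropies(design, params, rng)
    df = df.merge(entropies, on=["item", "set_size"], how="left")
    return df.reset_index(drop=True)


def generate_spr_trials(
    design: ExperimentDesign, params: GenerativeParams
) -> pd.DataFrame:
    """Self-paced reading trials at the particle: rt_ms = 1000 / speed.

    Speed (words/s) is Gaussian on the reciprocal scale with crossed random
    effects; draws with speed <= 0.1 are resampled (guards against negative
    reading times).  A configured fraction of trials is replaced by uniform
    30-99 ms presses so the < 100 ms exclusion rule has work to do.
    Comprehension accuracy is Bernoulli per trial.
    """
    if params.scale != "reciprocal_speed":
        raise DesignError("generate_spr_trials requires scale='reciprocal_speed'")
    rng = np.random.default_rng(params.seed)
    df = _target_trials(design, params, rng)
    mu = _linear_predictor(df, params, rng)
    speed = rng.normal(mu, params.residual_sd)
    bad = speed <= 0.1
    while bad.any():
        speed[bad] = rng.normal(mu[bad], params.residual_sd)
        bad = speed <= 0.1
    rt = 1000.0 / speed
    contaminated = rng.random(len(df)) < params.sub100_fraction
    rt[contaminated] = rng.uniform(30.0, 99.0, size=int(contaminated.sum()))
    df["rt_ms"] = rt
    df["question_correct"] = rng.random(len(df)) < params.accuracy
    df["question_rt_ms"] = np.exp(
        rng.normal(params.question_rt_log_mean, params.question_rt_log_sd,
                   size=len(df))
    )
    df["seed"] = params.seed
    return df


def generate_et_trials(
    design: ExperimentDesign,
    params: GenerativeParams,
    *,
    emit_fixations: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[FixationSequence]]:
    """Eye-tracking measures built compositionally from a lognormal FFD.

    FFD = exp(Gaussian linear predictor on the log-ms scale);
    FPRT = FFD + refixation time (probability ``p_refix``);
    TFT  = FPRT + re-reading time (probability ``p_reread``);
    RPD  = FPRT + regression time (probability ``p_regress``).
    Containment (FFD <= FPRT <= TFT, FPRT <= RPD) therefore holds by
    construction.  With ``emit_fixations`` the function additionally returns
    full fixation sequences whose recomputed measures equal the emitted ones
    exactly, for end-to-end testing of the measure definitions.  Blink/track
    loss flags are planted at ``blink_rate``.
    """
    if params.scale != "log_ms":
        raise DesignError("generate_et_trials requires scale='log_ms'")
    rng = np.random.default_rng(params.seed)
    df = _target_trials(design, params, rng)
    n = len(df)
    mu = _linear_predictor(df, params, rng)
    ffd = np.exp(rng.normal(mu, params.residual_sd))

    def increment(p: float, log_mean: float, log_sd: float) -> np.ndarray:
        on = rng.random(n) < p
        return np.where(on, np.exp(rng.normal(log_mean, log_sd, size=n)), 0.0)

    refix = increment(params.p_refix, params.refix_log_mean, params.refix_log_sd)
    reread = increment(params.p_reread, params.reread_log_mean,
                       params.reread_log_sd)
    regress = increment(params.p_regress, params.regress_log_mean,
                        params.regress_log_sd)

    df["ffd_ms"] = ffd
    df["fprt_ms"] = ffd + refix
    df["tft_ms"] = df["fprt_ms"] + reread
    df["rpd_ms"] = df["fprt_ms"] + regress
    df["blink_or_trackloss"] = rng.random(n) < params.blink_rate
    df["question_correct"] = rng.random(n) < params.accuracy
    df["question_rt_ms"] = np.exp(
        rng.normal(params.question_rt_log_mean, params.question_rt_log_sd,
                   size=n)
    )
    df["seed"] = params.seed
    if not emit_fixations:
        return df

    sequences = [
        _emit_sequence(row, rng)
        for row in df.itertuples(index=False)
    ]
    df["trial"] = [s.trial_id for s in sequences]
    return df, sequences


def _emit_sequence(row, rng: np.random.Generator) -> FixationSequence:
    """Build one fixation sequence realizing the row's four measures exactly.

    Layout over an abstract 9-word sentence with the target span (5, 6):
    first-pass fixations on regions 1-4, entry into the span (FFD, optional
    refixation), an optional regression to region 3 (the regression-time
    increment), exit to region 7 (terminates the go-past region), an optional
    later re-reading fixation in the span (the re-reading increment), and a
    final fixation on region 8.
    """
    span_lo = PARTICLE_INDEX - 1
    pre = [(r, float(np.round(rng.uniform(150, 300), 1))) for r in range(1, 5)]
    ffd = float(row.ffd_ms)
    refix = float(row.fprt_ms) - ffd
    regress = float(row.rpd_ms) - float(row.fprt_ms)
    reread = float(row.tft_ms) - float(row.fprt_ms)
    fixes = list(pre)
    fixes.append((span_lo, ffd))
    if refix > 0:
        fixes.append((PARTICLE_INDEX, refix))
    if regress > 0:
        fixes.append((3, regress))
    fixes.append((PARTICLE_INDEX + 1, float(np.round(rng.uniform(150, 300), 1))))
    if reread > 0:
        fixes.append((span_lo, reread))
    fixes.append((PARTICLE_INDEX + 2, float(np.round(rng.uniform(150, 300), 1))))
    return FixationSequence(
        trial_id=f"{row.participant}:{row.item}",
        fixations=fixes,
        blink_or_trackloss=bool(row.blink_or_trackloss),
    )


# ---------------------------------------------------------------------------
# Cloze generation


@dataclass
class ClozeGenConfig:
    """Configuration of the synthetic cloze-norming study.

    The real norming study used 48 candidate items, 63 fillers and 126
    respondents split over four lists (~31 respondents per item x condition).
    ``concentration`` is the symmetric Dirichlet parameter over each particle
    inventory: small values concentrate mass on one particle (low entropy),
    large values approach uniform (entropy -> log2 of the inventory size).
    """

    n_items: int = 48
    n_fillers: int = 63
    n_respondents: int = 31
    small_inventory: int = 4   # must be <= 6
    large_inventory: int = 12  # must be >= 10
    concentration_small: float = 0.5
    concentration_large: float = 0.5
    nonparticle_rate: float = 0.05
    #: fraction of items whose designated target is not the modal particle
    nonmodal_target_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.small_inventory > 6:
            raise DesignError("small-set inventory must be <= 6 particles")
        if self.large_inventory < 10:
            raise DesignError("large-set inventory must be >= 10 particles")

    @property
    def sentences_per_list(self) -> int:
        """Targets (one condition of every item) plus fillers per list."""
        return self.n_items + self.n_fillers


def generate_cloze_responses(
    cfg: ClozeGenConfig,
    *,
    planted_fail_items: Sequence[int] = (),
) -> tuple[list[ClozeResponseSet], dict[str, str]]:
    """Draw multinomial completion counts per item x condition.

    Probabilities over the condition's particle inventory are Dirichlet
    distributed; non-particle completions occur at ``nonparticle_rate``.  Items
    listed in ``planted_fail_items`` are constructed to fail the selection
    rules with certainty: their large-set conditions elicit exactly one
    particle type, so the large > small type-count rule can never hold.  This
    gives exact ground truth for select_items tests.

    Returns the response sets and a map item_id -> designated target particle.
    """
    rng = np.random.default_rng(cfg.seed)
    particles_small = [f"ps{k}" for k in range(cfg.small_inventory)]
    particles_large = [f"pl{k}" for k in range(cfg.large_inventory)]
    out: list[ClozeResponseSet] = []
    targets: dict[str, str] = {}
    fail = set(planted_fail_items)
    for i in range(cfg.n_items):
        item_id = f"c{i + 1:02d}"
        item_counts: dict[tuple[str, str], dict[str, int]] = {}
        for ss, dist in CONDITION_ORDER:
            if ss == "small":
                inventory = particles_small
                conc = cfg.concentration_small
            elif i in fail:
                inventory = particles_small[:1]
                conc = cfg.concentration_large
            else:
                inventory = particles_large
                conc = cfg.concentration_large
            probs = rng.dirichlet(np.full(len(inventory), conc))
            n_particle = int(
                rng.binomial(cfg.n_respondents, 1 - cfg.nonparticle_rate)
            )
            n_particle = max(n_particle, 1)
            counts = rng.multinomial(n_particle, probs)
            completions = {
                p: int(c) for p, c in zip(inventory, counts) if c > 0
            }
            n_other = cfg.n_respondents - n_particle
            if n_other > 0:
                completions["dergarten"] = n_other  # non-particle noun filler
            item_counts[(ss, dist)] = completions
            is_particle = {c: not c.startswith("derg") for c in completions}
            out.append(
                ClozeResponseSet(
                    item_id=item_id,
                    set_size=ss,
                    distance=dist,
                    completions=completions,
                    is_particle=is_particle,
                    n_respondents=cfg.n_respondents,
                )
            )
        # designated target: modal small-set particle, or deliberately the
        # second-ranked one for a configured fraction of items
        small_counts: dict[str, int] = {}
        for d in ("short", "long"):
            for p, c in item_counts[("small", d)].items():
                if not p.startswith("derg"):
                    small_counts[p] = small_counts.get(p, 0) + c
        ranked = sorted(small_counts, key=small_counts.get, reverse=True)
        nonmodal = rng.random() < cfg.nonmodal_target_rate and len(ranked) > 1
        targets[item_id] = ranked[1] if nonmodal else ranked[0]
    return out, targets


# ---------------------------------------------------------------------------
# CSV writers matching the reader schemas


def write_spr_table(trials: pd.DataFrame, path) -> None:
    cols = ["participant", "item", "set_size", "distance", "entropy_bits",
            "rt_ms", "question_correct", "question_rt_ms", "seed"]
    trials[cols].to_csv(path, index=False)


def write_fixation_table(sequences: Sequence[FixationSequence], path) -> None:
    rows = []
    for seq in sequences:
        for order, (region, dur) in enumerate(seq.fixations, start=1):
            rows.append(
                {
                    "trial": seq.trial_id,
                    "order": order,
                    "region": region,
                    "duration_ms": dur,
                    "blink_flag": seq.blink_or_trackloss,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_design_table(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, index=False)


def write_cloze_table(
    responses: Sequence[ClozeResponseSet], path
) -> None:
    """Expand counts back to one row per respondent (the reader's schema)."""
    rows = []
    for rs in responses:
        respondent = 0
        for comp, count in rs.completions.items():
            for _ in range(count):
                respondent += 1
                rows.append(
                    {
                        "item": rs.item_id,
                        "set_size": rs.set_size,
                        "distance": rs.distance,
                        "respondent": f"r{respondent:03d}",
                        "completion": comp,
                        "is_particle": rs.is_particle.get(comp, False),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
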