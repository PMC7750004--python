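"""Activation-decay predictions for a delayed verb particle.

The simulator formalizes the locality prediction: when a base verb is read, all
of its plausible particles are pre-activated from a finite pool of spreading
activation W.  With n candidate particles each receives W/n, so a small set
(high predictability) means a higher starting activation per particle.  The
base-level activation of a particle then decays as a power function of the time
t elapsed since pre-activation (ACT-R style), and retrieval latency at the
particle is an exponential function of its activation at retrieval:

    A(n, t) = ln(t^-d) + W/n          (decayed base level + pool share)
    T(n, t) = F * exp(-A) = F * t^d * exp(-W/n)

With decay rate d > 0 latency grows with the verb-particle distance, and the
growth is steeper for large particle sets — the crossing 2x2 pattern in which a
distance (locality) cost appears mainly when predictability is low.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class DecayConfigError(ValueError):
    """Invalid decay-simulator configuration or arguments."""


@dataclass
class DecayConfig:
    """Parameters of the decay simulator.

    pool_w       activation units shared among the n candidate particles
    decay_rate   ACT-R decay exponent d in (0, 1]; 0.5 is the conventional value
    latency_factor_ms  F, scales activation to milliseconds
    t_short, t_long    seconds elapsed between pre-activation and the particle
                       in the short and long distance conditions
    noise_sd     SD of Gaussian noise added to activation (0 = deterministic)

    The distance manipulation is in words; ``times_from_words`` maps a word
    count to seconds as t = t0 + words * seconds_per_word.
    """

    pool_w: float = 1.0
    decay_rate: float = 0.5
    latency_factor_ms: float = 200.0
    t_short: float = 0.8
    t_long: float = 1.6
    noise_sd: float = 0.0
    t0: float = 0.4
    seconds_per_word: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.decay_rate <= 1):
            raise DecayConfigError("decay_rate must be in (0, 1]")
        if self.latency_factor_ms <= 0:
            raise DecayConfigError("latency_factor_ms must be positive")
        if self.pool_w < 0:
            raise DecayConfigError("pool_w must be non-negative")
        if self.noise_sd < 0:
            raise DecayConfigError("noise_sd must be non-negative")
        if not (self.t_long > self.t_short > 0):
            if self.t_short <= 0:
                raise DecayConfigError("t_short must be positive")
            # t_long == t_short is tolerated with a warning (degenerate design)
            if self.t_long < self.t_short:
                raise DecayConfigError("t_long must be >= t_short")

    def times_from_words(self, words_short: int, words_long: int) -> "DecayConfig":
        """Return a config with t_short/t_long derived from intervening words."""
        return replace(
            self,
            t_short=self.t0 + words_short * self.seconds_per_word,
            t_long=self.t0 + words_long * self.seconds_per_word,
        )


def activation(n: int, cfg: DecayConfig, t: float) -> float:
    """A(n, t) = ln(t^-d) + W/n."""
    if n < 1 or int(n) != n:
        raise DecayConfigError(f"set size n must be a positive integer, got {n}")
    if t <= 0:
        raise DecayConfigError(f"elapsed time t must be positive, got {t}")
    return math.log(t ** (-cfg.decay_rate)) + cfg.pool_w / n


def predict_latency(
    n: int,
    cfg: DecayConfig,
    t: float,
    *,
    rng: np.random.Generator | None = None,
) -> float:
    """Retrieval latency in ms: F * exp(-A(n, t)).

    With ``noise_sd`` > 0 a Gaussian perturbation is added to the activation
    before the latency mapping; pass ``rng`` for reproducibility.
    """
    a = activation(n, cfg, t)
    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        a = a + rng.normal(0.0, cfg.noise_sd)
    return cfg.latency_factor_ms * math.exp(-a)


@dataclass
class PredictedLatencies:
    """Predicted mean latency (ms) per 2x2 cell plus the derived contrasts."""

    small_short: float
    small_long: float
    large_short: float
    large_long: float
    set_size_effect_short: float = field(init=False)
    set_size_effect_long: float = field(init=False)
    distance_effect_small: float = field(init=False)
    distance_effect_large: float = field(init=False)
    interaction: float = field(init=False)

    def __post_init__(self) -> None:
        self.set_size_effect_short = self.large_short - self.small_short
        self.set_size_effect_long = self.large_long - self.small_long
        self.distance_effect_small = self.small_long - self.small_short
        self.distance_effect_large = self.large_long - self.large_short
        # difference of distance effects: > 0 means the locality slow-down is
        # larger for the large (low-predictability) set
        self.interaction = self.distance_effect_large - self.distance_effect_small

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("small", "short", self.small_short),
            ("small", "long", self.small_long),
            ("large", "short", self.large_short),
            ("large", "long", self.large_long),
        ]
        return pd.DataFrame(rows, columns=["set_size", "distance", "latency_ms"])


def predict_design(
    cfg: DecayConfig,
    n_small: int,
    n_large: int,
    *,
    n_noise_reps: int = 0,
    rng: np.random.Generator | None = None,
) -> PredictedLatencies:
    """Fill the 2x2 design with predicted latencies and compute contrasts.

    Deterministic when noise is off; with ``noise_sd`` > 0 and
    ``n_noise_reps`` > 0, each cell is the mean of that many noisy replicates.
    """
    if not n_small < n_large:
        raise DecayConfigError("n_small must be < n_large")
    if cfg.t_short == cfg.t_long:
        warnings.warn(
            "degenerate design: t_short == t_long, distance effects are zero",
            stacklevel=2,
        )

    def cell(n: int, t: float) -> float:
        if cfg.noise_sd > 0 and n_noise_reps > 0:
            vals = [predict_latency(n, cfg, t, rng=rng) for _ in range(n_noise_reps)]
            return float(np.mean(vals))
        noiseless = replace(cfg, noise_sd=0.0)
        return predict_latency(n, noiseless, t)

    return PredictedLatencies(
        small_short=cell(n_small, cfg.t_short),
        small_long=cell(n_small, cfg.t_long),
        large_short=cell(n_large, cfg.t_short),
        large_long=cell(n_large, cfg.t_long),
    )


def closed_form_latency(n: int, cfg: DecayConfig, t: float) -> float:
    """Algebraic form T = F * t^d * exp(-W/n); oracle for predict_latency."""
    return cfg.latency_factor_ms * t ** cfg.decay_rate * math.exp(-cfg.pool_w / n)


def write_prediction_table(pred: PredictedLatencies, path) -> None:
    pred.to_frame().to_csv(path, index=False)


def plot_predictions(pred: PredictedLatencies, path=None):
    """Two-line interaction plot of the 2x2 predicted latencies."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(["short", "long"], [pred.small_short, pred.small_long],
            marker="o", label="small set (predictable)")
    ax.plot(["short", "long"], [pred.large_short, pred.large_long],
            marker="s", label="large set (unpredictable)")
    ax.set_xlabel("distance")
    ax.set_ylabel("predicted latency (ms)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
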