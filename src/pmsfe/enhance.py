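"""Per-trial feature enhancement of spectral band powers.

Each trial contributes 192 values (theta/alpha/beta x 64 electrodes). The
enhancement first squashes every value through a fixed-slope logistic
sigmoid, sigma(A) = 1 / (1 + exp(-0.15 * A)), which tempers the squared-
magnitude scale of band powers, then min-max rescales the 192 squashed
values of that trial jointly to [0, 1]. The result makes the within-trial
topographic structure occupy the full dynamic range regardless of the
trial's absolute power scale.

The transform has an equivalent single-expression closed form

    A' = (e^{-s*minA} - e^{-s*A}) * (1 + e^{-s*maxA})
         -----------------------------------------------
         (e^{-s*minA} - e^{-s*maxA}) * (1 + e^{-s*A})

with s the slope and min/max taken over the trial's raw values; it is kept
here as a verification oracle (evaluated in log space for stability) while
the production path is the explicit sigmoid -> min-max composition. Reading
the published closed form with min/max applied to -s*A instead yields the
reversed map 1 - A' (maximum -> 0); that variant is available via
``literal_eq9`` for comparison.

A degenerate trial - all 192 values equal within tolerance - has no range
to rescale; it maps to 0.5 everywhere and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .spectral import BandPowerSet

__all__ = [
    "EnhancementConfig",
    "SquashedBandSet",
    "TrialExtremes",
    "EnhancedBandSet",
    "sigmoid_squash",
    "squash_band_set",
    "trial_extremes",
    "minmax_rescale",
    "enhance",
    "enhance_closed_form",
]

#: fixed sigmoid slope of the enhancement transform
DEFAULT_SLOPE = 0.15


@dataclass(frozen=True)
class EnhancementConfig:
    """Parameters of the enhancement transform.

    slope
        Sigmoid steepness s in sigma(A) = 1/(1 + exp(-s*A)); default 0.15.
    epsilon_degenerate
        If the squashed per-trial range max* - min* is <= this, the trial is
        treated as constant (degenerate) and mapped to all-0.5.
    literal_eq9
        Use the reversed closed-form reading (min -> 1, max -> 0). Off by
        default; see module docstring.
    """

    slope: float = DEFAULT_SLOPE
    epsilon_degenerate: float = 1e-12
    literal_eq9: bool = False

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.epsilon_degenerate < 0:
            raise ValueError("epsilon_degenerate must be >= 0")


@dataclass
class SquashedBandSet:
    """Sigmoid-squashed band vectors of one trial; every entry in (0, 1)."""

    theta_s: np.ndarray
    alpha_s: np.ndarray
    beta_s: np.ndarray
    trial_id: int

    def values(self) -> np.ndarray:
        return np.concatenate([self.theta_s, self.alpha_s, self.beta_s])


@dataclass(frozen=True)
class TrialExtremes:
    """Joint max and min of a trial's squashed values across all three bands."""

    max_star: float
    min_star: float

    def __post_init__(self) -> None:
        if self.min_star > self.max_star:
            raise ValueError("min_star must be <= max_star")


@dataclass
class EnhancedBandSet:
    """Enhanced band vectors of one trial; entries in [0, 1].

    For a non-degenerate trial at least one entry is exactly 0 (the trial
    minimum) and one exactly 1 (the trial maximum). ``degenerate`` marks
    constant trials that were mapped to all-0.5.
    """

    theta_e: np.ndarray
    alpha_e: np.ndarray
    beta_e: np.ndarray
    trial_id: int
    degenerate: bool = False

    def stacked(self) -> np.ndarray:
        return np.stack([self.theta_e, self.alpha_e, self.beta_e])

    def values(self) -> np.ndarray:
        return self.stacked().ravel()


def sigmoid_squash(values: np.ndarray, cfg: EnhancementConfig = EnhancementConfig()) -> np.ndarray:
    """Elementwise logistic squash 1/(1 + exp(-slope * A)) into (0, 1)."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("sigmoid_squash requires finite inputs")
    return expit(cfg.slope * values)


def squash_band_set(raw: BandPowerSet, cfg: EnhancementConfig = EnhancementConfig()) -> SquashedBandSet:
    return SquashedBandSet(
        theta_s=sigmoid_squash(raw.theta, cfg),
        alpha_s=sigmoid_squash(raw.alpha, cfg),
        beta_s=sigmoid_squash(raw.beta, cfg),
        trial_id=raw.trial_id,
    )


def trial_extremes(s: SquashedBandSet) -> TrialExtremes:
    """Max and min over the concatenation of the trial's three band vectors."""
    v = s.values()
    if not np.all(np.isfinite(v)):
        raise ValueError("trial_extremes requires finite inputs")
    return TrialExtremes(max_star=float(np.max(v)), min_star=float(np.min(v)))


def minmax_rescale(
    s: SquashedBandSet,
    ext: TrialExtremes,
    eps: float = 1e-12,
) -> EnhancedBandSet:
    """Joint min-max rescale of the trial's squashed values to [0, 1].

    A trial whose range max* - min* is <= ``eps`` is degenerate: all outputs
    are 0.5 and the result is flagged (not an error), so downstream maps
    remain valid images.
    """
    span = ext.max_star - ext.min_star
    if span <= eps:
        half = np.full_like(s.theta_s, 0.5)
        return EnhancedBandSet(
            theta_e=half.copy(),
            alpha_e=half.copy(),
            beta_e=half.copy(),
            trial_id=s.trial_id,
            degenerate=True,
        )
    return EnhancedBandSet(
        theta_e=(s.theta_s - ext.min_star) / span,
        alpha_e=(s.alpha_s - ext.min_star) / span,
        beta_e=(s.beta_s - ext.min_star) / span,
        trial_id=s.trial_id,
        degenerate=False,
    )


def enhance(raw: BandPowerSet, cfg: EnhancementConfig = EnhancementConfig()) -> EnhancedBandSet:
    """Production enhancement path: sigmoid squash, then per-trial min-max.

    Numerically stable for arbitrarily large |A| (the sigmoid saturates
    smoothly). With ``cfg.literal_eq9`` the reversed map 1 - A' is returned.
    """
    squashed = squash_band_set(raw, cfg)
    ext = trial_extremes(squashed)
    out = minmax_rescale(squashed, ext, eps=cfg.epsilon_degenerate)
    if cfg.literal_eq9 and not out.degenerate:
        out = EnhancedBandSet(
            theta_e=1.0 - out.theta_e,
            alpha_e=1.0 - out.alpha_e,
            beta_e=1.0 - out.beta_e,
            trial_id=out.trial_id,
            degenerate=False,
        )
    return out


def _closed_form_values(values: np.ndarray, slope: float) -> np.ndarray:
    # log-space evaluation of the closed form; u = -s*A, so the trial's raw
    # minimum corresponds to u_max and the raw maximum to u_min
    u = -slope * values
    u_max = np.max(u)
    u_min = np.min(u)
    with np.errstate(divide="ignore"):  # exact endpoints give log1p(-1) = -inf
        log_num = np.log1p(-np.exp(u - u_max)) + np.logaddexp(0.0, u_min)
        log_den = np.log1p(-np.exp(u_min - u_max)) + np.logaddexp(0.0, u)
    return np.exp(log_num - log_den)


def enhance_closed_form(
    raw: BandPowerSet,
    cfg: EnhancementConfig = EnhancementConfig(),
) -> EnhancedBandSet:
    """Single-expression enhancement, algebraically equal to :func:`enhance`.

    Kept as an independent verification route; agrees with the composition
    path to ~1e-10 absolute on non-degenerate trials. Degenerate trials
    follow the same all-0.5 rule.
    """
    v = raw.values()
    squashed = sigmoid_squash(v, cfg)
    span = float(np.max(squashed) - np.min(squashed))
    n = raw.n_electrodes
    if span <= cfg.epsilon_degenerate:
        half = np.full(n, 0.5)
        return EnhancedBandSet(
            theta_e=half.copy(),
            alpha_e=half.copy(),
            beta_e=half.copy(),
            trial_id=raw.trial_id,
            degenerate=True,
        )
    enhanced = _closed_form_values(v, cfg.slope)
    if cfg.literal_eq9:
        enhanced = 1.0 - enhanced
    return EnhancedBandSet(
        theta_e=enhanced[:n],
        alpha_e=enhanced[n : 2 * n],
        beta_e=enhanced[2 * n :],
        trial_id=raw.trial_id,
        degenerate=False,
    )
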