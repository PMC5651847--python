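"""Synthetic visual-search observers.

Generates per-trial accuracy and reaction times with the statistical
structure the mixed-model analysis assumes: Bernoulli correctness whose
log-odds rise with the target's apparent shading, Gamma reaction times
whose log-mean falls with shading, participant-level random intercepts on
both, and a set-size cost that decays as shading grows (search becomes
efficient when the target is conspicuous).

For participant j on a trial with normalized shading s and set size n:

    u_j ~ Normal(0, sigma_u^2),  v_j ~ Normal(0, sigma_v^2)
    P(correct) = g + (1 - g) * logistic(beta0 + beta1 * s + u_j)
    rt ~ Gamma(shape k, mean mu),
    log mu = alpha0 + alpha1 * s + alpha2 * exp(-efficiency_decay * s) * log n + v_j

The defaults qualitatively reproduce the behavioural pattern (accuracy
rising and RT falling with departure from the reference orientation;
set-size cost vanishing at 90 degrees); they are deliberately not fitted
to any published figure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .countershade import ShadingCurve
from .scene import TrialDesign

__all__ = ["ObserverParams", "default_params", "simulate_trials"]


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer parameters (see module docstring for the model)."""

    beta0: float = 0.0            # accuracy intercept, log-odds at zero shading
    beta1: float = 3.0            # log-odds gained per unit normalized shading
    guess_floor: float = 0.0      # forced-choice guessing floor g
    sigma_u: float = 0.8          # SD of participant accuracy intercepts (log-odds)
    alpha0: float = 1.18          # log mean RT (log-seconds) at s=0, one item
    alpha1: float = -1.5          # log-RT change per unit shading (< 0)
    alpha2: float = 0.3           # set-size slope: log-seconds per log-item at s=0
    efficiency_decay: float = 3.0 # rate at which the set-size slope vanishes in s
    gamma_shape: float = 4.0      # RT Gamma shape k (CV = 1/sqrt(k))
    sigma_v: float = 0.3          # SD of participant RT intercepts (log-seconds)

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ValueError("random-intercept SDs must be non-negative")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if not 0.0 <= self.guess_floor < 1.0:
            raise ValueError("guess_floor must be in [0, 1)")

    def set_size_slope(self, s: float) -> float:
        """Log-RT cost per log-item at normalized shading s (closed form)."""
        return self.alpha2 * np.exp(-self.efficiency_decay * s)


def default_params(
    calibration: str = "qualitative",
    guess_floor_items: int | None = None,
) -> ObserverParams:
    """Documented default observers.

    ``calibration='qualitative'`` returns the class defaults; ``'none'``
    zeroes both random-intercept SDs, giving deterministic participant
    means for recovery and degenerate-model tests.  ``guess_floor_items``
    (when given) sets the guessing floor to 1/(n_items + 1), the chance
    rate of the forced-choice identification stage; the mixed-model
    analysis ignores the floor, so it stays off by default.
    """
    p = ObserverParams()
    if calibration == "none":
        p = replace(p, sigma_u=0.0, sigma_v=0.0)
    elif calibration != "qualitative":
        raise ValueError("calibration must be 'qualitative' or 'none'")
    if guess_floor_items is not None:
        p = replace(p, guess_floor=1.0 / (guess_floor_items + 1))
    return p


def _shading_lookup(shading) -> dict[float, float]:
    """Normalize the level -> shading argument to a plain dict."""
    if isinstance(shading, ShadingCurve):
        return {float(l): float(s) for l, s in zip(shading.levels, shading.normalized)}
    if isinstance(shading, dict):
        return {float(k): float(v) for k, v in shading.items()}
    raise TypeError("shading must be a ShadingCurve or a {level: shading} dict")


def simulate_trials(
    design: TrialDesign,
    n_participants: int,
    shading,
    params: ObserverParams | None = None,
    seed: int = 0,
    axis: str = "pitch",
) -> pd.DataFrame:
    """Simulate every participant running the full trial design.

    ``shading`` maps departure level (degrees) to normalized apparent
    shading in [0, 1] (a :class:`ShadingCurve` or dict).  Returns a trial
    table with columns participant, axis, level, n_distractors, correct,
    rt — the unit of analysis of the search experiments.  Fully
    reproducible from ``seed``.
    """
    params = params or default_params()
    lut = _shading_lookup(shading)
    missing = set(map(float, design.table["level"])) - set(lut)
    if missing:
        raise ValueError(f"shading values missing for levels {sorted(missing)}")
    if any(not 0.0 <= v <= 1.0 for v in lut.values()):
        raise ValueError("normalized shading must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_trials = design.n_trials
    s = design.table["level"].map(lut).to_numpy(dtype=float)
    log_n = np.log(design.table["n_distractors"].to_numpy(dtype=float))

    u = rng.normal(0.0, params.sigma_u, size=n_participants)
    v = rng.normal(0.0, params.sigma_v, size=n_participants)
    frames = []
    for j in range(n_participants):
        p_correct = params.guess_floor + (1.0 - params.guess_floor) * expit(
            params.beta0 + params.beta1 * s + u[j]
        )
        correct = rng.random(n_trials) < p_correct
        mu = np.exp(
            params.alpha0
            + params.alpha1 * s
            + params.alpha2 * np.exp(-params.efficiency_decay * s) * log_n
            + v[j]
        )
        rt = rng.gamma(shape=params.gamma_shape, scale=mu / params.gamma_shape)
        frames.append(
            pd.DataFrame(
                {
                    "participant": j,
                    "axis": axis,
                    "level": design.table["level"].to_numpy(),
                    "n_distractors": design.table["n_distractors"].to_numpy(),
                    "correct": correct.astype(int),
                    "rt": rt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
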