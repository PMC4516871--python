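"""Poisson-click stereo stimuli, adaptive difficulty, and the logLR decision variable.

The auditory stimulus is a 1 s stereo train of brief clicks. Per trial the
left-ear count ``c_l`` and right-ear count ``c_r`` sum to a fixed total
``omega`` drawn from {25, 32, 39, 46}. An online staircase maps a target
evidence value E ∈ (−1, 1) to a right-click count through a logistic link
with sensitivity ``beta``, and adapts ``beta`` multiplicatively to hold the
observer near 75% correct.

The decision variable is the running sum of per-click log-likelihood ratios
log P(click side | button) / P(click side | saccade), with the click-side
likelihoods estimated from pooled counts over all trials of each choice.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("alphapress.stimulus")

__all__ = [
    "OMEGA_VALUES",
    "ClickStimulus",
    "AdaptiveState",
    "LikelihoodTable",
    "DVTrace",
    "generate_click_train",
    "forward_evidence",
    "target_right_count",
    "update_beta",
    "select_stimulus",
    "build_stimulus_bank",
    "estimate_click_likelihoods",
    "compute_dv_trace",
]

#: Allowed per-trial click totals (left + right).
OMEGA_VALUES = (25, 32, 39, 46)

#: Safety bounds for the adaptive sensitivity parameter.
BETA_MIN = 0.5
BETA_MAX = 200.0


@dataclass(frozen=True)
class ClickStimulus:
    """One stereo click train.

    Click times are seconds within the 1 s stimulus, sorted ascending.
    ``target_e`` is the evidence value the staircase aimed for and
    ``beta_at_generation`` the sensitivity under which the counts were chosen.
    """

    left_times: np.ndarray
    right_times: np.ndarray
    omega: int
    target_e: float
    beta_at_generation: float

    @property
    def c_l(self) -> int:
        return len(self.left_times)

    @property
    def c_r(self) -> int:
        return len(self.right_times)

    def __post_init__(self) -> None:
        if self.omega not in OMEGA_VALUES:
            raise ValueError(f"omega must be one of {OMEGA_VALUES}, got {self.omega}")
        if self.c_l + self.c_r != self.omega:
            raise ValueError("click counts must sum to omega")
        for t in (self.left_times, self.right_times):
            if len(t) and (t.min() < 0.0 or t.max() > 1.0):
                raise ValueError("click times must lie in [0, 1] s")

    def realized_evidence(self, beta: float) -> float:
        """Evidence value implied by the realized counts at sensitivity ``beta``."""
        return forward_evidence(self.c_r, self.c_l, beta)


@dataclass
class AdaptiveState:
    """State of the online difficulty staircase.

    ``beta`` starts at 8 and is updated multiplicatively from the percent
    correct over the last 20 valid trials. The update fires once per block
    of ``update_interval`` newly recorded trials: re-applying the
    compounding rule every trial on an overlapping window turns β into a
    high-gain random walk (the window lags the change it caused), whereas
    block updates keep the loop stable around the 75% set point.
    """

    beta: float = 8.0
    window: deque = field(default_factory=lambda: deque(maxlen=20))
    update_interval: int = 20
    _since_update: int = 0
    _bound_warned: bool = False

    @property
    def accuracy(self) -> float:
        """Percent correct over the current window (NaN while empty)."""
        if not self.window:
            return float("nan")
        return 100.0 * sum(self.window) / len(self.window)

    def record(self, correct: bool) -> None:
        self.window.append(bool(correct))
        self._since_update += 1

    def step(self) -> float:
        """Apply the multiplicative update when a fresh block has accrued; returns beta."""
        if len(self.window) == self.window.maxlen and self._since_update >= self.update_interval:
            self.beta = update_beta(self.beta, self.accuracy)
            self._since_update = 0
            if self.beta in (BETA_MIN, BETA_MAX) and not self._bound_warned:
                logger.warning(
                    "staircase beta saturated at bound %.1f; the observer's "
                    "accuracy may be insensitive to difficulty", self.beta,
                )
                self._bound_warned = True
        return self.beta


@dataclass(frozen=True)
class LikelihoodTable:
    """Per-click side likelihoods conditioned on the eventual choice."""

    p_right_given_button: float
    p_right_given_saccade: float

    @property
    def p_left_given_button(self) -> float:
        return 1.0 - self.p_right_given_button

    @property
    def p_left_given_saccade(self) -> float:
        return 1.0 - self.p_right_given_saccade

    def __post_init__(self) -> None:
        for p in (self.p_right_given_button, self.p_right_given_saccade):
            if not 0.0 < p < 1.0:
                raise ValueError("likelihood cells must lie strictly in (0, 1)")

    @property
    def log_lr_right(self) -> float:
        """logLR contributed by a single right-ear click."""
        return math.log(self.p_right_given_button / self.p_right_given_saccade)

    @property
    def log_lr_left(self) -> float:
        return math.log(self.p_left_given_button / self.p_left_given_saccade)


@dataclass(frozen=True)
class DVTrace:
    """Piecewise-constant decision variable over the merged click sequence."""

    times: np.ndarray
    values: np.ndarray

    @property
    def dv_end(self) -> float:
        """DV after the final click (0 for a clickless stimulus)."""
        return float(self.values[-1]) if len(self.values) else 0.0

    def value_at(self, t: float) -> float:
        """DV at time ``t`` (sum over clicks at times <= t)."""
        i = int(np.searchsorted(self.times, t, side="right"))
        return float(self.values[i - 1]) if i > 0 else 0.0


def generate_click_train(
    omega: int, c_r: int, rng: np.random.Generator, *, target_e: float = 0.0, beta: float = 8.0
) -> ClickStimulus:
    """Draw a stereo click train with ``c_r`` right and ``omega - c_r`` left clicks.

    Conditional on its count, a homogeneous Poisson process on [0, 1] places
    events as i.i.d. uniform order statistics, so times are sorted uniforms.
    """
    if omega not in OMEGA_VALUES:
        raise ValueError(f"omega must be one of {OMEGA_VALUES}, got {omega}")
    if not 0 <= c_r <= omega:
        raise ValueError(f"c_r must be in [0, {omega}], got {c_r}")
    right = np.sort(rng.uniform(0.0, 1.0, size=c_r))
    left = np.sort(rng.uniform(0.0, 1.0, size=omega - c_r))
    return ClickStimulus(
        left_times=left,
        right_times=right,
        omega=omega,
        target_e=float(target_e),
        beta_at_generation=float(beta),
    )


def forward_evidence(c_r: int, c_l: int, beta: float) -> float:
    """Evidence E = 2 / (1 + exp(−β (Cr − Cl)/(Cr + Cl))) − 1 ∈ (−1, 1)."""
    if c_r + c_l <= 0:
        raise ValueError("c_r + c_l must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = beta * (c_r - c_l) / (c_r + c_l)
    return 2.0 / (1.0 + math.exp(-x)) - 1.0


def target_right_count(e: float, beta: float, omega: int) -> int:
    """Right-click count whose realized evidence best matches ``e``.

    Inverts the forward evidence map: Cr = Ω/2 · (1 + L/β) with
    L = logit((E+1)/2), rounded to the nearest integer and clipped to
    [0, Ω].
    """
    if not -1.0 < e < 1.0:
        raise ValueError("e must lie strictly in (-1, 1)")
    if beta <= 0:
        raise ValueError("beta must be positive")
    p = (e + 1.0) / 2.0
    ell = math.log(p / (1.0 - p))
    c_r = 0.5 * omega * (1.0 + ell / beta)
    return int(np.clip(round(c_r), 0, omega))


def update_beta(beta_old: float, accuracy_a: float) -> float:
    """Staircase update β_new = β_old · 1.2^((A − 75)/10), clipped to safe bounds.

    ``accuracy_a`` is percent correct over the trailing window; accuracy above
    the 75% set point raises β (smaller click imbalance, harder trials).
    """
    if beta_old <= 0:
        raise ValueError("beta_old must be positive")
    if not 0.0 <= accuracy_a <= 100.0:
        raise ValueError("accuracy must be a percentage in [0, 100]")
    beta_new = beta_old * 1.2 ** ((accuracy_a - 75.0) / 10.0)
    return float(np.clip(beta_new, BETA_MIN, BETA_MAX))


def select_stimulus(e_target: float, bank: Sequence[ClickStimulus], beta: float) -> ClickStimulus:
    """Pick the bank stimulus whose realized evidence at ``beta`` is nearest to ``e_target``.

    Ties break toward the lowest index, so selection is deterministic.
    """
    if not bank:
        raise ValueError("stimulus bank is empty")
    errors = [abs(e_target - s.realized_evidence(beta)) for s in bank]
    return bank[int(np.argmin(errors))]


def build_stimulus_bank(
    beta: float, rng: np.random.Generator, *, n_stimuli: int = 10, omega: int | None = None
) -> list[ClickStimulus]:
    """Pre-generate candidate stimuli at the current sensitivity.

    Each candidate's right-click count targets a fresh uniform(−1, 1)
    evidence draw; all candidates share one ``omega`` (drawn here when not
    given), mirroring a bank regenerated per trial.
    """
    if omega is None:
        omega = int(rng.choice(OMEGA_VALUES))
    bank = []
    for _ in range(n_stimuli):
        e = float(rng.uniform(-1.0, 1.0))
        c_r = target_right_count(e, beta, omega)
        bank.append(generate_click_train(omega, c_r, rng, target_e=e, beta=beta))
    return bank


def estimate_click_likelihoods(trials: Iterable) -> LikelihoodTable:
    """Estimate P(click side | choice) from pooled click counts.

    For each choice class, p(right | choice) is the summed right-click count
    over that class's trials divided by the summed click total. Zero or full
    cells are floored at 1/(1 + Σω) for the class, keeping logs finite.

    ``trials`` needs items with ``stimulus`` (`ClickStimulus`) and ``choice``
    ("button" / "saccade") attributes.
    """
    counts = {"button": [0, 0], "saccade": [0, 0]}  # [sum c_r, sum omega]
    for tr in trials:
        if tr.choice not in counts:
            raise ValueError(f"unknown choice {tr.choice!r}")
        counts[tr.choice][0] += tr.stimulus.c_r
        counts[tr.choice][1] += tr.stimulus.omega
    probs = {}
    for choice, (sum_cr, sum_omega) in counts.items():
        if sum_omega == 0:
            raise ValueError(f"no clicks observed for choice class {choice!r}")
        floor = 1.0 / (1.0 + sum_omega)
        probs[choice] = float(np.clip(sum_cr / sum_omega, floor, 1.0 - floor))
    return LikelihoodTable(
        p_right_given_button=probs["button"], p_right_given_saccade=probs["saccade"]
    )


def compute_dv_trace(stimulus: ClickStimulus, table: LikelihoodTable) -> DVTrace:
    """Running logLR over the merged click sequence, ascending in time.

    DV(t) = Σ_{clicks i: t_i <= t} log P(e_i | button) / P(e_i | saccade).
    """
    times = np.concatenate([stimulus.right_times, stimulus.left_times])
    increments = np.concatenate(
        [
            np.full(stimulus.c_r, table.log_lr_right),
            np.full(stimulus.c_l, table.log_lr_left),
        ]
    )
    order = np.argsort(times, kind="stable")
    times = times[order]
    values = np.cumsum(increments[order])
    return DVTrace(times=times, values=values)
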