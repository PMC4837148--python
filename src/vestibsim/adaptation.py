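"""Acute adaptation of the vestibular-nuclei synapses by error backpropagation.

With the head stationary in a dark room, any eye movement is retinal slip
(e = v_eye + v_head = v_eye) and the desired eye velocity is zero.  The onset
of tonic baseline stimulation entrains the recruited afferents to the pulse
rate, unbalancing the weighted sum and producing nystagmus.  Adaptation
descends the squared error with a Fahlman-modified derivative:

    e      = d_v - v
    delta  = e * (1.1 - v_hat**2)          (v_hat = v / output_gain)
    w_i   += alpha_s * delta * r_i          (homosynaptic component)
    b     -= alpha_b * delta                (heterosynaptic component)

The per-synapse update scales with each afferent's own activity r_i, so a
large alpha_s mimics homosynaptic long-term depression (only entrained
synapses are depressed, in proportion to their drive); the offset update is
activity-independent, so a large alpha_b mimics heterosynaptic depression
that attenuates all inputs equally while leaving the weights untouched.  The
sign of the offset update is the error-reducing one given that the offset
enters the drive with a minus sign.

Adaptation proceeds in three phases: healthy -> bilateral vestibular loss
(residual discharge only; the healthy resting balance already satisfies the
zero-error condition) -> baseline-stimulation onset, after which modulation
experiments run on the frozen weights.  An epoch is one modulation-free
interval of ``bins_per_epoch`` time bins with fresh residual-noise samples;
updates are applied online, per bin.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._seeding import spawn_rng
from .exceptions import ConvergenceError, ParameterError
from .nuclei import SynapticState, init_healthy_weights
from .population import LEFT, AfferentPopulation, StimulationConfig, recruited_count

#: Default bias/synapse learning-rate ratio (moderate, mixed LTD regime).
DEFAULT_LEARNING_RATIO = 2.0e3

CONDITION_BVL = "bvl"
CONDITION_BASELINE = "baseline"


@dataclasses.dataclass(frozen=True)
class AdaptationConfig:
    """Learning rates and stopping rules for one adaptation phase.

    ``alpha_s`` is the per-synapse learning rate, ``alpha_b`` the offset
    learning rate (default alpha_s * 2e3).  An epoch converges when its mean
    absolute error drops to ``tolerance`` (arbitrary velocity units).
    """

    alpha_s: float = 1.0e-4
    alpha_b: float = 1.0e-4 * DEFAULT_LEARNING_RATIO
    max_epochs: int = 200
    tolerance: float = 0.05
    desired_velocity: float = 0.0
    bins_per_epoch: int = 200
    divergence_patience: int = 10

    def __post_init__(self) -> None:
        if self.alpha_s < 0 or self.alpha_b < 0:
            raise ParameterError("learning rates must be >= 0")
        if self.alpha_s == 0 and self.alpha_b == 0:
            raise ParameterError("alpha_s and alpha_b cannot both be 0")
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be > 0")
        if self.max_epochs < 1 or self.bins_per_epoch < 1:
            raise ParameterError("max_epochs and bins_per_epoch must be >= 1")

    def replace(self, **changes) -> "AdaptationConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def with_ratio(cls, ratio: float, alpha_s: float = 1.0e-4, **kw) -> "AdaptationConfig":
        """Config with alpha_b = ratio * alpha_s."""
        return cls(alpha_s=alpha_s, alpha_b=ratio * alpha_s, **kw)


@dataclasses.dataclass
class AdaptationHistory:
    """Per-epoch mean |error| trace of one adaptation phase."""

    errors: np.ndarray
    epochs: int
    converged: bool
    final_state: SynapticState

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(self.epochs), "mean_abs_error": self.errors})


def retinal_slip(v_eye: float, v_head: float = 0.0) -> float:
    """Retinal slip e = v_eye + v_head; with a stationary head, e = v_eye."""
    return v_eye + v_head


def _step(state: SynapticState, rates: np.ndarray, config: AdaptationConfig) -> float:
    """One online update, in place.  Returns the error e = d_v - v."""
    r = np.asarray(rates, dtype=float) / state.rate_scale
    arg = r @ state.weights - state.bias
    v_hat = np.tanh(state.input_scale * arg)
    v = state.output_gain * v_hat
    e = config.desired_velocity - v
    if not np.isfinite(e):
        raise ConvergenceError(f"non-finite error during adaptation (drive={arg!r})")
    delta = e * (1.1 - v_hat * v_hat)
    if config.alpha_s:
        state.weights += config.alpha_s * delta * r
    if config.alpha_b:
        state.bias -= config.alpha_b * delta
    return float(e)


def update_step(state: SynapticState, rates: np.ndarray, config: AdaptationConfig) -> SynapticState:
    """Single backpropagation step; returns the updated state (input untouched)."""
    new = state.copy()
    _step(new, rates, config)
    return new


def adapt_to_condition(
    state: SynapticState,
    pop: AfferentPopulation,
    stim_condition: str,
    config: AdaptationConfig,
    *,
    stim: StimulationConfig | None = None,
    stim_side: str = LEFT,
    seed: int = 0,
) -> AdaptationHistory:
    """Adapt weights and offset until the resting eye velocity is quiet.

    ``stim_condition`` is ``"bvl"`` (residual discharge only on both sides) or
    ``"baseline"`` (tonic unmodulated stimulation of ``stim`` on the
    stimulated side).  Iterates online updates over epochs of freshly sampled
    residual rates until the epoch-mean |e| reaches the tolerance or
    ``max_epochs`` is hit.  Raises ConvergenceError if the epoch error doubles
    for ``divergence_patience`` consecutive epochs.  Deterministic given seed.
    """
    if stim_condition not in (CONDITION_BVL, CONDITION_BASELINE):
        raise ParameterError(f"stim_condition must be '{CONDITION_BVL}' or '{CONDITION_BASELINE}'")
    if stim_condition == CONDITION_BASELINE:
        if stim is None:
            raise ParameterError("baseline adaptation requires a StimulationConfig")
        count = recruited_count(stim, pop.n_per_side, 0.0)
        mask = pop.stimulated_mask(count, stim_side)
        baseline_rate = stim.baseline_rate
    else:
        mask = None

    rng = spawn_rng(seed)
    st = state.copy()
    errors: list[float] = []
    growth_streak = 0
    quiet_epochs = 0
    converged = False
    for _epoch in range(config.max_epochs):
        rates = pop.draw_residual(rng, config.bins_per_epoch)
        if mask is not None:
            rates[:, mask] = np.maximum(rates[:, mask], baseline_rate)
        abs_err = 0.0
        for row in rates:
            abs_err += abs(_step(st, row, config))
        epoch_err = abs_err / config.bins_per_epoch
        errors.append(epoch_err)
        if epoch_err <= config.tolerance:
            # require a full epoch *spent* at tolerance, i.e. a quiet epoch
            # following the one in which the error first crossed it, so the
            # settling transient is not part of the converged epoch
            quiet_epochs += 1
            if quiet_epochs >= 2:
                converged = True
                break
        else:
            quiet_epochs = 0
        if len(errors) >= 2 and epoch_err > 2.0 * errors[-2]:
            growth_streak += 1
            if growth_streak >= config.divergence_patience:
                raise ConvergenceError(
                    f"adaptation diverging: epoch error doubled {growth_streak} consecutive epochs"
                )
        else:
            growth_streak = 0
    return AdaptationHistory(
        errors=np.asarray(errors),
        epochs=len(errors),
        converged=converged,
        final_state=st,
    )


@dataclasses.dataclass
class ThreePhaseResult:
    """States and histories of the healthy -> BVL -> baseline-onset sequence."""

    population: AfferentPopulation
    healthy: SynapticState
    post_bvl: SynapticState
    post_baseline: SynapticState
    bvl_history: AdaptationHistory
    baseline_history: AdaptationHistory


def adapt_three_phase(
    pop: AfferentPopulation,
    stim: StimulationConfig,
    config: AdaptationConfig,
    *,
    mean_magnitude: float = 1.0,
    spread: float = 0.2,
    stim_side: str = LEFT,
    seed: int = 0,
    **nuclei_kwargs,
) -> ThreePhaseResult:
    """Run the full acute sequence and return all intermediate states.

    Phase seeds are derived from ``seed`` so the whole sequence is
    reproducible and the phases draw independent noise.
    """
    healthy = init_healthy_weights(pop, mean_magnitude=mean_magnitude, spread=spread, seed=seed, **nuclei_kwargs)
    bvl_hist = adapt_to_condition(healthy, pop, CONDITION_BVL, config, seed=seed * 2 + 1)
    base_hist = adapt_to_condition(
        bvl_hist.final_state, pop, CONDITION_BASELINE, config, stim=stim, stim_side=stim_side, seed=seed * 2 + 2
    )
    return ThreePhaseResult(
        population=pop,
        healthy=healthy,
        post_bvl=bvl_hist.final_state,
        post_baseline=base_hist.final_state,
        bvl_history=bvl_hist,
        baseline_history=base_hist,
    )
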