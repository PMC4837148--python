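"""Bilateral vestibular afferent populations and the electrode-nerve interface.

After bilateral vestibular loss (BVL) the semicircular-canal afferents are no
longer driven by hair cells and revert to a residual resting discharge that is
independent of head motion.  Each afferent is characterised by a mean resting
rate (drawn from a lognormal distribution across the population) and an
inter-spike-interval coefficient of variation (CV): regular units have CV below
0.1, irregular units above.

A monopolar stimulating electrode injects charge that spreads roughly
spherically, so the number of recruited afferents grows with the injected
current.  Recruited afferents are entrained: their firing rate locks to the
stimulation pulse rate whenever it exceeds their residual resting rate,

    fr_i = max(PR_b + PR_m, residual_i),

where PR_b is the baseline pulse rate and PR_m the (signed) rate-modulation
term.  Pulse-amplitude modulation (PAM) changes *how many* afferents are
recruited; pulse-rate modulation (PRM) changes the rate imposed on the
recruited set.  A 2-Hz sinusoidal envelope modulates either quantity around its
baseline.

Recruitment follows an area-type law: the recruited fraction scales as
baseline_fraction * (1 + m)**recruitment_exponent with a quadratic exponent by
default, which reproduces the 22.5% / 62.5% recruitment swing of a +/-25%
amplitude modulation around a 40% baseline.  Recruitment is nested: each
afferent carries a fixed recruitment rank (conceptually its distance from the
electrode), and the set recruited at a lower current is always a prefix of the
set recruited at a higher current.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeding import spawn_rng
from .exceptions import ParameterError

LEFT = "left"
RIGHT = "right"

#: CV boundary between regular and irregular afferents.
REGULAR_CV_BOUNDARY = 0.1

#: Population defaults: lognormal arithmetic mean/SD of residual resting rates
#: (spikes/s) and the regular/irregular split.
DEFAULT_RATE_MEAN = 26.3
DEFAULT_RATE_SD = 6.6
DEFAULT_REGULAR_FRACTION = 0.67
DEFAULT_CV_RANGE_REGULAR = (0.01, 0.1)
DEFAULT_CV_RANGE_IRREGULAR = (0.1, 0.3)


@dataclasses.dataclass(frozen=True)
class StimulationConfig:
    """Prosthetic stimulation settings.

    Parameters
    ----------
    baseline_amplitude : float
        Baseline current amplitude A_b in normalized units (the recruitment
        law is expressed in fractions of A_b, so 1.0 is the natural choice).
    amp_mod_depth : float
        Peak amplitude modulation as a fraction of A_b (A_m = depth * A_b).
    baseline_rate : float
        Baseline pulse rate PR_b in pulses/s.
    rate_mod_depth : float
        Peak rate modulation as a fraction of PR_b (PR_m = depth * PR_b).
    mod_freq : float
        Frequency of the sinusoidal modulation envelope (Hz).
    baseline_fraction : float
        Fraction of one side's afferents recruited at A_b with no modulation.
    recruitment_exponent : float
        Exponent of the recruitment law; 2 corresponds to an area-type
        (geometric) dependence of recruited count on current.
    """

    baseline_amplitude: float = 1.0
    amp_mod_depth: float = 0.0
    baseline_rate: float = 200.0
    rate_mod_depth: float = 0.0
    mod_freq: float = 2.0
    baseline_fraction: float = 0.40
    recruitment_exponent: float = 2.0

    def __post_init__(self) -> None:
        problems = []
        if not 0.0 <= self.amp_mod_depth <= 1.0:
            problems.append(f"amp_mod_depth must be in [0, 1], got {self.amp_mod_depth}")
        if not 0.0 <= self.rate_mod_depth <= 1.0:
            problems.append(f"rate_mod_depth must be in [0, 1], got {self.rate_mod_depth}")
        if self.baseline_rate < 0:
            problems.append(f"baseline_rate must be >= 0, got {self.baseline_rate}")
        if self.mod_freq <= 0:
            problems.append(f"mod_freq must be > 0, got {self.mod_freq}")
        if self.baseline_amplitude <= 0:
            problems.append(f"baseline_amplitude must be > 0, got {self.baseline_amplitude}")
        if not 0.0 < self.baseline_fraction <= 1.0:
            problems.append(f"baseline_fraction must be in (0, 1], got {self.baseline_fraction}")
        if not problems:
            peak = self.baseline_fraction * (1.0 + self.amp_mod_depth) ** self.recruitment_exponent
            if peak > 1.0 + 1e-12:
                problems.append(
                    "peak recruited fraction exceeds 1: "
                    f"baseline_fraction*(1+amp_mod_depth)**recruitment_exponent = {peak:.3f}"
                )
        if problems:
            raise ParameterError("; ".join(problems))

    @property
    def amp_envelope_peak(self) -> float:
        """A_m: amplitude-modulation envelope peak in current units."""
        return self.baseline_amplitude * self.amp_mod_depth

    @property
    def rate_envelope_peak(self) -> float:
        """PR_m: rate-modulation envelope peak in pulses/s."""
        return self.baseline_rate * self.rate_mod_depth

    def replace(self, **changes) -> "StimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass
class AfferentPopulation:
    """Bilateral population of canal afferents, stored as parallel arrays.

    The first ``n_per_side`` entries are the left side, the rest the right.
    ``recruitment_rank`` is a fixed permutation within each side; an afferent
    is recruited whenever its rank is below the instantaneous recruited count.
    """

    mean_rest_rate: np.ndarray
    cv: np.ndarray
    side: np.ndarray
    recruitment_rank: np.ndarray
    n_per_side: int
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.n_total
        for name in ("mean_rest_rate", "cv", "side", "recruitment_rank"):
            arr = np.asarray(getattr(self, name))
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ParameterError(f"{name} must have shape ({n},), got {arr.shape}")
        if np.any(self.mean_rest_rate <= 0):
            raise ParameterError("all mean_rest_rate values must be > 0")
        if np.any(self.cv <= 0):
            raise ParameterError("all cv values must be > 0")
        for s in (LEFT, RIGHT):
            ranks = np.sort(self.recruitment_rank[self.side == s])
            if not np.array_equal(ranks, np.arange(self.n_per_side)):
                raise ParameterError(f"recruitment_rank on side {s!r} must be a permutation of 0..n-1")

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_side

    @property
    def is_regular(self) -> np.ndarray:
        return self.cv < REGULAR_CV_BOUNDARY

    def side_mask(self, side: str) -> np.ndarray:
        if side not in (LEFT, RIGHT):
            raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
        return self.side == side

    def stimulated_mask(self, count: int, side: str = LEFT) -> np.ndarray:
        """Boolean mask of the ``count`` lowest-rank afferents on ``side``."""
        return self.side_mask(side) & (self.recruitment_rank < int(count))

    def draw_residual(self, rng: np.random.Generator, n_bins: int | None = None) -> np.ndarray:
        """Sample residual resting rates, one per afferent per time bin.

        Each afferent's rate is drawn from a normal law with mean u_i and
        SD cv_i * u_i, truncated at zero (negative draws are clipped).
        Returns shape (n_total,) if ``n_bins`` is None, else (n_bins, n_total).
        """
        size = self.n_total if n_bins is None else (int(n_bins), self.n_total)
        draws = rng.normal(self.mean_rest_rate, self.cv * self.mean_rest_rate, size=size)
        return np.clip(draws, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_total),
                "side": self.side,
                "mean_rest_rate": self.mean_rest_rate,
                "cv": self.cv,
                "is_regular": self.is_regular,
                "recruitment_rank": self.recruitment_rank,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int | None = None) -> "AfferentPopulation":
        n_per_side = int((frame["side"] == LEFT).sum())
        return cls(
            mean_rest_rate=frame["mean_rest_rate"].to_numpy(float),
            cv=frame["cv"].to_numpy(float),
            side=frame["side"].to_numpy(str),
            recruitment_rank=frame["recruitment_rank"].to_numpy(int),
            n_per_side=n_per_side,
            seed=seed,
        )


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Convert an arithmetic mean/SD to the lognormal log-scale (mu, sigma)."""
    if mean <= 0 or sd <= 0:
        raise ParameterError("lognormal mean and sd must be > 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def sample_population(
    n_per_side: int = 1000,
    rate_mean: float = DEFAULT_RATE_MEAN,
    rate_sd: float = DEFAULT_RATE_SD,
    regular_fraction: float = DEFAULT_REGULAR_FRACTION,
    cv_range_regular: Sequence[float] = DEFAULT_CV_RANGE_REGULAR,
    cv_range_irregular: Sequence[float] = DEFAULT_CV_RANGE_IRREGULAR,
    seed: int = 0,
) -> AfferentPopulation:
    """Sample a bilateral afferent population.

    Mean resting rates are lognormal with the given *arithmetic* mean and SD;
    CVs are uniform within the class range; exactly
    ``round(regular_fraction * n_per_side)`` afferents per side are regular.
    Recruitment ranks are a fixed random permutation per side.  Deterministic
    given ``seed``.
    """
    if n_per_side < 1:
        raise ParameterError(f"n_per_side must be >= 1, got {n_per_side}")
    if not 0.0 <= regular_fraction <= 1.0:
        raise ParameterError(f"regular_fraction must be in [0, 1], got {regular_fraction}")
    lo_r, hi_r = map(float, cv_range_regular)
    lo_i, hi_i = map(float, cv_range_irregular)
    if not (0.0 < lo_r < hi_r <= REGULAR_CV_BOUNDARY):
        raise ParameterError(f"cv_range_regular must lie within (0, {REGULAR_CV_BOUNDARY}], got {cv_range_regular}")
    if not (REGULAR_CV_BOUNDARY <= lo_i < hi_i):
        raise ParameterError(f"cv_range_irregular must lie within [{REGULAR_CV_BOUNDARY}, inf), got {cv_range_irregular}")

    mu, sigma = lognormal_params_from_moments(rate_mean, rate_sd)
    rng = spawn_rng(seed)
    n_regular = int(round(regular_fraction * n_per_side))

    rates = rng.lognormal(mu, sigma, size=2 * n_per_side)
    cv = np.empty(2 * n_per_side)
    side = np.empty(2 * n_per_side, dtype=object)
    rank = np.empty(2 * n_per_side, dtype=np.int64)
    for k, s in enumerate((LEFT, RIGHT)):
        sl = slice(k * n_per_side, (k + 1) * n_per_side)
        c = np.empty(n_per_side)
        c[:n_regular] = rng.uniform(lo_r, hi_r, size=n_regular)
        c[n_regular:] = rng.uniform(lo_i, hi_i, size=n_per_side - n_regular)
        cv[sl] = c
        side[sl] = s
        rank[sl] = rng.permutation(n_per_side)
    return AfferentPopulation(
        mean_rest_rate=rates,
        cv=cv,
        side=side.astype(str),
        recruitment_rank=rank,
        n_per_side=n_per_side,
        seed=seed,
    )


def modulation_envelope(t, depth: float, freq: float):
    """Signed sinusoidal modulation envelope depth * sin(2*pi*freq*t)."""
    if not 0.0 <= depth <= 1.0:
        raise ParameterError(f"depth must be in [0, 1], got {depth}")
    if freq <= 0:
        raise ParameterError(f"freq must be > 0, got {freq}")
    return depth * np.sin(2.0 * np.pi * freq * np.asarray(t, dtype=float))


def recruited_count(config: StimulationConfig, n_per_side: int, instantaneous_amp_mod=0.0):
    """Number of afferents recruited at a given instantaneous amplitude modulation.

    round(n * baseline_fraction * (1 + m)**recruitment_exponent), clamped to
    [0, n_per_side].  Monotone non-decreasing in ``instantaneous_amp_mod``;
    recruitment is nested by recruitment rank.  Accepts scalars or arrays.
    """
    m = np.asarray(instantaneous_amp_mod, dtype=float)
    if np.any(m < -1.0) or np.any(m > 1.0):
        raise ParameterError("instantaneous_amp_mod must be in [-1, 1]")
    frac = config.baseline_fraction * (1.0 + m) ** config.recruitment_exponent
    counts = np.clip(np.round(frac * n_per_side), 0, n_per_side).astype(np.int64)
    return int(counts) if counts.ndim == 0 else counts


def instantaneous_rates(
    pop: AfferentPopulation,
    config: StimulationConfig,
    t: float,
    stim_side: str = LEFT,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-afferent instantaneous firing rates (spikes/s) at time ``t``.

    Recruited afferents on the stimulated side are entrained to the
    instantaneous pulse rate whenever it exceeds their residual sample; all
    other afferents emit their residual sample.
    """
    rng = rng if rng is not None else spawn_rng(0)
    residual = pop.draw_residual(rng)
    m_amp = modulation_envelope(t, config.amp_mod_depth, config.mod_freq)
    count = recruited_count(config, pop.n_per_side, m_amp)
    stim_rate = config.baseline_rate * (1.0 + modulation_envelope(t, config.rate_mod_depth, config.mod_freq))
    mask = pop.stimulated_mask(count, stim_side)
    return np.where(mask, np.maximum(stim_rate, residual), residual)


def ensemble_rate_change_pam(
    pop: AfferentPopulation,
    config: StimulationConfig,
    stim_side: str = LEFT,
    instantaneous_amp_mod: float | None = None,
) -> float:
    """Change in summed ensemble firing rate at peak amplitude modulation.

    Sum over the additionally recruited afferents (ranks between the baseline
    count and the modulated count) of (PR_b - mean_rest_rate_i).  With a
    negative envelope value the de-recruited afferents contribute with the
    opposite sign.
    """
    m = config.amp_mod_depth if instantaneous_amp_mod is None else instantaneous_amp_mod
    n0 = recruited_count(config, pop.n_per_side, 0.0)
    n1 = recruited_count(config, pop.n_per_side, m)
    lo, hi = min(n0, n1), max(n0, n1)
    on_side = pop.side_mask(stim_side)
    band = on_side & (pop.recruitment_rank >= lo) & (pop.recruitment_rank < hi)
    total = float(np.sum(config.baseline_rate - pop.mean_rest_rate[band]))
    return total if n1 >= n0 else -total


def ensemble_rate_change_prm(
    config: StimulationConfig,
    n_per_side: int,
    instantaneous_rate_mod: float | None = None,
) -> float:
    """Change in summed ensemble firing rate at peak rate modulation.

    (baseline recruited count) x (peak modulated rate - PR_b).  The printed
    formula's modulated-rate symbol is read as the absolute modulated rate
    PR_b * (1 + depth), so the change per afferent is PR_b * depth.
    """
    m = config.rate_mod_depth if instantaneous_rate_mod is None else instantaneous_rate_mod
    n0 = recruited_count(config, n_per_side, 0.0)
    return float(n0) * config.baseline_rate * m


def delta_charge(config: StimulationConfig) -> float:
    """Summary change in delivered charge per second for a modulation setting.

    PR_b*A_m + PR_m*A_b + PR_m*A_m with A_m and PR_m the envelope peaks;
    reduces to PR_b*A_m for pure PAM and PR_m*A_b for pure PRM.
    """
    a_m = config.amp_envelope_peak
    pr_m = config.rate_envelope_peak
    return config.baseline_rate * a_m + pr_m * config.baseline_amplitude + pr_m * a_m


def rate_time_series(
    pop: AfferentPopulation,
    config: StimulationConfig,
    times,
    stim_side: str = LEFT,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format per-afferent rate trace: columns (time, afferent_id, rate)."""
    rng = spawn_rng(seed)
    frames = []
    for t in np.asarray(times, dtype=float):
        rates = instantaneous_rates(pop, config, t, stim_side=stim_side, rng=rng)
        frames.append(pd.DataFrame({"time": t, "afferent_id": np.arange(pop.n_total), "rate": rates}))
    return pd.concat(frames, ignore_index=True)


def population_to_csv(pop: AfferentPopulation, path) -> None:
    pop.to_frame().to_csv(path, index=False)


def population_from_csv(path) -> AfferentPopulation:
    return AfferentPopulation.from_frame(pd.read_csv(path))
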