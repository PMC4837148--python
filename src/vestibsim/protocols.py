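"""Stimulation protocols: PAM, PRM and hybrid comodulation on the adapted model.

After the model has adapted away the stimulation-onset nystagmus, a 2-Hz
sinusoidal envelope modulates the pulse amplitude (PAM: the recruited count
swings with the envelope), the pulse rate (PRM: the entrained rate swings), or
both (hybrid comodulation), with the synaptic weights frozen.  Performance is
summarized by the positive and negative peak eye velocities (PEV, NEV)
obtained from half-wave sinusoid fits to the cycle-averaged output.

The scan helpers reproduce the main parameter studies: residual rate x
baseline pulse rate, bias/synapse learning-rate ratio, modulation depth, and
the 2-D comodulation surface with its equipotent contour.  Every scan cell
runs from an independent deterministic sub-seed derived from the master seed
and the cell index.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seeding import spawn_rng
from .adaptation import AdaptationConfig, ThreePhaseResult, adapt_three_phase
from .exceptions import ParameterError, StateError
from .nuclei import SynapticState, eye_velocity
from .population import (
    LEFT,
    AfferentPopulation,
    StimulationConfig,
    modulation_envelope,
    recruited_count,
    sample_population,
)

MODE_PAM = "pam"
MODE_PRM = "prm"
MODE_HYBRID = "hybrid"
MODE_BASELINE = "baseline"

#: Default bins per modulation cycle (dt = 2.5 ms at 2 Hz).
BINS_PER_CYCLE = 200


@dataclasses.dataclass
class SimulationTrace:
    """Eye-velocity trace of a modulation run."""

    time: np.ndarray
    v: np.ndarray
    mod_freq: float
    bins_per_cycle: int

    @property
    def n_cycles(self) -> int:
        return self.v.size // self.bins_per_cycle

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "eye_velocity": self.v})


@dataclasses.dataclass
class ModulationResult:
    """Half-wave sinusoid fit of a cycle-averaged eye-velocity trace."""

    pev: float
    nev: float
    n_cycles: int
    fit_residual: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pev) and np.isfinite(self.nev)):
            raise ParameterError("pev and nev must be finite")


@dataclasses.dataclass
class ScanGrid:
    """Long-format results of a parameter scan plus its axis definitions."""

    axes: dict
    table: pd.DataFrame
    meta: dict

    def pivot(self, value: str, index: str, columns: str) -> pd.DataFrame:
        return self.table.pivot(index=index, columns=columns, values=value)

    def save(self, csv_path, meta_path=None) -> None:
        self.table.to_csv(csv_path, index=False)
        if meta_path is not None:
            import json

            with open(meta_path, "w") as fh:
                json.dump(
                    {"axes": {k: np.asarray(v).tolist() for k, v in self.axes.items()}, **self.meta},
                    fh,
                    indent=2,
                )


def config_for_mode(
    base: StimulationConfig, mode: str, amp_depth: float | None = None, rate_depth: float | None = None
) -> StimulationConfig:
    """Stimulation config with depths consistent with the requested mode."""
    if mode == MODE_PAM:
        return base.replace(amp_mod_depth=0.25 if amp_depth is None else amp_depth, rate_mod_depth=0.0)
    if mode == MODE_PRM:
        return base.replace(amp_mod_depth=0.0, rate_mod_depth=0.25 if rate_depth is None else rate_depth)
    if mode == MODE_HYBRID:
        return base.replace(
            amp_mod_depth=0.25 if amp_depth is None else amp_depth,
            rate_mod_depth=0.25 if rate_depth is None else rate_depth,
        )
    if mode == MODE_BASELINE:
        return base.replace(amp_mod_depth=0.0, rate_mod_depth=0.0)
    raise ParameterError(
        f"mode must be one of '{MODE_PAM}', '{MODE_PRM}', '{MODE_HYBRID}', '{MODE_BASELINE}', got {mode!r}"
    )


def _check_mode(config: StimulationConfig, mode: str) -> None:
    if mode == MODE_PAM and (config.amp_mod_depth <= 0 or config.rate_mod_depth != 0):
        raise ParameterError("PAM requires amp_mod_depth > 0 and rate_mod_depth == 0")
    if mode == MODE_PRM and (config.rate_mod_depth <= 0 or config.amp_mod_depth != 0):
        raise ParameterError("PRM requires rate_mod_depth > 0 and amp_mod_depth == 0")
    if mode == MODE_HYBRID and (config.amp_mod_depth <= 0 or config.rate_mod_depth <= 0):
        raise ParameterError("hybrid requires both depths > 0")
    if mode == MODE_BASELINE and (config.amp_mod_depth != 0 or config.rate_mod_depth != 0):
        raise ParameterError("baseline (null) mode requires both depths == 0")
    if mode not in (MODE_PAM, MODE_PRM, MODE_HYBRID, MODE_BASELINE):
        raise ParameterError(f"unknown mode {mode!r}")


def resting_velocity(state: SynapticState, pop: AfferentPopulation, config: StimulationConfig, stim_side: str = LEFT) -> float:
    """Deterministic eye velocity at mean rates under unmodulated stimulation."""
    rates = pop.mean_rest_rate.copy()
    mask = pop.stimulated_mask(recruited_count(config, pop.n_per_side, 0.0), stim_side)
    rates[mask] = np.maximum(rates[mask], config.baseline_rate)
    return eye_velocity(state, rates)


def run_modulation(
    state: SynapticState,
    pop: AfferentPopulation,
    config: StimulationConfig,
    mode: str,
    n_cycles: int = 4,
    seed: int = 0,
    *,
    stim_side: str = LEFT,
    bins_per_cycle: int = BINS_PER_CYCLE,
    rest_tolerance: float = 0.5,
) -> SimulationTrace:
    """Simulate ``n_cycles`` of sinusoidal modulation with frozen weights.

    The state must be adapted to the baseline condition (resting velocity
    within ``rest_tolerance``), otherwise the onset transient would masquerade
    as a modulation response.  Deterministic given seed.
    """
    _check_mode(config, mode)
    if n_cycles < 2:
        raise ParameterError("need at least 2 modulation cycles")
    rest = resting_velocity(state, pop, config, stim_side)
    if abs(rest) > rest_tolerance:
        raise StateError(
            f"state is not adapted to this baseline (resting velocity {rest:.3f} a.u. "
            f"exceeds {rest_tolerance}); run baseline adaptation first"
        )
    rng = spawn_rng(seed)
    n_bins = n_cycles * bins_per_cycle
    t = np.arange(n_bins) / (bins_per_cycle * config.mod_freq)
    counts = recruited_count(config, pop.n_per_side, modulation_envelope(t, config.amp_mod_depth, config.mod_freq))
    stim_rate = config.baseline_rate * (1.0 + modulation_envelope(t, config.rate_mod_depth, config.mod_freq))

    rates = pop.draw_residual(rng, n_bins)
    on_side = pop.side_mask(stim_side)
    recruited = on_side[None, :] & (pop.recruitment_rank[None, :] < counts[:, None])
    rates = np.where(recruited, np.maximum(rates, stim_rate[:, None]), rates)

    arg = (rates / state.rate_scale) @ state.weights - state.bias
    v = state.output_gain * np.tanh(state.input_scale * arg)
    return SimulationTrace(time=t, v=v, mod_freq=config.mod_freq, bins_per_cycle=bins_per_cycle)


def peak_eye_velocity(trace: SimulationTrace, mod_freq: float | None = None) -> ModulationResult:
    """PEV/NEV by half-wave sinusoid fits of the cycle-averaged trace.

    The first cycle is discarded, the remaining cycles are averaged by phase,
    and a sinusoid amplitude plus an intercept is least-squares fitted to
    each half-cycle separately (the intercept keeps any residual resting
    nystagmus from leaking into the modulation amplitude, mirroring the
    offset term of the clinical per-cycle fits).  PEV is the positive-half
    amplitude (clamped at 0 from below) and NEV the negated negative-half
    amplitude (clamped at 0 from above), so PEV >= 0 >= NEV always holds.
    """
    if trace.n_cycles < 2:
        raise ParameterError("trace must cover at least 2 full cycles")
    bpc = trace.bins_per_cycle
    cycles = trace.v[: trace.n_cycles * bpc].reshape(trace.n_cycles, bpc)[1:]
    mean_cycle = cycles.mean(axis=0)
    phase = 2.0 * np.pi * np.arange(bpc) / bpc
    s = np.sin(phase)
    pos = phase < np.pi
    neg = ~pos

    def _half_amp(mask):
        design = np.column_stack([s[mask], np.ones(mask.sum())])
        coef, *_ = np.linalg.lstsq(design, mean_cycle[mask], rcond=None)
        return float(coef[0])

    a_pos = _half_amp(pos)
    a_neg = _half_amp(neg)
    fit = np.where(pos, max(a_pos, 0.0) * s, max(a_neg, 0.0) * s)
    residual = float(np.sqrt(np.mean((mean_cycle - fit) ** 2)))
    return ModulationResult(
        pev=max(a_pos, 0.0),
        nev=min(-a_neg, 0.0),
        n_cycles=trace.n_cycles - 1,
        fit_residual=residual,
    )


# ---------------------------------------------------------------------------
# Model building convenience


def default_acute_model(
    seed: int = 0,
    *,
    stim: StimulationConfig | None = None,
    adapt: AdaptationConfig | None = None,
    n_per_side: int = 1000,
    rate_mean: float = 26.3,
    rate_sd: float = 6.6,
    **nuclei_kwargs,
) -> ThreePhaseResult:
    """Sample a population and run the three-phase acute adaptation.

    This is the standard preamble of every protocol: 1000 afferents per side,
    200-pps baseline recruiting 40% of one side, bias/synapse learning-rate
    ratio 2e3, all overridable.
    """
    stim = stim if stim is not None else StimulationConfig()
    adapt = adapt if adapt is not None else AdaptationConfig()
    pop = sample_population(n_per_side=n_per_side, rate_mean=rate_mean, rate_sd=rate_sd, seed=seed)
    return adapt_three_phase(pop, stim, adapt, seed=seed + 1, **nuclei_kwargs)


def _measure(state, pop, base, mode, amp, rate, seed, n_cycles=4):
    cfg = config_for_mode(base, mode, amp_depth=amp, rate_depth=rate)
    trace = run_modulation(state, pop, cfg, mode, n_cycles=n_cycles, seed=seed)
    return peak_eye_velocity(trace)


# ---------------------------------------------------------------------------
# Scans


def scan_residual_vs_baseline(
    residual_means: Sequence[float] | None = None,
    baseline_rates: Sequence[float] | None = None,
    master_seed: int = 0,
    *,
    depth: float = 0.25,
    baseline_fraction: float = 0.40,
    n_per_side: int = 1000,
    adapt: AdaptationConfig | None = None,
) -> ScanGrid:
    """PEV(PAM) - PEV(PRM) over residual-rate means and baseline pulse rates.

    Each cell resamples the population, re-runs the three-phase adaptation at
    that baseline rate, and measures both modalities at the fixed depth.
    """
    residual_means = np.asarray(residual_means if residual_means is not None else np.linspace(5, 60, 12), float)
    baseline_rates = np.asarray(baseline_rates if baseline_rates is not None else np.linspace(50, 400, 12), float)
    adapt = adapt if adapt is not None else AdaptationConfig()
    rows = []
    for i, res in enumerate(residual_means):
        for j, prb in enumerate(baseline_rates):
            idx = i * len(baseline_rates) + j
            cell_seed = int(spawn_rng(master_seed, idx).integers(2**31))
            stim = StimulationConfig(baseline_rate=float(prb), baseline_fraction=baseline_fraction)
            pop = sample_population(n_per_side=n_per_side, rate_mean=float(res), seed=cell_seed)
            model = adapt_three_phase(pop, stim, adapt, seed=cell_seed + 1)
            pam = _measure(model.post_baseline, pop, stim, MODE_PAM, depth, 0.0, cell_seed + 2)
            prm = _measure(model.post_baseline, pop, stim, MODE_PRM, 0.0, depth, cell_seed + 3)
            rows.append(
                {
                    "residual_mean": res,
                    "baseline_rate": prb,
                    "pev_pam": pam.pev,
                    "nev_pam": pam.nev,
                    "pev_prm": prm.pev,
                    "nev_prm": prm.nev,
                    "pev_diff": pam.pev - prm.pev,
                    "seed": cell_seed,
                }
            )
    return ScanGrid(
        axes={"residual_mean": residual_means, "baseline_rate": baseline_rates},
        table=pd.DataFrame(rows),
        meta={"master_seed": master_seed, "depth": depth, "n_per_side": n_per_side},
    )


def scan_learning_ratio(
    ratios: Sequence[float] | None = None,
    master_seed: int = 0,
    *,
    stim: StimulationConfig | None = None,
    depth: float = 0.25,
    alpha_s: float = 1.0e-4,
    n_per_side: int = 1000,
) -> ScanGrid:
    """PRM output and PAM symmetry across bias/synapse learning-rate ratios.

    Per ratio the baseline phase is re-adapted from scratch; the table reports
    PEV for PRM and the PAM symmetry ratio PEV/|NEV| (toward 1 when the offset
    absorbs the onset error and spares the weights).
    """
    ratios = np.asarray(ratios if ratios is not None else np.logspace(0, 5, 11), float)
    stim = stim if stim is not None else StimulationConfig()
    rows = []
    for idx, ratio in enumerate(ratios):
        cell_seed = int(spawn_rng(master_seed, idx).integers(2**31))
        adapt = AdaptationConfig.with_ratio(float(ratio), alpha_s=alpha_s)
        pop = sample_population(n_per_side=n_per_side, seed=cell_seed)
        model = adapt_three_phase(pop, stim, adapt, seed=cell_seed + 1)
        pam = _measure(model.post_baseline, pop, stim, MODE_PAM, depth, 0.0, cell_seed + 2)
        prm = _measure(model.post_baseline, pop, stim, MODE_PRM, 0.0, depth, cell_seed + 3)
        symmetry = pam.pev / abs(pam.nev) if abs(pam.nev) > 1e-9 else np.inf
        rows.append(
            {
                "ratio": ratio,
                "pev_prm": prm.pev,
                "pev_pam": pam.pev,
                "nev_pam": pam.nev,
                "pam_symmetry": symmetry,
                "seed": cell_seed,
            }
        )
    return ScanGrid(
        axes={"ratio": ratios},
        table=pd.DataFrame(rows),
        meta={"master_seed": master_seed, "depth": depth, "n_per_side": n_per_side},
    )


def transition_midpoint(x: np.ndarray, y: np.ndarray, *, log_x: bool = True) -> float:
    """Locate where a monotone-trend curve crosses midway between its plateaus.

    The plateaus are the first and last samples; the crossing is found on the
    first straddling segment and interpolated linearly (in log10(x) when
    ``log_x``).  Used to place the hetero/homosynaptic transition of the
    learning-ratio scan.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ParameterError("need at least 3 scan points to locate a transition")
    lo, hi = y[0], y[-1]
    if np.isclose(lo, hi):
        raise ParameterError("no transition: the curve's end plateaus are equal")
    mid = 0.5 * (lo + hi)
    xs = np.log10(x) if log_x else x
    for k in range(y.size - 1):
        y0, y1 = y[k], y[k + 1]
        if (y0 - mid) * (y1 - mid) <= 0 and y0 != y1:
            frac = (mid - y0) / (y1 - y0)
            xm = xs[k] + frac * (xs[k + 1] - xs[k])
            return float(10**xm) if log_x else float(xm)
    raise ParameterError("curve never crosses the midpoint between its plateaus")


def learning_ratio_transition(grid: ScanGrid) -> dict:
    """Transition ratios of a learning-ratio scan.

    Returns the midpoints of the PAM-symmetry decline and the PRM-PEV rise,
    plus their geometric mean as the single transition estimate (the two
    indicators move together across the hetero/homosynaptic boundary).
    """
    t = grid.table.sort_values("ratio")
    r = t["ratio"].to_numpy()

    def _safe_mid(values):
        try:
            return transition_midpoint(r, values)
        except ParameterError:
            return float("nan")

    sym_mid = _safe_mid(t["pam_symmetry"].to_numpy())
    prm_mid = _safe_mid(t["pev_prm"].to_numpy())
    both = [m for m in (sym_mid, prm_mid) if np.isfinite(m)]
    combined = float(np.exp(np.mean(np.log(both)))) if both else float("nan")
    return {
        "symmetry_midpoint": sym_mid,
        "prm_rise_midpoint": prm_mid,
        "transition_ratio": combined,
    }


def scan_modulation_depth(
    depths: Sequence[float] | None = None,
    baseline_rates: Sequence[float] = (100.0, 200.0),
    master_seed: int = 0,
    *,
    adapt: AdaptationConfig | None = None,
    n_per_side: int = 1000,
) -> ScanGrid:
    """Raw and 10%-normalized PEV across modulation depths for PAM and PRM."""
    depths = np.asarray(depths if depths is not None else np.arange(0.1, 0.51, 0.1), float)
    adapt = adapt if adapt is not None else AdaptationConfig()
    rows = []
    for j, prb in enumerate(baseline_rates):
        cell_seed = int(spawn_rng(master_seed, j).integers(2**31))
        stim = StimulationConfig(baseline_rate=float(prb))
        pop = sample_population(n_per_side=n_per_side, seed=cell_seed)
        model = adapt_three_phase(pop, stim, adapt, seed=cell_seed + 1)
        for mode in (MODE_PAM, MODE_PRM):
            pevs = []
            for k, d in enumerate(depths):
                amp = d if mode == MODE_PAM else 0.0
                rate = d if mode == MODE_PRM else 0.0
                res = _measure(model.post_baseline, pop, stim, mode, amp, rate, cell_seed + 10 + k)
                pevs.append(res.pev)
            ref = pevs[0] if pevs[0] > 0 else np.nan
            for d, p in zip(depths, pevs):
                rows.append(
                    {
                        "baseline_rate": prb,
                        "mode": mode,
                        "depth": d,
                        "pev": p,
                        "pev_normalized": p / ref,
                        "seed": cell_seed,
                    }
                )
    return ScanGrid(
        axes={"depth": depths, "baseline_rate": np.asarray(baseline_rates, float), "mode": np.asarray([MODE_PAM, MODE_PRM])},
        table=pd.DataFrame(rows),
        meta={"master_seed": master_seed, "n_per_side": n_per_side},
    )


def normalized_depth_slope(depths: np.ndarray, pevs: np.ndarray) -> float:
    """Linear-fit slope of PEV normalized to its lowest-depth value,
    expressed per 10% of modulation depth (1.0 means +100% PEV per +10%)."""
    depths = np.asarray(depths, float)
    pevs = np.asarray(pevs, float)
    norm = pevs / pevs[0]
    slope = np.polyfit(depths / 0.1, norm, 1)[0]
    return float(slope)


def comodulation_surface(
    pam_depths: Sequence[float] | None = None,
    prm_depths: Sequence[float] | None = None,
    master_seed: int = 0,
    *,
    stim: StimulationConfig | None = None,
    adapt: AdaptationConfig | None = None,
    n_per_side: int = 1000,
    model: ThreePhaseResult | None = None,
) -> ScanGrid:
    """PEV over the 2-D grid of amplitude x rate modulation depths.

    The margins (one depth zero) reproduce the pure-PAM and pure-PRM curves.
    A pre-adapted ``model`` may be supplied to reuse across grids.
    """
    pam_depths = np.asarray(pam_depths if pam_depths is not None else np.linspace(0, 0.5, 6), float)
    prm_depths = np.asarray(prm_depths if prm_depths is not None else np.linspace(0, 1.0, 6), float)
    stim = stim if stim is not None else StimulationConfig()
    if model is None:
        seed0 = int(spawn_rng(master_seed, 0).integers(2**31))
        pop = sample_population(n_per_side=n_per_side, seed=seed0)
        model = adapt_three_phase(pop, stim, adapt if adapt is not None else AdaptationConfig(), seed=seed0 + 1)
    pop = model.population
    rows = []
    for i, a in enumerate(pam_depths):
        for j, p in enumerate(prm_depths):
            run_seed = int(spawn_rng(master_seed, 1, i * len(prm_depths) + j).integers(2**31))
            if a == 0 and p == 0:
                pev, nev = 0.0, 0.0
            else:
                mode = MODE_HYBRID if (a > 0 and p > 0) else (MODE_PAM if a > 0 else MODE_PRM)
                res = _measure(model.post_baseline, pop, stim, mode, a, p, run_seed)
                pev, nev = res.pev, res.nev
            rows.append({"pam_depth": a, "prm_depth": p, "pev": pev, "nev": nev, "seed": run_seed})
    return ScanGrid(
        axes={"pam_depth": pam_depths, "prm_depth": prm_depths},
        table=pd.DataFrame(rows),
        meta={"master_seed": master_seed, "n_per_side": n_per_side},
    )


def equipotent_contour(
    model: ThreePhaseResult,
    pam_depths: Iterable[float],
    *,
    stim: StimulationConfig | None = None,
    target_pev: float | None = None,
    reference_pam_depth: float = 0.25,
    tol: float = 0.01,
    max_iter: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Rate-modulation depth making each amplitude depth equipotent to a target.

    The target defaults to the PEV of pure PAM at ``reference_pam_depth``.
    For each amplitude depth, the rate depth is bisected until the PEV matches
    within ``tol`` (fraction of the target).  Rows where the target is not
    reachable within rate depth <= 1 carry NaN.
    """
    stim = stim if stim is not None else StimulationConfig()
    pop = model.population
    state = model.post_baseline
    if target_pev is None:
        target_pev = _measure(state, pop, stim, MODE_PAM, reference_pam_depth, 0.0, seed).pev
    rows = []
    for i, a in enumerate(pam_depths):
        run_seed = int(spawn_rng(seed, i).integers(2**31))

        def pev_at(p: float) -> float:
            if a == 0 and p == 0:
                return 0.0
            mode = MODE_HYBRID if (a > 0 and p > 0) else (MODE_PAM if a > 0 else MODE_PRM)
            return _measure(state, pop, stim, mode, a, p, run_seed).pev

        lo, hi = 0.0, 1.0
        f_lo, f_hi = pev_at(lo) - target_pev, pev_at(hi) - target_pev
        if f_lo >= 0:
            prm_depth, pev = 0.0, f_lo + target_pev
        elif f_hi < 0:
            prm_depth, pev = np.nan, f_hi + target_pev
        else:
            pev = np.nan
            for _ in range(max_iter):
                mid = 0.5 * (lo + hi)
                f_mid = pev_at(mid) - target_pev
                if abs(f_mid) <= tol * target_pev:
                    pev = f_mid + target_pev
                    break
                if f_mid < 0:
                    lo = mid
                else:
                    hi = mid
            prm_depth = 0.5 * (lo + hi)
            if np.isnan(pev):
                pev = pev_at(prm_depth)
        rows.append({"pam_depth": float(a), "prm_depth": prm_depth, "pev": pev, "target_pev": target_pev})
    return pd.DataFrame(rows)
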