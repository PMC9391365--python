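"""Synthetic subject-level datasets with the structure the analysis assumes.

The generator couples three pieces:

* a K-armed softmax agent that picks a mental strategy for every
  IMAGINE_REWARD block and updates the strategy's value from the feedback it
  perceives (a temporal-difference / Rescorla-Wagner block update), with
  optimistic initialization so that early training explores the strategy set;
* a BOLD forward model — strategy efficacy drives a boxcar neural amplitude,
  convolved with a canonical double-gamma HRF, on top of AR(1) noise, a slow
  linear drift and aliased physiological sinusoids shared with CSF/WM voxels;
* the online feedback engine running in-the-loop during training runs, with
  the arm's polarity; the agent perceives the displayed value at a 5 s
  hemodynamic lag.

Arm semantics.  In the standard arm the display tracks SN/VTA percent signal
change, so effective strategies earn positive feedback and the agent can
converge on them.  In the inverted (control) arm the display is sign-flipped:
no strategy ever earns sustained positive feedback.  Because participants are
instructed to upregulate, a persistently "failing" strategy is abandoned
rather than assigned an ever more aversive value — strategy values are
floored at the neutral prior.  The inverted-arm agent therefore cycles
through its strategies without converging, the behaviour the control group is
meant to produce.  Non-learners (learning rate 0) keep constant values and
choose uniformly throughout.

The dorsolateral prefrontal series carries a task component (imagery
engagement), a temporal-difference tracking component whose weight decays
with learning progress, and independent noise; during training runs an
IMAGINE-specific dlPFC-to-SN/VTA coupling of configurable strength is added
(the quantity the PPI analysis estimates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import (IMAGINE, MID_RANGES, MIDTrialSpec, RunDesign,
                     SessionDesign, build_mid_design, build_session_design,
                     labels_per_volume, mid_run_length)
from .feedback import FeedbackEngine, trace_frame

BASELINE_LEVEL = 100.0
PERCEIVED_LAG_S = 5.0  # hemodynamic delay participants were familiarized with

REGIONS = ("SN_VTA", "dlPFC", "control_parahippocampus")


# ---------------------------------------------------------------------------
# hemodynamic response


def hrf(t, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
        dispersion: float = 1.0, u_dispersion: float = 1.0,
        ratio: float = 1.0 / 6.0):
    """Canonical double-gamma HRF, normalized to unit peak.

    Peak near 5-6 s, undershoot near 16 s; hrf(0) = 0.
    """
    t = np.asarray(t, dtype=float)
    pos = sps.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    neg = sps.gamma.pdf(t, undershoot_delay / u_dispersion, scale=u_dispersion)
    h = pos - ratio * neg
    dense = np.arange(0, 32.0, 0.01)
    peak = (sps.gamma.pdf(dense, peak_delay / dispersion, scale=dispersion)
            - ratio * sps.gamma.pdf(dense, undershoot_delay / u_dispersion,
                                    scale=u_dispersion)).max()
    return h / peak


def hrf_kernel(tr: float, duration: float = 32.0) -> np.ndarray:
    """HRF sampled on the TR grid, for discrete convolution."""
    return hrf(np.arange(0.0, duration, tr))


# ---------------------------------------------------------------------------
# temporal-difference error


def td_error(r_next: float, v_next: float, v_current: float,
             gamma: float = 1.0) -> float:
    """Full TD error: R_{t+1} + gamma * V(S_{t+1}) - V(S_t)."""
    if not (0.0 < gamma <= 1.0):
        raise ValueError("discount gamma must be in (0, 1]")
    return r_next + gamma * v_next - v_current


def td_error_collapsed(feedback_next: float, feedback_current: float) -> float:
    """Collapsed continuous-feedback TD error: the difference between
    consecutive feedback states."""
    return feedback_next - feedback_current


# ---------------------------------------------------------------------------
# agent


@dataclass
class AgentParams:
    """K-armed softmax strategy-selection agent.

    efficacies
        True ability of each mental strategy to raise SN/VTA activity, in
        [0, 1]; the agent never observes these directly.
    learning_rate
        alpha of the block-level value update; 0 defines a non-learner.
    temperature
        softmax temperature (feedback display units).
    value_init
        optimistic initial value (display units; the display clamp is a
        natural upper bound).
    value_floor
        lower bound on strategy values; the neutral prior for abandoned
        strategies (see module docstring).
    """

    efficacies: np.ndarray
    learning_rate: float = 0.35
    temperature: float = 0.12
    discount: float = 1.0
    value_init: float = 1.0
    value_floor: float = 0.0
    #: per-run multipliers on the softmax temperature: participants are
    #: instructed to try out strategies early in training and commit to the
    #: best one later, so early runs are deliberately exploratory
    exploration: dict = field(
        default_factory=lambda: {"baseline": 1.0, "training1": 5.0,
                                 "training2": 1.5, "transfer": 1.0})

    def __post_init__(self):
        self.efficacies = np.asarray(self.efficacies, dtype=float)
        if self.efficacies.ndim != 1 or self.efficacies.size < 1:
            raise ValueError("efficacies must be a non-empty 1-d array")
        if np.any((self.efficacies < 0) | (self.efficacies > 1)):
            raise ValueError("efficacies must lie in [0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def n_strategies(self) -> int:
        return self.efficacies.size


@dataclass
class AgentState:
    """Mutable agent state plus per-run records."""

    values: np.ndarray
    chosen: dict = field(default_factory=dict)          # run_type -> [block strategy]
    rewards: dict = field(default_factory=dict)         # run_type -> [block reward]
    delta_trace: dict = field(default_factory=dict)     # run_type -> per-volume delta
    value_history: list = field(default_factory=list)   # snapshot after each update


def agent_select(values: np.ndarray, temperature: float, rng) -> int:
    """Softmax draw over values / temperature (seed-deterministic)."""
    v = np.asarray(values, dtype=float) / temperature
    p = np.exp(v - v.max())
    p /= p.sum()
    return int(rng.choice(p.size, p=p))


def agent_update(values: np.ndarray, chosen: int, block_feedback: float,
                 alpha: float, floor: float = -np.inf) -> np.ndarray:
    """Update the chosen strategy's value toward the perceived block feedback.

    V_chosen <- max(floor, V_chosen + alpha * (feedback - V_chosen)); other
    values unchanged.
    """
    out = np.array(values, dtype=float)
    delta = block_feedback - out[chosen]
    out[chosen] = max(floor, out[chosen] + alpha * delta)
    return out


# ---------------------------------------------------------------------------
# noise / coupling / subject parameters


@dataclass
class NoiseParams:
    """AR(1) + drift + physiological noise for region time series.

    innovation_sd defaults to a stationary SD of 2.0 signal units, i.e. a
    contrast-to-noise ratio of about 0.5 for a unit regulation gain.
    """

    ar_coefficient: float = 0.3
    innovation_sd: float = 2.0 * np.sqrt(1.0 - 0.3 ** 2)
    drift_slope: float = 0.002                      # signal units per second
    physio_amplitudes: tuple = (0.3, 0.2)
    physio_frequencies: tuple = (0.25, 1.0)         # Hz, aliased on the TR grid

    @property
    def stationary_sd(self) -> float:
        return self.innovation_sd / np.sqrt(1.0 - self.ar_coefficient ** 2)


@dataclass
class CouplingParams:
    """dlPFC construction: task drive, TD tracking, and PPI modulation."""

    dlpfc_td_weight_initial: float = 1.0
    dlpfc_td_weight_decay: float = 0.85
    dlpfc_task_gain: float = 1.0
    connectivity_modulation: float = 0.6   # IMAGINE-specific dlPFC->SN/VTA gain
    dlpfc_noise_sd: float = 1.0


@dataclass
class MIDParams:
    """Generative gains for the MID session (dlPFC response per trial)."""

    general_gain: float = 1.0     # signal units per CHF
    adaptive_gain: float = 0.5    # signal units per range-normalized CHF
    cue_response: float = 0.5     # unmodulated response to any reward cue


@dataclass
class SubjectParams:
    agent: AgentParams
    regulation_gain: float = 1.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    mid: MIDParams = field(default_factory=MIDParams)
    arm: str = "standard"


@dataclass
class SubjectDataset:
    design: SessionDesign
    roi_series: dict            # run_type -> DataFrame (one column per region)
    csf_wm: dict                # run_type -> voxel x time ndarray
    motion: dict                # run_type -> DataFrame with 6 columns
    feedback: dict              # run_type -> FeedbackTrace DataFrame
    agent: AgentState
    truth: SubjectParams


@dataclass
class MIDDataset:
    trials: list
    tr: float
    n_volumes: int
    roi_series: pd.DataFrame
    csf_wm: np.ndarray
    motion: pd.DataFrame
    truth: MIDParams


# ---------------------------------------------------------------------------
# noise pieces


def ar1_series(n: int, phi: float, innovation_sd: float, rng) -> np.ndarray:
    """Stationary AR(1) series (first sample drawn from the stationary law)."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, innovation_sd / np.sqrt(1.0 - phi ** 2))
    eps = rng.normal(0.0, innovation_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def _physio_basis(n: int, tr: float, noise: NoiseParams, rng) -> np.ndarray:
    """Physiological sinusoids sampled (aliased) on the TR grid, one row per
    component, with random phases."""
    t = np.arange(n) * tr
    rows = []
    for amp, freq in zip(noise.physio_amplitudes, noise.physio_frequencies):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        rows.append(amp * np.sin(2.0 * np.pi * freq * t + phase))
    return np.array(rows)


def _region_noise(n: int, tr: float, noise: NoiseParams, rng,
                  physio: np.ndarray | None, physio_loading: float) -> np.ndarray:
    out = ar1_series(n, noise.ar_coefficient, noise.innovation_sd, rng)
    out += noise.drift_slope * np.arange(n) * tr
    if physio is not None and physio_loading:
        out += physio_loading * physio.sum(axis=0)
    return out


# ---------------------------------------------------------------------------
# single-run simulation


def _imagine_blocks(run: RunDesign):
    return [b for b in run.blocks if b.condition == IMAGINE]


def _block_slice(block, tr: float) -> slice:
    return slice(int(round(block.onset / tr)), int(round(block.end / tr)))


def _convolve_amplitude(amp: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(amp, kernel)[: amp.size]


def _sustained_conv(amp: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """HRF convolution normalized so a sustained unit amplitude plateaus at
    1: the regulation gain is then the sustained percent signal change a
    full-efficacy strategy produces."""
    return np.convolve(amp, kernel)[: amp.size] / kernel.sum()


def _simulate_nf_run(run: RunDesign, params: SubjectParams, state: AgentState,
                     rng, kernel: np.ndarray):
    """Simulate one neurofeedback-session run (any type).

    Returns (snvta_base, neural_efficacy_amplitude, trace_df_or_None) and
    mutates the agent state (choices; value updates in training runs).
    """
    n, tr = run.n_volumes, run.tr
    agent = params.agent
    tau = agent.temperature * agent.exploration.get(run.run_type, 1.0)
    physio = _physio_basis(n, tr, params.noise, rng)
    noise = _region_noise(n, tr, params.noise, rng, physio, physio_loading=1.0)
    labels = labels_per_volume(run, 0.0)

    amp_e = np.zeros(n)          # chosen-strategy efficacy per volume
    chosen: list[int] = []
    rewards: list[float] = []

    if not run.feedback_enabled:
        for _ in _imagine_blocks(run):
            k = agent_select(state.values, tau, rng)
            chosen.append(k)
        for blk, k in zip(_imagine_blocks(run), chosen):
            amp_e[_block_slice(blk, tr)] = agent.efficacies[k]
        bold = _sustained_conv(params.regulation_gain * amp_e, kernel)
        snvta = BASELINE_LEVEL + bold + noise
        state.chosen[run.run_type] = chosen
        return snvta, amp_e, None, physio

    # training run: engine in the loop, block-wise sequential generation
    engine = FeedbackEngine(run.polarity)
    lag = int(np.ceil(PERCEIVED_LAG_S / tr))
    raw = np.empty(n)
    displayed = np.full(n, np.nan)
    trace_rows = []
    imagine_windows: list[tuple[int, int]] = []   # lagged perception windows

    def perceive(window):
        lo, hi = window
        vals = displayed[lo:min(hi, n)]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else 0.0

    for blk in run.blocks:
        sl = _block_slice(blk, tr)
        if blk.condition == IMAGINE:
            # learn from the previous IMAGINE block before choosing again
            if imagine_windows and agent.learning_rate > 0:
                r = perceive(imagine_windows[-1])
                rewards.append(r)
                state.values = agent_update(state.values, chosen[-1], r,
                                            agent.learning_rate,
                                            agent.value_floor)
                state.value_history.append(state.values.copy())
            k = agent_select(state.values, tau, rng)
            chosen.append(k)
            amp_e[sl] = agent.efficacies[k]
            imagine_windows.append((sl.start + lag, sl.stop + lag))
        bold = _sustained_conv(params.regulation_gain * amp_e[: sl.stop],
                               kernel)
        for t in range(sl.start, sl.stop):
            raw[t] = BASELINE_LEVEL + bold[t] + noise[t]
            row = engine.step(raw[t], labels[t])
            trace_rows.append(row)
            if row.valid:
                displayed[t] = row.displayed
    # final IMAGINE block: perceive whatever lagged samples exist
    if imagine_windows and agent.learning_rate > 0:
        r = perceive(imagine_windows[-1])
        rewards.append(r)
        state.values = agent_update(state.values, chosen[-1], r,
                                    agent.learning_rate, agent.value_floor)
        state.value_history.append(state.values.copy())

    state.chosen[run.run_type] = chosen
    state.rewards[run.run_type] = rewards
    return raw, amp_e, trace_frame(trace_rows), physio


def _td_regressor(snvta: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Per-TR stick series scaled by the collapsed TD trace (backward
    difference of the SN/VTA signal), convolved with the HRF."""
    delta = np.zeros_like(snvta)
    delta[1:] = np.diff(snvta)
    return _convolve_amplitude(delta, kernel), delta


def _learning_progress(state: AgentState, agent: AgentParams) -> float:
    """Realized learning in [0, 1]: how far mean chosen efficacy in training
    run 2 moved from the strategy-set mean toward the best strategy."""
    chosen2 = state.chosen.get("training2")
    if not chosen2:
        return 0.0
    e = agent.efficacies
    attained = e[np.asarray(chosen2)].mean()
    denom = e.max() - e.mean()
    if denom <= 1e-12:
        return 0.0
    return float(np.clip((attained - e.mean()) / denom, 0.0, 1.0))


def simulate_subject(params: SubjectParams, design: SessionDesign | None = None,
                     seed: int | np.random.SeedSequence = 0, *,
                     include_amygdala: bool = False) -> SubjectDataset:
    """Simulate one subject's full neurofeedback session.

    Runs are generated in session order so that the agent's values evolve
    through training and carry into the transfer run.  Same seed, same
    params: bit-identical dataset.
    """
    if design is None:
        design = build_session_design(arm=params.arm)
    if design.arm != params.arm:
        raise ValueError("design arm and subject arm disagree")
    rng = np.random.default_rng(seed)
    tr = design.runs[0].tr
    kernel = hrf_kernel(tr)
    state = AgentState(values=np.full(params.agent.n_strategies,
                                      params.agent.value_init))

    roi, csf_wm, motion, fb = {}, {}, {}, {}
    n_csf_voxels = 60
    for run in design.runs:
        snvta, amp_e, trace, physio = _simulate_nf_run(run, params, state, rng,
                                                       kernel)
        n = run.n_volumes
        # dlPFC: task engagement + TD tracking (training runs) + noise
        cp = params.coupling
        task = _sustained_conv(amp_e, kernel)
        dlpfc = BASELINE_LEVEL + cp.dlpfc_task_gain * task
        if run.feedback_enabled:
            td_reg, delta = _td_regressor(snvta, kernel)
            state.delta_trace[run.run_type] = delta
            if run.run_type == "training1":
                w = cp.dlpfc_td_weight_initial
            else:
                w = cp.dlpfc_td_weight_initial * (
                    1.0 - cp.dlpfc_td_weight_decay
                    * _learning_progress(state, params.agent))
            dlpfc = dlpfc + w * td_reg
        dlpfc = dlpfc + 0.2 * physio.sum(axis=0) + ar1_series(
            n, params.noise.ar_coefficient,
            cp.dlpfc_noise_sd * np.sqrt(1.0 - params.noise.ar_coefficient ** 2),
            rng)
        # IMAGINE-specific dlPFC -> SN/VTA coupling (what the PPI estimates)
        if run.feedback_enabled and cp.connectivity_modulation:
            ind = (labels_per_volume(run, 0.0) == IMAGINE).astype(float)
            snvta = snvta + cp.connectivity_modulation * (
                ind - ind.mean()) * (dlpfc - dlpfc.mean())

        control = BASELINE_LEVEL + _region_noise(n, tr, params.noise, rng,
                                                 physio, physio_loading=0.8)
        cols = {"SN_VTA": snvta, "dlPFC": dlpfc,
                "control_parahippocampus": control}
        if include_amygdala:
            cols["amygdala"] = BASELINE_LEVEL + _region_noise(
                n, tr, params.noise, rng, physio, physio_loading=0.5)
        roi[run.run_type] = pd.DataFrame(cols)

        loadings = rng.uniform(0.5, 1.5, size=(n_csf_voxels, physio.shape[0]))
        csf_wm[run.run_type] = (BASELINE_LEVEL + loadings @ physio
                                + rng.normal(0.0, 1.0, size=(n_csf_voxels, n)))
        motion[run.run_type] = pd.DataFrame(
            {f"motion_{i}": ar1_series(n, 0.5, 0.02, rng) for i in range(6)})
        if trace is not None:
            fb[run.run_type] = trace

    return SubjectDataset(design=design, roi_series=roi, csf_wm=csf_wm,
                          motion=motion, feedback=fb, agent=state,
                          truth=params)


# ---------------------------------------------------------------------------
# MID session


def simulate_mid_subject(params: SubjectParams, trials: list[MIDTrialSpec],
                         seed: int | np.random.SeedSequence = 0,
                         tr: float = 2.0) -> MIDDataset:
    """Simulate the MID session (dlPFC + control region).

    The dlPFC response to a reward cue is
    ``cue_response + general_gain * magnitude + adaptive_gain * (magnitude /
    cue-type range)``: general sensitivity scales with absolute reward,
    adaptive coding with reward normalized to its context range.
    """
    rng = np.random.default_rng(seed)
    n = mid_run_length(trials, tr)
    t_grid = np.arange(n) * tr
    mid = params.mid
    signal = np.zeros(n)
    for trial in trials:
        resp = 0.0
        if trial.cue_type != "none":
            lo, hi = MID_RANGES[trial.cue_type]
            resp = (mid.cue_response + mid.general_gain * trial.magnitude
                    + mid.adaptive_gain * trial.magnitude / hi)
        else:
            resp = 0.0
        dt = t_grid - trial.cue_onset
        mask = dt >= 0
        signal[mask] += resp * hrf(dt[mask])
    physio = _physio_basis(n, tr, params.noise, rng)
    # dlPFC is a larger cortical ROI than the midbrain: noise at the same
    # level as its neurofeedback-session series
    cort = NoiseParams(
        ar_coefficient=params.noise.ar_coefficient,
        innovation_sd=params.coupling.dlpfc_noise_sd
        * np.sqrt(1.0 - params.noise.ar_coefficient ** 2),
        drift_slope=params.noise.drift_slope,
        physio_amplitudes=params.noise.physio_amplitudes,
        physio_frequencies=params.noise.physio_frequencies)
    dlpfc = BASELINE_LEVEL + signal + _region_noise(
        n, tr, cort, rng, physio, physio_loading=0.2)
    control = BASELINE_LEVEL + _region_noise(n, tr, params.noise, rng, physio,
                                             physio_loading=0.8)
    roi = pd.DataFrame({"dlPFC": dlpfc, "control_parahippocampus": control})
    loadings = rng.uniform(0.5, 1.5, size=(60, physio.shape[0]))
    csf_wm = BASELINE_LEVEL + loadings @ physio + rng.normal(0.0, 1.0,
                                                             size=(60, n))
    motion = pd.DataFrame(
        {f"motion_{i}": ar1_series(n, 0.5, 0.02, rng) for i in range(6)})
    return MIDDataset(trials=list(trials), tr=tr, n_volumes=n, roi_series=roi,
                      csf_wm=csf_wm, motion=motion, truth=mid)


# ---------------------------------------------------------------------------
# cohorts


def _draw_subject_params(archetype: str, arm: str, rng,
                         mid_coupling: bool = True) -> SubjectParams:
    """Draw one subject's parameters around the archetype means.

    A regulator owns one clearly effective imagery strategy (efficacy
    0.6-0.95) among mediocre alternatives and learns from feedback; a
    non-regulator neither learns (learning rate 0) nor has a discriminable
    strategy set (flat efficacies).  Regulation gain (sustained percent
    signal change at full efficacy) is log-normally spread so that true
    between-subject variation in transfer is comparable to its measurement
    noise — the regime a reliable training-transfer correlation requires.
    """
    gain = float(4.0 * np.exp(rng.normal(0.0, 0.35)))
    if archetype == "regulator":
        e_best = rng.uniform(0.6, 0.95)
        efficacies = np.append(rng.uniform(0.1, 0.4, size=4), e_best)
        rng.shuffle(efficacies)
        alpha = float(rng.uniform(0.3, 0.5))
    elif archetype == "non_regulator":
        base = rng.uniform(0.2, 0.45)
        efficacies = np.clip(base + rng.uniform(-0.03, 0.03, size=5), 0.0, 1.0)
        alpha = 0.0
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    agent = AgentParams(efficacies=efficacies, learning_rate=alpha,
                        temperature=0.10)
    capacity = 0.0
    if alpha > 0:
        capacity = float(np.clip(gain * (efficacies.max() - efficacies.mean())
                                 / 3.0, 0.0, 1.0))
    general_gain = float(max(0.2, rng.normal(1.0, 0.2)))
    if mid_coupling:
        adaptive_gain = float(max(0.05, 0.2 + 0.8 * capacity
                                  + rng.normal(0.0, 0.05)))
    else:
        adaptive_gain = float(max(0.05, rng.normal(0.5, 0.15)))
    mid = MIDParams(general_gain=general_gain, adaptive_gain=adaptive_gain)
    return SubjectParams(agent=agent, regulation_gain=gain, mid=mid, arm=arm)


def simulate_cohort(mix: dict[str, int], seed: int, *, arm: str = "standard",
                    study_id: str = "study2", mid_coupling: bool = True,
                    include_mid: bool = False,
                    design_kwargs: dict | None = None):
    """Simulate a cohort; returns (datasets, manifest DataFrame[, mid sets]).

    ``mix`` maps archetype name -> count, e.g. {"regulator": 20,
    "non_regulator": 20}; allocation is deterministic (archetypes in the
    given order), parameter draws and simulations are seed-deterministic.
    """
    if not mix or sum(mix.values()) < 1:
        raise ValueError("cohort mix must contain at least one subject")
    ss = np.random.SeedSequence(seed)
    datasets, mid_sets, rows = [], [], []
    idx = 0
    for archetype, count in mix.items():
        for _ in range(count):
            idx += 1
            sub_ss = ss.spawn(1)[0]
            param_rng = np.random.default_rng(sub_ss.spawn(1)[0])
            params = _draw_subject_params(archetype, arm, param_rng,
                                          mid_coupling=mid_coupling)
            design = build_session_design(subject_id=f"sub-{idx:03d}", arm=arm,
                                          study_id=study_id,
                                          **(design_kwargs or {}))
            ds = simulate_subject(params, design, seed=sub_ss.spawn(1)[0])
            datasets.append(ds)
            if include_mid:
                trial_seed = int(sub_ss.generate_state(1)[0] % (2 ** 31))
                trials = build_mid_design(trial_seed)
                mid_sets.append(simulate_mid_subject(
                    params, trials, seed=sub_ss.spawn(1)[0]))
            rows.append({
                "subject_id": design.subject_id, "arm": arm,
                "study_id": study_id, "archetype": archetype,
                "learning_rate": params.agent.learning_rate,
                "temperature": params.agent.temperature,
                "regulation_gain": params.regulation_gain,
                "efficacy_max": float(params.agent.efficacies.max()),
                "efficacy_mean": float(params.agent.efficacies.mean()),
                "mid_general_gain": params.mid.general_gain,
                "mid_adaptive_gain": params.mid.adaptive_gain,
            })
    manifest = pd.DataFrame(rows)
    if include_mid:
        return datasets, manifest, mid_sets
    return datasets, manifest


def export_nifti(dataset: SubjectDataset, run_type: str, out_dir,
                 grid: tuple = (2, 2, 2), weight_decay: float = 0.5):
    """Optional NIfTI export: a small voxel grid per region (region series
    plus independent voxel noise is NOT added — each voxel carries the region
    series scaled by its mask weight) and a matching ROI-weight mask.

    Returns the written file paths.
    """
    import nibabel as nib
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    affine = np.eye(4)
    for region, series in dataset.roi_series[run_type].items():
        n_vox = int(np.prod(grid))
        weights = weight_decay ** np.arange(n_vox)
        vox = np.outer(weights, series.to_numpy(float))
        img = nib.Nifti1Image(
            vox.reshape(*grid, -1).astype(np.float32), affine)
        mask = nib.Nifti1Image(
            weights.reshape(grid).astype(np.float32), affine)
        img_path = out_dir / f"{region}_{run_type}.nii.gz"
        mask_path = out_dir / f"{region}_mask.nii.gz"
        nib.save(img, img_path)
        nib.save(mask, mask_path)
        paths += [img_path, mask_path]
    return paths
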