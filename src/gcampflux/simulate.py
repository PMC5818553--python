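"""Forward model: stimulus trains -> axonal spikes -> presynaptic Ca2+ ->
indicator fluorescence -> synthetic movies, with full ground truth.

The model chain mirrors how a presynaptic GCaMP signal arises at the larval
NMJ.  Each electrical stimulus either triggers one axonal action potential
(AP), a short high-frequency burst of APs (hyperexcitable terminals), or
fails (conduction block while the axon is refractory).  Each AP injects a
fixed increment of cytosolic free Ca2+ into a single well-mixed compartment
that is cleared by a passive leak plus a saturable, ATP-dependent extrusion
pump (PMCA-like).  The indicator binds Ca2+ cooperatively (Hill binding)
with optional first-order binding kinetics, and boutons are rendered as
radially tapered disks onto noisy camera frames.

Every simulated trial carries a :class:`SimulationGroundTruth` record (AP
times, per-pulse delivery, latent Ca2+, noiseless dF/F, waveform label) so
the analysis modules can be validated against a known answer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StimulusProtocol",
    "ExcitabilityProfile",
    "CalciumModel",
    "IndicatorModel",
    "BoutonSpec",
    "ImagingModel",
    "FrameStack",
    "SpikeTrain",
    "SimulationGroundTruth",
    "generate_spike_trains",
    "true_waveform_label",
    "simulate_calcium",
    "hill_occupancy",
    "fluorescence_from_calcium",
    "saturation_ceiling",
    "simulate_trial",
    "add_trace_noise",
    "bouton_footprint",
    "render_movie",
    "render_coloc_pair",
    "make_roi_set",
    "generate_focal_record",
]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """A single stimulation trial: a constant-frequency pulse train.

    Times are absolute seconds from the start of the recording.  The number
    of pulses is ``floor(frequency * train_duration)`` with the first pulse
    delivered exactly at ``onset_time``.
    """

    frequency: float            # Hz
    train_duration: float = 2.0  # s
    onset_time: float = 1.0      # s
    record_duration: float = 8.0  # s
    pulse_width: float = 1e-4    # s (0.1 ms stimulus pulse)
    inter_trial_interval: float = 4.0  # s

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.onset_time < 0:
            raise ValueError("onset_time must be nonnegative")
        if self.onset_time + self.train_duration > self.record_duration:
            raise ValueError("train must end within the record")

    @property
    def n_pulses(self) -> int:
        return int(math.floor(self.frequency * self.train_duration + 1e-9))

    @property
    def pulse_times(self) -> np.ndarray:
        return self.onset_time + np.arange(self.n_pulses) / self.frequency

    @property
    def train_end(self) -> float:
        return self.onset_time + self.train_duration


@dataclass(frozen=True)
class ExcitabilityProfile:
    """How the motor axon translates stimulus pulses into APs.

    ``aps_per_stimulus > 1`` models supernumerary repetitive firing (a burst
    at ``burst_rate`` per pulse); ``failure_recovery_time`` models conduction
    failure: a pulse arriving before the axon has recovered from its last AP
    is not delivered.  ``rebound_*`` model post-train spontaneous firing seen
    under extreme hyperexcitability, starting ``rebound_delay`` after train
    end (0 duration means no post-train events).
    """

    aps_per_stimulus: int = 1
    burst_rate: float = 100.0       # Hz, intra-burst firing rate
    refractory_period: float = 0.002  # s
    failure_recovery_time: float = 0.005  # s
    rebound_rate: float = 0.0       # Hz
    rebound_duration: float = 0.0   # s
    rebound_delay: float = 1.0      # s after train end

    def __post_init__(self) -> None:
        if self.aps_per_stimulus < 0:
            raise ValueError("aps_per_stimulus must be >= 0")
        if self.aps_per_stimulus > 1 and self.burst_rate <= 0:
            raise ValueError("burst_rate must be positive for bursts")
        if self.refractory_period < 0:
            raise ValueError("refractory_period must be >= 0")
        if self.aps_per_stimulus > 1 and 1.0 / self.burst_rate < self.refractory_period:
            raise ValueError(
                "inconsistent profile: burst spacing "
                f"{1.0 / self.burst_rate:g} s shorter than refractory period "
                f"{self.refractory_period:g} s"
            )


PumpSchedule = Callable[[float], float]


@dataclass(frozen=True)
class CalciumModel:
    """Single-compartment residual-Ca2+ dynamics (leaky integrator).

    dCa/dt = -k_leak*(Ca - ca_rest)
             - scale(t)*pump_vmax*(Ca - ca_rest)/((Ca - ca_rest) + pump_km)
             + delta_ca_per_ap * sum_i delta(t - t_i)

    ``pump_scale_schedule`` maps elapsed experiment time (s) to a multiplier
    in [0, 1] on the pump's maximal rate; it implements metabolic rundown
    (mitochondrial uncoupling) and high-pH pump suppression.  ``None`` means
    a constant 1 (time-invariant model).
    """

    ca_rest: float = 50.0          # nM
    delta_ca_per_ap: float = 20.0  # nM per AP
    k_leak: float = 0.3            # 1/s
    pump_vmax: float = 0.0         # nM/s
    pump_km: float = 300.0         # nM
    pump_scale_schedule: PumpSchedule | None = None

    def __post_init__(self) -> None:
        if min(self.ca_rest, self.delta_ca_per_ap, self.k_leak,
               self.pump_vmax, self.pump_km) < 0:
            raise ValueError("rates and concentrations must be nonnegative")

    def pump_scale(self, t: float) -> float:
        if self.pump_scale_schedule is None:
            return 1.0
        return float(np.clip(self.pump_scale_schedule(t), 0.0, 1.0))


@dataclass(frozen=True)
class IndicatorModel:
    """Cooperative Ca2+ indicator: Hill binding with optional kinetics.

    ``rmax`` is the maximum dF/F at saturation relative to the Ca2+-free
    fluorescence; ``binding_tau`` is the first-order relaxation time of the
    bound fraction toward its quasi-static value (0 means instantaneous).
    """

    kd: float = 234.0        # nM
    hill_n: float = 3.3
    rmax: float = 1.5
    binding_tau: float = 0.0  # s
    f0: float = 100.0        # arbitrary fluorescence units at rest occupancy 0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.rmax <= 0 or self.binding_tau < 0 or self.f0 <= 0:
            raise ValueError("rmax, f0 must be positive; binding_tau >= 0")


# Published indicator parameters; rmax/binding_tau are package defaults.
INDICATOR_PRESETS: dict[str, IndicatorModel] = {
    "GCaMP1.3": IndicatorModel(kd=234.0, hill_n=3.3, rmax=1.5, binding_tau=0.08),
    "GCaMP6m": IndicatorModel(kd=167.0, hill_n=2.96, rmax=4.0, binding_tau=0.08),
    # Hill coefficient not published for myrGCaMP5; GCaMP-family placeholder.
    "myrGCaMP5": IndicatorModel(kd=447.0, hill_n=3.3, rmax=3.0, binding_tau=0.08),
}


@dataclass(frozen=True)
class BoutonSpec:
    """One rendered bouton: a radially tapered disk."""

    center: tuple[float, float]   # (row, col) pixels
    radius: float                 # pixels
    f0: float                     # peak baseline brightness (intensity units)
    terminal_type: str = "Ib"     # Ib | Is | II
    nmj_id: int = 0


@dataclass(frozen=True)
class ImagingModel:
    """Camera/rendering parameters for synthetic movies."""

    frame_rate: float = 25.0
    frame_shape: tuple[int, int] = (256, 256)
    boutons: tuple[BoutonSpec, ...] = ()
    background_level: float = 100.0
    noise_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        h, w = self.frame_shape
        for b in self.boutons:
            r, c = b.center
            if not (b.radius <= r <= h - 1 - b.radius
                    and b.radius <= c <= w - 1 - b.radius):
                raise ValueError(f"bouton at {b.center} extends outside the frame")


@dataclass
class FrameStack:
    """Time-ordered grayscale frames plus acquisition metadata."""

    frames: np.ndarray          # (T, H, W) float
    frame_rate: float
    channel: str = "green"

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps at exposure midpoints."""
        return (np.arange(self.frames.shape[0]) + 0.5) / self.frame_rate


@dataclass
class SpikeTrain:
    """AP event times and the per-pulse delivery record behind them."""

    ap_times: np.ndarray        # s, strictly increasing
    delivered: np.ndarray       # bool per stimulus pulse
    pulse_times: np.ndarray     # s
    rebound_times: np.ndarray   # s, post-train events


@dataclass
class SimulationGroundTruth:
    """Everything a test needs to judge the analysis modules."""

    spikes: SpikeTrain
    ca_time: np.ndarray         # fine grid, s
    ca_trace: np.ndarray        # nM on the fine grid
    time: np.ndarray            # frame-midpoint times, s
    dff: np.ndarray             # noiseless frame-averaged dF/F
    true_label: str
    params: dict = field(default_factory=dict)

    @property
    def ap_times(self) -> np.ndarray:
        return self.spikes.ap_times


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def generate_spike_trains(
    protocol: StimulusProtocol,
    excitability: ExcitabilityProfile,
    seed: int = 0,
    delivery_override: Sequence[bool] | None = None,
) -> SpikeTrain:
    """Walk the stimulus train pulse by pulse and emit AP event times.

    A pulse is delivered unless the previous AP lies within
    ``failure_recovery_time`` of the pulse; a delivered pulse emits
    ``aps_per_stimulus`` events spaced at ``1/burst_rate``.  Optional
    ``delivery_override`` prescribes the per-pulse delivery outcome
    explicitly (used to construct ground-truth waveform scenarios).
    Deterministic given the seed (held for future stochastic extensions).
    """

    del seed  # current event placement is deterministic
    pulses = protocol.pulse_times
    if delivery_override is not None and len(delivery_override) != len(pulses):
        raise ValueError("delivery_override length must equal the pulse count")

    events: list[float] = []
    delivered = np.zeros(len(pulses), dtype=bool)
    last_event = -np.inf
    for i, tp in enumerate(pulses):
        if delivery_override is not None:
            ok = bool(delivery_override[i])
        else:
            # small tolerance so a gap of exactly the recovery time delivers
            ok = (tp - last_event) >= excitability.failure_recovery_time - 1e-9
        if ok and excitability.aps_per_stimulus > 0:
            burst = tp + np.arange(excitability.aps_per_stimulus) / excitability.burst_rate
            events.extend(burst.tolist())
            last_event = burst[-1]
            delivered[i] = True

    rebound: list[float] = []
    if excitability.rebound_duration > 0 and excitability.rebound_rate > 0:
        t = protocol.train_end + excitability.rebound_delay
        t_stop = t + excitability.rebound_duration
        while t < min(t_stop, protocol.record_duration):
            rebound.append(t)
            t += 1.0 / excitability.rebound_rate
    events.extend(rebound)

    ap = np.asarray(sorted(events), dtype=float)
    return SpikeTrain(
        ap_times=ap,
        delivered=delivered,
        pulse_times=pulses,
        rebound_times=np.asarray(rebound, dtype=float),
    )


def true_waveform_label(spikes: SpikeTrain) -> str:
    """Ground-truth waveform class implied by the delivery record."""

    d = spikes.delivered
    if d.size == 0 or not d.any():
        return "no_response"
    if d.all():
        return "rebound" if spikes.rebound_times.size else "normal"
    last = int(np.max(np.nonzero(d)[0]))
    # failures only after the last delivered pulse -> terminal block
    if d[: last + 1].all():
        return "aborted"
    return "intermittent"


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

def _drift(dca: float, t: float, model: CalciumModel) -> float:
    pump = 0.0
    if model.pump_vmax > 0 and dca > 0:
        pump = model.pump_scale(t) * model.pump_vmax * dca / (dca + model.pump_km)
    return -model.k_leak * dca - pump


def simulate_calcium(
    ap_times: np.ndarray,
    model: CalciumModel,
    time_grid: np.ndarray,
    schedule_offset: float = 0.0,
) -> np.ndarray:
    """Integrate the residual-Ca2+ ODE on ``time_grid`` (nM).

    Each AP adds ``delta_ca_per_ap`` instantaneously.  With the pump off the
    linear part is stepped exactly (superposed exponentials); with the
    saturable pump on, explicit RK4 between grid nodes with event splitting.
    ``schedule_offset`` shifts the pump schedule clock (e.g. incubation time
    already elapsed before this trial).
    """

    t = np.asarray(time_grid, dtype=float)
    ap = np.asarray(ap_times, dtype=float)
    if ap.size and np.any(np.diff(ap) <= 0):
        raise ValueError("ap_times must be strictly increasing")

    if model.pump_vmax == 0:
        # exact: dCa(t) = sum_i delta * exp(-k (t - t_i)) for t >= t_i
        if ap.size == 0:
            return np.full_like(t, model.ca_rest)
        lags = t[:, None] - ap[None, :]
        contrib = np.where(lags >= 0, np.exp(-model.k_leak * np.clip(lags, 0, None)), 0.0)
        return model.ca_rest + model.delta_ca_per_ap * contrib.sum(axis=1)

    # RK4 with event splitting
    def sched_drift(dca: float, tt: float) -> float:
        return _drift(dca, tt + schedule_offset, model)

    def rk4(dca: float, t0: float, t1: float) -> float:
        h = t1 - t0
        if h <= 0:
            return dca
        k1 = sched_drift(dca, t0)
        k2 = sched_drift(dca + 0.5 * h * k1, t0 + 0.5 * h)
        k3 = sched_drift(dca + 0.5 * h * k2, t0 + 0.5 * h)
        k4 = sched_drift(dca + h * k3, t1)
        return dca + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    out = np.empty_like(t)
    dca = 0.0
    t_cur = t[0]
    # events strictly before the first node contribute via integration below;
    # treat the grid as starting at t[0] with rest state before any event.
    ev = ap[ap >= t_cur - 1e-12]
    iev = 0
    first = True
    for j, tn in enumerate(t):
        if first:
            # apply events exactly at the first node
            while iev < ev.size and ev[iev] <= tn + 1e-12:
                dca += model.delta_ca_per_ap
                iev += 1
            out[0] = model.ca_rest + dca
            t_cur = tn
            first = False
            continue
        while iev < ev.size and ev[iev] <= tn + 1e-12:
            dca = rk4(dca, t_cur, ev[iev])
            dca += model.delta_ca_per_ap
            t_cur = ev[iev]
            iev += 1
        dca = rk4(dca, t_cur, tn)
        t_cur = tn
        if not np.isfinite(dca):
            raise RuntimeError(f"calcium solver produced non-finite state at t={tn:g} s")
        dca = max(dca, 0.0)
        out[j] = model.ca_rest + dca
    return out


# ---------------------------------------------------------------------------
# indicator
# ---------------------------------------------------------------------------

def hill_occupancy(ca: np.ndarray | float, indicator: IndicatorModel) -> np.ndarray | float:
    """Quasi-static bound fraction theta = Ca^n / (Ca^n + Kd^n)."""

    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0) or not np.all(np.isfinite(ca)):
        raise ValueError("ca must be finite and nonnegative")
    ratio = np.power(np.divide(indicator.kd, ca, out=np.full_like(ca, np.inf),
                               where=ca > 0), indicator.hill_n)
    theta = 1.0 / (1.0 + ratio)
    return theta if theta.ndim else float(theta)


def saturation_ceiling(indicator: IndicatorModel, ca_rest: float) -> float:
    """Analytic dF/F ceiling rmax*(1 - theta_rest)/(1 + rmax*theta_rest)."""

    th0 = hill_occupancy(ca_rest, indicator)
    return indicator.rmax * (1.0 - th0) / (1.0 + indicator.rmax * th0)


def fluorescence_from_calcium(
    ca_trace: np.ndarray,
    indicator: IndicatorModel,
    dt: float | None = None,
    ca_rest: float | None = None,
) -> np.ndarray:
    """Map a Ca2+ trace (nM) to dF/F.

    dF/F = rmax*(theta - theta_rest)/(1 + rmax*theta_rest) where theta is the
    bound fraction, relaxed toward its quasi-static value with time constant
    ``binding_tau`` (requires ``dt``).  ``ca_rest`` defaults to the first
    sample of the trace.
    """

    ca = np.asarray(ca_trace, dtype=float)
    theta_qs = np.asarray(hill_occupancy(ca, indicator))
    rest = float(ca[0]) if ca_rest is None else float(ca_rest)
    th0 = float(hill_occupancy(rest, indicator))

    if indicator.binding_tau > 0:
        if dt is None:
            raise ValueError("dt is required when binding_tau > 0")
        # exact update for a piecewise-constant target
        decay = math.exp(-dt / indicator.binding_tau)
        theta = np.empty_like(theta_qs)
        theta[0] = th0 if ca[0] == rest else theta_qs[0]
        for i in range(1, theta_qs.size):
            theta[i] = theta_qs[i] + (theta[i - 1] - theta_qs[i]) * decay
    else:
        theta = theta_qs

    return indicator.rmax * (theta - th0) / (1.0 + indicator.rmax * th0)


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------

def simulate_trial(
    protocol: StimulusProtocol,
    excitability: ExcitabilityProfile,
    calcium: CalciumModel,
    indicator: IndicatorModel,
    frame_rate: float = 25.0,
    oversample: int = 10,
    seed: int = 0,
    delivery_override: Sequence[bool] | None = None,
    schedule_offset: float = 0.0,
) -> SimulationGroundTruth:
    """Run the full chain for one bouton and one trial.

    The ODE runs on a grid ``oversample``-times finer than the frame rate;
    frame values are block means of the fine-grid dF/F (camera exposure
    averaging) timestamped at exposure midpoints.
    """

    spikes = generate_spike_trains(protocol, excitability, seed=seed,
                                   delivery_override=delivery_override)
    if spikes.ap_times.size and excitability.aps_per_stimulus > 1:
        if 1.0 / (frame_rate * oversample) > 1.0 / excitability.burst_rate:
            raise ValueError("time grid too coarse for the burst rate")

    n_frames = int(round(protocol.record_duration * frame_rate))
    dt = 1.0 / (frame_rate * oversample)
    fine_t = (np.arange(n_frames * oversample) + 0.5) * dt
    ca = simulate_calcium(spikes.ap_times, calcium, fine_t,
                          schedule_offset=schedule_offset)
    dff_fine = fluorescence_from_calcium(ca, indicator, dt=dt,
                                         ca_rest=calcium.ca_rest)
    dff = dff_fine.reshape(n_frames, oversample).mean(axis=1)
    times = (np.arange(n_frames) + 0.5) / frame_rate

    return SimulationGroundTruth(
        spikes=spikes,
        ca_time=fine_t,
        ca_trace=ca,
        time=times,
        dff=dff,
        true_label=true_waveform_label(spikes),
        params={
            "protocol": protocol,
            "excitability": excitability,
            "calcium": calcium,
            "indicator": indicator,
            "frame_rate": frame_rate,
            "oversample": oversample,
            "seed": seed,
        },
    )


def add_trace_noise(dff: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Additive Gaussian noise on a dF/F trace (camera read noise in dF/F units)."""

    rng = np.random.default_rng(seed)
    return dff + rng.normal(0.0, sigma, size=dff.shape)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def bouton_footprint(spec: BoutonSpec, shape: tuple[int, int]) -> np.ndarray:
    """Radially tapered disk weight map: w = 1 - (r/radius)^2 inside the disk."""

    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    d2 = (rr - spec.center[0]) ** 2 + (cc - spec.center[1]) ** 2
    w = 1.0 - d2 / spec.radius**2
    return np.clip(w, 0.0, None)


def _check_overlaps(weights: list[np.ndarray]) -> None:
    if len(weights) < 2:
        return
    cover = np.zeros_like(weights[0], dtype=int)
    for w in weights:
        cover += w > 0
    if (cover > 1).any():
        warnings.warn("overlapping bouton footprints; extraction ROIs will mix signals",
                      stacklevel=3)


def render_movie(
    dff_traces: np.ndarray,
    imaging: ImagingModel,
    channel: str = "green",
) -> FrameStack:
    """Render per-bouton dF/F traces into a noisy movie.

    Pixel model: background + sum_b f0_b * w_b(r) * (1 + dFF_b(t)) plus
    i.i.d. Gaussian read noise of ``noise_sigma``; bit-deterministic given
    ``rng_seed``.
    """

    dff_traces = np.atleast_2d(np.asarray(dff_traces, dtype=float))
    if dff_traces.shape[0] != len(imaging.boutons):
        raise ValueError("one dF/F trace per bouton is required")
    n_frames = dff_traces.shape[1]
    h, w = imaging.frame_shape
    weights = [bouton_footprint(b, imaging.frame_shape) for b in imaging.boutons]
    _check_overlaps(weights)

    frames = np.full((n_frames, h, w), float(imaging.background_level))
    for b, wmap, trace in zip(imaging.boutons, weights, dff_traces):
        frames += b.f0 * wmap[None, :, :] * (1.0 + trace)[:, None, None]
    if imaging.noise_sigma > 0:
        rng = np.random.default_rng(imaging.rng_seed)
        frames += rng.normal(0.0, imaging.noise_sigma, size=frames.shape)
    return FrameStack(frames=frames, frame_rate=imaging.frame_rate, channel=channel)


def make_roi_set(imaging: ImagingModel, bg_size: tuple[int, int] = (6, 6)):
    """Build the extractor's RoiSet matching a rendered movie.

    Bouton ROI = the footprint support; background ROI = a small homogeneous
    rectangle adjacent to the bouton, guaranteed free of any footprint.
    """

    from .extract import RoiSet  # local import to avoid a cycle

    h, w = imaging.frame_shape
    occupied = np.zeros((h, w), dtype=bool)
    weights = {}
    for i, b in enumerate(imaging.boutons):
        wmap = bouton_footprint(b, imaging.frame_shape)
        weights[i] = wmap > 0
        occupied |= weights[i]

    boutons, backgrounds, types, nmjs = {}, {}, {}, {}
    bh, bw = bg_size
    for i, b in enumerate(imaging.boutons):
        r0, c0 = b.center
        placed = False
        for dr, dc in ((0, 2.5 * b.radius), (0, -2.5 * b.radius),
                       (2.5 * b.radius, 0), (-2.5 * b.radius, 0),
                       (2.5 * b.radius, 2.5 * b.radius)):
            rs = int(round(r0 + dr - bh / 2))
            cs = int(round(c0 + dc - bw / 2))
            if rs < 0 or cs < 0 or rs + bh > h or cs + bw > w:
                continue
            mask = np.zeros((h, w), dtype=bool)
            mask[rs: rs + bh, cs: cs + bw] = True
            if not (mask & occupied).any():
                backgrounds[i] = mask
                placed = True
                break
        if not placed:
            raise ValueError(f"no homogeneous background region found for bouton {i}")
        boutons[i] = weights[i]
        types[i] = b.terminal_type
        nmjs[i] = b.nmj_id
    return RoiSet(boutons=boutons, backgrounds=backgrounds,
                  terminal_type=types, nmj_id=nmjs)


def render_coloc_pair(
    imaging: ImagingModel,
    occupancy_flags: Sequence[bool],
    puncta_per_bouton: Sequence[int] | None = None,
    punctum_radius: float = 1.5,
    punctum_brightness: float = 150.0,
    seed: int = 0,
):
    """Render a (green bouton, red mitochondria) single-frame channel pair.

    Red puncta are small disks placed inside boutons flagged occupied.
    Returns (green FrameStack, red FrameStack, truth table) where the truth
    table lists per-bouton occupancy and punctum count.
    """

    import pandas as pd

    flags = list(occupancy_flags)
    if len(flags) != len(imaging.boutons):
        raise ValueError("one occupancy flag per bouton is required")
    counts = list(puncta_per_bouton) if puncta_per_bouton is not None \
        else [1 if f else 0 for f in flags]
    for b, f, c in zip(imaging.boutons, flags, counts):
        if f and punctum_radius >= b.radius:
            raise ValueError("punctum larger than its host bouton")
        if f and c < 1:
            raise ValueError("occupied bouton needs at least one punctum")

    rng = np.random.default_rng(seed)
    h, w = imaging.frame_shape
    green = np.full((h, w), float(imaging.background_level))
    red = np.full((h, w), float(imaging.background_level))
    for b, f, c in zip(imaging.boutons, flags, counts):
        green += b.f0 * bouton_footprint(b, imaging.frame_shape)
        if not f:
            continue
        for _ in range(c):
            # place the punctum fully inside the host footprint
            max_off = max(b.radius - punctum_radius - 0.5, 0.0)
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, max_off)
            pc = (b.center[0] + rad * np.sin(ang), b.center[1] + rad * np.cos(ang))
            red += punctum_brightness * bouton_footprint(
                BoutonSpec(center=pc, radius=punctum_radius, f0=1.0), imaging.frame_shape)
    if imaging.noise_sigma > 0:
        green += rng.normal(0.0, imaging.noise_sigma, size=green.shape)
        red += rng.normal(0.0, imaging.noise_sigma, size=red.shape)

    truth = pd.DataFrame({
        "bouton_id": np.arange(len(flags)),
        "nmj_id": [b.nmj_id for b in imaging.boutons],
        "occupied": flags,
        "puncta": counts,
    })
    fs = imaging.frame_rate
    return (FrameStack(green[None], fs, "green"),
            FrameStack(red[None], fs, "red"),
            truth)


# ---------------------------------------------------------------------------
# focal electrode record
# ---------------------------------------------------------------------------

def generate_focal_record(
    ap_times: np.ndarray,
    quantal_amplitude: float = 1.0,
    kernel_tau: float = 0.005,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 10_000.0,
    duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Loose-patch event-train trace: one biexponential deflection per AP.

    The kernel (rise tau = kernel_tau/5, decay tau = kernel_tau) is scaled so
    its peak equals ``quantal_amplitude`` and aligned so the peak falls at the
    AP time.  Returns (time, amplitude) at ``sampling_rate``.
    """

    if kernel_tau <= 0 or quantal_amplitude <= 0:
        raise ValueError("kernel_tau and quantal_amplitude must be positive")
    if sampling_rate < 10.0 / kernel_tau:
        raise ValueError("sampling_rate must be at least 10 / kernel_tau")

    ap = np.asarray(ap_times, dtype=float)
    if duration is None:
        duration = (float(ap.max()) + 10 * kernel_tau) if ap.size else 10 * kernel_tau
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate

    tau_d, tau_r = kernel_tau, kernel_tau / 5.0
    t_peak = math.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)
    kt = np.arange(0, 8 * tau_d, 1.0 / sampling_rate)
    kernel = np.exp(-kt / tau_d) - np.exp(-kt / tau_r)
    kernel *= quantal_amplitude / kernel.max()

    del t_peak  # peak index taken from the sampled kernel directly
    y = np.zeros(n)
    peak_idx = int(np.argmax(kernel))
    for ta in ap:
        i0 = int(round(ta * sampling_rate)) - peak_idx
        j0 = max(i0, 0)
        j1 = min(i0 + kernel.size, n)
        if j1 > j0:
            y[j0:j1] += kernel[j0 - i0: j1 - i0]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y += rng.normal(0.0, noise_sigma, size=n)
    return t, y
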