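"""Scenario presets and desk-scale experiment runners.

Presets are JSON files shipped with the package.  They are illustrative:
the genetic and pharmacological conditions they name are characterized in
the literature by qualitative effects (burst firing, conduction failure,
pump suppression, metabolic rundown), not by measured parameters, so preset
parameters are tuned only to reproduce ordinal relations (which terminal
type responds at which frequency, which condition slows decay).

Runners produce kinetics tables at the dF/F-trace level: deterministic
forward-model traces per (terminal type, frequency) plus independent
Gaussian read noise per bouton, which is what the downstream analysis
actually consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from . import classify, kinetics
from .simulate import (
    INDICATOR_PRESETS,
    CalciumModel,
    ExcitabilityProfile,
    IndicatorModel,
    StimulusProtocol,
    add_trace_noise,
    simulate_trial,
)

__all__ = [
    "Scenario",
    "available_presets",
    "load_preset",
    "run_frequency_scan",
    "thresholds_by_type",
    "classification_bank",
    "run_classification",
    "dnp_time_course",
]

TERMINAL_TYPES = ("Ib", "Is", "II")
DEFAULT_NOISE_SIGMA = 0.01  # dF/F units of camera read noise on a trace


@dataclass(frozen=True)
class Scenario:
    name: str
    description: str
    indicator: IndicatorModel
    excitability: dict[str, ExcitabilityProfile]
    calcium: dict[str, CalciumModel]


def _build_schedule(spec: dict):
    kind = spec.get("kind", "constant")
    if kind == "constant":
        v = float(spec.get("value", 1.0))
        return None if v == 1.0 else (lambda t, v=v: v)
    if kind == "linear_rundown":
        dur = float(spec["duration_s"])
        return lambda t, dur=dur: max(0.0, 1.0 - t / dur)
    raise ValueError(f"unknown pump schedule kind {kind!r}")


def _read_json(name: str) -> dict:
    path = resources.files("gcampflux.presets").joinpath(f"{name}.json")
    with path.open("r") as fh:
        return json.load(fh)


def available_presets() -> list[str]:
    return sorted(p.name.removesuffix(".json")
                  for p in resources.files("gcampflux.presets").iterdir()
                  if p.name.endswith(".json"))


def load_preset(name: str) -> Scenario:
    """Load a scenario preset, resolving its base and overrides."""

    raw = _read_json(name)
    if "base" in raw:
        base_raw = _read_json(raw["base"])
    else:
        base_raw = raw
    for key in ("types", "indicator"):
        if key not in base_raw:
            raise ValueError(f"preset {name!r}: base is missing {key!r}")

    schedule_spec = raw.get("pump_scale", base_raw.get("pump_scale",
                                                       {"kind": "constant", "value": 1.0}))
    schedule = _build_schedule(schedule_spec)
    indicator = INDICATOR_PRESETS[raw.get("indicator", base_raw["indicator"])]

    exc: dict[str, ExcitabilityProfile] = {}
    cal: dict[str, CalciumModel] = {}
    overrides = raw.get("overrides", {})
    for ttype in TERMINAL_TYPES:
        spec = base_raw["types"][ttype]
        e_kwargs = dict(spec["excitability"])
        c_kwargs = dict(spec["calcium"])
        if ttype in overrides:
            e_kwargs.update(overrides[ttype].get("excitability", {}))
            c_kwargs.update(overrides[ttype].get("calcium", {}))
        exc[ttype] = ExcitabilityProfile(**e_kwargs)
        cal[ttype] = CalciumModel(pump_scale_schedule=schedule, **c_kwargs)
    return Scenario(name=raw["name"], description=raw.get("description", ""),
                    indicator=indicator, excitability=exc, calcium=cal)


def run_frequency_scan(
    preset: str | Scenario = "wt",
    frequencies: tuple[float, ...] = (2.0, 10.0, 20.0, 40.0),
    n_nmjs: int = 2,
    boutons_per_nmj: int = 6,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    schedule_offset: float = 0.0,
    terminal_types: tuple[str, ...] = TERMINAL_TYPES,
    record_duration: float = 8.0,
) -> pd.DataFrame:
    """Kinetics table for one preset across stimulation frequencies.

    Every bouton of a given type shares the deterministic forward-model
    trace and receives independent read noise; N_B is estimated per bouton
    from its own baseline, exactly as the extractor would.
    """

    scen = load_preset(preset) if isinstance(preset, str) else preset
    results: list[kinetics.KineticsResult] = []
    bouton_id = 0
    for f in frequencies:
        protocol = StimulusProtocol(frequency=f, record_duration=record_duration)
        for ttype in terminal_types:
            truth = simulate_trial(protocol, scen.excitability[ttype],
                                   scen.calcium[ttype], scen.indicator,
                                   schedule_offset=schedule_offset)
            for nmj in range(n_nmjs):
                for b in range(boutons_per_nmj):
                    sub = (seed * 1_000_003 + bouton_id * 7919 + 13) % 2**31
                    dff = add_trace_noise(truth.dff, noise_sigma, sub)
                    base = dff[truth.time < protocol.onset_time][-25:]
                    n_b = float(np.std(base))
                    res = kinetics.analyze_trace(dff, truth.time, protocol, n_b,
                                                 bouton_id=bouton_id,
                                                 terminal_type=ttype, nmj_id=nmj)
                    results.append(res)
                    bouton_id += 1
    return kinetics.results_frame(results)


def thresholds_by_type(df: pd.DataFrame) -> dict[str, float | None]:
    """Operational threshold frequency per terminal type (None = above max tested)."""

    out = {}
    for ttype, grp in df.groupby("terminal_type"):
        out[str(ttype)] = kinetics.frequency_response(grp).threshold_frequency
    return out


# ---------------------------------------------------------------------------
# waveform-classification scenario bank
# ---------------------------------------------------------------------------

def classification_bank(
    frequency: float = 10.0,
    train_duration: float = 4.0,
    record_duration: float = 12.0,
) -> dict[str, dict]:
    """Ground-truth waveform scenarios built on the type II terminal model.

    Keys are the true labels; values hold the simulation arguments (delivery
    pattern / rebound profile) that realize each waveform.  The default
    protocol (10 Hz, 4 s train) makes each 10-pulse failure block last 1 s,
    long enough for a clear sag against the type II clearance rate.
    """

    protocol = StimulusProtocol(frequency=frequency, train_duration=train_duration,
                                record_duration=record_duration)
    n = protocol.n_pulses
    half = n // 2
    quarter = n // 4
    blocks = ([True] * quarter + [False] * quarter) * 2
    blocks += [True] * (n - len(blocks))
    return {
        "normal": {"delivery_override": None, "rebound": False},
        "aborted": {"delivery_override": [True] * half + [False] * (n - half),
                    "rebound": False},
        "intermittent": {"delivery_override": blocks, "rebound": False},
        "no_response": {"delivery_override": [False] * n, "rebound": False},
        "rebound": {"delivery_override": None, "rebound": True},
    }


def run_classification(
    n_runs: int = 200,
    snr: float = 10.0,
    seed: int = 0,
    frequency: float = 10.0,
    train_duration: float = 4.0,
    record_duration: float = 12.0,
    noiseless: bool = False,
    rules: classify.ClassifierRules = classify.ClassifierRules(),
) -> pd.DataFrame:
    """Classify simulated traces against ground truth; one row per run.

    SNR is defined as (peak dF/F of the reference normal trace) / (read
    noise sigma); the same sigma applies to every scenario so weak waveforms
    are genuinely harder.
    """

    scen = load_preset("wt")
    protocol = StimulusProtocol(frequency=frequency, train_duration=train_duration,
                                record_duration=record_duration)
    bank = classification_bank(frequency=frequency, train_duration=train_duration,
                               record_duration=record_duration)
    labels = list(bank)

    # reference amplitude for the noise level
    ref = simulate_trial(protocol, scen.excitability["II"], scen.calcium["II"],
                         scen.indicator)
    sigma = 0.0 if noiseless else float(ref.dff.max()) / snr

    rows = []
    for i in range(n_runs):
        truth_label = labels[i % len(labels)]
        args = bank[truth_label]
        exc = scen.excitability["II"]
        if args["rebound"]:
            exc = replace(exc, rebound_rate=60.0, rebound_duration=0.4,
                          rebound_delay=1.2)
        truth = simulate_trial(protocol, exc, scen.calcium["II"], scen.indicator,
                               delivery_override=args["delivery_override"])
        dff = add_trace_noise(truth.dff, sigma, seed * 100_003 + i) \
            if sigma > 0 else truth.dff
        base = dff[truth.time < protocol.onset_time][-25:]
        n_b = float(np.std(base))
        kin = kinetics.analyze_trace(dff, truth.time, protocol, n_b)
        pred = classify.classify_waveform(dff, truth.time, protocol, kin, rules)
        rows.append({"run": i, "truth": truth.true_label, "predicted": pred.label,
                     "rebound_flag": pred.rebound})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metabolic rundown time course
# ---------------------------------------------------------------------------

def dnp_time_course(
    incubation_min: tuple[float, ...] = (0.0, 20.0, 60.0),
    frequency: float = 40.0,
    terminal_type: str = "Ib",
    n_boutons: int = 8,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    record_duration: float = 12.0,
) -> pd.DataFrame:
    """Median recovered half-decay time vs simulated incubation time.

    The pump rundown schedule is evaluated at the incubation offset, so each
    trial sees the clearance capacity remaining at that point of the
    treatment.
    """

    scen = load_preset("dnp")
    protocol = StimulusProtocol(frequency=frequency, record_duration=record_duration)
    rows = []
    for minutes in incubation_min:
        truth = simulate_trial(protocol, scen.excitability[terminal_type],
                               scen.calcium[terminal_type], scen.indicator,
                               schedule_offset=minutes * 60.0)
        decays = []
        for b in range(n_boutons):
            dff = add_trace_noise(truth.dff, noise_sigma,
                                  seed * 7919 + int(minutes) * 101 + b)
            base = dff[truth.time < protocol.onset_time][-25:]
            kin = kinetics.analyze_trace(dff, truth.time, protocol,
                                         float(np.std(base)))
            if kin.responder and not kin.decay_censored:
                decays.append(kin.t_half_decay)
        rows.append({"incubation_min": minutes,
                     "median_t_half_decay_s": float(np.median(decays)) if decays else float("nan"),
                     "n_measured": len(decays)})
    return pd.DataFrame(rows)
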