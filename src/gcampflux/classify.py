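"""Waveform taxonomy for dF/F traces: normal / aborted / intermittent /
no_response, plus post-train rebound.

The source taxonomy was applied by eye; this module operationalizes it as a
rule cascade on the smoothed trace.  All thresholds are fractional (the
classifier is invariant to uniform scaling of the trace) and exposed in
:class:`ClassifierRules`:

1. not a responder -> ``no_response``;
2. during the train, a *drop episode* is a run of >= ``min_gap`` frames in
   which the trace sits more than ``drop_frac`` below its running peak
   (and the drop depth exceeds ``min_drop_nb`` baseline-noise units, so
   noise cannot fake an episode).  An episode that ends before train end
   (the trace recovered) makes the trace ``intermittent``; a terminal
   episode with no recovery makes it ``aborted``;
3. after train end, once the trace has fallen below 50% of the peak, a
   renewed excursion above ``rebound_frac * max_dff`` flags ``rebound``
   (replaces ``normal`` only; reported as evidence otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticsResult, smooth
from .simulate import StimulusProtocol

__all__ = ["ClassifierRules", "WaveformLabel", "classify_waveform", "label_tally"]

LABELS = ("normal", "aborted", "intermittent", "no_response", "rebound")


@dataclass(frozen=True)
class ClassifierRules:
    drop_frac: float = 0.3      # fractional decline from running peak
    min_gap: int = 3            # frames an episode must persist
    rebound_frac: float = 0.5   # of max dF/F, post-train renewed excursion
    min_amp_frac: float = 0.2   # running peak must reach this much of max dF/F
    min_drop_nb: float = 1.5    # drop depth in units of N_B


@dataclass
class WaveformLabel:
    label: str
    evidence: list[float] = field(default_factory=list)  # episode onset times, s
    rebound: bool = False
    rebound_time: float | None = None


def _close_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill False runs shorter than ``max_gap`` that are flanked by True (so a
    single noisy frame cannot split one episode into two)."""

    out = mask.copy()
    n = out.size
    i = 0
    while i < n:
        if not out[i]:
            j = i
            while j < n and not out[j]:
                j += 1
            if 0 < i and j < n and (j - i) < max_gap:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def _drop_episodes(s: np.ndarray, t: np.ndarray, protocol: StimulusProtocol,
                   kin: KineticsResult, rules: ClassifierRules):
    """(onset time, recovered?) for each qualifying in-train drop episode."""

    idx = np.nonzero((t >= protocol.onset_time) & (t <= protocol.train_end))[0]
    if idx.size == 0:
        return []
    seg = s[idx]
    run_peak = np.maximum.accumulate(seg)
    depth = run_peak - seg
    floor = rules.min_amp_frac * float(run_peak[-1])
    dropping = (
        (run_peak >= floor)
        & (depth > rules.drop_frac * run_peak)
        & (depth > rules.min_drop_nb * kin.n_b)
    )
    dropping = _close_gaps(dropping, rules.min_gap)

    episodes: list[tuple[float, bool]] = []
    j = 0
    n = dropping.size
    while j < n:
        if dropping[j]:
            k = j
            while k < n and dropping[k]:
                k += 1
            if (k - j) >= rules.min_gap:
                episodes.append((float(t[idx[j]]), k < n))  # recovered unless terminal
            j = k
        else:
            j += 1
    return episodes


def _detect_rebound(s: np.ndarray, t: np.ndarray, protocol: StimulusProtocol,
                    kin: KineticsResult, rules: ClassifierRules) -> float | None:
    """Post-train renewed excursion with a noise-scaled hysteresis band.

    The amplitude reference is the in-train peak of the smoothed trace (for
    2-s trains this equals max dF/F, whose search window spans the train).
    """

    in_train = (t >= protocol.onset_time) & (t <= protocol.train_end)
    amp = float(s[in_train].max())
    h = rules.min_drop_nb * kin.n_b
    after = np.nonzero(t >= protocol.train_end)[0]
    below = False
    for j in after:
        if s[j] < 0.5 * amp:
            below = True
        elif below and s[j] > rules.rebound_frac * amp + h:
            # hysteresis only on the renewed rise: a decaying trace that
            # grazes the 50% line cannot re-trigger on noise alone
            return float(t[j])
    return None


def classify_waveform(
    dff: np.ndarray,
    time: np.ndarray,
    protocol: StimulusProtocol,
    kin: KineticsResult,
    rules: ClassifierRules = ClassifierRules(),
    presmoothed: bool = False,
) -> WaveformLabel:
    """Apply the rule cascade to one trace (smoothed internally by default)."""

    s = np.asarray(dff, dtype=float) if presmoothed else smooth(dff)
    if not kin.responder:
        return WaveformLabel(label="no_response")

    episodes = _drop_episodes(s, time, protocol, kin, rules)
    rebound_t = _detect_rebound(s, time, protocol, kin, rules)
    evidence = [e[0] for e in episodes]

    if any(recovered for _, recovered in episodes):
        label = "intermittent"
    elif episodes:
        label = "aborted"
    elif rebound_t is not None:
        label = "rebound"
    else:
        label = "normal"
    return WaveformLabel(label=label, evidence=evidence,
                         rebound=rebound_t is not None, rebound_time=rebound_t)


def label_tally(labels: dict[str, list[str]]) -> pd.DataFrame:
    """Per-condition tally of waveform labels ("NMJs exhibiting each wave form").

    ``labels`` maps a condition/genotype name to a list of labels (one per
    NMJ, e.g. the terminal-level majority label).
    """

    rows = []
    for cond, lst in labels.items():
        counts = {lab: lst.count(lab) for lab in LABELS}
        counts["condition"] = cond
        counts["n_total"] = len(lst)
        rows.append(counts)
    return pd.DataFrame(rows).set_index("condition")


def terminal_consensus(labels: list[str]) -> str:
    """Majority label across the boutons of one terminal (ties -> first seen)."""

    if not labels:
        raise ValueError("no bouton labels supplied")
    best, best_n = labels[0], 0
    seen = []
    for lab in labels:
        if lab in seen:
            continue
        seen.append(lab)
        n = labels.count(lab)
        if n > best_n:
            best, best_n = lab, n
    return best
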