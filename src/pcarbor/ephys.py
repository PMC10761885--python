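"""Spike-train feature extraction and model-validation gates.

Features mirror the standard current-clamp repertoire for Purkinje cells:
AP amplitude (peak minus threshold-crossing voltage), AP width at
half-amplitude, afterhyperpolarization depth (absolute = ISI minimum; slow =
minimum over the last 50% of each ISI), voltage base (median of pre-stimulus
samples), mean spike frequency ((count - 1) / (last - first spike time)),
spike count, ISI coefficient of variation (sample sd / mean, needing >= 3
spikes — the convention of the standard feature-extraction libraries), and
the sag ratio of hyperpolarizing steps.

Validation gates reproduce the acceptance windows used when screening model
populations: spontaneous rate 5-50 Hz, frequency caps of 150 Hz at 0.5 nA and
200 Hz at 1 nA, burst spike counts of 9-10 at 50 Hz, 4-6 at 100 Hz and 3-4 at
200 Hz, evaluated as a conjunction that fails closed on missing protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusAnnotation",
    "VoltageTrace",
    "FeatureSet",
    "ValidationGates",
    "ValidationResult",
    "detect_spikes",
    "extract_features",
    "sag_ratio",
    "validate_model",
]


@dataclass(frozen=True)
class StimulusAnnotation:
    kind: str = "none"  # step | sinusoid | none
    amplitude_na: float = 0.0
    onset_ms: float = 0.0
    offset_ms: float = 0.0


@dataclass
class VoltageTrace:
    v_mv: np.ndarray
    dt_ms: float
    stimulus: StimulusAnnotation = field(default_factory=StimulusAnnotation)
    annotations: dict = field(default_factory=dict)  # generator ground truth

    def __post_init__(self):
        self.v_mv = np.asarray(self.v_mv, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.v_mv.size < 2:
            raise ValueError("trace needs >= 2 samples")

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.v_mv.size) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return (self.v_mv.size - 1) * self.dt_ms


@dataclass
class FeatureSet:
    """Per-trace features; fields are None when undefined (e.g. < 2 spikes)."""

    spike_count: int
    mean_frequency_hz: float | None
    isi_cv: float | None
    ap_amplitude_mv: float | None
    ap_width_ms: float | None
    ahp_depth_absolute_mv: float | None
    ahp_depth_slow_mv: float | None
    voltage_base_mv: float
    sag_ratio: float | None = None


# ---------------------------------------------------------------------------

def detect_spikes(
    trace: VoltageTrace, threshold_mv: float = -20.0, refractory_ms: float = 1.0
) -> np.ndarray:
    """Spike times (ms) at upward threshold crossings, refractory-separated."""
    v = trace.v_mv
    cross = np.flatnonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv)) + 1
    times = []
    last = -np.inf
    for i in cross:
        t = i * trace.dt_ms
        if t - last >= refractory_ms:
            times.append(t)
            last = t
    return np.asarray(times)


def _voltage_base(trace: VoltageTrace) -> float:
    stim = trace.stimulus
    if stim.kind != "none" and stim.onset_ms > 0:
        n = max(1, int(stim.onset_ms / trace.dt_ms))
        return float(np.median(trace.v_mv[:n]))
    # no stimulus annotation: use the first 10% of the trace
    n = max(1, trace.v_mv.size // 10)
    return float(np.median(trace.v_mv[:n]))


def extract_features(
    trace: VoltageTrace, threshold_mv: float = -20.0, refractory_ms: float = 1.0
) -> FeatureSet:
    v = trace.v_mv
    dt = trace.dt_ms
    spikes = detect_spikes(trace, threshold_mv, refractory_ms)
    idx = np.rint(spikes / dt).astype(int)
    base = _voltage_base(trace)

    if len(spikes) < 2:
        return FeatureSet(
            spike_count=len(spikes),
            mean_frequency_hz=None,
            isi_cv=None,
            ap_amplitude_mv=None,
            ap_width_ms=None,
            ahp_depth_absolute_mv=None,
            ahp_depth_slow_mv=None,
            voltage_base_mv=base,
        )

    isis = np.diff(spikes)
    mean_freq = (len(spikes) - 1) / (spikes[-1] - spikes[0]) * 1000.0
    isi_cv = float(isis.std(ddof=1) / isis.mean()) if len(spikes) >= 3 else None

    # per-spike shape features, window = until the next crossing (or ISI-median
    # horizon for the last spike)
    amps, widths, ahp_abs, ahp_slow = [], [], [], []
    horizon = int(np.median(isis) / dt)
    for k, i in enumerate(idx):
        j = idx[k + 1] if k + 1 < len(idx) else min(v.size, i + horizon)
        win = v[i:j]
        if win.size == 0:
            continue
        cross_v = v[i]
        peak = float(win.max())
        amps.append(peak - cross_v)
        half = cross_v + 0.5 * (peak - cross_v)
        above = win >= half
        widths.append(float(np.count_nonzero(above)) * dt)
        if k + 1 < len(idx):
            ahp_abs.append(float(win.min()))
            tail = win[win.size // 2:]
            if tail.size:
                ahp_slow.append(float(tail.min()))

    return FeatureSet(
        spike_count=len(spikes),
        mean_frequency_hz=float(mean_freq),
        isi_cv=isi_cv,
        ap_amplitude_mv=float(np.mean(amps)) if amps else None,
        ap_width_ms=float(np.mean(widths)) if widths else None,
        ahp_depth_absolute_mv=float(np.mean(ahp_abs)) if ahp_abs else None,
        ahp_depth_slow_mv=float(np.mean(ahp_slow)) if ahp_slow else None,
        voltage_base_mv=base,
    )


def sag_ratio(trace: VoltageTrace) -> float:
    """(peak - steady-state) / peak deflection of a hyperpolarizing step.

    Deflections are measured relative to the pre-step baseline; 0 for a pure
    RC (non-sagging) response, approaching 1 for full relaxation.
    """
    stim = trace.stimulus
    if stim.kind != "step":
        raise ValueError("sag ratio needs an annotated current step")
    if stim.amplitude_na >= 0:
        raise ValueError("sag ratio is defined for hyperpolarizing steps only")
    dt = trace.dt_ms
    i0, i1 = int(stim.onset_ms / dt), int(stim.offset_ms / dt)
    i1 = min(i1, trace.v_mv.size)
    base = float(np.median(trace.v_mv[: max(1, i0)]))
    win = trace.v_mv[i0:i1]
    peak = float(win.min() - base)
    n_ss = max(1, int(0.2 * win.size))
    steady = float(win[-n_ss:].mean() - base)
    if peak >= 0:
        return 0.0
    ratio = (abs(peak) - abs(steady)) / abs(peak)
    return float(max(0.0, ratio))


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationGates:
    spontaneous_range_hz: tuple[float, float] = (5.0, 50.0)
    max_freq_0p5na_hz: float = 150.0
    max_freq_1na_hz: float = 200.0
    burst_windows: dict = field(
        default_factory=lambda: {
            "burst_50Hz": (9, 10),
            "burst_100Hz": (4, 6),
            "burst_200Hz": (3, 4),
        }
    )
    rin_reference_mohm: float = 14.0


@dataclass
class ValidationResult:
    gates: dict[str, bool | None]  # None = not evaluated
    reasons: list[str]

    @property
    def passed(self) -> bool:
        return all(v is True for v in self.gates.values())


def validate_model(
    features: dict[str, FeatureSet], gates: ValidationGates | None = None
) -> ValidationResult:
    """Apply the validation gates to per-protocol feature sets.

    ``features`` keys: 'spontaneous', 'step_0p5nA', 'step_1nA' (required) and
    optionally 'burst_50Hz', 'burst_100Hz', 'burst_200Hz'. A missing required
    protocol leaves its gate unevaluated and the overall result fails closed.
    """
    gates = gates or ValidationGates()
    result: dict[str, bool | None] = {}
    reasons: list[str] = []

    def freq_of(key):
        fs = features.get(key)
        return None if fs is None else fs.mean_frequency_hz

    lo, hi = gates.spontaneous_range_hz
    f = freq_of("spontaneous")
    if f is None:
        result["spontaneous"] = None
        reasons.append("spontaneous protocol missing: not evaluated")
    elif lo <= f <= hi:
        result["spontaneous"] = True
    else:
        result["spontaneous"] = False
        reasons.append(f"spontaneous {f:g} Hz out of {lo:g}-{hi:g} Hz")

    for key, cap in (
        ("step_0p5nA", gates.max_freq_0p5na_hz),
        ("step_1nA", gates.max_freq_1na_hz),
    ):
        f = freq_of(key)
        if f is None:
            result[key] = None
            reasons.append(f"{key} protocol missing: not evaluated")
        elif f <= cap:
            result[key] = True
        else:
            result[key] = False
            reasons.append(f"{key} {f:g} Hz exceeds cap {cap:g} Hz")

    for key, (lo_n, hi_n) in gates.burst_windows.items():
        fs = features.get(key)
        if fs is None:
            continue  # burst protocols are optional
        if lo_n <= fs.spike_count <= hi_n:
            result[key] = True
        else:
            result[key] = False
            reasons.append(
                f"{key}: {fs.spike_count} spikes outside {lo_n}-{hi_n} window"
            )

    return ValidationResult(result, reasons)
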