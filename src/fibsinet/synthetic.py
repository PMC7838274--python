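"""Synthetic calcium-network and sEPSC recordings with ground truth.

Two generators emulate the data the analysis pipeline consumes:

* :func:`generate_calcium_network` — a dish of cells imaged together at
  ~1 frame/s for minutes. Each active cell fires Poisson-timed calcium
  transients (difference-of-exponentials kinetics, lognormal amplitudes)
  on top of a slow sinusoidal baseline drift plus Gaussian noise. A
  configurable *silent* subpopulation contributes drift + noise only.
  Network-wide synchronous waves occur at a Poisson rate; each cell joins
  each wave independently with probability ``coupling_p``.

* :func:`generate_epsc_recording` — a 180 s, 2 kHz voltage-clamp trace
  built as Gaussian noise plus a sum of bi-exponential synaptic currents
  whose amplitudes and interevent intervals are drawn from a planted
  mixture of components (e.g. small/short, small/long, large), the
  ground truth for cluster-recovery benchmarks.

Ground truth (event times, amplitudes, component ids, wave times, silent
flags) is returned alongside the traces so every downstream stage can be
scored. All randomness flows from one integer seed through named
per-cell substreams, so adding cells never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fibsi import Trace

__all__ = [
    "CalciumNetworkParams",
    "EpscClusterSpec",
    "EpscParams",
    "ConditionEffect",
    "GroundTruth",
    "generate_calcium_network",
    "generate_epsc_recording",
    "apply_condition_effect",
    "biexp_kernel",
]

# Substream roles (SeedSequence spawn keys): (0,) = network-level draws,
# (1, i) = cell i's private stream, (2, i) = cell i's wave-participation
# uniforms. Participation uses `uniform < coupling_p`, so lowering the
# coupling probability can only shrink each cell's set of joined waves.
_NETWORK_KEY = 0
_CELL_KEY = 1
_WAVE_KEY = 2


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class CalciumNetworkParams:
    """Study conditions for a simulated calcium-imaging field.

    Defaults mirror the recordings the pipeline targets: ~1 frame/s
    imaging of a few dozen co-cultured dorsal horn neurons for five
    minutes, large-SNR transients (mean amplitude ~50 AU vs ~0.5 AU
    noise, so silent cells fluctuate at the ~1–2 AU level), a silent
    fraction of 20%, and occasional network waves joined by a
    ``coupling_p`` fraction of active cells.
    """

    n_cells: int = 20
    frac_silent: float = 0.2
    duration_s: float = 300.0
    frame_interval_s: float = 1.0
    event_rate_hz: float = 0.02
    amp_mean: float = 50.0
    amp_sd: float = 15.0
    rise_s: float = 1.5
    decay_s: float = 6.0
    sync_wave_rate_hz: float = 0.02
    coupling_p: float = 0.6
    drift_amp: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0
    condition: str = "naive"
    # optional per-cell multiplicative overrides (len n_cells); used by
    # apply_condition_effect to target a subset of cells
    cell_amp_scale: np.ndarray | None = None
    cell_rate_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("event_rate_hz", "sync_wave_rate_hz", "amp_mean", "amp_sd",
                     "rise_s", "decay_s", "drift_amp", "noise_sd", "duration_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        for name in ("frac_silent", "coupling_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for arr_name in ("cell_amp_scale", "cell_rate_scale"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != self.n_cells or np.any(arr < 0) or not np.all(np.isfinite(arr)):
                    raise ValueError(f"{arr_name} must be n_cells non-negative finite values")
                setattr(self, arr_name, arr)


@dataclass
class EpscClusterSpec:
    """One planted sEPSC mixture component.

    ``iei_sd_ms`` defaults to 20% of the mean; intervals are drawn from a
    normal truncated below at one sample so components stay separated in
    the interevent-interval dimension.
    """

    weight: float
    amp_mean_pA: float
    amp_sd_pA: float
    iei_mean_ms: float
    iei_sd_ms: float | None = None

    def __post_init__(self) -> None:
        if self.iei_sd_ms is None:
            self.iei_sd_ms = 0.2 * self.iei_mean_ms
        if self.weight <= 0 or self.amp_mean_pA <= 0 or self.iei_mean_ms <= 0:
            raise ValueError("weight, amp_mean_pA and iei_mean_ms must be positive")


def default_epsc_clusters() -> list[EpscClusterSpec]:
    """Three components: small/short, small/long, large (amps 15/15/80 pA;
    IEIs 20/2000/200 ms; sds 20% of means)."""
    return [
        EpscClusterSpec(1 / 3, 15.0, 3.0, 20.0),
        EpscClusterSpec(1 / 3, 15.0, 3.0, 2000.0),
        EpscClusterSpec(1 / 3, 80.0, 16.0, 200.0),
    ]


@dataclass
class EpscParams:
    """Study conditions for a simulated voltage-clamp sEPSC recording."""

    duration_s: float = 180.0
    sample_rate_hz: float = 2000.0
    cluster_specs: list[EpscClusterSpec] = field(default_factory=default_epsc_clusters)
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 7.5
    noise_sd_pA: float = 2.0
    polarity: str = "inward"
    seed: int = 0
    cell_id: str = "epsc_cell"

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("duration_s and sample_rate_hz must be positive")
        if not self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("tau_rise_ms must be smaller than tau_decay_ms")
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd_pA must be >= 0")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")
        w = sum(c.weight for c in self.cluster_specs)
        if self.cluster_specs and abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth: one row per event, wave times, per-cell silent flags."""

    events: pd.DataFrame  # cell_id, event_time_s, amplitude, cluster_id, is_wave
    wave_times: np.ndarray
    silent: dict[str, bool]
    condition: str = "naive"


@dataclass
class ConditionEffect:
    """A pharmacological/treatment effect expressed on generator parameters.

    Multiplicative factors apply to event amplitude, event rate and wave
    coupling; ``activate_silent`` switches the silent subpopulation to
    active (the unmasking effect). ``subset`` restricts amplitude/rate
    factors to the given cell indices.
    """

    amplitude_factor: float = 1.0
    rate_factor: float = 1.0
    coupling_factor: float = 1.0
    activate_silent: bool = False
    subset: np.ndarray | None = None
    label: str = "treated"

    def __post_init__(self) -> None:
        for name in ("amplitude_factor", "rate_factor", "coupling_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def biexp_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient normalized to unit peak.

    ``k(t) = (exp(-t/decay) - exp(-t/rise)) / k(t*)`` for t >= 0, where
    ``t* = rise*decay/(decay-rise) * ln(decay/rise)`` is the peak time.
    """
    if not 0 < rise < decay:
        raise ValueError("need 0 < rise < decay")
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay) - np.exp(-np.maximum(t, 0) / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return k / peak


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Convert a desired distribution mean/sd to lognormal mu/sigma."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def generate_calcium_network(params: CalciumNetworkParams) -> tuple[list[Trace], GroundTruth]:
    """Simulate one imaging field; returns traces and planted ground truth."""
    p = params
    n_frames = int(np.floor(p.duration_s / p.frame_interval_s)) + 1
    t = np.arange(n_frames) * p.frame_interval_s

    net = _rng(p.seed, _NETWORK_KEY)
    n_silent = int(round(p.frac_silent * p.n_cells))
    silent_idx = set(net.choice(p.n_cells, size=n_silent, replace=False).tolist())
    wave_times = _poisson_times(net, p.sync_wave_rate_hz, p.duration_s)

    mu, sigma = (0.0, 0.0)
    if p.amp_mean > 0:
        mu, sigma = _lognormal_params(p.amp_mean, max(p.amp_sd, 1e-12))

    # transient kernel evaluated once on the frame grid
    kern_len = int(np.ceil((p.rise_s + 8 * p.decay_s) / p.frame_interval_s)) + 1
    kern_t = np.arange(kern_len) * p.frame_interval_s
    kern = biexp_kernel(kern_t, p.rise_s, p.decay_s)

    traces: list[Trace] = []
    truth_rows: list[dict] = []
    silent_flags: dict[str, bool] = {}
    for i in range(p.n_cells):
        cid = f"cell{i:03d}"
        is_silent = i in silent_idx
        silent_flags[cid] = is_silent
        rng = _rng(p.seed, _CELL_KEY, i)
        wave_u = _rng(p.seed, _WAVE_KEY, i).uniform(size=len(wave_times))

        phase = rng.uniform(0.0, 2 * np.pi)
        y = p.drift_amp * np.sin(2 * np.pi * t / max(p.duration_s, 1e-9) + phase)
        y = y + rng.normal(0.0, p.noise_sd, size=n_frames)

        amp_scale = 1.0 if p.cell_amp_scale is None else p.cell_amp_scale[i]
        rate_scale = 1.0 if p.cell_rate_scale is None else p.cell_rate_scale[i]

        ev_times = np.empty(0)
        if not is_silent:
            ev_times = _poisson_times(rng, p.event_rate_hz * rate_scale, p.duration_s)
        ev_is_wave = np.zeros(len(ev_times), dtype=bool)
        if not is_silent and len(wave_times):
            joined = wave_times[wave_u < p.coupling_p]
            ev_times = np.concatenate([ev_times, joined])
            ev_is_wave = np.concatenate([ev_is_wave, np.ones(len(joined), dtype=bool)])
        order = np.argsort(ev_times, kind="stable")
        ev_times, ev_is_wave = ev_times[order], ev_is_wave[order]

        amps = np.empty(0)
        if len(ev_times):
            amps = rng.lognormal(mu, max(sigma, 1e-12), size=len(ev_times)) * amp_scale
            for et, a in zip(ev_times, amps):
                j = int(np.round(et / p.frame_interval_s))  # onset within one frame
                j = min(j, n_frames - 1)
                m = min(kern_len, n_frames - j)
                y[j : j + m] += a * kern[:m]

        for et, a, w in zip(ev_times, amps, ev_is_wave):
            truth_rows.append(
                {"cell_id": cid, "event_time_s": float(et), "amplitude": float(a),
                 "cluster_id": -1, "is_wave": bool(w)}
            )
        traces.append(Trace(cid, t, y, modality="calcium"))

    events = pd.DataFrame(
        truth_rows, columns=["cell_id", "event_time_s", "amplitude", "cluster_id", "is_wave"]
    )
    return traces, GroundTruth(events, wave_times, silent_flags, p.condition)


def generate_epsc_recording(params: EpscParams) -> tuple[Trace, GroundTruth]:
    """Simulate a voltage-clamp sEPSC recording from a planted mixture."""
    p = params
    fs = p.sample_rate_hz
    n = int(np.floor(p.duration_s * fs)) + 1
    t = np.arange(n) / fs
    rng = _rng(p.seed, _CELL_KEY, 0)

    dt_ms = 1000.0 / fs
    specs = p.cluster_specs
    weights = np.array([c.weight for c in specs]) if specs else np.empty(0)

    times_s: list[float] = []
    amps: list[float] = []
    comp_ids: list[int] = []
    if specs:
        t_ms = 0.0
        while True:
            c = int(rng.choice(len(specs), p=weights))
            spec = specs[c]
            iei = rng.normal(spec.iei_mean_ms, spec.iei_sd_ms)
            iei = max(iei, dt_ms)  # truncate below at one sample
            t_ms += iei
            if t_ms >= p.duration_s * 1000.0:
                break
            amp = max(rng.normal(spec.amp_mean_pA, spec.amp_sd_pA), 0.1)
            times_s.append(t_ms / 1000.0)
            amps.append(amp)
            comp_ids.append(c)

    kern_len = int(np.ceil((p.tau_rise_ms + 8 * p.tau_decay_ms) / 1000.0 * fs)) + 1
    kern = biexp_kernel(np.arange(kern_len) / fs, p.tau_rise_ms / 1000.0, p.tau_decay_ms / 1000.0)
    sign = -1.0 if p.polarity == "inward" else 1.0

    y = rng.normal(0.0, p.noise_sd_pA, size=n)
    for et, a in zip(times_s, amps):
        j = int(np.round(et * fs))
        if j >= n:
            continue
        m = min(kern_len, n - j)
        y[j : j + m] += sign * a * kern[:m]

    events = pd.DataFrame(
        {
            "cell_id": p.cell_id,
            "event_time_s": times_s,
            "amplitude": amps,
            "cluster_id": comp_ids,
            "is_wave": False,
        },
        columns=["cell_id", "event_time_s", "amplitude", "cluster_id", "is_wave"],
    )
    trace = Trace(p.cell_id, t, y, modality="current")
    return trace, GroundTruth(events, np.empty(0), {p.cell_id: False}, "epsc")


def apply_condition_effect(params, effect: ConditionEffect):
    """Return new generator parameters with a condition effect applied.

    Works on :class:`CalciumNetworkParams`. Amplitude and rate factors
    apply globally or, when ``effect.subset`` is given, only to those
    cell indices (via per-cell scale vectors); the coupling factor
    rescales the wave-participation probability (clipped to 1); the
    silent→active switch zeroes the silent fraction. Unaffected fields
    are unchanged.
    """
    if not isinstance(params, CalciumNetworkParams):
        raise TypeError("apply_condition_effect expects CalciumNetworkParams")
    p = params
    changes: dict = {"condition": effect.label}
    if effect.subset is None:
        if effect.amplitude_factor != 1.0:
            changes["amp_mean"] = p.amp_mean * effect.amplitude_factor
        if effect.rate_factor != 1.0:
            changes["event_rate_hz"] = p.event_rate_hz * effect.rate_factor
    else:
        subset = np.asarray(effect.subset, dtype=int)
        if effect.amplitude_factor != 1.0:
            scale = np.ones(p.n_cells) if p.cell_amp_scale is None else p.cell_amp_scale.copy()
            scale[subset] *= effect.amplitude_factor
            changes["cell_amp_scale"] = scale
        if effect.rate_factor != 1.0:
            scale = np.ones(p.n_cells) if p.cell_rate_scale is None else p.cell_rate_scale.copy()
            scale[subset] *= effect.rate_factor
            changes["cell_rate_scale"] = scale
    if effect.coupling_factor != 1.0:
        changes["coupling_p"] = min(p.coupling_p * effect.coupling_factor, 1.0)
    if effect.activate_silent:
        changes["frac_silent"] = 0.0
    return replace(p, **changes)
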