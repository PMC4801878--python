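"""Ground-truth synthetic EEG-fNIRS recordings.

Every pipeline stage is testable against recordings with known truth: sparse
event trains drive voxel-level Delta[HbO]/Delta[HbR] responses (flexible
two-lobe gamma-family waveforms expressing non-canonical, long, lateralized
and inverted morphologies), the channel optical densities follow the same
forward conventions the reconstruction assumes, and realistic physiological
noise (cardiac ~1.1 Hz, respiration ~0.25 Hz, Mayer waves ~0.1 Hz, 1/f
drift, white noise) plus step/spike motion artifacts is superposed before
exponentiating into raw two-wavelength intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .events import EventSet
from .forward import HeadModel, SensitivityMap
from .preprocess import RawRecording
from .reconstruction import CHROMOPHORES, ExtinctionTable, default_extinction

__all__ = [
    "HRSpec",
    "NoiseSpec",
    "make_event_train",
    "hr_waveform",
    "simulate_recording",
    "simulate_null",
    "noise_od_sd",
    "calibrate_amplitude",
    "fit_response_params",
]


@dataclass
class HRSpec:
    """Hemodynamic response morphology relative to the event marker.

    The waveform's 5%-of-peak support is exactly [onset_shift_s,
    onset_shift_s + duration_s] and its main-lobe peak sits at
    onset_shift_s + time_to_peak_s.  ``hbr_ratio`` scales (and sign-flips)
    HbR relative to HbO; ``undershoot_ratio`` adds an opposite-signed second
    lobe in the tail; inverted polarity flips both chromophores;
    ``lateral_gain`` scales the affected and unaffected (mirror) sides.
    """

    onset_shift_s: float = -5.0
    time_to_peak_s: float = 8.0
    duration_s: float = 22.0
    hbo_amplitude_uM: float = 1.0
    hbr_ratio: float = -1.0 / 3.0
    undershoot_ratio: float = 0.0
    polarity: str = "normal"
    lateral_gain: tuple[float, float] = (1.0, 0.5)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not (0 < self.time_to_peak_s < self.duration_s):
            raise ValueError("time_to_peak must lie inside the response duration")
        if self.polarity not in ("normal", "inverted"):
            raise ValueError("polarity must be 'normal' or 'inverted'")


@dataclass
class NoiseSpec:
    """Physiological + instrumental noise, in channel Delta-OD units.

    Cardiac pulsation dominates raw fNIRS fluctuations; Mayer waves and
    respiration sit inside or near the analysis band; the 1/f term models
    slow hemodynamic drift.  Motion artifacts are occasional steps/spikes
    shared across channels, annotated as artifact segments.
    """

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.02
    resp_hz: float = 0.25
    resp_amp: float = 0.003
    mayer_hz: float = 0.1
    mayer_amp: float = 0.003
    pink_slope: float = 1.0
    pink_sd: float = 0.002
    white_sd: float = 0.002
    motion_rate_per_min: float = 0.0
    motion_step: float = 0.05
    motion_spike: float = 0.1

    def __post_init__(self) -> None:
        for a in (self.cardiac_amp, self.resp_amp, self.mayer_amp, self.pink_sd, self.white_sd):
            if a < 0:
                raise ValueError("noise amplitudes must be >= 0")


def make_event_train(
    duration_s: float,
    rate_per_min: float,
    refractory_s: float,
    seed: int | np.random.Generator,
    label: str = "ied",
    margin_s: tuple[float, float] = (0.0, 0.0),
) -> EventSet:
    """Homogeneous Poisson train thinned by a refractory period.

    ``margin_s`` keeps events away from the run edges (e.g. to admit full
    epoch windows).  Raises when the requested density is infeasible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t0, t1 = margin_s[0], duration_s - margin_s[1]
    usable = t1 - t0
    if rate_per_min < 0 or usable <= 0:
        raise ValueError("invalid rate or margins")
    if rate_per_min == 0:
        return EventSet(times=np.array([]), labels=np.array([], object))
    if refractory_s > 0 and rate_per_min / 60.0 * refractory_s > 1.0:
        # mean arrival interval shorter than the refractory period: the
        # requested rate cannot be realized after thinning
        raise ValueError("event density incompatible with the refractory period")
    times = []
    t = t0
    rate = rate_per_min / 60.0
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= t1:
            break
        if not times or t - times[-1] >= refractory_s:
            times.append(t)
    return EventSet(times=np.array(times), labels=np.array([label] * len(times), object))


_SUPPORT_LEVEL = 0.05  # the lobe's nominal support is where it exceeds this


def _lobe_crossings(a: float) -> tuple[float, float]:
    """5%-of-peak crossings of u^a exp(a(1-u)) on either side of the peak u=1."""
    ln_p = np.log(_SUPPORT_LEVEL)
    g = lambda u: a * (np.log(u) + 1 - u) - ln_p
    u_low = np.exp(ln_p / a - 2.0)  # g(u_low) = -a(1+u_low) < 0
    ur = brentq(g, u_low, 1.0 - 1e-12)
    u_high = 2.0
    while g(u_high) > 0:
        u_high *= 2.0
    uf = brentq(g, 1.0 + 1e-12, u_high)
    return ur, uf


def _lobe_alpha(rho: float) -> float:
    """Shape exponent putting the peak at fraction ``rho`` of the 5% support."""

    def f(a: float) -> float:
        ur, uf = _lobe_crossings(a)
        return (1 - ur) / (uf - ur) - rho

    return brentq(f, 0.02, 2000.0)


def _lobe(t: np.ndarray, onset: float, peak: float, end: float) -> np.ndarray:
    """Unit-peak lobe with 5% support exactly [onset, end] and max at ``peak``.

    The gamma-family kernel is right-skewed (peak in the first half of the
    support); later peaks are expressed by time-reversing the kernel.
    """
    t = np.asarray(t, float)
    rho = (peak - onset) / (end - onset)
    rho = min(max(rho, 0.03), 0.97)
    if rho > 0.5:
        return _lobe(onset + end - t, onset, onset + (end - peak), end)
    rho = min(rho, 0.49)  # rho -> 0.5 needs an unbounded shape exponent
    a = _lobe_alpha(rho)
    ur, uf = _lobe_crossings(a)
    scale = (end - onset) / (uf - ur)
    u = (t - onset) / scale + ur
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = np.exp(a * (np.log(u[pos]) + 1 - u[pos]))
    return out


def hr_waveform(spec: HRSpec, t_grid: np.ndarray) -> np.ndarray:
    """Chromophore traces (2, len(t_grid)) in uM, rows (HbO, HbR).

    Main lobe peaks at onset + time_to_peak; with ``undershoot_ratio`` > 0 an
    opposite-signed lobe fills the tail so the overall 5% support still ends
    at onset + duration.
    """
    t = np.asarray(t_grid, float)
    on, dur, ttp = spec.onset_shift_s, spec.duration_s, spec.time_to_peak_s
    if spec.undershoot_ratio > 0:
        split = max(0.6 * dur, min(1.25 * ttp, 0.8 * dur))
        main = _lobe(t, on, on + ttp, on + split)
        u_on = on + 0.9 * split
        u_peak = u_on + 0.4 * (on + dur - u_on)
        under = _lobe(t, u_on, u_peak, on + dur)
        hbo = main - spec.undershoot_ratio * under
    else:
        hbo = _lobe(t, on, on + ttp, on + dur)
    hbo = spec.hbo_amplitude_uM * hbo
    if spec.polarity == "inverted":
        hbo = -hbo
    hbr = spec.hbr_ratio * hbo
    return np.stack([hbo, hbr], axis=0)


def fit_response_params(
    trace: np.ndarray,
    times_s: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.005, 0.3),
    filter_order: int = 4,
) -> dict:
    """Estimate onset / time-to-peak / duration by fitting the waveform family
    through the analysis band to an observed event-locked trace.

    The 0.005 Hz high-pass deforms any slow bump (zero-DC compensation lobes
    narrow its apparent support), so threshold crossings of the filtered
    trace systematically underestimate onset and duration.  Fitting the
    band-passed model instead makes the estimator consistent with the
    measurement chain.  Returns the fitted parameters and the model-trace
    correlation.
    """
    from scipy import signal as _sig
    from scipy.optimize import least_squares

    trace = np.asarray(trace, float)
    times_s = np.asarray(times_s, float)
    sos = _sig.butter(filter_order, band, btype="bandpass", fs=fs, output="sos")
    pad = int(120 * fs)
    t_ext = np.concatenate(
        [
            times_s[0] + (np.arange(-pad, 0)) / fs,
            times_s,
            times_s[-1] + (np.arange(1, pad + 1)) / fs,
        ]
    )

    def model(theta):
        onset, ttp, dur, amp = theta
        ttp = min(max(ttp, 0.02 * dur + 1e-3), 0.98 * dur - 1e-3)
        spec = HRSpec(
            onset_shift_s=onset, time_to_peak_s=ttp, duration_s=dur, hbo_amplitude_uM=amp
        )
        w = hr_waveform(spec, t_ext)[0]
        return _sig.sosfiltfilt(sos, w)[pad : pad + len(times_s)]

    # threshold-crossing initialization
    peak_i = int(np.argmax(np.abs(trace)))
    amp0 = trace[peak_i]
    thr = 0.05 * abs(amp0)
    i = peak_i
    while i > 0 and abs(trace[i - 1]) >= thr:
        i -= 1
    j = peak_i
    while j < len(trace) - 1 and abs(trace[j + 1]) >= thr:
        j += 1
    on0, end0 = times_s[i], times_s[j]
    x0 = np.array([on0, times_s[peak_i] - on0, max(end0 - on0, 6.0), amp0])

    res = least_squares(
        lambda th: model(th) - trace,
        x0,
        bounds=([-18.0, 0.5, 4.0, -np.inf], [15.0, 35.0, 50.0, np.inf]),
        x_scale=[5.0, 5.0, 10.0, max(abs(amp0), 1e-12)],
        max_nfev=60,
    )
    onset, ttp, dur, amp = res.x
    m = model(res.x)
    denom = np.linalg.norm(m) * np.linalg.norm(trace)
    corr = float(m @ trace / denom) if denom > 0 else 0.0
    return {
        "onset_s": float(onset),
        "time_to_peak_s": float(ttp),
        "duration_s": float(dur),
        "amplitude": float(amp),
        "model_correlation": corr,
    }


def noise_od_sd(
    noise: NoiseSpec,
    band: tuple[float, float] | None = (0.005, 0.3),
    fs: float = 20.0,
) -> float:
    """Standard deviation of the noise Delta-OD, by default within the
    analysis band (0.005-0.3 Hz) — the noise the event-related analysis
    actually competes against.  ``band=None`` gives the raw broadband sd.

    Analytic: oscillatory components contribute amp^2/2 scaled by the
    band-pass power response at their frequency; pink and white variance is
    integrated against the filter response.
    """
    if band is None:
        osc = noise.cardiac_amp**2 / 2 + noise.resp_amp**2 / 2 + noise.mayer_amp**2 / 2
        return float(np.sqrt(osc + noise.pink_sd**2 + noise.white_sd**2))
    from scipy import signal as _sig

    sos = _sig.butter(4, band, btype="bandpass", fs=fs, output="sos")

    def h2(freqs):
        _, h = _sig.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs) / fs)
        return np.abs(h) ** 4  # forward-backward filtering squares |H|^2

    var = 0.0
    for f_hz, amp in (
        (noise.cardiac_hz, noise.cardiac_amp),
        (noise.resp_hz, noise.resp_amp),
        (noise.mayer_hz, noise.mayer_amp),
    ):
        var += amp**2 / 2 * float(h2([f_hz])[0])
    f = np.linspace(1e-4, fs / 2, 4000)
    hh = h2(f)
    if noise.white_sd > 0:
        var += noise.white_sd**2 * float(np.trapezoid(hh, f) / (fs / 2))
    if noise.pink_sd > 0:
        # pink spectrum ~ f^-slope normalized to unit variance over [f0, Nyquist]
        f0 = 1.0 / 600.0  # generated per run; slowest resolvable scale ~10 min
        p = f ** (-noise.pink_slope)
        p[f < f0] = f0 ** (-noise.pink_slope)
        p /= np.trapezoid(p, f)
        var += noise.pink_sd**2 * float(np.trapezoid(p * hh, f))
    return float(np.sqrt(var))


def _pink(n: int, slope: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-slope / 2.0)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _channel_signal_coeffs(
    channels: list[tuple[str, str]],
    smaps: dict[tuple[str, str], dict[int, SensitivityMap]],
    masks: dict[str, np.ndarray],
    gains: dict[str, float],
    extinction: ExtinctionTable,
    wavelengths: tuple[int, int],
) -> np.ndarray:
    """(n_ch, n_wl, n_chrom) Delta-OD per uM of chromophore response."""
    n_ch = len(channels)
    coeff = np.zeros((n_ch, len(wavelengths), 2))
    for ci, ch in enumerate(channels):
        for wi, wl in enumerate(wavelengths):
            vals = smaps[ch][wl].values
            ksum = sum(g * float(vals[masks[side]].sum()) for side, g in gains.items())
            for cc, chrom in enumerate(CHROMOPHORES):
                coeff[ci, wi, cc] = extinction(chrom, wl) * ksum
    return coeff


def simulate_recording(
    head: HeadModel,
    channels: list[tuple[str, str]],
    smaps: dict[tuple[str, str], dict[int, SensitivityMap]],
    voi_mask: np.ndarray,
    mirror_mask: np.ndarray,
    events: EventSet,
    hr: HRSpec,
    noise: NoiseSpec,
    seed: int,
    duration_s: float,
    fs: float = 20.0,
    i0: float = 1.0e6,
    extinction: ExtinctionTable | None = None,
    wavelengths: tuple[int, int] = (690, 830),
) -> tuple[RawRecording, dict]:
    """Forward-simulate a raw two-wavelength recording plus full ground truth.

    Voxel concentrations place the HR waveform in the target VOI (affected
    lateral gain) and its mirror (unaffected gain) at every event time;
    channel Delta-OD follows the sensitivity maps and extinction table;
    intensities are I0 * exp(-(signal + noise)); motion artifacts are
    injected with matching annotations.  The master seed fans out to
    independent substreams per noise component.
    """
    extinction = extinction or default_extinction()
    nt = int(round(duration_s * fs))
    t = np.arange(nt) / fs
    if np.any((events.times < 0) | (events.times > duration_s)):
        raise ValueError("event outside the run")
    # only IED markers drive a response; control markers are passive
    times = events.select("ied") if "ied" in set(events.labels) else np.asarray(events.times)

    # event-locked waveform train, shared by every active voxel
    train = np.zeros((2, nt))
    wave_t = np.arange(
        int(np.floor(hr.onset_shift_s * fs)),
        int(np.ceil((hr.onset_shift_s + hr.duration_s) * fs)) + 1,
    )
    wave = hr_waveform(hr, wave_t / fs)
    for ev in times:
        k = wave_t + int(round(ev * fs))
        ok = (k >= 0) & (k < nt)
        train[:, k[ok]] += wave[:, ok]

    masks = {"affected": np.asarray(voi_mask, bool), "unaffected": np.asarray(mirror_mask, bool)}
    gains = {"affected": hr.lateral_gain[0], "unaffected": hr.lateral_gain[1]}
    coeff = _channel_signal_coeffs(channels, smaps, masks, gains, extinction, wavelengths)
    od_signal = np.einsum("cwk,kt->cwt", coeff, train)

    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_osc, r_pink, r_white, r_motion, r_amp, _ = streams
    n_ch = len(channels)
    od_noise = np.zeros((n_ch, len(wavelengths), nt))
    for (f_hz, amp) in (
        (noise.cardiac_hz, noise.cardiac_amp),
        (noise.resp_hz, noise.resp_amp),
        (noise.mayer_hz, noise.mayer_amp),
    ):
        if amp == 0:
            continue
        phase = r_osc.uniform(0, 2 * np.pi, size=(n_ch, len(wavelengths), 1))
        jitter = 1.0 + 0.02 * r_osc.standard_normal((n_ch, len(wavelengths), 1))
        od_noise += amp * np.sin(2 * np.pi * f_hz * jitter * t[None, None, :] + phase)
    if noise.pink_sd > 0:
        for c in range(n_ch):
            for w in range(len(wavelengths)):
                od_noise[c, w] += _pink(nt, noise.pink_slope, noise.pink_sd, r_pink)
    if noise.white_sd > 0:
        od_noise += noise.white_sd * r_white.standard_normal((n_ch, len(wavelengths), nt))

    artifacts: list[tuple[float, float]] = []
    n_motion = r_motion.poisson(noise.motion_rate_per_min * duration_s / 60.0)
    for _ in range(n_motion):
        t0 = r_motion.uniform(0, duration_s)
        kind = r_motion.choice(["step", "spike"])
        scale = r_amp.uniform(0.5, 1.5, size=(n_ch, len(wavelengths), 1))
        k0 = int(t0 * fs)
        if kind == "step":
            seg_len = r_motion.uniform(6.0, 12.0)
            od_noise[:, :, k0:] += noise.motion_step * scale
            artifacts.append((max(0.0, t0 - 1.0), min(duration_s, t0 + seg_len)))
        else:
            width = max(2, int(0.3 * fs))
            k1 = min(nt, k0 + width)
            od_noise[:, :, k0:k1] += noise.motion_spike * scale
            artifacts.append((max(0.0, t0 - 1.0), min(duration_s, t0 + width / fs + 1.0)))

    od_total = od_signal + od_noise
    intensity = i0 * np.exp(-od_total)
    raw = RawRecording(
        channel_ids=list(channels),
        intensity=intensity,
        fs=fs,
        wavelengths=wavelengths,
        artifact_segments=sorted(artifacts),
    )
    truth = {
        "od_signal": od_signal,
        "od_noise_sd": noise_od_sd(noise),
        "train": train,
        "waveform_times_s": wave_t / fs,
        "waveform": wave,
        "voi_mask": masks["affected"],
        "mirror_mask": masks["unaffected"],
        "support_s": (hr.onset_shift_s, hr.onset_shift_s + hr.duration_s),
        "events": events,
    }
    return raw, truth


def simulate_null(
    head: HeadModel,
    channels: list[tuple[str, str]],
    smaps: dict[tuple[str, str], dict[int, SensitivityMap]],
    voi_mask: np.ndarray,
    mirror_mask: np.ndarray,
    events: EventSet,
    hr: HRSpec,
    noise: NoiseSpec,
    seed: int,
    duration_s: float,
    **kw,
) -> tuple[RawRecording, dict]:
    """Same recording with the evoked response amplitude forced to zero."""
    return simulate_recording(
        head,
        channels,
        smaps,
        voi_mask,
        mirror_mask,
        events,
        replace(hr, hbo_amplitude_uM=0.0),
        noise,
        seed,
        duration_s,
        **kw,
    )


def calibrate_amplitude(
    channels: list[tuple[str, str]],
    smaps: dict[tuple[str, str], dict[int, SensitivityMap]],
    voi_mask: np.ndarray,
    mirror_mask: np.ndarray,
    hr: HRSpec,
    noise: NoiseSpec,
    peak_to_noise: float = 0.5,
    extinction: ExtinctionTable | None = None,
    wavelengths: tuple[int, int] = (690, 830),
) -> float:
    """HbO amplitude (uM) so the best channel's single-event Delta-OD peak
    equals ``peak_to_noise`` times the raw noise standard deviation."""
    extinction = extinction or default_extinction()
    masks = {"affected": np.asarray(voi_mask, bool), "unaffected": np.asarray(mirror_mask, bool)}
    gains = {"affected": hr.lateral_gain[0], "unaffected": hr.lateral_gain[1]}
    coeff = _channel_signal_coeffs(channels, smaps, masks, gains, extinction, wavelengths)
    tg = np.linspace(hr.onset_shift_s, hr.onset_shift_s + hr.duration_s, 400)
    unit = replace(hr, hbo_amplitude_uM=1.0)
    wave = hr_waveform(unit, tg)
    per_uM = float(np.max(np.abs(np.einsum("cwk,kt->cwt", coeff, wave))))
    if per_uM <= 0:
        raise ValueError("montage has no sensitivity to the VOI")
    return peak_to_noise * noise_od_sd(noise) / per_uM
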