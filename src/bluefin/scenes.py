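"""Ground-truthed synthetic Antarctic soundscapes.

Emulates the content of the public AcousticTrends_BlueFinLibrary annotated
recordings so every downstream stage (features, SNR, detectors, evaluation)
can be exercised without the real data: tonal Antarctic blue whale song units
(constant ~25-28 Hz unit A, downswept unit B to 19.5 Hz, unit C near
18.5-19 Hz), fin whale 20 Hz pulses in the 15-30 Hz band with optional
high-frequency components near 90-100 Hz, blue D-calls and fin downsweeps,
all over Gaussian background noise with a configurable spectral slope plus a
band-limited 20-30 Hz "chorus" (the aggregate of many distant callers, the
dominant confounder for both detectors).  Optional multipath echoes and
duty-cycled recording schedules complete the emulation.

Tonal units are linear-FM chirps with raised-cosine edge tapers (0.2 s) to
avoid spectral splatter.  Each scene event requests a target SNR in the
band-limited sense of :func:`bluefin.annotations.measure_snr`; amplitudes are
calibrated closed-loop (render, measure, rescale) because that statistic's
unconventional form makes analytic inversion unreliable.  Scenes are
bit-reproducible given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

from .annotations import SNR_BANDS, Annotation, measure_snr
from .detectors import unit_a_frequency

#: Ground truth is simply a list of annotations implied by the event list.
GroundTruth = list


@dataclass(frozen=True)
class CallUnit:
    """One tonal unit of a call: a linear-FM chirp segment.

    ``f_start_hz`` / ``f_end_hz`` of None stand for the year-dependent
    unit-A frequency, substituted at synthesis time.
    """

    offset_s: float
    duration_s: float
    f_start_hz: float | None
    f_end_hz: float | None
    amplitude: float = 1.0


@dataclass(frozen=True)
class CallTemplate:
    """Recipe for one call: ordered tonal units plus an optional
    high-frequency component (centre Hz, bandwidth Hz, level dB relative to
    the tonal units' RMS)."""

    label: str
    units: tuple[CallUnit, ...]
    hf_component: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("template needs at least one unit")
        offsets = [u.offset_s for u in self.units]
        if any(b < a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("unit offsets must be non-decreasing")
        for u in self.units:
            if u.duration_s <= 0:
                raise ValueError("unit durations must be positive")

    @property
    def duration_s(self) -> float:
        return max(u.offset_s + u.duration_s for u in self.units)

    def resolved_units(self, f_a: float) -> list[CallUnit]:
        """Units with None frequencies replaced by the unit-A frequency."""
        return [
            replace(
                u,
                f_start_hz=f_a if u.f_start_hz is None else u.f_start_hz,
                f_end_hz=f_a if u.f_end_hz is None else u.f_end_hz,
            )
            for u in self.units
        ]

    def frequency_box(self, f_a: float, margin_hz: float = 1.5) -> tuple[float, float]:
        """(low, high) frequency bounds of the call's energy, with margin."""
        freqs = [
            f
            for u in self.resolved_units(f_a)
            for f in (u.f_start_hz, u.f_end_hz)
        ]
        lo = max(min(freqs) - margin_hz, 0.5)
        hi = max(freqs) + margin_hz
        if self.hf_component is not None:
            center, bw, _ = self.hf_component
            hi = max(hi, center + bw / 2.0 + margin_hz)
        return lo, hi


def default_templates() -> dict[str, CallTemplate]:
    """One representative template per classification label.

    Blue song units use the drifting unit-A frequency (None placeholder);
    unit C sits at 18.75 Hz, the midpoint of its 18.5-19.0 Hz band.  The fin
    20 Hz pulse is a ~1 s downsweep through the 15-30 Hz detection band; its
    "Plus" form adds a secondary component near 95 Hz at -10 dB.  D-call and
    downsweep durations/bands follow their usual field descriptions.
    """
    a_unit = CallUnit(0.0, 8.0, None, None, 1.0)
    b_unit = CallUnit(8.0, 2.0, None, 19.5, 0.9)
    c_unit = CallUnit(10.0, 2.0, 18.75, 18.75, 0.8)
    pulse = CallUnit(0.0, 1.0, 23.0, 17.0, 1.0)
    return {
        "Bm-Ant-A": CallTemplate("Bm-Ant-A", (a_unit,)),
        "Bm-Ant-B": CallTemplate("Bm-Ant-B", (a_unit, b_unit)),
        "Bm-Ant-Z": CallTemplate("Bm-Ant-Z", (a_unit, b_unit, c_unit)),
        "Bm-D": CallTemplate("Bm-D", (CallUnit(0.0, 3.0, 70.0, 35.0, 1.0),)),
        "Bp-20Hz": CallTemplate("Bp-20Hz", (pulse,)),
        "Bp-20Plus": CallTemplate("Bp-20Plus", (pulse,), hf_component=(95.0, 10.0, -10.0)),
        "Bp-Downsweep": CallTemplate(
            "Bp-Downsweep", (CallUnit(0.0, 0.8, 75.0, 40.0, 1.0),)
        ),
        "Unidentified": CallTemplate(
            "Unidentified", (CallUnit(0.0, 1.5, 50.0, 30.0, 1.0),)
        ),
    }


def _raised_cosine_taper(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    n_ramp = min(n_ramp, n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] *= ramp
        env[n - n_ramp :] *= ramp[::-1]
    return env


def synthesize_call(
    template: CallTemplate,
    sample_rate: float,
    days_since_reference: float = 0.0,
    taper_s: float = 0.2,
) -> np.ndarray:
    """Render one call as a waveform of unit nominal amplitude.

    Tonal units are linear-FM chirps with raised-cosine edge tapers; for
    blue song templates the unit-A frequency comes from the drift model at
    ``days_since_reference``.  The optional high-frequency component is a
    band-spanning sweep whose RMS sits ``level_db`` below the tonal RMS.

    Raises
    ------
    ValueError
        If any unit frequency reaches the Nyquist frequency.
    """
    nyq = sample_rate / 2.0
    f_a = unit_a_frequency(days_since_reference)
    units = template.resolved_units(f_a)
    for u in units:
        for f in (u.f_start_hz, u.f_end_hz):
            if not 0.0 < f < nyq:
                raise ValueError(
                    f"unit frequency {f} Hz outside (0, Nyquist={nyq} Hz)"
                )
    n_total = int(np.ceil(template.duration_s * sample_rate))
    x = np.zeros(n_total)
    for u in units:
        n_u = int(round(u.duration_s * sample_rate))
        if n_u == 0:
            continue
        t = np.arange(n_u) / sample_rate
        sweep = (u.f_end_hz - u.f_start_hz) / u.duration_s
        phase = 2.0 * np.pi * (u.f_start_hz * t + 0.5 * sweep * t**2)
        seg = u.amplitude * np.sin(phase)
        seg *= _raised_cosine_taper(n_u, int(round(taper_s * sample_rate)))
        i0 = int(round(u.offset_s * sample_rate))
        x[i0 : i0 + n_u] += seg[: max(n_total - i0, 0)]
    if template.hf_component is not None:
        center, bw, level_db = template.hf_component
        if center + bw / 2.0 >= nyq:
            raise ValueError("high-frequency component reaches Nyquist")
        tonal_rms = float(np.sqrt(np.mean(x**2)))
        dur = template.duration_s
        t = np.arange(n_total) / sample_rate
        sweep = -bw / dur
        phase = 2.0 * np.pi * ((center + bw / 2.0) * t + 0.5 * sweep * t**2)
        hf = np.sin(phase) * _raised_cosine_taper(
            n_total, int(round(taper_s * sample_rate))
        )
        hf_rms = float(np.sqrt(np.mean(hf**2)))
        if hf_rms > 0:
            hf *= tonal_rms * 10.0 ** (level_db / 20.0) / hf_rms
        x += hf
    return x


# ---------------------------------------------------------------------------
# Scene specification and rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneEvent:
    """One call placed in a scene at a target band-limited SNR (dB)."""

    label: str
    start_s: float
    snr_db: float
    template: CallTemplate | None = None


@dataclass
class SceneSpec:
    """Recipe for a synthetic acoustic scene.

    ``noise_level`` is the broadband background RMS in linear (arbitrary)
    units; ``chorus_level_db`` sets the 20-30 Hz chorus RMS relative to it
    (None disables the chorus).  ``echoes`` lists multipath arrivals as
    (delay s, level dB) applied to every event; echoes are *not* added to the
    ground truth.  ``duty`` is (recorded s, cycle s) or None for continuous
    recording.  The seed fixes the rendered audio bit-exactly.
    """

    duration_s: float
    sample_rate: float = 250.0
    noise_level: float = 1.0
    noise_slope_db_per_octave: float = -1.0
    chorus_band: tuple[float, float] = (20.0, 30.0)
    chorus_level_db: float | None = -3.0
    events: list[SceneEvent] = field(default_factory=list)
    echoes: list[tuple[float, float]] | None = None
    duty: tuple[float, float] | None = None
    days_since_reference: float = 4464.0  # 1 June 2014
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("scene duration must be positive")
        for ev in self.events:
            if not 0.0 <= ev.start_s < self.duration_s:
                raise ValueError(
                    f"event at {ev.start_s} s outside scene [0, {self.duration_s})"
                )
        if self.duty is not None:
            rec, cyc = self.duty
            if not 0.0 < rec <= cyc:
                raise ValueError("duty cycle needs 0 < recorded <= cycle length")


def _shaped_noise(
    rng: np.random.Generator,
    n: int,
    sample_rate: float,
    rms: float,
    slope_db_per_octave: float,
    f_ref: float = 10.0,
) -> np.ndarray:
    """Gaussian noise with a power-law spectral slope, scaled to target RMS."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    f_safe = np.maximum(freqs, 0.5)  # cap the low-frequency rise
    gain = 10.0 ** (slope_db_per_octave * np.log2(f_safe / f_ref) / 20.0)
    shaped = np.fft.irfft(spectrum * gain, n)
    level = np.sqrt(np.mean(shaped**2))
    return shaped * (rms / level) if level > 0 else shaped


def _band_noise(
    rng: np.random.Generator,
    n: int,
    sample_rate: float,
    band: tuple[float, float],
    rms: float,
) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=sample_rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    level = np.sqrt(np.mean(x**2))
    return x * (rms / level) if level > 0 else x


def _snr_band(label: str, box: tuple[float, float], nyq: float) -> tuple[float, float]:
    if label in SNR_BANDS:
        return SNR_BANDS[label]
    return (max(box[0], 1.0), min(box[1], nyq - 1.0))


def _calibrate_amplitude(
    context: np.ndarray,
    ann: Annotation,
    call: np.ndarray,
    i_call: int,
    sample_rate: float,
    band: tuple[float, float],
    target_db: float,
    tol_db: float = 0.25,
    max_iter: int = 8,
) -> float:
    """Closed-loop amplitude calibration against the local background.

    Starts from a power-additivity guess for the required in-box RMS, then
    renders, measures the band-limited SNR statistic, and rescales (the
    statistic grows ~40 log10(amplitude) well above the noise floor).
    """
    base = measure_snr(ann, context, sample_rate, band=band)
    sos = butter(4, band, btype="bandpass", fs=sample_rate, output="sos")
    call_rms = float(np.sqrt(np.mean(sosfiltfilt(sos, call) ** 2)))
    if call_rms == 0.0:
        return 0.0
    req_diff = np.sqrt(np.sqrt(base.var_n) * 10.0 ** (target_db / 20.0))
    req_z = base.z_n + req_diff
    amp = float(np.sqrt(max(req_z**2 - base.z_sn**2, (0.3 * req_z) ** 2)) / call_rms)
    trial = np.array(context)
    for _ in range(max_iter):
        trial[:] = context
        trial[i_call : i_call + call.size] += amp * call
        m = measure_snr(ann, trial, sample_rate, band=band)
        if not m.defined:
            amp *= 2.0
            continue
        err = target_db - m.snr_db
        if abs(err) < tol_db:
            break
        amp *= 10.0 ** (np.clip(err, -20.0, 20.0) / 40.0)
    return amp


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to (audio, ground-truth annotations).

    Background (sloped noise + chorus) is present everywhere; each event's
    call is amplitude-calibrated so that the band-limited SNR statistic
    measured on its truth record returns the requested SNR; echoes, if
    configured, are appended per event but never added to the truth.  The
    duty cycle, if any, is applied last (see :func:`apply_duty_cycle`).
    Identical specs (including seed) give bit-identical output.
    """
    fs = spec.sample_rate
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * fs))
    background = _shaped_noise(
        rng, n, fs, spec.noise_level, spec.noise_slope_db_per_octave
    )
    if spec.chorus_level_db is not None:
        chorus_rms = spec.noise_level * 10.0 ** (spec.chorus_level_db / 20.0)
        background = background + _band_noise(rng, n, fs, spec.chorus_band, chorus_rms)

    templates = default_templates()
    f_a = unit_a_frequency(spec.days_since_reference)
    audio = background.copy()
    truth: GroundTruth = []
    for ev in spec.events:
        template = ev.template if ev.template is not None else templates[ev.label]
        call = synthesize_call(template, fs, spec.days_since_reference)
        begin, end = ev.start_s, ev.start_s + template.duration_s
        if end > spec.duration_s:
            warnings.warn(
                f"event at {ev.start_s:.1f} s extends past the scene end; dropped",
                stacklevel=2,
            )
            continue
        box = template.frequency_box(f_a)
        ann = Annotation(begin, end, box[0], box[1], template.label)
        band = _snr_band(template.label, box, fs / 2.0)

        # calibrate on a local context window (pad for buffer+noise+filter edges)
        d = ann.duration
        pad = 1.0 + d / 2.0 + 2.0
        c0 = max(int(round((begin - pad) * fs)), 0)
        c1 = min(int(round((end + pad) * fs)), n)
        local_ann = Annotation(
            begin - c0 / fs, end - c0 / fs, box[0], box[1], template.label
        )
        i_call = int(round(begin * fs))
        amp = _calibrate_amplitude(
            background[c0:c1], local_ann, call, i_call - c0, fs, band, ev.snr_db
        )

        audio[i_call : i_call + call.size] += amp * call
        if spec.echoes:
            for delay_s, level_db in spec.echoes:
                j = int(round((begin + delay_s) * fs))
                seg = (amp * 10.0 ** (level_db / 20.0)) * call
                j1 = min(j + seg.size, n)
                if j1 > j >= 0:
                    audio[j:j1] += seg[: j1 - j]
        truth.append(ann)

    if spec.duty is not None:
        audio, truth = apply_duty_cycle(audio, truth, spec.duty, fs)
    return audio, truth


def apply_duty_cycle(
    audio: np.ndarray,
    truth: GroundTruth,
    duty: tuple[float, float] | None,
    sample_rate: float,
) -> tuple[np.ndarray, GroundTruth]:
    """Restrict audio to the recorded windows of a duty cycle.

    ``duty = (recorded_s, cycle_s)``: each cycle keeps its first
    ``recorded_s`` seconds.  The recorded windows are concatenated into a
    compressed timeline; truth records are clipped to window boundaries
    (a record straddling an edge is truncated there) and records entirely
    inside unrecorded gaps are dropped with a warning.  ``duty = None`` (or a
    fully-on cycle) is the identity.
    """
    if duty is None:
        return audio, list(truth)
    rec, cyc = duty
    if not 0.0 < rec <= cyc:
        raise ValueError("duty cycle needs 0 < recorded <= cycle length")
    if rec == cyc:
        return audio, list(truth)

    n = audio.size
    total_s = n / sample_rate
    pieces = []
    new_truth: GroundTruth = []
    contributed = [False] * len(truth)
    offset_s = 0.0
    k = 0
    while k * cyc < total_s:
        w0 = k * cyc
        w1 = min(w0 + rec, total_s)
        i0, i1 = int(round(w0 * sample_rate)), int(round(w1 * sample_rate))
        pieces.append(audio[i0:i1])
        for idx, ann in enumerate(truth):
            nb, ne = max(ann.begin, w0), min(ann.end, w1)
            if ne > nb:
                contributed[idx] = True
                new_truth.append(
                    Annotation(
                        begin=offset_s + (nb - w0),
                        end=offset_s + (ne - w0),
                        f_low=ann.f_low,
                        f_high=ann.f_high,
                        label=ann.label,
                        site_year=ann.site_year,
                        source_file=ann.source_file,
                    )
                )
        offset_s += (i1 - i0) / sample_rate
        k += 1
    n_dropped = contributed.count(False)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} truth record(s) fell entirely outside recorded duty "
            "windows and were dropped",
            stacklevel=2,
        )
    new_truth.sort(key=lambda a: a.begin)
    return np.concatenate(pieces) if pieces else audio[:0], new_truth


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------


def write_wav(path, audio: np.ndarray, sample_rate: float) -> None:
    """Write a mono float32 WAV file."""
    wavfile.write(path, int(round(sample_rate)), np.asarray(audio, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file as (float64 waveform, sample rate).

    Integer PCM is rescaled to [-1, 1)."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
    return data.astype(float), float(rate)
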