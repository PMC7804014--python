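"""Annotation data model, selection-table I/O, features, and SNR measurement.

Manual annotations are time-frequency boxes drawn around individual calls,
exchanged as tab-separated "selection tables" (the dialect produced by
spectrogram-review software): a header row naming at least begin/end time in
seconds, low/high frequency in Hz, and a classification label drawn from the
eight-label vocabulary used for Antarctic blue and fin whale sounds.

Two physical measurements are made on each annotation:

* duration/frequency percentile features -- the time span containing the
  central 90% of in-box energy (``t90``) and the 5th/95th percentile
  frequencies of the in-box energy distribution (``f5``/``f95``);

* a band-limited signal-to-noise statistic.  With ``d`` the annotation
  duration, RMS signal+noise level ``Z_sn`` is measured over the annotation,
  and noise is measured over two flanking windows of ``d/2`` s each, separated
  from the annotation by a 1 s buffer so that loosely drawn boxes do not leak
  signal into the noise estimate.  The statistic reported is

      SNR_dB = 20 * log10( (Z_sn - Z_n)**2 / sqrt(var_n) )

  where ``Z_n`` is the RMS level over the concatenated noise windows and
  ``var_n`` the variance of instantaneous power there.  This mixes amplitude
  and power conventions, but it is the form used for detector
  characterisation in this field and is implemented verbatim; a conventional
  power-ratio SNR is provided separately for comparison and is never used on
  the replication path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .spectrogram import SpectrogramParams, stft_power

#: The eight-label classification vocabulary for Antarctic blue (Bm) and fin
#: (Bp) whale sounds: blue song units A / A+B / full Z-call, blue FM D-calls,
#: fin 20 Hz pulses without / with a high-frequency component, fin downsweeps,
#: and unidentifiable transients.
LABELS = (
    "Bm-Ant-A",
    "Bm-Ant-B",
    "Bm-Ant-Z",
    "Bm-D",
    "Bp-20Hz",
    "Bp-20Plus",
    "Bp-Downsweep",
    "Unidentified",
)

#: Pooled label groups evaluated by each detector.
BLUE_SONG_LABELS = ("Bm-Ant-A", "Bm-Ant-B", "Bm-Ant-Z")
FIN_PULSE_LABELS = ("Bp-20Hz", "Bp-20Plus")

#: Default SNR measurement bands (Hz) per classification.
SNR_BANDS = {
    "Bm-Ant-A": (17.0, 29.0),
    "Bm-Ant-B": (17.0, 29.0),
    "Bm-Ant-Z": (17.0, 29.0),
    "Bp-20Hz": (20.0, 30.0),
    "Bp-20Plus": (20.0, 30.0),
}


@dataclass
class Annotation:
    """One manually marked call: a time-frequency box plus a label.

    Times are seconds from the start of the recording, 0-based, with the
    half-open convention ``[begin, end)``; frequencies in Hz.
    """

    begin: float
    end: float
    f_low: float
    f_high: float
    label: str
    site_year: str = ""
    source_file: str = ""

    def __post_init__(self) -> None:
        if not self.end > self.begin:
            raise ValueError(f"annotation end ({self.end}) must exceed begin ({self.begin})")
        if not 0.0 < self.f_low < self.f_high:
            raise ValueError(
                f"annotation needs 0 < f_low < f_high, got ({self.f_low}, {self.f_high})"
            )
        if self.label not in LABELS:
            raise ValueError(f"unknown classification label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.begin

    def overlaps(self, begin: float, end: float) -> bool:
        """Any positive time overlap with the half-open interval [begin, end)."""
        return self.begin < end and begin < self.end


@dataclass(frozen=True)
class FeatureSummary:
    """Energy-percentile features of one annotation.

    ``t90`` is the time span between the 5th and 95th percentiles of the
    within-box cumulative energy over time; ``f5``/``f95`` are the analogous
    frequency percentiles.  ``defined`` is False when the box holds no energy.
    """

    t90: float
    f5: float
    f95: float
    defined: bool = True


@dataclass(frozen=True)
class SnrMeasurement:
    """Band-limited SNR of one annotation.

    ``z_sn``/``z_n`` are RMS levels of the band-passed series over the
    annotation and the concatenated noise windows; ``var_n`` is the variance
    of instantaneous power over the noise windows.  ``snr_db`` is NaN when
    flagged undefined (degenerate noise, or signal level at or below noise).
    """

    z_sn: float
    z_n: float
    var_n: float
    snr_db: float
    band: tuple[float, float]
    defined: bool = True


# ---------------------------------------------------------------------------
# Selection-table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {
    "begin": "Begin Time (s)",
    "end": "End Time (s)",
    "f_low": "Low Freq (Hz)",
    "f_high": "High Freq (Hz)",
}
_LABEL_COLUMNS = ("Classification", "Call Type", "Label", "Tags", "Species")


def read_selection_table(path) -> list[Annotation]:
    """Read annotations from a tab-separated selection table.

    Columns are located by header name, never by position.  The label is
    taken from the first of ``Classification``, ``Call Type``, ``Label``,
    ``Tags`` or ``Species`` present.

    Raises
    ------
    ValueError
        Naming the missing column, or, for malformed numeric fields, the
        1-based data row at fault.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _REQUIRED_COLUMNS.values():
        if column not in table.columns:
            raise ValueError(f"selection table is missing required column {column!r}")
    label_col = next((c for c in _LABEL_COLUMNS if c in table.columns), None)
    if label_col is None:
        raise ValueError(
            "selection table is missing a label column "
            f"(one of {', '.join(_LABEL_COLUMNS)})"
        )
    annotations = []
    for i, row in enumerate(table.itertuples(index=False), start=1):
        record = dict(zip(table.columns, row))
        numeric = {}
        for field, column in _REQUIRED_COLUMNS.items():
            try:
                numeric[field] = float(record[column])
            except (TypeError, ValueError) as err:
                raise ValueError(
                    f"row {i}: non-numeric value {record[column]!r} "
                    f"in column {column!r}"
                ) from err
        annotations.append(
            Annotation(
                begin=numeric["begin"],
                end=numeric["end"],
                f_low=numeric["f_low"],
                f_high=numeric["f_high"],
                label=str(record[label_col]),
                site_year=str(record.get("Site Year", "") or ""),
                source_file=str(record.get("Begin File", "") or ""),
            )
        )
    return annotations


def write_selection_table(annotations: Iterable[Annotation], path) -> None:
    """Write annotations as a tab-separated selection table.

    Numeric fields use a fixed ``%.6f`` format so that write -> read -> write
    round-trips are byte-identical.
    """
    rows = list(annotations)
    table = pd.DataFrame(
        {
            "Selection": np.arange(1, len(rows) + 1),
            "Begin Time (s)": [f"{a.begin:.6f}" for a in rows],
            "End Time (s)": [f"{a.end:.6f}" for a in rows],
            "Low Freq (Hz)": [f"{a.f_low:.6f}" for a in rows],
            "High Freq (Hz)": [f"{a.f_high:.6f}" for a in rows],
            "Classification": [a.label for a in rows],
            "Site Year": [a.site_year for a in rows],
            "Begin File": [a.source_file for a in rows],
        }
    )
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def _percentile_crossing(cumulative: np.ndarray, coords: np.ndarray, q: float) -> float:
    """Coordinate at which the normalised cumulative distribution crosses q."""
    total = cumulative[-1]
    return float(np.interp(q * total, cumulative, coords))


def measure_features(
    ann: Annotation,
    audio: np.ndarray,
    sample_rate: float,
    params: SpectrogramParams | None = None,
) -> FeatureSummary:
    """Energy-percentile duration and frequency bounds of one annotation.

    The spectrogram is restricted to the annotation's time-frequency box;
    ``t90`` spans the 5th-95th percentiles of cumulative energy over time,
    ``f5``/``f95`` the 5th/95th percentiles over frequency, both found by
    linear interpolation on the cumulative marginal energy.
    """
    if params is None:
        params = SpectrogramParams()
    power, times, freqs = stft_power(audio, sample_rate, params)
    in_time = (times >= ann.begin) & (times <= ann.end)
    in_freq = (freqs >= ann.f_low) & (freqs <= ann.f_high)
    if not in_time.any() or not in_freq.any():
        return FeatureSummary(np.nan, np.nan, np.nan, defined=False)
    box = power[np.ix_(in_time, in_freq)]
    total = box.sum()
    if total <= 0.0:
        return FeatureSummary(np.nan, np.nan, np.nan, defined=False)
    t_marginal = box.sum(axis=1).cumsum()
    f_marginal = box.sum(axis=0).cumsum()
    t5 = _percentile_crossing(t_marginal, times[in_time], 0.05)
    t95 = _percentile_crossing(t_marginal, times[in_time], 0.95)
    f5 = _percentile_crossing(f_marginal, freqs[in_freq], 0.05)
    f95 = _percentile_crossing(f_marginal, freqs[in_freq], 0.95)
    return FeatureSummary(t90=t95 - t5, f5=f5, f95=f95)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------


def _bandpass(
    audio: np.ndarray, sample_rate: float, band: tuple[float, float]
) -> np.ndarray:
    """4th-order zero-phase Butterworth band-pass."""
    lo, hi = band
    nyq = sample_rate / 2.0
    if not 0.0 < lo < hi < nyq:
        raise ValueError(f"band {band} must satisfy 0 < lo < hi < Nyquist ({nyq} Hz)")
    sos = butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, audio)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def default_band(label: str) -> tuple[float, float]:
    """Default SNR measurement band for a classification label."""
    try:
        return SNR_BANDS[label]
    except KeyError:
        raise KeyError(
            f"no default SNR band for label {label!r}; pass band= explicitly"
        ) from None


def measure_snr(
    ann: Annotation,
    audio: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] | None = None,
    buffer_s: float = 1.0,
) -> SnrMeasurement:
    """Band-limited SNR of one annotation against its flanking noise.

    With ``d = ann.duration``, the noise windows are
    ``[begin - buffer - d/2, begin - buffer)`` and
    ``[end + buffer, end + buffer + d/2)``; noise statistics are computed
    over the concatenated samples of both windows.  Noise windows that would
    cross a file edge shrink symmetrically (both to the shorter available
    length) with a warning; if no noise samples fit at all, a ValueError
    names the shortfall.
    """
    if band is None:
        band = default_band(ann.label)
    audio = np.asarray(audio, dtype=float)
    n = audio.size
    d = ann.duration
    half = d / 2.0

    file_end = n / sample_rate
    avail_before = ann.begin - buffer_s
    avail_after = file_end - (ann.end + buffer_s)
    usable_half = min(half, avail_before, avail_after)
    if usable_half <= 0.0:
        raise ValueError(
            "insufficient context audio for SNR measurement: need "
            f"{buffer_s + half:.3f} s beyond both annotation edges, have "
            f"{max(avail_before, 0.0):.3f} s before and {max(avail_after, 0.0):.3f} s after"
        )
    if usable_half < half:
        warnings.warn(
            f"noise windows shrunk from {half:.3f} s to {usable_half:.3f} s "
            "per side to stay inside the file",
            stacklevel=2,
        )

    filtered = _bandpass(audio, sample_rate, band)

    def segment(t0: float, t1: float) -> np.ndarray:
        i0 = max(int(round(t0 * sample_rate)), 0)
        i1 = min(int(round(t1 * sample_rate)), n)
        return filtered[i0:i1]

    signal = segment(ann.begin, ann.end)
    noise = np.concatenate(
        [
            segment(ann.begin - buffer_s - usable_half, ann.begin - buffer_s),
            segment(ann.end + buffer_s, ann.end + buffer_s + usable_half),
        ]
    )
    if signal.size == 0 or noise.size == 0:
        raise ValueError("annotation or noise window contains no samples")

    z_sn = _rms(signal)
    z_n = _rms(noise)
    var_n = float(np.var(np.square(noise)))
    if var_n <= 0.0 or z_sn <= z_n:
        return SnrMeasurement(z_sn, z_n, var_n, np.nan, band, defined=False)
    snr_db = 20.0 * np.log10((z_sn - z_n) ** 2 / np.sqrt(var_n))
    return SnrMeasurement(z_sn, z_n, var_n, float(snr_db), band)


def conventional_snr(
    ann: Annotation,
    audio: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] | None = None,
    buffer_s: float = 1.0,
) -> float:
    """Conventional band-limited SNR, 10*log10((P_sn - P_n) / P_n), in dB.

    Provided for comparison only; the characterisation pipeline always uses
    :func:`measure_snr`.  Returns NaN when the annotation power does not
    exceed the noise power.
    """
    if band is None:
        band = default_band(ann.label)
    m = measure_snr(ann, audio, sample_rate, band=band, buffer_s=buffer_s)
    p_sn, p_n = m.z_sn**2, m.z_n**2
    if p_n <= 0.0 or p_sn <= p_n:
        return float("nan")
    return float(10.0 * np.log10((p_sn - p_n) / p_n))


def mean_duration(
    annotations: Sequence[Annotation], labels: Iterable[str] | None = None
) -> float:
    """Arithmetic mean duration (s) of annotations, optionally label-filtered.

    This is the d-bar statistic that sets automated detection boundaries and
    the refractory period.
    """
    if labels is not None:
        wanted = set(labels)
        annotations = [a for a in annotations if a.label in wanted]
    if not annotations:
        raise ValueError("no annotations remain after label filtering")
    return float(np.mean([a.duration for a in annotations]))
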