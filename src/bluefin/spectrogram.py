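"""STFT power spectrogram and decaying-average noise normalisation.

Both detectors operate on magnitude-squared short-time Fourier spectra.  The
defaults mirror the operating configuration used for low-frequency baleen
whale detection at a 250 Hz sample rate: a 1.024 s analysis window with no
overlap between successive frames (the detection "time resolution"), which at
250 Hz gives a 256-sample window and one-sided bins of 250/256 ~ 0.977 Hz,
printed in configuration tables as 0.98 Hz.

Background noise is removed with a per-bin exponentially decaying average
("average subtraction"): at each time step the current running average is
subtracted from the spectral slice, and the average is then updated towards
that slice with update constant ``alpha``.  Subtracting *before* updating
prevents a transient call from instantly cancelling itself out of the
spectrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window


@dataclass(frozen=True)
class SpectrogramParams:
    """Frontend parameters.

    Parameters
    ----------
    window_s:
        Analysis window length in seconds.  ``window_s * sample_rate`` must
        round to a positive integer number of samples.
    hop_s:
        Frame advance in seconds.  The detection configuration uses
        ``hop_s == window_s`` (no overlap); spectrogram *display* conventions
        with high overlap are deliberately not used on the detection path.
    window:
        Window function name understood by :func:`scipy.signal.get_window`.
    """

    window_s: float = 1.024
    hop_s: float = 1.024
    window: str = "hann"

    def n_window(self, sample_rate: float) -> int:
        n = int(round(self.window_s * sample_rate))
        if n <= 0:
            raise ValueError("window length must span at least one sample")
        return n

    def n_hop(self, sample_rate: float) -> int:
        n = int(round(self.hop_s * sample_rate))
        if n <= 0:
            raise ValueError("hop must span at least one sample")
        if self.hop_s > self.window_s:
            raise ValueError("hop must not exceed the window length")
        return n

    def freq_resolution(self, sample_rate: float) -> float:
        """Width of one frequency bin in Hz (sample_rate / window samples)."""
        return sample_rate / self.n_window(sample_rate)


def stft_power(
    audio: np.ndarray,
    sample_rate: float,
    params: SpectrogramParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude-squared STFT of a mono waveform.

    Returns ``(power, times, freqs)`` where ``power`` has shape
    ``(n_frames, n_bins)``: ``power[t, f] = |FFT(window * frame_t)[f]|**2``
    (one-sided, no additional scaling), ``times`` are frame *centre* times in
    seconds and ``freqs`` the one-sided bin frequencies in Hz.

    Raises
    ------
    ValueError
        If the audio is shorter than one analysis window.
    """
    if params is None:
        params = SpectrogramParams()
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be a 1-D mono waveform")
    n_win = params.n_window(sample_rate)
    n_hop = params.n_hop(sample_rate)
    if audio.size < n_win:
        raise ValueError(
            f"audio of {audio.size} samples is shorter than one "
            f"{n_win}-sample analysis window"
        )
    n_frames = 1 + (audio.size - n_win) // n_hop
    win = get_window(params.window, n_win, fftbins=True)
    starts = np.arange(n_frames) * n_hop
    frames = np.lib.stride_tricks.as_strided(
        audio,
        shape=(n_frames, n_win),
        strides=(audio.strides[0] * n_hop, audio.strides[0]),
    )
    spec = np.fft.rfft(frames * win, axis=1)
    power = np.abs(spec) ** 2
    times = (starts + n_win / 2.0) / sample_rate
    freqs = np.fft.rfftfreq(n_win, d=1.0 / sample_rate)
    return power, times, freqs


def average_subtraction(matrix: np.ndarray, alpha: float) -> np.ndarray:
    """Subtract a per-bin exponentially decaying average from a spectrogram.

    For each time slice ``t`` and frequency bin ``f``::

        out[t, f] = S[t, f] - A[t-1, f]
        A[t, f]   = (1 - alpha) * A[t-1, f] + alpha * S[t, f]

    with the running average initialised to the first slice
    (``A[0] = S[0]``, so ``out[0] = 0``).  Negative values are retained;
    the energy-sum detector clips them at zero itself.

    Parameters
    ----------
    matrix:
        Spectrogram power, shape ``(n_frames, n_bins)``.
    alpha:
        Update constant in ``(0, 1]``.  ``alpha = 1`` reduces to a first
        difference along time.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("update constant alpha must be in (0, 1]")
    S = np.asarray(matrix, dtype=float)
    if S.ndim != 2:
        raise ValueError("matrix must be 2-D (time x frequency)")
    out = np.empty_like(S)
    avg = S[0].copy()
    out[0] = 0.0
    for t in range(1, S.shape[0]):
        out[t] = S[t] - avg
        avg += alpha * (S[t] - avg)
    return out
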