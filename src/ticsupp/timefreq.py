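"""Event-related spectral perturbation (ERSP) on a log-spaced frequency grid.

An ERSP map expresses, in dB, how spectral power in the 5 s window before a
motor event (tic or blink) deviates from the power in a pre-event baseline
(-5..-4 s).  Power is estimated with complex Morlet wavelets whose length
grows from 3 cycles at 1 Hz to 15 cycles at 50 Hz, epochs are
reflection-padded so the full time grid is populated, power is averaged
across epochs before conversion to dB, and the baseline reference is the
mean log power over the baseline columns (a geometric-mean baseline), which
makes every ERSP row average to exactly 0 dB inside the baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

__all__ = [
    "ERSPGrid",
    "ERSPTensor",
    "DeltaERSP",
    "GridMismatchError",
    "compute_ersp",
    "collapse_suppression",
    "delta_ersp",
]

#: analysis window relative to event onset, seconds
WINDOW_S = (-5.0, 0.0)


class GridMismatchError(ValueError):
    """Two ERSP tensors do not share the same time-frequency grid."""


def _default_cycles(freqs: np.ndarray) -> np.ndarray:
    """Wavelet length in cycles: 3 at 1 Hz, growing linearly to 15 at 50 Hz."""
    return 3.0 + 12.0 * (freqs - 1.0) / 49.0


@dataclass(frozen=True)
class ERSPGrid:
    """Time-frequency grid: log-spaced frequencies, linear latencies, baseline."""

    freqs_hz: np.ndarray
    times_s: np.ndarray
    baseline_s: tuple[float, float] = (-5.0, -4.0)
    n_cycles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        freqs = np.asarray(self.freqs_hz, dtype=float)
        times = np.asarray(self.times_s, dtype=float)
        if freqs.ndim != 1 or np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be a strictly increasing 1-D array")
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D array")
        if not (WINDOW_S[0] <= times[0] and times[-1] <= WINDOW_S[1]):
            raise ValueError(f"time grid must lie within {WINDOW_S} s")
        b0, b1 = self.baseline_s
        if not (times[0] <= b0 < b1 <= times[-1]):
            raise ValueError("baseline window must lie inside the time grid")
        cycles = self.n_cycles
        cycles = _default_cycles(freqs) if cycles is None else np.asarray(cycles, float)
        if cycles.shape != freqs.shape or np.any(cycles <= 0):
            raise ValueError("n_cycles must be positive and match freqs_hz")
        object.__setattr__(self, "freqs_hz", freqs)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "n_cycles", cycles)

    @classmethod
    def default(cls) -> "ERSPGrid":
        """50 log-spaced frequencies in [1, 50] Hz x 1251 latencies in [-5, 0] s."""
        return cls.regular(50, 1251)

    @classmethod
    def regular(
        cls,
        n_freqs: int,
        n_times: int,
        fmin: float = 1.0,
        fmax: float = 50.0,
        baseline_s: tuple[float, float] = (-5.0, -4.0),
    ) -> "ERSPGrid":
        freqs = np.logspace(np.log10(fmin), np.log10(fmax), n_freqs)
        times = np.linspace(WINDOW_S[0], WINDOW_S[1], n_times)
        return cls(freqs_hz=freqs, times_s=times, baseline_s=baseline_s)

    @property
    def times_ms(self) -> np.ndarray:
        return self.times_s * 1000.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.freqs_hz.size, self.times_s.size)

    @property
    def baseline_columns(self) -> np.ndarray:
        b0, b1 = self.baseline_s
        return (self.times_s >= b0) & (self.times_s <= b1)

    def matches(self, other: "ERSPGrid") -> bool:
        return (
            self.freqs_hz.shape == other.freqs_hz.shape
            and self.times_s.shape == other.times_s.shape
            and np.allclose(self.freqs_hz, other.freqs_hz)
            and np.allclose(self.times_s, other.times_s)
            and self.baseline_s == other.baseline_s
        )


@dataclass(frozen=True)
class ERSPTensor:
    """Baseline-referenced dB power on an :class:`ERSPGrid`."""

    values: np.ndarray  # (n_freqs, n_times) dB
    grid: ERSPGrid
    n_epochs: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(f"values shape {values.shape} != grid shape {self.grid.shape}")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class DeltaERSP:
    """The suppression-minus-free contrast (Supp_Vrb + Supp_Rwd)/2 - NoSupp, dB."""

    values: np.ndarray
    grid: ERSPGrid


def morlet_power(
    epochs: np.ndarray,
    sampling_rate: float,
    freqs_hz: np.ndarray,
    n_cycles: np.ndarray,
) -> np.ndarray:
    """Single-trial wavelet power, shape ``(n_freqs, n_epochs, n_samples)``.

    The Morlet filter bank is applied in the frequency domain (a Gaussian
    transfer function centred on each analysis frequency, zero at DC and
    negative frequencies), which is equivalent to convolution with a complex
    Morlet wavelet of unit passband gain.  Epochs are reflection-padded by
    four standard deviations of the longest wavelet so the filter output is
    defined over the full epoch.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_ep, n = epochs.shape
    sigma_t = n_cycles / (2.0 * np.pi * freqs_hz)
    pad = int(np.ceil(4.0 * sigma_t.max() * sampling_rate))
    if pad > n - 1:
        raise ValueError(
            "epoch too short for the lowest-frequency wavelet "
            f"(need at least {pad + 1} samples, got {n})"
        )
    padded = np.pad(epochs, ((0, 0), (pad, pad)), mode="reflect")
    nfft = next_fast_len(padded.shape[1])
    spec = fft(padded, n=nfft, axis=-1)
    f_fft = np.fft.fftfreq(nfft, 1.0 / sampling_rate)
    sigma_f = 1.0 / (2.0 * np.pi * sigma_t)
    gain = 2.0 * np.exp(
        -0.5 * ((f_fft[None, :] - freqs_hz[:, None]) / sigma_f[:, None]) ** 2
    )
    gain[:, f_fft <= 0] = 0.0
    analytic = ifft(spec[None, :, :] * gain[:, None, :], axis=-1)[..., pad : pad + n]
    return np.abs(analytic) ** 2


def compute_ersp(
    epochs: np.ndarray,
    sampling_rate: float,
    grid: ERSPGrid | None = None,
) -> ERSPTensor:
    """ERSP of a set of pre-event epochs.

    Parameters
    ----------
    epochs
        ``(n_epochs, n_samples)`` raw amplitude; the epoch spans [-5, 0] s so
        ``n_samples`` must equal ``5 * sampling_rate`` (rounded).
    sampling_rate
        Hz; must exceed twice the highest analysis frequency.
    grid
        Output grid; defaults to the 50 x 1251 grid.

    Returns
    -------
    ERSPTensor
        ``10*log10(power / baseline)`` where power is averaged across epochs
        and baseline is the per-frequency geometric mean of that averaged
        power over the baseline window.
    """
    grid = ERSPGrid.default() if grid is None else grid
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 1:
        raise ValueError("need at least one epoch")
    if not np.all(np.isfinite(epochs)):
        raise ValueError("epochs contain non-finite samples")
    if sampling_rate <= 2.0 * grid.freqs_hz[-1]:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz is not above the Nyquist limit for "
            f"{grid.freqs_hz[-1]} Hz"
        )
    n_expected = int(round((WINDOW_S[1] - WINDOW_S[0]) * sampling_rate))
    if epochs.shape[1] != n_expected:
        raise ValueError(
            f"epochs have {epochs.shape[1]} samples; expected {n_expected} "
            f"for a {WINDOW_S} s window at {sampling_rate} Hz"
        )

    power = morlet_power(epochs, sampling_rate, grid.freqs_hz, grid.n_cycles)
    mean_power = power.mean(axis=1)  # average over epochs before dB
    sample_times = WINDOW_S[0] + np.arange(epochs.shape[1]) / sampling_rate
    log_power = 10.0 * np.log10(mean_power)
    on_grid = np.vstack(
        [np.interp(grid.times_s, sample_times, row) for row in log_power]
    )
    base = grid.baseline_columns
    values = on_grid - on_grid[:, base].mean(axis=1, keepdims=True)
    return ERSPTensor(values=values, grid=grid, n_epochs=epochs.shape[0])


def _check_grids(*tensors) -> ERSPGrid:
    grid = tensors[0].grid
    for t in tensors[1:]:
        if not grid.matches(t.grid):
            raise GridMismatchError("ERSP tensors are on different grids")
    return grid


def collapse_suppression(ersp_vrb: ERSPTensor, ersp_rwd: ERSPTensor) -> ERSPTensor:
    """Element-wise mean of the two suppression-condition ERSPs (Supp_Ave)."""
    grid = _check_grids(ersp_vrb, ersp_rwd)
    return ERSPTensor(
        values=(ersp_vrb.values + ersp_rwd.values) / 2.0,
        grid=grid,
        n_epochs=ersp_vrb.n_epochs + ersp_rwd.n_epochs,
    )


def delta_ersp(
    ersp_vrb: ERSPTensor, ersp_rwd: ERSPTensor, ersp_nosupp: ERSPTensor
) -> DeltaERSP:
    """(Supp_Vrb + Supp_Rwd)/2 - NoSupp, element-wise."""
    grid = _check_grids(ersp_vrb, ersp_rwd, ersp_nosupp)
    values = (ersp_vrb.values + ersp_rwd.values) / 2.0 - ersp_nosupp.values
    return DeltaERSP(values=values, grid=grid)
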