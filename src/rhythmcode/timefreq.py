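"""Quadratic time-frequency analysis of single-channel EEG segments.

Implements the discrete Wigner-Ville distribution (WVD), its smoothed
pseudo variant (SPWVD) with separable time and lag windows, and the
reassigned SPWVD (RSPWVD) in which every plane value is relocated to the
local centre of gravity of the energy distribution.

Discretisation conventions
--------------------------
The analytic signal ``z`` of the (mean-removed) input is evaluated on the
instantaneous autocorrelation ``z[n+m] * conj(z[n-m])`` and transformed
over the lag ``m`` with an ``N``-point FFT, which places frequency bin
``k`` at ``k * fs / (2 N)`` Hz, so the grid spans ``[0, fs/2)``.  Time
indices are 0-based; times in seconds are ``index / fs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, hilbert
from scipy.signal.windows import hamming

from .errors import InvalidInputError, InvalidSpecError

__all__ = [
    "SignalSegment",
    "SmoothingSpec",
    "TimeFrequencyPlane",
    "analytic_signal",
    "compute_wvd",
    "compute_spwvd",
    "reassignment_coordinates",
    "compute_rspwvd",
    "blocked_rspwvd",
]

#: grid points whose SPWVD magnitude falls below this fraction of the plane
#: maximum keep their own coordinates instead of being reassigned
EPS_RELATIVE = 1e-12


@dataclass(frozen=True)
class SignalSegment:
    """One channel x one trial of raw EEG samples plus sampling metadata."""

    samples: np.ndarray
    fs: float
    channel: str = ""
    trial_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise InvalidInputError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("samples contain non-finite values")
        min_len = int(np.ceil(0.2 * self.fs))
        if samples.size < min_len:
            raise InvalidInputError(
                f"segment of {samples.size} samples is shorter than one 0.2 s "
                f"timestamp ({min_len} samples at fs={self.fs})"
            )

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.samples.size / self.fs

    def tail(self, seconds: float) -> "SignalSegment":
        """Return the final ``seconds`` of the segment."""
        n = int(round(seconds * self.fs))
        if n > self.samples.size:
            raise InvalidInputError(
                f"cannot take final {seconds} s from a {self.duration:.3f} s segment"
            )
        return SignalSegment(
            self.samples[self.samples.size - n:], self.fs,
            self.channel, self.trial_id, self.subject_id,
        )


def _check_window(w: np.ndarray, name: str) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size % 2 == 0:
        raise InvalidSpecError(f"{name} window must be 1-D with odd length, got shape {w.shape}")
    if not np.allclose(w, w[::-1], rtol=0, atol=1e-12):
        raise InvalidSpecError(f"{name} window must be symmetric about its centre")
    return w


@dataclass(frozen=True)
class SmoothingSpec:
    """Separable smoothing windows for the SPWVD and their reassignment kernels.

    ``g`` smooths along time (normalised to unit sum) and ``h`` windows the
    lag axis (normalised to unit peak).  ``tau_g`` is the elementwise product
    of the centred index grid with ``g`` and ``d_h`` the discrete derivative
    of ``h``; both are derived automatically and drive the centre-of-gravity
    coordinates.  Length-1 windows mean "no smoothing" on that axis.
    """

    g: np.ndarray
    h: np.ndarray
    tau_g: np.ndarray = field(default=None)  # type: ignore[assignment]
    d_h: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        g = _check_window(self.g, "time-smoothing (g)")
        h = _check_window(self.h, "lag-smoothing (h)")
        total = g.sum()
        if total <= 0:
            raise InvalidSpecError("time-smoothing window must have positive sum")
        g = g / total
        peak = np.abs(h).max()
        if peak <= 0:
            raise InvalidSpecError("lag-smoothing window must have a positive peak")
        h = h / peak
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "h", h)
        if self.tau_g is None:
            half = (g.size - 1) // 2
            object.__setattr__(self, "tau_g", np.arange(-half, half + 1) * g)
        else:
            tau_g = np.asarray(self.tau_g, dtype=float)
            if tau_g.size != g.size:
                raise InvalidSpecError("tau_g must have the same length as g")
            object.__setattr__(self, "tau_g", tau_g)
        if self.d_h is None:
            d_h = np.gradient(h) if h.size > 1 else np.zeros(1)
            object.__setattr__(self, "d_h", d_h)
        else:
            d_h = np.asarray(self.d_h, dtype=float)
            if d_h.size != h.size:
                raise InvalidSpecError("d_h must have the same length as h")
            object.__setattr__(self, "d_h", d_h)

    @classmethod
    def default(cls, n_samples: int) -> "SmoothingSpec":
        """Conventional Hamming windows: g of length ~n/10, h of length ~n/4."""
        def odd(x: float) -> int:
            m = max(int(round(x)), 1)
            return m if m % 2 == 1 else m + 1

        lg, lh = odd(n_samples / 10), odd(n_samples / 4)
        g = hamming(lg, sym=True) if lg > 1 else np.ones(1)
        h = hamming(lh, sym=True) if lh > 1 else np.ones(1)
        return cls(g=g, h=h)

    @classmethod
    def unit(cls) -> "SmoothingSpec":
        """Degenerate spec: no smoothing on either axis (SPWVD == WVD)."""
        return cls(g=np.ones(1), h=np.ones(1))


@dataclass(frozen=True)
class TimeFrequencyPlane:
    """Discretised power distribution over a frequency grid x time grid."""

    values: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray  # Hz, ascending
    times: np.ndarray  # s, ascending, uniform at 1/fs

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        freqs = np.asarray(self.freqs, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if values.shape != (freqs.size, times.size):
            raise InvalidInputError(
                f"plane shape {values.shape} does not match grids "
                f"({freqs.size} freqs x {times.size} times)"
            )
        if freqs.size > 1 and np.any(np.diff(freqs) <= 0):
            raise InvalidInputError("frequency grid must be strictly increasing")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise InvalidInputError("time grid must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "times", times)

    @property
    def total_energy(self) -> float:
        return float(self.values.sum())


def analytic_signal(seg: SignalSegment) -> np.ndarray:
    """Analytic (one-sided-spectrum) signal of the mean-removed segment.

    The real part equals the mean-removed input; suppressing negative
    frequencies removes the interference between positive- and
    negative-frequency images in the discrete WVD.
    """
    x = seg.samples
    if x.size < 4:
        raise InvalidInputError("analytic signal requires at least 4 samples")
    return hilbert(x - x.mean())


# ---------------------------------------------------------------------------
# core kernels (batched over blocks; axis order = (block, lag/freq, time))
# ---------------------------------------------------------------------------

def _signed_lags(n: int) -> np.ndarray:
    r = np.arange(n)
    return np.where(r <= n // 2, r, r - n)


def _lag_products(z_blocks: np.ndarray) -> np.ndarray:
    """Instantaneous autocorrelation z[n+m] conj(z[n-m]) on the wrapped lag grid."""
    _, n = z_blocks.shape
    m = _signed_lags(n)
    idx = np.arange(n)
    i1 = idx[None, :] + m[:, None]
    i2 = idx[None, :] - m[:, None]
    valid = (i1 >= 0) & (i1 < n) & (i2 >= 0) & (i2 < n)
    a = z_blocks[:, np.clip(i1, 0, n - 1)] * np.conj(z_blocks[:, np.clip(i2, 0, n - 1)])
    a[:, ~valid] = 0.0
    return a


def _lag_weights(window: np.ndarray, n: int) -> np.ndarray:
    """Place a centred lag window onto the wrapped lag grid of length n.

    A length-1 window means no lag smoothing: all-ones for h itself and
    all-zeros for its (identically zero) derivative.
    """
    if window.size == 1:
        return np.full(n, window[0])
    m = _signed_lags(n)
    half = (window.size - 1) // 2
    w = np.zeros(n)
    inside = np.abs(m) <= half
    w[inside] = window[m[inside] + half]
    return w


def _time_smooth(a: np.ndarray, g: np.ndarray) -> np.ndarray:
    if g.size == 1:
        return a * g[0]
    return fftconvolve(a, g[None, None, :], mode="same", axes=2)


def _spwvd_blocks(
    z_blocks: np.ndarray, spec: SmoothingSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (tf1, tf2, tf3): the SPWVD and its two reassignment companions.

    tf1 uses (g, h); tf2 substitutes tau_g for g (time centre of gravity);
    tf3 substitutes d_h for h (frequency centre of gravity).
    """
    n = z_blocks.shape[1]
    if spec.g.size >= n or spec.h.size > n:
        raise InvalidSpecError(
            f"smoothing windows (g={spec.g.size}, h={spec.h.size}) must be "
            f"shorter than the {n}-sample segment"
        )
    a = _lag_products(z_blocks)
    w_h = _lag_weights(spec.h, n)[None, :, None]
    w_dh = _lag_weights(spec.d_h if spec.h.size > 1 else np.zeros(1), n)[None, :, None]
    a_g = _time_smooth(a, spec.g)
    a_tg = _time_smooth(a, spec.tau_g)
    tf1 = np.fft.fft(w_h * a_g, axis=1)
    tf2 = np.fft.fft(w_h * a_tg, axis=1)
    tf3 = np.fft.fft(w_dh * a_g, axis=1)
    return tf1, tf2, tf3


def _real_plane(tf: np.ndarray) -> np.ndarray:
    scale = np.abs(tf.real).max()
    if scale > 0:
        residue = np.abs(tf.imag).max() / scale
        if residue > 1e-9:
            raise InvalidInputError(
                f"unexpected imaginary residue {residue:.2e} in time-frequency plane"
            )
    return tf.real


def _grids(n: int, fs: float, offset: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.arange(n) * fs / (2.0 * n)
    times = offset + np.arange(n) / fs
    return freqs, times


def compute_wvd(seg: SignalSegment) -> TimeFrequencyPlane:
    """Discrete Wigner-Ville distribution of the analytic signal."""
    z = analytic_signal(seg)
    tf1, _, _ = _spwvd_blocks(z[None, :], SmoothingSpec.unit())
    freqs, times = _grids(z.size, seg.fs)
    return TimeFrequencyPlane(_real_plane(tf1)[0], freqs, times)


def compute_spwvd(seg: SignalSegment, spec: SmoothingSpec) -> TimeFrequencyPlane:
    """Smoothed pseudo-WVD with separable time (g) and lag (h) windows."""
    z = analytic_signal(seg)
    tf1, _, _ = _spwvd_blocks(z[None, :], spec)
    freqs, times = _grids(z.size, seg.fs)
    return TimeFrequencyPlane(_real_plane(tf1)[0], freqs, times)


def _coordinates(
    tf1: np.ndarray, tf2: np.ndarray, tf3: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Centre-of-gravity coordinates (time bins, frequency bins) per block.

    Returns fractional bin indices; points below the epsilon guard keep
    their own coordinates.
    """
    _, n, _ = tf1.shape
    spw = tf1.real
    mag = np.abs(spw)
    floor = EPS_RELATIVE * mag.max(axis=(1, 2), keepdims=True)
    safe = mag >= np.maximum(floor, np.finfo(float).tiny)
    denom = np.where(safe, spw, 1.0)
    dn = np.where(safe, -(tf2.real / denom), 0.0)
    dk = np.where(safe, -(n / (2.0 * np.pi)) * (tf3.imag / denom), 0.0)
    k_idx = np.arange(n)[None, :, None]
    n_idx = np.arange(n)[None, None, :]
    return n_idx + dn, k_idx + dk


def reassignment_coordinates(
    seg: SignalSegment, spec: SmoothingSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Reassigned coordinates (t_hat seconds, f_hat Hz) on the SPWVD grid.

    Each point of the plane maps to the centre of gravity of the local
    energy distribution; where the SPWVD magnitude is below the epsilon
    guard the point maps to itself.
    """
    z = analytic_signal(seg)
    tf1, tf2, tf3 = _spwvd_blocks(z[None, :], spec)
    n_hat, k_hat = _coordinates(tf1, tf2, tf3)
    n = z.size
    return n_hat[0] / seg.fs, k_hat[0] * seg.fs / (2.0 * n)


def _reassign_blocks(
    tf1: np.ndarray, n_hat: np.ndarray, k_hat: np.ndarray
) -> np.ndarray:
    """Accumulate SPWVD values at the nearest reassigned bin (clamped)."""
    b, n, _ = tf1.shape
    spw = tf1.real
    ni = np.clip(np.rint(n_hat), 0, n - 1).astype(np.intp)
    ki = np.clip(np.rint(k_hat), 0, n - 1).astype(np.intp)
    out = np.zeros_like(spw)
    bi = np.broadcast_to(np.arange(b)[:, None, None], spw.shape)
    np.add.at(out, (bi, ki, ni), spw)
    return out


def compute_rspwvd(seg: SignalSegment, spec: SmoothingSpec) -> TimeFrequencyPlane:
    """Reassigned SPWVD: every value relocated to its centre of gravity.

    Total plane energy is conserved exactly (nearest-bin accumulation with
    boundary clamping).
    """
    z = analytic_signal(seg)
    tf1, tf2, tf3 = _spwvd_blocks(z[None, :], spec)
    n_hat, k_hat = _coordinates(tf1, tf2, tf3)
    _real_plane(tf1)  # validate imaginary residue
    out = _reassign_blocks(tf1, n_hat, k_hat)
    freqs, times = _grids(z.size, seg.fs)
    return TimeFrequencyPlane(out[0], freqs, times)


def blocked_rspwvd(
    seg: SignalSegment,
    spec: SmoothingSpec | None = None,
    block_s: float = 2.0,
    interval: float = 0.2,
) -> TimeFrequencyPlane:
    """RSPWVD of a long segment computed in non-overlapping aligned blocks.

    The quadratic cost of the WVD makes whole-segment evaluation of a 30 s
    recording impractical, so the segment is cut into blocks of ``block_s``
    seconds whose edges coincide with timestamp edges (``block_s`` must be
    a positive multiple of ``interval``), each block is reassigned
    independently, and the per-block planes are concatenated along time.
    ``spec=None`` uses :meth:`SmoothingSpec.default` for the block length.
    Trailing samples beyond the last whole block are dropped.
    """
    ratio = block_s / interval
    if block_s <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise InvalidSpecError(
            f"block length {block_s} s must be a positive multiple of the "
            f"{interval} s timestamp interval"
        )
    n_block = int(round(block_s * seg.fs))
    if abs(n_block - block_s * seg.fs) > 1e-6:
        raise InvalidSpecError(
            f"block length {block_s} s is not a whole number of samples at fs={seg.fs}"
        )
    n_blocks = seg.samples.size // n_block
    if n_blocks < 1:
        raise InvalidInputError(
            f"segment of {seg.duration:.3f} s is shorter than one {block_s} s block"
        )
    if spec is None:
        spec = SmoothingSpec.default(n_block)
    z = analytic_signal(seg)[: n_blocks * n_block]
    z_blocks = z.reshape(n_blocks, n_block)
    tf1, tf2, tf3 = _spwvd_blocks(z_blocks, spec)
    n_hat, k_hat = _coordinates(tf1, tf2, tf3)
    _real_plane(tf1)
    out = _reassign_blocks(tf1, n_hat, k_hat)
    values = np.concatenate(list(out), axis=1)
    freqs, times = _grids(n_block, seg.fs)
    times = np.arange(n_blocks * n_block) / seg.fs
    return TimeFrequencyPlane(values, freqs, times)


def export_plane(plane: TimeFrequencyPlane, path) -> None:
    """Write a plane as a gzipped delimited matrix with grid header lines."""
    import gzip

    with gzip.open(path, "wt") as fh:
        fh.write("freqs\t" + "\t".join(f"{f:.6g}" for f in plane.freqs) + "\n")
        fh.write("times\t" + "\t".join(f"{t:.6g}" for t in plane.times) + "\n")
        np.savetxt(fh, plane.values, delimiter="\t", fmt="%.9e")
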