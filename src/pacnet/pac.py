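"""Phase-amplitude coupling via the Kullback-Leibler modulation index.

The strength with which a slow oscillation's phase modulates a fast
oscillation's amplitude is quantified by (i) binning the slow phase into N
equal bins over [-pi, pi) (N = 18 by default, i.e. 20 degree bins), (ii)
averaging the fast envelope within each bin and normalising the bin means
to a probability vector p, and (iii) measuring how far p is from uniform:

    H(p)  = -sum_j p_j log p_j
    KL    = log N - H(p)
    MI    = KL / log N

MI is 0 for a uniform amplitude-by-phase distribution (no coupling) and 1
when all amplitude concentrates in a single phase bin. It is invariant to
the logarithm base and to any positive rescaling of the amplitude series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import Band, Recording
from .spectral import analytic_signal, bandpass_signal, edge_samples

__all__ = [
    "PhaseAmplitudeHistogram",
    "MiResult",
    "phase_amplitude_histogram",
    "modulation_index",
    "mi_from_series",
    "channel_mi",
    "surrogate_mi",
]


@dataclass
class PhaseAmplitudeHistogram:
    """Mean amplitude by phase bin, and its normalised distribution p."""

    n_bins: int
    bin_edges: np.ndarray  # N+1 edges spanning [-pi, pi]
    mean_amplitude: np.ndarray  # per-bin mean envelope, 0 for empty bins
    p: np.ndarray  # normalised mean amplitudes, sums to 1


@dataclass
class MiResult:
    mi: float
    entropy: float
    kl: float
    channel: str = ""
    phase_band: Band | None = None
    amp_band: Band | None = None


def phase_amplitude_histogram(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18
) -> PhaseAmplitudeHistogram:
    """Bin the amplitude series by the phase series.

    Bins are half-open [edge_i, edge_{i+1}) of equal width 2*pi/N; a phase
    of exactly +pi wraps into the last bin. Empty bins contribute zero mean
    amplitude.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude series must have equal length")
    finite = np.isfinite(phase) & np.isfinite(amplitude)
    if not finite.any():
        raise ValueError("no finite (phase, amplitude) samples")
    phase, amplitude = phase[finite], amplitude[finite]
    if np.any(amplitude < 0):
        raise ValueError("amplitude series must be non-negative")

    width = 2 * math.pi / n_bins
    idx = np.floor((phase + math.pi) / width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # phase == +pi lands in the last bin
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    mean_amp = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = mean_amp.sum()
    if total <= 0:
        raise ValueError("degenerate histogram: all mean amplitudes are zero")
    return PhaseAmplitudeHistogram(
        n_bins=n_bins,
        bin_edges=np.linspace(-math.pi, math.pi, n_bins + 1),
        mean_amplitude=mean_amp,
        p=mean_amp / total,
    )


def modulation_index(
    hist: PhaseAmplitudeHistogram, log_base: float = math.e
) -> MiResult:
    """Normalised KL divergence of p from uniform; 0*log 0 taken as 0.

    The result is independent of ``log_base`` (the base cancels in the
    ratio KL / log N); the parameter exists to make that checkable.
    """
    p = hist.p
    nz = p > 0
    log = np.log(p[nz]) / math.log(log_base)
    entropy = float(-(p[nz] * log).sum())
    log_n = math.log(hist.n_bins) / math.log(log_base)
    kl = log_n - entropy
    return MiResult(mi=kl / log_n, entropy=entropy, kl=kl)


def mi_from_series(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18
) -> MiResult:
    """Histogram + modulation index in one step."""
    return modulation_index(phase_amplitude_histogram(phase, amplitude, n_bins))


def channel_mi(
    rec: Recording,
    phase_band: Band,
    amp_band: Band,
    n_bins: int = 18,
    cycles: float = 4.0,
    min_cycles: float = 10.0,
) -> list[MiResult]:
    """Per-channel modulation index for one recording.

    Pipeline per channel: zero-phase band-pass at the phase band and the
    amplitude band, Hilbert phase of the former and envelope of the latter,
    edge-trimmed, histogrammed, and reduced to MI. Channel order is that of
    the recording.
    """
    if rec.duration_s < min_cycles / phase_band.f_lo:
        raise ValueError(
            f"recording too short: {rec.duration_s:.1f} s < "
            f"{min_cycles:g} cycles of {phase_band.name} f_lo "
            f"({min_cycles / phase_band.f_lo:.1f} s)"
        )
    slow = bandpass_signal(rec.data, rec.fs, phase_band, cycles)
    fast = bandpass_signal(rec.data, rec.fs, amp_band, cycles)
    trim = max(
        edge_samples(phase_band, rec.fs, rec.n_samples, cycles),
        edge_samples(amp_band, rec.fs, rec.n_samples, cycles),
    )
    sl = slice(trim, rec.n_samples - trim) if trim else slice(None)
    results = []
    for i, label in enumerate(rec.channels):
        ph = analytic_signal(slow[i], rec.fs, phase_band, label).phase[sl]
        am = analytic_signal(fast[i], rec.fs, amp_band, label).amplitude[sl]
        res = mi_from_series(ph, am, n_bins)
        res.channel = label
        res.phase_band = phase_band
        res.amp_band = amp_band
        results.append(res)
    return results


def surrogate_mi(
    phase: np.ndarray,
    amplitude: np.ndarray,
    rng: np.random.Generator,
    fs: float,
    n_bins: int = 18,
    min_shift_s: float = 1.0,
) -> MiResult:
    """MI after a random circular shift of the amplitude series.

    Shifting by at least ``min_shift_s`` destroys the phase-amplitude
    alignment while preserving both marginals, giving a no-coupling floor.
    """
    n = len(amplitude)
    lo = int(min_shift_s * fs)
    if lo >= n - lo:
        raise ValueError("series too short for the requested minimum shift")
    shift = int(rng.integers(lo, n - lo))
    return mi_from_series(phase, np.roll(amplitude, shift), n_bins)
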