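"""Phase-encoded retinotopy analysis.

A periodic stimulus (rotating wedge or expanding/contracting ring) sweeps
the visual field; the response phase at the stimulus frequency encodes a
voxel's preferred visual-field position. Runs with opposite sweep direction
carry the hemodynamic delay with the same sign but the stimulus phase with
opposite signs, so conjugating the reverse-run Fourier coefficient before
complex averaging cancels the delay and leaves the delay-free stimulus
phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PhaseMap:
    """Per-location phase (radians, (-pi, pi]), amplitude, and coherence."""

    phase: np.ndarray
    amplitude: np.ndarray
    coherence: np.ndarray


def _dct_basis(n: int, n_comp: int) -> np.ndarray:
    """Unit-norm DCT-II regressors (excluding the constant) plus the constant."""
    t = np.arange(n)
    basis = [np.ones(n) / np.sqrt(n)]
    for k in range(1, n_comp + 1):
        b = np.cos(np.pi * k * (2 * t + 1) / (2 * n))
        basis.append(b / np.linalg.norm(b))
    return np.stack(basis, axis=1)


def preprocess_timeseries(ts: np.ndarray, tr_s: float, period_s: float) -> np.ndarray:
    """Percent signal change, high-pass, and first-quarter-cycle discard.

    Each series (last axis = time) is divided by its temporal mean and
    scaled to percent; drifts below the cutoff 1/(3 x period) Hz are removed
    by regressing out a discrete-cosine basis (which also removes the mean);
    finally the first quarter stimulus cycle is dropped, which both skips
    onset transients and, for the usual n-and-a-quarter-cycle acquisitions,
    leaves an integer number of cycles on the clock.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    if period_s <= 0:
        raise ValueError("period must be positive")
    if n * tr_s <= 1.25 * period_s:
        raise ValueError("series must cover more than 1.25 stimulus cycles")
    mean = ts.mean(axis=-1, keepdims=True)
    if np.any(mean == 0):
        raise ValueError("zero temporal mean")
    psc = 100.0 * ts / mean

    cutoff_hz = 1.0 / (3.0 * period_s)
    # DCT component k spans frequency k / (2 n tr); drop those below cutoff
    n_comp = int(np.floor(cutoff_hz * 2 * n * tr_s))
    basis = _dct_basis(n, n_comp)
    coef = psc @ basis
    filtered = psc - coef @ basis.T

    drop = int(round(period_s / (4.0 * tr_s)))
    return filtered[..., drop:]


def fourier_coefficient(
    ts: np.ndarray, stimulus_freq_hz: float, tr_s: float, t_start_s: float = 0.0
) -> np.ndarray:
    """Complex DFT coefficient at the bin nearest the stimulus frequency.

    Amplitude follows the raw numpy convention: a unit cosine of N samples
    yields magnitude N/2; the phase of cos(2 pi f t + psi) is psi.

    ``t_start_s`` references the phase to the stimulus clock when the series
    does not start at stimulus time zero — e.g. after the first quarter
    cycle has been discarded, pass the duration of the discarded samples so
    that phases stay stimulus-locked (otherwise every run acquires a common
    but delay-confounding phase offset of 2 pi f t_start).
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    if stimulus_freq_hz > 0.5 / tr_s:
        raise ValueError("stimulus frequency beyond Nyquist")
    spec = np.fft.rfft(ts, axis=-1)
    k = int(round(stimulus_freq_hz * n * tr_s))
    coef = spec[..., k]
    if t_start_s:
        coef = coef * np.exp(-2j * np.pi * stimulus_freq_hz * t_start_s)
    return coef


def spectral_coherence(ts: np.ndarray, stimulus_freq_hz: float, tr_s: float) -> np.ndarray:
    """Amplitude at the stimulus frequency over total spectral amplitude."""
    spec = np.abs(np.fft.rfft(np.asarray(ts, dtype=float), axis=-1))
    n = ts.shape[-1]
    k = int(round(stimulus_freq_hz * n * tr_s))
    total = spec[..., 1:].sum(axis=-1)  # exclude DC
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, spec[..., k] / total, 0.0)


def combine_directions(coef_forward: np.ndarray, coef_reverse: np.ndarray) -> PhaseMap:
    """Average opposite-direction runs to cancel the hemodynamic delay.

    The reverse run's coefficient is conjugated (its stimulus phase runs
    with opposite sign while the delay keeps its sign), then complex-averaged
    with the forward run. The combined phase is the delay-free stimulus
    phase; the combined amplitude shrinks by cos(2 pi f delay).
    """
    cf = np.asarray(coef_forward)
    cr = np.asarray(coef_reverse)
    if cf.shape != cr.shape:
        raise ValueError("mismatched coefficient shapes")
    comb = 0.5 * (cf + np.conj(cr))
    amp_mean = 0.5 * (np.abs(cf) + np.abs(cr))
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(amp_mean > 0, np.abs(comb) / amp_mean, 0.0)
    return PhaseMap(
        phase=np.angle(comb),
        amplitude=np.abs(comb),
        coherence=np.clip(coherence, 0.0, 1.0),
    )


def foveal_exclusion_mask(
    eccentricity_phase: np.ndarray,
    cycle_fraction: float = 1.0 / 3.0,
    phase_origin: float = 0.0,
) -> np.ndarray:
    """Mask retaining locations outside the inner part of the phase cycle.

    The eccentricity phase increases from the foveal origin through one full
    cycle across the stimulated field; the returned mask is True where the
    wrapped phase distance from the origin is at least ``cycle_fraction`` of
    a full cycle, i.e. it excludes the innermost (foveal) band.
    """
    if not 0 < cycle_fraction < 1:
        raise ValueError("cycle_fraction must lie in (0, 1)")
    phase = np.asarray(eccentricity_phase, dtype=float)
    rel = (phase - phase_origin) % (2.0 * np.pi)
    return rel >= cycle_fraction * 2.0 * np.pi
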