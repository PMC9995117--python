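"""Quantitative relaxometry from multi-echo dual-flip-angle FLASH data.

The spoiled gradient-echo (FLASH) steady-state signal is

    S(alpha, TE) = A sin(alpha) (1 - E1) / (1 - cos(alpha) E1) exp(-TE R2*),
    E1 = exp(-TR R1),

with A proportional to proton density. Two multi-echo acquisitions with
proton-density weighting (small flip angle) and T1 weighting (large flip
angle) determine R2* through a joint log-linear fit with a shared decay
(ESTATICS), and R1 and A through the rational short-TR dual-flip-angle
approximation of the Ernst equation applied to the TE=0 intercepts, with
apparent flip angles corrected by a B1+ efficiency map. PD maps are
calibrated so their white-matter mean equals 69 percent units, and the
macromolecular tissue volume fraction is MTVF = 100% - PD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_TE = tuple(np.linspace(0.0028, 0.0161, 6))
PD_WM_CALIBRATION = 69.0  # percent units


@dataclass
class FlashProtocol:
    """Acquisition parameters of the dual-contrast multi-echo FLASH protocol.

    Defaults follow a 0.5 mm multi-parameter-mapping protocol: TR = 25 ms for
    both contrasts, six equidistant echoes 2.8-16.1 ms, nominal flip angles
    5 deg (PDw) and 24 deg (T1w). Angles are stored in radians; the contrast
    order is (PDw, T1w) throughout.
    """

    tr_s: tuple[float, float] = (0.025, 0.025)
    te_s: tuple[float, ...] = DEFAULT_TE
    nominal_fa_rad: tuple[float, float] = (np.deg2rad(5.0), np.deg2rad(24.0))
    labels: tuple[str, str] = ("PDw", "T1w")

    def __post_init__(self) -> None:
        te = np.asarray(self.te_s)
        if te.ndim != 1 or len(te) < 1 or np.any(np.diff(te) <= 0):
            raise ValueError("te_s must be strictly increasing")
        for fa in self.nominal_fa_rad:
            if not 0 < fa < np.pi / 2:
                raise ValueError("flip angles must lie in (0, pi/2)")
        for tr in self.tr_s:
            if tr <= te[-1]:
                raise ValueError("TR must exceed the longest echo time")

    @property
    def n_echoes(self) -> int:
        return len(self.te_s)


@dataclass
class MultiEchoSignals:
    """Observed or simulated FLASH magnitudes, indexed [contrast, echo, location]."""

    signal: np.ndarray
    protocol: FlashProtocol
    b1_efficiency: np.ndarray | None = None  # achieved/nominal flip angle, per location

    def __post_init__(self) -> None:
        if self.signal.ndim != 3 or self.signal.shape[0] != 2:
            raise ValueError("signal must have shape (2, n_echoes, n_locations)")
        if self.signal.shape[1] != self.protocol.n_echoes:
            raise ValueError("echo dimension does not match protocol")
        if self.b1_efficiency is not None and np.any(self.b1_efficiency <= 0):
            raise ValueError("b1_efficiency must be positive")


@dataclass
class QMRIMaps:
    """Quantitative parameter maps per location.

    r1 and r2s in 1/s, pd and mtvf in percent units; ``amplitude_a`` is the
    PD-proportional TE=0 signal amplitude before calibration. ``valid`` flags
    locations where all fits succeeded.
    """

    r1: np.ndarray
    r2s: np.ndarray
    pd: np.ndarray | None = None
    mtvf: np.ndarray | None = None
    amplitude_a: np.ndarray | None = None
    valid: np.ndarray | None = field(default=None)

    @property
    def n_invalid(self) -> int:
        return 0 if self.valid is None else int((~self.valid).sum())


def flash_signal(amplitude_a, r1, r2s, fa_rad, tr_s, te_s):
    """Exact spoiled FLASH steady-state signal (Ernst equation with T2* decay)."""
    amplitude_a, r1, r2s = np.asarray(amplitude_a), np.asarray(r1), np.asarray(r2s)
    e1 = np.exp(-tr_s * r1)
    return (
        amplitude_a
        * np.sin(fa_rad)
        * (1.0 - e1)
        / (1.0 - np.cos(fa_rad) * e1)
        * np.exp(-te_s * r2s)
    )


def estatics_fit(signals: MultiEchoSignals | np.ndarray, protocol: FlashProtocol | None = None):
    """Joint log-linear R2* fit with a shared decay across contrasts.

    Ordinary least squares of log signal on [PDw intercept, T1w intercept,
    -TE] over all echoes of both contrasts, per location. Returns
    ``(r2s, intercepts, valid)`` with ``intercepts`` of shape
    (2, n_locations) holding the TE=0 extrapolations of each contrast.
    Locations with any non-positive or non-finite signal are flagged invalid
    (NaN outputs) rather than raised.
    """
    if isinstance(signals, MultiEchoSignals):
        protocol = signals.protocol
        sig = signals.signal
    else:
        if protocol is None:
            raise ValueError("protocol required when passing a bare array")
        sig = np.asarray(signals)
    n_e = protocol.n_echoes
    te = np.asarray(protocol.te_s)
    # design: rows ordered (contrast, echo)
    x = np.zeros((2 * n_e, 3))
    x[:n_e, 0] = 1.0
    x[n_e:, 1] = 1.0
    x[:n_e, 2] = -te
    x[n_e:, 2] = -te
    pinv = np.linalg.pinv(x)

    flat = sig.reshape(2 * n_e, -1)
    valid = np.all(np.isfinite(flat) & (flat > 0), axis=0)
    logs = np.full_like(flat, np.nan, dtype=float)
    logs[:, valid] = np.log(flat[:, valid])
    beta = pinv @ np.where(np.isfinite(logs), logs, 0.0)
    beta[:, ~valid] = np.nan
    intercepts = np.exp(beta[:2])
    r2s = beta[2]
    return r2s, intercepts, valid


def dfa_fit(
    intercepts: np.ndarray,
    protocol: FlashProtocol,
    b1_efficiency: np.ndarray | float | None = None,
):
    """Rational dual-flip-angle estimation of R1 and amplitude A.

    Uses the short-TR small-angle approximation of the Ernst equation on the
    TE=0 intercepts S_PD, S_T1 of the two contrasts:

        R1 = (S_T1 a_T1 / TR_T1 - S_PD a_PD / TR_PD)
             / (2 (S_PD / a_PD - S_T1 / a_T1))
        A  = S_PD S_T1 (TR_T1 a_PD / a_T1 - TR_PD a_T1 / a_PD)
             / (S_PD TR_T1 a_PD - S_T1 TR_PD a_T1)

    where the a are the achieved flip angles, i.e. B1+ efficiency times the
    nominal angles. Locations with a non-positive denominator (non-physical
    signal ordering) are flagged invalid, not raised. Returns
    ``(r1, amplitude_a, valid)``.
    """
    s_pd, s_t1 = np.asarray(intercepts[0], dtype=float), np.asarray(intercepts[1], dtype=float)
    ft = 1.0 if b1_efficiency is None else np.asarray(b1_efficiency, dtype=float)
    a_pd = ft * protocol.nominal_fa_rad[0]
    a_t1 = ft * protocol.nominal_fa_rad[1]
    tr_pd, tr_t1 = protocol.tr_s

    with np.errstate(divide="ignore", invalid="ignore"):
        den_r1 = s_pd / a_pd - s_t1 / a_t1
        r1 = (s_t1 * a_t1 / tr_t1 - s_pd * a_pd / tr_pd) / (2.0 * den_r1)
        den_a = s_pd * tr_t1 * a_pd - s_t1 * tr_pd * a_t1
        a = s_pd * s_t1 * (tr_t1 * a_pd / a_t1 - tr_pd * a_t1 / a_pd) / den_a
    valid = (
        np.isfinite(s_pd)
        & np.isfinite(s_t1)
        & (den_r1 > 0)
        & np.isfinite(r1)
        & (r1 > 0)
    )
    r1 = np.where(valid, r1, np.nan)
    a = np.where(valid, a, np.nan)
    return r1, a, valid


def calibrate_pd(
    amplitude_a: np.ndarray,
    wm_mask: np.ndarray,
    calibration_constant: float = PD_WM_CALIBRATION,
) -> np.ndarray:
    """Scale the amplitude map so its white-matter mean equals the constant (pu)."""
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")
    m = np.nanmean(np.asarray(amplitude_a, dtype=float)[wm_mask])
    if not np.isfinite(m) or m <= 0:
        raise ValueError("mean amplitude over the white-matter mask must be positive")
    return np.asarray(amplitude_a, dtype=float) * (calibration_constant / m)


def mtvf(pd: np.ndarray) -> np.ndarray:
    """Macromolecular tissue volume fraction, 100% minus proton density."""
    return 100.0 - np.asarray(pd, dtype=float)


def fit_qmri(
    signals: MultiEchoSignals,
    wm_mask: np.ndarray | None = None,
    calibration_constant: float = PD_WM_CALIBRATION,
) -> QMRIMaps:
    """Full relaxometry chain: ESTATICS, dual-flip-angle R1/A, PD calibration."""
    r2s, intercepts, valid_e = estatics_fit(signals)
    r1, amp, valid_d = dfa_fit(intercepts, signals.protocol, signals.b1_efficiency)
    valid = valid_e & valid_d
    pd = mt = None
    if wm_mask is not None:
        pd = calibrate_pd(amp, wm_mask, calibration_constant)
        mt = mtvf(pd)
    return QMRIMaps(r1=r1, r2s=r2s, pd=pd, mtvf=mt, amplitude_a=amp, valid=valid)
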