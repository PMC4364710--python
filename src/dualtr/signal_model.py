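"""Steady-state signal model for spoiled gradient echo with two alternating TRs.

A turbo-FLASH readout in which a saturation block precedes every second
excitation experiences two alternating effective repetition times.  With
perfect spoiling the longitudinal magnetization settles into a two-pulse
steady state: the excitation that follows the *longer* recovery interval
produces the stronger signal, the one following the shorter interval the
weaker.  This module provides

* :func:`steady_state_signals` — the closed-form dual-TR signal pair for a
  single flip angle,
* :func:`steady_state_signals_general` — its generalization to two distinct
  flip angles (one per excitation), used by the flip-angle adaptation,
* :func:`bloch_steady_state` — an independent fixed-point iteration of the
  two-pulse Bloch recursion, used as a numerical oracle,
* :func:`ernst_signal` — the classic single-TR spoiled-GRE (Ernst) signal,
* :func:`afi_flip_angle` — the actual-flip-angle-imaging (AFI) inversion that
  recovers the flip angle from the two steady-state signals.

All interfaces take and return flip angles in **degrees**; radians appear
only internally.  Signal amplitudes are real non-negative magnitudes in
units of the equilibrium magnetization ``m0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "SequenceParams",
    "SignalPair",
    "steady_state_signals",
    "steady_state_signals_general",
    "bloch_steady_state",
    "ernst_signal",
    "afi_flip_angle",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class SequenceParams:
    """Timing and relaxation constants shared by every signal computation.

    Parameters
    ----------
    tr1_ms, tr2_ms
        The two alternating effective repetition times in milliseconds.
        ``tr1_ms`` is the short interval (no saturation block), ``tr2_ms``
        the long one, although the model is symmetric under exchange.
    te_ms
        Echo time in milliseconds; must be shorter than both TRs.
    t1_ms
        Longitudinal relaxation time in milliseconds.
    t2star_ms
        Effective transverse relaxation time in milliseconds; weights every
        signal by ``exp(-TE/T2*)``.
    m0
        Equilibrium magnetization in arbitrary units.  All artifact metrics
        are ratios, so ``m0`` cancels; the default of 1 is therefore
        universal.
    """

    tr1_ms: float
    tr2_ms: float
    te_ms: float
    t1_ms: float
    t2star_ms: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tr1_ms", "tr2_ms", "te_ms", "t1_ms", "t2star_ms", "m0"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")
        if self.te_ms >= min(self.tr1_ms, self.tr2_ms):
            raise ValueError(
                f"te_ms ({self.te_ms}) must be shorter than both repetition times "
                f"(min TR = {min(self.tr1_ms, self.tr2_ms)})"
            )

    @property
    def te_decay(self) -> float:
        """The ``exp(-TE/T2*)`` echo-time attenuation factor."""
        return float(np.exp(-self.te_ms / self.t2star_ms))


@dataclass(frozen=True)
class SignalPair:
    """The two steady-state signal amplitudes of the alternating acquisition.

    ``s_strong`` is the signal of the excitation that follows the recovery
    interval ``tr2_ms``; when ``tr2_ms >= tr1_ms`` (the usual situation with
    the saturation block shortening every other interval) this is the larger
    of the two.  ``s_weak`` follows ``tr1_ms``.  When the two TRs are equal
    the pair is degenerate and both fields carry the same value.
    """

    s_strong: ArrayLike
    s_weak: ArrayLike


def _validate_angle(theta_deg: ArrayLike, name: str, upper: float = 180.0) -> np.ndarray:
    theta = np.asarray(theta_deg, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError(f"{name} must be finite, got {theta_deg!r}")
    if np.any(theta < 0) or np.any(theta > upper):
        raise ValueError(f"{name} must lie in [0, {upper}] degrees, got values outside that range")
    return theta


def _dual_tr_signals(cos1: ArrayLike, cos2: ArrayLike, sin1: ArrayLike,
                     sin2: ArrayLike, p: SequenceParams) -> tuple[np.ndarray, np.ndarray]:
    """Core dual-TR steady state.

    Pulse 1 (angle with cos1/sin1) follows the recovery interval ``tr2_ms``;
    pulse 2 follows ``tr1_ms``.  Returns (signal at pulse 1, signal at pulse 2).
    """
    e1 = np.exp(-p.tr1_ms / p.t1_ms)
    e2 = np.exp(-p.tr2_ms / p.t1_ms)
    denom = 1.0 - cos1 * cos2 * e1 * e2
    s1 = p.m0 * (1.0 + e2 * ((1.0 - e1) * cos2 - 1.0)) / denom * p.te_decay * sin1
    s2 = p.m0 * (1.0 + e1 * ((1.0 - e2) * cos1 - 1.0)) / denom * p.te_decay * sin2
    return np.asarray(s1), np.asarray(s2)


def _as_pair(s1: np.ndarray, s2: np.ndarray, p: SequenceParams) -> SignalPair:
    # Strong/weak is decided by the recovery interval, not by magnitude:
    # the pulse after the longer interval is labelled strong.
    if p.tr2_ms >= p.tr1_ms:
        strong, weak = s1, s2
    else:
        strong, weak = s2, s1
    if strong.ndim == 0:
        return SignalPair(float(strong), float(weak))
    return SignalPair(strong, weak)


def steady_state_signals(theta_deg: ArrayLike, p: SequenceParams) -> SignalPair:
    """Dual-TR steady-state signal pair for a single flip angle.

    Evaluates the closed-form solution of the two-pulse recursion

    .. math::

        S_1 = M_0\\,\\frac{1 + e^{-TR_2/T_1}\\bigl((1 - e^{-TR_1/T_1})\\cos\\theta - 1\\bigr)}
                         {1 - \\cos^2\\theta\\, e^{-(TR_1+TR_2)/T_1}}
              \\; e^{-TE/T_2^*} \\sin\\theta,

    with :math:`S_2` obtained by exchanging :math:`TR_1` and :math:`TR_2`
    in the numerator.  Accepts scalars or arrays (broadcast elementwise).

    Angles above 90° are accepted (up to 180°) but lie outside the regime the
    artifact analysis targets.
    """
    theta = _validate_angle(theta_deg, "theta_deg")
    rad = np.deg2rad(theta)
    c, s = np.cos(rad), np.sin(rad)
    s1, s2 = _dual_tr_signals(c, c, s, s, p)
    return _as_pair(s1, s2, p)


def steady_state_signals_general(theta1_deg: ArrayLike, theta2_deg: ArrayLike,
                                 p: SequenceParams) -> SignalPair:
    """Dual-TR steady state with a distinct flip angle per excitation.

    ``theta1_deg`` is the flip of the pulse following the long recovery
    interval ``tr2_ms`` (its signal is ``s_strong`` when ``tr2 >= tr1``);
    ``theta2_deg`` flips the pulse following ``tr1_ms``.  With equal angles
    this reduces exactly to :func:`steady_state_signals`.
    """
    t1 = _validate_angle(theta1_deg, "theta1_deg")
    t2 = _validate_angle(theta2_deg, "theta2_deg")
    r1, r2 = np.deg2rad(t1), np.deg2rad(t2)
    s1, s2 = _dual_tr_signals(np.cos(r1), np.cos(r2), np.sin(r1), np.sin(r2), p)
    return _as_pair(s1, s2, p)


def bloch_steady_state(theta1_deg: float, theta2_deg: float, p: SequenceParams,
                       tol: float = 1e-13, max_cycles: int = 100_000) -> SignalPair:
    """Numerically iterate the two-pulse cycle to its fixed point.

    Independent oracle for the closed forms: assumes perfect spoiling, so
    after an excitation by angle alpha the longitudinal magnetization is
    multiplied by cos(alpha) and then relaxes toward ``m0`` as
    ``Mz -> m0 + (Mz - m0) * exp(-TR/T1)`` over the following interval.
    Iteration stops when one full cycle changes both signals by less than
    ``tol`` in relative terms.

    Raises
    ------
    RuntimeError
        If the fixed point is not reached within ``max_cycles`` cycles.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    th1 = float(_validate_angle(theta1_deg, "theta1_deg"))
    th2 = float(_validate_angle(theta2_deg, "theta2_deg"))
    c1, s1 = np.cos(np.deg2rad(th1)), np.sin(np.deg2rad(th1))
    c2, s2 = np.cos(np.deg2rad(th2)), np.sin(np.deg2rad(th2))
    e1 = np.exp(-p.tr1_ms / p.t1_ms)
    e2 = np.exp(-p.tr2_ms / p.t1_ms)

    mz_before_2 = p.m0  # longitudinal magnetization just before pulse 2
    prev = (np.inf, np.inf)
    scale = p.te_decay
    for _ in range(max_cycles):
        # pulse 2 (after the short interval tr1), then relax over tr2
        sig2 = mz_before_2 * s2 * scale
        mz = p.m0 + (mz_before_2 * c2 - p.m0) * e2
        # pulse 1 (after the long interval tr2), then relax over tr1
        sig1 = mz * s1 * scale
        mz_before_2 = p.m0 + (mz * c1 - p.m0) * e1
        ref = max(abs(sig1), abs(sig2), p.m0 * 1e-300)
        if abs(sig1 - prev[0]) <= tol * ref and abs(sig2 - prev[1]) <= tol * ref:
            return _as_pair(np.asarray(sig1), np.asarray(sig2), p)
        prev = (sig1, sig2)
    raise RuntimeError(
        f"two-pulse Bloch iteration did not converge within {max_cycles} cycles (tol={tol})"
    )


def ernst_signal(theta_deg: ArrayLike, tr_ms: float, p: SequenceParams) -> ArrayLike:
    """Single-TR spoiled-GRE steady-state (Ernst) signal.

    ``m0 * (1 - E) * sin(theta) / (1 - E*cos(theta)) * exp(-TE/T2*)`` with
    ``E = exp(-tr_ms/t1_ms)``.  The dual-TR pair collapses to this limit
    when both repetition times equal ``tr_ms``.
    """
    if tr_ms <= 0:
        raise ValueError(f"tr_ms must be positive, got {tr_ms}")
    theta = _validate_angle(theta_deg, "theta_deg")
    rad = np.deg2rad(theta)
    e = np.exp(-tr_ms / p.t1_ms)
    out = p.m0 * (1.0 - e) * np.sin(rad) / (1.0 - e * np.cos(rad)) * p.te_decay
    return float(out) if out.ndim == 0 else out


def afi_flip_angle(s_strong: ArrayLike, s_weak: ArrayLike,
                   tr1_ms: float, tr2_ms: float) -> ArrayLike:
    """Recover the flip angle from the dual-TR signal pair (AFI inversion).

    Uses the short-TR approximation of actual flip angle imaging: with
    ``r = s_weak / s_strong`` and ``n = tr2_ms / tr1_ms``,

    .. math:: \\theta = \\arccos\\frac{r\\,n - 1}{n - r}.

    The argument is clamped to [-1, 1] so that noise-free boundary cases
    (``r`` exactly 1 or 0) remain valid.  Accurate to well under half a
    degree for the short TRs (TR << T1) the sequence uses.
    """
    if tr2_ms <= tr1_ms:
        raise ValueError(f"afi_flip_angle requires tr2_ms > tr1_ms, got {tr1_ms} and {tr2_ms}")
    strong = np.asarray(s_strong, dtype=float)
    weak = np.asarray(s_weak, dtype=float)
    if np.any(strong <= 0):
        raise ValueError("s_strong must be strictly positive")
    r = weak / strong
    if np.any(r > 1.0 + 1e-12):
        raise ValueError("s_weak must not exceed s_strong (signal ratio r <= 1 required)")
    n = tr2_ms / tr1_ms
    arg = np.clip((r * n - 1.0) / (n - r), -1.0, 1.0)
    out = np.rad2deg(np.arccos(arg))
    return float(out) if out.ndim == 0 else out
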