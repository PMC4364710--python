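"""Flip-angle adaptation: equalize the two alternating steady-state signals.

The ghost exists because the two excitations produce different signals.  One
countermeasure is to lower the flip angle of the pulse that follows the long
recovery interval until both signals match: solve S1(theta1, theta2) =
S2(theta1, theta2) for theta1 at fixed theta2.  Applied on a scanner this is
a transmit-voltage change, i.e. a single multiplicative scale on the whole
flip-angle map — so the condition can only be met exactly at one nominal
angle, and the artifact is nulled there but not elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .phantom import FlipMap, ImagePair, simulate_image_pair
from .signal_model import SequenceParams, steady_state_signals_general

__all__ = ["AdaptationResult", "solve_adapted_flip", "adapted_image_pair"]


@dataclass(frozen=True)
class AdaptationResult:
    """Solution of the signal-matching condition at one nominal angle.

    ``scale = theta1_deg / theta2_nominal_deg`` is the multiplicative factor
    a transmit-voltage change would apply; it lies in (0, 1] when TR2 > TR1
    (the long-interval pulse must be weakened).  ``residual`` is
    ``|S1 - S2|`` at the solution.  ``bracketed`` is False when no sign
    change existed and the boundary minimizer was returned instead.
    """

    theta2_nominal_deg: float
    theta1_deg: float
    scale: float
    residual: float
    bracketed: bool = True


def _signal_gap(theta1: float, theta2: float, p: SequenceParams) -> float:
    pair = steady_state_signals_general(theta1, theta2, p)
    return pair.s_strong - pair.s_weak


def solve_adapted_flip(theta2_deg: float, p: SequenceParams,
                       tol: float = 1e-12) -> AdaptationResult:
    """Solve S1 = S2 for theta1 in (0, theta2] at fixed theta2.

    At equal angles the long-recovery signal dominates (S1 >= S2) while for
    theta1 -> 0 its sine factor kills S1, so the gap S1 - S2 changes sign
    inside (0, theta2] whenever the TRs differ; Brent root finding refines
    the bracket to ``tol`` degrees.  With equal TRs the gap is identically
    zero and theta1 = theta2 is returned exactly.
    """
    if not 0 < theta2_deg <= 90:
        raise ValueError(f"theta2_deg must lie in (0, 90], got {theta2_deg}")
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if p.tr1_ms == p.tr2_ms:
        return AdaptationResult(theta2_deg, theta2_deg, 1.0, 0.0)

    lo = 1e-9
    gap_lo = _signal_gap(lo, theta2_deg, p)
    gap_hi = _signal_gap(theta2_deg, theta2_deg, p)
    if gap_lo * gap_hi > 0:
        # No sign change: fall back to the boundary with the smaller |gap|.
        theta1 = theta2_deg if abs(gap_hi) <= abs(gap_lo) else lo
        return AdaptationResult(theta2_deg, theta1, theta1 / theta2_deg,
                                abs(_signal_gap(theta1, theta2_deg, p)), bracketed=False)
    theta1 = float(brentq(_signal_gap, lo, theta2_deg, args=(theta2_deg, p),
                          xtol=tol, rtol=8.9e-16))
    residual = abs(_signal_gap(theta1, theta2_deg, p))
    return AdaptationResult(theta2_deg, theta1, theta1 / theta2_deg, residual)


def adapted_image_pair(fm: FlipMap, theta2_nominal_deg: float,
                       p: SequenceParams) -> ImagePair:
    """Simulate the image pair with the adaptation solved at one nominal angle.

    The scale ``theta1(theta2_nominal) / theta2_nominal`` is computed once
    and applied multiplicatively to the whole map — modelling a transmit
    voltage change rather than a per-pixel adjustment.  Consequently the two
    images agree only where the local flip angle equals the nominal one.
    """
    result = solve_adapted_flip(theta2_nominal_deg, p)
    return simulate_image_pair(fm, p, theta1_scale=result.scale)
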