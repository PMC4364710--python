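"""Synthetic flip-angle phantoms and the simulated dual-TR image pair.

The artifact study runs entirely on synthetic input: a circular phantom whose
excitation flip angle varies linearly across the disc (1°–90° inside, 0°
outside), standing in for the strongly inhomogeneous transmit field at 7 T.
From such a map the two pixelwise steady-state signal images — one per
effective TR — are computed; every downstream k-space experiment consumes
that pair.

The pipeline is fully deterministic: identical arguments produce bit-identical
maps and images, with no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import SequenceParams, steady_state_signals_general

__all__ = [
    "FlipMap",
    "ImagePair",
    "make_gradient_flip_map",
    "make_uniform_flip_map",
    "simulate_image_pair",
    "save_flip_map",
    "load_flip_map",
]


@dataclass(frozen=True)
class FlipMap:
    """A 2-D flip-angle field (degrees) with compact circular support.

    Rows are the phase-encode direction, columns the readout direction.
    ``grid`` holds the flip angle in degrees; ``mask`` is True exactly where
    the flip angle is positive (inside the disc).  ``radius_px`` is the disc
    radius in pixels; it must stay below ``n/4`` so that the half-FOV ghost
    replica never overlaps the phantom itself.
    """

    grid: np.ndarray
    mask: np.ndarray
    n: int
    radius_px: float
    gradient_axis: str
    theta_min_deg: float
    theta_max_deg: float


@dataclass(frozen=True)
class ImagePair:
    """The two pixelwise steady-state signal images.

    ``img_strong`` holds the signal of the excitation following the long
    recovery interval, ``img_weak`` the other.  ``theta1_scale`` records any
    multiplicative flip-angle scaling applied to the strong excitation (the
    flip-angle-adaptation mechanism); 1 means the plain equal-angle pair.
    """

    img_strong: np.ndarray
    img_weak: np.ndarray
    params: SequenceParams
    theta1_scale: float = 1.0


def _disc_geometry(n: int, radius_frac: float) -> tuple[np.ndarray, float, float]:
    if n % 4 != 0:
        raise ValueError(f"grid size n must be divisible by 4, got {n}")
    if not 0 < radius_frac < 0.25:
        raise ValueError(
            f"radius_frac must lie in (0, 0.25) so the half-FOV ghost clears the phantom, "
            f"got {radius_frac}"
        )
    radius = radius_frac * n
    center = n / 2.0
    yy, xx = np.indices((n, n), dtype=float)
    mask = (yy - center) ** 2 + (xx - center) ** 2 <= radius**2
    return mask, radius, center


def make_gradient_flip_map(n: int = 256, radius_frac: float = 0.22,
                           theta_min_deg: float = 1.0, theta_max_deg: float = 90.0,
                           gradient_axis: str = "readout") -> FlipMap:
    """Circular phantom with a linear flip-angle gradient across the disc.

    Inside the centered disc of radius ``radius_frac * n`` the flip angle
    varies linearly along ``gradient_axis`` from ``theta_min_deg`` at one
    edge of the disc to ``theta_max_deg`` at the other; it is exactly zero
    outside.  With the default readout-axis gradient every readout column
    sees a single flip angle, so metric curves bin cleanly by column.
    """
    if theta_min_deg >= theta_max_deg:
        raise ValueError(
            f"theta_min_deg ({theta_min_deg}) must be below theta_max_deg ({theta_max_deg})"
        )
    if gradient_axis not in ("readout", "phase_encode"):
        raise ValueError(f"gradient_axis must be 'readout' or 'phase_encode', got {gradient_axis!r}")
    mask, radius, center = _disc_geometry(n, radius_frac)
    yy, xx = np.indices((n, n), dtype=float)
    coord = xx if gradient_axis == "readout" else yy
    frac = np.clip((coord - (center - radius)) / (2.0 * radius), 0.0, 1.0)
    grid = np.where(mask, theta_min_deg + frac * (theta_max_deg - theta_min_deg), 0.0)
    return FlipMap(grid=grid, mask=mask, n=n, radius_px=radius,
                   gradient_axis=gradient_axis, theta_min_deg=theta_min_deg,
                   theta_max_deg=theta_max_deg)


def make_uniform_flip_map(n: int = 256, radius_frac: float = 0.22,
                          theta_deg: float = 45.0) -> FlipMap:
    """Circular phantom with a spatially constant flip angle inside the disc."""
    if theta_deg <= 0:
        raise ValueError(f"theta_deg must be positive (empty phantom otherwise), got {theta_deg}")
    mask, radius, _ = _disc_geometry(n, radius_frac)
    grid = np.where(mask, float(theta_deg), 0.0)
    return FlipMap(grid=grid, mask=mask, n=n, radius_px=radius,
                   gradient_axis="readout", theta_min_deg=theta_deg, theta_max_deg=theta_deg)


def simulate_image_pair(fm: FlipMap, p: SequenceParams,
                        theta1_scale: float = 1.0) -> ImagePair:
    """Compute the two steady-state signal images pixelwise from a flip map.

    The excitation after the short interval uses the map itself
    (``theta2 = fm.grid``); the excitation after the long interval uses
    ``theta1 = theta1_scale * fm.grid``.  A scale of 1 reproduces the plain
    equal-angle pair; other values model a transmit-voltage change for every
    second pulse, which scales the whole map multiplicatively.
    """
    if not 0 < theta1_scale <= 2:
        raise ValueError(f"theta1_scale must lie in (0, 2], got {theta1_scale}")
    theta2 = fm.grid
    theta1 = theta1_scale * theta2
    if np.max(theta1) > 180.0:
        raise ValueError(
            f"scaled flip angle reaches {np.max(theta1):.1f} degrees, beyond the 180 degree limit"
        )
    pair = steady_state_signals_general(theta1, theta2, p)
    strong = np.where(fm.mask, pair.s_strong, 0.0)
    weak = np.where(fm.mask, pair.s_weak, 0.0)
    return ImagePair(img_strong=strong, img_weak=weak, params=p, theta1_scale=theta1_scale)


def save_flip_map(fm: FlipMap, path) -> None:
    """Write a flip map as a plain-text grid (one row per line, degrees)."""
    np.savetxt(path, fm.grid, fmt="%.10g")


def load_flip_map(path, gradient_axis: str = "readout") -> FlipMap:
    """Read a plain-text flip-angle grid written by :func:`save_flip_map`.

    The support mask is recovered as the positive entries; the nominal
    radius is inferred from the mask area (``sqrt(area/pi)``), which is exact
    for discs and a reasonable summary for user-supplied shapes.
    """
    grid = np.atleast_2d(np.loadtxt(path, dtype=float))
    if grid.shape[0] != grid.shape[1]:
        raise ValueError(f"flip map must be square, got shape {grid.shape}")
    if np.any(grid < 0) or np.any(grid > 180):
        raise ValueError("flip map values must lie in [0, 180] degrees")
    n = grid.shape[0]
    if n % 4 != 0:
        raise ValueError(f"flip map size must be divisible by 4, got {n}")
    mask = grid > 0
    if not mask.any():
        raise ValueError("flip map has empty support (all zeros)")
    radius = float(np.sqrt(mask.sum() / np.pi))
    inside = grid[mask]
    return FlipMap(grid=grid, mask=mask, n=n, radius_px=radius,
                   gradient_axis=gradient_axis,
                   theta_min_deg=float(inside.min()), theta_max_deg=float(inside.max()))
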