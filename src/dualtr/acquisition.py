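"""k-space assembly: Fourier transforms, line interleaving, reordering,
zero filling, and the center-line correction factor.

Each excitation acquires one phase-encode line, so a sequence alternating
between two steady-state signals fills even and odd lines from two different
images.  The functions here build the combined k-space for every scheme the
artifact study compares:

* ``interleave`` — the as-acquired situation: even lines from the strong
  image, odd lines from the weak one; the period-2 modulation aliases into a
  half-FOV ghost.
* ``reorder`` — weak lines pushed to the outer halves of k-space (a low-pass
  placement), strong lines holding the contrast-determining center;
  ``reorder_inverted`` swaps the roles.
* ``zero_fill`` — outer half simply zeroed, the classic truncation (Gibbs)
  reference case.
* center-line correction — weak lines rescaled by the inverse of the
  weak/strong DC-row ratio.

Conventions: rows are phase encode with ``ky = row - n//2`` (DC at row
``n//2``), columns are readout; transforms are centered and unitary, so
Parseval holds exactly and magnitude metrics are convention-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "KSpaceGrid",
    "AssemblyResult",
    "forward_kspace",
    "reconstruct",
    "assemble_interleaved",
    "assemble_reordered",
    "assemble_zero_filled",
    "assemble_single",
    "estimate_correction_factor",
    "apply_correction",
    "acquisition_order",
]


@dataclass(frozen=True)
class KSpaceGrid:
    """A centered n-by-n complex k-space grid (unitary transform convention)."""

    data: np.ndarray

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def row_of_ky(self, ky: int) -> int:
        """Row index of phase-encode line ``ky`` (DC ky=0 sits at row n//2)."""
        return ky + self.n // 2

    def ky_of_row(self, row: int) -> int:
        return row - self.n // 2


@dataclass(frozen=True)
class AssemblyResult:
    """A combined k-space plus the per-line provenance record.

    ``weak_lines[row]`` is True where that phase-encode row was taken from
    the weak-signal k-space.  ``correction_applied`` holds the scalar factor
    whose inverse was multiplied onto the weak lines, or None.
    """

    kspace: KSpaceGrid
    weak_lines: np.ndarray
    scheme: str
    correction_applied: Optional[float] = None

    def provenance(self) -> dict:
        """JSON-serializable record of how this k-space was assembled."""
        n = self.kspace.n
        return {
            "scheme": self.scheme,
            "n": n,
            "weak_ky": [int(r - n // 2) for r in np.flatnonzero(self.weak_lines)],
            "correction_applied": self.correction_applied,
        }


def _check_square(arr: np.ndarray) -> int:
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"expected a square 2-D grid, got shape {arr.shape}")
    n = arr.shape[0]
    if n % 4 != 0:
        raise ValueError(f"grid size must be divisible by 4, got {n}")
    return n


def forward_kspace(image: np.ndarray) -> KSpaceGrid:
    """Centered unitary 2-D Fourier transform of an image."""
    image = np.asarray(image)
    _check_square(image)
    data = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image), norm="ortho"))
    return KSpaceGrid(data=data)


def reconstruct(k: KSpaceGrid) -> np.ndarray:
    """Magnitude of the centered unitary inverse transform."""
    _check_square(k.data)
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k.data), norm="ortho"))
    return np.abs(img)


def _check_same_shape(k_strong: KSpaceGrid, k_weak: KSpaceGrid) -> int:
    n = _check_square(k_strong.data)
    if k_weak.data.shape != k_strong.data.shape:
        raise ValueError(
            f"k-space shapes differ: {k_strong.data.shape} vs {k_weak.data.shape}"
        )
    return n


def assemble_interleaved(k_strong: KSpaceGrid, k_weak: KSpaceGrid) -> AssemblyResult:
    """Even phase-encode lines (ky mod 2 == 0, incl. DC) from the strong
    k-space, odd lines from the weak one — the as-acquired artifact case."""
    n = _check_same_shape(k_strong, k_weak)
    ky = np.arange(n) - n // 2
    weak_lines = (ky % 2) != 0
    data = np.where(weak_lines[:, None], k_weak.data, k_strong.data)
    return AssemblyResult(KSpaceGrid(data), weak_lines, "interleave")


def _outer_rows(n: int) -> np.ndarray:
    """Rows with ky in [-n/2, -n/4-1] or [n/4, n/2-1] (the outer halves)."""
    ky = np.arange(n) - n // 2
    return (ky < -n // 4) | (ky >= n // 4)


def assemble_reordered(k_strong: KSpaceGrid, k_weak: KSpaceGrid,
                       inverted: bool = False) -> AssemblyResult:
    """Weak lines distributed equally to the uppermost/lowermost k-space ends.

    Default: weak lines occupy ky in [-n/2, -n/4-1] and [n/4, n/2-1] (for
    n=64 that is -32..-17 and +16..+31) while the strong lines hold the
    central half — a low-pass placement of the weaker signal.  ``inverted``
    swaps the roles (weak signal in the center), which trades phantom signal
    for the same ringing.
    """
    n = _check_same_shape(k_strong, k_weak)
    weak_lines = _outer_rows(n)
    if inverted:
        weak_lines = ~weak_lines
    data = np.where(weak_lines[:, None], k_weak.data, k_strong.data)
    scheme = "reorder_inverted" if inverted else "reorder"
    return AssemblyResult(KSpaceGrid(data), weak_lines, scheme)


def assemble_zero_filled(k_strong: KSpaceGrid) -> AssemblyResult:
    """Strong lines in the central half of k-space, zeros outside.

    The truncation reference: reconstructing this exhibits plain Gibbs
    ringing, against which the reordered assembly is compared.
    """
    n = _check_square(k_strong.data)
    outer = _outer_rows(n)
    data = np.where(outer[:, None], 0.0, k_strong.data)
    return AssemblyResult(KSpaceGrid(data), np.zeros(n, dtype=bool), "zero_fill")


def assemble_single(k: KSpaceGrid, which: str) -> AssemblyResult:
    """Trivial assembly using every line from one source ('strong' or 'weak')."""
    n = _check_square(k.data)
    if which == "strong":
        return AssemblyResult(KSpaceGrid(k.data.copy()), np.zeros(n, dtype=bool), "strong_only")
    if which == "weak":
        return AssemblyResult(KSpaceGrid(k.data.copy()), np.ones(n, dtype=bool), "weak_only")
    raise ValueError(f"which must be 'strong' or 'weak', got {which!r}")


def estimate_correction_factor(k_strong: KSpaceGrid, k_weak: KSpaceGrid,
                               strategy: str = "center_ratio") -> float:
    """Weak/strong ratio estimated from the k-space center (DC) lines.

    The sequence can acquire the ky=0 line twice, once per effective TR, and
    use the ratio of the two center lines as a global correction factor for
    all weak lines.  Three estimators are offered:

    * ``center_ratio`` (default): magnitude ratio of the two k-space center
      samples (ky=0, kx=0), i.e. the ratio of the total image signals.  This
      is the signal-weighted mean of the local weak/strong ratio, so the
      corrected ghost nulls near the signal-weighted mean flip angle; exact
      for homogeneous phantoms.
    * ``l1_ratio``: ratio of the L1 norms of the two DC rows.  Also
      degenerate-safe, but dominated by the low-flip-angle columns that
      carry most of the line's energy.
    * ``masked_pointwise_mean``: mean of the pointwise magnitude ratios over
      DC-row entries whose strong magnitude exceeds 1e-6 of the row maximum.

    Returns a value in (0, 1] for an unadapted pair with TR2 > TR1.
    """
    n = _check_same_shape(k_strong, k_weak)
    dc = n // 2
    strong_row = np.abs(k_strong.data[dc])
    weak_row = np.abs(k_weak.data[dc])
    if strong_row.sum() == 0:
        raise ValueError("degenerate input: the strong k-space center line is identically zero")
    if strategy == "center_ratio":
        if strong_row[dc] == 0:
            raise ValueError("degenerate input: the strong k-space center sample is zero")
        return float(weak_row[dc] / strong_row[dc])
    if strategy == "l1_ratio":
        return float(weak_row.sum() / strong_row.sum())
    if strategy == "masked_pointwise_mean":
        keep = strong_row > 1e-6 * strong_row.max()
        return float(np.mean(weak_row[keep] / strong_row[keep]))
    raise ValueError(f"unknown correction strategy {strategy!r}")


def apply_correction(a: AssemblyResult, factor: float) -> AssemblyResult:
    """Multiply every weak-provenance line by ``1/factor``.

    Raising the weak lines to the strong level cancels the period-2
    modulation exactly when the phantom is homogeneous; for inhomogeneous
    excitation the single global factor can only null one flip angle.
    """
    if factor <= 0:
        raise ValueError(f"correction factor must be positive, got {factor}")
    if not a.weak_lines.any():
        raise ValueError(f"assembly '{a.scheme}' has no weak lines to correct")
    data = a.kspace.data.copy()
    data[a.weak_lines] /= factor
    return replace(a, kspace=KSpaceGrid(data), correction_applied=float(factor))


def acquisition_order(n: int) -> list[int]:
    """Acquisition order of phase-encode indices under the reordered scheme.

    The weak-signal excitations are assigned the outer indices
    (for n=64: -32..-17 and +16..+31) and the strong ones the central block
    (-16..+15), each block traversed in ascending order, with weak and strong
    acquisitions alternating.  The alternation leads with the weak block and
    flips phase at the half-way point so that ky=0 — the contrast-determining
    center — is acquired exactly in the middle of the acquisition (0-based
    position n//2).  For n=64 the order begins -32, -16, -31, -15, ...

    This ordering only matters for the scanner-facing sequence logic; the
    simulated steady-state images are time-invariant and unaffected by it.
    """
    if n <= 0 or n % 4 != 0:
        raise ValueError(f"number of lines must be a positive multiple of 4, got {n}")
    m = n // 4
    weak = list(range(-n // 2, -m)) + list(range(m, n // 2))  # ascending, 2m entries
    strong = list(range(-m, m))  # ascending, 2m entries
    order: list[int] = []
    for k in range(m - 1):
        order += [weak[k], strong[k]]
    for k in range(m - 1, 2 * m):
        order += [strong[k], weak[k]]
    return order


def save_kspace_text(k: KSpaceGrid, real_path, imag_path) -> None:
    """Export a k-space grid as two plain-text matrices (real and imaginary)."""
    np.savetxt(real_path, k.data.real, fmt="%.10g")
    np.savetxt(imag_path, k.data.imag, fmt="%.10g")
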