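"""Partition of the wavenumber axis into contiguous fixed-width segments.

The segment scheme is the search space for binary wavelength selection:
one bit per segment. All segments share the width floor(n_vars /
n_segments); the division remainder goes to the last segment, so e.g.
6539 variables over 21 segments give twenty segments of 311 and a final
segment of 319.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentScheme",
    "make_segments",
    "mask_to_variables",
    "segments_to_wavenumber_ranges",
]


@dataclass(frozen=True)
class SegmentScheme:
    """Contiguous, non-overlapping cover of [0, n_vars) by half-open index ranges."""

    n_vars: int
    n_segments: int
    boundaries: tuple[tuple[int, int], ...]

    @property
    def widths(self) -> list[int]:
        return [e - s for s, e in self.boundaries]


def make_segments(n_vars: int, n_segments: int = 21) -> SegmentScheme:
    """Split ``n_vars`` spectral variables into ``n_segments`` contiguous blocks.

    The first ``n_segments - 1`` blocks have width floor(n_vars/n_segments);
    the last block absorbs the remainder.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_vars < n_segments:
        raise ValueError(f"n_vars ({n_vars}) < n_segments ({n_segments})")
    base = n_vars // n_segments
    bounds = [(i * base, (i + 1) * base) for i in range(n_segments - 1)]
    bounds.append(((n_segments - 1) * base, n_vars))
    return SegmentScheme(n_vars, n_segments, tuple(bounds))


def mask_to_variables(mask, scheme: SegmentScheme) -> np.ndarray:
    """Expand a segment bitmask to the sorted variable indices it covers."""
    mask = np.asarray(mask)
    if mask.size != scheme.n_segments:
        raise ValueError(
            f"mask length {mask.size} != n_segments {scheme.n_segments}"
        )
    parts = [
        np.arange(s, e)
        for (s, e), bit in zip(scheme.boundaries, mask)
        if bit
    ]
    if not parts:
        return np.array([], dtype=int)
    return np.concatenate(parts)


def segments_to_wavenumber_ranges(
    mask, scheme: SegmentScheme, wavenumbers
) -> list[tuple[float, float]]:
    """Report selected segments as merged (low, high) wavenumber ranges.

    Maximal runs of adjacent selected segments merge into one range;
    endpoints are the extreme grid values covered, so low <= high
    regardless of grid direction.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    mask = np.asarray(mask)
    if mask.size != scheme.n_segments:
        raise ValueError(
            f"mask length {mask.size} != n_segments {scheme.n_segments}"
        )
    if wavenumbers.size != scheme.n_vars:
        raise ValueError(
            f"wavenumber grid length {wavenumbers.size} != n_vars {scheme.n_vars}"
        )
    ranges: list[tuple[float, float]] = []
    run_start: int | None = None
    for k in range(scheme.n_segments + 1):
        selected = k < scheme.n_segments and bool(mask[k])
        if selected and run_start is None:
            run_start = k
        elif not selected and run_start is not None:
            lo_idx = scheme.boundaries[run_start][0]
            hi_idx = scheme.boundaries[k - 1][1]
            chunk = wavenumbers[lo_idx:hi_idx]
            ranges.append((float(chunk.min()), float(chunk.max())))
            run_start = None
    return ranges
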