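"""Variable-width DIA isolation-window design from precursor density.

Given a survey list of precursor m/z values, the precursor selection range
(default 380-980 m/z) is partitioned into a fixed number of contiguous
windows (default 60) whose edges sit at equal-count quantile boundaries of
the in-range precursors: narrow windows where precursor density is high,
wide ones in sparse regions, with per-window precursor counts differing by
at most one.  Interior edges are placed midway between the two precursors
flanking each chunk boundary, so edges depend only on the empirical
distribution (duplicating every precursor leaves them unchanged when chunk
boundaries fall in the same inter-precursor gaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WindowScheme", "compute_variable_windows"]


@dataclass
class WindowScheme:
    """Contiguous [low, high) isolation windows exactly covering the range."""

    low: float
    high: float
    edges: np.ndarray  # n_windows + 1, edges[0] = low, edges[-1] = high
    counts: np.ndarray  # in-range precursors per window

    @property
    def n_windows(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window": np.arange(1, self.n_windows + 1),
            "low_mz": self.edges[:-1],
            "high_mz": self.edges[1:],
            "width_mz": self.widths,
            "precursor_count": self.counts,
        }).set_index("window")


def compute_variable_windows(
    mz: np.ndarray,
    n_windows: int = 60,
    mz_range: tuple[float, float] = (380.0, 980.0),
    min_width: float = 0.0,
) -> WindowScheme:
    """Equal-count variable-width isolation windows over ``mz_range``.

    Precursors outside the range are ignored.  Raises when fewer in-range
    precursors than windows are available.  ``min_width`` > 0 enforces a
    minimum window width by pushing coincident/close edges apart (counts
    are then re-tallied and may differ by more than one).
    """
    low, high = map(float, mz_range)
    if high <= low:
        raise ValueError("mz_range must be increasing")
    x = np.sort(np.asarray(mz, dtype=float))
    x = x[(x >= low) & (x <= high)]
    n = len(x)
    if n < n_windows:
        raise ValueError(
            f"only {n} in-range precursors for {n_windows} windows; "
            f"use a smaller n_windows"
        )
    # chunk boundaries with per-chunk counts differing by <= 1
    bounds = (np.arange(1, n_windows) * n) // n_windows  # sorted indices
    interior = (x[bounds - 1] + x[bounds]) / 2.0
    edges = np.concatenate([[low], interior, [high]])

    if min_width > 0:
        if (high - low) < n_windows * min_width:
            raise ValueError("range too narrow for the requested minimum width")
        for i in range(1, len(edges)):
            edges[i] = max(edges[i], edges[i - 1] + min_width)
        edges[-1] = high
        for i in range(len(edges) - 2, 0, -1):
            edges[i] = min(edges[i], edges[i + 1] - min_width)

    counts = np.histogram(x, bins=edges)[0]
    if counts.sum() != n:  # points exactly on `high` belong to the last window
        counts[-1] += n - counts.sum()
    return WindowScheme(low=low, high=high, edges=edges, counts=counts)
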