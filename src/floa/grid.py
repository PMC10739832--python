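"""Normalized-time frame grids.

Movement cycles are resampled onto a common grid of equally spaced time
points (by convention 101 frames, i.e. 0..100 percent of movement), so that
curves from different trials are directly comparable frame by frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrameGrid"]


@dataclass(frozen=True)
class FrameGrid:
    """Equally spaced time points on a closed interval, endpoints included.

    Parameters
    ----------
    n_frames : int
        Number of grid points, at least 2.
    t_min, t_max : float
        Domain endpoints in normalized-time units.
    """

    n_frames: int = 101
    t_min: float = 0.0
    t_max: float = 100.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not self.t_max > self.t_min:
            raise ValueError("t_max must exceed t_min")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.t_min, self.t_max, self.n_frames)

    def __len__(self) -> int:
        return self.n_frames
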