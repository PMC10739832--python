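"""Curve containers and pre-processing for paired method-comparison data.

A :class:`CurveDataset` holds angle curves indexed by
(method, subject, session, replicate) on a shared frame grid, for one
scenario (one joint x anatomical plane).  Pre-processing mirrors standard
practice for motion-capture angle curves:

* time normalization — resample each movement cycle onto the common
  101-frame percent-of-movement grid;
* range of motion — subtract the initial angle so every curve starts at 0;
* sign alignment — flip the sign of one method's curves in scenarios
  where the two systems define the positive direction oppositely.

:class:`DifferenceCurves` holds the frame-wise between-method differences
d_ijk = y_m1,ijk - y_m2,ijk that the mixed model is fitted to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import FrameGrid

__all__ = [
    "CurveDataset",
    "DifferenceCurves",
    "time_normalize",
    "range_of_motion",
    "align_sign",
    "compute_differences",
]


def time_normalize(raw_curve: np.ndarray, target: FrameGrid) -> np.ndarray:
    """Linearly interpolate a raw-length curve onto *target* (endpoints kept)."""
    y = np.asarray(raw_curve, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("raw curve must be 1-D with length >= 2")
    src = np.linspace(0.0, 1.0, y.size)
    dst = np.linspace(0.0, 1.0, target.n_frames)
    out = np.interp(dst, src, y)
    out[0], out[-1] = y[0], y[-1]
    return out


def range_of_motion(curve: np.ndarray) -> np.ndarray:
    """Rebaseline: subtract the initial angle, so curve[0] becomes 0."""
    y = np.asarray(curve, dtype=float)
    if y.size == 0:
        raise ValueError("empty curve")
    return y - y[0]


@dataclass
class CurveDataset:
    """Curves keyed by (method, subject, session, replicate), shared grid."""

    curves: dict[tuple, np.ndarray]
    grid: FrameGrid
    scenario: str = ""

    def __post_init__(self) -> None:
        methods = self.methods
        if len(methods) > 2:
            raise ValueError(f"expected at most two methods, got {methods}")
        for key, y in self.curves.items():
            if len(y) != self.grid.n_frames:
                raise ValueError(f"curve {key} length {len(y)} does not "
                                 f"match grid ({self.grid.n_frames})")

    @property
    def methods(self) -> list:
        return sorted({k[0] for k in self.curves})

    def n_curves(self) -> int:
        return len(self.curves)

    def map_values(self, fn) -> "CurveDataset":
        return CurveDataset({k: fn(v) for k, v in self.curves.items()},
                            self.grid, self.scenario)


@dataclass
class DifferenceCurves:
    """Between-method difference curves d_ijk keyed by (subject, session,
    replicate)."""

    diffs: dict[tuple, np.ndarray]
    grid: FrameGrid
    scenario: str = ""

    @property
    def index(self) -> list[tuple]:
        return sorted(self.diffs)

    def to_matrix(self) -> np.ndarray:
        """(n_curves, n_frames) matrix in sorted key order."""
        return np.array([self.diffs[k] for k in self.index])

    def n_curves(self) -> int:
        return len(self.diffs)

    @property
    def subjects(self) -> list:
        return sorted({k[0] for k in self.diffs})


def align_sign(dataset: CurveDataset, rules: dict) -> CurveDataset:
    """Multiply specified (scenario -> {method: ±1}) curves by -1 or +1.

    Used e.g. to align the low-spine angles of a markerless system whose
    positive direction is opposite to the marker-based convention.
    """
    for scenario in rules:
        if scenario != dataset.scenario:
            raise ValueError(f"rule scenario {scenario!r} does not match "
                             f"dataset scenario {dataset.scenario!r}")
    per_method = rules.get(dataset.scenario, {})
    for mult in per_method.values():
        if mult not in (+1, -1):
            raise ValueError(f"multiplier must be ±1, got {mult}")
    new = {}
    for key, y in dataset.curves.items():
        mult = per_method.get(key[0], 1)
        new[key] = mult * y
    return CurveDataset(new, dataset.grid, dataset.scenario)


def compute_differences(dataset: CurveDataset,
                        order: tuple | None = None) -> DifferenceCurves:
    """Frame-wise differences d_ijk = y_m1,ijk - y_m2,ijk.

    *order* gives (m1, m2); default is the sorted pair of method labels.
    Curves without a counterpart in the other method are excluded with a
    warning.
    """
    methods = dataset.methods
    if order is None:
        if len(methods) != 2:
            raise ValueError("dataset must contain exactly two methods")
        order = (methods[0], methods[1])
    m1, m2 = order
    keys1 = {k[1:] for k in dataset.curves if k[0] == m1}
    keys2 = {k[1:] for k in dataset.curves if k[0] == m2}
    paired = keys1 & keys2
    unpaired = (keys1 | keys2) - paired
    if unpaired:
        warnings.warn(f"excluding {len(unpaired)} unpaired curve(s): "
                      f"{sorted(unpaired)[:5]}", stacklevel=2)
    diffs = {ijk: dataset.curves[(m1, *ijk)] - dataset.curves[(m2, *ijk)]
             for ijk in paired}
    return DifferenceCurves(diffs, dataset.grid, dataset.scenario)
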