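"""Long-format CSV readers/writers and configuration handling.

The on-disk exchange format is a long table with columns
``method, subject, session, replicate, frame, value, scenario`` — one row
per (curve, frame), frames 0-based.  (The biomechanics convention of
"frame 25 to 75" is 1-based percent-of-movement; 0-based frame f is
percent f of movement on a 101-frame grid.)
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import FLoABand
from .datasets import CurveDataset
from .grid import FrameGrid

__all__ = ["read_curves", "write_curves", "write_band", "load_config",
           "CONFIG_DEFAULTS", "scenario_estimator_kwargs"]

log = logging.getLogger("floa")

REQUIRED_COLUMNS = ["method", "subject", "session", "replicate",
                    "frame", "value"]

CONFIG_DEFAULTS: dict = {
    "multiplier": 2.0,
    "threshold": 0.95,
    "variance_fraction": 0.99,
    "candidate_knots": [0, 1, 3, 9, 19, 32],
    "n_inner_knots": None,
    "random_basis": "eigen",
    "random_covariance": None,
    "error": {"family": "ARMA", "p": 2, "q": 1},
    "preprocess": {"range_of_motion": False, "sign_rules": {}},
    "optim": {"n_starts": 3, "seed": 0},
}


def read_curves(path, validation: str = "strict",
                scenario: str | None = None) -> CurveDataset:
    """Read a long-format curve CSV into a :class:`CurveDataset`.

    ``strict`` errors on duplicate keys or frame gaps; ``permissive``
    drops incomplete curves with a logged warning.  The frame grid is
    inferred from the maximum frame index.
    """
    if validation not in ("strict", "permissive"):
        raise ValueError(f"unknown validation mode {validation!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if not np.issubdtype(df["value"].dtype, np.number):
        raise ValueError("column 'value' is not numeric")
    if scenario is None and "scenario" in df.columns:
        scenarios = df["scenario"].unique()
        if len(scenarios) > 1:
            raise ValueError(f"multiple scenarios in file: {scenarios}; "
                             "pass scenario= to select one")
        scenario = str(scenarios[0])
    elif scenario is not None and "scenario" in df.columns:
        df = df[df["scenario"] == scenario]
    n_frames = int(df["frame"].max()) + 1
    grid = FrameGrid(n_frames=n_frames, t_min=0.0, t_max=float(n_frames - 1))
    keycols = ["method", "subject", "session", "replicate"]
    dup = df.duplicated(subset=keycols + ["frame"])
    if dup.any():
        if validation == "strict":
            bad = df[dup].iloc[0]
            raise ValueError("duplicate (curve, frame) rows, first at "
                             f"{tuple(bad[keycols + ['frame']])}")
        df = df[~dup]
    curves = {}
    for key, sub in df.groupby(keycols, sort=True):
        frames = sub["frame"].to_numpy()
        if len(frames) != n_frames or set(frames) != set(range(n_frames)):
            missing_frames = sorted(set(range(n_frames)) - set(frames))
            if validation == "strict":
                raise ValueError(f"curve {key} missing frames "
                                 f"{missing_frames[:5]}")
            log.warning("dropping incomplete curve %s (missing %d frames)",
                        key, len(missing_frames))
            continue
        curves[tuple(key)] = (sub.sort_values("frame")["value"]
                              .to_numpy(dtype=float))
    return CurveDataset(curves, grid, scenario=scenario or "")


def write_curves(dataset: CurveDataset, path) -> None:
    """Write a :class:`CurveDataset` as the long CSV (full precision)."""
    rows = []
    for (m, i, j, k), y in sorted(dataset.curves.items()):
        for f, v in enumerate(y):
            rows.append((m, i, j, k, f, repr(float(v)), dataset.scenario))
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS + ["scenario"])
    df.to_csv(path, index=False)


def write_band(band: FLoABand, path) -> None:
    """Band CSV: frame, bias, lower, upper, variance (full precision)."""
    df = pd.DataFrame({
        "frame": np.arange(len(band.bias)),
        "bias": band.bias, "lower": band.lower, "upper": band.upper,
        "variance": band.variance,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def _merge(defaults: dict, override: dict, path="") -> dict:
    out = {}
    for k, v in defaults.items():
        if k in override:
            o = override[k]
            out[k] = _merge(v, o, f"{path}{k}.") if isinstance(v, dict) \
                and isinstance(o, dict) else o
        else:
            out[k] = v
    unknown = set(override) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: "
                         f"{sorted(path + k for k in unknown)}")
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML/JSON config, apply defaults, reject unknown keys."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if overrides:
        data = {**data, **overrides}
    cfg = _merge(CONFIG_DEFAULTS, data)
    fam = str(cfg["error"]["family"]).lower()
    if fam not in ("iid", "ar1", "car1", "arma"):
        raise ValueError(f"error.family: unknown family {fam!r}")
    cfg["error"]["family"] = fam
    if not (0 < cfg["threshold"] <= 1):
        raise ValueError("threshold: must be in (0, 1]")
    if not (0 < cfg["variance_fraction"] <= 1):
        raise ValueError("variance_fraction: must be in (0, 1]")
    return cfg


def scenario_estimator_kwargs(config: dict) -> dict:
    """Translate a config mapping into FunctionalLimitsOfAgreement kwargs."""
    cfg = _merge(CONFIG_DEFAULTS, config or {})
    return dict(
        n_inner_knots=cfg["n_inner_knots"],
        knot_candidates=tuple(cfg["candidate_knots"]),
        r2_threshold=cfg["threshold"],
        random_basis=cfg["random_basis"],
        random_covariance=cfg["random_covariance"],
        variance_fraction=cfg["variance_fraction"],
        error=cfg["error"]["family"],
        ar_order=int(cfg["error"]["p"]),
        ma_order=int(cfg["error"]["q"]),
        multiplier=cfg["multiplier"],
        rebaseline=bool(cfg["preprocess"]["range_of_motion"]),
        sign_rules=cfg["preprocess"]["sign_rules"] or None,
        n_starts=int(cfg["optim"]["n_starts"]),
        seed=int(cfg["optim"]["seed"]),
    )


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default))
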