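"""Normalization of chemical-probing reactivities to unpaired probabilities.

Raw probing signals (SHAPE acylation reactivities, in-line cleavage
intensities) report backbone flexibility: large values suggest an unpaired
nucleotide, small values a paired one.  This module rescales them to
``q[i] in [0, 1]``, interpreted as the experimental probability that
nucleotide ``i`` is unpaired.

Two monotone maps are provided:

* SHAPE: a continuous piecewise-linear map through configurable breakpoints
  anchored on the conventional moderate (~0.3) and high (~0.7) reactivity
  thresholds, clamped to 1 above an upper cap (default 2.2).  Negative
  (background-subtracted) reactivities are clamped to 0 first.
* In-line: quantile normalization — values at or below the lower percentile
  map to 0, at or above the upper percentile to 1, linear in between.

Missing values are carried as ``NaN`` and later replaced by a fill
probability (default 0.5 = "no information": the downstream paired and
unpaired Boltzmann weights coincide there).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default SHAPE breakpoints as (raw, target) knots of the piecewise map.
DEFAULT_SHAPE_BREAKPOINTS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.25, 0.35),
    (0.3, 0.55),
    (0.7, 0.85),
    (2.2, 1.0),
)


@dataclass(frozen=True)
class NormalizationConfig:
    """Tunable knobs of both normalization maps.

    ``shape_breakpoints`` are the knots of the SHAPE map (strictly increasing
    in both coordinates, targets spanning exactly [0, 1]);
    ``inline_low``/``inline_high`` are clip percentiles in [0, 100];
    ``missing_fill`` replaces missing entries when the profile is resolved.
    """

    shape_breakpoints: tuple[tuple[float, float], ...] = DEFAULT_SHAPE_BREAKPOINTS
    inline_low: float = 2.5
    inline_high: float = 97.5
    missing_fill: float = 0.5

    def __post_init__(self) -> None:
        bp = tuple((float(r), float(t)) for r, t in self.shape_breakpoints)
        object.__setattr__(self, "shape_breakpoints", bp)
        raws = [r for r, _ in bp]
        targets = [t for _, t in bp]
        if len(bp) < 2:
            raise ValueError("need at least two breakpoints")
        if any(b <= a for a, b in zip(raws, raws[1:])):
            raise ValueError("breakpoint raw values must be strictly increasing")
        if any(b <= a for a, b in zip(targets, targets[1:])):
            raise ValueError("breakpoint target values must be strictly increasing")
        if targets[0] != 0.0 or targets[-1] != 1.0:
            raise ValueError("breakpoint targets must span [0, 1]")
        if not (0.0 <= self.inline_low < self.inline_high <= 100.0):
            raise ValueError("require 0 <= low < high <= 100 for clip percentiles")
        if not (0.0 <= self.missing_fill <= 1.0):
            raise ValueError("missing fill must be a probability in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationConfig":
        kwargs = dict(d)
        if "shape_breakpoints" in kwargs:
            kwargs["shape_breakpoints"] = tuple(
                tuple(p) for p in kwargs["shape_breakpoints"]
            )
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "shape_breakpoints": [list(p) for p in self.shape_breakpoints],
            "inline_low": self.inline_low,
            "inline_high": self.inline_high,
            "missing_fill": self.missing_fill,
        }


@dataclass(frozen=True)
class ReactivityProfile:
    """Raw probing values (NaN = missing) plus their normalized counterpart."""

    raw: np.ndarray
    kind: str  # "shape" | "inline"
    q: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("shape", "inline"):
            raise ValueError(f"unknown probing kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.raw)


def normalize_shape(
    raw: np.ndarray, config: NormalizationConfig | None = None
) -> np.ndarray:
    """Map raw SHAPE reactivities to unpaired probabilities.

    Negative values clamp to 0; values above the last breakpoint clamp to 1;
    NaN (missing) propagates.
    """
    config = config or NormalizationConfig()
    xs = np.array([r for r, _ in config.shape_breakpoints])
    ys = np.array([t for _, t in config.shape_breakpoints])
    raw = np.asarray(raw, dtype=float)
    clamped = np.where(np.isnan(raw), np.nan, np.clip(raw, xs[0], None))
    return np.interp(clamped, xs, ys)  # right end clamps to ys[-1]; NaN passes


def normalize_inline(
    raw: np.ndarray, config: NormalizationConfig | None = None
) -> np.ndarray:
    """Quantile-normalize in-line probing intensities to [0, 1].

    Outliers below the ``inline_low`` / above the ``inline_high`` percentile
    clamp to 0 / 1; the rest is linear.  A constant profile carries no scale
    information and maps to all 0.5 with a warning.
    """
    config = config or NormalizationConfig()
    raw = np.asarray(raw, dtype=float)
    observed = raw[~np.isnan(raw)]
    if observed.size < 2:
        raise ValueError("in-line normalization needs at least 2 observed values")
    lo = np.percentile(observed, config.inline_low)
    hi = np.percentile(observed, config.inline_high)
    if hi == lo:
        logger.warning(
            "in-line reactivities are constant; degenerate scale, returning all 0.5"
        )
        return np.where(np.isnan(raw), np.nan, 0.5)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


def resolve_missing(q: np.ndarray, fill: float = 0.5) -> np.ndarray:
    """Replace missing (NaN) entries of a normalized profile by ``fill``."""
    if not (0.0 <= fill <= 1.0) or math.isnan(fill):
        raise ValueError(f"fill value {fill} is not a probability in [0, 1]")
    q = np.asarray(q, dtype=float)
    return np.where(np.isnan(q), fill, q)


def make_profile(
    raw: np.ndarray, kind: str = "shape", config: NormalizationConfig | None = None
) -> ReactivityProfile:
    """Normalize *raw* by probing kind, keeping missing entries as NaN."""
    if kind == "shape":
        q = normalize_shape(raw, config)
    else:
        q = normalize_inline(raw, config)
    return ReactivityProfile(raw=np.asarray(raw, dtype=float), kind=kind, q=q)
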