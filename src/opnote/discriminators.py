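"""Threshold discriminators: binary video classification from frame scores.

A discriminator reduces a video's temporally ordered frame classifications
for one step to a single scalar, the *discrimination number* (delta), and
predicts the step present in the video iff ``delta >= tau`` for a fitted
*discrimination threshold* (tau).  Six families are defined:

====================  =====================================================
family                discrimination number
====================  =====================================================
binary_integer        count of positive frames (after 0.5 binarization)
binary_fraction       that count divided by the frame count
probability_integer   sum of the raw frame probabilities
probability_fraction  that sum divided by the frame count
chain_integer         longest consecutive run of positive frames
chain_fraction        that run length divided by the frame count
====================  =====================================================

``tau`` is fitted per step by linear grid search from 0, maximizing the
support-weighted F1 of the resulting video classifications against video
ground truth; ties are broken toward the smallest ``tau``.  Default grid
strides and maxima: integer families stride 100 (chain_integer stride 1)
up to 16200 — the smallest stride multiple covering the longest training
video of 16103 frames — and fraction families stride 0.01 (chain_fraction
0.001) up to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .frame_model import FrameProbabilitySequence, binarize

__all__ = [
    "Family",
    "DiscriminatorSpec",
    "FittedDiscriminator",
    "integer_grid_max",
    "discrimination_number",
    "predict",
    "fit_threshold",
    "ensemble_predict",
    "threshold_stability",
    "FRACTION_FAMILIES",
    "CHAIN_FAMILIES",
]


class Family(str, Enum):
    BINARY_INTEGER = "binary_integer"
    BINARY_FRACTION = "binary_fraction"
    PROBABILITY_INTEGER = "probability_integer"
    PROBABILITY_FRACTION = "probability_fraction"
    CHAIN_INTEGER = "chain_integer"
    CHAIN_FRACTION = "chain_fraction"


FRACTION_FAMILIES = (
    Family.BINARY_FRACTION,
    Family.PROBABILITY_FRACTION,
    Family.CHAIN_FRACTION,
)
CHAIN_FAMILIES = (Family.CHAIN_INTEGER, Family.CHAIN_FRACTION)

#: Default grid (stride, maximum) per family.
DEFAULT_GRIDS: dict[Family, tuple[float, float]] = {
    Family.BINARY_INTEGER: (100.0, 16200.0),
    Family.BINARY_FRACTION: (0.01, 1.0),
    Family.PROBABILITY_INTEGER: (100.0, 16200.0),
    Family.PROBABILITY_FRACTION: (0.01, 1.0),
    Family.CHAIN_INTEGER: (1.0, 16200.0),
    Family.CHAIN_FRACTION: (0.001, 1.0),
}


def integer_grid_max(longest_video_frames: int, stride: int = 100) -> int:
    """Smallest stride multiple at or above the longest video length.

    The integer-family grid maximum is set so that the grid covers every
    attainable discrimination number; with the longest training video at
    16103 frames and stride 100 this gives 16200.
    """
    return int(math.ceil(longest_video_frames / stride) * stride)


@dataclass(frozen=True)
class DiscriminatorSpec:
    """A discriminator family plus its threshold search grid."""

    family: Family
    grid_start: float = 0.0
    grid_stride: float | None = None
    grid_max: float | None = None

    def __post_init__(self) -> None:
        family = Family(self.family)
        object.__setattr__(self, "family", family)
        stride, gmax = DEFAULT_GRIDS[family]
        if self.grid_stride is None:
            object.__setattr__(self, "grid_stride", stride)
        if self.grid_max is None:
            object.__setattr__(self, "grid_max", gmax)
        if self.grid_stride <= 0:
            raise ValueError("grid stride must be positive")
        if self.grid_max < self.grid_start:
            raise ValueError("grid maximum below grid start")

    def grid(self) -> np.ndarray:
        """The threshold lattice, both endpoints included.

        Built from integer multiples of the stride (rounded to 12 decimals)
        so fractional strides do not accumulate floating-point error.
        """
        n = int(math.floor((self.grid_max - self.grid_start) / self.grid_stride + 1e-9))
        taus = self.grid_start + np.arange(n + 1) * self.grid_stride
        taus = np.round(taus, 12)
        if taus[-1] < self.grid_max - 1e-12:
            taus = np.append(taus, self.grid_max)
        return taus


@dataclass(frozen=True)
class FittedDiscriminator:
    """A discriminator spec with its fitted per-step threshold."""

    spec: DiscriminatorSpec
    tau: float
    fit_score: float

    def __post_init__(self) -> None:
        if not (self.spec.grid_start <= self.tau <= self.spec.grid_max):
            raise ValueError(
                f"tau {self.tau} outside grid "
                f"[{self.spec.grid_start}, {self.spec.grid_max}]"
            )


def _longest_run(binary: np.ndarray) -> int:
    """Length of the longest consecutive run of ones."""
    x = np.asarray(binary, dtype=bool)
    if not x.any():
        return 0
    padded = np.concatenate(([0], x.view(np.uint8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return int((edges[1::2] - edges[::2]).max())


def _as_probabilities(seq: FrameProbabilitySequence | np.ndarray) -> np.ndarray:
    if isinstance(seq, FrameProbabilitySequence):
        return seq.probabilities
    return np.asarray(seq, dtype=np.float64)


def discrimination_number(
    spec: DiscriminatorSpec, seq: FrameProbabilitySequence | np.ndarray
) -> float:
    """Compute the scalar summary delta of a frame-probability sequence.

    Binary and chain families consume the 0.5-binarized sequence;
    probability families consume the raw probabilities.

    Raises
    ------
    ValueError
        On an empty sequence (delta is undefined for zero frames).
    """
    p = _as_probabilities(seq)
    if p.size == 0:
        raise ValueError("discrimination number undefined for an empty sequence")
    n = p.size
    family = spec.family
    if family in (Family.PROBABILITY_INTEGER, Family.PROBABILITY_FRACTION):
        total = float(p.sum())
        return total if family is Family.PROBABILITY_INTEGER else total / n
    hard = binarize(p)
    if family in (Family.BINARY_INTEGER, Family.BINARY_FRACTION):
        count = float(hard.sum())
        return count if family is Family.BINARY_INTEGER else count / n
    run = float(_longest_run(hard))
    return run if family is Family.CHAIN_INTEGER else run / n


def predict(
    fitted: FittedDiscriminator, seq: FrameProbabilitySequence | np.ndarray
) -> bool:
    """Positive-video prediction: ``delta >= tau`` (inclusive)."""
    return bool(discrimination_number(fitted.spec, seq) >= fitted.tau)


def _weighted_f1_curve(
    deltas: np.ndarray, truth: np.ndarray, taus: np.ndarray
) -> np.ndarray:
    """Support-weighted F1 of ``delta >= tau`` predictions, for every tau.

    Vectorized over the threshold lattice; matches
    :func:`opnote.evaluation.weighted_f1` (a class with zero
    precision+recall contributes F1 = 0).
    """
    y = np.asarray(truth, dtype=bool)
    d = np.asarray(deltas, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    pred = d[None, :] >= taus[:, None]
    tp = pred[:, y].sum(axis=1)
    fp = pred[:, ~y].sum(axis=1)
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        f1_pos = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
        f1_neg = np.where(2 * tn + fn + fp > 0, 2 * tn / (2 * tn + fn + fp), 0.0)
    return (n_pos * f1_pos + n_neg * f1_neg) / y.size


def fit_threshold(
    spec: DiscriminatorSpec,
    training: Sequence[tuple[FrameProbabilitySequence | np.ndarray, bool]],
) -> FittedDiscriminator:
    """Linear grid search for the threshold maximizing weighted F1.

    Every lattice point from ``grid_start`` to ``grid_max`` is evaluated
    against the training videos' true presence; the maximizing ``tau`` is
    returned with its training score, ties broken toward the smallest
    ``tau``.

    Raises
    ------
    ValueError
        On an empty training set.
    """
    if len(training) == 0:
        raise ValueError("cannot fit a threshold on an empty training set")
    deltas = np.array(
        [discrimination_number(spec, seq) for seq, _ in training], dtype=np.float64
    )
    truth = np.array([bool(t) for _, t in training])
    return fit_threshold_from_deltas(spec, deltas, truth)


def fit_threshold_from_deltas(
    spec: DiscriminatorSpec, deltas: np.ndarray, truth: np.ndarray
) -> FittedDiscriminator:
    """Grid-search fit from precomputed discrimination numbers."""
    deltas = np.asarray(deltas, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if deltas.size == 0:
        raise ValueError("cannot fit a threshold on an empty training set")
    taus = spec.grid()
    scores = _weighted_f1_curve(deltas, truth, taus)
    best = int(np.argmax(scores))  # first maximum -> smallest tau
    return FittedDiscriminator(
        spec=spec, tau=float(taus[best]), fit_score=float(scores[best])
    )


def ensemble_predict(
    a: Sequence[bool] | np.ndarray,
    b: Sequence[bool] | np.ndarray,
    op: str,
) -> np.ndarray:
    """Combine two aligned prediction vectors with intersection (AND) or
    union (OR)."""
    av = np.asarray(a, dtype=bool)
    bv = np.asarray(b, dtype=bool)
    if av.shape != bv.shape:
        raise ValueError(
            f"prediction vectors of different lengths: {av.shape} vs {bv.shape}"
        )
    if op == "intersection":
        return av & bv
    if op == "union":
        return av | bv
    raise ValueError(f"unknown ensemble operator {op!r}")


def threshold_stability(
    fitted: FittedDiscriminator,
    training: Sequence[tuple[FrameProbabilitySequence | np.ndarray, bool]],
    k: int = 5,
) -> list[tuple[float, float]]:
    """Weighted F1 at thresholds ``tau + i * stride`` for ``i`` in [-k, k].

    An inspection aid for probing how sensitive the fitted operating point
    is to small threshold perturbations; lattice points outside the grid
    bounds are skipped.
    """
    spec = fitted.spec
    deltas = np.array(
        [discrimination_number(spec, seq) for seq, _ in training], dtype=np.float64
    )
    truth = np.array([bool(t) for _, t in training])
    offsets = np.arange(-k, k + 1)
    taus = np.round(fitted.tau + offsets * spec.grid_stride, 12)
    keep = (taus >= spec.grid_start - 1e-12) & (taus <= spec.grid_max + 1e-12)
    taus = taus[keep]
    scores = _weighted_f1_curve(deltas, truth, taus)
    return [(float(t), float(s)) for t, s in zip(taus, scores)]
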