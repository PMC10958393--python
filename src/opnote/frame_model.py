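"""The frame-classifier contract and a deterministic mock.

Stage I of the pipeline is, conceptually, one binary image classifier per
step scoring every 1-fps frame of a video with a probability that the step
is visible.  This package treats that classifier as a pluggable contract:
anything that produces a :class:`FrameProbabilitySequence` per step per
video can drive the discriminator and accumulator stages.

:func:`mock_classifier` is the bundled implementation used for synthetic
experiments.  It draws frame probabilities from configurable class
distributions around a ground-truth label track and superimposes
*flicker*: with a fixed per-frame marginal probability the frame's score
is resampled from the opposite class's distribution, emulating the
spurious misclassifications (endoscope occlusions and the like) that
break runs of positive frames in real footage.  By default frames flick
independently; because a real frame classifier's errors are temporally
correlated — an occlusion or a misrecognized scene persists over
consecutive frames — flicker can instead be drawn in episodes of
geometric duration (``flicker_burst_mean`` > 1) for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import FrameLabelTrack

__all__ = [
    "FrameProbabilitySequence",
    "NoiseConfig",
    "binarize",
    "mock_classifier",
]


@dataclass(frozen=True)
class FrameProbabilitySequence:
    """Per-frame step probabilities for one step in one video."""

    video_id: str
    step_id: int
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 1:
            raise ValueError("probabilities must be a 1-D sequence")
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError(
                f"video {self.video_id}, step {self.step_id}: "
                "probabilities outside [0, 1]"
            )
        object.__setattr__(self, "probabilities", p)

    @property
    def n_frames(self) -> int:
        return int(self.probabilities.size)


@dataclass(frozen=True)
class NoiseConfig:
    """Noise model for the mock frame classifier.

    ``positive_range`` / ``negative_range`` are uniform supports for the
    probability assigned to truly positive / truly negative frames.
    ``flicker`` is the *marginal* per-frame probability that the score is
    instead drawn from the opposite class's range; flicked frames arrive
    in episodes of geometric duration with mean ``flicker_burst_mean``
    frames (1.0 makes frames flick independently).
    """

    positive_range: tuple[float, float] = (0.6, 1.0)
    negative_range: tuple[float, float] = (0.0, 0.4)
    flicker: float = 0.0
    flicker_burst_mean: float = 1.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("positive_range", self.positive_range),
            ("negative_range", self.negative_range),
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= 1")
        if not (0.0 <= self.flicker <= 1.0):
            raise ValueError(f"flicker rate {self.flicker} outside [0, 1]")
        if self.flicker_burst_mean < 1.0:
            raise ValueError("flicker_burst_mean must be at least 1 frame")

    @classmethod
    def degenerate(cls, flicker: float = 0.0,
                   flicker_burst_mean: float = 1.0) -> "NoiseConfig":
        """Noise-free class scores: positives 1.0 exactly, negatives 0.0."""
        return cls(positive_range=(1.0, 1.0), negative_range=(0.0, 0.0),
                   flicker=flicker, flicker_burst_mean=flicker_burst_mean)


def binarize(
    seq: FrameProbabilitySequence | np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Threshold frame probabilities into binary frame classifications.

    A frame is positive iff its probability is **greater than or equal to**
    the threshold (a tie counts as positive, matching the discriminators'
    inclusive decision rule).

    Raises
    ------
    ValueError
        If ``threshold`` lies outside the open interval (0, 1).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    p = (
        seq.probabilities
        if isinstance(seq, FrameProbabilitySequence)
        else np.asarray(seq, dtype=np.float64)
    )
    return (p >= threshold).astype(np.uint8)


def _flicker_mask(
    rng: np.random.Generator, n: int, rate: float, burst_mean: float
) -> np.ndarray:
    """Boolean flicker mask with marginal frequency ``rate``.

    A two-state alternating renewal process: flicker episodes have
    geometric length with mean ``burst_mean``; clean stretches have the
    geometric length that makes the stationary flicked fraction equal
    ``rate``.  ``burst_mean`` 1 reduces to independent per-frame draws.
    """
    if n == 0 or rate <= 0.0:
        return np.zeros(n, dtype=bool)
    if rate >= 1.0:
        return np.ones(n, dtype=bool)
    if burst_mean <= 1.0:
        return rng.random(n) < rate
    leave = 1.0 / burst_mean  # P(exit a flicker episode per frame)
    enter = min(1.0, rate * leave / (1.0 - rate))
    mask = np.zeros(n, dtype=bool)
    state = bool(rng.random() < rate)
    t = 0
    while t < n:
        p = leave if state else enter
        length = int(rng.geometric(p))
        if state:
            mask[t : t + length] = True
        t += length
        state = not state
    return mask


def mock_classifier(
    truth: FrameLabelTrack,
    noise: NoiseConfig,
    seed: int | np.random.Generator,
) -> FrameProbabilitySequence:
    """Simulate Stage-I frame probabilities around a ground-truth track.

    Seed-reproducible.  With ``flicker`` 0 and degenerate class ranges the
    output binarizes back to the truth exactly.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = truth.n_frames
    pos = rng.uniform(*noise.positive_range, size=n)
    neg = rng.uniform(*noise.negative_range, size=n)
    flicked = _flicker_mask(rng, n, noise.flicker, noise.flicker_burst_mean)
    effective_positive = (truth.labels.astype(bool)) ^ flicked
    p = np.where(effective_positive, pos, neg)
    return FrameProbabilitySequence(
        video_id=truth.video_id, step_id=truth.step_id, probabilities=p
    )
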