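"""Per-frame label tracks from sparse step annotations.

Annotators mark each step occurrence with a single timestamp.  At 1 fps a
timestamp in seconds is a frame index, and the annotated step is taken to
run from its timestamp up to the timestamp of the next *non-instrument*
annotation (instrument steps overlap the core step they serve, so an
instrument annotation does not close the surrounding window).  Windows are
half-open ``[start, next_start)`` on 0-based frame indices; a step
annotated several times accumulates the union of its windows.

Class balancing for frame-classifier training keeps every positive frame
and subsamples an equal number of negative frames from the same video.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .catalog import Category, StepCatalog

__all__ = [
    "LabelError",
    "StepAnnotation",
    "FrameLabelTrack",
    "expand_annotations",
    "balance_negatives",
]

FRAME_RATE = 1.0  # frames per second; timestamps in seconds are frame indices


class LabelError(ValueError):
    """An annotation or label track violates its contract."""


@dataclass(frozen=True)
class StepAnnotation:
    """A single expert annotation: step ``step_id`` begins at
    ``timestamp_s`` seconds into video ``video_id``."""

    video_id: str
    step_id: int
    timestamp_s: int

    def __post_init__(self) -> None:
        if self.timestamp_s < 0:
            raise LabelError(
                f"video {self.video_id}: negative timestamp {self.timestamp_s}"
            )


@dataclass(frozen=True)
class FrameLabelTrack:
    """Binary per-frame labels for one step in one video (1 fps)."""

    video_id: str
    step_id: int
    labels: np.ndarray
    frame_rate: float = FRAME_RATE

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.uint8)
        if labels.ndim != 1:
            raise LabelError("labels must be a 1-D sequence")
        if labels.size and labels.max() > 1:
            raise LabelError("labels must be binary")
        object.__setattr__(self, "labels", labels)

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


def expand_annotations(
    annotations: Iterable[StepAnnotation],
    video_length_frames: int,
    catalog: StepCatalog,
) -> dict[int, FrameLabelTrack]:
    """Expand timestamp annotations into one binary track per catalog step.

    Each annotation of step ``s`` at time ``t`` marks frames ``[t, t')``
    positive for ``s``, where ``t'`` is the next strictly later timestamp
    of a non-instrument annotation, or the video end if there is none.
    Steps never annotated yield all-zero tracks.

    Raises
    ------
    LabelError
        If an annotation lies at or past the video end, naming the video
        and timestamp.
    """
    anns = sorted(annotations, key=lambda a: (a.timestamp_s, a.step_id))
    video_id = anns[0].video_id if anns else ""
    for a in anns:
        if a.step_id not in catalog:
            raise LabelError(
                f"video {a.video_id}: annotation for unknown step {a.step_id}"
            )
        if a.timestamp_s >= video_length_frames:
            raise LabelError(
                f"video {a.video_id}: annotation at t={a.timestamp_s}s lies "
                f"past the video end ({video_length_frames} frames)"
            )
    boundary_times = np.array(
        sorted(
            {
                a.timestamp_s
                for a in anns
                if catalog.get(a.step_id).category is not Category.INSTRUMENT
            }
        ),
        dtype=np.int64,
    )
    tracks = {
        step.step_id: np.zeros(video_length_frames, dtype=np.uint8)
        for step in catalog
    }
    for a in anns:
        later = boundary_times[boundary_times > a.timestamp_s]
        end = int(later[0]) if later.size else video_length_frames
        tracks[a.step_id][a.timestamp_s : end] = 1
    return {
        sid: FrameLabelTrack(video_id=video_id, step_id=sid, labels=arr)
        for sid, arr in tracks.items()
    }


def balance_negatives(
    track: FrameLabelTrack, seed: int | np.random.Generator
) -> list[int]:
    """Subsample negative frames of a positive video to match the positive count.

    Returns a sorted, seed-reproducible subset of negative frame indices of
    size equal to the number of positive frames (all negatives if fewer
    exist), disjoint from the positive frames.

    Raises
    ------
    LabelError
        If the track has no positive frame — videos without the step are
        not used for frame-classifier training.
    """
    n_pos = track.n_positive
    if n_pos == 0:
        raise LabelError(
            f"video {track.video_id}, step {track.step_id}: no positive "
            "frames; negative videos are not used for training"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    negatives = np.flatnonzero(track.labels == 0)
    k = min(n_pos, negatives.size)
    chosen = rng.choice(negatives, size=k, replace=False)
    return sorted(int(i) for i in chosen)
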