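"""Synthetic surgical-video datasets for exercising the pipeline end to end.

The generator emulates the statistical shape of an annotated endoscopic
pituitary surgery video collection: variable video lengths (lognormal
around a 74-minute median at 1 fps), category-dependent step presence
(core steps in most videos, optional and instrument steps in far fewer),
per-occurrence step durations of roughly one to eleven minutes, and
frame-probability noise with configurable flicker.  It produces, per
video: timestamp annotations, a ground-truth presence vector respecting
the catalog's reliance rules, per-step frame-label tracks and mock frame
probabilities, and a per-frame 3-phase timeline.

Construction: present non-instrument steps are laid out sequentially
inside their phase's time block (core steps keep catalog order, optional
steps are shuffled among them — steps are not strictly sequential in real
surgery), with random idle gaps absorbing any slack; instrument steps are
placed inside the window of the core step they serve.  A sampled video
length shorter than the scheduled steps is grown to fit; only an
explicitly fixed length that cannot hold its steps is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .catalog import Category, StepCatalog, reliance_rules
from .frame_model import FrameProbabilitySequence, NoiseConfig, mock_classifier
from .labels import FrameLabelTrack, StepAnnotation

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "SyntheticVideo",
    "SyntheticDataset",
    "simulate_dataset",
    "train_test_split",
]

#: Instrument -> preferred host core steps (the core step the instrument serves).
_PREFERRED_HOSTS: dict[int, tuple[int, ...]] = {
    8: (6,),
    11: (9, 10),
    12: (9, 10),
    18: (17,),
    19: (17,),
    20: (17,),
}

_DEFAULT_PRESENCE = {"core": 0.9, "optional": 0.3, "instrument": 0.4}


class SimulationError(ValueError):
    """A simulation configuration cannot be realized."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Parameters
    ----------
    n_videos
        Number of videos (97 mirrors a one-centre collection with a
        77/20 train/test split).
    length_median_frames, length_sigma
        Lognormal video-length model at 1 fps.  The 4440-frame median is
        74 minutes; sigma 0.5 makes the longest of ~100 draws roughly
        3.5x the median, matching a longest training video of ~16k frames.
    fixed_length_frames
        If set, every video has exactly this many frames (errors if the
        scheduled steps do not fit).
    presence_prob
        Per-category probability that a step occurs in a video.
    per_step_presence
        Optional per-step overrides of the category probabilities.
    duration_range_frames
        Uniform support for a step occurrence's duration (60-660 frames =
        1-11 minutes).
    noise
        Frame-probability noise for the mock classifier.
    seed
        Root seed; expanded into independent per-video substreams.
    """

    n_videos: int = 97
    length_median_frames: float = 4440.0
    length_sigma: float = 0.5
    fixed_length_frames: int | None = None
    presence_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PRESENCE)
    )
    per_step_presence: Mapping[int, float] | None = None
    duration_range_frames: tuple[int, int] = (60, 660)
    noise: NoiseConfig = field(default_factory=lambda: NoiseConfig(flicker=0.05))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_videos < 1:
            raise SimulationError("n_videos must be at least 1")
        for cat, p in self.presence_prob.items():
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"presence probability for {cat} outside [0, 1]")
        lo, hi = self.duration_range_frames
        if not (1 <= lo <= hi):
            raise SimulationError("duration range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class SyntheticVideo:
    """One simulated video with its annotations, truth and frame scores."""

    video_id: str
    n_frames: int
    annotations: tuple[StepAnnotation, ...]
    presence: dict[int, bool]
    tracks: dict[int, FrameLabelTrack]
    probabilities: dict[int, FrameProbabilitySequence]
    phase_timeline: np.ndarray


@dataclass(frozen=True)
class SyntheticDataset:
    """A collection of synthetic videos sharing one catalog and config."""

    videos: tuple[SyntheticVideo, ...]
    catalog: StepCatalog
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.videos)

    def __iter__(self):
        return iter(self.videos)

    def video_ids(self) -> list[str]:
        return [v.video_id for v in self.videos]

    def presence(self) -> dict[int, dict[str, bool]]:
        """Ground truth as ``step_id -> video_id -> bool``."""
        return {
            sid: {v.video_id: v.presence[sid] for v in self.videos}
            for sid in self.catalog.step_ids
        }


def _step_presence_prob(config: SimulationConfig, step) -> float:
    if config.per_step_presence and step.step_id in config.per_step_presence:
        return float(config.per_step_presence[step.step_id])
    return float(config.presence_prob[step.category.value])


def _sample_presence(
    rng: np.random.Generator, config: SimulationConfig, catalog: StepCatalog
) -> dict[int, bool]:
    present = {
        s.step_id: bool(rng.random() < _step_presence_prob(config, s))
        for s in catalog
    }
    # Repair: add a required partner (uniformly chosen) until every reliant
    # present step has at least one of its reliance set present.  Additions
    # only, so the loop terminates.
    rules = reliance_rules(catalog)
    changed = True
    while changed:
        changed = False
        for sid in sorted(rules):
            requires = rules[sid]
            if present[sid] and not any(present[r] for r in requires):
                chosen = int(rng.choice(sorted(requires)))
                present[chosen] = True
                changed = True
    return present


def _simulate_video(
    video_id: str,
    rng: np.random.Generator,
    config: SimulationConfig,
    catalog: StepCatalog,
) -> SyntheticVideo:
    present = _sample_presence(rng, config, catalog)
    lo, hi = config.duration_range_frames

    # Scheduled (non-instrument) steps per phase, cores anchored in catalog
    # order, optional steps inserted at random positions among them.
    phase_order: dict[int, list[int]] = {1: [], 2: [], 3: []}
    for phase_id in (1, 2, 3):
        cores = [
            s.step_id
            for s in catalog
            if s.phase_id == phase_id
            and s.category is Category.CORE
            and present[s.step_id]
        ]
        optionals = [
            s.step_id
            for s in catalog
            if s.phase_id == phase_id
            and s.category is Category.OPTIONAL
            and present[s.step_id]
        ]
        order = list(cores)
        for o in optionals:
            order.insert(int(rng.integers(0, len(order) + 1)), o)
        phase_order[phase_id] = order

    durations = {
        sid: int(rng.integers(lo, hi + 1))
        for order in phase_order.values()
        for sid in order
    }
    total_needed = sum(durations.values())

    if config.fixed_length_frames is not None:
        if config.fixed_length_frames < max(total_needed, 1):
            raise SimulationError(
                f"video {video_id}: fixed length {config.fixed_length_frames} "
                f"frames too short for the {total_needed} frames of scheduled "
                "core/optional steps; configure a larger length"
            )
        n_frames = int(config.fixed_length_frames)
    else:
        sampled = int(
            round(
                float(
                    rng.lognormal(
                        mean=np.log(config.length_median_frames),
                        sigma=config.length_sigma,
                    )
                )
            )
        )
        n_frames = max(sampled, total_needed, 1)

    # Split the slack across phases (weighted by how busy each phase is),
    # then across the idle gaps around each phase's steps.
    slack = n_frames - total_needed
    weights = np.array([len(phase_order[p]) + 1 for p in (1, 2, 3)], dtype=float)
    phase_slack = rng.multinomial(slack, weights / weights.sum())

    starts: dict[int, int] = {}
    phase_timeline = np.zeros(n_frames, dtype=np.int8)
    t = 0
    for idx, phase_id in enumerate((1, 2, 3)):
        order = phase_order[phase_id]
        block = sum(durations[s] for s in order) + int(phase_slack[idx])
        gaps = rng.multinomial(
            int(phase_slack[idx]), np.full(len(order) + 1, 1.0 / (len(order) + 1))
        )
        phase_timeline[t : t + block] = phase_id
        cursor = t + int(gaps[0])
        for i, sid in enumerate(order):
            starts[sid] = cursor
            cursor += durations[sid] + int(gaps[i + 1])
        t += block
    if t < n_frames:  # multinomial rounding never triggers this; belt and braces
        phase_timeline[t:] = 3

    # Instruments overlap a host core/optional step in their phase.
    for s in catalog:
        sid = s.step_id
        if s.category is not Category.INSTRUMENT or not present[sid]:
            continue
        candidates = [h for h in _PREFERRED_HOSTS.get(sid, ()) if h in starts]
        if not candidates:
            candidates = [
                h for h in phase_order[s.phase_id] if h in starts
            ]
        if not candidates:
            present[sid] = False  # nothing in this phase to overlap with
            continue
        host = int(rng.choice(candidates))
        offset = int(rng.integers(0, max(1, (durations[host] * 3) // 4)))
        starts[sid] = starts[host] + offset
        durations[sid] = durations[host] - offset

    annotations = tuple(
        sorted(
            (
                StepAnnotation(video_id=video_id, step_id=sid, timestamp_s=start)
                for sid, start in starts.items()
            ),
            key=lambda a: (a.timestamp_s, a.step_id),
        )
    )

    tracks: dict[int, FrameLabelTrack] = {}
    for s in catalog:
        sid = s.step_id
        labels = np.zeros(n_frames, dtype=np.uint8)
        if sid in starts:
            labels[starts[sid] : starts[sid] + durations[sid]] = 1
        tracks[sid] = FrameLabelTrack(video_id=video_id, step_id=sid, labels=labels)

    probabilities = {
        sid: mock_classifier(tracks[sid], config.noise, rng)
        for sid in catalog.step_ids
    }
    presence = {sid: sid in starts for sid in catalog.step_ids}
    return SyntheticVideo(
        video_id=video_id,
        n_frames=n_frames,
        annotations=annotations,
        presence=presence,
        tracks=tracks,
        probabilities=probabilities,
        phase_timeline=phase_timeline,
    )


def simulate_dataset(
    config: SimulationConfig, catalog: StepCatalog
) -> SyntheticDataset:
    """Generate a seed-reproducible synthetic dataset.

    The root seed is expanded into independent per-video substreams, so a
    dataset is reproducible regardless of generation order.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_videos)
    width = max(3, len(str(config.n_videos)))
    videos = tuple(
        _simulate_video(
            f"v{i + 1:0{width}d}", np.random.default_rng(children[i]), config, catalog
        )
        for i in range(config.n_videos)
    )
    return SyntheticDataset(videos=videos, catalog=catalog, config=config)


def train_test_split(
    dataset: SyntheticDataset, n_test: int, seed: int
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Randomly hold out ``n_test`` videos, fixed by ``seed`` for all stages.

    Raises
    ------
    SimulationError
        If ``n_test`` is not strictly between 0 and the dataset size.
    """
    n = len(dataset)
    if not (0 < n_test < n):
        raise SimulationError(
            f"n_test must be strictly between 0 and {n}, got {n_test}"
        )
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    train = tuple(v for i, v in enumerate(dataset.videos) if i not in test_idx)
    test = tuple(v for i, v in enumerate(dataset.videos) if i in test_idx)
    return (
        SyntheticDataset(videos=train, catalog=dataset.catalog, config=dataset.config),
        SyntheticDataset(videos=test, catalog=dataset.catalog, config=dataset.config),
    )
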