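"""On-disk formats: CSV/YAML/JSON readers and writers for every artifact.

Layout of a dataset directory (written by ``opnote simulate`` and read by
the other subcommands; external data in the same formats is accepted
interchangeably)::

    manifest.json            video ids, frame counts, generation config echo
    annotations.csv          video_id,step_id,timestamp_s
    truth.csv                video_id,S01..S27 (0/1 presence)
    probs/<video_id>.csv     one row per frame, 27 probability columns
    phases/<video_id>.csv    one row per frame, single `phase` column

Fitted models are YAML mapping family -> step id -> {tau, fit_score};
predictions are CSV with the same shape as truth.csv.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .catalog import StepCatalog
from .discriminators import DiscriminatorSpec, Family, FittedDiscriminator
from .frame_model import FrameProbabilitySequence
from .labels import FrameLabelTrack, StepAnnotation
from .simulate import SimulationConfig, SyntheticDataset, SyntheticVideo

__all__ = [
    "step_columns",
    "write_annotations",
    "read_annotations",
    "write_presence",
    "read_presence",
    "write_label_tracks",
    "write_model",
    "read_model",
    "write_dataset",
    "load_dataset",
]


def step_columns(catalog: StepCatalog) -> list[str]:
    return [s.label for s in catalog]


def write_annotations(annotations: Iterable[StepAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"video_id": a.video_id, "step_id": a.step_id, "timestamp_s": a.timestamp_s}
            for a in annotations
        ],
        columns=["video_id", "step_id", "timestamp_s"],
    )
    df.to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[StepAnnotation]:
    df = pd.read_csv(path)
    return [
        StepAnnotation(
            video_id=str(r.video_id),
            step_id=int(r.step_id),
            timestamp_s=int(r.timestamp_s),
        )
        for r in df.itertuples()
    ]


def _presence_frame(
    presence: Mapping[str, Mapping[int, bool]], catalog: StepCatalog
) -> pd.DataFrame:
    rows = []
    for video_id in sorted(presence):
        row: dict = {"video_id": video_id}
        for s in catalog:
            row[s.label] = int(bool(presence[video_id][s.step_id]))
        rows.append(row)
    return pd.DataFrame(rows, columns=["video_id", *step_columns(catalog)])


def write_presence(
    presence: Mapping[str, Mapping[int, bool]],
    catalog: StepCatalog,
    path: str | Path,
) -> None:
    """Write a ``video_id -> step_id -> bool`` mapping as a 0/1 CSV."""
    _presence_frame(presence, catalog).to_csv(path, index=False)


def read_presence(
    path: str | Path, catalog: StepCatalog
) -> dict[str, dict[int, bool]]:
    df = pd.read_csv(path)
    out: dict[str, dict[int, bool]] = {}
    for r in df.itertuples():
        out[str(r.video_id)] = {
            s.step_id: bool(int(getattr(r, s.label))) for s in catalog
        }
    return out


def write_label_tracks(
    tracks: Mapping[int, FrameLabelTrack], catalog: StepCatalog, path: str | Path
) -> None:
    data = {s.label: tracks[s.step_id].labels for s in catalog}
    pd.DataFrame(data).to_csv(path, index=False)


def write_probabilities(
    probabilities: Mapping[int, FrameProbabilitySequence],
    catalog: StepCatalog,
    path: str | Path,
) -> None:
    data = {s.label: probabilities[s.step_id].probabilities for s in catalog}
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")


def read_probabilities(
    path: str | Path, video_id: str, catalog: StepCatalog
) -> dict[int, FrameProbabilitySequence]:
    df = pd.read_csv(path)
    return {
        s.step_id: FrameProbabilitySequence(
            video_id=video_id,
            step_id=s.step_id,
            probabilities=df[s.label].to_numpy(dtype=np.float64),
        )
        for s in catalog
    }


def write_model(
    fitted: Mapping[Family, Mapping[int, FittedDiscriminator]], path: str | Path
) -> None:
    doc = {
        family.value: {
            int(sid): {"tau": f.tau, "fit_score": f.fit_score}
            for sid, f in by_step.items()
        }
        for family, by_step in fitted.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_model(path: str | Path) -> dict[Family, dict[int, FittedDiscriminator]]:
    doc = yaml.safe_load(Path(path).read_text())
    out: dict[Family, dict[int, FittedDiscriminator]] = {}
    for family_name, by_step in doc.items():
        family = Family(family_name)
        spec = DiscriminatorSpec(family=family)
        out[family] = {
            int(sid): FittedDiscriminator(
                spec=spec, tau=float(rec["tau"]), fit_score=float(rec["fit_score"])
            )
            for sid, rec in by_step.items()
        }
    return out


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "probs").mkdir(parents=True, exist_ok=True)
    (out / "phases").mkdir(parents=True, exist_ok=True)
    catalog = dataset.catalog
    all_annotations = [a for v in dataset for a in v.annotations]
    write_annotations(all_annotations, out / "annotations.csv")
    presence = {v.video_id: v.presence for v in dataset}
    write_presence(presence, catalog, out / "truth.csv")
    for v in dataset:
        write_probabilities(v.probabilities, catalog, out / "probs" / f"{v.video_id}.csv")
        pd.DataFrame({"phase": v.phase_timeline}).to_csv(
            out / "phases" / f"{v.video_id}.csv", index=False
        )
    manifest = {
        "videos": [
            {"video_id": v.video_id, "n_frames": v.n_frames} for v in dataset
        ],
        "n_videos": len(dataset),
        "seed": dataset.config.seed,
        "noise": {
            "positive_range": list(dataset.config.noise.positive_range),
            "negative_range": list(dataset.config.noise.negative_range),
            "flicker": dataset.config.noise.flicker,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(data_dir: str | Path, catalog: StepCatalog) -> SyntheticDataset:
    """Load a dataset directory back into memory (tracks are not persisted
    and come back empty; presence, probabilities, annotations and phase
    timelines round-trip)."""
    root = Path(data_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {root}")
    manifest = json.loads(manifest_path.read_text())
    presence = read_presence(root / "truth.csv", catalog)
    annotations = read_annotations(root / "annotations.csv")
    by_video: dict[str, list[StepAnnotation]] = {}
    for a in annotations:
        by_video.setdefault(a.video_id, []).append(a)
    videos = []
    for rec in manifest["videos"]:
        vid = rec["video_id"]
        probs = read_probabilities(root / "probs" / f"{vid}.csv", vid, catalog)
        phase_path = root / "phases" / f"{vid}.csv"
        timeline = (
            pd.read_csv(phase_path)["phase"].to_numpy(dtype=np.int8)
            if phase_path.exists()
            else np.zeros(0, dtype=np.int8)
        )
        videos.append(
            SyntheticVideo(
                video_id=vid,
                n_frames=int(rec["n_frames"]),
                annotations=tuple(by_video.get(vid, ())),
                presence=presence[vid],
                tracks={},
                probabilities=probs,
                phase_timeline=timeline,
            )
        )
    config = SimulationConfig(n_videos=len(videos), seed=int(manifest.get("seed", 0)))
    return SyntheticDataset(videos=tuple(videos), catalog=catalog, config=config)
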