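"""Class-structured synthetic multichannel EEG-like data.

The generator emulates the shape of a 14-channel, 128 Hz, 15-second-window
EEG dataset: records grouped under subjects, several segments per record,
two classes.  The learnable class signal is injected through *channel
dominance* — a class-dependent per-channel amplitude boost that changes
which channel tends to be the per-timepoint extreme — because the
ChMinMaxPat features are functions of extreme-channel identities only.
Spectral structure, rhythms and artifacts are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .eeg_data import DatasetManifest, EegSegment, write_manifest, write_segment

#: Channel names of the 14-channel consumer headset montage the defaults model.
DEFAULT_CHANNELS_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)


def default_dominance_map(nc: int = 14, separation: float = 1.5) -> dict[int, np.ndarray]:
    """Two complementary channel-boost patterns.

    Class 0 boosts the first (left-frontal) channels, class 1 the last
    (right-frontal) ones, so the per-timepoint argmax/argmin channel
    distributions differ between classes.  ``separation`` scales the boost;
    0 removes the class signal entirely.
    """
    if nc < 2:
        raise ValueError("need at least two channels")
    w0 = np.zeros(nc)
    w1 = np.zeros(nc)
    w0[0] = separation
    w0[1] = 0.5 * separation
    w1[-1] = separation
    w1[-2] = 0.5 * separation
    return {0: w0, 1: w1}


@dataclass
class SynthConfig:
    """Generation parameters; the defaults are the package's study conditions.

    14 channels at 128 Hz in 15 s windows give L = 1920 samples per segment;
    20 records per class with 4 segments each give a 40-record, 160-segment
    dataset.  Each sample is i.i.d. Gaussian baseline noise (``noise_sd``)
    plus a class-dependent per-channel boost drawn around the dominance
    weight (``boost_sd``); a per-record per-channel offset (``record_sd``)
    makes segments from one record more alike than segments across records.
    """

    nc: int = 14
    fs: float = 128.0
    segment_seconds: float = 15.0
    n_records_per_class: int = 20
    segments_per_record: int = 4
    dominance_map: Mapping[int, np.ndarray] | None = None
    noise_sd: float = 1.0
    boost_sd: float = 0.5
    record_sd: float = 0.25
    seed: int = 0
    class_names: Mapping[int, str] = field(
        default_factory=lambda: {0: "control", 1: "condition"}
    )

    def __post_init__(self) -> None:
        if self.nc < 2:
            raise ValueError("degenerate config: need at least two channels")
        if self.n_records_per_class < 1 or self.segments_per_record < 1:
            raise ValueError("degenerate config: need at least one record and one segment")
        if self.noise_sd <= 0 or self.boost_sd < 0 or self.record_sd < 0:
            raise ValueError("noise_sd must be positive; boost_sd/record_sd non-negative")
        L = self.fs * self.segment_seconds
        if abs(L - round(L)) > 1e-9 or round(L) < 1:
            raise ValueError(f"fs x segment_seconds must be a positive integer, got {L}")
        if self.dominance_map is None:
            self.dominance_map = default_dominance_map(self.nc)
        dm = {int(k): np.asarray(v, dtype=float) for k, v in self.dominance_map.items()}
        if sorted(dm) != [0, 1]:
            raise ValueError("dominance_map must be defined for classes 0 and 1")
        for k, w in dm.items():
            if w.shape != (self.nc,):
                raise ValueError(f"dominance weights for class {k} must have length nc={self.nc}")
        self.dominance_map = dm

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.segment_seconds))


def generate_segments(cfg: SynthConfig) -> list[EegSegment]:
    """Generate the dataset in memory, fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    channels = (
        DEFAULT_CHANNELS_14
        if cfg.nc == len(DEFAULT_CHANNELS_14)
        else tuple(f"CH{i + 1}" for i in range(cfg.nc))
    )
    L = cfg.n_samples
    segments: list[EegSegment] = []
    rec_counter = 0
    for label in (0, 1):
        boost_mean = cfg.dominance_map[label]
        for _ in range(cfg.n_records_per_class):
            rec_counter += 1
            record_id = f"r{rec_counter:03d}"
            subject_id = f"s{rec_counter:03d}"  # one record per subject
            offset = rng.normal(0.0, cfg.record_sd, size=cfg.nc)
            for si in range(cfg.segments_per_record):
                noise = rng.normal(0.0, cfg.noise_sd, size=(L, cfg.nc))
                boost = rng.normal(boost_mean, cfg.boost_sd, size=(L, cfg.nc))
                segments.append(
                    EegSegment(
                        segment_id=f"{record_id}_seg{si + 1:02d}",
                        record_id=record_id,
                        subject_id=subject_id,
                        class_label=label,
                        data=noise + boost + offset,
                        fs=cfg.fs,
                        channel_names=channels,
                    )
                )
    return segments


def build_manifest(segments: list[EegSegment], cfg: SynthConfig,
                   base_dir: Path | None = None) -> DatasetManifest:
    rows = pd.DataFrame(
        {
            "segment_path": [f"{s.segment_id}.csv" for s in segments],
            "segment_id": [s.segment_id for s in segments],
            "record_id": [s.record_id for s in segments],
            "subject_id": [s.subject_id for s in segments],
            "class_label": [s.class_label for s in segments],
            "class_name": [cfg.class_names.get(s.class_label, str(s.class_label))
                           for s in segments],
        }
    )
    return DatasetManifest(rows=rows, class_names=dict(cfg.class_names), base_dir=base_dir)


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> DatasetManifest:
    """Write segment CSVs plus ``manifest.csv`` under ``out_dir``.

    The output tree is byte-identical across runs with the same config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    segments = generate_segments(cfg)
    for seg in segments:
        write_segment(seg, out_dir / f"{seg.segment_id}.csv")
    manifest = build_manifest(segments, cfg, base_dir=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def shuffle_labels(manifest: DatasetManifest, seed: int) -> DatasetManifest:
    """Permute class labels across records (negative-control fixture).

    The permutation acts on whole records, preserving the per-class record
    counts and the record -> single-label invariant.
    """
    rec_labels = manifest.record_labels()
    records = list(rec_labels)
    labels = [rec_labels[r] for r in records]
    if len(set(labels)) < 2:
        raise ValueError("cannot shuffle labels of a single-class manifest")
    rng = np.random.default_rng(seed)
    permuted = [labels[i] for i in rng.permutation(len(labels))]
    new_map = dict(zip(records, permuted))
    rows = manifest.rows.copy()
    rows["class_label"] = [new_map[r] for r in rows["record_id"]]
    if "class_name" in rows.columns:
        rows["class_name"] = [
            manifest.class_names.get(int(l), str(l)) for l in rows["class_label"]
        ]
    return DatasetManifest(
        rows=rows, class_names=dict(manifest.class_names), base_dir=manifest.base_dir
    )
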