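"""Reading, writing and cross-validation bookkeeping for EEG segment datasets.

A dataset is a collection of fixed-length multichannel EEG windows
("segments"), each stored as one samples x channels CSV whose header row
carries the channel names.  A manifest CSV ties segments to their record,
subject and binary class label.  Records group the segments that were cut
from one continuous recording; leave-one-record-out (LORO) cross-validation
holds out whole records so that correlated windows never straddle the
train/test split.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ("segment_path", "segment_id", "record_id", "subject_id", "class_label")


class ManifestError(ValueError):
    """Raised when a dataset manifest violates its invariants."""


class SegmentError(ValueError):
    """Raised when a segment file cannot be parsed or fails validation."""


@dataclass(frozen=True, eq=False)
class EegSegment:
    """One multichannel EEG window with its provenance metadata.

    ``data`` is an ``L x nc`` float array (microvolt-scale, arbitrary
    units); ``channel_names`` fixes the montage order that downstream
    lobe decoding relies on.
    """

    segment_id: str
    record_id: str
    subject_id: str
    class_label: int
    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise SegmentError(
                f"segment {self.segment_id!r}: data must be a non-empty 2-D matrix, "
                f"got shape {data.shape}"
            )
        if not np.isfinite(data).all():
            raise SegmentError(f"segment {self.segment_id!r}: data contains non-finite values")
        if len(self.channel_names) != data.shape[1]:
            raise SegmentError(
                f"segment {self.segment_id!r}: {len(self.channel_names)} channel names "
                f"for {data.shape[1]} data columns"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class DatasetManifest:
    """Validated table of segments with their record/subject/label metadata."""

    rows: pd.DataFrame
    class_names: dict[int, str]
    base_dir: Path | None = None

    def __post_init__(self) -> None:
        self.rows = self.rows.reset_index(drop=True)
        _validate_rows(self.rows)
        labels = sorted(int(v) for v in self.rows["class_label"].unique())
        for lab in labels:
            self.class_names.setdefault(lab, str(lab))

    @property
    def n_segments(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> np.ndarray:
        """Per-segment class labels in manifest row order."""
        return self.rows["class_label"].to_numpy(dtype=int)

    @property
    def segment_ids(self) -> list[str]:
        return self.rows["segment_id"].tolist()

    @property
    def record_ids(self) -> list[str]:
        """Distinct record ids in order of first appearance."""
        return list(dict.fromkeys(self.rows["record_id"]))

    @property
    def classes(self) -> tuple[int, int]:
        labs = sorted(int(v) for v in self.rows["class_label"].unique())
        return labs[0], labs[1]

    def record_labels(self) -> dict[str, int]:
        return {
            str(rec): int(grp["class_label"].iloc[0])
            for rec, grp in self.rows.groupby("record_id", sort=False)
        }

    def iter_rows(self) -> Iterator[pd.Series]:
        for _, row in self.rows.iterrows():
            yield row

    def resolve_path(self, segment_path: str) -> Path:
        p = Path(segment_path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every segment to exactly one cross-validation fold."""

    scheme: str
    assignments: Mapping[str, int]
    n_folds: int

    def fold_of(self, segment_id: str) -> int:
        return self.assignments[segment_id]

    def test_indices(self, manifest: DatasetManifest) -> list[np.ndarray]:
        """Per-fold integer row indices into the manifest."""
        folds = np.array([self.assignments[s] for s in manifest.segment_ids])
        return [np.flatnonzero(folds == f) for f in range(self.n_folds)]


def _validate_rows(rows: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ManifestError(f"manifest is missing required columns: {missing}")
    if len(rows) == 0:
        raise ManifestError("manifest contains no segments")
    if rows["segment_id"].duplicated().any():
        dup = rows.loc[rows["segment_id"].duplicated(), "segment_id"].iloc[0]
        raise ManifestError(f"duplicate segment_id {dup!r}")
    labels = rows["class_label"].unique()
    if len(labels) != 2:
        raise ManifestError(
            f"manifest must contain exactly two class labels, found {sorted(labels.tolist())}"
        )
    for rec, grp in rows.groupby("record_id", sort=False):
        if grp["class_label"].nunique() > 1:
            raise ManifestError(
                f"record {rec!r} spans multiple class labels "
                f"{sorted(grp['class_label'].unique().tolist())}"
            )
        if grp["subject_id"].nunique() > 1:
            raise ManifestError(f"record {rec!r} spans multiple subjects")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read and validate a dataset manifest CSV.

    Required columns: ``segment_path,segment_id,record_id,subject_id,
    class_label``.  An optional ``class_name`` column supplies human-readable
    class names.  Relative segment paths are resolved against the manifest's
    own directory.
    """
    path = Path(path)
    try:
        rows = pd.read_csv(path, dtype={"segment_id": str, "record_id": str, "subject_id": str})
    except pd.errors.EmptyDataError:
        raise ManifestError(f"manifest {path}: no segments (empty file)") from None
    class_names: dict[int, str] = {}
    if "class_name" in rows.columns:
        for lab, grp in rows.groupby("class_label"):
            names = grp["class_name"].unique()
            if len(names) > 1:
                raise ManifestError(f"class label {lab} maps to multiple class names {list(names)}")
            class_names[int(lab)] = str(names[0])
    return DatasetManifest(rows=rows, class_names=class_names, base_dir=path.parent)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    cols = [c for c in manifest.rows.columns if c in MANIFEST_COLUMNS or c == "class_name"]
    manifest.rows.to_csv(path, index=False, columns=cols)


def load_segment(
    path: str | Path,
    manifest_row: Mapping[str, object],
    fs: float = 128.0,
    expected_channels: int | None = None,
) -> EegSegment:
    """Load one segment file (CSV, or EDF via :mod:`mne`) as an :class:`EegSegment`.

    CSV layout is samples x channels with the header row holding channel
    names.  For EDF input the channel order is taken from the file; pass
    ``expected_channels`` to enforce the montage width either way.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        data, channel_names, fs = _read_edf(path)
    else:
        data, channel_names = _read_segment_csv(path)
    if expected_channels is not None and data.shape[1] != expected_channels:
        raise SegmentError(
            f"{path}: expected {expected_channels} channels, found {data.shape[1]}"
        )
    return EegSegment(
        segment_id=str(manifest_row["segment_id"]),
        record_id=str(manifest_row["record_id"]),
        subject_id=str(manifest_row["subject_id"]),
        class_label=int(manifest_row["class_label"]),  # type: ignore[arg-type]
        data=data,
        fs=fs,
        channel_names=tuple(channel_names),
    )


def _read_segment_csv(path: Path) -> tuple[np.ndarray, list[str]]:
    with open(path, "r") as fh:
        header = fh.readline().strip()
        if not header:
            raise SegmentError(f"{path}: empty segment file")
        channel_names = header.split(",")
        body = fh.read()
    try:
        data = np.loadtxt(io.StringIO(body), delimiter=",", ndmin=2)
    except ValueError as exc:
        # locate the offending cell for a useful error message
        for i, line in enumerate(body.splitlines(), start=2):
            cells = line.split(",")
            if len(cells) != len(channel_names):
                raise SegmentError(
                    f"{path}: row {i} has {len(cells)} cells, expected {len(channel_names)}"
                ) from None
            for j, cell in enumerate(cells):
                try:
                    float(cell)
                except ValueError:
                    raise SegmentError(
                        f"{path}: non-numeric cell {cell!r} at row {i}, column "
                        f"{j + 1} ({channel_names[j]})"
                    ) from None
        raise SegmentError(f"{path}: {exc}") from None
    if data.shape[1] != len(channel_names):
        raise SegmentError(
            f"{path}: header has {len(channel_names)} channels but rows have {data.shape[1]}"
        )
    if np.isnan(data).any():
        r, c = np.argwhere(np.isnan(data))[0]
        raise SegmentError(
            f"{path}: missing/NaN value at row {int(r) + 2}, column {int(c) + 1} "
            f"({channel_names[int(c)]})"
        )
    return data, channel_names


def _read_edf(path: Path) -> tuple[np.ndarray, list[str], float]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise SegmentError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data().T  # mne returns channels x samples
    return np.asarray(data, dtype=float), list(raw.ch_names), float(raw.info["sfreq"])


def write_segment(segment: EegSegment, path: str | Path) -> None:
    """Write a segment as CSV at full precision (bit-exact CSV round-trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(segment.channel_names) + "\n")
        for row in segment.data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def segment_windows(
    data: np.ndarray, fs: float, window_seconds: float
) -> list[np.ndarray]:
    """Cut a continuous record into consecutive non-overlapping windows.

    A trailing remainder shorter than the window is dropped.
    """
    data = np.asarray(data, dtype=float)
    length = int(round(fs * window_seconds))
    if length < 1:
        raise ValueError("window must span at least one sample")
    n = data.shape[0] // length
    return [data[i * length:(i + 1) * length] for i in range(n)]


def make_folds(
    manifest: DatasetManifest,
    scheme: str,
    n_folds: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Build a cross-validation fold plan.

    ``kfold``: segments are shuffled with ``seed`` then split into
    ``n_folds`` near-equal parts (unstratified).  ``loro``: one fold per
    record, in order of first appearance, so no record is ever split across
    folds; ``n_folds`` is ignored and becomes the number of records.
    """
    ids = manifest.segment_ids
    if scheme == "kfold":
        if n_folds < 2:
            raise ValueError("kfold requires n_folds >= 2")
        if n_folds > len(ids):
            raise ValueError(f"n_folds={n_folds} exceeds the {len(ids)} segments available")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(ids))
        assignments: dict[str, int] = {}
        for fold, chunk in enumerate(np.array_split(perm, n_folds)):
            for idx in chunk:
                assignments[ids[int(idx)]] = fold
        return FoldPlan(scheme="kfold", assignments=assignments, n_folds=n_folds)
    if scheme == "loro":
        records = manifest.record_ids
        if len(records) < 2:
            raise ValueError("loro requires at least two records")
        rec_fold = {rec: i for i, rec in enumerate(records)}
        assignments = {
            str(row["segment_id"]): rec_fold[str(row["record_id"])]
            for row in manifest.iter_rows()
        }
        return FoldPlan(scheme="loro", assignments=assignments, n_folds=len(records))
    raise ValueError(f"unknown CV scheme {scheme!r} (expected 'kfold' or 'loro')")
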