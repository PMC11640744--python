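"""ChMinMaxPat: channel min/max transition-pattern feature extraction.

At every timepoint of an ``L x nc`` segment, four channel identities are
read off: the channel holding the maximum value (id1), the minimum value
(id2), and the maximum/minimum deviation from the channel-mean at that
timepoint (id3, id4).  Ordered identity pairs feed six ``nc x nc``
transition tables (row-normalized) and six integer "map" signals whose
value at a timepoint is ``(first-1)*nc + (second-1)``.  Flattened tables,
map histograms and their concatenations give 15 feature vectors per
segment: fv1-fv6 (tables, length nc^2 each), fv7 = concat(fv1..fv6),
fv8-fv13 (histograms, length nc^2 each), fv14 = concat(fv8..fv13) and
fv15 = concat(fv7, fv14), i.e. 196 / 1176 / 2352 features at nc = 14.

Deviations may be taken as absolute values (default) or kept signed.  In
signed mode the deviation argmax/argmin provably coincide with the raw
argmax/argmin (subtracting the per-timepoint mean is a constant shift
across channels), so id3 == id1 and id4 == id2 and several tables
degenerate; the mode is kept for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .eeg_data import DatasetManifest, EegSegment, load_segment

N_FEATURE_VECTORS = 15
N_TABLES = 6
DEFAULT_EPSILON = 1e-10

#: (first, second) identity index for each of the six ordered pairs, in
#: table order: (id1,id2), (id1,id3), (id1,id4), (id2,id3), (id2,id4), (id3,id4).
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class IdentityQuad(NamedTuple):
    """1-based extreme-channel identities at one timepoint."""

    id1: int  # argmax of channel values
    id2: int  # argmin of channel values
    id3: int  # argmax of deviation from the timepoint mean
    id4: int  # argmin of deviation from the timepoint mean


@dataclass
class TransitionTables:
    """Six nc x nc ordered-identity-pair matrices (counts, then row-normalized)."""

    tables: list[np.ndarray]
    epsilon: float = DEFAULT_EPSILON
    normalized: bool = False

    @property
    def nc(self) -> int:
        return self.tables[0].shape[0]


@dataclass
class MapSignals:
    """Six length-L integer signals with values in 0 .. nc^2 - 1."""

    maps: list[np.ndarray]
    nc: int

    @property
    def length(self) -> int:
        return len(self.maps[0])


@dataclass
class FeatureBundle:
    """The 15 ChMinMaxPat feature vectors of one segment (1-based access)."""

    vectors: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.vectors) != N_FEATURE_VECTORS:
            raise ValueError(f"expected {N_FEATURE_VECTORS} vectors, got {len(self.vectors)}")

    def fv(self, k: int) -> np.ndarray:
        if not 1 <= k <= N_FEATURE_VECTORS:
            raise IndexError(f"feature vector index {k} out of 1..{N_FEATURE_VECTORS}")
        return self.vectors[k - 1]

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.vectors)


def _check_mode(distance_mode: str) -> None:
    if distance_mode not in ("absolute", "signed"):
        raise ValueError(f"distance_mode must be 'absolute' or 'signed', got {distance_mode!r}")


def extract_identities(vec: Sequence[float], distance_mode: str = "absolute") -> IdentityQuad:
    """Extreme-channel identities of one channel vector (ties -> lowest index).

    id1/id2 are the (1-based) argmax/argmin of the raw values; id3/id4 the
    argmax/argmin of the deviation from the vector mean, absolute or signed
    per ``distance_mode``.
    """
    _check_mode(distance_mode)
    v = np.asarray(vec, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("channel vector must be 1-D with at least two channels")
    if not np.isfinite(v).all():
        raise ValueError("channel vector contains non-finite values")
    dist = v - v.mean()
    if distance_mode == "absolute":
        dist = np.abs(dist)
    return IdentityQuad(
        id1=int(np.argmax(v)) + 1,
        id2=int(np.argmin(v)) + 1,
        id3=int(np.argmax(dist)) + 1,
        id4=int(np.argmin(dist)) + 1,
    )


def _identity_arrays(data: np.ndarray, distance_mode: str) -> np.ndarray:
    """Per-timepoint identities for a whole segment; returns (L, 4) 1-based ints."""
    _check_mode(distance_mode)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("segment data must be L x nc with nc >= 2")
    if not np.isfinite(data).all():
        bad = int(np.argwhere(~np.isfinite(data).all(axis=1))[0, 0])
        raise ValueError(f"non-finite channel values at timepoint {bad}")
    dist = data - data.mean(axis=1, keepdims=True)
    if distance_mode == "absolute":
        dist = np.abs(dist)
    ids = np.empty((data.shape[0], 4), dtype=np.int64)
    ids[:, 0] = np.argmax(data, axis=1)
    ids[:, 1] = np.argmin(data, axis=1)
    ids[:, 2] = np.argmax(dist, axis=1)
    ids[:, 3] = np.argmin(dist, axis=1)
    return ids + 1


def accumulate(
    segment: EegSegment | np.ndarray,
    distance_mode: str = "absolute",
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[TransitionTables, MapSignals]:
    """Accumulate the six transition tables (raw counts) and map signals.

    For each timepoint with identities (id1..id4), the count at
    ``tt_k[first, second]`` is incremented and ``(first-1)*nc + (second-1)``
    appended to ``map_k`` for each of the six ordered pairs.
    """
    data = segment.data if isinstance(segment, EegSegment) else np.asarray(segment, dtype=float)
    ids = _identity_arrays(data, distance_mode)
    nc = data.shape[1]
    tables: list[np.ndarray] = []
    maps: list[np.ndarray] = []
    for a, b in _PAIRS:
        code = (ids[:, a] - 1) * nc + (ids[:, b] - 1)
        maps.append(code)
        tables.append(np.bincount(code, minlength=nc * nc).reshape(nc, nc).astype(float))
    return (
        TransitionTables(tables=tables, epsilon=epsilon, normalized=False),
        MapSignals(maps=maps, nc=nc),
    )


def normalize_tables(tt: TransitionTables) -> TransitionTables:
    """Row-normalize each table: row / (row sum + epsilon).

    All-zero rows stay all-zero; populated rows sum to 1 up to the
    epsilon-induced deficit.
    """
    if tt.normalized:
        return tt
    out = []
    for t in tt.tables:
        sums = t.sum(axis=1, keepdims=True)
        out.append(t / (sums + tt.epsilon))
    return TransitionTables(tables=out, epsilon=tt.epsilon, normalized=True)


def build_bundle(tt: TransitionTables, maps: MapSignals) -> FeatureBundle:
    """Assemble the 15 feature vectors from normalized tables and map signals.

    fv1-fv6: row-major flattenings of the normalized tables; fv8-fv13: raw
    count histograms of the map signals over bins 0 .. nc^2 - 1;
    fv7/fv14/fv15: concatenations.
    """
    if not tt.normalized:
        tt = normalize_tables(tt)
    nc = tt.nc
    nbins = nc * nc
    fv_tables = [t.ravel(order="C").copy() for t in tt.tables]
    fv_hists = []
    for m in maps.maps:
        if m.size and (m.min() < 0 or m.max() >= nbins):
            raise ValueError(f"map value out of range 0..{nbins - 1}")
        fv_hists.append(np.bincount(m, minlength=nbins).astype(float))
    fv7 = np.concatenate(fv_tables)
    fv14 = np.concatenate(fv_hists)
    fv15 = np.concatenate([fv7, fv14])
    return FeatureBundle(vectors=(*fv_tables, fv7, *fv_hists, fv14, fv15))


def extract_bundle(
    segment: EegSegment | np.ndarray,
    distance_mode: str = "absolute",
    epsilon: float = DEFAULT_EPSILON,
) -> FeatureBundle:
    """Full ChMinMaxPat pass over one segment."""
    tt, maps = accumulate(segment, distance_mode=distance_mode, epsilon=epsilon)
    return build_bundle(normalize_tables(tt), maps)


def extract_features(
    dataset: DatasetManifest | Iterable[EegSegment],
    distance_mode: str = "absolute",
    epsilon: float = DEFAULT_EPSILON,
    expected_channels: int | None = None,
) -> tuple[list[np.ndarray], list[str]]:
    """Extract all 15 feature matrices for a dataset.

    Accepts either a manifest (segment files are loaded from disk) or an
    iterable of in-memory segments.  Returns ``(matrices, segment_ids)``
    where ``matrices[k-1]`` is the n_segments x len(fv_k) matrix for feature
    vector ``k``, rows in dataset order.
    """
    bundles: list[FeatureBundle] = []
    ids: list[str] = []
    if isinstance(dataset, DatasetManifest):
        segments: Iterable[EegSegment] = (
            load_segment(
                dataset.resolve_path(str(row["segment_path"])),
                row,
                expected_channels=expected_channels,
            )
            for row in dataset.iter_rows()
        )
    else:
        segments = dataset
    for seg in segments:
        try:
            bundles.append(extract_bundle(seg, distance_mode=distance_mode, epsilon=epsilon))
        except ValueError as exc:
            raise ValueError(f"segment {seg.segment_id!r}: {exc}") from exc
        ids.append(seg.segment_id)
    if not bundles:
        raise ValueError("no segments to extract features from")
    matrices = [
        np.vstack([b.fv(k) for b in bundles]) for k in range(1, N_FEATURE_VECTORS + 1)
    ]
    return matrices, ids


def feature_lengths(nc: int) -> tuple[int, ...]:
    """Expected lengths of fv1..fv15 for an nc-channel montage."""
    single = nc * nc
    return (*(single,) * 6, 6 * single, *(single,) * 6, 6 * single, 12 * single)
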