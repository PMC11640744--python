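"""Directed Lobish (DLob): symbolic explanation of selected features.

Every ChMinMaxPat feature index encodes an ordered pair of channels (and,
inside a concatenated vector, which of the 12 constituent blocks it came
from).  A lookup table maps each channel to one of eight lobe/hemisphere
symbols — FL, TL, PL, OL (left frontal/temporal/parietal/occipital) and
OR, PR, TR, FR (right occipital/parietal/temporal/frontal).  Decoding the
selected feature indices in descending-weight order and emitting the two
channel symbols per feature yields one DLob string per feature vector;
symbol histograms, Shannon entropies (bits; at most log2 8 = 3) and 8x8
directed transition-count matrices summarize it for connectome-style
rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .selection import SelectionResult

ALPHABET = ("FL", "TL", "PL", "OL", "OR", "PR", "TR", "FR")
_SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}

#: Channel -> lobe symbols for the 14-channel montage
#: (AF3 F7 F3 FC5 | T7 | P7 | O1 | O2 | P8 | T8 | FC6 F4 F8 AF4).
DEFAULT_LUT_14 = (
    "FL", "FL", "FL", "FL", "TL", "PL", "OL",
    "OR", "PR", "TR", "FR", "FR", "FR", "FR",
)


def validate_lut(lut: Sequence[str], nc: int) -> tuple[str, ...]:
    lut = tuple(lut)
    if len(lut) != nc:
        raise ValueError(f"LUT has {len(lut)} entries for nc={nc} channels")
    bad = [s for s in lut if s not in _SYMBOL_INDEX]
    if bad:
        raise ValueError(f"LUT entries outside the DLob alphabet: {bad}")
    return lut


@dataclass(frozen=True, eq=False)
class DlobReport:
    """Symbolic summary of one selected feature vector."""

    string: tuple[str, ...]          # length 2*nf
    histogram: np.ndarray            # counts over the 8-symbol alphabet
    entropy: float                   # bits, in [0, 3]
    transitions: np.ndarray          # 8x8 directed transition counts


def decode_index(value: int, nc: int) -> tuple[int, int, int]:
    """Invert the map encoding of a 1-based feature index.

    Returns ``(first, second, table)`` with channels 1-based and ``table``
    in 1..12 identifying the constituent block inside the general
    concatenated vector.  Valid for any feature vector: an index into a
    single table/histogram vector (length nc^2) simply decodes to table 1.
    """
    nbins = nc * nc
    if not 1 <= value <= 12 * nbins:
        raise ValueError(f"feature index {value} out of range 1..{12 * nbins}")
    mul = (value - 1) // nbins
    rem = value - nbins * mul
    first = (rem - 1) // nc + 1
    second = (rem - 1) % nc + 1
    return first, second, mul + 1


def encode_pair(first: int, second: int, nc: int, table: int = 1) -> int:
    """The 1-based feature index of channel pair (first, second) in block ``table``."""
    if not (1 <= first <= nc and 1 <= second <= nc):
        raise ValueError("channel indices out of range")
    return (table - 1) * nc * nc + (first - 1) * nc + (second - 1) + 1


def build_string(
    sel: SelectionResult, nc: int, lut: Sequence[str] = DEFAULT_LUT_14
) -> tuple[str, ...]:
    """DLob string of a selection: two symbols per selected feature,
    in descending-weight order."""
    lut = validate_lut(lut, nc)
    symbols: list[str] = []
    for idx in sel.selected_indices:
        first, second, _ = decode_index(int(idx) + 1, nc)  # indices stored 0-based
        symbols.append(lut[first - 1])
        symbols.append(lut[second - 1])
    return tuple(symbols)


def symbol_histogram(string: Sequence[str]) -> np.ndarray:
    counts = np.zeros(len(ALPHABET), dtype=int)
    for s in string:
        try:
            counts[_SYMBOL_INDEX[s]] += 1
        except KeyError:
            raise ValueError(f"symbol {s!r} is not in the DLob alphabet") from None
    return counts


def string_entropy(string: Sequence[str]) -> float:
    """Shannon entropy (base 2) of the symbol distribution; at most 3 bits."""
    if len(string) == 0:
        raise ValueError("cannot compute the entropy of an empty string")
    counts = symbol_histogram(string)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def transition_matrix(string: Sequence[str]) -> np.ndarray:
    """8x8 directed counts of consecutive symbol pairs, in alphabet order."""
    T = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=int)
    idx = [_SYMBOL_INDEX[s] if s in _SYMBOL_INDEX else -1 for s in string]
    if any(i < 0 for i in idx):
        bad = string[idx.index(-1)]
        raise ValueError(f"symbol {bad!r} is not in the DLob alphabet")
    for a, b in zip(idx[:-1], idx[1:]):
        T[a, b] += 1
    return T


def report_one(sel: SelectionResult, nc: int, lut: Sequence[str] = DEFAULT_LUT_14) -> DlobReport:
    string = build_string(sel, nc, lut)
    return DlobReport(
        string=string,
        histogram=symbol_histogram(string),
        entropy=string_entropy(string),
        transitions=transition_matrix(string),
    )


def report(
    selections: Sequence[SelectionResult],
    nc: int,
    lut: Sequence[str] = DEFAULT_LUT_14,
) -> tuple[list[DlobReport], np.ndarray]:
    """Per-feature-vector DLob reports plus pooled symbol frequencies.

    The pooled vector is the sum of the per-report histograms (the
    aggregate lobe-usage profile across all feature vectors).
    """
    reports = [report_one(sel, nc, lut) for sel in selections]
    pooled = np.sum([r.histogram for r in reports], axis=0)
    return reports, pooled


def render_connectome(transitions: np.ndarray, out_path: str, lut_title: str = "") -> None:
    """Optional chord-style rendering of a transition matrix (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(ALPHABET)
    angles = 2 * np.pi * np.arange(n) / n
    xy = np.c_[np.cos(angles), np.sin(angles)]
    fig, ax = plt.subplots(figsize=(5, 5))
    maxw = transitions.max() or 1
    for i in range(n):
        for j in range(n):
            if transitions[i, j] > 0 and i != j:
                ax.annotate(
                    "", xy=xy[j], xytext=xy[i],
                    arrowprops=dict(
                        arrowstyle="-|>", alpha=0.3 + 0.7 * transitions[i, j] / maxw,
                        color="tab:blue",
                    ),
                )
    for i, sym in enumerate(ALPHABET):
        ax.text(*(1.12 * xy[i]), sym, ha="center", va="center", fontsize=11)
        ax.plot(*xy[i], "o", color="tab:gray")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    if lut_title:
        ax.set_title(lut_title)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
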