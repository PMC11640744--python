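"""End-to-end orchestration: extract -> select -> classify -> fuse -> explain.

``run_pipeline`` executes the whole self-organized pipeline on a dataset
manifest under one or more cross-validation schemes, writes every
intermediate artifact (selection results, per-feature-vector and fused
outcomes, metrics, DLob reports, a machine-readable run log) and returns
the results in memory.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import Outcome, fuse, tknn
from .dlob import DEFAULT_LUT_14, report as dlob_report, validate_lut
from .eeg_data import DatasetManifest, FoldPlan, make_folds
from .features import DEFAULT_EPSILON, N_FEATURE_VECTORS, extract_features
from .selection import SelectionResult, apply_selection, cumulative_select, nca_weights

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class MetricsReport:
    """Binary confusion counts and the four headline metrics.

    ``confusion`` rows are true (negative, positive), columns predicted
    (negative, positive).  Degenerate denominators yield NaN and the metric
    name is listed in ``undefined`` rather than being forced to 0.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    acc: float
    sen: float
    spe: float
    gm: float
    confusion: np.ndarray
    positive_class: int
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "acc": self.acc, "sen": self.sen, "spe": self.spe, "gm": self.gm,
            "confusion": self.confusion.tolist(),
            "positive_class": self.positive_class,
            "undefined": list(self.undefined),
        }


def compute_metrics(
    true_labels: np.ndarray, predicted_labels: np.ndarray, positive_class: int
) -> MetricsReport:
    """Accuracy, sensitivity, specificity and geometric mean for two classes.

    acc = (tp+tn)/n, sen = tp/(tp+fn), spe = tn/(fp+tn), gm = sqrt(sen*spe).
    """
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("true and predicted label vectors differ in length")
    classes = np.unique(np.concatenate([y, p]))
    if len(classes) > 2:
        raise ValueError(f"more than two classes present: {classes.tolist()}")
    pos = positive_class
    tp = int(np.sum((y == pos) & (p == pos)))
    fn = int(np.sum((y == pos) & (p != pos)))
    tn = int(np.sum((y != pos) & (p != pos)))
    fp = int(np.sum((y != pos) & (p == pos)))
    n = tp + fn + tn + fp
    undefined: list[str] = []
    acc = (tp + tn) / n if n else math.nan
    if tp + fn:
        sen = tp / (tp + fn)
    else:
        sen, undefined = math.nan, undefined + ["sen"]
    if fp + tn:
        spe = tn / (fp + tn)
    else:
        spe, undefined = math.nan, undefined + ["spe"]
    gm = math.sqrt(sen * spe) if not (math.isnan(sen) or math.isnan(spe)) else math.nan
    if math.isnan(gm):
        undefined.append("gm")
    confusion = np.array([[tn, fp], [fn, tp]])
    return MetricsReport(
        tp=tp, fn=fn, tn=tn, fp=fp, acc=acc, sen=sen, spe=spe, gm=gm,
        confusion=confusion, positive_class=pos, undefined=tuple(undefined),
    )


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults reproduce the method's published
    settings (absolute deviations, threshold 0.99, the full 60-cell kNN
    grid, 10-fold and leave-one-record-out CV)."""

    distance_mode: str = "absolute"
    epsilon: float = DEFAULT_EPSILON
    threshold: float = 0.99
    nca_sigma: float = 1.0
    nca_lambda: float | None = None
    nca_iters: int = 100
    nca_lr: float = 0.1
    cv_schemes: tuple[str, ...] = ("kfold",)
    n_folds: int = 10
    seed: int = 0
    lut: tuple[str, ...] | None = None  # None -> montage default (14 channels)
    positive_class: int | None = None   # None -> infer (non-control class)
    out_dir: str | Path | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["out_dir"] = str(d["out_dir"]) if d["out_dir"] is not None else None
        d["cv_schemes"] = list(self.cv_schemes)
        d["lut"] = list(self.lut) if self.lut is not None else None
        return d


@dataclass
class SchemeResult:
    """Per-CV-scheme classification results."""

    folds: FoldPlan
    fv_outcomes: list[Outcome]
    fused: Outcome
    metrics: MetricsReport


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    config: RunConfig
    segment_ids: list[str]
    labels: np.ndarray
    selections: list[SelectionResult]
    schemes: dict[str, SchemeResult]
    dlob_reports: list
    pooled_symbols: np.ndarray


def infer_positive_class(manifest: DatasetManifest) -> int:
    """The condition (non-control) class: if one class is named like
    'control', the other is positive; otherwise the larger label."""
    lo, hi = manifest.classes
    for lab, name in manifest.class_names.items():
        if str(name).strip().lower() in ("control", "ctrl", "baseline"):
            return hi if int(lab) == lo else lo
    return hi


def run_pipeline(cfg: RunConfig, manifest: DatasetManifest) -> PipelineResult:
    """Execute the full pipeline on a dataset.

    Stages: ChMinMaxPat extraction of the 15 feature matrices; per-matrix
    NCA weighting and cumulative-weight selection (selection is computed
    once on the full dataset, before CV, which is optimistic and is
    documented as such); per-matrix tkNN under each CV scheme; IMV fusion
    of the 15 outcomes; metrics; DLob reports from the selections.
    """
    stage = "extract"
    try:
        nc = _montage_width(manifest)
        matrices, segment_ids = extract_features(
            manifest, distance_mode=cfg.distance_mode, epsilon=cfg.epsilon
        )
        labels = manifest.labels

        stage = "select"
        selections: list[SelectionResult] = []
        selected: list[np.ndarray] = []
        for k, X in enumerate(matrices, start=1):
            w = nca_weights(
                X, labels, sigma=cfg.nca_sigma, lam=cfg.nca_lambda,
                iters=cfg.nca_iters, lr=cfg.nca_lr, seed=cfg.seed,
            )
            sel = cumulative_select(w, threshold=cfg.threshold)
            selections.append(sel)
            selected.append(apply_selection(X, sel))
            logger.info("fv%02d: selected %d of %d features", k, sel.nf, X.shape[1])

        stage = "classify"
        schemes: dict[str, SchemeResult] = {}
        pos = cfg.positive_class if cfg.positive_class is not None else infer_positive_class(manifest)
        for scheme in cfg.cv_schemes:
            folds = make_folds(manifest, scheme, n_folds=cfg.n_folds, seed=cfg.seed)
            fv_outcomes = [
                tknn(X, labels, folds, manifest) for X in selected
            ]
            fused = fuse(fv_outcomes, labels)
            metrics = compute_metrics(labels, fused.predictions, pos)
            schemes[scheme] = SchemeResult(
                folds=folds, fv_outcomes=fv_outcomes, fused=fused, metrics=metrics
            )
            logger.info("%s: fused accuracy %.4f (%s)", scheme, fused.accuracy, fused.provenance)

        stage = "explain"
        lut = validate_lut(cfg.lut, nc) if cfg.lut is not None else _default_lut(nc)
        reports, pooled = dlob_report(selections, nc, lut)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        config=cfg, segment_ids=segment_ids, labels=labels,
        selections=selections, schemes=schemes,
        dlob_reports=reports, pooled_symbols=pooled,
    )
    if cfg.out_dir is not None:
        write_results(result, Path(cfg.out_dir))
    return result


def _montage_width(manifest: DatasetManifest) -> int:
    from .eeg_data import load_segment

    row = next(manifest.iter_rows())
    seg = load_segment(manifest.resolve_path(str(row["segment_path"])), row)
    return seg.n_channels


def _default_lut(nc: int) -> tuple[str, ...]:
    if nc == len(DEFAULT_LUT_14):
        return DEFAULT_LUT_14
    raise ValueError(
        f"no default lobe LUT for nc={nc}; supply RunConfig.lut explicitly"
    )


# ---------------------------------------------------------------------------
# artifact output

def write_results(result: PipelineResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    (out_dir / "selection").mkdir(parents=True, exist_ok=True)
    (out_dir / "dlob").mkdir(exist_ok=True)
    for k, sel in enumerate(result.selections, start=1):
        pd.DataFrame(
            {"feature_index": np.arange(1, len(sel.weights) + 1), "weight": sel.weights}
        ).to_csv(out_dir / "selection" / f"fv{k:02d}_weights.csv", index=False)
        with open(out_dir / "selection" / f"fv{k:02d}_selection.json", "w") as fh:
            json.dump(
                {
                    "order": (sel.order + 1).tolist(),
                    "nf": sel.nf,
                    "threshold": sel.threshold,
                    "selected_indices": (sel.selected_indices + 1).tolist(),
                },
                fh, indent=1, sort_keys=True,
            )
    for scheme, sres in result.schemes.items():
        sdir = out_dir / "outcomes" / scheme
        sdir.mkdir(parents=True, exist_ok=True)
        for k, out in enumerate(sres.fv_outcomes, start=1):
            _write_outcome(out, result, sdir / f"fv{k:02d}_outcome.csv")
        _write_outcome(sres.fused, result, sdir / "fused_outcome.csv")
        with open(sdir / "candidates.json", "w") as fh:
            json.dump(
                {
                    f"fv{k:02d}": {"provenance": o.provenance, "accuracy": o.accuracy}
                    for k, o in enumerate(sres.fv_outcomes, start=1)
                }
                | {"fused": {"provenance": sres.fused.provenance,
                             "accuracy": sres.fused.accuracy}},
                fh, indent=1, sort_keys=True,
            )
        (out_dir / "metrics").mkdir(exist_ok=True)
        with open(out_dir / "metrics" / f"{scheme}_metrics.json", "w") as fh:
            json.dump(sres.metrics.to_dict(), fh, indent=1, sort_keys=True)
    with open(out_dir / "dlob" / "strings.txt", "w") as fh:
        for rep in result.dlob_reports:
            fh.write(" ".join(rep.string) + "\n")
    pd.DataFrame(
        {
            "fv": [f"fv{k:02d}" for k in range(1, len(result.dlob_reports) + 1)],
            "entropy_bits": [rep.entropy for rep in result.dlob_reports],
            "length": [len(rep.string) for rep in result.dlob_reports],
        }
    ).to_csv(out_dir / "dlob" / "entropies.csv", index=False)
    from .dlob import ALPHABET

    for k, rep in enumerate(result.dlob_reports, start=1):
        pd.DataFrame(rep.transitions, index=ALPHABET, columns=ALPHABET).to_csv(
            out_dir / "dlob" / f"fv{k:02d}_transitions.csv"
        )
    pd.DataFrame({"symbol": ALPHABET, "count": result.pooled_symbols}).to_csv(
        out_dir / "dlob" / "pooled_frequencies.csv", index=False
    )
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(
            {
                "config": result.config.to_dict(),
                "n_segments": len(result.segment_ids),
                "versions": {
                    "chminmaxpat": __version__,
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                    "python": platform.python_version(),
                },
            },
            fh, indent=1, sort_keys=True,
        )


def _write_outcome(outcome: Outcome, result: PipelineResult, path: Path) -> None:
    pd.DataFrame(
        {
            "segment_id": result.segment_ids,
            "true": result.labels,
            "predicted": outcome.predictions,
        }
    ).to_csv(path, index=False)
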