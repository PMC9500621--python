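"""File formats, run configuration and the end-to-end pipeline.

Box tables are CSV with header ``image_id,source,x_min,y_min,x_max,y_max``
(``source`` is a detector name, ``gold``, or a combiner name).  A detection
failure may be encoded either as a row with empty coordinate fields or by
omitting the (image_id, source) row; readers accept both, writers omit the
row.  Labels are CSV ``image_id,class_label``.  Edge maps are 8-bit
single-channel PNG/TIFF, normalized to [0, 1] on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .boxes import Box, ImageSize, make_box, rescale_box
from .combining import COMBINERS
from .edge_scoring import (
    DEFAULT_MAX_ITERATIONS,
    BinaryEdgeMap,
    EdgeMap,
    binarize_edge_map,
    intermode_threshold_info,
    normalize_edge_map,
)
from .metrics import GROUPS, EvalRecord, MetricsSummary, aggregate
from .preprocess import PreprocessConfig
from .selection import CandidateSet, select_roi

__all__ = [
    "RunConfig",
    "BOX_COLUMNS",
    "read_edge_map",
    "write_edge_map",
    "write_binary_edge_map",
    "read_box_table",
    "write_box_table",
    "candidate_sets",
    "gold_boxes",
    "read_labels",
    "write_labels",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

BOX_COLUMNS = ["image_id", "source", "x_min", "y_min", "x_max", "y_max"]

#: Detector listing order used throughout (also the selection tie-break order).
DEFAULT_MODEL_ORDER = ["faster_rcnn", "ssd", "efficientdet_d0", "centernet"]


@dataclass
class RunConfig:
    """Knobs of a pipeline run; defaults reproduce the four-detector setup."""

    model_order: list[str] = field(default_factory=lambda: list(DEFAULT_MODEL_ORDER))
    intermode_max_iterations: int = DEFAULT_MAX_ITERATIONS
    model_input_sizes: Optional[dict[str, tuple[int, int]]] = None  # (width, height)
    combiners: list[str] = field(default_factory=lambda: list(COMBINERS))
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.model_order:
            raise ValueError("model_order must be nonempty")
        if len(set(self.model_order)) != len(self.model_order):
            raise ValueError("model_order entries must be unique")
        unknown = set(self.combiners) - set(COMBINERS)
        if unknown:
            raise ValueError(f"unknown combiners: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        pp = data.pop("preprocess", None)
        cfg = cls(**data)
        if pp:
            cfg.preprocess = PreprocessConfig(**pp)
        if cfg.model_input_sizes:
            cfg.model_input_sizes = {
                k: (int(v[0]), int(v[1])) for k, v in cfg.model_input_sizes.items()
            }
        return cfg


# ---------------------------------------------------------------------------
# Images


def read_edge_map(path: str | Path) -> EdgeMap:
    """Read an 8-bit single-channel edge image and normalize it to [0, 1]."""
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        if raw.shape[2] >= 3 and (raw[..., :3] == raw[..., :1]).all():
            raw = raw[..., 0]  # grayscale stored as replicated RGB
        else:
            raise ValueError(f"{path}: expected a single-channel edge image")
    return normalize_edge_map(raw)


def write_edge_map(path: str | Path, raw: np.ndarray) -> None:
    """Write a raw 8-bit edge image."""
    raw = np.asarray(raw)
    if raw.dtype != np.uint8:
        if raw.min() < 0 or raw.max() > 255:
            raise ValueError("raw edge image values must lie in [0, 255]")
        raw = raw.astype(np.uint8)
    iio.imwrite(Path(path), raw)


def write_binary_edge_map(path: str | Path, bem: BinaryEdgeMap) -> None:
    """Write a binarized edge map as a 0/255 image for inspection."""
    iio.imwrite(Path(path), (bem.values * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# Box tables


def read_box_table(
    path: str | Path, expected_columns: Iterable[str] = BOX_COLUMNS
) -> dict[str, dict[str, Optional[Box]]]:
    """Read a box CSV/JSON into {image_id: {source: Box or None}}.

    Rows with all-empty coordinates mark detection failures.  Malformed rows
    raise an error naming the offending (1-based, header-inclusive) line.
    """
    path = Path(path)
    expected = list(expected_columns)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path, dtype={"image_id": str, "source": str})
    else:
        df = pd.read_csv(path, dtype={"image_id": str, "source": str})
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    coord_cols = ["x_min", "y_min", "x_max", "y_max"]
    out: dict[str, dict[str, Optional[Box]]] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header line + 1-based
        coords = [row[c] for c in coord_cols]
        blank = [pd.isna(v) for v in coords]
        if all(blank):
            box = None
        elif any(blank):
            raise ValueError(f"{path}:{line}: partially empty coordinates")
        else:
            try:
                box = make_box(*(int(v) for v in coords))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{line}: {exc}") from exc
        out.setdefault(str(row["image_id"]), {})[str(row["source"])] = box
    return out


def write_box_table(
    path: str | Path, rows: Iterable[tuple[str, str, Optional[Box]]]
) -> None:
    """Write (image_id, source, box) rows as CSV; failed detections are omitted."""
    data = [
        {
            "image_id": image_id,
            "source": source,
            "x_min": b.x_min,
            "y_min": b.y_min,
            "x_max": b.x_max,
            "y_max": b.y_max,
        }
        for image_id, source, b in rows
        if b is not None
    ]
    pd.DataFrame(data, columns=BOX_COLUMNS).to_csv(path, index=False)


def candidate_sets(
    table: Mapping[str, Mapping[str, Optional[Box]]],
    model_order: Iterable[str],
    size_manifest: Optional[Mapping[str, ImageSize]] = None,
) -> dict[str, CandidateSet]:
    """Arrange a box table into per-image CandidateSets in model order.

    Sources absent from ``model_order`` trigger a warning and are ignored.
    With a ``size_manifest`` ({image_id: ImageSize}), boxes are validated
    against their image frame, raising on out-of-frame boxes.
    """
    order = list(model_order)
    out: dict[str, CandidateSet] = {}
    for image_id, sources in table.items():
        unknown = set(sources) - set(order)
        if unknown:
            logger.warning(
                "image %s: ignoring unknown sources %s", image_id, sorted(unknown)
            )
        entries: dict[str, Optional[Box]] = {}
        for name in order:
            box = sources.get(name)
            if (
                box is not None
                and size_manifest is not None
                and image_id in size_manifest
                and not box.within(size_manifest[image_id])
            ):
                raise ValueError(
                    f"image {image_id}: box {box} from {name!r} exceeds "
                    f"the declared image size"
                )
            entries[name] = box
        out[image_id] = CandidateSet(image_id=image_id, entries=entries)
    return out


def gold_boxes(
    table: Mapping[str, Mapping[str, Optional[Box]]], source: str = "gold"
) -> dict[str, Box]:
    """Extract the gold box per image from a box table."""
    out = {}
    for image_id, sources in table.items():
        box = sources.get(source)
        if box is None:
            raise ValueError(f"image {image_id}: missing gold box")
        out[image_id] = box
    return out


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    missing = {"image_id", "class_label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["image_id"], df["class_label"]))


def write_labels(path: str | Path, labels: Mapping[str, str]) -> None:
    pd.DataFrame(
        [{"image_id": k, "class_label": v} for k, v in labels.items()]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline


def _summary_dict(s: MetricsSummary) -> dict:
    return {
        "n_images": s.n_images,
        "n_detected": s.n_detected,
        "detection_rate": s.detection_rate,
        "detection_rate_rounded": round(s.detection_rate),
        "precision_mean": s.precision_mean,
        "precision_sd": s.precision_sd,
        "recall_mean": s.recall_mean,
        "recall_sd": s.recall_sd,
        "f1_mean": s.f1_mean,
        "f1_sd": s.f1_sd,
    }


def run_pipeline(
    edge_dir: str | Path,
    candidates_path: str | Path,
    gold_path: str | Path,
    labels_path: str | Path,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
) -> dict:
    """Run selection + all combiners over a directory of images and evaluate.

    Per image: load the edge map, normalize, threshold and binarize once,
    rescale candidate boxes into the image frame when model input sizes are
    configured, apply edge-based selection and every configured combiner, and
    score each method (and each raw detector) against the gold box.  Writes
    ``predictions.csv``, ``scores.csv`` and ``report.json`` under ``out_dir``
    and returns the report dict.  Reruns are bit-identical.
    """
    config = config or RunConfig()
    edge_dir = Path(edge_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gold = gold_boxes(read_box_table(gold_path))
    cand_table = read_box_table(candidates_path)
    labels = read_labels(labels_path)
    candidates = candidate_sets(cand_table, config.model_order)

    missing_maps = sorted(
        image_id
        for image_id in candidates
        if not (edge_dir / f"{image_id}.png").exists()
        and not (edge_dir / f"{image_id}.tif").exists()
    )
    if missing_maps:
        raise FileNotFoundError(
            f"missing edge maps for images: {', '.join(missing_maps)}"
        )

    methods = (
        ["edge_selection"] + list(config.combiners) + list(config.model_order)
    )
    records: dict[str, list[EvalRecord]] = {m: [] for m in methods}
    prediction_rows: list[tuple[str, str, Optional[Box]]] = []
    score_rows: list[dict] = []
    counters = {"intermode_fallback": 0, "empty_intersection": 0, "all_failed": 0}

    for image_id in sorted(gold):
        path = edge_dir / f"{image_id}.png"
        if not path.exists():
            path = edge_dir / f"{image_id}.tif"
        em = read_edge_map(path)
        label = labels[image_id]
        cand = candidates.get(
            image_id, CandidateSet(image_id, {m: None for m in config.model_order})
        )
        if config.model_input_sizes:
            entries = {}
            for name, box in cand.entries.items():
                if box is not None and name in config.model_input_sizes:
                    w, h = config.model_input_sizes[name]
                    box = rescale_box(box, ImageSize(w, h), em.size)
                entries[name] = box
            cand = CandidateSet(image_id, entries)

        threshold, used_fallback = intermode_threshold_info(
            em, max_iterations=config.intermode_max_iterations
        )
        if used_fallback:
            counters["intermode_fallback"] += 1
        bem = binarize_edge_map(em, threshold)
        result = select_roi(em, cand, bem=bem)
        if result.selected_model is None:
            counters["all_failed"] += 1
        logger.info(
            "image %s: threshold=%.4f selected=%s",
            image_id,
            threshold,
            result.selected_model,
        )
        for name, score in result.scores.items():
            score_rows.append(
                {
                    "image_id": image_id,
                    "model": name,
                    "S": score.S,
                    "D": score.D,
                    "SD": score.SD,
                }
            )

        predictions: dict[str, Optional[Box]] = {"edge_selection": result.selected_box}
        for comb in config.combiners:
            box = COMBINERS[comb](cand)
            if comb == "intersection" and box is None and cand.present():
                counters["empty_intersection"] += 1
            predictions[comb] = box
        for name in config.model_order:
            predictions[name] = cand.entries.get(name)

        for method, box in predictions.items():
            records[method].append(
                EvalRecord.from_boxes(image_id, label, gold[image_id], box)
            )
            prediction_rows.append((image_id, method, box))

    write_box_table(out_dir / "predictions.csv", prediction_rows)
    pd.DataFrame(score_rows).to_csv(out_dir / "scores.csv", index=False)

    report = {
        "methods": {
            method: {
                group: _summary_dict(aggregate(recs, group))
                for group in GROUPS
                if any(group == "all" or r.class_label == group for r in recs)
            }
            for method, recs in records.items()
        },
        "counters": counters,
        "n_images": len(gold),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
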