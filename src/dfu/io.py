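"""Readers and writers for the package's small text formats.

Histograms travel as JSON ``{"scale": [...], "freqs": [...]}`` or as CSV
with one row per histogram (columns ``f1..fK``, optionally preceded by a
``histogram_id`` and followed by a ``gold`` column).  Annotation records
and scored items are plain CSVs with required, named columns; ordinal
scales live in small YAML/JSON files rather than code.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .annotations import AnnotationRecord
from .core import Histogram, OrdinalScale, _generic_scale

__all__ = [
    "load_scale",
    "histogram_to_json",
    "histogram_from_json",
    "read_histograms_csv",
    "read_annotations_csv",
    "read_scores_csv",
]


def load_scale(path: str | Path) -> OrdinalScale:
    """Read an ordinal scale from a YAML/JSON file.

    Accepts either a bare list of category names (in increasing order)
    or a mapping with a ``labels`` key.
    """
    data = yaml.safe_load(Path(path).read_text())
    labels = data["labels"] if isinstance(data, dict) else data
    if not isinstance(labels, list):
        raise ValueError(f"{path}: expected a list of labels or a 'labels' key")
    return OrdinalScale(tuple(str(x) for x in labels))


def histogram_to_json(h: Histogram) -> str:
    return json.dumps({"scale": list(h.scale.labels), "freqs": list(h.freqs)})


def histogram_from_json(text: str) -> Histogram:
    data = json.loads(text)
    return Histogram(data["freqs"], OrdinalScale(tuple(data["scale"])))


def _freq_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    cols.sort(key=lambda c: int(c[1:]))
    if len(cols) < 2:
        raise ValueError(
            f"no f1..fK frequency columns found (columns: {list(df.columns)})"
        )
    expected = [f"f{i}" for i in range(1, len(cols) + 1)]
    if cols != expected:
        raise ValueError(f"frequency columns must be contiguous f1..fK, got {cols}")
    return cols


def read_histograms_csv(path: str | Path,
                        counts: bool = False,
                        scale: OrdinalScale | None = None,
                        ) -> tuple[pd.DataFrame, list[Histogram]]:
    """Read one histogram per row from columns f1..fK.

    ``counts=True`` treats the cells as raw counts and normalises.
    Returns the raw frame (for id/gold columns) and the histograms.
    """
    df = pd.read_csv(path)
    fcols = _freq_columns(df)
    scale = scale or _generic_scale(len(fcols))
    hs = []
    for idx, row in df.iterrows():
        vals = row[fcols].astype(float).tolist()
        try:
            h = (Histogram.from_counts(vals, scale) if counts
                 else Histogram(vals, scale))
        except ValueError as e:
            raise ValueError(f"{path} row {idx}: {e}") from None
        hs.append(h)
    return df, hs


def read_annotations_csv(path: str | Path) -> list[AnnotationRecord]:
    """Read annotation records: columns item_id, rater_id, label[, country]."""
    df = pd.read_csv(path, dtype=str)
    missing = {"item_id", "rater_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    has_country = "country" in df.columns
    return [
        AnnotationRecord(
            item_id=row.item_id,
            rater_id=row.rater_id,
            label=row.label,
            country=(row.country if has_country and pd.notna(row.country) else None),
        )
        for row in df.itertuples()
    ]


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    """Read scored items: columns item_id, date[, region], score."""
    df = pd.read_csv(path)
    missing = {"item_id", "date", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df["score"] = df["score"].astype(float)
    return df
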