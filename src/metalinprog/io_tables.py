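"""Readers and writers for count tables, label files, models and reports.

Count tables are plain UTF-8 TSV: one header row of feature names, first
column the sample identifier, one row per sample.  The mothur ``.shared``
dialect (columns ``label``, ``Group``, ``numOtus``, then one column per OTU)
is also accepted; the ``Group`` column becomes the sample identifier.
Reports and fitted models are serialized as versioned JSON at full double
precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FORMAT_VERSION = 1


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


class AlignmentError(ValueError):
    """Sample identifiers in the label file and count table disagree."""


@dataclass
class CountTable:
    """An n x m matrix of nonnegative integer read counts.

    Rows are samples, columns are features (OTUs, taxa or pathways);
    ``counts[i, j]`` is the number of reads of feature j in sample i.
    """

    samples: list[str]
    features: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if n < 2 or m < 1:
            raise ValueError(f"count table must be at least 2x1, got {n}x{m}")
        if len(self.samples) != n or len(self.features) != m:
            raise ValueError("identifier lists do not match count matrix shape")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.features)) != m:
            raise ValueError("duplicate feature identifiers")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.samples[i]!r}, "
                f"feature {self.features[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]


@dataclass
class LabelSet:
    """Per-sample class labels over c >= 2 ordered categories."""

    sample_ids: list[str]
    labels: list[str]
    classes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        if self.classes is None:
            # first-appearance order; every class trivially has >= 1 sample
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.classes = list(seen)
        # an explicit class catalogue may name classes absent from this
        # (possibly subset) label list; fitting re-validates presence
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels not in class list: {sorted(unknown)}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


def _validate_numeric_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    """Convert a feature frame to integer counts, naming any bad cell."""
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[np.argmax(bad.to_numpy())]
            raise ParseError(
                f"{path}: non-numeric count at sample {row!r}, feature {col!r}"
            )
        if (converted < 0).any():
            row = df.index[np.argmax((converted < 0).to_numpy())]
            raise ParseError(
                f"{path}: negative count at sample {row!r}, feature {col!r}"
            )
        frac = np.mod(converted.to_numpy(dtype=float), 1.0)
        if np.any(frac != 0):
            row = df.index[int(np.argmax(frac != 0))]
            raise ParseError(
                f"{path}: non-integer count at sample {row!r}, feature {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=np.int64)
    return values


def read_count_table(path: str | Path, dialect: str = "plain_tsv") -> CountTable:
    """Read a count table from ``path``.

    dialect ``plain_tsv``: header of feature names, first column sample id.
    dialect ``mothur_shared``: mothur .shared layout; if the file holds
    several ``label`` blocks (distance cutoffs) only the first is kept.
    """
    path = Path(path)
    if dialect == "plain_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        samples = [str(s) for s in df.index]
        features = [str(f) for f in df.columns]
    elif dialect == "mothur_shared":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["label", "Group", "numOtus"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing mothur columns {missing}")
        first_label = df["label"].iloc[0]
        df = df[df["label"] == first_label]
        otu_cols = [c for c in df.columns if c not in required]
        declared = pd.to_numeric(df["numOtus"], errors="coerce")
        if declared.isna().any() or (declared != len(otu_cols)).any():
            raise ParseError(
                f"{path}: numOtus does not match the {len(otu_cols)} OTU columns"
            )
        samples = [str(s) for s in df["Group"]]
        features = otu_cols
        df = df[otu_cols].set_axis(samples, axis=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample identifiers {dupes}")
    counts = _validate_numeric_frame(df, str(path))
    return CountTable(samples=samples, features=features, counts=counts)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as plain TSV (round-trips with read_count_table)."""
    df = pd.DataFrame(table.counts, index=table.samples, columns=table.features)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_labels(path: str | Path) -> LabelSet:
    """Read a two-column TSV (sample id, class label); no header row."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    if df.isna().any().any():
        row = int(np.argmax(df.isna().any(axis=1).to_numpy()))
        raise ParseError(f"{path}: missing field on line {row + 1}")
    return LabelSet(sample_ids=list(df[0]), labels=list(df[1]))


def write_labels(labels: LabelSet, path: str | Path) -> None:
    pd.DataFrame({0: labels.sample_ids, 1: labels.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def align_labels(table: CountTable, labels: LabelSet) -> LabelSet:
    """Reorder ``labels`` to match ``table.samples``; alignment is by id.

    Raises AlignmentError listing every unmatched sample on either side.
    """
    by_id = dict(zip(labels.sample_ids, labels.labels))
    missing = [s for s in table.samples if s not in by_id]
    extra = [s for s in labels.sample_ids if s not in set(table.samples)]
    if missing or extra:
        raise AlignmentError(
            f"label/count mismatch: counts lack labels for {missing}; "
            f"labels name unknown samples {extra}"
        )
    return LabelSet(
        sample_ids=list(table.samples),
        labels=[by_id[s] for s in table.samples],
        classes=list(labels.classes),
    )


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__type__": type(obj).__name__,
            **{
                f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(report, path: str | Path) -> None:
    """Serialize any report dataclass (or plain dict) as versioned JSON.

    Numeric fields keep full double precision (repr round-trip).
    """
    payload = {"format_version": FORMAT_VERSION, "report": _to_jsonable(report)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def read_report(path: str | Path) -> dict:
    """Read a report back as a plain dict (the ``report`` payload)."""
    payload = json.loads(Path(path).read_text())
    if "format_version" not in payload:
        raise ParseError(f"{path}: not a metalinprog report (no format_version)")
    return payload["report"]


def write_model(model, path: str | Path) -> None:
    """Serialize a fitted model (Binary or Multiclass) as JSON."""
    write_report(model, path)


def read_model(path: str | Path):
    """Deserialize a model written by :func:`write_model`."""
    from . import models  # local import: io has no model logic

    payload = read_report(path)
    kind = payload.pop("__type__", None)
    if kind == "BinaryModel":
        cls = models.BinaryModel
    elif kind == "MulticlassModel":
        cls = models.MulticlassModel
    else:
        raise ParseError(f"{path}: unknown model type {kind!r}")
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in payload.items() if k in names}
    for key in ("beta", "beta0", "B"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    return cls(**kwargs)
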