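"""Building the pedagogical label table from heterogeneous source datasets.

Three public fundus-photograph collections annotate disease in three
dialects: per-eye diagnostic *keywords* (ODIR style), one-hot *condition
columns* (RFMID style), and single *category names* (JSIEC style).  An
expert-authored rule table maps each dialect's raw vocabulary onto the
common fine classes C0–C38; classes left with fewer than 50 images are then
removed, and the surviving multilabel records are split into train and test
sets with iterative multilabel stratification.

A deterministic synthetic generator emits source tables in all three
dialects with configurable class weights and label co-occurrence, so the
whole pipeline is exercisable without downloading any real dataset.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from collections import Counter
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DIALECTS",
    "SourceLabelTable",
    "MappingRule",
    "LabelledImageRecord",
    "load_mapping_rules",
    "published_class_counts",
    "apply_mapping",
    "filter_small_classes",
    "split_train_test",
    "synth_source_tables",
    "records_to_frame",
    "write_resident_csv",
    "read_resident_csv",
]

DIALECTS = ("odir", "rfmid", "jsiec")


def _norm(label: str) -> str:
    """Exact matching after lowercasing and whitespace normalisation."""
    return " ".join(label.lower().split())


@dataclass(frozen=True)
class MappingRule:
    dialect: str
    raw_label: str
    target: str  # fine class code C0..C38


@dataclass
class SourceLabelTable:
    """A raw label table in one source dialect."""

    dialect: str
    rows: List[Tuple[str, List[str]]]  # (image_id, raw labels)

    def __post_init__(self):
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        ids = [r[0] for r in self.rows]
        if len(ids) != len(set(ids)):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate image ids in {self.dialect} table: {dup[:5]}")

    def to_csv(self, path) -> None:
        """Write the table in its dialect's native CSV shape."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            if self.dialect == "odir":
                w.writerow(["image_id", "keywords"])
                for image_id, labels in self.rows:
                    w.writerow([image_id, ";".join(labels)])
            elif self.dialect == "jsiec":
                w.writerow(["image_id", "category"])
                for image_id, labels in self.rows:
                    (label,) = labels  # single-category dialect
                    w.writerow([image_id, label])
            else:  # rfmid: one-hot columns
                columns = sorted({l for _, labels in self.rows for l in labels})
                w.writerow(["image_id", *columns])
                for image_id, labels in self.rows:
                    present = set(labels)
                    w.writerow([image_id, *[int(c in present) for c in columns]])

    @classmethod
    def from_csv(cls, path, dialect: str) -> "SourceLabelTable":
        df = pd.read_csv(path, dtype=str).fillna("")
        rows: List[Tuple[str, List[str]]] = []
        if dialect == "odir":
            for _, r in df.iterrows():
                labels = [k for k in r["keywords"].split(";") if k]
                rows.append((r["image_id"], labels))
        elif dialect == "jsiec":
            rows = [(r["image_id"], [r["category"]]) for _, r in df.iterrows()]
        elif dialect == "rfmid":
            cols = [c for c in df.columns if c != "image_id"]
            for _, r in df.iterrows():
                rows.append((r["image_id"], [c for c in cols if r[c] == "1"]))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        return cls(dialect=dialect, rows=rows)


@dataclass
class LabelledImageRecord:
    image_id: str
    source: str
    labels: frozenset
    split: str = "unassigned"  # train | test | unassigned


def load_mapping_rules(path=None) -> List[MappingRule]:
    """Load the dialect->fine-class rule table (default: packaged file)."""
    if path is None:
        text = resources.files("retinacoach.data").joinpath(
            "mapping_rules.csv").read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    rules = []
    seen = set()
    for row in csv.DictReader(io.StringIO(text)):
        key = (row["dialect"], _norm(row["raw_label"]))
        if key in seen:
            raise ValueError(f"duplicate mapping rule {key}")
        seen.add(key)
        rules.append(MappingRule(row["dialect"], row["raw_label"], row["target"]))
    return rules


def published_class_counts() -> pd.DataFrame:
    """Published per-class train/test supports of the curated dataset.

    Returns a frame indexed by fine class code with columns ``train``,
    ``test`` and ``total``; it doubles as the realistic class-frequency
    profile for the synthetic generator.
    """
    text = resources.files("retinacoach.data").joinpath(
        "class_counts.csv").read_text(encoding="utf-8")
    df = pd.read_csv(io.StringIO(text)).set_index("code")
    df["total"] = df["train"] + df["test"]
    return df


def apply_mapping(table: SourceLabelTable,
                  rules: Sequence[MappingRule] | None = None,
                  ) -> List[LabelledImageRecord]:
    """Map a source table's raw labels to fine classes.

    Unmapped raw labels are dropped; rows whose mapped label set is empty
    are excluded entirely (an image must belong to at least one selected
    class to enter the curated dataset).
    """
    if rules is None:
        rules = load_mapping_rules()
    lookup = {(r.dialect, _norm(r.raw_label)): r.target for r in rules}
    if not any(d == table.dialect for d, _ in lookup):
        raise ValueError(f"rules do not cover dialect {table.dialect!r}")
    out = []
    for image_id, raw_labels in table.rows:
        mapped = {
            lookup[(table.dialect, _norm(raw))]
            for raw in raw_labels
            if (table.dialect, _norm(raw)) in lookup
        }
        if mapped:
            out.append(LabelledImageRecord(image_id=image_id,
                                           source=table.dialect,
                                           labels=frozenset(mapped)))
    return out


def filter_small_classes(
    records: Sequence[LabelledImageRecord], min_count: int = 50
) -> Tuple[List[LabelledImageRecord], List[str]]:
    """Drop classes with fewer than ``min_count`` images.

    Removed classes disappear from every label set; records left with no
    labels are excluded.  Returns the surviving records and the sorted
    retained-class list.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(c for r in records for c in r.labels)
    retained = {c for c, n in counts.items() if n >= min_count}
    out = []
    for r in records:
        kept = r.labels & retained
        if kept:
            out.append(replace(r, labels=frozenset(kept)))
    return out, sorted(retained, key=lambda c: (len(c), c))


def split_train_test(
    records: Sequence[LabelledImageRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> List[LabelledImageRecord]:
    """Assign train/test splits by iterative multilabel stratification.

    Labels are processed rarest first; each image goes to the split whose
    remaining demand for that label is largest (ties: larger overall
    remaining demand, then a seeded coin).  Deterministic given the seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    records = list(records)
    counts = Counter(c for r in records for c in r.labels)
    small = [c for c, n in counts.items() if n < 2]
    if small:
        warnings.warn(
            f"classes with < 2 images cannot be stratified: {sorted(small)}"
        )
    fractions = {"train": train_fraction, "test": 1.0 - train_fraction}
    # remaining per-split demand for each label, and overall
    demand = {s: {c: n * fractions[s] for c, n in counts.items()}
              for s in ("train", "test")}
    overall = {s: len(records) * fractions[s] for s in ("train", "test")}
    assigned: Dict[int, str] = {}
    unassigned = set(range(len(records)))

    def label_pool(label):
        return [i for i in unassigned if label in records[i].labels]

    while unassigned:
        remaining_counts = Counter(
            c for i in unassigned for c in records[i].labels
        )
        if remaining_counts:
            label = min(remaining_counts, key=lambda c: (remaining_counts[c], c))
            pool = label_pool(label)
        else:  # records with no labels cannot occur post-curation; guard anyway
            label, pool = None, sorted(unassigned)
        for i in sorted(pool):
            keys = {}
            for s in ("train", "test"):
                lab_demand = demand[s][label] if label is not None else 0.0
                keys[s] = (lab_demand, overall[s], rng.random())
            choice = max(("train", "test"), key=lambda s: keys[s])
            assigned[i] = choice
            unassigned.discard(i)
            overall[choice] -= 1.0
            for c in records[i].labels:
                demand[choice][c] -= 1.0
    return [replace(r, split=assigned[i]) for i, r in enumerate(records)]


# ---------------------------------------------------------------------------
# synthetic source tables

# raw vocabulary used when rendering a fine class in each dialect; derived
# from the packaged rule table (first matching rule per class wins)
def _dialect_vocab(rules: Sequence[MappingRule]) -> Dict[str, Dict[str, str]]:
    vocab: Dict[str, Dict[str, str]] = {d: {} for d in DIALECTS}
    for r in rules:
        vocab[r.dialect].setdefault(r.target, r.raw_label)
    return vocab


def synth_source_tables(
    n_images: int,
    class_weights: Mapping[str, float] | None = None,
    co_occurrence: float = 0.15,
    seed: int = 0,
) -> Dict[str, SourceLabelTable]:
    """Generate one synthetic source table per dialect.

    Each image draws a primary class from ``class_weights`` (default: the
    published class-frequency profile), is attributed to a dialect that can
    express that class, and with probability ``co_occurrence`` receives a
    second co-occurring class (never in the single-category JSIEC dialect).
    Deterministic given the seed.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rules = load_mapping_rules()
    vocab = _dialect_vocab(rules)
    if class_weights is None:
        totals = published_class_counts()["total"]
        class_weights = (totals / totals.sum()).to_dict()
    classes = sorted(class_weights, key=lambda c: (len(c), c))
    w = np.asarray([class_weights[c] for c in classes], dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("class weights must sum to 1")
    rng = np.random.default_rng(seed)
    rows: Dict[str, List[Tuple[str, List[str]]]] = {d: [] for d in DIALECTS}
    for i in range(n_images):
        primary = classes[rng.choice(len(classes), p=w)]
        candidates = [d for d in DIALECTS if primary in vocab[d]]
        dialect = candidates[rng.integers(len(candidates))]
        labels = {primary}
        if dialect != "jsiec" and rng.random() < co_occurrence:
            extra = classes[rng.choice(len(classes), p=w)]
            if extra in vocab[dialect]:
                labels.add(extra)
        raw = [vocab[dialect][c] for c in sorted(labels, key=lambda c: (len(c), c))]
        rows[dialect].append((f"{dialect}_{i:06d}", raw))
    return {d: SourceLabelTable(dialect=d, rows=rows[d]) for d in DIALECTS}


# ---------------------------------------------------------------------------
# curated-table round trip

def records_to_frame(records: Sequence[LabelledImageRecord]) -> pd.DataFrame:
    """Curated records as a 0/1-encoded DataFrame (one column per class)."""
    classes = sorted({c for r in records for c in r.labels},
                     key=lambda c: (len(c), c))
    data = {
        "image_id": [r.image_id for r in records],
        "source": [r.source for r in records],
        "split": [r.split for r in records],
    }
    for c in classes:
        data[c] = [int(c in r.labels) for r in records]
    return pd.DataFrame(data)


def write_resident_csv(records: Sequence[LabelledImageRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_resident_csv(path) -> List[LabelledImageRecord]:
    df = pd.read_csv(path)
    classes = [c for c in df.columns if c not in ("image_id", "source", "split")]
    return [
        LabelledImageRecord(
            image_id=str(r["image_id"]),
            source=str(r["source"]),
            labels=frozenset(c for c in classes if r[c] == 1),
            split=str(r["split"]),
        )
        for _, r in df.iterrows()
    ]
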