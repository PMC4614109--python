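"""Data containers, activity curation, and delimited-text I/O.

A QSAR dataset is a compounds x descriptors table of real-valued molecular
descriptors plus a per-compound activity annotation.  Activity is encoded
with the class codes 1 (active) and 2 (inactive); optionally each compound
carries a pIC50 potency (-log10 of the half-maximal inhibitory
concentration, in molar units) from which classes are derived by removing
compounds of intermediate potency.

The CSV dialect is fixed: comma-separated, UTF-8, ``.`` decimal, mandatory
header row, one ID column, one label (or pIC50) column, every remaining
column a numeric descriptor.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    CurationError,
    DuplicateCompoundError,
    MissingColumnError,
    ModelFormatError,
    NonNumericCellError,
    StandardizationError,
    UnknownLabelError,
)

logger = logging.getLogger(__name__)

ACTIVE = 1
INACTIVE = 2

MODEL_FORMAT = "elm-model/1"
DATASET_LABEL_COLUMN = "CLASS"
DATASET_PIC50_COLUMN = "PIC50"


@dataclass
class DescriptorMatrix:
    """A compounds x descriptors matrix with named rows and columns.

    Parameters
    ----------
    compound_ids : list of str
        Unique compound identifiers, one per row.
    descriptor_names : list of str
        Unique descriptor names, one per column.
    values : ndarray of shape (n_compounds, n_descriptors)
        Finite real descriptor values.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.compound_ids) != n:
            raise ValueError(
                f"{len(self.compound_ids)} compound IDs for {n} rows"
            )
        if len(self.descriptor_names) != p:
            raise ValueError(
                f"{len(self.descriptor_names)} descriptor names for {p} columns"
            )
        if len(set(self.compound_ids)) != n:
            raise DuplicateCompoundError("compound IDs are not unique")
        if len(set(self.descriptor_names)) != p:
            raise ValueError("descriptor names are not unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise NonNumericCellError(
                f"non-finite value at compound {self.compound_ids[r]!r}, "
                f"descriptor {self.descriptor_names[c]!r}"
            )

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def subset(self, names: list[str]) -> "DescriptorMatrix":
        """Return a new matrix restricted to ``names``, in that order."""
        index = {d: j for j, d in enumerate(self.descriptor_names)}
        missing = [d for d in names if d not in index]
        if missing:
            raise MissingColumnError(f"descriptors not in matrix: {missing}")
        cols = [index[d] for d in names]
        return DescriptorMatrix(
            list(self.compound_ids), list(names), self.values[:, cols].copy()
        )

    def take_rows(self, rows: np.ndarray) -> "DescriptorMatrix":
        rows = np.asarray(rows)
        return DescriptorMatrix(
            [self.compound_ids[i] for i in rows],
            list(self.descriptor_names),
            self.values[rows].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.descriptor_names
        )


@dataclass
class LabeledDataset:
    """A descriptor matrix with class codes and optional pIC50 values."""

    matrix: DescriptorMatrix
    labels: np.ndarray
    pic50: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.matrix.n_compounds,):
            raise ValueError("one label per compound is required")
        bad = set(np.unique(self.labels)) - {ACTIVE, INACTIVE}
        if bad:
            raise UnknownLabelError(f"labels outside {{1, 2}}: {sorted(bad)}")
        if self.pic50 is not None:
            self.pic50 = np.asarray(self.pic50, dtype=float)
            if self.pic50.shape != (self.matrix.n_compounds,):
                raise ValueError("one pIC50 per compound is required")

    @property
    def n_compounds(self) -> int:
        return self.matrix.n_compounds

    @property
    def y(self) -> np.ndarray:
        """Class codes as a float vector (the regression response)."""
        return self.labels.astype(float)

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == ACTIVE)), int(np.sum(self.labels == INACTIVE))

    def take(self, rows: np.ndarray) -> "LabeledDataset":
        rows = np.asarray(rows)
        return LabeledDataset(
            self.matrix.take_rows(rows),
            self.labels[rows].copy(),
            None if self.pic50 is None else self.pic50[rows].copy(),
        )

    def subset_descriptors(self, names: list[str]) -> "LabeledDataset":
        return LabeledDataset(
            self.matrix.subset(names),
            self.labels.copy(),
            None if self.pic50 is None else self.pic50.copy(),
        )


@dataclass(frozen=True)
class CurationRule:
    """Potency window whose interior is discarded as intermediate activity.

    Compounds with ``low < pIC50 < high`` are removed; pIC50 >= ``high`` is
    active, pIC50 <= ``low`` is inactive.  Boundary values are kept.
    """

    low: float = 5.0
    high: float = 6.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"low ({self.low}) must be < high ({self.high})")


def _parse_label_token(token: object) -> int:
    """Map a class-mode label cell to 1/2."""
    if isinstance(token, str):
        t = token.strip().lower()
        if t == "active":
            return ACTIVE
        if t == "inactive":
            return INACTIVE
        try:
            token = float(t)
        except ValueError:
            raise UnknownLabelError(f"unknown label token {token!r}") from None
    value = float(token)  # type: ignore[arg-type]
    if value == ACTIVE:
        return ACTIVE
    if value == INACTIVE:
        return INACTIVE
    raise UnknownLabelError(f"unknown label code {token!r} (expected 1 or 2)")


def load_dataset(
    path: str,
    label_column: str = DATASET_LABEL_COLUMN,
    id_column: Optional[str] = None,
    label_kind: str = "class",
    permissive: bool = False,
) -> LabeledDataset:
    """Load a descriptor table from CSV.

    Parameters
    ----------
    path : str
        CSV file with a header row.
    label_column : str
        Column holding 1/2 codes or "active"/"inactive" strings
        (``label_kind="class"``) or pIC50 reals (``label_kind="pic50"``).
    id_column : str, optional
        Compound-ID column; the first column by default.
    label_kind : {"class", "pic50"}
        How to interpret the label column.  In pIC50 mode the returned
        dataset has no class labels applied yet beyond a provisional
        thresholding at the window midpoint; run
        :func:`curate_by_activity` to derive final labels.
    permissive : bool
        Drop (and log) descriptor columns containing non-finite cells
        instead of raising.
    """
    frame = pd.read_csv(path, header=0, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise MissingColumnError("CSV needs an ID column and a label column")
    if id_column is None:
        id_column = frame.columns[0]
    for col in (id_column, label_column):
        if col not in frame.columns:
            raise MissingColumnError(f"column {col!r} not found in {path}")

    ids = [str(v) for v in frame[id_column]]
    if len(set(ids)) != len(ids):
        dupes = sorted({v for v in ids if ids.count(v) > 1})
        raise DuplicateCompoundError(f"duplicate compound IDs: {dupes[:5]}")

    label_cells = frame[label_column].tolist()
    # the reserved annotation columns this module itself writes are never
    # descriptors, so a saved dataset reloads cleanly in either label mode
    reserved = {DATASET_LABEL_COLUMN, DATASET_PIC50_COLUMN}
    descriptor_cols = [
        c
        for c in frame.columns
        if c not in (id_column, label_column) and c not in reserved
    ]
    if not descriptor_cols:
        raise MissingColumnError("no descriptor columns in input")

    # pd.to_numeric locates unparseable/non-finite cells; the kept columns
    # are then converted with numpy, whose parsing is correctly rounded
    # (exact round-trip of 17-significant-digit decimal text)
    raw = frame[descriptor_cols]
    coerced = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    finite = np.isfinite(coerced)
    if not finite.all():
        if permissive:
            bad_cols = [
                descriptor_cols[j]
                for j in range(coerced.shape[1])
                if not finite[:, j].all()
            ]
            logger.warning(
                "dropping %d descriptor column(s) with non-numeric cells: %s",
                len(bad_cols),
                bad_cols,
            )
            descriptor_cols = [c for c in descriptor_cols if c not in set(bad_cols)]
            if not descriptor_cols:
                raise NonNumericCellError("every descriptor column has bad cells")
        else:
            r, c = np.argwhere(~finite)[0]
            raise NonNumericCellError(
                f"non-numeric descriptor cell at row {ids[r]!r}, "
                f"column {descriptor_cols[c]!r}"
            )
    values = frame[descriptor_cols].to_numpy(dtype=str).astype(float)

    matrix = DescriptorMatrix(ids, descriptor_cols, values)

    if label_kind == "class":
        labels = np.array([_parse_label_token(t) for t in label_cells])
        return LabeledDataset(matrix, labels)
    if label_kind == "pic50":
        try:
            pic50 = np.array([float(t) for t in label_cells])
        except ValueError as exc:
            raise UnknownLabelError(f"non-numeric pIC50 cell: {exc}") from None
        if not np.all(np.isfinite(pic50)):
            raise UnknownLabelError("non-finite pIC50 value")
        rule = CurationRule()
        provisional = np.where(
            pic50 >= (rule.low + rule.high) / 2.0, ACTIVE, INACTIVE
        )
        return LabeledDataset(matrix, provisional, pic50)
    raise ValueError(f"label_kind must be 'class' or 'pic50', got {label_kind!r}")


def save_dataset(dataset: LabeledDataset, path: str) -> None:
    """Write a dataset back to the fixed CSV dialect (inverse of load)."""
    frame = dataset.matrix.to_frame()
    frame.insert(0, DATASET_LABEL_COLUMN, dataset.labels)
    if dataset.pic50 is not None:
        frame.insert(1, DATASET_PIC50_COLUMN, dataset.pic50)
    frame.index.name = "COMPOUND"
    frame.to_csv(path, float_format="%.17g")


@dataclass
class CurationReport:
    n_input: int
    n_removed: int
    n_active: int
    n_inactive: int
    rule: CurationRule

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_active": self.n_active,
            "n_inactive": self.n_inactive,
            "low": self.rule.low,
            "high": self.rule.high,
        }


def curate_by_activity(
    dataset: LabeledDataset, rule: CurationRule = CurationRule()
) -> tuple[LabeledDataset, CurationReport]:
    """Remove intermediate-potency compounds and relabel the rest.

    Compounds with pIC50 strictly inside ``(rule.low, rule.high)`` are
    discarded; the remainder are labeled active (pIC50 >= high) or
    inactive (pIC50 <= low).
    """
    if dataset.pic50 is None:
        raise CurationError("curation requires pIC50 values for every compound")
    pic50 = dataset.pic50
    keep = (pic50 <= rule.low) | (pic50 >= rule.high)
    n_removed = int(np.sum(~keep))
    if not keep.any():
        raise CurationError("curation removed every compound")
    kept = dataset.take(np.flatnonzero(keep))
    labels = np.where(kept.pic50 >= rule.high, ACTIVE, INACTIVE)
    n_active = int(np.sum(labels == ACTIVE))
    n_inactive = int(np.sum(labels == INACTIVE))
    if n_active == 0 or n_inactive == 0:
        raise CurationError(
            f"one class empty after curation (active={n_active}, "
            f"inactive={n_inactive})"
        )
    curated = LabeledDataset(kept.matrix, labels, kept.pic50)
    report = CurationReport(
        dataset.n_compounds, n_removed, n_active, n_inactive, rule
    )
    logger.info(
        "curation: %d in, %d removed, %d active, %d inactive",
        report.n_input, report.n_removed, report.n_active, report.n_inactive,
    )
    return curated, report


@dataclass
class Standardizer:
    """Per-descriptor z-score statistics fitted on training data.

    Zero-variance descriptors are excluded at fit time (a constant column
    has no least-squares slope and would divide by zero); their names are
    recorded in ``dropped_names``.
    """

    descriptor_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped_names: list[str] = field(default_factory=list)

    def transform(self, matrix: DescriptorMatrix) -> DescriptorMatrix:
        sub = matrix.subset(self.descriptor_names)
        return DescriptorMatrix(
            sub.compound_ids,
            sub.descriptor_names,
            (sub.values - self.means) / self.sds,
        )

    def inverse_transform(self, matrix: DescriptorMatrix) -> DescriptorMatrix:
        sub = matrix.subset(self.descriptor_names)
        return DescriptorMatrix(
            sub.compound_ids,
            sub.descriptor_names,
            sub.values * self.sds + self.means,
        )


def standardize(
    matrix: DescriptorMatrix,
) -> tuple[DescriptorMatrix, Standardizer]:
    """Z-score every descriptor column (mean 0, sample sd 1).

    Returns the transformed matrix and the fitted :class:`Standardizer`.
    Columns with zero sample variance are excluded and reported on the
    standardizer.
    """
    if matrix.n_compounds < 2:
        raise StandardizationError("standardization needs at least 2 compounds")
    means = matrix.values.mean(axis=0)
    sds = matrix.values.std(axis=0, ddof=1)
    keep = sds > 0.0
    if not keep.any():
        raise StandardizationError("all descriptor columns are constant")
    dropped = [d for d, k in zip(matrix.descriptor_names, keep) if not k]
    if dropped:
        logger.info("excluding %d constant descriptor(s): %s", len(dropped), dropped)
    names = [d for d, k in zip(matrix.descriptor_names, keep) if k]
    stats = Standardizer(names, means[keep], sds[keep], dropped)
    return stats.transform(matrix), stats


# --- model serialization -------------------------------------------------
#
# Flat key<TAB>value text; list-valued fields are JSON-encoded on one line.
# repr() of Python floats round-trips exactly (17 significant digits).


def save_model(model, path: str) -> None:
    """Serialize an ELMModel to versioned flat text (lossless round-trip)."""
    if len(model.descriptor_names) == 0:
        raise ModelFormatError("refusing to save a model with no descriptors")
    lines = [
        f"format\t{MODEL_FORMAT}",
        f"descriptor_names\t{json.dumps(model.descriptor_names)}",
        f"weights\t{json.dumps([float(w) for w in model.weights])}",
        f"threshold\t{float(model.threshold)!r}",
        f"threshold_mode\t{model.threshold_mode}",
        f"class_encoding\tactive=1,inactive=2",
        f"std_means\t{json.dumps([float(v) for v in model.standardizer.means])}",
        f"std_sds\t{json.dumps([float(v) for v in model.standardizer.sds])}",
        f"std_dropped\t{json.dumps(model.standardizer.dropped_names)}",
        f"seed\t{json.dumps(model.seed)}",
        f"config\t{json.dumps(model.config, sort_keys=True)}",
        "end\t.",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path: str):
    """Read a model file written by :func:`save_model`."""
    from .elm_core import ELMModel  # local import avoids a cycle

    fields: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if "\t" not in line:
                raise ModelFormatError(f"malformed line in model file: {line!r}")
            key, value = line.split("\t", 1)
            fields[key] = value
    if fields.get("format") != MODEL_FORMAT:
        raise ModelFormatError(
            f"unsupported model format {fields.get('format')!r}"
        )
    if "end" not in fields:
        raise ModelFormatError("model file is truncated (no end marker)")
    try:
        names = json.loads(fields["descriptor_names"])
        weights = np.array(json.loads(fields["weights"]), dtype=float)
        threshold = float(fields["threshold"])
        mode = fields["threshold_mode"]
        std = Standardizer(
            names,
            np.array(json.loads(fields["std_means"]), dtype=float),
            np.array(json.loads(fields["std_sds"]), dtype=float),
            json.loads(fields["std_dropped"]),
        )
        seed = json.loads(fields["seed"])
        config = json.loads(fields["config"])
    except (KeyError, ValueError) as exc:
        raise ModelFormatError(f"corrupted model file: {exc}") from None
    if len(weights) != len(names) or len(names) == 0:
        raise ModelFormatError("model file fields are inconsistent")
    if not (np.all(np.isfinite(weights)) and math.isfinite(threshold)):
        raise ModelFormatError("model file holds non-finite parameters")
    return ELMModel(
        descriptor_names=names,
        weights=weights,
        threshold=threshold,
        threshold_mode=mode,
        standardizer=std,
        seed=seed,
        config=config,
    )
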