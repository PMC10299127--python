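"""Reading parcellated ROI time series and phenotype labels; persisting channel stacks.

Time-series tables follow the ABIDE-preprocessed ``.1D`` convention: plain
whitespace- or tab-delimited numeric text, one row per timepoint and one
column per ROI, with an optional single header row.  Channel stacks are
stored in HDF5 (dataset ``"stack"``) with string attributes identifying
subject, atlas, connectivity method and stacking strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ATLAS_ROIS",
    "FormatError",
    "RoiTimeSeries",
    "PhenotypeTable",
    "read_timeseries",
    "write_timeseries",
    "read_phenotype",
    "write_phenotype",
    "write_stack",
    "read_stack",
]

#: ROI counts for parcellations with a registry entry.  Unknown atlas names
#: are accepted with any column count.
ATLAS_ROIS: dict[str, int] = {
    "AAL": 116,
    "Dosenbach": 161,
    "CC200": 200,
}

#: Accepted phenotype label tokens, normalized to {"case", "control"}.
#: Numeric codes follow the ABIDE convention (1 = case, 2 = control).
LABEL_TOKENS: dict[str, str] = {
    "1": "case",
    "asd": "case",
    "case": "case",
    "autistic": "case",
    "2": "control",
    "control": "control",
    "td": "control",
}


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class RoiTimeSeries:
    """One subject's parcellated signal table of shape T x N."""

    subject_id: str
    atlas: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(f"time series must be 2-D, got shape {self.data.shape}")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise FormatError(f"need T >= 2 and N >= 2, got T={t}, N={n}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("time series contains missing or non-finite values")
        expected = ATLAS_ROIS.get(self.atlas)
        if expected is not None and n != expected:
            raise FormatError(
                f"atlas {self.atlas!r} declares {expected} ROIs but table has {n} columns"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class PhenotypeTable:
    """Mapping subject_id -> binary diagnostic label ("case" / "control")."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"case", "control"}
        if bad:
            raise FormatError(f"labels must be 'case' or 'control', got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, subject_id: str) -> str:
        return self.labels[subject_id]

    def items(self):
        return self.labels.items()


def _is_numeric_row(tokens: list[str]) -> bool:
    try:
        for tok in tokens:
            float(tok)
    except ValueError:
        return False
    return True


def read_timeseries(path: str | Path, atlas: str, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a delimited time-series table.

    A single leading header row is auto-detected (any non-numeric token).
    Errors name the 1-based offending line.
    """
    path = Path(path)
    rows: list[list[float]] = []
    n_cols: int | None = None
    with open(path) as fh:
        lines = fh.readlines()
    # header detection: a non-numeric first non-blank line is skipped
    start = 0
    for i, line in enumerate(lines):
        tokens = line.split()
        if not tokens:
            continue
        if not _is_numeric_row(tokens):
            start = i + 1
        break
    for lineno, line in enumerate(lines[start:], start=start + 1):
        tokens = line.split()
        if not tokens:
            continue  # blank (trailing) lines are ignored
        if not _is_numeric_row(tokens):
            raise FormatError(f"{path}: non-numeric value on line {lineno}")
        values = [float(t) for t in tokens]
        if any(not np.isfinite(v) for v in values):
            raise FormatError(f"{path}: non-finite value on line {lineno}")
        if n_cols is None:
            n_cols = len(values)
        elif len(values) != n_cols:
            raise FormatError(
                f"{path}: ragged row on line {lineno} "
                f"({len(values)} columns, expected {n_cols})"
            )
        rows.append(values)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    expected = ATLAS_ROIS.get(atlas)
    if expected is not None and n_cols != expected:
        raise FormatError(
            f"{path}: atlas {atlas!r} declares {expected} ROIs, table has {n_cols} columns"
        )
    sid = subject_id if subject_id is not None else path.stem
    return RoiTimeSeries(subject_id=sid, atlas=atlas, data=np.array(rows, dtype=float))


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.data, delimiter="\t", fmt="%.10g")


def read_phenotype(path: str | Path) -> PhenotypeTable:
    """Read a CSV with ``subject_id`` and ``label`` columns."""
    df = pd.read_csv(path, dtype=str)
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    labels: dict[str, str] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"]).strip()
        if sid in labels:
            raise FormatError(f"{path}: duplicate subject_id {sid!r}")
        token = str(row["label"]).strip().lower()
        if token not in LABEL_TOKENS:
            raise FormatError(
                f"{path}: unknown label {row['label']!r} for {sid!r}; "
                f"accepted tokens: {sorted(set(LABEL_TOKENS))}"
            )
        labels[sid] = LABEL_TOKENS[token]
    return PhenotypeTable(labels=labels)


def write_phenotype(table: PhenotypeTable, path: str | Path) -> None:
    pd.DataFrame(
        [(sid, lab) for sid, lab in table.items()],
        columns=["subject_id", "label"],
    ).to_csv(path, index=False)


def write_stack(stack, path: str | Path) -> None:
    """Persist a channel stack to HDF5 (lossless round-trip)."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("stack", data=np.asarray(stack.channels, dtype=np.float64))
        ds.attrs["subject_id"] = stack.subject_id
        ds.attrs["atlas"] = stack.atlas
        ds.attrs["method"] = stack.method
        ds.attrs["strategy"] = stack.strategy


def read_stack(path: str | Path):
    import h5py

    from .enhance import Stack3D

    with h5py.File(path, "r") as fh:
        if "stack" not in fh:
            raise FormatError(f"{path}: missing dataset 'stack'")
        ds = fh["stack"]
        arr = np.asarray(ds[...], dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] != arr.shape[1]:
            raise FormatError(
                f"{path}: expected an N x N x 3 stack, got shape {arr.shape}"
            )
        return Stack3D(
            subject_id=str(ds.attrs["subject_id"]),
            atlas=str(ds.attrs["atlas"]),
            method=str(ds.attrs["method"]),
            strategy=str(ds.attrs["strategy"]),
            channels=arr,
        )
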