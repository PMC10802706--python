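"""On-disk artifacts and the packaged 53-ROI / 7-network parcellation.

Time courses are headerless CSV/TSV matrices (time in rows, ROIs in
columns) with a JSON sidecar carrying the repetition time and scan
identifiers.  Behavioral tables are delimited text with a header row.
The parcellation table ships with the package and fixes the canonical
ROI order used by every downstream matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

NETWORKS = ("SC", "AUD", "SM", "VS", "CC", "DM", "CB")
NETWORK_SIZES = {"SC": 5, "AUD": 2, "SM": 9, "VS": 9, "CC": 17, "DM": 7, "CB": 4}
N_ROIS = 53


class ParcellationError(RuntimeError):
    """Packaged parcellation resource failed its integrity check."""


class TimecourseParseError(ValueError):
    """A time-course matrix contains a non-numeric or non-finite cell."""


class DimensionError(ValueError):
    """Matrix shape inconsistent with the parcellation."""


class SchemaError(ValueError):
    """Behavioral table is missing a required column."""


class NestingError(ValueError):
    """A family identifier spans more than one site."""


@dataclass(frozen=True)
class ParcellationMeta:
    """ROI -> functional-network lookup for the fixed 53-ROI parcellation."""

    table: pd.DataFrame

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> pd.Series:
        return self.table["network"]

    def rois_in(self, network: str) -> np.ndarray:
        """Indices of the ROIs belonging to one functional network."""
        return self.table.index[self.table["network"] == network].to_numpy()

    def network_counts(self) -> dict:
        return self.table["network"].value_counts().to_dict()


@dataclass
class RoiTimecourse:
    """One scan's T x R matrix of ROI activation time courses."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    scan_id: str = ""
    session_id: str = ""
    motion: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError(f"time course must be 2-D, got {self.data.ndim}-D")
        if not np.isfinite(self.data).all():
            t, r = np.argwhere(~np.isfinite(self.data))[0]
            raise TimecourseParseError(
                f"non-finite value at row {t}, column {r} of time course"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.n_timepoints, 6):
                raise DimensionError(
                    f"motion must be T x 6, got {self.motion.shape}"
                )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimecourse":
        """Copy of this scan with the data matrix replaced."""
        return RoiTimecourse(
            data=data,
            tr_seconds=self.tr_seconds,
            subject_id=self.subject_id,
            scan_id=self.scan_id,
            session_id=self.session_id,
            motion=None if self.motion is None else self.motion.copy(),
        )


@dataclass
class BehaviorTable:
    """Per-subject scores, covariates and the site/family grouping."""

    table: pd.DataFrame
    cognitive_scores: list = field(default_factory=list)
    psychiatric_scores: list = field(default_factory=list)

    REQUIRED = ("subject_id", "site_id", "family_id", "age", "gender", "race",
                "height", "weight")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"behavior table missing required columns: {missing}")
        if self.table["subject_id"].duplicated().any():
            raise SchemaError("duplicate subject_id in behavior table")
        if self.table[["site_id", "family_id"]].isna().any().any():
            raise SchemaError("site_id/family_id must be non-missing")
        sites_per_family = self.table.groupby("family_id")["site_id"].nunique()
        bad = sites_per_family[sites_per_family > 1]
        if len(bad):
            raise NestingError(
                f"families spanning multiple sites: {list(bad.index[:5])}"
            )
        for c in ("gender", "race", "site_id", "family_id"):
            self.table[c] = self.table[c].astype("category")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def score_columns(self) -> list:
        return list(self.cognitive_scores) + list(self.psychiatric_scores)


def load_parcellation() -> ParcellationMeta:
    """Load the packaged 53-ROI, 7-network parcellation table.

    ROI labels are generic per-network placeholders; the network
    partition (SC=5, AUD=2, SM=9, VS=9, CC=17, DM=7, CB=4) is the
    computational contract and is verified on every load.
    """
    with resources.files("dfcstates.data").joinpath("parcellation53.csv").open() as fh:
        table = pd.read_csv(fh)
    expected_cols = {"roi_index", "roi_label", "network"}
    if set(table.columns) != expected_cols:
        raise ParcellationError(f"unexpected columns {set(table.columns)}")
    if len(table) != N_ROIS:
        raise ParcellationError(f"expected {N_ROIS} ROIs, found {len(table)}")
    if not (table["roi_index"].to_numpy() == np.arange(N_ROIS)).all():
        raise ParcellationError("roi_index must be 0..52 in order")
    counts = table["network"].value_counts().to_dict()
    if counts != NETWORK_SIZES:
        raise ParcellationError(f"network counts {counts} != {NETWORK_SIZES}")
    return ParcellationMeta(table=table.set_index("roi_index", drop=False))


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_timecourse(
    path, sidecar, parcellation: Optional[ParcellationMeta] = None
) -> RoiTimecourse:
    """Read a headerless delimited T x R matrix plus its JSON sidecar."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    try:
        data = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise TimecourseParseError(f"{path}: {exc}") from exc
    with open(sidecar) as fh:
        meta = json.load(fh)
    motion = None
    if "motion_path" in meta:
        motion = np.loadtxt(Path(sidecar).parent / meta["motion_path"],
                            delimiter=delim, ndmin=2)
    tc = RoiTimecourse(
        data=data,
        tr_seconds=float(meta["tr_seconds"]),
        subject_id=str(meta.get("subject_id", "")),
        scan_id=str(meta.get("scan_id", "")),
        session_id=str(meta.get("session_id", "")),
        motion=motion,
    )
    if parcellation is not None and tc.n_rois != parcellation.n_rois:
        raise DimensionError(
            f"{path}: {tc.n_rois} columns but parcellation has "
            f"{parcellation.n_rois} ROIs"
        )
    return tc


def write_timecourse(tc: RoiTimecourse, path, sidecar) -> None:
    """Write a time course as headerless CSV plus JSON sidecar."""
    np.savetxt(path, tc.data, delimiter=",", fmt="%.17g")
    meta = {
        "tr_seconds": tc.tr_seconds,
        "subject_id": tc.subject_id,
        "scan_id": tc.scan_id,
        "session_id": tc.session_id,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_behavior(path, cognitive_scores=None, psychiatric_scores=None) -> BehaviorTable:
    """Read the per-subject behavioral/covariate table (CSV with header).

    Score columns are auto-detected by prefix (``nihtbx_`` cognitive,
    ``cbcl_`` psychiatric) unless given explicitly.  Missing score
    values are kept as NaN — flagged downstream, never dropped here.
    """
    table = pd.read_csv(path, delimiter=_sniff_delimiter(Path(path)))
    if cognitive_scores is None:
        cognitive_scores = [c for c in table.columns if c.startswith("nihtbx_")]
    if psychiatric_scores is None:
        psychiatric_scores = [c for c in table.columns if c.startswith("cbcl_")]
    return BehaviorTable(
        table=table,
        cognitive_scores=list(cognitive_scores),
        psychiatric_scores=list(psychiatric_scores),
    )


def write_behavior(bt: BehaviorTable, path) -> None:
    bt.table.to_csv(path, index=False)
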