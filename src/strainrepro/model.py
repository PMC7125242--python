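"""Study data model and segmental-to-global strain aggregation.

The left ventricle is partitioned on the standard AHA 17-segment model with
the apical cap (segment 17) excluded, leaving 16 segments: 1-6 basal, 7-12
mid-ventricular, 13-16 apical.  A global strain value (GLS, GCS or GRS) is
the unweighted mean of the 16 segmental values; when each observer analyses
the images twice, the two replicate readings are averaged before anything
else.  Datasets are tidy long-format tables, one row per
(animal, state, component, segment, observer, replicate) reading, with the
strain value in percent.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_SEGMENTS = 16

#: Canonical long-format dataset columns.
DATASET_COLUMNS = [
    "animal_id",
    "state",
    "component",
    "segment_id",
    "observer_id",
    "replicate",
    "value",
]

#: Columns identifying a unique reading.
KEY_COLUMNS = DATASET_COLUMNS[:-1]

#: Global-strain output columns (after replicate averaging).
GLOBAL_COLUMNS = ["animal_id", "state", "component", "observer_id", "value"]


class State(str, enum.Enum):
    """Inotropic state: baseline, dobutamine (hyper-), verapamil (hypo-contractility)."""

    BL = "BL"
    Dob = "Dob"
    Ver = "Ver"


class Component(str, enum.Enum):
    """Strain direction; globals are conventionally GLS/GCS <= 0, GRS >= 0."""

    longitudinal = "longitudinal"
    circumferential = "circumferential"
    radial = "radial"


class Region(str, enum.Enum):
    basal = "basal"
    mid = "mid"
    apical = "apical"


#: Short global-strain labels per component.
GLOBAL_LABEL = {
    Component.longitudinal: "GLS",
    Component.circumferential: "GCS",
    Component.radial: "GRS",
}


class DatasetError(ValueError):
    """Malformed or incomplete strain dataset."""


def segment_region(segment_id: int) -> Region:
    """Map an AHA segment id (1-16) to its ventricular level."""
    if not 1 <= int(segment_id) <= N_SEGMENTS:
        raise ValueError(
            f"segment_id must be in 1..{N_SEGMENTS} (apical cap 17 excluded), got {segment_id}"
        )
    if segment_id <= 6:
        return Region.basal
    if segment_id <= 12:
        return Region.mid
    return Region.apical


@dataclass(frozen=True)
class StrainMeasurement:
    """One segmental strain reading, in percent."""

    animal_id: str
    state: State
    component: Component
    segment_id: int
    observer_id: str
    replicate: int
    value: float

    def __post_init__(self) -> None:
        segment_region(self.segment_id)  # range check
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if not math.isfinite(self.value):
            raise ValueError(f"strain value must be finite, got {self.value}")

    @property
    def region(self) -> Region:
        return segment_region(self.segment_id)


def average_replicates(readings: Sequence[float]) -> float:
    """Arithmetic mean of one cell's replicate readings.

    A single replicate is returned unchanged; an empty list signals a missing
    cell and raises :class:`DatasetError`.
    """
    values = np.asarray(readings, dtype=float)
    if values.size == 0:
        raise DatasetError("no replicate readings for this cell")
    if not np.all(np.isfinite(values)):
        raise DatasetError("non-finite replicate reading")
    return float(values.mean())


def aggregate_global(
    segment_values: Mapping[int, float],
    policy: str = "strict",
    min_segments: int = 12,
) -> float:
    """Unweighted mean of segmental values -> one global strain value.

    ``policy='strict'`` (default) requires all 16 segments and raises a
    :class:`DatasetError` naming the missing ones; ``policy='lenient'``
    accepts partial coverage down to ``min_segments``.  The mean is taken
    per segment (each of the 16 segments weighs equally), not per
    basal/mid/apical level.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")
    segments = sorted(segment_values)
    for seg in segments:
        segment_region(seg)  # range check
    missing = sorted(set(range(1, N_SEGMENTS + 1)) - set(segments))
    if policy == "strict" and missing:
        raise DatasetError(f"missing segments under strict policy: {missing}")
    if policy == "lenient" and len(segments) < min_segments:
        raise DatasetError(
            f"only {len(segments)} segments present, lenient policy requires >= {min_segments}"
        )
    values = np.asarray([segment_values[s] for s in segments], dtype=float)
    if not np.all(np.isfinite(values)):
        raise DatasetError("non-finite segmental value")
    return float(values.mean())


def _coerce_tokens(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    bad_state = set(out["state"].unique()) - {s.value for s in State}
    if bad_state:
        raise DatasetError(f"unknown state token(s): {sorted(bad_state)}")
    bad_comp = set(out["component"].unique()) - {c.value for c in Component}
    if bad_comp:
        raise DatasetError(f"unknown component token(s): {sorted(bad_comp)}")
    try:
        out["segment_id"] = out["segment_id"].astype(int)
        out["replicate"] = out["replicate"].astype(int)
        out["value"] = out["value"].astype(float)
    except (TypeError, ValueError) as exc:
        raise DatasetError(f"non-numeric segment_id/replicate/value: {exc}") from exc
    out["animal_id"] = out["animal_id"].astype(str)
    out["observer_id"] = out["observer_id"].astype(str)
    return out


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format dataset; returns a typed copy.

    Checks column presence, state/component tokens, segment range (the
    apical cap, segment 17, is rejected), finite values, replicate >= 1 and
    uniqueness of the reading key.
    """
    missing_cols = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"missing column(s): {missing_cols}")
    out = _coerce_tokens(df[DATASET_COLUMNS])
    bad_seg = out.loc[~out["segment_id"].between(1, N_SEGMENTS), "segment_id"].unique()
    if bad_seg.size:
        raise DatasetError(
            f"segment_id out of range 1..{N_SEGMENTS}: {sorted(bad_seg.tolist())}"
        )
    if (out["replicate"] < 1).any():
        raise DatasetError("replicate must be >= 1")
    if not np.isfinite(out["value"]).all():
        raise DatasetError("non-finite strain value in dataset")
    dup = out.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        raise DatasetError(
            f"{int(dup.sum())} duplicate reading key(s), e.g. "
            f"{out.loc[dup, KEY_COLUMNS].iloc[0].to_dict()}"
        )
    return out


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a long-format strain CSV (UTF-8, comma, header)."""
    df = pd.read_csv(path)
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a validated long-format strain CSV (round-trips with read_dataset)."""
    validate_dataset(df).to_csv(path, index=False)


def records_to_frame(records: Iterable[StrainMeasurement]) -> pd.DataFrame:
    rows = [
        (r.animal_id, r.state.value, r.component.value, r.segment_id,
         r.observer_id, r.replicate, r.value)
        for r in records
    ]
    return validate_dataset(pd.DataFrame(rows, columns=DATASET_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[StrainMeasurement]:
    df = validate_dataset(df)
    return [
        StrainMeasurement(
            animal_id=row.animal_id,
            state=State(row.state),
            component=Component(row.component),
            segment_id=int(row.segment_id),
            observer_id=row.observer_id,
            replicate=int(row.replicate),
            value=float(row.value),
        )
        for row in df.itertuples(index=False)
    ]


def _warn_sign_convention(globals_df: pd.DataFrame) -> None:
    # GLS/GCS are shortening (negative), GRS thickening (positive); violations
    # are plausible in noisy or synthetic data, so warn rather than reject.
    shortening = globals_df["component"].isin(
        [Component.longitudinal.value, Component.circumferential.value]
    )
    n_bad = int((shortening & (globals_df["value"] > 0)).sum())
    n_bad += int((~shortening & (globals_df["value"] < 0)).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} global strain value(s) violate the usual sign convention "
            "(GLS/GCS <= 0, GRS >= 0)",
            UserWarning,
            stacklevel=3,
        )


def aggregate_dataset(
    df: pd.DataFrame,
    *,
    average_over_replicates: bool = True,
    policy: str = "strict",
    min_segments: int = 12,
) -> pd.DataFrame:
    """Aggregate segmental readings to global strain values.

    Replicates are averaged per segment first (the study's convention), then
    segments are averaged to the global value; the two orders commute because
    both are means over a fixed index set.  With
    ``average_over_replicates=False`` the replicate column is kept, yielding
    one global value per (animal, state, component, observer, replicate) —
    the form needed for intra-observer (replicate 1 vs replicate 2) analysis.
    """
    df = validate_dataset(df)
    group_cols = ["animal_id", "state", "component", "observer_id"]
    if not average_over_replicates:
        group_cols = group_cols + ["replicate"]
    else:
        df = (
            df.groupby(group_cols + ["segment_id"], as_index=False, sort=True)["value"]
            .mean()
        )
    rows = []
    for key, grp in df.groupby(group_cols, sort=True):
        seg_map = dict(zip(grp["segment_id"], grp["value"]))
        if len(seg_map) != len(grp):
            raise DatasetError(f"duplicate segment within cell {key}")
        value = aggregate_global(seg_map, policy=policy, min_segments=min_segments)
        rows.append((*key, value))
    out = pd.DataFrame(rows, columns=group_cols + ["value"])
    _warn_sign_convention(out)
    return out
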