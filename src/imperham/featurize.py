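"""Assemble per-sample feature vectors from media-panel attributes.

Column labels follow the grammar ``<medium_name>|<attribute_id>`` (attribute
ids 1..18), media-major, so a selection result is portable across runs.  The
conformer-delta correction re-expresses each group's rows (and target) as
deviations from its lowest-energy member; the solvation mode instead appends
the sample's solvent dielectric constant as one extra column and applies no
delta treatment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_io import ConformerGroup
from .engines import ATTRIBUTE_NAMES, EnergyAttributes, Medium

__all__ = ["FeatureMatrix", "assemble", "delta_correct", "add_solvation_context"]

DIELECTRIC_COLUMN = "solvent_dielectric"


@dataclass
class FeatureMatrix:
    """Samples x labelled feature columns, with optional group metadata."""

    sample_ids: list[str]
    columns: list[str]
    values: np.ndarray
    group_ids: list[str] | None = None
    reference_flags: list[bool] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.columns)} columns"
            )
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column labels")
        if self.group_ids is not None and len(self.group_ids) != len(self.sample_ids):
            raise ValueError("group_ids length mismatch")
        if self.reference_flags is not None:
            if len(self.reference_flags) != len(self.sample_ids):
                raise ValueError("reference_flags length mismatch")
            if self.group_ids is not None:
                per_group: dict[str, int] = {}
                for g, r in zip(self.group_ids, self.reference_flags):
                    per_group[g] = per_group.get(g, 0) + bool(r)
                bad = {g: c for g, c in per_group.items() if c != 1}
                if bad:
                    raise ValueError(f"groups without exactly one reference: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column_index(self, label: str) -> int:
        try:
            return self.columns.index(label)
        except ValueError:
            raise KeyError(f"no column {label!r}") from None

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.column_index(label)]

    def subset_columns(self, labels: Sequence[str]) -> "FeatureMatrix":
        idx = [self.column_index(c) for c in labels]
        return replace(self, columns=list(labels), values=self.values[:, idx])

    def drop_column(self, label: str) -> "FeatureMatrix":
        keep = [c for c in self.columns if c != label]
        if len(keep) == len(self.columns):
            raise KeyError(f"no column {label!r}")
        return self.subset_columns(keep)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "sample_id", self.sample_ids)
        if self.group_ids is not None:
            df["group_id"] = self.group_ids
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = [c for c in ("sample_id", "group_id") if c in df.columns]
        feature_cols = [c for c in df.columns if c not in meta]
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            columns=feature_cols,
            values=df[feature_cols].to_numpy(dtype=float),
            group_ids=[str(g) for g in df["group_id"]] if "group_id" in df else None,
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_dataframe(pd.read_csv(path))


def column_label(medium_name: str, attribute_id: int) -> str:
    return f"{medium_name}|{attribute_id}"


def split_label(label: str) -> tuple[str, int | None]:
    """Return (medium, attribute_id); the dielectric column has no attribute."""
    if label == DIELECTRIC_COLUMN:
        return (DIELECTRIC_COLUMN, None)
    medium, attr = label.rsplit("|", 1)
    return medium, int(attr)


def assemble(
    panel_results: Mapping[str, Mapping[str, EnergyAttributes]],
    media: Sequence[Medium],
    attributes: Sequence[int] | None = None,
    group_ids: Mapping[str, str] | None = None,
) -> FeatureMatrix:
    """Build the representation pool: one row per sample, media-major columns.

    ``panel_results`` maps sample_id -> medium name -> attributes; every
    sample must cover every requested medium.  Values are copied without
    transformation.
    """
    attributes = list(attributes) if attributes is not None else list(range(1, 19))
    for a in attributes:
        if a not in ATTRIBUTE_NAMES:
            raise ValueError(f"unknown attribute id {a}")
    sample_ids = list(panel_results)
    columns = [column_label(m.name, a) for m in media for a in attributes]
    values = np.empty((len(sample_ids), len(columns)))
    for i, sid in enumerate(sample_ids):
        per_medium = panel_results[sid]
        j = 0
        for m in media:
            if m.name not in per_medium:
                raise KeyError(f"sample {sid!r} has no result for medium {m.name!r}")
            attrs = per_medium[m.name]
            for a in attributes:
                values[i, j] = attrs[a]
                j += 1
    gids = [group_ids[s] for s in sample_ids] if group_ids is not None else None
    return FeatureMatrix(sample_ids, columns, values, group_ids=gids)


def delta_correct(
    fm: FeatureMatrix,
    groups: Sequence[ConformerGroup] | Mapping[str, str],
    total_energy_column: str,
    target: np.ndarray | None = None,
    drop_reference_rows: bool = False,
) -> tuple[FeatureMatrix, dict[str, str], np.ndarray | None]:
    """Re-express every feature row (and target) relative to its group's
    lowest-energy conformer.

    Within each group the member minimal in ``total_energy_column`` becomes
    the reference; its row maps to exact zero and every other row to
    row - reference_row.  Ties on the minimum go to the lowest sample index
    (a warning is issued).  Returns the corrected matrix, the map
    group_id -> reference sample_id, and the identically corrected target
    (``target - reference_target``) when one is passed.
    """
    if isinstance(groups, Mapping):
        sample_to_group = {str(k): str(v) for k, v in groups.items()}
    else:
        sample_to_group = {}
        for g in groups:
            for mid in g.members:
                sample_to_group[mid] = g.group_id
    missing = [s for s in fm.sample_ids if s not in sample_to_group]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing[:5]}")

    e_col = fm.column_index(total_energy_column)
    row_of = {s: i for i, s in enumerate(fm.sample_ids)}
    members_by_group: dict[str, list[int]] = {}
    for s in fm.sample_ids:
        members_by_group.setdefault(sample_to_group[s], []).append(row_of[s])
    if any(len(v) == 0 for v in members_by_group.values()):
        raise ValueError("empty group")

    target = None if target is None else np.asarray(target, dtype=float)
    values = fm.values.copy()
    corrected_target = target.copy() if target is not None else None
    reference_map: dict[str, str] = {}
    flags = [False] * fm.n_samples
    for gid, rows in members_by_group.items():
        col = fm.values[rows, e_col]
        lowest = min(col)
        winners = [r for r, v in zip(rows, col) if v == lowest]
        if len(winners) > 1:
            warnings.warn(
                f"group {gid!r}: tie at minimum {total_energy_column}; "
                "taking the lowest sample index"
            )
        ref = winners[0]
        reference_map[gid] = fm.sample_ids[ref]
        flags[ref] = True
        ref_row = fm.values[ref].copy()
        for r in rows:
            values[r] = fm.values[r] - ref_row
        if corrected_target is not None:
            ref_t = target[ref]
            for r in rows:
                corrected_target[r] = target[r] - ref_t

    out = FeatureMatrix(
        sample_ids=list(fm.sample_ids),
        columns=list(fm.columns),
        values=values,
        group_ids=[sample_to_group[s] for s in fm.sample_ids],
        reference_flags=flags,
    )
    if drop_reference_rows:
        keep = [i for i, f in enumerate(flags) if not f]
        out = FeatureMatrix(
            sample_ids=[out.sample_ids[i] for i in keep],
            columns=out.columns,
            values=out.values[keep],
            group_ids=[out.group_ids[i] for i in keep],
        )
        if corrected_target is not None:
            corrected_target = corrected_target[keep]
    return out, reference_map, corrected_target


def add_solvation_context(
    fm: FeatureMatrix, sample_solvent_eps: Mapping[str, float] | Sequence[float]
) -> FeatureMatrix:
    """Append the per-sample solvent dielectric constant as one extra column.

    Used in solvation mode, where no delta correction applies; all other
    columns are untouched.
    """
    if isinstance(sample_solvent_eps, Mapping):
        missing = [s for s in fm.sample_ids if s not in sample_solvent_eps]
        if missing:
            raise ValueError(f"missing dielectric for samples: {missing[:5]}")
        eps = np.array([float(sample_solvent_eps[s]) for s in fm.sample_ids])
    else:
        eps = np.asarray(sample_solvent_eps, dtype=float)
        if eps.shape != (fm.n_samples,):
            raise ValueError("dielectric vector length mismatch")
    if np.any(eps < 1.0):
        raise ValueError("dielectric constants must be >= 1")
    return FeatureMatrix(
        sample_ids=list(fm.sample_ids),
        columns=list(fm.columns) + [DIELECTRIC_COLUMN],
        values=np.column_stack([fm.values, eps]),
        group_ids=list(fm.group_ids) if fm.group_ids is not None else None,
        reference_flags=list(fm.reference_flags) if fm.reference_flags is not None else None,
    )


def write_metadata(
    path: str | Path,
    media: Sequence[Medium],
    attributes: Sequence[int],
    reference_map: Mapping[str, str] | None = None,
) -> None:
    """Sidecar JSON recording the panel, attribute subset and delta provenance."""
    payload = {
        "media": [
            {"name": m.name, "dielectric": m.dielectric, "engine_key": m.engine_key,
             "hb_strength": m.hb_strength}
            for m in media
        ],
        "attributes": list(attributes),
        "delta_reference_map": dict(reference_map) if reference_map else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
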