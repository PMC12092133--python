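"""Tabular readers/writers for manifests, arrangements, ratings and RDMs.

All interchange formats are plain text: TSV with header rows (UTF-8, '.'
decimal) for behavioural tables, labelled CSV for RDMs, JSON for summary
reports.  Row order of the input files never affects downstream results —
every reader reorders to the canonical stimulus order of the manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Arrangement,
    RatingMatrix,
    RDM,
    SchemaError,
    StimulusSet,
)

# ---------------------------------------------------------------------------
# stimulus manifest


def write_manifest(stimset: StimulusSet, path: str | Path) -> None:
    pd.DataFrame(
        {"stimulus_id": stimset.stimulus_ids, "class_label": stimset.class_labels}
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path, strict_design: bool = False) -> StimulusSet:
    """Read a stimulus manifest TSV (stimulus_id, class_label).

    With ``strict_design=True`` the balanced study design (6 stimuli in each
    of the 5 classes) is enforced.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("stimulus_id", "class_label"):
        if col not in df.columns:
            raise SchemaError(f"manifest is missing column {col!r}")
    stimset = StimulusSet(
        tuple(df["stimulus_id"]), tuple(df["class_label"]), None
    )
    if strict_design:
        stimset.validate_design(n_per_class=6)
    return stimset


# ---------------------------------------------------------------------------
# arrangements

ARRANGEMENT_COLUMNS = ("participant_id", "session", "stimulus_id",
                       "class_label", "x_cm", "y_cm")


def write_arrangements(
    arrangements: list[Arrangement], stimset: StimulusSet, path: str | Path
) -> None:
    rows = []
    for arr in arrangements:
        for sid, (x, y) in zip(arr.stimulus_ids, arr.coords):
            rows.append(
                (arr.participant_id, arr.session, sid, stimset.class_of(sid), x, y)
            )
    pd.DataFrame(rows, columns=ARRANGEMENT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_arrangements(path: str | Path, stimset: StimulusSet) -> list[Arrangement]:
    """Read an arrangement table, validating the schema row by row.

    Each (participant, session) must place every manifest stimulus exactly
    once; violations raise :class:`SchemaError` naming the offender.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("participant_id", "session", "stimulus_id", "x_cm", "y_cm"):
        if col not in df.columns:
            raise SchemaError(f"arrangement table is missing column {col!r}")
    known = set(stimset.stimulus_ids)
    for col in ("x_cm", "y_cm"):
        bad = df[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            row = bad.iloc[0]
            raise SchemaError(
                f"non-numeric coordinate {col}={row[col]!r} for participant "
                f"{row['participant_id']!r}, stimulus {row['stimulus_id']!r}"
            )
    arrangements = []
    for (pid, session), grp in df.groupby(
        ["participant_id", "session"], sort=True
    ):
        seen = grp["stimulus_id"].tolist()
        unknown = sorted(set(seen) - known)
        if unknown:
            raise SchemaError(
                f"participant {pid!r} session {session}: unknown stimulus "
                f"{unknown[0]!r}"
            )
        dupes = sorted({s for s in seen if seen.count(s) > 1})
        if dupes:
            raise SchemaError(
                f"participant {pid!r} session {session}: duplicate row for "
                f"stimulus {dupes[0]!r}"
            )
        missing = sorted(known - set(seen))
        if missing:
            raise SchemaError(
                f"participant {pid!r} session {session}: missing stimulus "
                f"{missing[0]!r}"
            )
        indexed = grp.set_index("stimulus_id")
        coords = indexed.loc[list(stimset.stimulus_ids), ["x_cm", "y_cm"]].to_numpy(
            dtype=float
        )
        arrangements.append(
            Arrangement(str(pid), int(session), stimset.stimulus_ids, coords)
        )
    return arrangements


# ---------------------------------------------------------------------------
# ratings

RATING_COLUMNS = ("participant_id", "stimulus_id", "dimension", "value")


def write_ratings(ratings: RatingMatrix, path: str | Path) -> None:
    rows = []
    for p, pid in enumerate(ratings.participant_ids):
        for s, sid in enumerate(ratings.stimulus_ids):
            for d, dim in enumerate(ratings.dimension_names):
                rows.append((pid, sid, dim, ratings.values[p, s, d]))
    pd.DataFrame(rows, columns=RATING_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ratings(
    path: str | Path,
    stimset: StimulusSet,
    dimension_names: tuple[str, ...] | None = None,
    count_dimensions: tuple[str, ...] | None = None,
) -> RatingMatrix:
    """Read a long-format rating table into a RatingMatrix.

    Dimensions are ordered by ``dimension_names`` if given, else by first
    appearance in the file.  Scale tags come from ``count_dimensions`` if
    given, else a dimension whose values are all non-negative integers is
    tagged ``count``.
    """
    df = pd.read_csv(path, sep="\t")
    for col in RATING_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"rating table is missing column {col!r}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    if not np.all(np.isfinite(vals)):
        row = df[~np.isfinite(vals)].iloc[0]
        raise SchemaError(
            f"non-numeric rating for participant {row['participant_id']!r}, "
            f"stimulus {row['stimulus_id']!r}, dimension {row['dimension']!r}"
        )
    df = df.assign(value=vals)
    if dimension_names is None:
        dimension_names = tuple(dict.fromkeys(df["dimension"]))
    participants = tuple(sorted(df["participant_id"].astype(str).unique()))
    sids = stimset.stimulus_ids
    values = np.full((len(participants), len(sids), len(dimension_names)), np.nan)
    pidx = {p: i for i, p in enumerate(participants)}
    sidx = {s: i for i, s in enumerate(sids)}
    didx = {d: i for i, d in enumerate(dimension_names)}
    for row in df.itertuples(index=False):
        if row.stimulus_id not in sidx:
            raise SchemaError(f"unknown stimulus {row.stimulus_id!r} in ratings")
        if row.dimension not in didx:
            raise SchemaError(f"unknown dimension {row.dimension!r} in ratings")
        i, j, k = pidx[str(row.participant_id)], sidx[row.stimulus_id], didx[row.dimension]
        if not np.isnan(values[i, j, k]):
            raise SchemaError(
                f"duplicate rating: participant {row.participant_id!r}, "
                f"stimulus {row.stimulus_id!r}, dimension {row.dimension!r}"
            )
        values[i, j, k] = row.value
    if np.any(np.isnan(values)):
        i, j, k = np.argwhere(np.isnan(values))[0]
        raise SchemaError(
            f"missing rating: participant {participants[i]!r}, stimulus "
            f"{sids[j]!r}, dimension {dimension_names[k]!r}"
        )
    if count_dimensions is None:
        count_dimensions = tuple(
            dim for k, dim in enumerate(dimension_names)
            if np.allclose(values[:, :, k], np.round(values[:, :, k]))
            and np.all(values[:, :, k] >= 0)
        )
    meta = tuple(
        "count" if d in set(count_dimensions) else "continuous_unit_interval"
        for d in dimension_names
    )
    return RatingMatrix(participants, sids, dimension_names, meta, values)


# ---------------------------------------------------------------------------
# RDMs and reports


def write_rdm(rdm: RDM, path: str | Path) -> None:
    pd.DataFrame(rdm.matrix, index=rdm.labels, columns=rdm.labels).to_csv(path)


def read_rdm(path: str | Path) -> RDM:
    df = pd.read_csv(path, index_col=0)
    if tuple(df.index) != tuple(df.columns):
        raise SchemaError("RDM row and column labels disagree")
    return RDM(tuple(df.index), df.to_numpy(dtype=float))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_report(results: dict, path: str | Path) -> None:
    """Write an analysis summary as pretty-printed JSON."""
    Path(path).write_text(
        json.dumps(results, indent=2, cls=_NumpyEncoder, allow_nan=True) + "\n"
    )
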