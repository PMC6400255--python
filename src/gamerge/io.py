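"""Readers and writers for unmerged reflection data and grouping documents.

Two input layouts are supported:

* ``table`` — a single delimited text file with a one-line header and columns
  ``subdataset h k l I sigI`` (whitespace- or tab-separated; ``#`` lines are
  comments).  Rows are grouped into sub-data sets by the ``subdataset``
  column.  Miller indices are the *measured* indices; they are reduced to the
  Friedel-unique representative on load.
* ``xds_ascii`` — one unmerged XDS_ASCII HKL file per sub-data set, parsed
  with gemmi.

Loading never drops data silently: observations rejected for non-positive
sigma or for falling outside the resolution range ``d in (d_min, d_max]`` are
counted in the returned :class:`LoadReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cell import UnitCell, d_spacing
from .reflections import Pool, ReflectionObservation, SubDataSet, reduce_friedel_array

__all__ = [
    "LoadReport",
    "read_pool",
    "write_pool",
    "write_grouping",
    "read_grouping",
]

TABLE_COLUMNS = ["subdataset", "h", "k", "l", "I", "sigI"]


@dataclass
class LoadReport:
    """Bookkeeping of what was kept and what was rejected during loading."""

    n_input: int = 0
    n_kept: int = 0
    n_rejected_sigma: int = 0
    n_rejected_resolution: int = 0
    per_file: dict = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return self.n_rejected_sigma + self.n_rejected_resolution

    def check(self) -> None:
        assert self.n_input == self.n_kept + self.n_rejected

    def to_text(self) -> str:
        lines = [
            "load report",
            f"  input observations:    {self.n_input}",
            f"  kept:                  {self.n_kept}",
            f"  rejected (sigma<=0):   {self.n_rejected_sigma}",
            f"  rejected (resolution): {self.n_rejected_resolution}",
        ]
        for src, counts in self.per_file.items():
            lines.append(f"  {src}: {counts}")
        return "\n".join(lines)


def _build_subdatasets(
    frame: pd.DataFrame,
    cell: UnitCell,
    resolution_range: tuple[float, float],
    report: LoadReport,
    symmetry_ops=None,
    source: str | None = None,
) -> list[SubDataSet]:
    """Filter, Friedel-reduce and group a raw observation frame by id."""
    d_max, d_min = resolution_range
    n0 = len(frame)
    report.n_input += n0

    sigma_ok = frame["sigI"].to_numpy() > 0
    n_sig = int((~sigma_ok).sum())
    frame = frame[sigma_ok]

    hkl = frame[["h", "k", "l"]].to_numpy(dtype=np.int64)
    if len(hkl) and np.any(np.all(hkl == 0, axis=1)):
        bad = np.nonzero(np.all(hkl == 0, axis=1))[0][0]
        raise ValueError(f"{source or 'input'}: row {frame.index[bad]} has index (0,0,0)")
    d = d_spacing(hkl, cell) if len(hkl) else np.empty(0)
    res_ok = (d > d_min) & (d <= d_max)
    n_res = int((~res_ok).sum())
    frame = frame[res_ok]
    hkl = hkl[res_ok]

    report.n_rejected_sigma += n_sig
    report.n_rejected_resolution += n_res
    report.n_kept += len(frame)
    if source is not None:
        report.per_file[source] = {
            "input": n0, "kept": len(frame), "sigma": n_sig, "resolution": n_res
        }

    rep, sign = reduce_friedel_array(hkl, symmetry_ops)
    ids = frame["subdataset"].astype(str).to_numpy()
    ivals = frame["I"].to_numpy(dtype=float)
    svals = frame["sigI"].to_numpy(dtype=float)

    subdatasets = []
    for sid in pd.unique(ids):
        mask = ids == sid
        obs = [
            ReflectionObservation(
                int(rep[i][0]), int(rep[i][1]), int(rep[i][2]),
                int(sign[i]), float(ivals[i]), float(svals[i]), sid,
            )
            for i in np.nonzero(mask)[0]
        ]
        subdatasets.append(SubDataSet(id=sid, observations=obs, source=source))
    return subdatasets


def read_pool(
    paths,
    format: str = "table",
    cell: UnitCell | None = None,
    resolution_range: tuple[float, float] = (1000.0, 0.1),
    symmetry_ops=None,
    reference_unique_count: int | str = "derived",
) -> tuple[Pool, LoadReport]:
    """Load a pool of sub-data sets from a table file or XDS_ASCII files.

    Returns ``(pool, load_report)``.  ``cell`` is required for the table
    format; for XDS_ASCII it defaults to the cell constants of the first
    file's header.
    """
    report = LoadReport()
    if format == "table":
        if cell is None:
            raise ValueError("table format requires an explicit unit cell")
        path = Path(paths if isinstance(paths, (str, Path)) else paths[0])
        try:
            frame = pd.read_csv(path, sep=r"\s+", comment="#", float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"cannot parse table {path}: {exc}") from exc
        missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        subdatasets = _build_subdatasets(
            frame, cell, resolution_range, report, symmetry_ops, source=str(path)
        )
    elif format == "xds_ascii":
        import gemmi

        file_list = [Path(p) for p in ([paths] if isinstance(paths, (str, Path)) else paths)]
        if not file_list:
            raise ValueError("no XDS_ASCII files given")
        subdatasets = []
        for p in file_list:
            try:
                xds = gemmi.read_xds_ascii(str(p))
            except Exception as exc:
                raise ValueError(f"cannot parse XDS_ASCII {p}: {exc}") from exc
            if cell is None:
                cell = UnitCell.from_parameters(xds.cell_constants)
            frame = pd.DataFrame(
                {
                    "subdataset": p.stem,
                    "h": np.asarray(xds.miller_array)[:, 0],
                    "k": np.asarray(xds.miller_array)[:, 1],
                    "l": np.asarray(xds.miller_array)[:, 2],
                    "I": np.asarray(xds.iobs_array),
                    "sigI": np.asarray(xds.sigma_array),
                }
            )
            subdatasets.extend(
                _build_subdatasets(
                    frame, cell, resolution_range, report, symmetry_ops, source=str(p)
                )
            )
    else:
        raise ValueError(f"unknown format {format!r}")

    if not subdatasets:
        raise ValueError("empty pool: no sub-data set survived loading")
    report.check()
    assert cell is not None
    pool = Pool(
        subdatasets=subdatasets,
        unit_cell=cell,
        resolution_range=resolution_range,
        reference_unique_count=reference_unique_count,
    )
    return pool, report


def write_pool(pool: Pool, path, header_comments: Sequence[str] = ()) -> None:
    """Write a pool in the internal table format (measured indices).

    The measured index is recovered from the stored representative and
    Friedel sign, so ``write_pool`` then ``read_pool`` reproduces all
    observations exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        cell = pool.unit_cell.parameters
        fh.write(f"# unit_cell = {' '.join(f'{x:g}' for x in cell)}\n")
        fh.write(f"# resolution_range = {pool.resolution_range[0]:g} {pool.resolution_range[1]:g}\n")
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for sds in pool.subdatasets:
            for o in sds.observations:
                h, k, l = (o.h, o.k, o.l) if o.friedel_sign > 0 else (-o.h, -o.k, -o.l)
                fh.write(f"{sds.id}\t{h}\t{k}\t{l}\t{o.intensity!r}\t{o.sigma!r}\n")


def write_grouping(labels, subdataset_ids: Sequence[str], path) -> None:
    """Write a machine-readable grouping document (JSON) mapping each
    sub-data-set id to its merging-group label, in stable pool order."""
    labels = list(int(x) for x in labels)
    ids = list(subdataset_ids)
    if not labels:
        raise ValueError("empty chromosome")
    if len(labels) != len(ids):
        raise ValueError(f"chromosome length {len(labels)} != pool size {len(ids)}")
    groups: dict[str, list[str]] = {}
    for sid, lab in zip(ids, labels):
        groups.setdefault(str(lab), []).append(sid)
    doc = {
        "subdatasets": [{"id": sid, "group": lab} for sid, lab in zip(ids, labels)],
        "groups": groups,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_grouping(path) -> tuple[list[str], list[int]]:
    """Read a grouping document; returns (ids, labels) in stored order."""
    with open(path) as fh:
        doc = json.load(fh)
    ids = [e["id"] for e in doc["subdatasets"]]
    labels = [int(e["group"]) for e in doc["subdatasets"]]
    return ids, labels
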