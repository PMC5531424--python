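"""Readers and writers for the pipeline's on-disk formats.

* Raw Ct tables: wide CSV, first column ``cell_id``, one column per assay
  (two reserved spike columns ``spike1``/``spike4``), per-reading quality
  flags in companion columns suffixed ``_flag`` (``OK``/``Failed``).
  A permissive Biomark-export variant is supported through a column map,
  including duplicate assay columns, which are collapsed on read:
  duplicates disagreeing by more than 1 cycle (or in detection) are
  flagged ``Inconsistent``.
* Expression matrices: TSV plus a JSON sidecar of per-cell labels.
* Lineage tracks: a cells TSV (clone_id, cell_id, parent_id, t_birth_h,
  t_end_h, end_event) plus an intervals TSV (cell_id, t_start_h,
  t_stop_h, shape); lineage topology additionally exports to Newick with
  branch lengths in hours.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .lineage import CellRecord, MorphologyTrack, Pedigree
from .qpcr import DEFAULT_FLOOR, ExpressionMatrix, QCReport, RawCtTable

__all__ = [
    "write_ct_csv",
    "read_ct_csv",
    "write_expression",
    "read_expression",
    "write_tracks",
    "read_tracks",
    "pedigree_to_newick",
    "write_newick",
    "write_json",
]

_DUP_SUFFIX = re.compile(r"\.\d+$")


class FormatError(ValueError):
    """Malformed input file; message names the file and offending field."""


# --------------------------------------------------------------------------
# raw Ct tables
# --------------------------------------------------------------------------


def write_ct_csv(table: RawCtTable, path: str | Path) -> None:
    out = table.ct.copy()
    for col in table.ct.columns:
        flags = table.flags[col]
        if (flags != "OK").any():
            out[f"{col}_flag"] = flags
    out.index.name = "cell_id"
    out.to_csv(path)


def read_ct_csv(
    path: str | Path,
    *,
    cell_id_col: str = "cell_id",
    assay_map: dict[str, str] | None = None,
    spike_assays: tuple[str, str] = ("spike1", "spike4"),
    collapse_duplicates: bool = True,
    meta_cols: tuple[str, ...] = (),
) -> RawCtTable:
    """Read a wide Ct CSV into a :class:`RawCtTable`.

    ``assay_map`` renames exported column headers to panel assay names
    (the permissive Biomark variant); ``meta_cols`` names annotation
    columns to divert into per-cell metadata.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - message plumbing
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.empty:
        raise FormatError(f"{path}: empty Ct table")
    df.index.name = cell_id_col

    meta = df[list(meta_cols)] if meta_cols else None
    df = df.drop(columns=list(meta_cols), errors="ignore")

    flag_cols = [c for c in df.columns if c.endswith("_flag")]
    flags_raw = {c[: -len("_flag")]: df[c].astype(str) for c in flag_cols}
    df = df.drop(columns=flag_cols)

    if assay_map:
        df = df.rename(columns=assay_map)
        flags_raw = {assay_map.get(k, k): v for k, v in flags_raw.items()}

    if collapse_duplicates:
        df, dup_flags = _collapse_duplicate_assays(df, path)
    else:
        dup_flags = {}

    try:
        ct = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric Ct value ({exc})") from exc

    flags = pd.DataFrame("OK", index=ct.index, columns=ct.columns)
    for col, series in flags_raw.items():
        if col in flags.columns:
            flags[col] = series.where(series.isin(["OK", "Failed", "Inconsistent"]), "OK")
    for col, mask in dup_flags.items():
        flags.loc[mask, col] = "Inconsistent"

    for s in spike_assays:
        if s not in ct.columns:
            raise FormatError(f"{path}: missing spike assay column {s!r}")
    return RawCtTable(ct, flags, meta, spike_assays)


def _collapse_duplicate_assays(
    df: pd.DataFrame, path: Path
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Average duplicate assay readings; disagreement > 1 cycle or mixed
    detection marks the reading Inconsistent (value dropped)."""
    base_of = {c: _DUP_SUFFIX.sub("", c) for c in df.columns}
    groups: dict[str, list[str]] = {}
    for col, base in base_of.items():
        groups.setdefault(base, []).append(col)
    out = {}
    inconsistent: dict[str, pd.Series] = {}
    for base, cols in groups.items():
        block = df[cols].apply(pd.to_numeric, errors="coerce")
        if len(cols) == 1:
            out[base] = block.iloc[:, 0]
            continue
        n_present = block.notna().sum(axis=1)
        mixed = (n_present > 0) & (n_present < len(cols))
        spread = block.max(axis=1) - block.min(axis=1)
        bad = mixed | (spread > 1.0)
        collapsed = block.mean(axis=1)
        single = n_present == 1
        collapsed[single] = block[single].bfill(axis=1).iloc[:, 0]
        collapsed[bad] = np.nan
        out[base] = collapsed
        if bad.any():
            inconsistent[base] = bad
    return pd.DataFrame(out, index=df.index), inconsistent


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """TSV of dCt values; labels and floor go to a ``.labels.json`` sidecar."""
    path = Path(path)
    matrix.values.rename_axis("cell_id").to_csv(path, sep="\t", float_format="%.6f")
    sidecar = {
        "floor": matrix.floor,
        "labels": None
        if matrix.labels is None
        else json.loads(matrix.labels.to_json(orient="index")),
    }
    path.with_suffix(path.suffix + ".labels.json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    floor = DEFAULT_FLOOR
    labels = None
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        floor = meta.get("floor", DEFAULT_FLOOR)
        if meta.get("labels") is not None:
            labels = pd.DataFrame.from_dict(meta["labels"], orient="index")
            labels.index = labels.index.astype(str)
            labels = labels.reindex(values.index.astype(str)).set_axis(values.index)
    return ExpressionMatrix(values, labels, floor)


def write_qc_report(report: QCReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


# --------------------------------------------------------------------------
# lineage tracks
# --------------------------------------------------------------------------


def write_tracks(
    pedigrees: list[Pedigree], cells_path: str | Path, intervals_path: str | Path
) -> None:
    cell_rows, interval_rows = [], []
    for ped in pedigrees:
        for cell in sorted(ped.cells.values(), key=lambda c: c.cell_id):
            cell_rows.append(
                {
                    "clone_id": ped.clone_id,
                    "cell_id": cell.cell_id,
                    "parent_id": "" if cell.parent_id is None else cell.parent_id,
                    "t_birth_h": cell.t_birth,
                    "t_end_h": cell.t_end,
                    "end_event": cell.end_event,
                }
            )
            if cell.track is not None:
                for a, b, s in cell.track.intervals:
                    interval_rows.append(
                        {
                            "cell_id": cell.cell_id,
                            "t_start_h": a,
                            "t_stop_h": b,
                            "shape": s,
                        }
                    )
    pd.DataFrame(cell_rows).to_csv(cells_path, sep="\t", index=False)
    pd.DataFrame(interval_rows).to_csv(intervals_path, sep="\t", index=False)


def read_tracks(
    cells_path: str | Path,
    intervals_path: str | Path,
    *,
    column_map: dict[str, str] | None = None,
) -> list[Pedigree]:
    """Load pedigrees from the cells + intervals TSV pair.

    ``column_map`` renames hand-curated spreadsheet headers to the
    canonical column names before parsing.
    """
    cells_path, intervals_path = Path(cells_path), Path(intervals_path)
    cells = pd.read_csv(cells_path, sep="\t", dtype={"parent_id": str, "cell_id": str})
    ivs = pd.read_csv(intervals_path, sep="\t", dtype={"cell_id": str})
    if column_map:
        cells = cells.rename(columns=column_map)
        ivs = ivs.rename(columns=column_map)
    required = {"clone_id", "cell_id", "parent_id", "t_birth_h", "t_end_h", "end_event"}
    missing = required - set(cells.columns)
    if missing:
        raise FormatError(f"{cells_path}: missing columns {sorted(missing)}")
    req_iv = {"cell_id", "t_start_h", "t_stop_h", "shape"}
    if not ivs.empty and (req_iv - set(ivs.columns)):
        raise FormatError(
            f"{intervals_path}: missing columns {sorted(req_iv - set(ivs.columns))}"
        )

    by_cell = {k: g for k, g in ivs.groupby("cell_id")} if not ivs.empty else {}
    pedigrees: dict[str, Pedigree] = {}
    generations: dict[str, int] = {}
    cells = cells.fillna({"parent_id": ""})
    for order_pass in range(2):  # two passes resolve out-of-order parents
        for i, row in cells.iterrows():
            cid = str(row["cell_id"])
            if cid in generations:
                continue
            parent = str(row["parent_id"]) if str(row["parent_id"]) else None
            if parent is None:
                generations[cid] = 1
            elif parent in generations:
                generations[cid] = generations[parent] + 1
    unresolved = set(cells["cell_id"].astype(str)) - set(generations)
    if unresolved:
        raise FormatError(
            f"{cells_path}: cells with unknown ancestry {sorted(unresolved)[:5]}"
        )

    for i, row in cells.iterrows():
        cid = str(row["cell_id"])
        clone = str(row["clone_id"])
        parent = str(row["parent_id"]) if str(row["parent_id"]) else None
        if row["end_event"] not in ("division", "censored"):
            raise FormatError(
                f"{cells_path}: row {i}: bad end_event {row['end_event']!r}"
            )
        track = None
        if cid in by_cell:
            g = by_cell[cid].sort_values("t_start_h")
            track = MorphologyTrack(
                cid,
                list(zip(g["t_start_h"], g["t_stop_h"], g["shape"])),
                float(row["t_birth_h"]),
                float(row["t_end_h"]),
                str(row["end_event"]),
            )
        ped = pedigrees.setdefault(clone, Pedigree(clone))
        ped.add(
            CellRecord(
                cid,
                clone,
                parent,
                generations[cid],
                float(row["t_birth_h"]),
                float(row["t_end_h"]),
                str(row["end_event"]),
                track,
            )
        )
    return [pedigrees[k] for k in sorted(pedigrees)]


# --------------------------------------------------------------------------
# newick / json
# --------------------------------------------------------------------------


def pedigree_to_newick(ped: Pedigree) -> str:
    """Newick string of a clone tree, branch lengths = lifetimes in hours."""
    tree = dendropy.Tree()
    nodes: dict[str, dendropy.Node] = {}
    founder = ped.founder
    for cell in sorted(ped.cells.values(), key=lambda c: c.cell_id):
        node = dendropy.Node(edge_length=cell.t_end - cell.t_birth)
        node.taxon = None
        node.label = cell.cell_id
        nodes[cell.cell_id] = node
    for cell in sorted(ped.cells.values(), key=lambda c: c.cell_id):
        if cell.parent_id is not None:
            nodes[cell.parent_id].add_child(nodes[cell.cell_id])
    tree.seed_node = nodes[founder.cell_id]
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def write_newick(pedigrees: list[Pedigree], path: str | Path) -> None:
    Path(path).write_text("".join(pedigree_to_newick(p) + "\n" for p in pedigrees))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
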