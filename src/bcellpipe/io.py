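"""Readers and writers for every on-disk artifact the pipeline touches.

All files are plain text: CSV tables, FASTA sequences, MatrixMarket + TSV
name files for matrices, and JSON for summaries.  Internal coordinates are
0-based half-open; report files use 1-based positions (noted in headers).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from .datatypes import CONTIG_COLUMNS, VALID_CHAINS, ContigTable, ElisaCurve, SensorgramSet
from .synthetic.germline import GermlineReference, GermlineSegment


class SchemaError(ValueError):
    """A table does not match its required schema."""


# ---------------------------------------------------------------- contigs

def write_contig_table(table: ContigTable, csv_path: str | Path, fasta_path: str | Path) -> None:
    table.df.to_csv(csv_path, index=False)
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in table.sequences.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def read_contig_annotations(
    csv_path: str | Path, fasta_path: str | Path | None = None
) -> ContigTable:
    """Read a 10x-style contig annotation CSV (plus optional contig FASTA).

    Rows with an unknown chain value are rejected with their line numbers;
    a missing required column raises :class:`SchemaError`.
    """
    df = pd.read_csv(csv_path, dtype={"cdr3_nt": str, "cdr3_aa": str}, keep_default_na=False)
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{csv_path}: missing required columns {missing}")
    bad = ~df["chain"].isin(VALID_CHAINS)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header line and 1-based
        raise SchemaError(
            f"{csv_path}: invalid chain values {sorted(df.loc[bad, 'chain'].unique())} "
            f"on lines {lines}"
        )
    df = df[CONTIG_COLUMNS + [c for c in df.columns if c not in CONTIG_COLUMNS]]
    df["donor"] = df["donor"].astype(int)
    sequences: dict[str, str] = {}
    if fasta_path is not None:
        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    return ContigTable(df.reset_index(drop=True), sequences)


# ---------------------------------------------------------------- germline

def write_germline_fasta(reference: GermlineReference, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seg.seq), id=seg.name, description=f"segment_type={seg.segment_type}")
        for seg in reference.v_segments + reference.j_segments
    ]
    SeqIO.write(records, str(path), "fasta")


def read_germline_fasta(path: str | Path, strain: str = "NOD") -> GermlineReference:
    vs, js = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seg_type = "V"
        if "segment_type=J" in rec.description or rec.id.upper().startswith("J"):
            seg_type = "J"
        seg = GermlineSegment(rec.id, seg_type, str(rec.seq))
        (js if seg_type == "J" else vs).append(seg)
    return GermlineReference(v_segments=vs, j_segments=js, strain=strain)


# ---------------------------------------------------------------- matrices

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a named matrix as dense CSV (.csv) or MatrixMarket (.mtx).

    MTX output places ``<stem>_rows.tsv`` and ``<stem>_cols.tsv`` next to
    the matrix file.
    """
    path = Path(path)
    if path.suffix == ".csv":
        matrix.to_csv(path)
    elif path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.csr_matrix(matrix.to_numpy()))
        path.with_name(path.stem + "_rows.tsv").write_text(
            "\n".join(map(str, matrix.index)) + "\n")
        path.with_name(path.stem + "_cols.tsv").write_text(
            "\n".join(map(str, matrix.columns)) + "\n")
    else:
        raise ValueError(f"unsupported matrix format: {path.suffix}")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` from either dialect."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, index_col=0)
    elif path.suffix == ".mtx":
        mat = spio.mmread(str(path)).toarray()
        rows = path.with_name(path.stem + "_rows.tsv").read_text().splitlines()
        cols = path.with_name(path.stem + "_cols.tsv").read_text().splitlines()
        if mat.shape != (len(rows), len(cols)):
            raise ValueError(
                f"{path}: matrix shape {mat.shape} does not match "
                f"name files ({len(rows)} x {len(cols)})"
            )
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        raise ValueError(f"unsupported matrix format: {path.suffix}")
    if df.size == 0:
        raise ValueError(f"{path}: empty matrix")
    return df


# ---------------------------------------------------------------- sensorgrams

def write_sensorgrams(sgrams: SensorgramSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# association_s={sgrams.association_s} "
                 f"dissociation_s={sgrams.dissociation_s}\n")
        sgrams.df.to_csv(fh, index=False)


def read_sensorgrams(path: str | Path) -> SensorgramSet:
    path = Path(path)
    assoc_s = dissoc_s = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            key, _, val = token.partition("=")
            if key == "association_s":
                assoc_s = float(val)
            elif key == "dissociation_s":
                dissoc_s = float(val)
    df = pd.read_csv(path, comment="#")
    if assoc_s is None:  # fall back to the phase boundaries in the data
        assoc = df[df["phase"] == "assoc"]["time_s"]
        assoc_s = float(assoc.max() - assoc.min()) if len(assoc) else 0.0
    if dissoc_s is None:
        dissoc = df[df["phase"] == "dissoc"]["time_s"]
        dissoc_s = float(dissoc.max() - dissoc.min()) if len(dissoc) else 0.0
    return SensorgramSet(df, assoc_s, dissoc_s)


# ---------------------------------------------------------------- ELISA

def write_elisa(curves: list[ElisaCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"dilution": c.dilution, "od450": c.od450, "group": c.group})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_elisa(path: str | Path) -> list[ElisaCurve]:
    df = pd.read_csv(path)
    for col in ("dilution", "od450", "group"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing ELISA column {col!r}")
    curves = []
    for group, grp in df.groupby("group", sort=True):
        grp = grp.sort_values("dilution")
        curves.append(ElisaCurve(
            dilution=grp["dilution"].to_numpy(),
            od450=grp["od450"].to_numpy(),
            group=str(group),
        ))
    return curves


# ---------------------------------------------------------------- atlas / misc

def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas.to_csv(path, index_label="population")


def read_atlas(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="population")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
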