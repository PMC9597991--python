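"""Readers and writers for the toolkit's file formats.

FASTA goes through Biopython.  PSSMs use the PSI-BLAST ``-out_ascii_pssm``
ASCII dialect: two header lines, then one row per position carrying the
1-based position index, the residue letter, 20 log-odds integers, 20
percentage columns and two trailing per-position statistics.  Only the 20
log-odds columns are retained.  Embedding matrices and feature tables are
plain TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    PSSM_COLUMNS,
    EmbeddingMatrix,
    FeatureMatrix,
    FormatError,
    ProteinRecord,
    PSSMProfile,
)

MODEL_BUNDLE_VERSION = "acrstack-model-1"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | os.PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

def read_pssm_ascii(path: str | os.PathLike, record_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Returns the first 20 numeric columns (log-odds, PSI-BLAST column order
    A R N D C Q E G H I L K M F P S T V W Y) and the sequence reconstructed
    from the residue-letter column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if record_id is None:
        record_id = path.stem.removesuffix(".pssm")

    rows: list[list[float]] = []
    letters: list[str] = []
    indices: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            # data rows start with an integer position then a residue letter
            if len(fields) < 2 or not fields[0].isdigit() or len(fields[1]) != 1 \
                    or not fields[1].isalpha():
                if rows:
                    break  # footer statistics reached
                continue  # header lines
            numeric = fields[2:]
            if len(numeric) != 42:
                raise FormatError(
                    f"{path}:{lineno}: expected 42 numeric fields after the residue "
                    f"letter, got {len(numeric)}"
                )
            try:
                values = [float(v) for v in numeric[:20]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric PSSM value") from exc
            indices.append(int(fields[0]))
            letters.append(fields[1].upper())
            rows.append(values)

    if not rows:
        raise FormatError(f"{path}: no PSSM rows found")
    if indices != list(range(1, len(indices) + 1)):
        raise FormatError(f"{path}: non-contiguous position indices")
    return PSSMProfile(record_id, np.array(rows), "".join(letters))


def write_pssm_ascii(profile: PSSMProfile, path: str | os.PathLike) -> None:
    """Write a profile in the ``-out_ascii_pssm`` dialect (round-trips with the reader).

    Percentage columns are filled with zeros and the two per-position
    statistics with ``0.00``; only the log-odds block carries information.
    """
    header = "  ".join(PSSM_COLUMNS)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted, and for "
            "round-trip use\n"
        )
        fh.write("            " + header + "   " + header + "\n")
        for i, (residue, row) in enumerate(zip(profile.sequence, profile.matrix)):
            scores = " ".join(f"{int(round(v)):3d}" for v in row)
            pcts = " ".join("0" for _ in range(20))
            fh.write(f"{i + 1:5d} {residue} {scores}  {pcts}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3113\n")


# ---------------------------------------------------------------------------
# Embeddings

def read_embedding_tsv(path: str | os.PathLike, record_id: str | None = None) -> EmbeddingMatrix:
    """Read an L x D per-residue embedding from a headerless TSV (one row per residue)."""
    path = Path(path)
    if record_id is None:
        record_id = path.name.split(".")[0]
    matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    return EmbeddingMatrix(record_id, matrix)


def write_embedding_tsv(emb: EmbeddingMatrix, path: str | os.PathLike) -> None:
    np.savetxt(path, emb.matrix, delimiter="\t", fmt="%.17g")


# ---------------------------------------------------------------------------
# Labels

def read_labels_tsv(path: str | os.PathLike) -> dict[str, int]:
    """Read an ``id<TAB>label`` table (binary labels, 1 = positive class)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if list(df.columns[:2]) != ["id", "label"]:
        raise FormatError(f"{path}: expected columns 'id' and 'label'")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise FormatError(f"{path}: duplicate ids {dupes}")
    return dict(zip(df["id"], df["label"].astype(int)))


def write_labels_tsv(labels: dict[str, int], path: str | os.PathLike) -> None:
    pd.DataFrame({"id": list(labels), "label": list(labels.values())}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Feature matrices

def write_feature_matrix(fm: FeatureMatrix, path: str | os.PathLike) -> None:
    """Write a feature matrix as TSV: header ``id`` + column names, 12 significant digits."""
    if len(set(fm.ids)) != len(fm.ids):
        raise FormatError("duplicate ids in feature matrix")
    with open(path, "w") as fh:
        fh.write("\t".join(["id", *fm.columns]) + "\n")
        for rid, row in zip(fm.ids, fm.data):
            fh.write(rid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_feature_matrix(path: str | os.PathLike, encoder: str | None = None) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if df.columns[0] != "id":
        raise FormatError(f"{path}: first column must be 'id'")
    if df["id"].duplicated().any():
        raise FormatError(f"{path}: duplicate ids")
    columns = list(df.columns[1:])
    data = df[columns].to_numpy(dtype=float) if columns else np.empty((len(df), 0))
    return FeatureMatrix(list(df["id"]), data.reshape(len(df), len(columns)),
                         columns, encoder=encoder)


# ---------------------------------------------------------------------------
# Model bundles

def save_model(model, path: str | os.PathLike) -> None:
    """Persist a fitted model as a single-file bundle with a format-version string."""
    joblib.dump({"format_version": MODEL_BUNDLE_VERSION, "model": model}, path)


def load_model(path: str | os.PathLike):
    bundle = joblib.load(path)
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise FormatError(f"{path}: not an acrstack model bundle")
    if bundle["format_version"] != MODEL_BUNDLE_VERSION:
        raise FormatError(
            f"{path}: bundle version {bundle['format_version']!r} does not match "
            f"library version {MODEL_BUNDLE_VERSION!r}"
        )
    return bundle["model"]
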