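"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic intervals use the BED convention: 0-based, half-open
[start, end). Count matrices are TSV with OCR ids as the row index and
sample ids as columns. Sequences and alignments travel as FASTA.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class BedParseError(ValueError):
    """Raised for malformed BED input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame with half-open int intervals.

    Malformed rows (fewer than three fields, non-integer or inverted
    coordinates) raise :class:`BedParseError` with the 1-based line number.
    """
    rows = []
    ncols = 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError("expected at least 3 tab-separated fields", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError("start/end must be integers", lineno) from None
            if start < 0 or end <= start:
                raise BedParseError(f"invalid interval [{start}, {end})", lineno)
            rows.append([fields[0], start, end, *fields[3:6]])
            ncols = max(ncols, min(len(fields), 6))
    out = pd.DataFrame(rows, columns=None)
    if out.empty:
        return pd.DataFrame(columns=list(BED_COLUMNS[:ncols]))
    out = out.iloc[:, :ncols]
    out.columns = list(BED_COLUMNS[: out.shape[1]])
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return out


def write_bed(df: pd.DataFrame, path, extra_cols: Iterable[str] = ()) -> None:
    cols = ["chrom", "start", "end"] + [c for c in extra_cols if c in df.columns]
    df.sort_values(["chrom", "start"])[cols].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: first column OCR ids, remaining columns one per sample."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return counts.astype(int)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="ocr_id")


def read_meta(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, species, bio_rep, tech_rep."""
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "species", "bio_rep", "tech_rep"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta.set_index("sample_id", drop=False)


ORTHOLOG_MAP_COLUMNS = (
    "ref_chrom",
    "ref_start",
    "ref_end",
    "species",
    "native_chrom",
    "native_start",
    "native_end",
)


def read_ortholog_map(path) -> pd.DataFrame:
    omap = pd.read_csv(path, sep="\t")
    missing = set(ORTHOLOG_MAP_COLUMNS) - set(omap.columns)
    if missing:
        raise ValueError(f"ortholog map missing columns: {sorted(missing)}")
    for col in ("ref_start", "ref_end", "native_start", "native_end"):
        omap[col] = omap[col].astype(int)
    return omap


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def fasta_string(sequences: Mapping[str, str]) -> str:
    buf = _io.StringIO()
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
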