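"""Shared helpers: exceptions, logging, and plain-text genomic format I/O.

Coordinates are 0-based half-open everywhere in memory; GTF is converted
to/from its on-disk 1-based inclusive convention at the I/O boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class CryptorfError(Exception):
    """Base class for package errors."""


class ConfigError(CryptorfError):
    """Invalid configuration or parameter value."""


class InputError(CryptorfError):
    """Malformed or inconsistent input data."""


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(f"cryptorf.{name}")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# BED6 (0-based half-open on disk and in memory)

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed6(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED6_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED6_COLS)]
    df.columns = BED6_COLS[: df.shape[1]]
    return df


# ---------------------------------------------------------------------------
# GTF (1-based inclusive on disk; converted to half-open on read)

GTF_COLS = [
    "seqname",
    "source",
    "feature",
    "start",
    "end",
    "score",
    "strand",
    "frame",
    "attribute",
]


def gtf_attributes(**kwargs: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kwargs.items())


def write_gtf(path: str | Path, rows: Sequence[dict]) -> None:
    """Write GTF rows whose start/end are 0-based half-open; converts on disk."""
    with open(path, "w") as fh:
        for row in rows:
            fields = [
                str(row["seqname"]),
                str(row.get("source", "cryptorf")),
                str(row["feature"]),
                str(int(row["start"]) + 1),  # to 1-based inclusive
                str(int(row["end"])),
                str(row.get("score", ".")),
                str(row.get("strand", ".")),
                str(row.get("frame", ".")),
                str(row.get("attribute", "")),
            ]
            fh.write("\t".join(fields) + "\n")


def read_gtf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=GTF_COLS, comment="#")
    df["start"] = df["start"] - 1  # back to 0-based half-open
    return df


def parse_gtf_attribute(attr: str, key: str) -> str | None:
    for part in attr.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip('"')
    return None
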