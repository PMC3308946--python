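"""Readers and writers for the external formats the pipeline touches.

FASTQ/FASTA carry amplicon reads (Phred+33 qualities); chromatogram traces
arrive as plain per-position peak-height tables; qPCR input is a tabular
file of cycle thresholds.  The two report writers mirror the published
isoform-count and site-frequency table layouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = frozenset("ACGTN")
CHANNELS = ("A", "C", "G", "T")


@dataclass
class Read:
    """A single sequencing read; qualities are Phred scores when present."""

    id: str
    sequence: str
    qualities: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"read {self.id}: invalid bases {sorted(bad)}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ChromatogramTrace:
    """Per-position four-channel (A,C,G,T) peak heights from a Sanger trace."""

    heights: np.ndarray  # shape (n, 4), columns in CHANNELS order
    called_bases: str

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.shape[1] != 4:
            raise ValueError("heights must be an (n, 4) array")
        if (self.heights < 0).any():
            raise ValueError("peak heights must be non-negative")
        if (self.heights.max(axis=1) <= 0).any():
            raise ValueError("every position needs at least one positive channel")
        if len(self.called_bases) != len(self.heights):
            raise ValueError("called_bases length must match heights")

    def __len__(self) -> int:
        return len(self.called_bases)

    def channel(self, base: str) -> np.ndarray:
        return self.heights[:, CHANNELS.index(base)]


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR well: target Ct plus the endogenous-control Ct for the sample."""

    sample_id: str
    group: str
    gene: str
    ct: float
    ref_ct: float

    def __post_init__(self) -> None:
        for name, value in (("ct", self.ct), ("ref_ct", self.ref_ct)):
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")


def _open(path: str | Path | IO[str], mode: str = "r") -> IO[str]:
    if hasattr(path, "read") or hasattr(path, "write"):
        return path  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path | IO[str]) -> Iterator[Read]:
    """Stream reads from a Phred+33 FASTQ file, in file order."""
    handle = _open(path)
    try:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
            if len(seq) != len(qual):
                raise ValueError(f"FASTQ record {i}: sequence/quality length mismatch")
            yield Read(
                id=title.split()[0] if title else title,
                sequence=seq,
                qualities=[ord(ch) - 33 for ch in qual],
            )
    finally:
        if handle is not path:
            handle.close()


def write_fastq(reads: Iterable[Read], path: str | Path | IO[str]) -> int:
    """Write reads as Phred+33 FASTQ; reads without qualities get Q40."""
    handle = _open(path, "w")
    n = 0
    try:
        for read in reads:
            quals = read.qualities if read.qualities is not None else [40] * len(read)
            qline = "".join(chr(min(q, 93) + 33) for q in quals)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qline}\n")
            n += 1
    finally:
        if handle is not path:
            handle.close()
    return n


def read_fasta(path: str | Path | IO[str]) -> Iterator[Read]:
    """Stream reads from a FASTA file (qualities absent)."""
    handle = _open(path)
    try:
        name: str | None = None
        chunks: list[str] = []
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield Read(id=name, sequence="".join(chunks))
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence data before first header")
                chunks.append(line)
        if name is not None:
            yield Read(id=name, sequence="".join(chunks))
    finally:
        if handle is not path:
            handle.close()


def read_trace_table(path: str | Path) -> ChromatogramTrace:
    """Load a chromatogram peak-height table.

    Expected columns: position, A, C, G, T and optionally call.  Without a
    call column the called base at each position is the argmax channel.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing channel column(s): {missing}")
    heights = df[list(CHANNELS)].to_numpy(dtype=float)
    if "call" in df.columns:
        called = "".join(str(b).strip().upper() for b in df["call"])
    else:
        called = "".join(CHANNELS[i] for i in heights.argmax(axis=1))
    return ChromatogramTrace(heights=heights, called_bases=called)


def write_trace_table(trace: ChromatogramTrace, path: str | Path) -> None:
    df = pd.DataFrame(trace.heights, columns=list(CHANNELS))
    df.insert(0, "position", np.arange(1, len(trace) + 1))
    df["call"] = list(trace.called_bases)
    df.to_csv(path, sep="\t", index=False)


def read_qpcr_table(path: str | Path) -> list[QpcrRecord]:
    """Load qPCR records from a TSV/CSV with columns sample_id, group, gene, ct, ref_ct."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "group", "gene", "ct", "ref_ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing column(s): {sorted(missing)}")
    return [
        QpcrRecord(
            sample_id=str(r.sample_id),
            group=str(r.group),
            gene=str(r.gene),
            ct=float(r.ct),
            ref_ct=float(r.ref_ct),
        )
        for r in df.itertuples()
    ]


# Report dialects.  Percentages are always rendered from counts at write
# time, never stored independently.

ISOFORM_TABLE_COLUMNS = [
    "label",
    "pattern",
    "count_lean",
    "pct_lean",
    "count_obob",
    "pct_obob",
    "count_total",
    "pct_total",
]
SITE_TABLE_COLUMNS = [
    "site",
    "pct_lean",
    "pct_obob",
    "delta_pct",
    "p_value",
    "p_adjusted",
]


def write_isoform_table(table: "pd.DataFrame | object", path: str | Path) -> None:
    """Write an isoform count table in the published layout (TSV)."""
    df = getattr(table, "to_frame", lambda: table)()
    out = pd.DataFrame(
        {
            "label": df["label"],
            "pattern": df["pattern"],
            "count_lean": df["count_lean"].astype(int),
            "pct_lean": df["pct_lean"].map(lambda v: f"{v:.2f}"),
            "count_obob": df["count_obob"].astype(int),
            "pct_obob": df["pct_obob"].map(lambda v: f"{v:.2f}"),
            "count_total": df["count_total"].astype(int),
            "pct_total": df["pct_total"].map(lambda v: f"{v:.2f}"),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_isoform_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_site_table(table: "pd.DataFrame | object", path: str | Path) -> None:
    """Write a per-site frequency/statistics table (TSV)."""
    df = getattr(table, "to_frame", lambda: table)()
    out = pd.DataFrame({"site": df["site"]})
    for col in ("pct_lean", "pct_obob", "delta_pct"):
        out[col] = df[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.2f}")
    for col in ("p_value", "p_adjusted"):
        if col in df:
            out[col] = df[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.3g}")
        else:
            out[col] = "NA"
    out.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
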