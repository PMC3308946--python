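"""Demultiplexing and quality filtering of barcoded amplicon reads.

Each amplicon read begins (on its sense strand) with the 454 adaptor A,
a 10-nt group barcode and the cassette forward primer, and ends with the
reverse complements of the reverse primer and adaptor B.  Reads may arrive
in either orientation; assignment searches both strands.

Quality filtering reimplements the two published accept/reject thresholds
of the Lucy screen: the mean per-base error probability must not exceed
0.025 and each of the two bases at either end must not exceed an error
probability of 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .io_formats import Read

# Published amplicon design constants.
ADAPTOR_A = "CGTATCGCCTCCCTCGCGCCATCAG"
ADAPTOR_B = "CTATGCGCCTTGCCAGCCCGCTCAG"
BARCODES: Mapping[str, str] = {
    "lean": "ACGAGTGCGT",
    "obob": "ACGCTCGACA",
}
FORWARD_PRIMER = "TGCTGATATGCTGGTGGGACT"
REVERSE_PRIMER = "TCGTCCCTCAGTCCAATCACAG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class DemuxConfig:
    adaptor_a: str = ADAPTOR_A
    adaptor_b: str = ADAPTOR_B
    barcodes: Mapping[str, str] = field(default_factory=lambda: dict(BARCODES))
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    max_barcode_mismatches: int = 1
    max_adaptor_mismatches: int = 1
    max_primer_mismatches: int = 2

    def __post_init__(self) -> None:
        for name, seq in (
            ("adaptor_a", self.adaptor_a),
            ("adaptor_b", self.adaptor_b),
            ("forward_primer", self.forward_primer),
            ("reverse_primer", self.reverse_primer),
            *((f"barcode[{g}]", b) for g, b in self.barcodes.items()),
        ):
            if not seq or set(seq.upper()) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty ACGT string")
        codes = list(self.barcodes.values())
        if len(set(codes)) != len(codes):
            raise ValueError("barcodes must be distinct")
        lengths = {len(b) for b in codes}
        if len(lengths) != 1:
            raise ValueError("barcodes must share one length")
        for i, x in enumerate(codes):
            for y in codes[i + 1 :]:
                if hamming(x, y) <= 2 * self.max_barcode_mismatches:
                    raise ValueError(
                        "barcode pair too close for the mismatch tolerance: "
                        f"{x} vs {y}"
                    )


@dataclass(frozen=True)
class QcThresholds:
    """Published Lucy screen thresholds (error probabilities)."""

    max_avg_error: float = 0.025
    max_end_error: float = 0.02
    end_window: int = 2

    def __post_init__(self) -> None:
        for name, p in (("max_avg_error", self.max_avg_error), ("max_end_error", self.max_end_error)):
            if not 0 < p < 1:
                raise ValueError(f"{name} must lie in (0,1)")
        if self.end_window < 1:
            raise ValueError("end_window must be >= 1")


@dataclass(frozen=True)
class DemuxResult:
    group: str | None
    read: Read | None
    reverse_complemented: bool = False

    @property
    def assigned(self) -> bool:
        return self.group is not None


def _match_prefix(seq: str, prefix: str, max_mm: int) -> bool:
    return len(seq) >= len(prefix) and hamming(seq[: len(prefix)], prefix) <= max_mm


def _assign_oriented(seq: str, cfg: DemuxConfig) -> tuple[str, int] | None:
    """Match adaptor A then the best barcode at the read start; return
    (group, insert_start) or None."""
    na = len(cfg.adaptor_a)
    nb = len(next(iter(cfg.barcodes.values())))
    np_ = len(cfg.forward_primer)
    if len(seq) <= na + nb + np_:
        return None
    if hamming(seq[:na], cfg.adaptor_a) > cfg.max_adaptor_mismatches:
        return None
    window = seq[na : na + nb]
    best_group, best_mm = None, None
    for group, barcode in cfg.barcodes.items():
        mm = hamming(window, barcode)
        if best_mm is None or mm < best_mm:
            best_group, best_mm = group, mm
    if best_mm is None or best_mm > cfg.max_barcode_mismatches:
        return None
    # The forward primer must sit directly after the barcode; reads whose
    # primer cannot be located are unassigned (no cassette to call).
    primer_at = na + nb
    if hamming(seq[primer_at : primer_at + np_], cfg.forward_primer) > cfg.max_primer_mismatches:
        return None
    return best_group, primer_at + np_


def _trim_tail(seq: str, quals: list[int] | None, cfg: DemuxConfig) -> tuple[str, list[int] | None]:
    """Strip the reverse-complemented adaptor B and reverse primer, if present."""
    for tail, max_mm in (
        (reverse_complement(cfg.adaptor_b), cfg.max_adaptor_mismatches),
        (reverse_complement(cfg.reverse_primer), cfg.max_primer_mismatches),
    ):
        n = len(tail)
        if len(seq) >= n and hamming(seq[-n:], tail) <= max_mm:
            seq = seq[:-n]
            if quals is not None:
                quals = quals[:-n]
    return seq, quals


def assign_group(read: Read, cfg: DemuxConfig | None = None) -> DemuxResult:
    """Assign a read to its barcode group and trim the amplicon scaffolding.

    The adaptor-A + barcode + forward-primer prefix is searched on the read
    and on its reverse complement; on a match the read is reoriented to the
    sense strand and trimmed of adaptor, barcode and primers.  Unassigned is
    a status, not an error.
    """
    if cfg is None:
        cfg = DemuxConfig()
    for flipped in (False, True):
        if flipped:
            seq = reverse_complement(read.sequence)
            quals = list(read.qualities)[::-1] if read.qualities is not None else None
        else:
            seq = read.sequence
            quals = list(read.qualities) if read.qualities is not None else None
        hit = _assign_oriented(seq, cfg)
        if hit is None:
            continue
        group, start = hit
        seq, quals = seq[start:], quals[start:] if quals is not None else None
        seq, quals = _trim_tail(seq, quals, cfg)
        trimmed = Read(id=read.id, sequence=seq, qualities=quals)
        return DemuxResult(group=group, read=trimmed, reverse_complemented=flipped)
    return DemuxResult(group=None, read=None)


def phred_to_error(q: float) -> float:
    """Error probability for a Phred score: 10^(-q/10)."""
    if q < 0:
        raise ValueError("Phred scores are non-negative")
    return 10.0 ** (-q / 10.0)


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str | None = None  # "average" or "end" when failed


def lucy_filter(read: Read, thr: QcThresholds | None = None) -> FilterResult:
    """Accept/reject a read on the two published error-probability thresholds."""
    if thr is None:
        thr = QcThresholds()
    if read.qualities is None:
        raise ValueError(f"read {read.id} has no qualities; filter inapplicable")
    errors = [phred_to_error(q) for q in read.qualities]
    if not errors:
        raise ValueError(f"read {read.id} is empty")
    if sum(errors) / len(errors) > thr.max_avg_error:
        return FilterResult(passed=False, reason="average")
    w = min(thr.end_window, len(errors))
    if any(e > thr.max_end_error for e in errors[:w] + errors[-w:]):
        return FilterResult(passed=False, reason="end")
    return FilterResult(passed=True)
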