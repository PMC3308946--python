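"""Per-read alignment to the cassette reference and editing-site calling.

Each trimmed, sense-oriented read is aligned glocally (reference global,
read end-gaps free) to the unedited cassette with affine gap penalties.
The base landing on each of the five site offsets is then read off:
A means unedited, G means edited (A-to-I editing surfaces as A->G in
cDNA), and anything else — C, T, N or a gap — is ambiguous sequencing
error.  A read with any ambiguous site is rejected as a whole; per-site
tallies that keep the unambiguous sites of such reads are available
downstream.

Alignment identity is assessed over the non-site reference positions only:
the five editable positions legitimately mismatch the unedited reference
on edited molecules and carry no information about read quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import Align

from .editing_model import CassetteReference, EditingCode, SITE_ORDER
from .io_formats import Read

UNEDITED = "unedited"
EDITED = "edited"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    min_identity: float = 0.8  # over non-site reference positions
    max_span_slack: int = 10  # extra read bases the cassette window may span

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0:
            raise ValueError("require match > 0 >= mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")


@dataclass(frozen=True)
class CassetteAlignment:
    """Mapping of reference positions onto a read, with a QC verdict."""

    read_id: str
    ref_to_read: Mapping[int, int | None]  # 1-based ref offset -> 0-based read index
    identity: float  # fraction of non-site reference positions matching
    score: float
    accepted: bool
    reject_reason: str | None = None


def _build_aligner(p: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    # Free end gaps on the target (the read): the short reference aligns
    # globally into a window of the read.
    try:
        aligner.end_insertion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
    return aligner


def align_to_reference(
    read: Read,
    ref: CassetteReference,
    params: AlignmentParams | None = None,
) -> CassetteAlignment:
    """Glocal alignment of the unedited cassette into a read.

    Rejects when the aligned span fails to place all five site offsets on
    read bases (reason ``span``) or when non-site identity falls below
    ``min_identity`` (reason ``identity``).
    """
    if params is None:
        params = AlignmentParams()
    if not read.sequence:
        raise ValueError(f"read {read.id} is empty")
    site_offsets = set(ref.site_offsets.values())

    mapping: dict[int, int | None] = {off: None for off in range(1, len(ref.sequence) + 1)}
    aligner = _build_aligner(params)
    alignment = aligner.align(read.sequence, ref.sequence)[0]
    tblocks, qblocks = alignment.aligned
    matches = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for k in range(qe - qs):
            qpos = qs + k + 1  # 1-based reference offset
            tidx = ts + k
            mapping[qpos] = tidx
            if qpos not in site_offsets and read.sequence[tidx] == ref.sequence[qpos - 1]:
                matches += 1
    n_nonsite = len(ref.sequence) - len(site_offsets)
    identity = matches / n_nonsite if n_nonsite else 1.0

    accepted, reason = True, None
    mapped = [idx for idx in mapping.values() if idx is not None]
    window = (max(mapped) - min(mapped) + 1) if mapped else 0
    if any(mapping[off] is None for off in site_offsets):
        accepted, reason = False, "span"
    elif window > len(ref.sequence) + params.max_span_slack:
        # A genuine cassette occupies a compact read window; a scattered,
        # heavily gapped placement is a spurious hit on flanking sequence.
        accepted, reason = False, "span"
    elif identity < params.min_identity:
        accepted, reason = False, "identity"
    return CassetteAlignment(
        read_id=read.id,
        ref_to_read=mapping,
        identity=identity,
        score=alignment.score,
        accepted=accepted,
        reject_reason=reason,
    )


@dataclass
class SiteCalls:
    """Editing-state calls for one read at the five cassette sites."""

    read_id: str
    group: str | None
    calls: Mapping[str, str]  # site -> unedited | edited | ambiguous
    status: str  # "classified" | "rejected"
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if set(self.calls) != set(SITE_ORDER):
            raise ValueError("calls must be keyed exactly by A,B,E,C,D")
        has_ambiguous = any(v == AMBIGUOUS for v in self.calls.values())
        if self.status == "classified" and has_ambiguous:
            raise ValueError("classified calls may not contain ambiguous sites")

    @property
    def classified(self) -> bool:
        return self.status == "classified"


def _call_base(base: str | None) -> str:
    if base == "A":
        return UNEDITED
    if base == "G":
        return EDITED
    return AMBIGUOUS  # C, T, N or a gap


def call_sites(
    read: Read,
    ref: CassetteReference,
    params: AlignmentParams | None = None,
    group: str | None = None,
) -> SiteCalls:
    """Align a read and call the editing state at each of the five sites."""
    aln = align_to_reference(read, ref, params)
    calls: dict[str, str] = {}
    for site in SITE_ORDER:
        idx = aln.ref_to_read[ref.site_offsets[site]]
        calls[site] = _call_base(read.sequence[idx] if idx is not None else None)
    if not aln.accepted:
        return SiteCalls(read.id, group, calls, "rejected", aln.reject_reason)
    ambiguous = [s for s in SITE_ORDER if calls[s] == AMBIGUOUS]
    if ambiguous:
        return SiteCalls(read.id, group, calls, "rejected", "ambiguous:" + "".join(ambiguous))
    return SiteCalls(read.id, group, calls, "classified")


def code_of(calls: SiteCalls) -> EditingCode:
    """Editing code of a classified read; ambiguous calls must be filtered first."""
    if not calls.classified:
        raise ValueError(
            f"read {calls.read_id} is not classified ({calls.reject_reason})"
        )
    return EditingCode(*(calls.calls[s] == EDITED for s in SITE_ORDER))


def call_many(
    reads: Iterable[tuple[Read, str | None]],
    ref: CassetteReference,
    params: AlignmentParams | None = None,
) -> list[SiteCalls]:
    """Call sites for (read, group) pairs; every input read is accounted for."""
    if params is None:
        params = AlignmentParams()
    return [call_sites(read, ref, params, group) for read, group in reads]


CALLS_TABLE_HEADER = ["read_id", "group", *SITE_ORDER, "status", "reason"]


def write_calls_table(calls: Iterable[SiteCalls], path) -> int:
    """Write per-read site calls as TSV (one row per read)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(CALLS_TABLE_HEADER) + "\n")
        for sc in calls:
            cells = [sc.read_id, sc.group or "", *(sc.calls[s] for s in SITE_ORDER),
                     sc.status, sc.reject_reason or ""]
            fh.write("\t".join(cells) + "\n")
            n += 1
    return n


def read_calls_table(path) -> list[SiteCalls]:
    """Read a calls TSV back into SiteCalls records."""
    out: list[SiteCalls] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALLS_TABLE_HEADER:
            raise ValueError(f"{path}: unexpected calls-table header {header}")
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            row = dict(zip(CALLS_TABLE_HEADER, cells))
            out.append(
                SiteCalls(
                    read_id=row["read_id"],
                    group=row["group"] or None,
                    calls={s: row[s] for s in SITE_ORDER},
                    status=row["status"],
                    reject_reason=row["reason"] or None,
                )
            )
    return out
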