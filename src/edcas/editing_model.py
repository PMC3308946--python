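"""Combinatorics of the 5-HT2C editing cassette.

The second intracellular loop of the serotonin 2C receptor transcript
carries five adenosines (sites A, B, E, C, D in 5'->3' order) that ADAR
enzymes can deaminate to inosine.  Inosine is read as guanosine by reverse
transcription, so editing appears in cDNA as A->G substitutions.  The five
binary states yield 2^5 = 32 mRNA isoforms; because the substitutions fall
in three codons, only 24 distinct amino-acid triplets are encoded.

This module defines the editing code, its rendering as the 19-character
dash-delimited pattern used in isoform tables, the translation of a code
into its protein triplet, and the unedited cassette reference sequence with
the five site offsets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Mapping

from Bio.Seq import Seq

#: Canonical 5'->3' site order used everywhere in this package.
SITE_ORDER = "ABECD"

# Unedited (INI) cassette core, reconstructed from the allele-specific
# hybridisation probes; the five editable adenosines sit at 1-based
# offsets 6, 8, 12, 13 and 18.
CASSETTE_CORE = "TAGCAATACGTAATCCTATTG"
CORE_SITE_OFFSETS: Mapping[str, int] = {"A": 6, "B": 8, "E": 12, "C": 13, "D": 18}
CORE_FRAME_OFFSET = 6

#: Allele-specific probe sequences (lower case as published); only the five
#: site positions are treated as authoritative — the VNV probe carries an
#: unexplained extra terminal base.
ISOFORM_PROBES: Mapping[str, str] = {
    "INI": "tagcaatacgtaatcctattg",
    "VNV": "tagcagtgcgtaatcctgttga",
    "VSV": "tagcagtgcgtagtcctgttg",
    "VGV": "tagcagtgcgtggtcctgttg",
    "VNI": "tagcagtgcgtaatcctattg",
}
PROBE_EDITED_SITES: Mapping[str, str] = {
    "INI": "",
    "VNV": "ABD",
    "VSV": "ABCD",
    "VGV": "ABECD",
    "VNI": "AB",
}

# Fixed filler flanks used only by the read simulator, sized so the full
# amplicon (adaptor + barcode + primers + cassette) is ~300 bp.
DEFAULT_FLANK5 = (
    "ATAGGCATAAGATGAACTAGTCTTGGTCCAAGTTAGCCAACCTAACTAGTCGATATGAGG"
    "AATCATGTCGGCTTGGCCTGAACTAGGCGT"
)
DEFAULT_FLANK3 = (
    "TACAGAATCGCCGATTCGCTCCGTGGATACGCGGTCAGCACTACCAGATCACAAGATGTG"
    "ACAGACAGTATGACCAATAGCTGCCA"
)

# 0-based indices of the five sites within the 19-character display pattern
# "AnA-nnn-AAn-nnn-Ann".
_PATTERN_SITE_INDEX = {"A": 0, "B": 2, "E": 8, "C": 9, "D": 16}
_PATTERN_TEMPLATE = "nnn-nnn-nnn-nnn-nnn"
PATTERN_LENGTH = 19


@dataclass(frozen=True, order=True)
class EditingCode:
    """Edited/unedited state at the five cassette sites (True = edited)."""

    a: bool
    b: bool
    e: bool
    c: bool
    d: bool

    @property
    def flags(self) -> tuple[bool, bool, bool, bool, bool]:
        return (self.a, self.b, self.e, self.c, self.d)

    @property
    def edited_sites(self) -> str:
        """Subset of 'ABECD' that is edited, in canonical order."""
        return "".join(s for s, f in zip(SITE_ORDER, self.flags) if f)

    @classmethod
    def from_sites(cls, sites: str) -> "EditingCode":
        sites = sites.upper()
        unknown = set(sites) - set(SITE_ORDER)
        if unknown:
            raise ValueError(f"unknown editing sites: {sorted(unknown)}")
        return cls(*(s in sites for s in SITE_ORDER))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.edited_sites or "unedited"


def enumerate_codes() -> list[EditingCode]:
    """All 32 editing codes, lexicographic over (a, b, e, c, d), unedited first."""
    return [EditingCode(*flags) for flags in product((False, True), repeat=5)]


@dataclass(frozen=True)
class CassetteReference:
    """Unedited cassette sequence with 1-based site offsets.

    ``sequence`` is the sense strand of the editing region; every site
    offset must hold an ``A`` (the unedited state).  ``frame_offset`` is the
    1-based start of the first affected codon.  The flanks are only used by
    the synthetic read generator to build realistic ~300 bp amplicons.
    """

    sequence: str
    site_offsets: Mapping[str, int]
    frame_offset: int
    amplicon_flank5: str = ""
    amplicon_flank3: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(self.site_offsets) != set(SITE_ORDER):
            raise ValueError("site_offsets must be keyed exactly by A,B,E,C,D")
        offsets = [self.site_offsets[s] for s in SITE_ORDER]
        if offsets != sorted(offsets) or len(set(offsets)) != 5:
            raise ValueError("site offsets must be strictly increasing A<B<E<C<D")
        for site, off in self.site_offsets.items():
            if not 1 <= off <= len(seq):
                raise ValueError(f"site {site} offset {off} outside sequence")
            if seq[off - 1] != "A":
                raise ValueError(f"reference must be unedited: site {site} is {seq[off - 1]}")
        # Codon structure: A,B at codon positions 1,3; E,C at positions 1,2 of
        # the codon two codons downstream; D at position 1 of the next codon.
        f = self.frame_offset
        oa, ob, oe, oc, od = offsets
        if (oa, ob) != (f, f + 2):
            raise ValueError("sites A and B must occupy positions 1 and 3 of the first codon")
        if (oe, oc) != (f + 6, f + 7):
            raise ValueError("sites E and C must occupy positions 1 and 2 of the third codon")
        if od != f + 12:
            raise ValueError("site D must occupy position 1 of the fifth codon")

    def edited_sequence(self, code: EditingCode) -> str:
        """Cassette sequence with G substituted at the code's edited sites."""
        seq = list(self.sequence)
        for site, flag in zip(SITE_ORDER, code.flags):
            if flag:
                seq[self.site_offsets[site] - 1] = "G"
        return "".join(seq)

    def codons(self) -> list[str]:
        """The in-frame codons of the editing region, starting at frame_offset."""
        start = self.frame_offset - 1
        usable = (len(self.sequence) - start) // 3 * 3
        region = self.sequence[start : start + usable]
        return [region[i : i + 3] for i in range(0, usable, 3)]


def default_reference() -> CassetteReference:
    """Built-in cassette reference derived from the unedited probe sequence.

    Validated on construction against the published edited-isoform probes:
    at each of the five site offsets, every probe carries G exactly at its
    edited sites and A elsewhere.
    """
    ref = CassetteReference(
        sequence=CASSETTE_CORE,
        site_offsets=dict(CORE_SITE_OFFSETS),
        frame_offset=CORE_FRAME_OFFSET,
        amplicon_flank5=DEFAULT_FLANK5,
        amplicon_flank3=DEFAULT_FLANK3,
    )
    for name, probe in ISOFORM_PROBES.items():
        edited = PROBE_EDITED_SITES[name]
        probe = probe.upper()
        for site, off in ref.site_offsets.items():
            expected = "G" if site in edited else "A"
            if probe[off - 1] != expected:
                raise AssertionError(
                    f"probe {name} disagrees with reference at site {site}"
                )
    return ref


def translate_code(code: EditingCode, ref: CassetteReference | None = None) -> str:
    """Protein triplet encoded by the three affected codons of a code.

    The edited cassette is translated in frame; the triplet is the amino
    acids of codons 1, 3 and 5 (the codons carrying sites A/B, E/C and D).
    Unedited yields INI; fully edited yields VGV.
    """
    if ref is None:
        ref = default_reference()
    start = ref.frame_offset - 1
    usable = (len(ref.sequence) - start) // 3 * 3
    region = ref.edited_sequence(code)[start : start + usable]
    aa = str(Seq(region).translate())
    return aa[0] + aa[2] + aa[4]


def count_distinct_proteins() -> int:
    """Number of distinct protein triplets over all 32 editing codes."""
    return len({translate_code(c) for c in enumerate_codes()})


def pattern_for_code(code: EditingCode) -> str:
    """Render a code as the 19-character display pattern, e.g. GnG-nnn-AAn-nnn-Gnn."""
    chars = list(_PATTERN_TEMPLATE)
    for site, flag in zip(SITE_ORDER, code.flags):
        chars[_PATTERN_SITE_INDEX[site]] = "G" if flag else "A"
    return "".join(chars)


def parse_pattern(pattern: str) -> EditingCode:
    """Inverse of :func:`pattern_for_code`; strict about shape."""
    if len(pattern) != PATTERN_LENGTH:
        raise ValueError(f"pattern must be {PATTERN_LENGTH} characters, got {len(pattern)}")
    site_by_index = {i: s for s, i in _PATTERN_SITE_INDEX.items()}
    flags: dict[str, bool] = {}
    for i, ch in enumerate(pattern):
        if i in (3, 7, 11, 15):
            if ch != "-":
                raise ValueError(f"expected '-' at pattern position {i + 1}")
        elif i in site_by_index:
            if ch not in "AG":
                raise ValueError(
                    f"site {site_by_index[i]} must be A or G, got {ch!r}"
                )
            flags[site_by_index[i]] = ch == "G"
        elif ch != "n":
            raise ValueError(f"expected 'n' at pattern position {i + 1}, got {ch!r}")
    return EditingCode(*(flags[s] for s in SITE_ORDER))


@dataclass(frozen=True)
class IsoformRecord:
    """One row of the 32-isoform taxonomy."""

    code: EditingCode
    pattern: str
    protein: str
    label: str
    edited_sites: str = field(default="")

    def __post_init__(self) -> None:
        if not self.edited_sites:
            object.__setattr__(self, "edited_sites", self.code.edited_sites)
        if parse_pattern(self.pattern) != self.code:
            raise ValueError(f"pattern {self.pattern} inconsistent with code {self.code}")
        if translate_code(self.code) != self.protein:
            raise ValueError(f"protein {self.protein} inconsistent with code {self.code}")


def load_taxonomy() -> list[IsoformRecord]:
    """The packaged 32-row isoform taxonomy, in published table order.

    Each record is validated on load: pattern and protein must both be
    derivable from the edited-site set.
    """
    records: list[IsoformRecord] = []
    path = resources.files("edcas").joinpath("data/isoform_taxonomy.tsv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            code = EditingCode.from_sites(row["edited_sites"].replace("-", ""))
            records.append(
                IsoformRecord(
                    code=code,
                    pattern=row["pattern"],
                    protein=row["protein"],
                    label=row["label"],
                )
            )
    if len(records) != 32 or len({r.code for r in records}) != 32:
        raise ValueError("taxonomy must contain each of the 32 codes exactly once")
    return records


def taxonomy_by_code() -> dict[EditingCode, IsoformRecord]:
    return {r.code: r for r in load_taxonomy()}


def isoform_name(code: EditingCode) -> str:
    """Short display name, e.g. 'VNV (ABD)' or 'INI (unedited)'."""
    protein = translate_code(code)
    sites = code.edited_sites or "unedited"
    return f"{protein} ({sites})"
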