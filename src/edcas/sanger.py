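"""Editing-frequency estimation from Sanger chromatogram peak heights.

At an editing site a partially edited RNA pool yields two superimposed
peaks: A (unedited molecules) and G (edited molecules, via A-to-I).  The
gross editing frequency is X = G / (A + G) on the two channel heights; a
site-specific multiplicative calibration converts it to the reported
frequency (factors 1.114 for site A and 1.009 for site B, unity for the
remaining sites, which were not calibrated).  Traces sequenced from the
antisense primer are handled by auto-detecting the orientation and
complementing channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .editing_model import CassetteReference, SITE_ORDER
from .io_formats import ChromatogramTrace, CHANNELS, Read
from .site_calling import AlignmentParams, align_to_reference

DEFAULT_FACTORS: Mapping[str, float] = {"A": 1.114, "B": 1.009, "E": 1.0, "C": 1.0, "D": 1.0}


@dataclass(frozen=True)
class SangerCalibration:
    factors: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FACTORS))

    def __post_init__(self) -> None:
        if set(self.factors) != set(SITE_ORDER):
            raise ValueError("calibration must cover exactly sites A,B,E,C,D")
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("calibration factors must be positive")

    def factor(self, site: str) -> float:
        if site not in self.factors:
            raise KeyError(f"unknown editing site {site!r}")
        return self.factors[site]


def gross_frequency(a_height: float, g_height: float) -> float:
    """Gross editing frequency X = G / (A + G) from two peak heights."""
    if a_height < 0 or g_height < 0:
        raise ValueError("peak heights must be non-negative")
    total = a_height + g_height
    if total == 0:
        raise ValueError("no signal: both A and G peak heights are zero")
    return g_height / total


def calibrated_frequency(
    site: str, gross: float, cal: SangerCalibration | None = None
) -> float:
    """Site-calibrated frequency, clamped to [0, 1]."""
    if cal is None:
        cal = SangerCalibration()
    if not 0 <= gross <= 1:
        raise ValueError("gross frequency must lie in [0, 1]")
    return min(1.0, max(0.0, cal.factor(site) * gross))


@dataclass(frozen=True)
class SiteEditingEstimate:
    site: str
    a_height: float
    g_height: float
    gross: float
    calibrated: float
    missing: bool = False


def reverse_complement_trace(trace: ChromatogramTrace) -> ChromatogramTrace:
    """Reverse the trace and swap complementary channels (A<->T, C<->G)."""
    comp_order = [CHANNELS.index(b) for b in ("T", "G", "C", "A")]
    heights = trace.heights[::-1, comp_order]
    called = trace.called_bases.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    return ChromatogramTrace(heights=heights.copy(), called_bases=called)


def _orient(trace: ChromatogramTrace, ref: CassetteReference, params: AlignmentParams):
    """Align the called-base sequence in both orientations; keep the better."""
    best = None
    for flipped in (False, True):
        t = reverse_complement_trace(trace) if flipped else trace
        aln = align_to_reference(Read(id="trace", sequence=t.called_bases), ref, params)
        key = (aln.accepted, aln.score)
        if best is None or key > best[0]:
            best = (key, t, aln)
    _, oriented, aln = best
    return oriented, aln


def trace_editing_profile(
    trace: ChromatogramTrace,
    ref: CassetteReference | None = None,
    cal: SangerCalibration | None = None,
    params: AlignmentParams | None = None,
) -> dict[str, SiteEditingEstimate]:
    """Per-site gross and calibrated editing frequencies from one trace.

    The trace's called-base sequence is aligned glocally to the unedited
    cassette; orientation (forward vs reverse-complement) is auto-detected
    by alignment score.  Sites outside the aligned span are flagged missing.
    """
    if ref is None:
        from .editing_model import default_reference

        ref = default_reference()
    if cal is None:
        cal = SangerCalibration()
    if params is None:
        params = AlignmentParams()
    oriented, aln = _orient(trace, ref, params)
    a_col, g_col = CHANNELS.index("A"), CHANNELS.index("G")
    profile: dict[str, SiteEditingEstimate] = {}
    for site in SITE_ORDER:
        idx = aln.ref_to_read[ref.site_offsets[site]]
        if idx is None:
            profile[site] = SiteEditingEstimate(site, float("nan"), float("nan"),
                                                float("nan"), float("nan"), missing=True)
            continue
        a_h = float(oriented.heights[idx, a_col])
        g_h = float(oriented.heights[idx, g_col])
        x = gross_frequency(a_h, g_h)
        profile[site] = SiteEditingEstimate(site, a_h, g_h, x, calibrated_frequency(site, x, cal))
    return profile
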