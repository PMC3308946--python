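"""Synthetic inputs for every pipeline stage.

The study's raw pyrosequencing reads were never deposited, so this module
generates amplicon reads with the same structure the wet-lab protocol
produced: 454 adaptor A, a 10-nt group barcode and the cassette forward
primer on the sense 5' end, fixed flanking sequence around the 21-nt
editing cassette, and the reverse complements of the reverse primer and
adaptor B on the 3' end (~300 bp in total).  Reads can be drawn either
from an explicit per-isoform count map (exact composition, for round-trip
checks against published counts) or from independent per-site Bernoulli
editing probabilities.  Substitution errors and Gaussian Phred qualities
are configurable; a fixed seed makes output byte-identical.

Chromatogram traces and qPCR cycle-threshold records are simulated with
the same philosophy: the generator arithmetic is simple enough that the
downstream estimators can be checked against the configured truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

from .editing_model import (
    CassetteReference,
    EditingCode,
    SITE_ORDER,
    default_reference,
)
from .io_formats import ChromatogramTrace, QpcrRecord, Read
from .preprocess import DemuxConfig, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ReadSimConfig:
    """Configuration of the amplicon read simulator.

    ``isoform_counts`` mode draws exactly the configured number of reads
    per (group, code); ``site_probs`` mode draws each site independently
    with the configured per-group probabilities for ``n_reads`` per group.
    """

    mode: str = "site_probs"  # "isoform_counts" | "site_probs"
    isoform_counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    # group -> {edited_sites ('-' or '' = unedited) -> count}
    site_probs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    # group -> {site -> editing probability}
    n_reads: Mapping[str, int] = field(default_factory=dict)  # site_probs mode
    base_error_rate: float = 0.0
    quality_mean: float = 35.0
    quality_sd: float = 2.0
    random_orientation: bool = True
    seed: int = 0
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    ref: CassetteReference = field(default_factory=default_reference)

    def __post_init__(self) -> None:
        if self.mode not in ("isoform_counts", "site_probs"):
            raise ValueError("mode must be 'isoform_counts' or 'site_probs'")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must lie in [0, 1)")
        for group, probs in self.site_probs.items():
            for site, p in probs.items():
                if site not in SITE_ORDER:
                    raise ValueError(f"unknown site {site!r} for group {group}")
                if not 0 <= p <= 1:
                    raise ValueError(f"site probability out of range: {site}={p}")
        for group, counts in self.isoform_counts.items():
            for sites, n in counts.items():
                if n < 0:
                    raise ValueError(f"negative count for {group}/{sites}")
                EditingCode.from_sites(sites.replace("-", ""))  # validates


def table1_counts() -> dict[str, dict[str, int]]:
    """The packaged published per-group isoform counts, keyed by group."""
    path = resources.files("edcas").joinpath("data/table1_counts.yaml")
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)["counts"]
    out: dict[str, dict[str, int]] = {"lean": {}, "obob": {}}
    for sites, per_group in raw.items():
        for group in ("lean", "obob"):
            out[group][str(sites)] = int(per_group[group])
    return out


def _sense_amplicon(cfg: ReadSimConfig, group: str, code: EditingCode) -> str:
    ref, demux = cfg.ref, cfg.demux
    return (
        demux.adaptor_a
        + demux.barcodes[group]
        + demux.forward_primer
        + ref.amplicon_flank5
        + ref.edited_sequence(code)
        + ref.amplicon_flank3
        + reverse_complement(demux.reverse_primer)
        + reverse_complement(demux.adaptor_b)
    )


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _qualities(n: int, cfg: ReadSimConfig, rng: np.random.Generator) -> list[int]:
    q = np.rint(rng.normal(cfg.quality_mean, cfg.quality_sd, size=n))
    return np.clip(q, 2, 41).astype(int).tolist()


def _codes_for_group(cfg: ReadSimConfig, group: str, rng: np.random.Generator) -> list[EditingCode]:
    if cfg.mode == "isoform_counts":
        codes: list[EditingCode] = []
        for sites, n in cfg.isoform_counts.get(group, {}).items():
            code = EditingCode.from_sites(sites.replace("-", ""))
            codes.extend([code] * n)
        return codes
    probs = cfg.site_probs.get(group, {})
    n = int(cfg.n_reads.get(group, 0))
    p = np.array([probs.get(s, 0.0) for s in SITE_ORDER])
    draws = rng.random((n, 5)) < p
    return [EditingCode(*map(bool, row)) for row in draws]


def simulate_reads(cfg: ReadSimConfig) -> Iterator[Read]:
    """Yield simulated amplicon reads, lean group first, deterministically."""
    rng = np.random.default_rng(cfg.seed)
    for group in sorted(cfg.demux.barcodes):
        for i, code in enumerate(_codes_for_group(cfg, group, rng)):
            seq = _sense_amplicon(cfg, group, code)
            flipped = bool(cfg.random_orientation and rng.random() < 0.5)
            if flipped:
                seq = reverse_complement(seq)
            seq = _inject_errors(seq, cfg.base_error_rate, rng)
            sites = code.edited_sites or "unedited"
            yield Read(
                id=f"sim|{group}|{i:06d}|{sites}|{'rc' if flipped else 'fw'}",
                sequence=seq,
                qualities=_qualities(len(seq), cfg, rng),
            )


@dataclass(frozen=True)
class TraceSimConfig:
    """Configuration of the chromatogram simulator."""

    mixture: Mapping[str, float] = field(default_factory=dict)  # site -> edited fraction
    peak_scale: float = 1000.0
    noise_sd: float = 0.0
    orientation: str = "forward"  # "forward" | "reverse_complement"
    seed: int = 0

    def __post_init__(self) -> None:
        for site, m in self.mixture.items():
            if site not in SITE_ORDER:
                raise ValueError(f"unknown site {site!r}")
            if not 0 <= m <= 1:
                raise ValueError(f"mixture fraction out of range: {site}={m}")
        if self.orientation not in ("forward", "reverse_complement"):
            raise ValueError("orientation must be 'forward' or 'reverse_complement'")


def simulate_trace(
    cfg: TraceSimConfig, ref: CassetteReference | None = None
) -> ChromatogramTrace:
    """Simulate a cassette chromatogram from a template mixture.

    At each editing site the A channel carries ``peak_scale * (1 - m)`` and
    the G channel ``peak_scale * m`` (m = edited template fraction); other
    positions put the full scale on the template base.  Gaussian noise is
    added to every channel and clamped at zero.
    """
    if ref is None:
        ref = default_reference()
    rng = np.random.default_rng(cfg.seed)
    offset_to_site = {off: site for site, off in ref.site_offsets.items()}
    n = len(ref.sequence)
    heights = np.zeros((n, 4))
    channel_index = {b: i for i, b in enumerate("ACGT")}
    for pos in range(1, n + 1):
        base = ref.sequence[pos - 1]
        site = offset_to_site.get(pos)
        m = cfg.mixture.get(site, 0.0) if site else 0.0
        if site is not None:
            heights[pos - 1, channel_index["A"]] = cfg.peak_scale * (1.0 - m)
            heights[pos - 1, channel_index["G"]] = cfg.peak_scale * m
        else:
            heights[pos - 1, channel_index[base]] = cfg.peak_scale
    if cfg.noise_sd > 0:
        heights = heights + rng.normal(0.0, cfg.noise_sd, size=heights.shape)
    heights = np.clip(heights, 0.0, None)
    # Keep every position callable even under extreme noise.
    flat = heights.max(axis=1) <= 0
    heights[flat, 0] = 1e-6
    called = "".join("ACGT"[i] for i in heights.argmax(axis=1))
    trace = ChromatogramTrace(heights=heights, called_bases=called)
    if cfg.orientation == "reverse_complement":
        from .sanger import reverse_complement_trace

        trace = reverse_complement_trace(trace)
    return trace


def simulate_qpcr(
    group_delta_ct: Mapping[tuple[str, str], float],
    sigma: float = 0.2,
    n_per_group: int = 8,
    seed: int = 0,
    ref_ct: float = 20.0,
    replicates: int = 3,
) -> list[QpcrRecord]:
    """Simulate triplicate qPCR records from true per-(group, gene) dCt values.

    Biological noise (``sigma``, in Ct units) is applied per sample; the
    technical replicates of a sample repeat its Ct, mirroring a design in
    which replicate wells are averaged before analysis.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[QpcrRecord] = []
    for (group, gene), dct in sorted(group_delta_ct.items()):
        for s in range(n_per_group):
            sample_dct = dct + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            ct = ref_ct + sample_dct
            for _ in range(replicates):
                records.append(
                    QpcrRecord(
                        sample_id=f"{group}_{s + 1:02d}",
                        group=group,
                        gene=gene,
                        ct=float(ct),
                        ref_ct=float(ref_ct),
                    )
                )
    return records
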