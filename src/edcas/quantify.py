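"""Aggregation of site calls into isoform and site-frequency tables.

Two summaries are produced from classified reads:

* the 32-row isoform count table (counts per group plus relative
  occurrences, all percentages taken against the combined two-group grand
  total, matching the published table convention);
* the per-site editing-frequency table with the lean-vs-ob/ob contrast:
  a two-sided Fisher exact test per site, Bonferroni-corrected over the
  five sites.  The site delta is reported as ob/ob minus lean, so a
  positive delta means increased editing in the obese group.

The module also implements the 2^-dCt relative-expression summary for the
qPCR assay (fold change versus the lean group, Welch t-test per gene with
Bonferroni correction across genes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .editing_model import (
    EditingCode,
    SITE_ORDER,
    load_taxonomy,
)
from .io_formats import QpcrRecord
from .site_calling import EDITED, AMBIGUOUS, SiteCalls, code_of

GROUPS = ("lean", "obob")


@dataclass(frozen=True)
class IsoformCountTable:
    """Per-isoform counts and relative occurrences (published table shape)."""

    frame: pd.DataFrame  # columns: label, pattern, protein, edited_sites,
    #                      count_lean, count_obob, count_total, pct_*

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    @property
    def grand_total(self) -> int:
        return int(self.frame["count_total"].sum())

    def row(self, sites: str) -> pd.Series:
        key = sites or "-"
        hit = self.frame[self.frame["edited_sites"] == key]
        if hit.empty:
            raise KeyError(f"no isoform row for edited sites {key!r}")
        return hit.iloc[0]


@dataclass(frozen=True)
class SiteFrequencyTable:
    """Per-site edited fractions per group, with optional test results."""

    frame: pd.DataFrame  # columns: site, edited_lean, total_lean, edited_obob,
    #                      total_obob, pct_lean, pct_obob, delta_pct[, p_value, p_adjusted]

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def row(self, site: str) -> pd.Series:
        return self.frame.set_index("site").loc[site]


def tabulate_isoforms(calls: Iterable[SiteCalls]) -> IsoformCountTable:
    """Count classified reads per (group, editing code).

    All 32 isoform rows are retained even at zero count; percentages are
    computed against the combined grand total and are 0.00 for an empty
    input rather than undefined.
    """
    counts: dict[tuple[str, EditingCode], int] = {}
    for sc in calls:
        if not sc.classified:
            raise ValueError(f"read {sc.read_id} is not classified; filter first")
        if sc.group not in GROUPS:
            raise ValueError(f"unknown group label {sc.group!r} (expected one of {GROUPS})")
        key = (sc.group, code_of(sc))
        counts[key] = counts.get(key, 0) + 1
    records = []
    for rec in load_taxonomy():
        lean = counts.get(("lean", rec.code), 0)
        obob = counts.get(("obob", rec.code), 0)
        records.append(
            {
                "label": rec.label,
                "pattern": rec.pattern,
                "protein": rec.protein,
                "edited_sites": rec.edited_sites or "-",
                "count_lean": lean,
                "count_obob": obob,
                "count_total": lean + obob,
            }
        )
    frame = pd.DataFrame.from_records(records)
    grand = frame["count_total"].sum()
    denom = grand if grand > 0 else 1  # render empty tables as 0.00
    for col in ("lean", "obob", "total"):
        frame[f"pct_{col}"] = 100.0 * frame[f"count_{col}"] / denom
    return IsoformCountTable(frame=frame)


def site_frequencies(
    calls: Iterable[SiteCalls],
    tally: str = "read",
) -> SiteFrequencyTable:
    """Per-site edited fraction per group.

    ``tally='read'`` (default) counts only fully classified reads, so every
    site shares one denominator per group.  ``tally='site'`` additionally
    keeps the unambiguous sites of rejected reads, giving slightly larger,
    site-specific denominators.
    """
    if tally not in ("read", "site"):
        raise ValueError("tally must be 'read' or 'site'")
    edited = {(g, s): 0 for g in GROUPS for s in SITE_ORDER}
    total = {(g, s): 0 for g in GROUPS for s in SITE_ORDER}
    for sc in calls:
        if sc.group not in GROUPS:
            raise ValueError(f"unknown group label {sc.group!r}")
        if tally == "read" and not sc.classified:
            continue
        for site in SITE_ORDER:
            state = sc.calls[site]
            if state == AMBIGUOUS:
                continue
            total[(sc.group, site)] += 1
            if state == EDITED:
                edited[(sc.group, site)] += 1
    records = []
    for site in SITE_ORDER:
        rec: dict[str, object] = {"site": site}
        for g in GROUPS:
            rec[f"edited_{g}"] = edited[(g, site)]
            rec[f"total_{g}"] = total[(g, site)]
            rec[f"pct_{g}"] = (
                100.0 * edited[(g, site)] / total[(g, site)]
                if total[(g, site)] > 0
                else float("nan")  # undefined, flagged as NaN, never silent 0
            )
        rec["delta_pct"] = rec["pct_obob"] - rec["pct_lean"]  # type: ignore[operator]
        records.append(rec)
    return SiteFrequencyTable(frame=pd.DataFrame.from_records(records))


@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test for a 2x2 table.

    The p-value is the sum, over all tables with the observed margins, of
    hypergeometric probabilities no larger than that of the observed table
    (probability-mass two-sided rule).  All computation is in log space,
    so totals of order 10^4 are handled exactly.  The odds ratio is the
    sample OR with a Haldane 0.5 continuity correction when a cell is 0.
    """
    (a, b), (c, d) = ((int(x) for x in row) for row in table)
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    r1, k1 = a + b, a + c
    if n == 0 or r1 in (0, n) or k1 in (0, n):
        # A degenerate margin admits a single table: no evidence either way.
        warnings.warn("Fisher test on a table with an empty margin; p = 1", stacklevel=2)
        or_ = _sample_or(a, b, c, d)
        return FisherResult(((a, b), (c, d)), or_, 1.0)

    # Support of the hypergeometric count in the top-left cell.
    lo = max(0, k1 - (n - r1))
    hi = min(k1, r1)
    xs = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(xs + 1)
        - gammaln(r1 - xs + 1)
        + gammaln(n - r1 + 1)
        - gammaln(k1 - xs + 1)
        - gammaln(n - r1 - (k1 - xs) + 1)
        - (gammaln(n + 1) - gammaln(k1 + 1) - gammaln(n - k1 + 1))
    )
    log_obs = logpmf[a - lo]
    # Relative tolerance guards against ties lost to floating point, as in
    # standard implementations.
    keep = logpmf <= log_obs + 1e-7
    p = float(np.exp(logsumexp(logpmf[keep])))
    p = min(p, 1.0)
    return FisherResult(((a, b), (c, d)), _sample_or(a, b, c, d), p)


def _sample_or(a: int, b: int, c: int, d: int) -> float:
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))  # type: ignore[assignment]
    return (a * d) / (b * c)


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def compare_sites(freq: SiteFrequencyTable) -> SiteFrequencyTable:
    """Fill per-site Fisher p-values, Bonferroni-corrected over the 5 sites."""
    frame = freq.frame.copy()
    ps = []
    for _, row in frame.iterrows():
        el, tl = int(row["edited_lean"]), int(row["total_lean"])
        eo, to = int(row["edited_obob"]), int(row["total_obob"])
        res = fisher_exact_2x2([[el, tl - el], [eo, to - eo]])
        ps.append(res.p_two_sided)
    frame["p_value"] = ps
    frame["p_adjusted"] = [bonferroni(p, len(frame)) for p in ps]
    return SiteFrequencyTable(frame=frame)


def qpcr_fold_change(
    records: Iterable[QpcrRecord],
    reference_group: str = "lean",
) -> pd.DataFrame:
    """Relative expression by the 2^-dCt method and fold change vs lean.

    Technical replicates are averaged per (sample, gene) before the dCt
    transform; per gene the groups are compared by a two-tailed Welch
    t-test on relative expression, Bonferroni-corrected across genes.
    Returns one row per (gene, group) with mean, sem, n, fold_change,
    p_value and p_adjusted (test results repeated on both group rows).
    """
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return pd.DataFrame(
            columns=[
                "gene", "group", "n", "mean_rel_expr", "sem_rel_expr",
                "fold_change", "p_value", "p_adjusted",
            ]
        )
    per_sample = (
        df.groupby(["gene", "group", "sample_id"])[["ct", "ref_ct"]].mean().reset_index()
    )
    per_sample["rel_expr"] = 2.0 ** -(per_sample["ct"] - per_sample["ref_ct"])

    genes = sorted(per_sample["gene"].unique())
    rows = []
    raw_p: dict[str, float] = {}
    for gene in genes:
        sub = per_sample[per_sample["gene"] == gene]
        by_group = {g: s["rel_expr"].to_numpy() for g, s in sub.groupby("group")}
        if reference_group not in by_group:
            raise ValueError(f"gene {gene}: reference group {reference_group!r} missing")
        ref_mean = by_group[reference_group].mean()
        groups = sorted(by_group)
        others = [g for g in groups if g != reference_group]
        if len(others) == 1 and len(by_group[others[0]]) > 1 and len(by_group[reference_group]) > 1:
            raw_p[gene] = float(
                stats.ttest_ind(
                    by_group[others[0]], by_group[reference_group], equal_var=False
                ).pvalue
            )
        else:
            raw_p[gene] = float("nan")
        for g in groups:
            vals = by_group[g]
            rows.append(
                {
                    "gene": gene,
                    "group": g,
                    "n": len(vals),
                    "mean_rel_expr": float(vals.mean()),
                    "sem_rel_expr": float(stats.sem(vals)) if len(vals) > 1 else float("nan"),
                    "fold_change": float(vals.mean() / ref_mean),
                }
            )
    out = pd.DataFrame(rows)
    m = sum(1 for p in raw_p.values() if not math.isnan(p))
    out["p_value"] = out["gene"].map(raw_p)
    out["p_adjusted"] = out["p_value"].map(
        lambda p: bonferroni(p, m) if not math.isnan(p) else float("nan")
    )
    return out
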