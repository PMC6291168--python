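"""Peak-set analytics: overlaps, top-N selection, TSS assignment,
genomic-feature classification and replicate correlation.

Conventions: peak "position" for TSS/region assignment is the interval
midpoint (integer floor). "Upstream" and "downstream" are the 3-kb
flanks 5' of the TSS and 3' of the TES in gene orientation; feature
precedence is upstream > genic > downstream > distal intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .core_io import BinnedTrackSet, GenomeAnnotation, PeakSet

logger = logging.getLogger(__name__)

REGION_LABELS = ("upstream", "genic", "downstream", "distal_intergenic")


@dataclass
class OverlapSummary:
    """Two-way peak overlap counts plus the merged-interval shared count."""

    n_a: int
    n_b: int
    n_a_overlapping_b: int
    n_b_overlapping_a: int
    merged_shared: int


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge strictly overlapping (not merely bookended) sorted intervals."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s < out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out)


def _count_overlapping(query: np.ndarray, subject: np.ndarray, min_overlap: int) -> int:
    """Number of query intervals sharing >= min_overlap bp with any
    individual subject interval (start-sorted sweep with a prefix-max
    bound on subject ends to prune candidates)."""
    if len(query) == 0 or len(subject) == 0:
        return 0
    order = np.lexsort((subject[:, 1], subject[:, 0]))
    starts, ends = subject[order, 0], subject[order, 1]
    max_end = np.maximum.accumulate(ends)
    n = 0
    for s, e in query:
        i_lo = int(np.searchsorted(max_end, s, side="right"))
        i_hi = int(np.searchsorted(starts, e, side="left"))
        hit = False
        for i in range(i_lo, i_hi):
            if min(e, ends[i]) - max(s, starts[i]) >= min_overlap:
                hit = True
                break
        n += hit
    return n


def overlap_peaks(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> OverlapSummary:
    """Two-way overlap summary between two peak sets (Venn-style).

    A peak counts as overlapping when it shares at least ``min_overlap``
    bp with at least one peak of the other set. ``merged_shared`` is the
    number of merged a+b intervals containing at least one peak from
    each set (the merged-interval reading of a Venn intersection).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n_ab = 0
    n_ba = 0
    shared = 0
    chroms = set(a.peaks["chrom"]) | set(b.peaks["chrom"])
    for chrom in chroms:
        ia = a.peaks.loc[a.peaks["chrom"] == chrom, ["start", "end"]].to_numpy(int)
        ib = b.peaks.loc[b.peaks["chrom"] == chrom, ["start", "end"]].to_numpy(int)
        n_ab += _count_overlapping(ia, ib, min_overlap)
        n_ba += _count_overlapping(ib, ia, min_overlap)
        if len(ia) and len(ib):
            merged = _merge_intervals(np.vstack([ia, ib]))
            for s, e in merged:
                has_a = _count_overlapping(np.array([[s, e]]), ia, 1) > 0
                has_b = _count_overlapping(np.array([[s, e]]), ib, 1) > 0
                shared += has_a and has_b
    return OverlapSummary(len(a), len(b), n_ab, n_ba, shared)


def select_top_peaks(p: PeakSet, n: int) -> PeakSet:
    """The n highest-score peaks; ties broken by (chrom, start) so the
    result is independent of input order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= len(p):
        if n > len(p):
            logger.warning("requested top %d of %d peaks; returning all", n, len(p))
        return PeakSet(p.target, p.condition, p.peaks.copy())
    df = p.peaks.sort_values(["score", "chrom", "start"],
                             ascending=[False, True, True], kind="mergesort")
    return PeakSet(p.target, p.condition, df.head(n).reset_index(drop=True))


def assign_nearest_tss(p: PeakSet, annotation: GenomeAnnotation,
                       max_dist: int = 1_000_000) -> pd.DataFrame:
    """Assign each peak to the nearest TSS within ``max_dist`` bp.

    Distance is measured from the peak midpoint. The signed distance is
    negative when the peak lies 5' of the TSS in gene orientation.
    Equidistant TSSs resolve to the smaller TSS coordinate (then
    lexicographic gene id), logged. Peaks with no TSS in range get
    gene_id None.
    """
    genes = annotation.genes
    tss_all = annotation.tss
    rows = []
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, sub in genes.groupby("chrom"):
        t = tss_all[sub["gene_id"]].to_numpy()
        order = np.lexsort((sub["gene_id"].to_numpy(), t))
        by_chrom[chrom] = pd.DataFrame({
            "gene_id": sub["gene_id"].to_numpy()[order],
            "tss": t[order],
            "strand": sub["strand"].to_numpy()[order],
        })
    for _, peak in p.peaks.iterrows():
        mid = (int(peak.start) + int(peak.end)) // 2
        sub = by_chrom.get(peak.chrom)
        gene_id, signed = None, np.nan
        if sub is not None and len(sub):
            d = np.abs(sub["tss"].to_numpy() - mid)
            best = int(np.argmin(d))  # argmin takes the first = smaller TSS on ties
            if (d == d[best]).sum() > 1:
                logger.info("peak %s: equidistant TSSs; kept smaller coordinate", peak["name"])
            if d[best] <= max_dist:
                gene_id = sub["gene_id"].iloc[best]
                tss = int(sub["tss"].iloc[best])
                signed = mid - tss if sub["strand"].iloc[best] == "+" else tss - mid
        rows.append({"name": peak["name"], "chrom": peak.chrom,
                     "midpoint": mid, "gene_id": gene_id, "distance": signed})
    return pd.DataFrame(rows)


def classify_regions(p: PeakSet, annotation: GenomeAnnotation,
                     flank: int = 3000) -> pd.Series:
    """Label each peak upstream / genic / downstream / distal_intergenic.

    Membership is by peak midpoint; upstream is the ``flank`` bp 5' of
    the TSS and downstream the ``flank`` bp 3' of the TES, both
    strand-aware; precedence upstream > genic > downstream > distal.
    """
    genes = annotation.genes
    labels = []
    gb = {c: s for c, s in genes.groupby("chrom")}
    for _, peak in p.peaks.iterrows():
        mid = (int(peak.start) + int(peak.end)) // 2
        sub = gb.get(peak.chrom)
        label = "distal_intergenic"
        if sub is not None:
            st = sub["start"].to_numpy()
            en = sub["end"].to_numpy()
            plus = (sub["strand"] == "+").to_numpy()
            up = np.where(plus, (mid >= st - flank) & (mid < st),
                          (mid >= en) & (mid < en + flank))
            genic = (mid >= st) & (mid < en)
            down = np.where(plus, (mid >= en) & (mid < en + flank),
                            (mid >= st - flank) & (mid < st))
            if up.any():
                label = "upstream"
            elif genic.any():
                label = "genic"
            elif down.any():
                label = "downstream"
        labels.append(label)
    return pd.Series(labels, index=p.peaks.index, name="region")


def replicate_correlation(rep1: BinnedTrackSet, rep2: BinnedTrackSet,
                          bin_size: int = 10_000) -> dict[str, float]:
    """Pearson r between two replicate track sets, per mark.

    Both track sets are re-binned to ``bin_size`` by summation and the
    correlation is computed over all bins genome-wide.
    """
    if rep1.marks != rep2.marks:
        raise ValueError("replicates carry different marks")
    if set(rep1.chroms) != set(rep2.chroms):
        raise ValueError("replicates cover different chromosomes")
    r1 = rep1.rebin(bin_size) if bin_size != rep1.bin_size else rep1
    r2 = rep2.rebin(bin_size) if bin_size != rep2.bin_size else rep2
    out = {}
    for j, mark in enumerate(r1.marks):
        x = np.concatenate([r1.counts[c][:, j] for c in sorted(r1.chroms)])
        y = np.concatenate([r2.counts[c][:, j] for c in sorted(r1.chroms)])
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"constant track for mark {mark}")
        out[mark] = float(pearsonr(x, y).statistic)
    return out
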