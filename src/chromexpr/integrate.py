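"""Integrative statistics linking chromatin state to expression.

Three analyses:

* :func:`differential_k27ac` — per-region differential H3K27Ac between
  control and double-knockdown coverage. Without replicates, the
  defensible exact test is a two-sided binomial test of the knockdown
  share of the region's pooled (library-size-normalized) counts, with
  Benjamini-Hochberg FDR across regions and a minimum |log2 fold
  change|. A region is "decreased" when q < alpha and
  log2fc <= -lfc_min.
* :func:`fisher_association` — one-sided Fisher exact enrichment
  between per-chromatin-class gene lists and expression-cluster gene
  lists, evaluated as a hypergeometric upper tail in log space.
* :func:`candidate_screen` — the five-criterion direct-target screen:
  (a) ERG and FLI1 peaks near the TSS, (b) such a TF peak overlapping a
  control H3K27Ac peak, (c) that H3K27Ac peak intersecting a decreased
  differential region, (d) double-knockdown expression below 30% of
  control, (e) double knockdown below both single knockdowns
  (day-3 group means, strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from ._stats import bh_adjust, fisher_enrichment
from .core_io import BinnedTrackSet, GenomeAnnotation, PeakSet
from .hmm import StatePath

logger = logging.getLogger(__name__)


@dataclass
class DifferentialRegion:
    chrom: str
    start: int
    end: int
    count_control: float
    count_knockdown: float
    log2fc: float
    p: float
    q: float
    direction: str  # decreased | increased | unchanged


@dataclass
class AssociationResult:
    """One (class, cluster) Fisher table with its enrichment statistics."""

    class_id: int
    cluster_id: object
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    p: float

    @property
    def universe(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass
class CandidateRecord:
    gene_id: str
    flags: dict = field(default_factory=dict)
    is_candidate: bool = False


# ---------------------------------------------------------------------------
# differential H3K27Ac
# ---------------------------------------------------------------------------

def regions_from_peaks(peaks: PeakSet) -> list[tuple[str, int, int]]:
    """Peak intervals with strictly overlapping ones merged (bookended
    peaks stay separate)."""
    out: list[tuple[str, int, int]] = []
    for chrom, sub in peaks.peaks.groupby("chrom"):
        iv = sub[["start", "end"]].to_numpy(int)
        iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
        cur = None
        for s, e in iv:
            if cur is not None and s < cur[1]:
                cur = (cur[0], max(cur[1], int(e)))
            else:
                if cur is not None:
                    out.append((chrom, cur[0], cur[1]))
                cur = (int(s), int(e))
        if cur is not None:
            out.append((chrom, cur[0], cur[1]))
    return out


def _region_counts(track: dict[str, np.ndarray], bin_size: int,
                   regions: list[tuple[str, int, int]]) -> np.ndarray:
    """Sum per-bin counts over each region, prorating partial bins."""
    out = np.zeros(len(regions))
    for i, (chrom, start, end) in enumerate(regions):
        vec = track.get(chrom)
        if vec is None:
            continue
        b0, b1 = start // bin_size, (end - 1) // bin_size
        for b in range(b0, min(b1 + 1, len(vec))):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            out[i] += vec[b] * (hi - lo) / bin_size
    return out


def differential_k27ac(control: BinnedTrackSet, knockdown: BinnedTrackSet,
                       regions: list[tuple[str, int, int]] | PeakSet,
                       control_mark: str = "H3K27Ac_ctrl",
                       knockdown_mark: str = "H3K27Ac_kd",
                       lfc_min: float = 1.0, alpha: float = 0.05
                       ) -> list[DifferentialRegion]:
    """Differential H3K27Ac calling per region.

    ``control`` and ``knockdown`` may be the same BinnedTrackSet holding
    both condition marks. Counts are normalized by total library size;
    each region gets a two-sided binomial test of its knockdown count
    against the expected share under no change, then BH correction.
    """
    if isinstance(regions, PeakSet):
        regions = regions_from_peaks(regions)
    ctrl_vec = control.mark_vector(control_mark)
    kd_vec = knockdown.mark_vector(knockdown_mark)
    total_c = sum(v.sum() for v in ctrl_vec.values())
    total_k = sum(v.sum() for v in kd_vec.values())
    if total_c == 0 or total_k == 0:
        raise ValueError("zero total counts in a condition")
    cnt_c = _region_counts(ctrl_vec, control.bin_size, regions)
    cnt_k = _region_counts(kd_vec, knockdown.bin_size, regions)
    p_null = total_k / (total_c + total_k)
    pvals = np.ones(len(regions))
    log2fc = np.zeros(len(regions))
    for i in range(len(regions)):
        kc, kk = cnt_c[i], cnt_k[i]
        n = int(round(kc + kk))
        if n > 0:
            pvals[i] = binomtest(int(round(kk)), n, p_null).pvalue
        norm_c = kc / total_c
        norm_k = kk / total_k
        if norm_c == 0 or norm_k == 0:
            norm_c += 0.5 / total_c
            norm_k += 0.5 / total_k
        log2fc[i] = np.log2(norm_k / norm_c)
    qvals = bh_adjust(pvals)
    out = []
    for i, (chrom, start, end) in enumerate(regions):
        if qvals[i] < alpha and log2fc[i] <= -lfc_min:
            direction = "decreased"
        elif qvals[i] < alpha and log2fc[i] >= lfc_min:
            direction = "increased"
        else:
            direction = "unchanged"
        out.append(DifferentialRegion(chrom, start, end, float(cnt_c[i]),
                                      float(cnt_k[i]), float(log2fc[i]),
                                      float(pvals[i]), float(qvals[i]), direction))
    return out


# ---------------------------------------------------------------------------
# class -> gene assignment and Fisher association
# ---------------------------------------------------------------------------

def genes_for_class(path: StatePath, annotation: GenomeAnnotation,
                    bin_size: int, window: int = 25_000) -> dict[int, set[str]]:
    """Gene lists per chromatin class: gene g belongs to class c iff at
    least one class-c bin lies within [TSS - window, TSS + window)."""
    tss = annotation.tss
    genes = annotation.genes
    out: dict[int, set[str]] = {c: set() for c in range(path.n_states)}
    for _, row in genes.iterrows():
        arr = path.states.get(row.chrom)
        if arr is None or len(arr) == 0:
            continue
        t = int(tss[row.gene_id])
        lo = max(0, (t - window) // bin_size)
        hi = min(len(arr), -(-(t + window) // bin_size))
        if lo >= hi:
            continue
        for c in np.unique(arr[lo:hi]):
            out[int(c)].add(row.gene_id)
    return out


def fisher_association(class_genes: dict[int, set[str]],
                       cluster_genes: dict[object, set[str]],
                       universe: set[str]) -> list[AssociationResult]:
    """One-sided Fisher enrichment for every (class, cluster) pair.

    Gene sets are intersected with ``universe`` first; p is the
    hypergeometric upper tail of the observed overlap.
    """
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    out = []
    for cid, cset in class_genes.items():
        cset = cset & universe
        for kid, kset in cluster_genes.items():
            kset = kset & universe
            n11 = len(cset & kset)
            n10 = len(cset) - n11
            n01 = len(kset) - n11
            n00 = N - n11 - n10 - n01
            odds, p = fisher_enrichment(n11, n10, n01, n00)
            out.append(AssociationResult(cid, kid, n11, n10, n01, n00, odds, p))
    return out


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "class": r.class_id, "cluster": r.cluster_id, "overlap": r.n11,
        "class_only": r.n10, "cluster_only": r.n01, "neither": r.n00,
        "odds_ratio": r.odds_ratio, "p": r.p,
    } for r in results])


# ---------------------------------------------------------------------------
# candidate screen
# ---------------------------------------------------------------------------

def _intervals_by_chrom(ps: PeakSet) -> dict[str, np.ndarray]:
    return {c: sub[["start", "end"]].to_numpy(int)
            for c, sub in ps.peaks.groupby("chrom")}


def _overlaps_any(s: int, e: int, iv: np.ndarray) -> np.ndarray:
    """Boolean mask of intervals sharing >= 1 bp with [s, e)."""
    if len(iv) == 0:
        return np.zeros(0, dtype=bool)
    return (iv[:, 0] < e) & (iv[:, 1] > s)


def candidate_screen(erg: PeakSet, fli1: PeakSet, k27ac_control: PeakSet,
                     diff: list[DifferentialRegion],
                     expr_group_means: pd.DataFrame,
                     annotation: GenomeAnnotation,
                     upstream_window: int = 25_000,
                     reduction_frac: float = 0.70,
                     tf_mode: str = "both",
                     day: int = 3) -> list[CandidateRecord]:
    """Run the five-criterion direct-target screen over all genes.

    ``expr_group_means`` is the collapsed gene x (treatment, day) linear
    matrix. ``tf_mode`` "both" requires an ERG and a FLI1 peak near the
    TSS; "either" accepts one of the two. A gene absent from the
    expression matrix fails the two expression criteria with a warning.
    """
    if tf_mode not in ("both", "either"):
        raise ValueError("tf_mode must be 'both' or 'either'")
    tss = annotation.tss
    erg_iv = _intervals_by_chrom(erg)
    fli_iv = _intervals_by_chrom(fli1)
    k27_iv = _intervals_by_chrom(k27ac_control)
    dec = {}
    for r in diff:
        if r.direction == "decreased":
            dec.setdefault(r.chrom, []).append((r.start, r.end))
    dec_iv = {c: np.array(v, dtype=int) for c, v in dec.items()}

    missing_expr = 0
    out = []
    for _, row in annotation.genes.iterrows():
        g = row.gene_id
        t = int(tss[g])
        lo, hi = t - upstream_window, t + upstream_window

        def near(iv: dict[str, np.ndarray]) -> np.ndarray:
            arr = iv.get(row.chrom, np.zeros((0, 2), dtype=int))
            if len(arr) == 0:
                return arr
            mid = (arr[:, 0] + arr[:, 1]) // 2
            return arr[(mid >= lo) & (mid < hi)]

        near_erg = near(erg_iv)
        near_fli = near(fli_iv)
        if tf_mode == "both":
            has_upstream = len(near_erg) > 0 and len(near_fli) > 0
        else:
            has_upstream = len(near_erg) > 0 or len(near_fli) > 0
        tf_near = (np.vstack([near_erg, near_fli])
                   if len(near_erg) or len(near_fli)
                   else np.zeros((0, 2), dtype=int))

        # (b) a nearby TF peak overlapping a control H3K27Ac peak,
        # (c) that H3K27Ac peak intersecting a decreased region
        k27_arr = k27_iv.get(row.chrom, np.zeros((0, 2), dtype=int))
        d_arr = dec_iv.get(row.chrom, np.zeros((0, 2), dtype=int))
        peak_in_k27 = False
        k27_reduced = False
        for s, e in tf_near:
            hit = _overlaps_any(int(s), int(e), k27_arr)
            if hit.any():
                peak_in_k27 = True
                for ks, ke in k27_arr[hit]:
                    if _overlaps_any(int(ks), int(ke), d_arr).any():
                        k27_reduced = True
                        break
            if k27_reduced:
                break

        if g in expr_group_means.index:
            ctrl = float(expr_group_means.loc[g, ("siControl", day)])
            e_kd = float(expr_group_means.loc[g, ("siERG", day)])
            f_kd = float(expr_group_means.loc[g, ("siFLI1", day)])
            combo = float(expr_group_means.loc[g, ("siERG+siFLI1", day)])
            expr_reduced = combo < (1.0 - reduction_frac) * ctrl
            combo_lowest = combo < e_kd and combo < f_kd
        else:
            missing_expr += 1
            expr_reduced = combo_lowest = False

        flags = {
            "has_upstream_peak": bool(has_upstream),
            "peak_in_k27ac": bool(peak_in_k27),
            "k27ac_reduced": bool(k27_reduced),
            "expr_reduced_70": bool(expr_reduced),
            "combo_exceeds_singles": bool(combo_lowest),
        }
        out.append(CandidateRecord(g, flags, all(flags.values())))
    if missing_expr:
        logger.warning("%d gene(s) absent from the expression matrix; "
                       "expression criteria set to False", missing_expr)
    return out


def candidates_table(records: list[CandidateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id, **r.flags, "is_candidate": r.is_candidate}
        rows.append(row)
    return pd.DataFrame(rows)
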