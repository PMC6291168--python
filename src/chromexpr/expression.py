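"""Expression pipeline: group means, probe filtering, probe collapse,
Z-scoring, gene clustering and day-3 regulation-pattern calling.

The pipeline reproduces the classic microarray workflow for a 4-siRNA
x 2-day knockdown design on a MAS5-like linear scale:

1. average replicates into the 8 (treatment, day) group means;
2. keep probes whose maximum group mean is >= 300 and whose CV across
   the 8 group means is >= 0.5 (sample sd, n-1);
3. collapse multi-probe genes to the probe with the largest summed
   signal;
4. Z-score each gene across the 8 groups and cluster with agglomerative
   average linkage on correlation distance;
5. separately, re-normalize within the four day-3 groups only and call
   one of eight regulation patterns (I-VIII) per gene, or "other".

Patterns encode how the two ETS factors combine: discretize each
knockdown's day-3 Z shift against siControl into up (U) / flat (F) /
down (D) at threshold ``delta`` and match the (siERG, siFLI1, combo)
triple:

=====  ==================  ===============================================
label  (E, F1, combo)      reading
=====  ==================  ===============================================
I      U, F, U (C >= E)    cooperative repression, ERG-predominant
II     F, U, U             cooperative repression, FLI1-predominant
III    U, U, U             redundant repression
IV     U, F, U (C < E)     ERG represses; FLI1 loss partially counteracts
V      U, F, F             ERG represses; FLI1 loss fully counteracts
VI     D, U, any           opposing: ERG promotes, FLI1 represses
VII    D, F, D (C <= E)    cooperative promotion, ERG-predominant
VIII   F, D, D             cooperative promotion, FLI1-predominant
=====  ==================  ===============================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core_io import DAYS, GROUPS, TREATMENTS, ExpressionMatrix

logger = logging.getLogger(__name__)

PATTERNS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass
class FilterParams:
    """Probe-retention thresholds on the 8 group means (both inclusive)."""

    min_signal: float = 300.0
    min_cv: float = 0.5

    def __post_init__(self) -> None:
        if self.min_signal <= 0 or self.min_cv < 0:
            raise ValueError("min_signal must be > 0 and min_cv >= 0")


@dataclass
class ClusterAssignment:
    labels: pd.Series          # gene -> cluster id, 1-based, ordered by size
    zscores: pd.DataFrame      # gene x group Z matrix used for clustering
    linkage_meta: str = "agglomerative/correlation/average"


@dataclass
class PatternAssignment:
    labels: pd.Series          # gene -> pattern label or "other"
    templates: dict = field(default_factory=dict)


def group_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean per (treatment, day) group, linear scale.

    Returns a probe x group DataFrame with MultiIndex columns in the
    canonical group order (day-3 block first).
    """
    meta = matrix.sample_meta
    cols = {}
    for treatment, day in GROUPS:
        samples = meta.index[(meta["treatment"] == treatment) & (meta["day"] == day)]
        if len(samples) == 0:
            raise ValueError(f"no samples for ({treatment}, day {day})")
        cols[(treatment, day)] = matrix.values[list(samples)].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(GROUPS, names=["treatment", "day"])
    return out


def filter_probes(gm: pd.DataFrame, params: FilterParams | None = None) -> list[str]:
    """Probes whose max group mean >= min_signal and CV >= min_cv.

    CV is the sample (n-1) standard deviation over the 8 group means
    divided by their mean; all-zero probes (undefined CV) fail and are
    logged.
    """
    params = params or FilterParams()
    vals = gm.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    zero = ~np.isfinite(cv)
    if zero.any():
        logger.warning("%d all-zero probe(s) excluded (CV undefined)", int(zero.sum()))
    cv_ok = np.where(np.isfinite(cv), cv >= params.min_cv, False)
    keep = (vals.max(axis=1) >= params.min_signal) & cv_ok
    return list(gm.index[keep])


def collapse_probes(retained: list[str], gm: pd.DataFrame,
                    probe_to_gene: pd.Series) -> pd.DataFrame:
    """Per gene, keep the retained probe with the largest summed group
    means; exact ties resolve to the lexicographically smaller probe id
    (logged). Returns a gene x group DataFrame."""
    missing = [p for p in retained if p not in probe_to_gene.index]
    if missing:
        raise ValueError(f"no gene mapping for probes {missing[:3]}...")
    sub = gm.loc[retained]
    totals = sub.sum(axis=1)
    df = pd.DataFrame({"probe": sub.index, "gene": probe_to_gene[sub.index].to_numpy(),
                       "total": totals.to_numpy()})
    df = df.sort_values(["gene", "total", "probe"],
                        ascending=[True, False, True], kind="mergesort")
    ties = df.duplicated(subset=["gene", "total"], keep=False)
    if ties.any():
        logger.warning("probe-collapse ties in %d gene(s); kept smaller probe id",
                       df.loc[ties, "gene"].nunique())
    best = df.drop_duplicates("gene", keep="first")
    out = sub.loc[best["probe"]].copy()
    out.index = pd.Index(best["gene"].to_numpy(), name="gene_id")
    return out.sort_index()


def zscore_rows(mat: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z (mean 0, sample sd 1); zero-variance rows raise."""
    vals = mat.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = mat.index[sd == 0][0]
        raise ValueError(f"zero-variance row {bad!r} reached Z-scoring; "
                         "the CV filter should have removed it")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=mat.index, columns=mat.columns)


def cluster_genes(gene_gm: pd.DataFrame, k_major: int) -> ClusterAssignment:
    """Cluster genes on their Z-scored 8-group profiles.

    Agglomerative clustering, correlation distance, average linkage,
    cut at ``k_major`` clusters; cluster ids are renumbered 1..k by
    descending size (ties by first-seen order). Input rows are sorted
    by gene id first so the result is independent of input order.
    """
    if len(gene_gm) < k_major:
        raise ValueError(f"need >= {k_major} genes, have {len(gene_gm)}")
    gene_gm = gene_gm.sort_index()
    z = zscore_rows(gene_gm)
    d = pdist(z.to_numpy(), metric="correlation")
    lk = linkage(d, method="average")
    raw = fcluster(lk, t=k_major, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    labels = pd.Series([remap[r] for r in raw], index=z.index, name="cluster")
    return ClusterAssignment(labels, z)


def subsplit_cluster(assignment: ClusterAssignment, gene_gm: pd.DataFrame,
                     cluster_id: int, k: int = 2) -> ClusterAssignment:
    """Re-cut one cluster into ``k`` sub-clusters (labels become e.g.
    "3-1", "3-2" style integers appended after the max id)."""
    members = assignment.labels.index[assignment.labels == cluster_id]
    sub = cluster_genes(gene_gm.loc[members], k)
    labels = assignment.labels.astype(str).copy()
    labels.loc[members] = [f"{cluster_id}-{v}" for v in sub.labels]
    return ClusterAssignment(labels, assignment.zscores, assignment.linkage_meta)


def day3_zscores(gene_gm: pd.DataFrame) -> pd.DataFrame:
    """Z across the four day-3 group means only (re-normalized); rows
    with zero day-3 variance become all-zero rather than raising."""
    cols = [(t, 3) for t in TREATMENTS]
    vals = gene_gm[cols].to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    mean = vals.mean(axis=1, keepdims=True)
    z = np.where(sd[:, None] > 0, (vals - mean) / np.where(sd == 0, 1, sd)[:, None], 0.0)
    return pd.DataFrame(z, index=gene_gm.index, columns=TREATMENTS)


#: pattern -> (sign_E, sign_F1, sign_combo, magnitude constraint)
#: signs: "U" up, "F" flat, "D" down, "*" any; constraint compares the
#: combo shift against a single-knockdown shift on the Z scale.
PATTERN_TEMPLATES: dict[str, tuple[str, str, str, str | None]] = {
    "I": ("U", "F", "U", "combo>=erg"),
    "II": ("F", "U", "U", None),
    "III": ("U", "U", "U", None),
    "IV": ("U", "F", "U", "combo<erg"),
    "V": ("U", "F", "F", None),
    "VI": ("D", "U", "*", None),
    "VII": ("D", "F", "D", "combo<=erg"),
    "VIII": ("F", "D", "D", None),
}


def classify_patterns(gene_gm: pd.DataFrame, delta: float = 0.5) -> PatternAssignment:
    """Call a day-3 regulation pattern (I-VIII or "other") per gene.

    Shifts are day-3 Z differences against siControl, discretized at
    ``delta``; templates are matched in order I..VIII, first match wins
    (I and IV are disambiguated by whether the combo shift reaches the
    siERG shift).
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    z = day3_zscores(gene_gm)
    dE = z["siERG"] - z["siControl"]
    dF = z["siFLI1"] - z["siControl"]
    dC = z["siERG+siFLI1"] - z["siControl"]

    def sign(x: float) -> str:
        return "U" if x >= delta else ("D" if x <= -delta else "F")

    labels = {}
    for gene in z.index:
        trip = (sign(dE[gene]), sign(dF[gene]), sign(dC[gene]))
        label = "other"
        for pat, (se, sf, sc, cons) in PATTERN_TEMPLATES.items():
            if trip[0] != se or trip[1] != sf or (sc != "*" and trip[2] != sc):
                continue
            if cons == "combo>=erg" and not dC[gene] >= dE[gene]:
                continue
            if cons == "combo<erg" and not dC[gene] < dE[gene]:
                continue
            if cons == "combo<=erg" and not dC[gene] <= dE[gene]:
                continue
            label = pat
            break
        labels[gene] = label
    return PatternAssignment(pd.Series(labels, name="pattern"),
                             dict(PATTERN_TEMPLATES))
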