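"""Domain containers and text-format I/O.

Everything downstream of this module speaks four containers:

* :class:`GenomeAnnotation` — chromosome sizes plus stranded gene records
  (TSS = ``start`` on '+', ``end`` on '-'; 0-based half-open throughout).
* :class:`PeakSet` — scored intervals for one ChIP target/condition.
* :class:`BinnedTrackSet` — genome-tiling fixed-width bin counts, one
  column per mark.
* :class:`ExpressionMatrix` — probes x samples normalized signal with a
  (treatment, day, replicate) design.

Formats are the plain-text genomics standards: BED3+, ENCODE narrowPeak,
bedGraph, and TSV tables. All coordinates are 0-based half-open (BED
convention); writers emit tab-separated, LF-terminated text.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four siRNA treatments of the knockdown design.
TREATMENTS = ("siControl", "siERG", "siFLI1", "siERG+siFLI1")
#: Sampling days.
DAYS = (3, 7)
#: The eight (treatment, day) groups, day-3 block first.
GROUPS = tuple((t, d) for d in DAYS for t in TREATMENTS)

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "summit_offset"]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# GenomeAnnotation
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus stranded gene records.

    ``genes`` is a DataFrame with columns
    ``gene_id, chrom, start, end, strand`` (0-based half-open, strand in
    {'+', '-'}). Gene ids must be unique and intervals must fit their
    chromosome.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True)
        required = ["gene_id", "chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in g.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if not g["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        for _, row in g.iterrows():
            if row.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {row.gene_id}: unknown chromosome {row.chrom!r}")
            if not (0 <= row.start < row.end <= self.chrom_sizes[row.chrom]):
                raise ValueError(
                    f"gene {row.gene_id}: interval [{row.start}, {row.end}) outside "
                    f"chromosome {row.chrom} of length {self.chrom_sizes[row.chrom]}"
                )
        self.genes = g

    @property
    def tss(self) -> pd.Series:
        """Transcription start site per gene (strand-aware), indexed by gene_id."""
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["start"], g["end"]),
            index=g["gene_id"], name="tss",
        )

    @property
    def tes(self) -> pd.Series:
        """Transcription end site per gene (opposite anchor to the TSS)."""
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["end"], g["start"]),
            index=g["gene_id"], name="tes",
        )

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.chrom_sizes[chrom] / bin_size)


def read_annotation(path: str | Path, chrom_sizes_path: str | Path | None = None) -> GenomeAnnotation:
    """Read a gene-annotation TSV (gene_id, chrom, start, end, strand).

    Chromosome sizes come from ``chrom_sizes_path`` (two-column
    ``chrom<TAB>length``) when given, otherwise each chromosome's size is
    taken as the maximum gene end observed on it.
    """
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if chrom_sizes_path is not None:
        cs = pd.read_csv(chrom_sizes_path, sep="\t", header=None, names=["chrom", "size"])
        sizes = dict(zip(cs["chrom"], cs["size"].astype(int)))
    else:
        sizes = genes.groupby("chrom")["end"].max().astype(int).to_dict()
        logger.warning("no chrom.sizes given; using max gene end per chromosome")
    return GenomeAnnotation(sizes, genes)


def write_annotation(ann: GenomeAnnotation, path: str | Path,
                     chrom_sizes_path: str | Path | None = None) -> None:
    ann.genes.to_csv(path, sep="\t", index=False, lineterminator="\n")
    if chrom_sizes_path is not None:
        with open(chrom_sizes_path, "w") as fh:
            for chrom, size in ann.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# PeakSet
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Scored intervals for one ChIP target under one condition.

    ``peaks`` columns: chrom, start, end, name, score, summit_offset
    (NaN when absent). For narrowPeak input, ``score`` is the
    signalValue column and the integer display score of column 5 is kept
    as ``bed_score`` — the choice of which to rank by is left to the
    caller. Rows are sorted by (chrom, start, end).
    """

    target: str
    condition: str = ""
    peaks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLUMNS))

    def __post_init__(self) -> None:
        df = self.peaks.reset_index(drop=True)
        for col in PEAK_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("score", "summit_offset") else ""
        if len(df):
            if (df["start"] >= df["end"]).any():
                bad = df.index[df["start"] >= df["end"]][0]
                raise ValueError(f"peak {bad}: start >= end")
            if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
                raise ValueError("non-finite peak score")
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.peaks = df

    def __len__(self) -> int:
        return len(self.peaks)

    def midpoints(self) -> pd.Series:
        return (self.peaks["start"] + self.peaks["end"]) // 2


def read_peaks(path: str | Path, format: str = "bed", target: str = "",
               condition: str = "") -> PeakSet:
    """Read a BED3+ or ENCODE narrowPeak file into a :class:`PeakSet`.

    narrowPeak: column 7 (signalValue) becomes ``score``, column 10 the
    summit offset (-1 -> missing); the integer column 5 is kept as
    ``bed_score``. BED: column 5, when present, becomes ``score``.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            minimum = 10 if format == "narrowPeak" else 3
            if len(fields) < minimum:
                raise ParseError(f"{path}: expected >= {minimum} fields at line {lineno}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: bad coordinates at line {lineno}") from exc
            if start >= end:
                raise ParseError(f"{path}: start >= end at line {lineno}")
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            if format == "narrowPeak":
                score = float(fields[6])
                summit = int(fields[9])
                rows.append({
                    "chrom": chrom, "start": start, "end": end, "name": name,
                    "score": score, "summit_offset": np.nan if summit < 0 else summit,
                    "bed_score": float(fields[4]),
                })
            else:
                score = float(fields[4]) if len(fields) > 4 else 0.0
                rows.append({"chrom": chrom, "start": start, "end": end,
                             "name": name, "score": score, "summit_offset": np.nan})
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS + (["bed_score"] if format == "narrowPeak" else []))
    return PeakSet(target=target, condition=condition, peaks=df)


def write_peaks(ps: PeakSet, path: str | Path, format: str = "bed") -> None:
    """Write a PeakSet as BED6-like (name, score, '.') or 10-column narrowPeak."""
    has_bed_score = "bed_score" in ps.peaks.columns
    with open(path, "w") as fh:
        for _, r in ps.peaks.iterrows():
            base = f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r['name']}"
            score = repr(float(r.score))
            if format == "narrowPeak":
                summit = -1 if pd.isna(r.summit_offset) else int(r.summit_offset)
                bed_score = 0
                if has_bed_score and not pd.isna(r["bed_score"]):
                    bed_score = int(r["bed_score"])
                fh.write(f"{base}\t{bed_score}\t.\t{score}\t-1\t-1\t{summit}\n")
            else:
                fh.write(f"{base}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# BinnedTrackSet
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrackSet:
    """Genome-tiling non-overlapping fixed-width bin counts.

    ``counts[chrom]`` is an ``(n_bins, M)`` float array, where
    ``n_bins = ceil(chrom_length / bin_size)`` and M = ``len(marks)``.
    """

    bin_size: int
    marks: list[str]
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        M = len(self.marks)
        for chrom, arr in self.counts.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != M:
                raise ValueError(f"{chrom}: counts shape {arr.shape} != (n_bins, {M})")
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative counts")
            self.counts[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self.counts)

    def mark_index(self, mark: str) -> int:
        try:
            return self.marks.index(mark)
        except ValueError:
            raise KeyError(f"unknown mark {mark!r}; have {self.marks}") from None

    def mark_vector(self, mark: str) -> dict[str, np.ndarray]:
        j = self.mark_index(mark)
        return {c: a[:, j] for c, a in self.counts.items()}

    def total(self, mark: str) -> float:
        j = self.mark_index(mark)
        return float(sum(a[:, j].sum() for a in self.counts.values()))

    def rebin(self, new_bin_size: int) -> "BinnedTrackSet":
        """Re-bin to a coarser grid by summation (new size must be a multiple)."""
        if new_bin_size % self.bin_size != 0:
            raise ValueError("new bin size must be a multiple of the current bin size")
        factor = new_bin_size // self.bin_size
        out = {}
        for chrom, arr in self.counts.items():
            n_new = math.ceil(arr.shape[0] / factor)
            padded = np.zeros((n_new * factor, arr.shape[1]))
            padded[: arr.shape[0]] = arr
            out[chrom] = padded.reshape(n_new, factor, arr.shape[1]).sum(axis=1)
        return BinnedTrackSet(new_bin_size, list(self.marks), out)


def read_binned_track(paths: dict[str, str | Path], annotation: GenomeAnnotation,
                      bin_size: int = 200) -> BinnedTrackSet:
    """Read one bedGraph per mark into a genome-tiling BinnedTrackSet.

    bedGraph intervals that cross bin boundaries are prorated by overlap
    fraction so total signal mass is conserved; bins with no record are
    zero, and chromosomes absent from a file are zero-filled with a
    logged warning.
    """
    marks = list(paths)
    counts = {
        chrom: np.zeros((math.ceil(size / bin_size), len(marks)))
        for chrom, size in annotation.chrom_sizes.items()
    }
    for j, mark in enumerate(marks):
        seen: set[str] = set()
        with open(paths[mark]) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{paths[mark]}: expected 4 fields at line {lineno}")
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if chrom not in counts:
                    raise ParseError(
                        f"{paths[mark]}: chromosome {chrom!r} at line {lineno} "
                        "absent from annotation")
                if value < 0:
                    raise ParseError(f"{paths[mark]}: negative value at line {lineno}")
                if start >= end:
                    raise ParseError(f"{paths[mark]}: start >= end at line {lineno}")
                seen.add(chrom)
                vec = counts[chrom][:, j]
                b0, b1 = start // bin_size, (end - 1) // bin_size
                if b0 == b1:
                    vec[b0] += value
                else:
                    # prorate by bp overlap with each spanned bin
                    span = end - start
                    for b in range(b0, b1 + 1):
                        lo = max(start, b * bin_size)
                        hi = min(end, (b + 1) * bin_size)
                        vec[b] += value * (hi - lo) / span
        for chrom in counts:
            if chrom not in seen:
                logger.warning("%s: no records for %s; zero-filled", paths[mark], chrom)
    return BinnedTrackSet(bin_size, marks, counts)


def write_bedgraph(tracks: BinnedTrackSet, mark: str, path: str | Path) -> None:
    """Write one mark as bedGraph (zero bins omitted)."""
    j = tracks.mark_index(mark)
    bs = tracks.bin_size
    with open(path, "w") as fh:
        for chrom, arr in tracks.counts.items():
            vec = arr[:, j]
            for b in np.nonzero(vec)[0]:
                fh.write(f"{chrom}\t{b * bs}\t{(b + 1) * bs}\t{float(vec[b])!r}\n")


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probes x samples normalized signal with the 8-group knockdown design.

    ``values``: DataFrame indexed by probe_id, one column per sample.
    ``probe_to_gene``: Series probe_id -> gene_id.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``treatment`` (one of the four siRNA levels), ``day`` (3 or 7) and
    ``replicate``.
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id {dup!r}")
        bad = set(self.sample_meta["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValueError(
                f"unknown treatment(s) {sorted(bad)}; allowed: {list(TREATMENTS)}")
        if not self.sample_meta["day"].isin(DAYS).all():
            raise ValueError(f"day must be one of {DAYS}")
        missing = [s for s in self.sample_meta.index if s not in self.values.columns]
        if missing:
            raise ValueError(f"samples in metadata but not in matrix: {missing}")
        self.values = self.values[list(self.sample_meta.index)]
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("expression values must be finite and >= 0")


def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV plus sample-metadata TSV.

    The matrix has a probe_id first column, an optional gene_id second
    column, then one column per sample. Metadata columns: sample,
    treatment, day, replicate.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    if "gene_id" in df.columns:
        probe_to_gene = df["gene_id"].astype(str)
        df = df.drop(columns="gene_id")
    else:
        probe_to_gene = pd.Series(df.index, index=df.index, name="gene_id")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            probe = df.index[coerced.isna()][0]
            raise ParseError(f"non-numeric value for probe {probe!r} in sample {col!r}")
        df[col] = coerced
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample")
    return ExpressionMatrix(df, probe_to_gene, meta)


def write_expression(em: ExpressionMatrix, path: str | Path, meta_path: str | Path) -> None:
    out = em.values.copy()
    out.insert(0, "gene_id", em.probe_to_gene)
    out.to_csv(path, sep="\t", lineterminator="\n")
    em.sample_meta.to_csv(meta_path, sep="\t", lineterminator="\n")
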