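"""Synthetic genome, chromatin tracks, peaks and expression with planted
ground truth.

The generator emulates the inputs of a combined ERG/FLI1-knockdown
study in endothelial cells: a small multi-chromosome genome with
annotated genes; a hidden chromatin-state path per chromosome sampled
from a sticky Markov chain; six Poisson count tracks per 200-bp bin
(ERG, FLI1, H3K4me3 and H3K27Ac under control and double-knockdown
conditions); ChIP peak sets consistent with the planted states; and an
8-group (4 siRNA treatments x 2 days) expression matrix with planted
cluster, pattern and direct-target structure. Every random draw comes
from one seeded generator, so identical configs produce byte-identical
outputs.

Planted structure worth knowing about:

* one state is the "EC enhancer": it emits ERG, FLI1 and H3K27Ac, and
  its knockdown-condition H3K27Ac rate is attenuated ``k27ac_attenuation``
  fold — its runs are the true differential-H3K27Ac regions;
* candidate genes are placed with their TSS near long EC-enhancer runs
  and given an expression effect that loses >70% of signal under the
  double knockdown, below either single knockdown, so they satisfy all
  five direct-target screen criteria by construction; the default
  effect vectors of every other block fail at least one expression
  criterion, so the planted candidates are exactly the genes the screen
  should return;
* expression is simulated on log2 scale and exponentiated to a
  MAS5-like linear scale, because the >=300 and CV filters act on
  linear signal; some flat genes sit below 300 everywhere and some are
  high but invariant, to exercise both probe filters; genes carry 1-3
  probes to exercise probe collapse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io
from .core_io import (
    DAYS, GROUPS, TREATMENTS, BinnedTrackSet, ExpressionMatrix,
    GenomeAnnotation, PeakSet,
)

DEFAULT_MARKS = ("ERG", "FLI1", "H3K4me3_ctrl", "H3K4me3_kd",
                 "H3K27Ac_ctrl", "H3K27Ac_kd")
DEFAULT_STATE_NAMES = ("quiescent", "promoter", "ec_enhancer", "generic_enhancer")

#: Poisson mean per 200-bp bin, rows = states, columns = DEFAULT_MARKS.
#: The knockdown H3K27Ac column is written pre-attenuation; the
#: generator divides the EC-enhancer entry by ``k27ac_attenuation``.
DEFAULT_EMISSION_RATES = (
    (0.1, 0.1, 0.1, 0.1, 0.1, 0.1),      # quiescent
    (0.5, 0.5, 25.0, 25.0, 0.5, 0.5),    # promoter
    (25.0, 25.0, 0.5, 0.5, 40.0, 40.0),  # ec_enhancer
    (0.1, 0.1, 0.5, 0.5, 40.0, 40.0),    # generic_enhancer
)

#: Target state occupancies for the default genome: mostly quiescent,
#: EC enhancers rare — so that an EC-enhancer run near a TSS is the
#: exception, not the rule, and class-vs-cluster association has
#: contrast to detect.
DEFAULT_STATE_WEIGHTS = (0.775, 0.10, 0.035, 0.09)


@dataclass
class ClusterBlock:
    """A planted expression block: ``effects`` are log2 fold-changes over
    the 8 (treatment, day) groups in canonical order (day-3 block first);
    ``pattern`` is the day-3 regulation pattern the block realizes."""

    label: str
    n_genes: int
    effects: tuple
    pattern: str = "other"
    noise_sd: float | None = None   # falls back to config.noise_sd


#: Default planted blocks. Effect sizes are chosen so that (a) every
#: block passes the linear-scale CV >= 0.5 filter, (b) each block's
#: day-3 profile discretizes unambiguously to its pattern at the 0.5-Z
#: threshold, and (c) no block except the candidates passes both
#: expression criteria of the direct-target screen.
DEFAULT_BLOCKS = (
    ClusterBlock("pattern_I", 30, (0, 2.0, 0, 3.0, 0, 1.0, 0, 1.5), "I"),
    ClusterBlock("pattern_IV", 30, (0, 2.5, 0, 1.2, 0, 2.5, 0, 1.2), "IV"),
    ClusterBlock("pattern_V", 30, (0, 2.0, 0, 0, 0, 2.0, 0, 0), "V"),
    ClusterBlock("pattern_VI", 30, (0, -4.0, 1.5, 0, 0, -4.0, 1.5, 0), "VI"),
)

#: Candidate (direct-target) effect: the double knockdown removes ~82%
#: of signal (2^-2.5), more than either single knockdown (2^-1).
CANDIDATE_EFFECT = (0, -1.0, -1.0, -2.5, 0, -1.0, -1.0, -2.5)


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome / chromatin
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    bin_size: int = 200
    marks: tuple = DEFAULT_MARKS
    state_names: tuple = DEFAULT_STATE_NAMES
    emission_rates: tuple = DEFAULT_EMISSION_RATES
    transition_stickiness: float = 0.95
    state_weights: tuple | None = DEFAULT_STATE_WEIGHTS  # None -> uniform
    ec_state: int = 2
    attenuated_mark: str = "H3K27Ac_kd"
    k27ac_attenuation: float = 4.0       # 1.0 -> null (no differential signal)
    tf_peak_rate_min: float = 10.0       # states emitting TF peaks
    k27ac_peak_rate_min: float = 20.0    # states emitting H3K27Ac peaks
    emission_noise: str = "poisson"      # or "nb"
    nb_dispersion: float = 10.0          # gamma shape for the "nb" option
    # genes / expression
    n_genes: int = 200
    gene_length: int = 2_000
    n_candidates: int = 12
    min_candidate_run_bins: int = 5
    candidate_tss_offset: int = 10_000
    cluster_spec: tuple = DEFAULT_BLOCKS
    candidate_effect: tuple = CANDIDATE_EFFECT
    flat_low_frac: float = 0.5
    replicates: int = 2
    noise_sd: float = 0.15
    baseline_log2_range: tuple = (8.6, 10.6)
    flat_low_log2_range: tuple = (5.0, 8.0)
    extra_probe_prob: float = 0.5
    extra_probe_scale_range: tuple = (0.4, 0.8)

    def __post_init__(self) -> None:
        rates = np.asarray(self.emission_rates, dtype=float)
        if rates.shape != (len(self.state_names), len(self.marks)):
            raise ValueError("emission_rates shape must be (n_states, n_marks)")
        if (rates < 0).any():
            raise ValueError("emission rates must be >= 0")
        if len(np.unique(rates, axis=0)) != rates.shape[0]:
            raise ValueError("emission_rates rows must be distinct")
        if not (0 < self.transition_stickiness < 1) and self.transition_stickiness != 1.0:
            raise ValueError("transition_stickiness must lie in (0, 1]")
        planted = sum(b.n_genes for b in self.cluster_spec) + self.n_candidates
        if planted > self.n_genes:
            raise ValueError("cluster_spec + candidates exceed n_genes")
        if self.attenuated_mark not in self.marks:
            raise ValueError(f"attenuated_mark {self.attenuated_mark!r} not in marks")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    def rates(self) -> np.ndarray:
        """Emission matrix with the knockdown attenuation applied."""
        r = np.asarray(self.emission_rates, dtype=float).copy()
        j = list(self.marks).index(self.attenuated_mark)
        r[self.ec_state, j] /= self.k27ac_attenuation
        return r


@dataclass
class GroundTruth:
    """Planted structure, written alongside the data; the pipeline under
    test must never read it."""

    state_paths: dict[str, list[int]]
    state_names: list[str]
    ec_state: int
    differential_regions: list[tuple[str, int, int]]
    cluster_labels: dict[str, str]
    pattern_labels: dict[str, str]
    candidates: list[str]
    passing_probes: list[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["differential_regions"] = [tuple(r) for r in d["differential_regions"]]
        return cls(**d)


@dataclass
class SimulationResult:
    config: SimulationConfig
    annotation: GenomeAnnotation
    gene_blocks: pd.Series
    tracks: BinnedTrackSet
    peaks: dict[str, PeakSet]
    expression: ExpressionMatrix
    truth: GroundTruth


# ---------------------------------------------------------------------------
# state paths
# ---------------------------------------------------------------------------

def transition_matrix(config: SimulationConfig) -> np.ndarray:
    """Transition matrix of the sticky hidden chain.

    With uniform occupancy (``state_weights`` None): stay probability
    exactly ``transition_stickiness``, remaining mass split uniformly
    over the other states. With target weights w: the mixture chain
    A = s*I + (1-s)*1 w^T, whose stationary distribution is exactly w
    (effective stay probability s + (1-s) w_i).
    """
    K = config.n_states
    s = config.transition_stickiness
    if K == 1 or s == 1.0:
        return np.eye(K)
    if config.state_weights is None:
        A = np.full((K, K), (1 - s) / (K - 1))
        np.fill_diagonal(A, s)
        return A
    w = np.asarray(config.state_weights, dtype=float)
    w = w / w.sum()
    return s * np.eye(K) + (1 - s) * np.tile(w, (K, 1))


def sample_state_paths(config: SimulationConfig,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    A = transition_matrix(config)
    K = config.n_states
    pi = (np.full(K, 1.0 / K) if config.state_weights is None
          else np.asarray(config.state_weights, dtype=float) / sum(config.state_weights))
    paths = {}
    cum = A.cumsum(axis=1)
    for chrom in config.chrom_names:
        n = config.n_bins
        path = np.empty(n, dtype=np.int64)
        path[0] = rng.choice(K, p=pi)
        u = rng.random(n)
        for t in range(1, n):
            path[t] = np.searchsorted(cum[path[t - 1]], u[t])
        paths[chrom] = path
    return paths


def _runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (state, start_bin, end_bin) half-open."""
    if len(path) == 0:
        return []
    boundaries = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(path)]))
    return [(int(path[s]), int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig, rng: np.random.Generator,
                    state_paths: dict[str, np.ndarray] | None = None
                    ) -> tuple[GenomeAnnotation, pd.Series]:
    """Place genes; returns the annotation plus a gene -> block label map.

    When ``state_paths`` is given, candidate genes are anchored with
    their TSS within ``candidate_tss_offset`` bp of a long EC-enhancer
    run so the direct-target ChIP criteria hold by construction; all
    other genes are placed uniformly without overlap.
    """
    L = config.gene_length
    total_bp = config.n_chroms * config.chrom_length
    if config.n_genes * L > 0.8 * total_bp:
        raise ValueError(
            f"{config.n_genes} genes of {L} bp do not fit {total_bp} bp; "
            "increase chrom_length or n_chroms")
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names}

    def fits(chrom: str, start: int) -> bool:
        end = start + L
        if start < 0 or end > config.chrom_length:
            return False
        return all(e <= start or s >= end for s, e in occupied[chrom])

    blocks: list[str] = []
    records: list[dict] = []

    def place(gene_id: str, block: str, chrom: str, start: int, strand: str) -> None:
        occupied[chrom].append((start, start + L))
        records.append({"gene_id": gene_id, "chrom": chrom, "start": start,
                        "end": start + L, "strand": strand})
        blocks.append(block)

    gene_no = 0

    def next_id() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"g{gene_no:04d}"

    # candidates first, anchored at long EC-enhancer runs
    if config.n_candidates > 0:
        if state_paths is None:
            raise ValueError("state_paths required to place candidate genes")
        anchors = []
        for chrom in config.chrom_names:
            for state, s, e in _runs(state_paths[chrom]):
                if state == config.ec_state and e - s >= config.min_candidate_run_bins:
                    anchors.append((chrom, (s + e) // 2 * config.bin_size))
        if not anchors:
            raise ValueError(
                "no EC-enhancer run long enough to anchor candidates; "
                "increase chrom_length or lower min_candidate_run_bins")
        for i in range(config.n_candidates):
            chrom, mid = anchors[i % len(anchors)]
            placed = False
            for _ in range(200):
                tss = int(mid + rng.integers(-config.candidate_tss_offset,
                                             config.candidate_tss_offset + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                start = tss if strand == "+" else tss - L
                if fits(chrom, start):
                    place(next_id(), "candidate", chrom, start, strand)
                    placed = True
                    break
            if not placed:
                raise ValueError("could not place candidate gene near its anchor")

    # everything else, uniform
    for block in [b.label for b in config.cluster_spec for _ in range(b.n_genes)]:
        _place_uniform(config, rng, fits, place, next_id(), block)
    n_flat = config.n_genes - config.n_candidates - sum(b.n_genes for b in config.cluster_spec)
    n_low = int(round(n_flat * config.flat_low_frac))
    for i in range(n_flat):
        _place_uniform(config, rng, fits, place, next_id(),
                       "flat_low" if i < n_low else "flat_quiet")

    genes = pd.DataFrame(records)
    ann = GenomeAnnotation({c: config.chrom_length for c in config.chrom_names}, genes)
    return ann, pd.Series(blocks, index=genes["gene_id"].to_numpy(), name="block")


def _place_uniform(config, rng, fits, place, gene_id, block):
    for _ in range(2000):
        chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - config.gene_length + 1))
        if fits(chrom, start):
            strand = "+" if rng.random() < 0.5 else "-"
            place(gene_id, block, chrom, start, strand)
            return
    raise ValueError("genome too crowded; increase chrom_length")


# ---------------------------------------------------------------------------
# chromatin
# ---------------------------------------------------------------------------

def generate_chromatin(config: SimulationConfig, rng: np.random.Generator,
                       state_paths: dict[str, np.ndarray]
                       ) -> tuple[BinnedTrackSet, dict[str, PeakSet],
                                  list[tuple[str, int, int]]]:
    """Emit the six count tracks, the TF / H3K27Ac peak sets and the
    true differential-H3K27Ac regions for the given hidden paths.

    Counts are Poisson (optionally gamma-overdispersed, ``emission_noise
    = "nb"``) with per-state means from the config. Peaks are maximal
    single-state runs: TF peaks from states whose ERG/FLI1 rate clears
    ``tf_peak_rate_min``, H3K27Ac peaks from states whose control
    H3K27Ac rate clears ``k27ac_peak_rate_min``; peak score is the mean
    observed count over the run and the summit sits at the maximal bin.
    """
    rates = config.rates()
    marks = list(config.marks)
    counts: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        lam = rates[state_paths[chrom]]
        if config.emission_noise == "nb":
            shape = config.nb_dispersion
            lam = rng.gamma(shape, np.maximum(lam, 1e-12) / shape)
        counts[chrom] = rng.poisson(lam).astype(float)
    tracks = BinnedTrackSet(config.bin_size, marks, counts)

    base_rates = np.asarray(config.emission_rates, dtype=float)
    tf_states = set(np.flatnonzero(base_rates[:, marks.index("ERG")]
                                   >= config.tf_peak_rate_min))
    k27_states = set(np.flatnonzero(base_rates[:, marks.index("H3K27Ac_ctrl")]
                                    >= config.k27ac_peak_rate_min))

    def peaks_for(states: set[int], score_mark: str, target: str,
                  condition: str) -> PeakSet:
        j = marks.index(score_mark)
        rows = []
        k = 0
        for chrom in config.chrom_names:
            for state, s, e in _runs(state_paths[chrom]):
                if state not in states:
                    continue
                vec = counts[chrom][s:e, j]
                k += 1
                rows.append({
                    "chrom": chrom,
                    "start": s * config.bin_size,
                    "end": e * config.bin_size,
                    "name": f"{target}_{k}",
                    "score": float(vec.mean()),
                    "summit_offset": int(vec.argmax()) * config.bin_size
                    + config.bin_size // 2,
                })
        return PeakSet(target, condition, pd.DataFrame(
            rows, columns=core_io.PEAK_COLUMNS))

    peak_sets = {
        "ERG": peaks_for(tf_states, "ERG", "ERG", "control"),
        "FLI1": peaks_for(tf_states, "FLI1", "FLI1", "control"),
        "H3K27Ac_ctrl": peaks_for(k27_states, "H3K27Ac_ctrl", "H3K27Ac", "control"),
    }
    diff_regions: list[tuple[str, int, int]] = []
    if config.k27ac_attenuation != 1.0:
        for chrom in config.chrom_names:
            for state, s, e in _runs(state_paths[chrom]):
                if state == config.ec_state:
                    diff_regions.append((chrom, s * config.bin_size,
                                         e * config.bin_size))
    return tracks, peak_sets, diff_regions


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _block_effects(config: SimulationConfig) -> dict[str, np.ndarray]:
    eff = {b.label: np.asarray(b.effects, dtype=float) for b in config.cluster_spec}
    eff["candidate"] = np.asarray(config.candidate_effect, dtype=float)
    eff["flat_low"] = np.zeros(8)
    eff["flat_quiet"] = np.zeros(8)
    return eff


def _block_noise(config: SimulationConfig) -> dict[str, float]:
    ns = {b.label: (config.noise_sd if b.noise_sd is None else b.noise_sd)
          for b in config.cluster_spec}
    for label in ("candidate", "flat_low", "flat_quiet"):
        ns[label] = config.noise_sd
    return ns


def generate_expression(config: SimulationConfig, rng: np.random.Generator,
                        gene_blocks: pd.Series
                        ) -> tuple[ExpressionMatrix, dict[str, str],
                                   dict[str, str], list[str]]:
    """Simulate the probe x sample matrix for the placed genes.

    Returns (matrix, cluster_labels, pattern_labels, passing_probes);
    labels cover planted blocks and candidates only (flat genes are
    expected to fail the filters). ``passing_probes`` is evaluated on
    the noiseless probe-level group means with the same max/CV formulas
    the filters define — at noise_sd 0 it is exact ground truth.
    """
    effects = _block_effects(config)
    noise = _block_noise(config)
    patterns = {b.label: b.pattern for b in config.cluster_spec}
    patterns["candidate"] = "other"

    samples = [f"{t}_d{d}_r{r + 1}" for (t, d) in GROUPS
               for r in range(config.replicates)]
    group_of = np.repeat(np.arange(8), config.replicates)
    meta = pd.DataFrame({
        "sample": samples,
        "treatment": [t for (t, d) in GROUPS for _ in range(config.replicates)],
        "day": [d for (t, d) in GROUPS for _ in range(config.replicates)],
        "replicate": [r + 1 for _ in GROUPS for r in range(config.replicates)],
    }).set_index("sample")

    lo, hi = config.baseline_log2_range
    qlo, qhi = config.flat_low_log2_range
    probe_rows = []
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    noiseless: list[np.ndarray] = []
    for gene_id, block in gene_blocks.items():
        baseline = (rng.uniform(qlo, qhi) if block == "flat_low"
                    else rng.uniform(lo, hi))
        eff = effects[block]
        sd = noise[block]
        n_probes = 1
        if config.extra_probe_prob > 0 and rng.random() < config.extra_probe_prob:
            n_probes += int(rng.integers(1, 3))
        for p in range(n_probes):
            scale = 1.0 if p == 0 else float(rng.uniform(*config.extra_probe_scale_range))
            eps = rng.normal(0, sd, size=len(samples)) if sd > 0 else np.zeros(len(samples))
            log2_vals = baseline + eff[group_of] + eps
            probe_rows.append(scale * np.power(2.0, log2_vals))
            probe_ids.append(f"{gene_id}_p{p + 1}")
            probe_gene.append(gene_id)
            noiseless.append(scale * np.power(2.0, baseline + eff))

    values = pd.DataFrame(np.vstack(probe_rows), index=pd.Index(probe_ids, name="probe_id"),
                          columns=samples)
    matrix = ExpressionMatrix(values, pd.Series(probe_gene, index=probe_ids,
                                                name="gene_id"), meta)

    cluster_labels = {g: b for g, b in gene_blocks.items()
                      if b not in ("flat_low", "flat_quiet")}
    pattern_labels = {g: patterns[b] for g, b in cluster_labels.items()}
    passing = []
    for pid, gm8 in zip(probe_ids, noiseless):
        mean = gm8.mean()
        cv = gm8.std(ddof=1) / mean if mean > 0 else np.nan
        if gm8.max() >= 300.0 and np.isfinite(cv) and cv >= 0.5:
            passing.append(pid)
    return matrix, cluster_labels, pattern_labels, passing


# ---------------------------------------------------------------------------
# orchestrator + writers
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: states -> genome -> chromatin -> expression."""
    rng = np.random.default_rng(config.seed)
    paths = sample_state_paths(config, rng)
    annotation, blocks = generate_genome(config, rng, paths)
    tracks, peak_sets, diff_regions = generate_chromatin(config, rng, paths)
    matrix, clusters, patterns, passing = generate_expression(config, rng, blocks)
    truth = GroundTruth(
        state_paths={c: p.tolist() for c, p in paths.items()},
        state_names=list(config.state_names),
        ec_state=config.ec_state,
        differential_regions=diff_regions,
        cluster_labels=clusters,
        pattern_labels=patterns,
        candidates=[g for g, b in blocks.items() if b == "candidate"],
        passing_probes=passing,
    )
    return SimulationResult(config, annotation, blocks, tracks, peak_sets,
                            matrix, truth)


def write_outputs(result: SimulationResult, outdir: str | Path) -> None:
    """Write every generated artifact as plain text under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    core_io.write_annotation(result.annotation, outdir / "annotation.tsv",
                             outdir / "chrom.sizes")
    for mark in result.tracks.marks:
        core_io.write_bedgraph(result.tracks, mark, outdir / f"{mark}.bedGraph")
    for name, ps in result.peaks.items():
        core_io.write_peaks(ps, outdir / f"{name}.narrowPeak", format="narrowPeak")
    core_io.write_expression(result.expression, outdir / "expression.tsv",
                             outdir / "samples.tsv")
    result.truth.to_json(outdir / "ground_truth.json")
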