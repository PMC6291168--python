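"""De novo k-mer motif enrichment and motif frequency comparison.

The finder is a transparent exact k-mer enumerator: 8-bp windows are
counted on both strands, collapsed to the canonical (lexicographically
smaller of k-mer / reverse complement) form, and compared against a
background of either per-sequence dinucleotide shuffles (composition-
preserving, Altschul-Erikson) or uniform-random sequences of matching
lengths. Enrichment keeps k-mers at fold >= 2 by default, ranked by a
one-sided Fisher exact p-value. Windows containing N are skipped.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._stats import fisher_enrichment

_COMP = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerEnrichment:
    kmer: str            # canonical 8-mer
    fg_count: int
    bg_count: int
    fold: float
    p: float


@dataclass
class MotifPattern:
    """A named IUPAC consensus; built-ins cover the ETS core, AP-1 and
    the GGAA repeat."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letter(s) {sorted(bad)}")
        self.consensus = self.consensus.upper()

    def expand(self) -> list[str]:
        """All exact DNA strings matching the consensus."""
        return ["".join(p) for p in
                itertools.product(*(IUPAC[c] for c in self.consensus))]


BUILTIN_MOTIFS = {
    "ETS_core": MotifPattern("ETS_core", "GGAW"),
    "AP1": MotifPattern("AP1", "TGASTCA"),
    "GGAA_repeat": MotifPattern("GGAA_repeat", "GGAAGGAA"),
}


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_kmers(seqs: list[str], k: int) -> tuple[Counter, int]:
    """Canonical k-mer occurrence counts over both strands.

    Every N-free window contributes 2 to its canonical k-mer (one per
    strand); returns (counts, total occurrences).
    """
    counts: Counter = Counter()
    total = 0
    for seq in seqs:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if "N" in w:
                continue
            counts[canonical(w)] += 2
            total += 2
    return counts, total


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle: a uniform random sequence with exactly
    the original dinucleotide (and hence mononucleotide) counts."""
    s = seq.upper()
    if len(s) < 3:
        return s
    letters = sorted(set(s))
    edges: dict[str, list[str]] = {a: [] for a in letters}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]
    while True:
        last_edge: dict[str, str] = {}
        for a in letters:
            if a == last or not edges[a]:
                continue
            last_edge[a] = edges[a][int(rng.integers(len(edges[a])))]
        ok = True
        for a in last_edge:
            seen = set()
            v = a
            while v in last_edge and v not in seen:
                seen.add(v)
                v = last_edge[v]
            if v != last:
                ok = False
                break
        if ok:
            break
    walk_lists: dict[str, list[str]] = {}
    for a in letters:
        rest = list(edges[a])
        if a in last_edge:
            rest.remove(last_edge[a])
        order = rng.permutation(len(rest))
        rest = [rest[i] for i in order]
        if a in last_edge:
            rest.append(last_edge[a])
        walk_lists[a] = rest
    out = [s[0]]
    ptr = {a: 0 for a in letters}
    v = s[0]
    for _ in range(len(s) - 1):
        nxt = walk_lists[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _uniform_background(seqs: list[str], rng: np.random.Generator) -> list[str]:
    return ["".join(rng.choice(list("ACGT"), size=len(s))) for s in seqs]


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def kmer_enrichment(fg: list[str], k: int = 8, bg_mode: str = "shuffle",
                    fold_min: float = 2.0, seed: int = 0,
                    n_background: int = 1) -> list[KmerEnrichment]:
    """Rank canonical k-mers enriched in ``fg`` over a seeded background.

    ``bg_mode`` "shuffle" uses ``n_background`` dinucleotide shuffles of
    each foreground sequence; "uniform_random" uses uniform random
    sequences of the same lengths. Results are filtered at fold >=
    ``fold_min`` and sorted by (p, -fold, kmer).
    """
    if bg_mode not in ("shuffle", "uniform_random"):
        raise ValueError(f"unknown background mode {bg_mode!r}")
    if not fg:
        raise ValueError("empty foreground sequence set")
    if k > min(len(s) for s in fg):
        raise ValueError("k exceeds the shortest foreground sequence")
    rng = np.random.default_rng(seed)
    bg: list[str] = []
    for _ in range(max(1, n_background)):
        if bg_mode == "shuffle":
            bg.extend(dinucleotide_shuffle(s, rng) for s in fg)
        else:
            bg.extend(_uniform_background(fg, rng))
    fg_counts, fg_total = count_kmers(fg, k)
    bg_counts, bg_total = count_kmers(bg, k)
    out = []
    for kmer, n_fg in fg_counts.items():
        n_bg = bg_counts.get(kmer, 0)
        fg_freq = n_fg / fg_total
        bg_freq = n_bg / bg_total if bg_total else 0.0
        fold = np.inf if bg_freq == 0 else fg_freq / bg_freq
        if fold < fold_min:
            continue
        _, p = fisher_enrichment(n_fg, fg_total - n_fg, n_bg, bg_total - n_bg)
        out.append(KmerEnrichment(kmer, n_fg, n_bg, float(fold), p))
    out.sort(key=lambda r: (r.p, -r.fold, r.kmer))
    return out


def _has_match(seq: str, patterns: set[str]) -> bool:
    s = seq.upper()
    k = len(next(iter(patterns)))
    for strand in (s, revcomp(s)):
        for i in range(len(strand) - k + 1):
            if strand[i:i + k] in patterns:
                return True
    return False


def compare_motif_frequency(seqs_a: list[str], seqs_b: list[str],
                            motif: MotifPattern) -> dict:
    """Fraction of sequences containing the motif (either strand) in
    each set, with a one-sided Fisher p for enrichment in set a."""
    if not seqs_a or not seqs_b:
        raise ValueError("empty sequence set")
    patterns = set(motif.expand())
    hit_a = sum(_has_match(s, patterns) for s in seqs_a)
    hit_b = sum(_has_match(s, patterns) for s in seqs_b)
    _, p = fisher_enrichment(hit_a, len(seqs_a) - hit_a,
                             hit_b, len(seqs_b) - hit_b)
    return {"freq_a": hit_a / len(seqs_a), "freq_b": hit_b / len(seqs_b),
            "n_a": len(seqs_a), "n_b": len(seqs_b), "p": p}
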