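"""Promoter motif scanning and binding-site authenticity nulls.

Implements a MATCH-style position-weight-matrix scanner (information-
vector weighted, min-max normalized so the consensus scores 1), a
conservation filter for candidate sites, and three randomization tests:
TSS proximity, dinucleotide-preserving sequence shuffles with per-base
conservation permutation, and a G/C-matched DNase-overlap null.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._stats import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "PromoterRecord",
    "BindingSite",
    "GenomicInterval",
    "scan_pwm",
    "conservation_filter",
    "predict_regulons",
    "tss_proximity_test",
    "dinucleotide_shuffle",
    "shuffle_conservation",
    "binding_site_null",
    "dnase_overlap_test",
    "compare_score_distributions",
    "DEFAULT_THRESHOLDS",
]

_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

DEFAULT_THRESHOLDS = {
    "min_score": 0.85,
    "min_core_score": 0.90,
    "min_coverage": 0.8,
    "min_mean": 0.6,
}

PWM_PSEUDOCOUNT = 0.25


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _ENC.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class PWM:
    """A position count matrix with a core sub-range (1-based, inclusive)."""

    id: str
    counts: np.ndarray  # (width, 4) in A, C, G, T order
    core: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be a width x 4 matrix")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError("each position must have a positive count sum")
        if self.core is None:
            self.core = (1, self.width)
        cs, ce = self.core
        if not (1 <= cs <= ce <= self.width):
            raise ValueError(f"core {self.core} outside [1, {self.width}]")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=1))

    def frequencies(self, pseudocount: float = PWM_PSEUDOCOUNT) -> np.ndarray:
        c = self.counts + pseudocount
        return c / c.sum(axis=1, keepdims=True)

    def reverse_complement(self) -> "PWM":
        rc_counts = self.counts[::-1, ::-1]
        cs, ce = self.core
        return PWM(self.id, rc_counts, (self.width - ce + 1, self.width - cs + 1))


@dataclass
class PromoterRecord:
    """A promoter sequence with its TSS position and conservation track."""

    gene: str
    tss_offset: int
    sequence: str
    conservation: np.ndarray | None = None
    planted: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.conservation is not None:
            self.conservation = np.asarray(self.conservation, dtype=float)
            if len(self.conservation) != len(self.sequence):
                raise ValueError(
                    f"{self.gene}: conservation length != sequence length"
                )
        if not (0 <= self.tss_offset <= len(self.sequence)):
            raise ValueError(f"{self.gene}: TSS offset outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """A PWM match, positioned relative to the TSS (downstream positive)."""

    gene: str
    start: int  # TSS-relative leftmost base
    strand: str  # '+' | '-'
    score: float
    width: int
    core_score: float = np.nan
    coverage: float = 0.0
    mean_conservation: float = np.nan


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a gene's promoter (or a chromosome)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}..{self.end}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def _score_table(pwm: PWM) -> tuple[np.ndarray, float, float]:
    """Per-position score contributions S[i, b] = I(i) * f(i, b)."""
    f = pwm.frequencies()
    info = (f * np.log(4.0 * f)).sum(axis=1)
    s = info[:, None] * f
    return s, float(s.min(axis=1).sum()), float(s.max(axis=1).sum())


def _similarity(
    windows: np.ndarray, table: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    w = table.shape[0]
    raw = table[np.arange(w)[None, :], windows].sum(axis=1)
    if hi == lo:  # flat matrix: every sequence matches the consensus equally
        return np.ones(len(raw))
    return (raw - lo) / (hi - lo)


def _window_scores(seq_i: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(full score, core score, valid) for every window, one strand."""
    w = pwm.width
    wins = np.lib.stride_tricks.sliding_window_view(seq_i, w)
    valid = (wins >= 0).all(axis=1)
    safe = np.where(wins >= 0, wins, 0)
    table, lo, hi = _score_table(pwm)
    full = _similarity(safe, table, lo, hi)
    cs, ce = pwm.core
    core_tab = table[cs - 1 : ce]
    core = _similarity(
        safe[:, cs - 1 : ce],
        core_tab,
        float(core_tab.min(axis=1).sum()),
        float(core_tab.max(axis=1).sum()),
    )
    return full, core, valid


def _site_conservation(
    promoter: PromoterRecord, start: int, width: int
) -> tuple[float, float]:
    if promoter.conservation is None:
        return 0.0, np.nan
    seg = promoter.conservation[start : start + width]
    covered = np.isfinite(seg)
    coverage = float(covered.mean())
    mean = float(seg[covered].mean()) if covered.any() else np.nan
    return coverage, mean


def scan_pwm(
    promoter: PromoterRecord,
    pwm: PWM,
    min_score: float = 0.85,
    min_core_score: float = 0.90,
) -> list[BindingSite]:
    """Scan both strands for MATCH-similarity hits above the thresholds.

    Windows containing N are skipped. Minus-strand matches are scored
    against the reverse complement and reported at the plus-strand
    leftmost coordinate; conservation is evaluated on plus-strand
    positions regardless of strand.
    """
    if len(promoter) < pwm.width:
        raise ValueError(
            f"promoter {promoter.gene} shorter than PWM width {pwm.width}"
        )
    seq_i = _encode(promoter.sequence)
    sites: list[BindingSite] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        full, core, valid = _window_scores(seq_i, mat)
        hits = np.flatnonzero(valid & (full >= min_score) & (core >= min_core_score))
        for j in hits:
            coverage, mean_cons = _site_conservation(promoter, int(j), pwm.width)
            sites.append(
                BindingSite(
                    gene=promoter.gene,
                    start=int(j) - promoter.tss_offset,
                    strand=strand,
                    score=float(full[j]),
                    width=pwm.width,
                    core_score=float(core[j]),
                    coverage=coverage,
                    mean_conservation=mean_cons,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def conservation_filter(
    site: BindingSite, min_coverage: float = 0.8, min_mean: float = 0.6
) -> bool:
    """Pass iff enough bases carry conservation scores and their mean is high."""
    if site.coverage < min_coverage:
        return False
    return np.isfinite(site.mean_conservation) and site.mean_conservation >= min_mean


def predict_regulons(
    promoters: list[PromoterRecord],
    pwms: list[PWM],
    tf_map: dict,
    thresholds: dict | None = None,
):
    """Scan + conservation-filter every promoter; emit one regulon per (TF, motif).

    `tf_map` maps motif id -> TF gene id. A gene is a target iff at least
    one of its sites passes both the similarity and conservation filters.
    """
    from .tfreg import TFRegulon

    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    per_motif: dict[str, dict[str, list[BindingSite]]] = defaultdict(dict)
    for pwm in pwms:
        for prom in promoters:
            passing = [
                s
                for s in scan_pwm(prom, pwm, th["min_score"], th["min_core_score"])
                if conservation_filter(s, th["min_coverage"], th["min_mean"])
            ]
            if passing:
                per_motif[pwm.id][prom.gene] = passing
    regulons = []
    for pwm in pwms:
        tf = tf_map[pwm.id]
        sites = {g: s for g, s in per_motif[pwm.id].items() if g != tf}
        if sites:
            regulons.append(
                TFRegulon(tf=tf, motif=pwm.id, targets=frozenset(sites), sites=sites)
            )
    return regulons


def tss_proximity_test(
    sites: list[BindingSite], half_window: int = 2000
) -> tuple[float, float]:
    """One-sided KS test of |TSS distance| vs Uniform(0, half_window).

    Alternative: distances are stochastically smaller than uniform
    (sites lie closer to the TSS). Returns (p, median distance).
    """
    if not sites:
        raise ValueError("no sites")
    dist = np.array([abs(s.start) for s in sites], dtype=float)
    res = stats.kstest(
        dist, stats.uniform(0, half_window).cdf, alternative="greater"
    )
    return float(res.pvalue), float(np.median(dist))


def dinucleotide_shuffle(sequence: str, seed=None) -> str:
    """Eulerian-path shuffle preserving all 16 dinucleotide counts.

    Altschul-Erickson: pick random terminal edges forming an arborescence
    into the last character's vertex, shuffle the remaining adjacency
    lists, then walk the Eulerian path from the first character. First
    and last bases are preserved exactly.
    """
    if len(sequence) < 2:
        return sequence
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(sequence, sequence[1:]):
        edges[a].append(b)
    last = sequence[-1]
    vertices = list(edges)
    while True:
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = set()
            u = v
            while u != last and u in last_edge and u not in seen:
                seen.add(u)
                u = last_edge[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    adj: dict[str, list[str]] = {}
    for v in vertices:
        lst = list(edges[v])
        if v != last:
            lst.remove(last_edge[v])
        rng.shuffle(lst)
        if v != last:
            lst.append(last_edge[v])
        adj[v] = lst
    out = [sequence[0]]
    ptr = dict.fromkeys(adj, 0)
    u = sequence[0]
    append = out.append
    for _ in range(len(sequence) - 1):
        lst = adj[u]
        i = ptr[u]
        ptr[u] = i + 1
        u = lst[i]
        append(u)
    return "".join(out)


def shuffle_conservation(promoter: PromoterRecord, seed=None) -> np.ndarray:
    """Permute conservation scores within positions sharing a base letter."""
    if promoter.conservation is None:
        raise ValueError(f"{promoter.gene}: no conservation track")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = promoter.conservation.copy()
    arr = np.frombuffer(promoter.sequence.encode(), dtype=np.uint8)
    for b in set(promoter.sequence):
        idx = np.flatnonzero(arr == ord(b))
        scores[idx] = scores[idx][rng.permutation(len(idx))]
    return scores


@dataclass
class BindingSiteNull:
    batch_counts: np.ndarray
    observed_count: int
    expected_count: float
    fdr: float | None


def _count_predicted(
    promoters: list[PromoterRecord], pwm: PWM, th: dict
) -> int:
    n = 0
    for prom in promoters:
        sites = scan_pwm(prom, pwm, th["min_score"], th["min_core_score"])
        if any(
            conservation_filter(s, th["min_coverage"], th["min_mean"]) for s in sites
        ):
            n += 1
    return n


def binding_site_null(
    promoters: list[PromoterRecord],
    pwm: PWM,
    n_batches: int = 1000,
    thresholds: dict | None = None,
    seed: int = 0,
) -> BindingSiteNull:
    """Shuffle-based null for the number of predicted target genes.

    Each batch dinucleotide-shuffles every promoter sequence, permutes
    conservation scores within base types, and recounts genes carrying
    at least one passing site. expected = median batch count and
    fdr = expected / observed (None when observed is 0).
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    observed = _count_predicted(promoters, pwm, th)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_batches, dtype=int)
    for b in range(n_batches):
        n = 0
        for prom in promoters:
            shuffled_seq = dinucleotide_shuffle(prom.sequence, rng)
            fake = PromoterRecord(
                gene=prom.gene,
                tss_offset=prom.tss_offset,
                sequence=shuffled_seq,
                conservation=None
                if prom.conservation is None
                else shuffle_conservation(
                    PromoterRecord(
                        prom.gene, prom.tss_offset, shuffled_seq, prom.conservation
                    ),
                    rng,
                ),
            )
            sites = scan_pwm(fake, pwm, th["min_score"], th["min_core_score"])
            if any(
                conservation_filter(s, th["min_coverage"], th["min_mean"])
                for s in sites
            ):
                n += 1
        counts[b] = n
    expected = float(np.median(counts))
    fdr = None if observed == 0 else expected / observed
    if fdr is None:
        logger.warning("binding_site_null: observed target count is 0; FDR undefined")
    return BindingSiteNull(counts, observed, expected, fdr)


@dataclass
class DnaseOverlapResult:
    n_genes_overlapping: int
    expected: float
    p: float
    null_counts: np.ndarray
    n_genes_tested: int
    excluded_genes: list


_MAX_REJECTION_FACTOR = 10_000


def dnase_overlap_test(
    sites: list[BindingSite],
    dnase: list[GenomicInterval],
    promoters: list[PromoterRecord],
    gc_floor: float = 0.79,
    n_rand: int = 1000,
    seed: int = 0,
) -> DnaseOverlapResult:
    """G/C-matched placement null for binding-site / open-chromatin overlap.

    observed = number of genes with >= 1 site overlapping an interval by
    >= 1 base. The null redraws, per gene, width-matched promoter
    stretches with G/C >= `gc_floor`; p is the fraction of the `n_rand`
    joint placements whose overlapping-gene count reaches the observed.
    """
    proms = {p.gene: p for p in promoters}
    by_gene_sites: dict[str, list[BindingSite]] = defaultdict(list)
    for s in sites:
        if s.gene not in proms:
            raise ValueError(f"site on {s.gene} without a promoter record")
        by_gene_sites[s.gene].append(s)
    by_gene_iv: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in dnase:
        by_gene_iv[iv.chrom].append(iv)

    genes = sorted(by_gene_sites)
    observed = 0
    for g in genes:
        prom = proms[g]
        hit = False
        for s in by_gene_sites[g]:
            a = s.start + prom.tss_offset
            if any(iv.overlaps(a, a + s.width) for iv in by_gene_iv.get(g, [])):
                hit = True
                break
        observed += hit
    if not dnase:
        return DnaseOverlapResult(0, 0.0, 1.0, np.zeros(n_rand, dtype=int), len(genes), [])

    rng = np.random.default_rng(seed)
    null_hits = []  # per gene: bool vector of length n_rand
    excluded = []
    for g in genes:
        prom = proms[g]
        width = by_gene_sites[g][0].width
        seq_i = _encode(prom.sequence)
        gc = np.isin(seq_i, (1, 2)).astype(int)
        win_gc = np.convolve(gc, np.ones(width, dtype=int), mode="valid")
        qualifying = np.flatnonzero(win_gc >= gc_floor * width - 1e-9)
        if len(qualifying) == 0:
            logger.warning(
                "gene %s has no %d-bp stretch with G/C >= %.2f; excluded from null",
                g, width, gc_floor,
            )
            excluded.append(g)
            continue
        starts = qualifying[rng.integers(0, len(qualifying), size=n_rand)]
        ivs = by_gene_iv.get(g, [])
        if ivs:
            iv_s = np.array([iv.start for iv in ivs])
            iv_e = np.array([iv.end for iv in ivs])
            hit = (
                (starts[:, None] < iv_e[None, :])
                & (iv_s[None, :] < (starts + width)[:, None])
            ).any(axis=1)
        else:
            hit = np.zeros(n_rand, dtype=bool)
        null_hits.append(hit)
    if null_hits:
        null_counts = np.vstack(null_hits).sum(axis=0)
    else:
        null_counts = np.zeros(n_rand, dtype=int)
    p = float(np.mean(null_counts >= observed))
    return DnaseOverlapResult(
        n_genes_overlapping=observed,
        expected=float(np.median(null_counts)),
        p=p,
        null_counts=null_counts,
        n_genes_tested=len(genes) - len(excluded),
        excluded_genes=excluded,
    )


def compare_score_distributions(
    foreground, background, alternative: str = "two-sided"
) -> float:
    """Rank-sum comparison of two per-gene score distributions."""
    fg = np.asarray(foreground, dtype=float)
    bg = np.asarray(background, dtype=float)
    fg = fg[np.isfinite(fg)]
    bg = bg[np.isfinite(bg)]
    if fg.size == 0 or bg.size == 0:
        raise ValueError("empty score set")
    _, p = rank_sum_test(fg, bg, alternative=alternative)
    return p
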