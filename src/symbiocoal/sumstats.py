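"""Alignment-level population-genetic summary statistics.

Implements the statistics the recombination-rate estimator consumes - per-site
nucleotide diversity (pi), Watterson's theta, and distance-binned proportions
of site pairs failing the four-gamete test - plus Tajima's D, folded allele
frequency spectra and Hudson's Fst with a non-parametric bootstrap.

All statistics treat sites with gaps/ambiguity as missing (complete-case:
such columns are excluded and counted) and use the alignment's usable length
as the per-site denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import HaplotypeAlignment

#: right edges of the four-gamete distance bins, bp (half-open on the left)
F4_BIN_EDGES = (10, 100, 1_000, 10_000, 100_000, 1_000_000)


@dataclass
class SummaryVector:
    """The feature vector of the regression-ABC fit.

    ``f4_bins`` holds one proportion per distance bin; NaN marks a bin with no
    eligible site pairs (missing, not zero).
    """

    pi: float
    watterson: float
    f4_bins: np.ndarray
    n_samples: int
    n_sites_used: int
    n_pairs_per_bin: np.ndarray = field(default_factory=lambda: np.zeros(6, dtype=int))
    n_pairs_beyond_last_bin: int = 0

    TSV_COLUMNS = (
        "pi",
        "watterson",
        "f4_bin1",
        "f4_bin2",
        "f4_bin3",
        "f4_bin4",
        "f4_bin5",
        "f4_bin6",
        "n_samples",
        "n_sites_used",
    )

    def as_row(self) -> list[float]:
        return [self.pi, self.watterson, *self.f4_bins.tolist(), self.n_samples, self.n_sites_used]


@dataclass
class FoldedAFS:
    """Folded allele frequency spectrum over biallelic sites."""

    counts: np.ndarray  # index i-1 = number of sites with minor allele count i
    n_samples: int
    n_excluded_sites: int = 0

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


@dataclass
class FstResult:
    fst: float
    ci_low: float
    ci_high: float
    n_bootstrap: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("bootstrap CI bounds out of order")


# ---------------------------------------------------------------------------
# variant matrix helpers
# ---------------------------------------------------------------------------

def _variant_columns(aln: HaplotypeAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(positions, minor-allele counts per site) over biallelic variant columns,
    plus internal caching of per-site carrier bitmasks on the alignment."""
    positions, masks, minor_counts = [], [], []
    n = aln.n_samples
    for pos in aln.variant_positions:
        col = aln.column(pos)
        alleles = sorted(set(col))
        if len(alleles) != 2:
            continue
        count_a = col.count(alleles[0])
        # mask the minor allele (ties: the lexicographically first of the two)
        minor = alleles[0] if count_a <= n - count_a else alleles[1]
        mask = 0
        for i, c in enumerate(col):
            if c == minor:
                mask |= 1 << i
        positions.append(pos)
        masks.append(mask)
        minor_counts.append(min(count_a, n - count_a))
    return (
        np.asarray(positions, dtype=np.int64),
        np.asarray(masks, dtype=np.uint64),
    ), np.asarray(minor_counts, dtype=np.int64)


def pairwise_difference_total(aln: HaplotypeAlignment) -> float:
    """Mean number of pairwise differences over all unordered sample pairs."""
    n = aln.n_samples
    total = 0.0
    for pos in aln.variant_positions:
        col = aln.column(pos)
        counts = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        same = sum(v * (v - 1) // 2 for v in counts.values())
        total += n * (n - 1) // 2 - same
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(aln: HaplotypeAlignment) -> float:
    """Per-site pi: mean pairwise differences over the usable length."""
    if aln.n_samples < 2:
        raise ValueError("pi requires at least two samples")
    return pairwise_difference_total(aln) / aln.usable_length


def watterson_theta(aln: HaplotypeAlignment) -> float:
    """Per-site Watterson's theta: S / (a_{n-1} * usable length)."""
    n = aln.n_samples
    if n < 2:
        raise ValueError("Watterson's theta requires at least two samples")
    a1 = sum(1.0 / i for i in range(1, n))
    return len(aln.variant_positions) / (a1 * aln.usable_length)


@dataclass
class TajimaResult:
    d: float
    defined: bool
    status: str = "ok"


def tajimas_d(aln: HaplotypeAlignment) -> TajimaResult:
    """Tajima's D with the standard 1989 variance constants.

    Returns an explicit undefined sentinel (``defined=False``, ``d=nan``) when
    the alignment is monomorphic, never a silent zero.
    """
    n = aln.n_samples
    s = len(aln.variant_positions)
    if s == 0:
        return TajimaResult(d=float("nan"), defined=False, status="no segregating sites")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_total = pairwise_difference_total(aln)
    d = (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))
    return TajimaResult(d=d, defined=True)


def folded_afs(aln: HaplotypeAlignment) -> FoldedAFS:
    """Folded spectrum of minor-allele counts over biallelic sites.

    Sites that are not biallelic are excluded and counted; ties at n/2 fall in
    the n/2 class by the folding itself.
    """
    n = aln.n_samples
    (_, _), minor_counts = _variant_columns(aln)
    counts = np.zeros(n // 2, dtype=np.int64)
    for c in minor_counts:
        counts[c - 1] += 1
    n_excluded = len(aln.variant_positions) - len(minor_counts)
    return FoldedAFS(counts=counts, n_samples=n, n_excluded_sites=n_excluded)


# ---------------------------------------------------------------------------
# four-gamete profile
# ---------------------------------------------------------------------------

def four_gamete_profile(
    aln: HaplotypeAlignment, bin_edges: tuple[int, ...] = F4_BIN_EDGES
) -> tuple[np.ndarray, np.ndarray, int]:
    """Distance-binned proportions of non-singleton site pairs showing all
    four haplotypic allele combinations.

    Pairs are binned by inter-site distance into half-open bins
    (0, e1], (e1, e2], ...; pairs beyond the last edge are excluded and
    counted. Returns ``(proportions, pairs_per_bin, n_beyond)`` with NaN for
    bins holding no pairs.
    """
    (positions, masks), minor_counts = _variant_columns(aln)
    keep = minor_counts >= 2  # non-singleton sites only
    positions, masks = positions[keep], masks[keep]
    nbins = len(bin_edges)
    failures = np.zeros(nbins, dtype=np.int64)
    totals = np.zeros(nbins, dtype=np.int64)
    n_beyond = 0
    m = len(positions)
    if m >= 2:
        full = np.uint64((1 << aln.n_samples) - 1)
        iu, ju = np.triu_indices(m, k=1)
        d = positions[ju] - positions[iu]
        a, b = masks[iu], masks[ju]
        four = (
            ((a & b) != 0)
            & ((a & ~b & full) != 0)
            & ((~a & b & full) != 0)
            & ((~a & ~b & full) != 0)
        )
        edges = np.asarray(bin_edges)
        which = np.searchsorted(edges, d, side="left")
        beyond = which >= nbins
        n_beyond = int(beyond.sum())
        which, four = which[~beyond], four[~beyond]
        np.add.at(totals, which, 1)
        np.add.at(failures, which, four.astype(np.int64))
    with np.errstate(invalid="ignore"):
        props = np.where(totals > 0, failures / np.maximum(totals, 1), np.nan)
    return props, totals, n_beyond


def summarize_alignment(aln: HaplotypeAlignment) -> SummaryVector:
    """The full ABC feature vector for one alignment."""
    props, totals, n_beyond = four_gamete_profile(aln)
    return SummaryVector(
        pi=nucleotide_diversity(aln),
        watterson=watterson_theta(aln),
        f4_bins=props,
        n_samples=aln.n_samples,
        n_sites_used=aln.usable_length,
        n_pairs_per_bin=totals,
        n_pairs_beyond_last_bin=n_beyond,
    )


# ---------------------------------------------------------------------------
# Hudson Fst
# ---------------------------------------------------------------------------

def _hudson_components(
    p1: np.ndarray, p2: np.ndarray, n1: np.ndarray | None, n2: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator/denominator. With sample sizes, the unbiased
    within-population heterozygosity correction is applied; without them the
    frequency-only form (p1-p2)^2 over p1(1-p2)+p2(1-p1) is used."""
    num = (p1 - p2) ** 2
    if n1 is not None and n2 is not None:
        num = num - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_between_hosts(
    p1: np.ndarray,
    p2: np.ndarray,
    n1: np.ndarray | int | None = None,
    n2: np.ndarray | int | None = None,
    n_bootstrap: int = 1_000,
    seed: int | None = None,
) -> FstResult:
    """Hudson's Fst between two host groups, ratio-of-averages across sites,
    with a percentile bootstrap over sites for the 95% interval.

    ``p1``/``p2`` are per-site allele frequencies; ``n1``/``n2`` optional
    haplotype sample sizes enabling the finite-sample correction.
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    if p1.size == 0 or p1.shape != p2.shape:
        raise ValueError("need equal-length, non-empty frequency vectors")
    n1a = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape) if n1 is not None else None
    n2a = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape) if n2 is not None else None
    num, den = _hudson_components(p1, p2, n1a, n2a)
    usable = den > 0
    if not usable.any():
        raise ValueError("no site with nonzero Hudson denominator")
    point = float(num[usable].sum() / den[usable].sum())

    rng = np.random.default_rng(seed)
    n_sites = int(usable.sum())
    nu, de = num[usable], den[usable]
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = rng.integers(n_sites, size=n_sites)
        d = de[idx].sum()
        boots[i] = nu[idx].sum() / d if d > 0 else np.nan
    boots = boots[~np.isnan(boots)]
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots.size else (point, point))
    return FstResult(fst=point, ci_low=float(min(lo, point)), ci_high=float(max(hi, point)),
                     n_bootstrap=n_bootstrap)


def host_group_frequencies(
    aln: HaplotypeAlignment, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-site frequencies of one reference allele in two host groups, over
    the alignment's biallelic variant columns."""
    if aln.host_ids is None:
        raise ValueError("alignment carries no host labels")
    ia = [i for i, h in enumerate(aln.host_ids) if h == group_a]
    ib = [i for i, h in enumerate(aln.host_ids) if h == group_b]
    if not ia or not ib:
        raise ValueError("both host groups must be non-empty")
    f1, f2 = [], []
    for pos in aln.variant_positions:
        col = aln.column(pos)
        alleles = sorted(set(col))
        if len(alleles) != 2:
            continue
        ref = alleles[0]
        f1.append(sum(col[i] == ref for i in ia) / len(ia))
        f2.append(sum(col[i] == ref for i in ib) / len(ib))
    return np.asarray(f1), np.asarray(f2), len(ia), len(ib)
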