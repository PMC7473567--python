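"""Within-host analysis from read data.

Three pieces: a pileup-based variant caller whose filters are (i) a coverage
window of mean +/- 1 SD of genome-wide depth, (ii) exclusion of sites near
indel-bearing columns, and (iii) a one-sided binomial test of the alternate
allele count against the sequencing error rate; a folded spectrum of
minor-allele read frequencies; and the read-backed four-gamete test that
tallies the four allelic configurations of a site pair across single read
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import PileupColumn


@dataclass
class WithinHostVariant:
    position: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_count: int
    error_prob_used: float

    def __post_init__(self) -> None:
        if not 0 < self.alt_count <= self.depth:
            raise ValueError("need 0 < alt_count <= depth")

    @property
    def alt_freq(self) -> float:
        return self.alt_count / self.depth


@dataclass
class WithinHostCallResult:
    """Variant calls plus the per-site diversity over retained columns."""

    variants: list[WithinHostVariant]
    pairwise_diversity: float  # mean 2p(1-p)*d/(d-1) per usable site
    n_usable_sites: int
    n_coverage_filtered: int
    n_indel_filtered: int
    status: str = "ok"


def _phred_error_rate(qualities: str) -> float:
    qs = np.frombuffer(qualities.encode(), dtype=np.uint8).astype(float) - 33.0
    return float(np.mean(10.0 ** (-qs / 10.0)))


def call_within_host_variants(
    columns: list[PileupColumn],
    error_rate: float | None = None,
    alpha: float = 0.05,
    indel_window: int = 5,
    bonferroni: bool = False,
) -> WithinHostCallResult:
    """Call within-host variants from pileup columns.

    A column is usable when its depth lies within one standard deviation of
    the genome-wide mean and it is not within ``indel_window`` bp of an
    indel-bearing column. On usable columns the most common alternate base is
    called a variant when the upper-tail binomial probability
    P(X >= alt_count | depth, error rate) falls below ``alpha``
    (Bonferroni-corrected over usable sites when requested).

    ``error_rate`` fixes a global per-base error probability; when None it is
    derived per site from the column's mean phred error.
    """
    if not columns:
        raise ValueError("no pileup columns supplied")
    depths = np.array([c.depth for c in columns], dtype=float)
    mean_d, sd_d = depths.mean(), depths.std()
    lo, hi = mean_d - sd_d, mean_d + sd_d

    indel_positions = [c.position for c in columns if c.has_indel]
    indel_arr = np.asarray(indel_positions, dtype=np.int64)

    def near_indel(pos: int) -> bool:
        if indel_arr.size == 0:
            return False
        i = np.searchsorted(indel_arr, pos)
        for j in (i - 1, i):
            if 0 <= j < indel_arr.size and abs(int(indel_arr[j]) - pos) <= indel_window:
                return True
        return False

    usable: list[PileupColumn] = []
    n_cov = n_indel = 0
    for c in columns:
        if not lo <= c.depth <= hi:
            n_cov += 1
        elif near_indel(c.position):
            n_indel += 1
        else:
            usable.append(c)
    if not usable:
        return WithinHostCallResult(
            variants=[],
            pairwise_diversity=float("nan"),
            n_usable_sites=0,
            n_coverage_filtered=n_cov,
            n_indel_filtered=n_indel,
            status="all columns filtered",
        )

    threshold = alpha / len(usable) if bonferroni else alpha
    variants: list[WithinHostVariant] = []
    div_total = 0.0
    for c in usable:
        counts = c.allele_counts()
        alt_items = [(k, v) for k, v in counts.items() if k not in (".", "*")]
        if not alt_items:
            continue
        alt_base, _ = max(alt_items, key=lambda kv: kv[1])
        alt_total = sum(v for _, v in alt_items)
        err = error_rate if error_rate is not None else _phred_error_rate(c.base_qualities)
        # P(X >= alt_total) under Binomial(depth, err)
        p_tail = float(stats.binom.sf(alt_total - 1, c.depth, err))
        if p_tail < threshold:
            variants.append(
                WithinHostVariant(
                    position=c.position,
                    ref_allele=c.ref_base,
                    alt_allele=alt_base,
                    depth=c.depth,
                    alt_count=alt_total,
                    error_prob_used=err,
                )
            )
            p = alt_total / c.depth
            d = c.depth
            div_total += 2 * p * (1 - p) * d / (d - 1)
    return WithinHostCallResult(
        variants=variants,
        pairwise_diversity=div_total / len(usable),
        n_usable_sites=len(usable),
        n_coverage_filtered=n_cov,
        n_indel_filtered=n_indel,
    )


@dataclass
class WithinHostAFS:
    bin_edges: np.ndarray   # n_bins + 1 edges over (0, 0.5]
    counts: np.ndarray
    status: str = "ok"


def within_host_folded_afs(
    variants: list[WithinHostVariant], n_bins: int = 10
) -> WithinHostAFS:
    """Histogram of minor-allele read frequencies, folded onto (0, 0.5]."""
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    if not variants:
        return WithinHostAFS(bin_edges=edges, counts=np.zeros(n_bins, dtype=int),
                             status="no variants")
    freqs = np.array([min(v.alt_freq, 1 - v.alt_freq) for v in variants])
    counts, _ = np.histogram(freqs, bins=edges)
    return WithinHostAFS(bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# read-backed four-gamete test
# ---------------------------------------------------------------------------

@dataclass
class SitePairPhase:
    """Configuration counts (AB, Ab, aB, ab) of a site pair on read pairs."""

    pos_a: int
    pos_b: int
    counts: dict[str, int]
    all_four_flag: bool
    status: str = "ok"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PhaseTally:
    pairs: list[SitePairPhase]
    n_discarded_observations: int = 0

    def flagged(self) -> list[SitePairPhase]:
        return [p for p in self.pairs if p.all_four_flag]


def read_pair_four_gamete(
    observations,
    site_alleles: dict[int, tuple[str, str]] | None = None,
    min_total: int = 100,
    min_prop: float = 0.05,
) -> PhaseTally:
    """Tally the four allelic configurations of every co-observed site pair.

    ``observations`` are the read-pair records (read id, two positions, the
    base seen at each). Site alleles default to the two most common bases
    observed per site; an observation carrying any other base at a site is
    discarded and counted. A pair is flagged as showing all four gametes only
    when its total count reaches ``min_total`` and every configuration's
    proportion strictly exceeds ``min_prop``; pairs below ``min_total`` are
    reported with a low-coverage status and never flagged.
    """
    by_site: dict[int, dict[str, int]] = {}
    for o in observations:
        by_site.setdefault(o.pos_a, {})[o.base_a] = by_site.setdefault(o.pos_a, {}).get(o.base_a, 0) + 1
        by_site.setdefault(o.pos_b, {})[o.base_b] = by_site.setdefault(o.pos_b, {}).get(o.base_b, 0) + 1
    if site_alleles is None:
        site_alleles = {}
        for pos, counts in by_site.items():
            top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
            if len(top) == 2:
                site_alleles[pos] = (top[0][0], top[1][0])

    tallies: dict[tuple[int, int], dict[str, int]] = {}
    n_discarded = 0
    for o in observations:
        key = (o.pos_a, o.pos_b) if o.pos_a < o.pos_b else (o.pos_b, o.pos_a)
        base_first, base_second = (
            (o.base_a, o.base_b) if o.pos_a < o.pos_b else (o.base_b, o.base_a)
        )
        al_a = site_alleles.get(key[0])
        al_b = site_alleles.get(key[1])
        if al_a is None or al_b is None or base_first not in al_a or base_second not in al_b:
            n_discarded += 1
            continue
        config = ("A" if base_first == al_a[0] else "a") + (
            "B" if base_second == al_b[0] else "b"
        )
        t = tallies.setdefault(key, {"AB": 0, "Ab": 0, "aB": 0, "ab": 0})
        t[config] += 1

    pairs = []
    for (pa, pb), counts in sorted(tallies.items()):
        total = sum(counts.values())
        if total < min_total:
            pairs.append(SitePairPhase(pa, pb, counts, all_four_flag=False,
                                       status="below minimum observations"))
            continue
        flag = all(v / total > min_prop for v in counts.values())
        pairs.append(SitePairPhase(pa, pb, counts, all_four_flag=flag))
    return PhaseTally(pairs=pairs, n_discarded_observations=n_discarded)
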