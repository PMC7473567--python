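"""Neutral Kingman coalescent with bacterial gene conversion.

Simulates haplotype samples under an exact ancestral-recombination-graph
construction in which recombination is gene conversion: an initiation event on
a lineage transfers a contiguous tract of fixed length ``l`` onto a second
ancestral lineage, splitting the carrier's ancestral material into tract and
complement. No clonal frame is imposed. Mutations follow an infinite-sites
model mapped onto distinct integer positions.

Time is measured in units of 2*Ne generations, so per-site rates ``theta``
(2*Ne*mu) and ``rho`` (2*Ne*r, gene-conversion initiations) enter the ancestral
process as ``theta/2`` and ``rho/2`` per lineage per unit time.

The construction is exact, not sequentially Markovian; it is intended for
desk-scale genomes (tens of kilobases), where the full ARG remains tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import HaplotypeAlignment

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationBudgetError(RuntimeError):
    """The ancestral process exceeded its event budget."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of one gene-conversion coalescent run.

    ``theta``/``rho`` are per-site population-scaled rates; ``tract_length``
    is the gene-conversion segment length in bp, fixed (not geometric) per run.
    """

    theta: float
    rho: float
    tract_length: int
    genome_length: int
    sample_size: int
    seed: int

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not 1 <= self.tract_length <= self.genome_length:
            raise ValueError("need 1 <= tract_length <= genome_length")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")


@dataclass
class SimReplicate:
    """One simulated sample: the alignment plus ARG bookkeeping."""

    alignment: HaplotypeAlignment
    n_recomb_events: int
    params: SimParams
    mutation_masks: dict[int, int] = field(default_factory=dict)  # position -> carrier bitmask


def expected_segregating_sites(params: SimParams) -> float:
    """Watterson's neutral expectation theta * L * sum_{i<n} 1/i."""
    n = params.sample_size
    a = sum(1.0 / i for i in range(1, n))
    return params.theta * params.genome_length * a


def harmonic(n_minus_1: int) -> float:
    return sum(1.0 / i for i in range(1, n_minus_1 + 1))


# segment = (start, end, mask); half-open integer interval [start, end) in [0, L)


def _merge(segs_a: list, segs_b: list, full_mask: int) -> list:
    """Union two lineages' material, OR-ing masks where they overlap and
    discarding any stretch whose mask reaches all samples (its local MRCA)."""
    events = []
    for s, e, m in segs_a:
        events.append((s, 1, m))
        events.append((e, -1, m))
    for s, e, m in segs_b:
        events.append((s, 2, m))
        events.append((e, -2, m))
    events.sort(key=lambda t: (t[0], -abs(t[1])))
    out = []
    cur_a = cur_b = 0
    prev = None
    for pos, kind, m in events:
        if prev is not None and pos > prev and (cur_a or cur_b):
            mask = cur_a | cur_b
            if mask != full_mask:
                if out and out[-1][1] == prev and out[-1][2] == mask:
                    out[-1] = (out[-1][0], pos, mask)
                else:
                    out.append((prev, pos, mask))
        if kind == 1:
            cur_a = m
        elif kind == -1:
            cur_a = 0
        elif kind == 2:
            cur_b = m
        else:
            cur_b = 0
        prev = pos
    return out


def _split(segs: list, lo: int, hi: int) -> tuple[list, list]:
    """Partition material into the part inside [lo, hi) and the part outside."""
    inside, outside = [], []
    for s, e, m in segs:
        a, b = max(s, lo), min(e, hi)
        if a < b:
            if s < a:
                outside.append((s, a, m))
            inside.append((a, b, m))
            if b < e:
                outside.append((b, e, m))
        else:
            outside.append((s, e, m))
    return inside, outside


def _material_length(segs: list) -> int:
    return sum(e - s for s, e, _ in segs)


def simulate_coalescent_gc(
    params: SimParams, max_events: int = 2_000_000
) -> SimReplicate:
    """Run the ancestral process and emit a sample of haplotypes.

    ``n_recomb_events`` counts effective gene-conversion events only, i.e.
    those whose tract boundary actually splits a lineage's ancestral material;
    with ``rho = 0`` it is exactly zero.
    """
    rng = np.random.default_rng(params.seed)
    n, L = params.sample_size, params.genome_length
    full_mask = (1 << n) - 1
    lineages: list[list] = [[(0, L, 1 << i)] for i in range(n)]
    mat_lengths: list[int] = [L] * n

    mutations: list[tuple[float, int, int]] = []  # (time-ordering dummy, site, mask) -> site,mask used
    used_sites: set[int] = set()
    mut_rate_site = params.theta / 2.0
    gc_rate_per_lineage = params.rho * L / 2.0
    tract = params.tract_length
    n_eff_gc = 0
    n_events = 0

    muts: list[tuple[int, int]] = []  # (0-based site, carrier mask)

    while lineages:
        k = len(lineages)
        if k == 1:
            # a lone lineage can only carry full-mask material, which is
            # discarded on creation, so this cannot be reached with material
            break
        rate_coal = k * (k - 1) / 2.0
        rate_gc = k * gc_rate_per_lineage
        total_rate = rate_coal + rate_gc
        dt = rng.exponential(1.0 / total_rate)

        # mutations dropped on all current lineages during dt
        total_mat = sum(mat_lengths)
        if mut_rate_site > 0 and total_mat > 0:
            n_mut = rng.poisson(dt * mut_rate_site * total_mat)
            for _ in range(n_mut):
                target = rng.integers(total_mat)
                li = 0
                while target >= mat_lengths[li]:
                    target -= mat_lengths[li]
                    li += 1
                site, mask = _locate(lineages[li], int(target))
                if site in used_sites:
                    site = _redraw_site(rng, lineages[li], used_sites)
                    if site is None:
                        continue
                    mask = _locate_site(lineages[li], site)
                used_sites.add(site)
                muts.append((site, mask))

        n_events += 1
        if n_events > max_events:
            raise SimulationBudgetError(
                f"ancestral process exceeded {max_events} events "
                f"(theta={params.theta}, rho={params.rho}, l={tract}, "
                f"L={L}, n={n})"
            )

        if rng.random() < rate_coal / total_rate:
            i, j = rng.choice(k, size=2, replace=False)
            i, j = int(i), int(j)
            merged = _merge(lineages[i], lineages[j], full_mask)
            for idx in sorted((i, j), reverse=True):
                del lineages[idx]
                del mat_lengths[idx]
            if merged:
                lineages.append(merged)
                mat_lengths.append(_material_length(merged))
        else:
            li = int(rng.integers(k))
            x = int(rng.integers(L))
            inside, outside = _split(lineages[li], x, min(x + tract, L))
            if inside and outside:
                n_eff_gc += 1
                lineages[li] = inside
                mat_lengths[li] = _material_length(inside)
                lineages.append(outside)
                mat_lengths.append(_material_length(outside))

    alignment = _emit_alignment(rng, params, muts)
    return SimReplicate(
        alignment=alignment,
        n_recomb_events=n_eff_gc,
        params=params,
        mutation_masks={site + 1: mask for site, mask in muts},
    )


def _locate(segs: list, offset: int) -> tuple[int, int]:
    """Material-offset -> (0-based genomic site, mask)."""
    for s, e, m in segs:
        if offset < e - s:
            return s + offset, m
        offset -= e - s
    raise AssertionError("offset beyond material")


def _locate_site(segs: list, site: int) -> int:
    for s, e, m in segs:
        if s <= site < e:
            return m
    raise AssertionError("site not in material")


def _redraw_site(rng, segs: list, used: set, tries: int = 30):
    """Infinite-sites collision: rejection-redraw within the same material."""
    total = _material_length(segs)
    for _ in range(tries):
        site, _ = _locate(segs, int(rng.integers(total)))
        if site not in used:
            return site
    return None


def _emit_alignment(rng, params: SimParams, muts: list) -> HaplotypeAlignment:
    n, L = params.sample_size, params.genome_length
    background = rng.integers(4, size=L).astype(np.uint8)
    seqs = np.tile(background, (n, 1))
    positions = []
    for site, mask in sorted(muts):
        ref = background[site]
        derived = (ref + 1 + rng.integers(3)) % 4
        carriers = [i for i in range(n) if mask >> i & 1]
        seqs[carriers, site] = derived
        positions.append(site + 1)
    as_bytes = _BASES[seqs]
    sequences = [a.tobytes().decode() for a in as_bytes]
    return HaplotypeAlignment(
        sample_ids=[f"hap{i}" for i in range(n)],
        sequences=sequences,
        variant_positions=positions,
        excluded_positions=[],
        genome_length=L,
    )
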