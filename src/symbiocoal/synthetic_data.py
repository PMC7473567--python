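"""Generators for every input the pipeline consumes.

Everything here is synthetic and seed-deterministic: multi-host consensus
alignments with the population structure the transmission model produces,
paired-read observations and pileups from within-host haplotype mixtures, and
VCF-style records with known filter truth. The read error model is independent
uniform substitution to one of the three other bases; reads carry no indel
errors (indel-bearing pileup columns for filter tests are injected explicitly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent_gc import SimParams, simulate_coalescent_gc
from .io_formats import HaplotypeAlignment, PileupColumn, SiteRecord
from .transmission_model import ForwardTransmissionSim, TransmissionParams, _effective_generations

_ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# consensus-genome metapopulations
# ---------------------------------------------------------------------------

def make_metapopulation_alignment(
    tparams: TransmissionParams | SimParams,
    hosts_sampled: int,
    symbionts_per_host: int,
    seed: int,
    genome_length: int = 10_000,
) -> HaplotypeAlignment:
    """Symbiont haplotypes sampled from several hosts, with host labels.

    With :class:`SimParams` the sample is panmictic (gene-conversion
    coalescent) and host labels are an arbitrary block partition; with
    :class:`TransmissionParams` sequences are emitted from a forward run of
    the structured inheritance model, so host labels carry real structure.
    """
    n_total = hosts_sampled * symbionts_per_host
    if isinstance(tparams, SimParams):
        params = SimParams(
            theta=tparams.theta,
            rho=tparams.rho,
            tract_length=tparams.tract_length,
            genome_length=tparams.genome_length,
            sample_size=n_total,
            seed=seed,
        )
        aln = simulate_coalescent_gc(params).alignment
        aln.host_ids = [f"host{i // symbionts_per_host}" for i in range(n_total)]
        aln.sample_ids = [
            f"host{i // symbionts_per_host}_sym{i % symbionts_per_host}" for i in range(n_total)
        ]
        return aln
    return _alignment_from_forward_run(
        tparams, hosts_sampled, symbionts_per_host, seed, genome_length
    )


def _alignment_from_forward_run(
    params: TransmissionParams,
    hosts_sampled: int,
    symbionts_per_host: int,
    seed: int,
    genome_length: int,
) -> HaplotypeAlignment:
    rng = np.random.default_rng(seed)
    sim = ForwardTransmissionSim(params, np.random.default_rng(int(rng.integers(2**31))))
    sim.run(_effective_generations(params))
    sim.switch_step()
    pools = sim._host_pools(min_size=symbionts_per_host)
    eligible = sorted(pools)
    if len(eligible) < hosts_sampled:
        raise ValueError("fewer hosts with enough symbionts than requested")
    hosts = [int(h) for h in rng.choice(np.asarray(eligible), size=hosts_sampled, replace=False)]
    nodes = sim.sample_cells(hosts, symbionts_per_host)

    # map every mutation event on the sampled cells' ancestry to genome sites
    paths = [sim.mutations_on_path(n) for n in nodes]
    events: dict[int, int] = {}
    for path in paths:
        for node_id, mult in path:
            events.setdefault(node_id, mult)
    total_sites = sum(events.values())
    if total_sites > genome_length // 2:
        raise ValueError("genome_length too short for the mutation count; increase it")
    site_pool = rng.choice(genome_length, size=total_sites, replace=False) + 1
    positions_of: dict[int, np.ndarray] = {}
    cursor = 0
    for node_id, mult in events.items():
        positions_of[node_id] = site_pool[cursor : cursor + mult]
        cursor += mult

    background = rng.integers(4, size=genome_length)
    derived = {
        node_id: (background[pos - 1] + 1 + rng.integers(3, size=len(pos))) % 4
        for node_id, pos in positions_of.items()
    }
    seqs = []
    for path in paths:
        g = background.copy()
        for node_id, _ in path:
            pos = positions_of[node_id]
            g[pos - 1] = derived[node_id]
        seqs.append("".join(_ALPHABET[b] for b in g))
    sample_ids = [
        f"host{h}_sym{j}" for h in hosts for j in range(symbionts_per_host)
    ]
    host_ids = [f"host{h}" for h in hosts for _ in range(symbionts_per_host)]
    return HaplotypeAlignment(sample_ids=sample_ids, sequences=seqs, host_ids=host_ids)


# ---------------------------------------------------------------------------
# reads: pileups and read-pair phasing observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimSpec:
    """Paired-read simulation from a weighted within-host haplotype mixture."""

    haplotypes: tuple[str, ...]
    weights: tuple[float, ...]
    depth: float
    error_rate: float
    read_length: int
    insert_mean: float
    insert_sd: float
    seed: int

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if len(self.weights) != len(self.haplotypes):
            raise ValueError("one weight per haplotype")
        if len({len(h) for h in self.haplotypes}) != 1:
            raise ValueError("haplotypes must be equal length")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.read_length > len(self.haplotypes[0]):
            raise ValueError("read_length exceeds haplotype length")


@dataclass
class PhaseObservation:
    """One co-observation of two variant sites on a single read pair."""

    read_id: str
    pos_a: int
    base_a: str
    pos_b: int
    base_b: str


@dataclass
class ReadSet:
    """Simulated paired reads plus derived pileup and phasing observations."""

    spec: ReadSimSpec
    reads: list[tuple[str, int, str]]  # (read_id, 1-based start, bases)
    pileup: list[PileupColumn]
    phase_observations: list[PhaseObservation]
    variant_positions: list[int]
    reference: str


def _quality_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * np.log10(error_rate))))
    return chr(33 + q)


def make_reads(spec: ReadSimSpec, chrom: str = "ref") -> ReadSet:
    """Draw paired reads from the mixture and build a consistent pileup.

    The pileup is assembled from the emitted reads themselves, so column
    depths equal the number of reads covering each position by construction.
    The reference for pileup encoding is the highest-weight haplotype.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(spec.haplotypes[0])
    R = spec.read_length
    ref = spec.haplotypes[int(np.argmax(spec.weights))]
    haps = [np.frombuffer(h.encode(), dtype=np.uint8) for h in spec.haplotypes]
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)

    variant_positions = [
        i + 1
        for i in range(L)
        if len({h[i] for h in spec.haplotypes}) > 1
    ]
    var_arr = np.asarray(variant_positions)

    n_pairs = int(round(spec.depth * L / (2 * R)))
    reads: list[tuple[str, int, str]] = []
    phase: list[PhaseObservation] = []
    hap_idx = rng.choice(len(haps), size=n_pairs, p=spec.weights)
    for k in range(n_pairs):
        h = haps[hap_idx[k]]
        insert = int(max(2 * R, round(rng.normal(spec.insert_mean, spec.insert_sd))))
        insert = min(insert, L)
        start = int(rng.integers(0, L - insert + 1))  # 0-based
        rid = f"rp{k}"
        segs = [(start, start + R), (start + insert - R, start + insert)]
        covered: dict[int, str] = {}
        for s, e in segs:
            bases = h[s:e].copy()
            if spec.error_rate > 0:
                err = rng.random(e - s) < spec.error_rate
                n_err = int(err.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err)
                    cur = np.searchsorted(base_codes, bases[err])
                    bases[err] = base_codes[(cur + shift) % 4]
            seq = bases.tobytes().decode()
            reads.append((rid, s + 1, seq))
            lo = np.searchsorted(var_arr, s + 1)
            hi = np.searchsorted(var_arr, e, side="right")
            for pos in var_arr[lo:hi]:
                covered[int(pos)] = seq[int(pos) - 1 - s]
        sites = sorted(covered)
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                phase.append(
                    PhaseObservation(rid, sites[i], covered[sites[i]], sites[j], covered[sites[j]])
                )

    pileup = _pileup_from_reads(reads, ref, chrom, _quality_char(spec.error_rate))
    return ReadSet(
        spec=spec,
        reads=reads,
        pileup=pileup,
        phase_observations=phase,
        variant_positions=variant_positions,
        reference=ref,
    )


def _pileup_from_reads(
    reads: list[tuple[str, int, str]], ref: str, chrom: str, qual_char: str
) -> list[PileupColumn]:
    calls: dict[int, list[str]] = {}
    for _, start, seq in reads:
        for off, base in enumerate(seq):
            pos = start + off
            calls.setdefault(pos, []).append("." if base == ref[pos - 1] else base)
    columns = []
    for pos in sorted(calls):
        cs = "".join(calls[pos])
        columns.append(
            PileupColumn(
                chrom=chrom,
                position=pos,
                ref_base=ref[pos - 1],
                depth=len(cs),
                base_calls=cs,
                base_qualities=qual_char * len(cs),
            )
        )
    return columns


def write_phase_tsv(observations: list[PhaseObservation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tpos_a\tbase_a\tpos_b\tbase_b\n")
        for o in observations:
            fh.write(f"{o.read_id}\t{o.pos_a}\t{o.base_a}\t{o.pos_b}\t{o.base_b}\n")


def read_phase_tsv(path: str | Path) -> list[PhaseObservation]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            rid, pa, ba, pb, bb = line.rstrip("\n").split("\t")
            out.append(PhaseObservation(rid, int(pa), ba, int(pb), bb))
    return out


def write_manifest(path: str | Path, **params) -> None:
    """Drop a JSON manifest (parameters + seed) beside a generated artifact."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# VCF filter fixtures
# ---------------------------------------------------------------------------

_PASSING = dict(quality_by_depth=10.0, fisher_strand=5.0, genotype_quality=90.0, mq0_reads=0)
_FAIL_VARIANTS = (
    dict(quality_by_depth=1.5),   # QD below 2
    dict(fisher_strand=75.0),     # FS above 60
    dict(genotype_quality=12.0),  # GQ below 20
    dict(mq0_reads=6),            # MQ0 above 5
)


def make_vcf_fixture(
    n_pass: int, n_fail: int, seed: int
) -> tuple[list[SiteRecord], list[bool]]:
    """SiteRecords with known genotyping-filter truth.

    Each failing record violates exactly one named threshold (cycling through
    QD, FS, GQ and MQ0); the boolean truth table is returned alongside, in
    record order.
    """
    if n_pass + n_fail < 1:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(seed)
    flags = [True] * n_pass + [False] * n_fail
    rng.shuffle(flags)
    records, truth = [], []
    n_emitted_fail = 0
    for i, ok in enumerate(flags):
        fields = dict(_PASSING)
        if not ok:
            fields.update(_FAIL_VARIANTS[n_emitted_fail % len(_FAIL_VARIANTS)])
            n_emitted_fail += 1
        ref, alt = (str(b) for b in rng.choice(list("ACGT"), size=2, replace=False))
        records.append(
            SiteRecord(
                position=10 * (i + 1),
                ref_allele=ref,
                alt_alleles=(alt,),
                allele_number=2,
                **fields,
            )
        )
        truth.append(ok)
    return records, truth


# ---------------------------------------------------------------------------
# the shared worked fixture
# ---------------------------------------------------------------------------

def fixture_F1() -> HaplotypeAlignment:
    """Four 100 bp haplotypes with three biallelic sites.

    Site 10 has minor-allele count 1, sites 50 and 90 count 2; the six
    pairwise difference counts are {2, 2, 3, 2, 1, 1}, totalling 11. Hand
    evaluation gives pi = 11/6/100, Watterson's theta = 3/(11/6)/100 and
    Tajima's D ~= 1.09.
    """
    base = list("A" * 100)
    seqs = []
    for carrier10, carrier50, carrier90 in (
        (True, True, True),
        (False, True, False),
        (False, False, True),
        (False, False, False),
    ):
        s = base.copy()
        if carrier10:
            s[9] = "T"
        if carrier50:
            s[49] = "T"
        if carrier90:
            s[89] = "T"
        seqs.append("".join(s))
    return HaplotypeAlignment(
        sample_ids=[f"F1_{i}" for i in range(4)],
        sequences=seqs,
        host_ids=[f"host{i}" for i in range(4)],
    )
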