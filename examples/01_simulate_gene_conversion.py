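"""Simulate a bacterial sample under the gene-conversion coalescent and
summarize its diversity and recombination signal.

Run: python examples/01_simulate_gene_conversion.py
"""

from symbiocoal import SimParams, simulate_coalescent_gc, summarize_alignment
from symbiocoal.coalescent_gc import expected_segregating_sites

params = SimParams(
    theta=1e-3,       # per-site 2*Ne*mu
    rho=1e-3,         # per-site 2*Ne*r, gene-conversion initiations
    tract_length=1_000,
    genome_length=20_000,
    sample_size=10,
    seed=7,
)
rep = simulate_coalescent_gc(params)
sv = summarize_alignment(rep.alignment)

print(f"segregating sites: {len(rep.alignment.variant_positions)} "
      f"(neutral expectation {expected_segregating_sites(params):.1f})")
print(f"gene-conversion events on the genealogy: {rep.n_recomb_events}")
print(f"pi = {sv.pi:.5f} per site, Watterson's theta = {sv.watterson:.5f} per site")
print("four-gamete failure proportion by distance bin (<=10, <=100, <=1e3, <=1e4 bp):")
print("  ", [f"{p:.3f}" if p == p else "empty" for p in sv.f4_bins[:4]])
print("Pairs of sites showing all four allele combinations require recombination")
print("between them; the proportion rises with distance as linkage decays.")
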