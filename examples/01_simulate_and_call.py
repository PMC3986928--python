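"""Simulate a pooled-diploid 454 assembly and call candidate variants.

Generates a small synthetic assembly with planted pool variants (two
genotypes, so true variants sit at frequencies k/4), sequencing errors
and homopolymer artifacts; masks and cleans it; then calls and filters
mismatches and prints the before/after density summary.
"""

from contigvar import (
    SimConfig,
    call_mismatches,
    mask_and_clean,
    post_filter,
    simulate_assembly,
    summarize,
)

cfg = SimConfig(seed=42, n_contigs=30, variant_rate=0.008, reads_per_contig_mean=10)
sim = simulate_assembly(cfg)
print(f"simulated {len(sim.contigs)} contigs, {len(sim.truth.variants)} planted variants")

cleaned = [mask_and_clean(c) for c in sim.contigs]
records = post_filter([r for m in cleaned for r in call_mismatches(m)])

before = summarize(records, cleaned, passed_only=False)
after = summarize(records, cleaned, passed_only=True)
print(f"candidate mismatches before binomial filter: {before.n_mismatch} "
      f"({before.density_per_100bp:.2f} /100 bp over {before.denom_bases} deep bases)")
print(f"candidate mismatches after  binomial filter: {after.n_mismatch} "
      f"({after.density_per_100bp:.2f} /100 bp)")
print(f"classes after filtering: {after.n_transition} transitions, "
      f"{after.n_transversion} transversions, {after.n_indel} indels, "
      f"{after.n_multiallelic} multiallelic")

# The density can only drop through the binomial filter: it discards
# minor-variant configurations that are improbably rare for a real
# variant at pool frequency >= 1/4.
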