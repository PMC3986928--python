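# contigvar

Quality-aware mismatch discovery and expression screening for 454
(pyrosequencing) transcriptome assemblies of pooled diploid samples.

## The problem

De novo transcriptome projects in non-model organisms often sequence
cDNA from a small pool of individuals — e.g. two diploid genotypes, so
four gametes — across several organ libraries, and assemble the reads
into contigs. Candidate SNPs/indels must then be mined from the padded
read alignments, where three artifact sources dominate: low-quality
base calls, homopolymer over/under-calls (the characteristic 454
error), and assembly artefacts. `contigvar` post-processes such
assemblies (ACE + QUAL files, as emitted by assemblers like MIRA):

- **mask** unreliable bases per alignment column: singleton variants,
  variants below frequency 0.1, and bases under quality 20 at
  polymorphic sites;
- **clean** away columns whose unmasked content is pads only — the
  footprint of homopolymer artifacts — and edit an IUPAC-coded
  consensus;
- **call mismatches** (columns with ≥ 2 unmasked states) with depth,
  minor-allele frequency, class (transition / transversion / indel /
  multiallelic) and a binomial false-positive probability;
- **filter**: with 2N pooled gametes a true variant has expected pool
  frequency p ≥ 1/2N, so a minor state seen t times in depth x with
  cumulative binomial probability
  P(X ≤ t) = Σ_{k≤t} C(x,k) p^k (1−p)^(x−k) < 0.05
  is flagged as a likely false positive; adjacent mismatches and sites
  under 8× depth are flagged too;
- **summarize** mismatch density per 100 bp over bases with depth ≥ 8,
  before and after the binomial filter.

Two companion analyses cover the expression side of such projects: a
**permutation test** flagging GO biological processes whose contigs
attract more reads than expected in an organ (observed zero-excluded
mean vs. 1000 permutations of the organ's counts over all contigs), and
**RaBoT**, a rarefaction bootstrap comparing the contig count of a
smaller read library against equal-size subsamples of a larger one.
A BLAST-hit screen separating green-plant contigs from contaminants is
included, plus a simulator that generates ground-truth assemblies
(planted pool variants at frequencies k/2N, substitution errors,
homopolymer indel artifacts) for end-to-end validation.

## Worked example

```sh
python examples/02_binomial_filter.py
```

```
P(X <= 3 | n=29, p=0.25) = 0.0455  -> discard
P(X  = 2 | n=8,  p=0.25) = 0.3115 (cumulative 0.6785) -> keep
```

Three minor-variant reads among 29 are too few for a real variant at
pool frequency 1/4 (P < 0.05): the site is discarded as a false
positive. Two of eight — the minimal configuration at the 8× depth
cutoff, since singletons were masked earlier — is entirely plausible
(point probability 0.31) and passes.

End to end (`python examples/01_simulate_and_call.py`):

```
simulated 30 contigs, 123 planted variants
candidate mismatches before binomial filter: 81 (2.23 /100 bp over 3637 deep bases)
candidate mismatches after  binomial filter: 80 (2.20 /100 bp)
classes after filtering: 13 transitions, 19 transversions, 48 indels, 0 multiallelic
```

The density (mismatches per 100 bp of depth ≥ 8 sequence) can only
drop through the binomial filter. The `examples/` directory holds one
short script per capability (simulation + calling, the binomial
rationale, GO permutation, RaBoT, the contaminant screen).

The same pipeline is scriptable from the shell:

```sh
contigvar simulate --seed 1 --n-contigs 20 --outdir fixtures/
contigvar call --ace fixtures/assembly.ace --qual fixtures/reads.qual \
    --mids fixtures/mids.tsv --out mismatches.tsv --summary summary.tsv
contigvar run --config run.yaml     # full configurable pipeline
```

## Layout

- `src/contigvar/assembly_io.py` — ACE/QUAL/MID parsing, padded-alignment model
- `src/contigvar/mask_clean.py` — masking rules, cleaning, IUPAC consensus
- `src/contigvar/mismatch.py` — mismatch records, binomial filter, density summary
- `src/contigvar/annotation.py` — green-plant contaminant screen, best-hit annotation
- `src/contigvar/go_expression.py` — GO-term over-expression permutation test
- `src/contigvar/rabot.py` — rarefaction bootstrap
- `src/contigvar/simulate.py` — ground-truth assembly and count-table simulators
- `src/contigvar/pipeline.py`, `cli.py` — orchestration and the thin `contigvar` CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
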