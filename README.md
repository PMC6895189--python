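# seqbug

Pileup-driven single-nucleotide error correction for genome assemblies, with
codon-level projection of corrections through gene annotations, validation
against independent resequencing, and a set of evolutionary site utilities.

Given per-base read-alignment metrics (bam-readcount-style TSV), `seqbug`
flags an assembly base as erroneous when the position is eligible (coverage
10–200×, indel fraction ≤ 10%) and the assembly base's read count is at most
one-fifth of the most frequent base's count; the assembly base is then
replaced by the most frequent base. Corrections are recorded in a VCF/TSV
ledger, projected through Ensembl-dialect GTF gene models into codons
(synonymous / non-synonymous / stop-gain / stop-loss / start-loss), and can
be cross-validated against a second individual's pileup (a site is validated
when the independent most-frequent base equals the corrected base).

Additional utilities: unique-substitution scanning over multi-species
protein alignments (gap-flank exclusion), root-to-tip branch-length
distances from rooted Newick trees, aggregation of five per-gene adaptation
signals into a ≥3-of-5 "multiple signs of adaptation" call, and an estimate
of the divergence-time bias attributable to assembly errors.

A fully deterministic simulator (`seqbug.simulate`) generates synthetic
genomes, gene models, injected assembly errors, two-individual pileups,
protein alignments, trees, and signal tables with known ground truth, so the
whole pipeline is testable without any downloads.

## CLI

One entry point with subcommands; every run writes a JSON manifest with
resolved parameters and input checksums.

```sh
# simulate a fixture set (genome, GTF, pileups, truth tables)
seqbug simulate --seed 1 --out-dir fixtures/

# correct an assembly from a readcount pileup
seqbug correct --assembly fixtures/assembly.fa \
    --pileup fixtures/same_individual.readcount.tsv \
    --min-cov 10 --max-cov 200 --max-indel 0.10 --ratio 5 \
    --out-prefix run

# project corrections into codon space through a GTF
seqbug project --gtf fixtures/genes.gtf --assembly fixtures/assembly.fa \
    --ledger run.corrections.vcf --out-prefix proj

# validate corrected sites against an independent individual's pileup
seqbug validate --ledger run.corrections.vcf \
    --pileup fixtures/independent.readcount.tsv --out-prefix val

# evolutionary site utilities
seqbug unique-subs --aln gene.faa --focal tiger
seqbug rtt --tree gene.nwk --focal tiger
seqbug msa --signals signals.tsv --threshold 3
seqbug divergence-bias --n-errors 982606 --genome-size 2.44e9 --mutation-rate 1.1e-9
```

## Layout

- `src/seqbug/pileup_io.py` — readcount TSV reader/writer, coverage histogram
- `src/seqbug/correction.py` — eligibility filters, one-fifth rule, ledger
- `src/seqbug/geneset.py` — GTF models, codon projection, effect classes
- `src/seqbug/validation.py` — independent-pileup validation, divergence bias
- `src/seqbug/signals.py` — unique substitutions, root-to-tip, MSA aggregation
- `src/seqbug/simulate.py` — synthetic fixtures with ground truth
- `src/seqbug/cli.py` — the `seqbug` command
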