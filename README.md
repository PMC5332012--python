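# bartrap

Deconvolution of pooled **bar**coded-**tra**nsposon drug-sensitivity screens.

## The problem

Forward genetic screens in haploid mouse embryonic stem cells use piggyBac
gene-trap transposons to disrupt one gene per cell, pooling ~10,000 mutants
and exposing the pool to a drug at a dose that kills half of wild-type-like
cells over the screening window. Each transposon carries a random 25-bp
barcode at each end (PB5/"Sims" and PB3/"West"), so the abundance of every
mutant can be read out by amplifying and sequencing the barcodes, and each
barcode is tied to its genomic integration site by paired-end sequencing of
inverse-PCR products (barcode at one end, transposon–genome junction at the
other). `bartrap` turns the raw FASTQ files of such a screen into ranked
gene hits:

1. **barcode counting** — extract the 25-mer after a fixed flank, then
   cluster near-identical barcodes (single-linkage, Levenshtein ≤ 2) so
   PCR/sequencing error clouds are counted together under a canonical
   representative;
2. **site linking** — parse inverse-PCR read pairs, map the junction with a
   built-in exact-seed aligner (or import SAM alignments), discard sites
   below 10 reads/million within their mapping run, combine same-library
   sites within 5 bp, and annotate sites with overlapping gene bodies from
   a GTF;
3. **differential abundance** — TMM normalization, common NB dispersion by
   quantile-adjusted conditional maximum likelihood, and a per-barcode
   exact test: conditional on the total count *t*, the P-value is
   `P = Σ {Pr(a', t−a') : Pr(a', t−a') ≤ Pr(a_obs, t−a_obs)} / Σ Pr`,
   with counts modelled NB(μ, φ), Var = μ + φμ²;
4. **gene aggregation** — genes supported by ≥ 2 significant,
   direction-consistent insertions, ranked by insertion count and Fisher's
   combined P (−2 Σ ln Pᵢ ~ χ²₂ₖ).

A simulator generates complete synthetic screens (genome, gene models,
mutant libraries at TTAA sites, drug/vehicle selection, barcode and
inverse-PCR FASTQs) with a machine-readable truth table, so every pipeline
claim is testable against known ground truth.

## Worked example

```sh
# simulate a small screen (1 pool, 200 mutants, error-free reads)
cat > sim.yaml <<EOF
n_chroms: 2
chrom_length: 100000
n_genes: 20
gene_length: 4000
n_pools: 1
n_mutants_per_pool: 200
barcode_pool_size: null
reads_per_sample: 60000
invpcr_reads_per_site: 60
error_rate: 0.0
EOF
bartrap simulate --config sim.yaml --seed 3 --out screen/

# run the full pipeline
cat > pipe.yaml <<EOF
sample_sheet: screen/samples.tsv
reference: screen/genome.fa
gtf: screen/genes.gtf
invpcr:
  L1: [screen/invpcr_L1_R1.fastq, screen/invpcr_L1_R2.fastq]
out_dir: screen/out
EOF
bartrap run --config pipe.yaml
```

`screen/out/mapping.tsv` then links every barcode to its integration site
and gene; the first lines of one such run look like

```
barcode                    chrom  pos    strand  end_label  library  reads  rpm          gene_id   gene_name  ambiguous
AAAATTGGACCGAGTAGACGGCGCA  chr1   59089  -       PB3        L1       63     5126.953125       none      none       False
AAACGGACGAGAGGTCTGTCTATGT  chr1   23165  -       PB3        L1       50     4069.010416666667 gene0003  Gene0003   False
```

i.e. the first barcode tags an intergenic insertion on chr1 (minus strand,
63 supporting inverse-PCR reads), the second disrupts `gene0003`. On this
error-free simulation every one of the 204 true integrations is recovered
at its exact TTAA position, and `screen/out/results.tsv` /
`screen/out/genes.tsv` hold the per-barcode exact-test results and the
gene-level ranking.

## Layout

| module | role |
| --- | --- |
| `bartrap.barcodes` | barcode extraction, error grouping, count matrix |
| `bartrap.sites` | inverse-PCR parsing, junction mapping, site filter/merge, gene annotation |
| `bartrap.differential` | TMM, qCML dispersion, exact NB test, fold changes |
| `bartrap.genes` | per-insertion join, gene-hit calling |
| `bartrap.simulate` | synthetic screens with ground truth |
| `bartrap.pipeline` / `bartrap.cli` | end-to-end driver and `bartrap` CLI |

See `docs/methods.md` for the model, parameter defaults and design notes.
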