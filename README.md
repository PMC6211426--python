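# polydose

Quantitative allele-dosage genotype calling for autopolyploids from VCF read
depths.

Standard genotype callers emit diploid-style calls, which discards most of
the information a sequencing experiment carries about an autopolyploid
locus. At a biallelic locus of ploidy *m*, an individual may carry any
dosage *d* = 0..*m* of the alternative allele — at *m* = 4 that is nulliplex
(AAAA) through tetraplex (CCCC) with three distinct heterozygote classes in
between — and the allele ratio alt/(ref+alt) of its reads is centred on
*d/m*. `polydose` reads per-sample allele depths from VCF files
(genotyping-by-sequencing or any other depth-preserving protocol),
classifies every individual into a dosage class, and writes polyploid
genotypes back to VCF. It is aimed at plant geneticists and breeders
working with autotetraploid and higher-ploidy species (potato, alfalfa,
switchgrass, sugarcane, ...) who need dosage-aware genotypes for linkage
mapping, GWAS or genomic prediction.

## The model

Per locus and ploidy *m*, individual *i*'s allele ratio *r_i* is modelled as
*N(d/m, σ²)* given dosage *d*, with σ scanned over a grid and chosen by
maximum evidence. Dosage-class weights come from one of three genetic
priors:

* **F1 full-sib** (`-I f1`) — offspring prior π(d | g1, g2) obtained by
  convolving the two parents' hypergeometric gamete distributions (random
  bivalent pairing), reproducing the polysomic segregation ratios 1:1, 3:1,
  1:2:1, 1:1:1:1; parent replicate samples constrain the parental pair
  (g1, g2).
* **Hardy–Weinberg** (`-I hw`) — Binomial(*m*, *p*) class frequencies for a
  panmictic panel, *p* estimated on a 0.01 grid.
* **Assumption-free** (`-I ploidy`) — uniform class weights.

Inference is greedy maximum likelihood by default or exact MAP with `-e`;
the evidence of each tested ploidy (`-M 2:16` searches all even levels)
gives a MAP ploidy posterior used both to pick the level and as a quality
filter. Each call also carries a *naive* posterior — classification
confidence under a uniform prior, with no genetic model — used to mask
unreliable individual calls (`-n`). See `docs/methods.md` for the full
model, numerical choices and limitations.

## Worked example

Simulate a tetraploid F1 family (simplex × simplex cross, 80 offspring, 12
replicates per parent, mean depth 60×) and call dosages under the F1 model
with exact inference, masking calls below naive probability 0.90 and
requiring a 75% call rate:

```sh
$ polydose simulate --model f1 --parent-dosages 1,1 --n-individuals 80 \
    --n-loci 50 --seed 42 -o f1_sim.vcf
wrote f1_sim.vcf and f1_sim.vcf.truth.tsv

$ polydose call -i f1_sim.vcf -o f1_calls.vcf -I f1 -e -M 4 -a AD \
    -g Ind -1 P1_ -2 P2_ -n 0.90 -c 0.75 -t 2
wrote 50 of 50 loci (pass=50)
```

All 50 loci pass the filters. The output VCF holds one genotype column per
selected sample; dosage *d* at ploidy 4 is written as 4−*d* reference plus
*d* alternative alleles, and INFO records the selected ploidy (`PLD`), its
posterior (`PLDP`) and the best σ (`SIG`):

```text
#CHROM POS  ID       REF ALT QUAL FILTER INFO                        FORMAT Ind0001
1      1000 loc00001 A   C   .    .      PLD=4;PLDP=1.0000;SIG=0.06  GT:AD  0/0/1/1:36,28
1      2000 loc00002 A   C   .    .      PLD=4;PLDP=1.0000;SIG=0.06  GT:AD  0/0/0/0:49,0
```

`Ind0001` is duplex (dosage 2, ratio 28/64 ≈ 0.44) at the first locus and
nulliplex at the second. A filter log (`f1_calls.vcf.filters.tsv`) records
one outcome per input locus. Scoring the emitted genotypes against the
simulator's truth table: 4661/4687 calls match (99.4%).

Input depths can come from any of three VCF dialects via `-a`: `AD`
(TASSEL/GATK-style allelic depths), `RA`/`AA` (reference/alternative
depths) or `RO`/`AO` (FREEBAYES observation counts). A `+` in the input and
output paths is a file-number wildcard expanded over `--sF`..`--eF`, and
samples are selected by name substring (`-g`, `-1`, `-2`) or by 1-based
column range (`-r`, `-k`, `-l`).

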