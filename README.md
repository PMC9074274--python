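# mixcat

Mix-assembly gene catalogue construction and evaluation for shotgun
metagenomes.

## The problem

Biome-specific gene catalogues — nonredundant sets of genes called on
assembled metagenome contigs — are the reference backbones onto which
metagenome and metatranscriptome reads are mapped.  Two assembly strategies
are in common use, with opposite failure modes:

* **Individual assembly** (one assembly per sample) keeps strains separated
  and assembles abundant genomes well, but misses genes whose per-sample
  coverage is too low, and leaves massive cross-sample redundancy to clean
  up.
* **Co-assembly** (all samples pooled) rescues rare genes by pooling
  coverage, but mixes closely related strains; their fine-scale variation
  branches the de Bruijn graph and fragments genes.

The **mix assembly** combines both: cluster the individual-assembly
proteins to remove redundancy, then cluster those representatives together
with the co-assembly proteins.  Clusters are seeded on the *longest*
sequence, so whenever a fragment from one strategy meets a complete
homolog from the other, the complete gene represents the cluster — the
merged catalogue is both larger and more complete than either input.

`mixcat` implements this construction and its evaluation framework, and
ships a synthetic-community simulator so the whole pipeline is testable
end to end without any sequencing data.

## The method

**Clustering criterion.** Proteins are clustered greedily at ≥ 95%
amino-acid identity (the species grain: conspecific prokaryotic strains
generally exceed 95% average amino-acid identity).  Sequences are sorted by
length; the longest unassigned protein seeds a cluster and absorbs every
unassigned protein *m* with

    identity(rep, m) ≥ 0.95   and   |aligned span on m| / |m| ≥ 0.95,

computed from the optimal BLOSUM62 local alignment (affine gaps 11/1).
Coverage is measured on the member, so fragments join their full-length
homolog's cluster.  The cascade runs this twice: stage 1 over all
individual-assembly proteins, stage 2 over {stage-1 representatives ∪
co-assembly proteins}, recording each final representative's provenance.

**Completeness.** Genes carry Prodigal-style partial codes:
`00` complete (start and stop codon), `01`/`10` partial, `11` incomplete.

**Normalization.** Before co-assembly, pooled reads are digitally
normalized: per-read depth is the median count of its canonical k-mers
(k = 31) over the pooled exact count table; a read of depth *d* is kept
with probability min(1, 70/*d*) and discarded when *d* < 2.

**Evaluation.** Catalogues are compared by mapping a fixed random subset of
forward reads per sample (default 10,000, seed 100) to the catalogue's
nucleotide sequences; a read counts to its best-scoring gene when the local
alignment covers ≥ 80% of the read at ≥ 90% identity (best-score ties are
tallied as ambiguous and counted to no gene).  Per-gene read-depth coverage
in the total metagenome is estimated as

    coverage_g = c_g · (r̄ / L_g) · (N / n)

with c_g the sampled count, r̄ the mean read-pair length, L_g the gene
length, N the total read pairs in the dataset and n the sampled reads; genes
are binned as low (0–50×), median (50–500×), high (500–5,000×) and very
high (5,000–250,000×) coverage.

## Worked example

```
$ python examples/03_mix_assembly_catalogues.py
catalogue     genes  >=100bp  complete  partial incomplete  total bp
individual      266      262        37      214         15     64857
coassembly      180      176        92       88          0     49494
mix             270      265        98      159         13     73065

mix provenance: 163 representatives from individual assemblies, 107 from the co-assembly
```

A simulated community (25 species × 8 genes, 14 samples, strain variation
in the abundant species) evaluated under all three strategies.  The mix
catalogue holds the most nonredundant genes *and* the most complete genes:
it keeps the co-assembly's rescued low-abundance genes while replacing
fragmented co-assembly genes with the longer versions recovered from
individual samples.  The individual assembly shows the strain-variation
signature — many partial genes — while the co-assembly, pooling everything,
has fewer genes overall.  `examples/04_read_mapping_evaluation.py` then maps
read subsets back: the mix catalogue reaches the highest per-sample mapping
rate (92.9% mean vs 86.0% individual and 63.8% co-assembly on this
scenario), and the co-assembly share of mapped reads falls from the
low-coverage bin to the higher bins.

Other examples: `01_simulate_community.py` (the generator),
`02_cluster_proteins.py` (the clustering criterion on a toy set),
`05_normalize_reads.py` (digital normalization).  A thin CLI exposes each
stage (`mixcat simulate|normalize|cluster|cascade|summarize|map-eval|
compare|remove-rrna|run`).

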