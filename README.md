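# kataegis

Detection and characterization of **kataegis** — localized hypermutation —
in per-clone somatic substitution catalogs.

Kataegis is a shower of clustered, strand-coordinated substitutions at C:G
pairs, produced when an AID/APOBEC cytidine deaminase attacks a stretch of
transiently exposed single-stranded DNA (for example during the resection
phase of double-strand-break repair). It was first characterized in breast
cancer genomes and can be recapitulated in yeast expressing hyperactive
deaminases. This package implements the complete analysis used to detect
and describe such events, for anyone with a table of per-clone (or
per-tumour) single-base substitutions:

* **intermutational distances (IMDs)** — for each mutation, the distance to
  the next downstream mutation on the same chromosome of the same clone —
  and the rainfall-plot table they underlie;
* a **two-group k-means split** of log₁₀(IMD) into *proximal* and *distal*
  groups, and a **calling threshold** set at the IMD that excludes 99% of
  the distal (scattered, singlet-like) group;
* **cluster calling**: a kataegic cluster is a maximal run of ≥ 5 adjacent
  mutations, each separated from the next by less than the threshold;
* a **Monte Carlo null model** that scatters the same mutation loads
  uniformly over the genome and measures how often the caller fires by
  chance;
* **signature analysis**: pyrimidine-oriented substitution spectra
  (C→T transitions vs C→G/C→A transversions), per-cluster strand polarity,
  −2/−1 flanking-context position frequency matrices (PFMs) with optional
  genomic-background normalization, and Sandelin–Wasserman motif
  similarity, score = Σ_columns [2 − Σ_b (p₁(b) − p₂(b))²], with a seeded
  permutation p-value;
* a **synthetic-data generator** that produces yeast-like genomes and
  catalogs with planted clusters and full ground truth, so the whole
  pipeline is testable end to end without any downloads.

The detection core is exposed as scikit-learn-style estimators
(`IMDPartitioner`, `KataegisDetector`) that support `get_params` /
`set_params` / `clone`; module-level functions (`compute_imds`,
`partition_imds`, `derive_threshold`, `call_clusters`, …) are thin wrappers
over them.

## Worked example

```python
import kataegis as kg

genome = kg.generate_genome(seed=0)            # 16 chromosomes, ~12.07 Mb
params = kg.preset("AID_star")                 # 40 clones, median load ~25
catalog, truth = kg.generate_catalog(genome, params, seed=1)

det = kg.KataegisDetector(exclusion=0.99, min_mutations=5).fit(catalog)
null = kg.estimate_cluster_probability(
    genome, 25, det.threshold_, 5, n_reps=100_000, seed=2
)
```

Printing the fitted attributes (`det.imds_`, `det.partition_.summary()`,
`det.clusters_`, `kg.spectrum`, `kg.aggregate_strand_coordination`) gives:

```
mutations: 1387 in 40 clones
IMD entries: 903 (terminal excluded: 308, chromosome singletons: 176)
proximal median: 870 bp, distal median: 177 kb
calling threshold (99% distal exclusion): 15.4 kb
clusters called: 32 (347 clustered mutations)
strand coordination: 0.91
kataegic spectrum: C>T 43%  C>G 50%  C>A 7%
null P(>=1 cluster/clone): 1.0e-05 (95% CI upper 5.6e-05)
```

Reading the numbers: the pooled IMDs are strongly bimodal — mutations
within kataegic stretches sit hundreds of bp apart (proximal median
870 bp), scattered singlets ~177 kb apart — so the k-means split is clean
and the derived threshold (15.4 kb here) separates the regimes. The 32
called clusters hold exactly 347 mutations, 91% of which occur on each
cluster's majority strand (all-C or all-G on the reference strand — the
hallmark of single-strand-specific deamination), and the clustered
spectrum is transversion-rich (C→G + C→A ≈ 57%), reflecting mutagenic
bypass of abasic sites within kataegic stretches. Randomly scattered
mutations at the same load trigger the caller in ~1 in 10⁵ clones, so
essentially every call on this catalog reflects planted structure.

The same pipeline runs from the shell:

```bash
kataegis simulate --preset AID_star --seed 5 --outdir run/data
kataegis detect    --catalog run/data/mutations.tsv --genome run/data/genome.fa --outdir run/detect
kataegis null      --genome run/data/genome.fa --threshold 8500 --n-reps 100000 --out run/null.json
kataegis signature --catalog run/data/mutations.tsv --genome run/data/genome.fa \
                   --clusters run/detect/clusters.bed --outdir run/signature
```

Input catalogs are plain TSV (`clone  chrom  pos  ref  alt`, 1-based
positions); single-sample or multi-sample VCF is also accepted
(`read_mutation_table(path, dialect="vcf")`). Genomes are FASTA, or a
`name<TAB>length` table when sequence is not needed.

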