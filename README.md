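# phagecomp

Comparative phage genomics toolkit: gene-sharing Jaccard clustering of phage
genomes, ortholog-group conservation/core/exclusivity queries, synonymous
codon-usage bias with tRNA-complement interpretation, GC window scanning and
intergenic-region composition, and genome-size-normalized phage–host abundance
time series with local similarity analysis (LSA). Seeded synthetic-data
generators make the whole pipeline testable without any downloads.

## Package layout

| Module | Contents |
| --- | --- |
| `phagecomp.genome_model` | FASTA/GFF3/GenBank/ortholog-TSV I/O; `GenomeRecord`, `GeneFeature`, `OrthologTable`; CDS extraction. Internal coordinates are 0-based half-open. |
| `phagecomp.ortho_cluster` | Per-genome ortholog-group sets, Jaccard index, reference-anchored clustering (`J(ref, X) >= cutoff`, default 0.1), conservation table, core and subset-exclusive OGs, pairwise J matrix. |
| `phagecomp.codon_trna` | Codon counting (table 11), synonymous usage per amino-acid family, the 1/k no-bias baseline, tRNA anticodon complements (strict Watson–Crick decoding, no wobble), rare-codon reports, target-codon gene ranking. |
| `phagecomp.gc_scan` | GC in fixed windows (default 100 bp, non-overlapping), base composition, intergenic (gene-free) regions with composition deviation, genome summaries. |
| `phagecomp.abundance_lsa` | Relative abundance `RA% = 100 * (m/T) / (L/1000)`, rank-normalized delay-bounded LSA with permutation p-values, phage–host reports, functional-category transcript profiles. |
| `phagecomp.synthetic_data` | Seeded generators: genome sets with planted cluster/core/exclusive OG structure, CDS sets with a specified codon-usage profile, lagged host/phage count series. Each writes a truth JSON. |
| `phagecomp.cli` | `phagecomp` executable with subcommands. |

## CLI

```sh
# generate a synthetic dataset, then run each stage on it
phagecomp simulate --scenario genomes --seed 1 --out sim/
phagecomp cluster --orthologs sim/orthologs.tsv --annotations sim/genomes.gff3 \
    --reference cluster0_g0 --cutoff 0.1 --out cluster_out/

phagecomp simulate --scenario timeseries --seed 1 --out ts/
phagecomp abundance --counts ts/counts.tsv --lengths ts/genome_lengths.tsv \
    --host host --seed 7 --out abundance_out/

phagecomp gcscan --fasta sim/genomes.fasta --gff sim/genomes.gff3 --out gc_out/
phagecomp codon --phage-fasta phage.fasta --phage-gff phage.gff3 \
    --host-fasta host.fasta --host-gff host.gff3 --out codon_out/
```

All subcommands accept `--config config.yaml` (flags override file values),
write plain TSV/JSON outputs plus a `manifest.json` (version, parameter hash,
seed), and exit with code 2 on validation errors. Runs are deterministic
given a seed.

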