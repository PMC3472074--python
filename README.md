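# apmsflow

A reusable pipeline for comparative affinity-purification mass-spectrometry
(AP-MS) analysis of receptor-associated complexes, built around spectral
counting across three receptor variants (`A4`, `X4C0`, `A4P_A5L`) assayed
with bait (`BAIT`, ligand-coated beads) and control (`CONTROL`, non-binding
mutant ligand) isolations:

* **Quantification** — replicate-averaged spectral counts, bait/control
  enrichment ratios with a symmetric pseudocount, and a specificity
  cut-off of mean + 1 sample SD over the pooled ratio distribution
  (applied inclusively).
* **Clustering** — agglomerative clustering of per-cell-line log2
  bait/control profiles under correlation distance (d = 1 − r, average
  linkage), with rule-based selection of clusters of interest
  (node correlation ≥ 0.6, low control detection) and flagging of
  control-dominated "background" clusters.
* **Network analysis** — interactome assembly from multiple edge-list
  sources with provenance, mapping coverage, induced subnetworks, Venn
  partitioning of proteins by the cell-line subset in which they were
  called specific, curated gene-set filtering, and subcellular-localization
  annotation by ontology rollup from six standard root terms.
* **Term enrichment** — one-sided hypergeometric overrepresentation with
  fold enrichment and Bonferroni correction (defaults: fold > 5,
  corrected p < 0.1).
* **Peptide coverage** — exact peptide-to-sequence mapping and
  construct-specific region validation (e.g. the tail-truncated variant
  must yield no peptides from the deleted cytoplasmic region).
* **Synthetic data** — a first-class generator that emits a complete,
  seeded input bundle (counts, design, interactome, annotations, gene
  sets, sequences, peptides, expectations) with planted ground truth for
  every stage.

## CLI

```sh
# write a synthetic input bundle with ground truth
apmsflow simulate --seed 1 --out bundle/

# full pipeline: quantify -> cluster -> network -> enrich -> validate-peptides
apmsflow run-all --bundle bundle/ --out results/

# individual stages (all thresholds exposed as flags)
apmsflow quantify --counts bundle/counts.tsv --design bundle/design.tsv --out results/
apmsflow cluster --enrichment results/enrichment.tsv --min-corr 0.6 --out results/
apmsflow network --enrichment results/enrichment.tsv --edges bundle/edges_db1.tsv \
    --edges bundle/edges_db2.sif --gene-set bundle/adhesome_like.txt \
    --annotations bundle/annotations.tsv --relations bundle/relations.tsv --out results/
apmsflow enrich --enrichment results/enrichment.tsv \
    --annotations bundle/annotations.tsv --relations bundle/relations.tsv --out results/
apmsflow validate-peptides --fasta bundle/constructs.fasta --regions bundle/regions.tsv \
    --peptides A4 bundle/peptides_A4.tsv --peptides X4C0 bundle/peptides_X4C0.tsv \
    --peptides A4P_A5L bundle/peptides_A4P_A5L.tsv \
    --expectations bundle/expectations.tsv --out results/
```

`run-all` writes nine artifacts (enrichment and threshold tables, Newick
dendrogram, cluster table, GraphML/SIF networks, Venn partition, term
enrichment, peptide coverage report) plus `manifest.json` with per-file
SHA-256 checksums and a `run.log` of all resolved parameters; reruns on
identical inputs are byte-identical.

## File formats

Tab-separated UTF-8 with header rows and `#` comments for tables
(counts, design, regions, annotations, relations, mapping, peptides,
expectations); FASTA for sequences; SIF (`A pp B`) or 2–3-column TSV for
interaction edges; one-symbol-per-line text for gene sets. Residue
coordinates are 1-based inclusive; gene symbols are upper-cased on load.
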