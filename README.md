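# sicnv

Spatially inferred copy-number (siCNV) analysis of spot-based
transcriptomics, plus a generative tissue simulator with ground-truth
copy numbers for end-to-end validation.

Given a spot-by-gene UMI count matrix and a genome gene-position table,
the package

1. applies spot-level QC and merges sections (`sicnv.genome_io`),
2. computes genome-ordered, reference-centred log2 residual profiles and
   segments them into six discrete copy states with an exact Viterbi HMM
   (`sicnv.inference`),
3. selects a "pure benign" low-burden reference set and groups spots into
   clones by hierarchical clustering (`sicnv.clones`),
4. builds clone phylogenies from per-clone CNV event sets — with inferred
   unobserved ancestors, fixed pixel formulas for branch lengths
   (`100·log2(ΔZ) + 300`) and clone diameters (`10·log2(spots)`), and a
   maximum-parsimony alternative (`sicnv.trees`),
5. produces organ-wide dual-threshold event maps, ground-truth evaluation
   metrics and clonal SNV allele-fraction summaries (`sicnv.summaries`).

The simulator (`sicnv.simulator`) grows virtual cells in a 2D domain
(move / divide / die / stagnate per step, ±1-copy segmental mutations at
division, local crowding), bins cells into Visium-like spots and samples
UMI counts whose intensity is proportional to copy number. Every
downstream stage can therefore be scored against known truth
(`sicnv.pipeline`).

## CLI

```sh
# synthetic experiment: counts (MatrixMarket), ground truth, cell table
sicnv simulate --config design.toml --seed 1 --out sim/

# residuals, HMM states and region events
sicnv infer --counts sim/counts --genes genes.tsv \
    --mode spots --min-spot-counts 500 --out out/

# organ-wide dual-threshold event map (35% dataset / 45% section defaults)
sicnv globalmap --states out/hmm_states.tsv --sections sections.csv \
    --genes genes.tsv --out map.csv

# clonal variant allele fractions and spot percentages
sicnv vaf --snv snv_counts.tsv --clones clones.csv --out vaf/

# end-to-end synthetic benchmark (clone recovery + category accuracy)
sicnv evaluate --seed 1 --out metrics.json
```

Input formats: counts as a MatrixMarket triplet directory
(`matrix.mtx` + `barcodes.tsv` + `features.tsv`), dense TSV (genes in
rows) or 10x-style HDF5; gene positions as headerless TSV
`(gene, chromosome, start, stop)`; annotations as `Barcode,Annotation`
CSV; SNV counts as TSV `(barcode, chrom, pos, ref_count, alt_count)`.

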