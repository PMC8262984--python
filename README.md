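# czbkit

Toolkit for surveying chemoreceptor zinc-binding (CZB) domain proteins and
for the quantitative analyses that accompany such surveys: domain
identification, architecture classification, conservation/logo matrices,
species-level co-occurrence, binding/dose-response model fitting, and
colorimetric image quantification. A synthetic-data module generates
labeled inputs for every stage so the whole pipeline is testable offline.

## What it does

- **`czbkit.detect`** — identifies CZB domains by four attributes: the
  3His/1Cys zinc-binding core, the seven-residue C-x-(L/F)-G-x-W-(Y/L)
  motif, coverage of the ~128-residue domain, and log-odds alignment to a
  profile of confirmed domains. Includes an iterative fixed-point search
  with a pluggable homology backend (a naive shared k-mer scorer is built
  in for tests; BLAST statistics are deliberately out of scope).
- **`czbkit.architecture`** — assigns each CZB protein to one of seven
  subgroups (soluble/membrane chemoreceptor, DGC, DGC+EAL, EAL-CZB,
  CheW-CZB, CZB-only), locates the CZB terminus, flags putative
  periplasmic CZBs between transmembrane segments, and summarizes
  subgroup fractions. A Kyte–Doolittle sliding-window TM predictor is
  provided as a stand-in for external annotation.
- **`czbkit.conservation`** — per-column identity/gap profiles over
  externally produced alignments, Cys-anchored 7×20 motif frequency
  matrices, and per-subgroup logo comparison.
- **`czbkit.cooccurrence`** — species-level aggregation: chemoreceptor vs
  diguanylate-cyclase possession categories and phylum distributions.
- **`czbkit.biochem`** — Hill dose-response with fixed coefficient
  (default 2, rising limb only), the two-state tight-binding (ligand
  depletion) quadratic for chelator titrations, linear inhibition fits,
  relative-biofilm normalization against untreated wild type per
  experiment, and paired t tests.
- **`czbkit.imaging`** — HSB hue-gated k-means segmentation of Congo-red
  colony images (red/brown/background pixel counts) and per-row intensity
  profiles of stained culture tubes with trapezoidal pellicle scoring.
- **`czbkit.synthetic`** — deterministic generators with ground truth:
  architecture-labeled proteins with near-miss decoys, noisy titrations,
  colony and tube images, and species tables.

## CLI

```bash
czbkit scan      --fasta in.fa --profile seed.fa --out calls.tsv \
                 [--his-window 45] [--min-coverage 100] [--score-threshold T]
czbkit classify  --calls calls.tsv --domains domains.tsv --fasta in.fa --out arch.tsv
czbkit conserve  --alignment aln.fa --reference-id DgcZ --reference-cys 52 \
                 --out-profile profile.tsv --out-logo logo.tsv
czbkit cooccur   --arch arch.tsv --taxonomy tax.tsv --out species.tsv
czbkit fit       --model hill|twostate|linear --csv data.csv --out fit.json \
                 [--n 2] [--max-dose 500]
czbkit quantify  --mode congo|pellicle --image img.png --out rep.json \
                 [--range 2000 2500]
czbkit simulate  --what proteins|doseresponse|colony|tube|species --seed 0 --out dir/
czbkit survey    --fasta in.fa --domains domains.tsv --taxonomy tax.tsv \
                 --profile seed.fa --out bundle/
```

`survey` chains scan → classify → conserve → cooccur and writes
`calls.tsv`, `arch.tsv`, `subgroups.tsv`, `profiles.tsv`, `logos/`,
`species.tsv` and a `summary.json` with subgroup fractions, category
counts and provenance. Exit codes: 0 success, 2 input error, 3 fit error.

## File formats

Plain FASTA (aligned FASTA with `-` gaps for profiles/alignments), TSV
domain tables (`protein_id, domain_name, start, end`; 1-based inclusive
coordinates), TSV taxonomy tables (`protein_id, species, genus, phylum,
candidate_phylum_flag`), dose-response CSV (`dose_uM, rep1..repN` with
`#`-comment metadata), PNG/TIFF RGB images. An optional schema-mapped
XLSX reader (`iolib.read_xlsx_table`) normalizes workbook sheets to these
schemas.

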