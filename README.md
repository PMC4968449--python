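# strainvar

Multi-strain variation analysis toolkit: private-variant identification
across an inbred strain panel, damage scoring of coding variants,
structural-variant (SV) merging and validation, candidate-gene discovery by
strain subtraction, and hypergeometric pathway over-representation — together
with seeded synthetic-data generators that plant ground truth, so the whole
pipeline is testable end to end without external downloads.

## Modules

| Module | Purpose |
| --- | --- |
| `strainvar.variant_model` | Domain types; readers/writers for multi-sample VCF (with pipe-delimited CSQ annotations), GFF3/GTF/BED gene models, GMT pathways, genotype-panel TSV |
| `strainvar.genotype_catalog` | Strains × sites genotype matrix; private-variant rule; pairwise sharing |
| `strainvar.consequence_scoring` | Amino-acid substitution distances from first principles, band classification (≤100 / 100–150 / >150), SIFT classes, consequence filters |
| `strainvar.sv_toolkit` | SV proximity/size filters, reciprocal-overlap deletion merging (strictly >0.9), insertion window merging, cross-strain private SVs, CDS overlap, validation sensitivity |
| `strainvar.concordance` | Genotype concordance against an external panel |
| `strainvar.candidate_discovery` | Private-missense gene sets; strain-subtraction candidate sets with damage filtering |
| `strainvar.pathway_ora` | Upper-tail hypergeometric test, Benjamini–Hochberg correction, significance calling |
| `strainvar.synthetic_data` | Seeded generators for every input, with planted truth sidecars |
| `strainvar.cli` | `strainvar` command-line interface |

## CLI

```bash
# generate a synthetic dataset with planted truth
strainvar simulate --n-strains 8 --n-sites 500 --seed 7 --out data/

# genotype matrix, private variants, pairwise sharing
strainvar catalog --vcf data/panel.vcf --strains STR01,...,STR08 --out cat/

# damage scoring, SV merging, concordance
strainvar consequences --vcf data/panel.vcf --strains ... --out cons/
strainvar sv-merge --sv-table data/sv_calls.tsv --out sv/
strainvar concordance --vcf data/panel.vcf --strains ... --panel data/genotype_panel.tsv --out conc/

# candidate genes: private-missense or strain subtraction
strainvar candidates-private --vcf data/panel.vcf --strains ... --focal STR01 --out cp/
strainvar candidates-subtract --vcf data/panel.vcf --strains ... \
    --target STR01 --exclude STR02 --exclude STR03 --out cs/

# pathway over-representation
strainvar ora --genes cs/genes.txt --gmt data/pathways.gmt --out ora/

# simulate -> catalog -> consequences -> candidates -> ora, verified against truth
strainvar full-run --seed 7 --out run/
```

Every subcommand writes `run_config.json` into its output directory;
re-running with the same inputs and seed reproduces outputs byte-identically.

## Conventions

Coordinates are 1-based inclusive internally (VCF convention); BED inputs
are converted on read. Multi-allelic VCF rows are decomposed into one record
per alternate allele. A "high quality" genotype requires FILTER == PASS and
GQ ≥ 20 (configurable). Indels are assumed upstream-normalized; site
identity is the exact (chrom, pos, ref, alt) tuple.
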