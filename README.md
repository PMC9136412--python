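# conglutin

A tested, reusable pipeline for profiling the conglutin seed storage
proteins of narrow-leafed lupin (NLL): reference-guided discovery and
structural classification of conglutin isoforms in a protein database,
peptide-level conservation mapping across accessions, rule-based selection
of MRM marker peptides, and batch-corrected relative quantitation with
family-level aggregation and multivariate summaries.

## Pipeline stages

| module | what it does |
| --- | --- |
| `conglutin.seqdb` | FASTA I/O, six-frame ORF prediction (150 nt cutoff), exact-sequence deduplication |
| `conglutin.align` | global pairwise alignment with free end gaps; percent identity |
| `conglutin.annotate` | screening against the 16 reference conglutins (default ≥ 75% identity), family-specific structural validation (cysteine skeletons, cupin_1 / TAXi / tryp_alpha_amyl domain windows), neighbor-joining trees, exact epitope scanning |
| `conglutin.conserve` | discovery-peptide filtering (allowed modifications, confidence), cross-accession presence matrix, six identification-frequency classes, exact mapping onto the references |
| `conglutin.assay` | in-silico tryptic digestion (1 missed cleavage, 8–30 aa), peptide specificity against a background proteome (unique / protein group / nonspecific), the five marker-selection gates, transition-list export |
| `conglutin.quant` | batch-effect removal (log10 linear model with injection-order covariate), replicate CV, percent-of-average normalisation, summed family profiles, PCA, one-minus-Pearson HCA, one-way ANOVA + Dunnett |
| `conglutin.synth` | synthetic versions of every input with known ground truth (reference set, variant/decoy/duplicate databases, identification tables, MRM abundance matrices) |

## Command line

```bash
# emit a complete synthetic input bundle with ground truth
conglutin simulate all --seed 1 -o bundle/

# build the search space from transcript/protein FASTA files
conglutin db build --transcripts tx.fasta --proteins extra.fasta \
    --min-orf-nt 150 -o database.fasta

# discover and classify conglutin isoforms
conglutin annotate classify --db database.fasta --refs bundle/references.fasta \
    --domains bundle/candidate_domains.tsv --identity-threshold 75 -o classified.tsv

# conservation mapping across accessions
conglutin conserve map --obs bundle/identifications.tsv \
    --refs bundle/references.fasta -o conserved

# marker selection and quantitation
conglutin assay select --candidates candidates.tsv --s2n-min 5 --top-k 8 -o markers.tsv
conglutin quant run --abundance bundle/abundance.tsv --markers bundle/markers.tsv \
    --control D7 -o quant_out/
```

## File formats

All interchange is plain text. Identification tables are TSV with columns
`accession, peptide, modifications, confidence, protein_id` (modifications
are semicolon-separated `Name(site)` entries). Abundance tables are TSV
with columns `peptide, accession, replicate, batch, injection_order, area`.
Domain annotations are TSV with `id` (or `subfamily`), `domain`, `start`,
`end` (1-based inclusive). Sequences are FASTA; trees are newick; peptide
coverage exports as BED-like intervals (0-based starts).

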