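# revertscan

Detection of **reversion mutations** — secondary somatic mutations that
restore the reading frame of a gene inactivated by a known pathogenic variant
(e.g. a germline frameshift deletion in *BRCA1/2*) — from aligned DNA
sequencing reads.

General-purpose aligners routinely misrepresent reads that carry a reversion:
the pathogenic indel is absorbed as mismatches, large deletions are hidden in
soft clips, and equivalent indel placements are chosen that do not coincide
with the patient's known allele. `revertscan` exploits prior knowledge of the
pathogenic variant to fix this locally:

1. **Soft-clip rescue** — clipped read ends are Smith-Waterman aligned inside
   the analysis window; a clip containing a sufficiently long perfectly
   matched run is converted back into aligned structure (recovering large
   deletions).
2. **Personalized realignment** — reads overlapping the pathogenic site are
   realigned against the window rewritten to contain the pathogenic allele,
   with indel-lenient scoring; a new alignment is accepted only if every
   aligned base matches the personalized sequence exactly, then lifted back
   to reference coordinates.
3. **Indel placement normalization** — sequence-equivalent indel placements
   are rewritten onto the pathogenic span (the genetically plausible choice).
4. **Translation check** — each read's variants are written into the
   transcript model and translated; a read whose protein keeps the canonical
   stop codon (net indel ≡ 0 mod 3, no premature stop) is a candidate
   reversion.
5. **Aggregation** — candidate reads are grouped into distinct reversion
   alleles with supporting-read lists, VAF against the local depth, and
   homopolymer-overlap flags (runs ≥ 5 nt by default).

## Command line

```sh
revertscan \
    --bam reads.bam --vcf pathogenic.vcf \
    --fasta ref.fa --transcript transcript.tsv \
    --out results/ \
    [--window 500] [--min-perfect 20] [--min-homopolymer 5] \
    [--match 2 --mismatch 3 --gap-open 2 --gap-extend 0.5] \
    [--keep-duplicates] [--min-mapq 0] [--min-support 1] [--no-plot]
```

Inputs: indexed BAM (plain SAM is accepted for testing), VCF v4.x with the
pathogenic variant(s) (multi-allelic records are split), FASTA reference, and
a transcript model as either a GTF/GFF3 subset (exon + CDS features of one
transcript) or a 6-column TSV: `gene  chrom  strand  exons("start-end;…")
cds_start  cds_end` with 0-based half-open coordinates.

Outputs per pathogenic variant: `alleles.tsv` (one row per distinct reversion
allele: key, category, support, depth, VAF, net indel, frame/stop verdicts,
homopolymer flag), `supporting_reads.tsv` (allele key → read id),
`allele_map.png` (lollipop map of alleles around the pathogenic site) and
`run.log`. Exit code 0 includes zero-allele results.

## Python API

```python
from revertscan import RunConfig, run_pipeline

cfg = RunConfig(bam_path="reads.sam", vcf_path="pathogenic.vcf",
                fasta_path="ref.fa", transcript_path="transcript.tsv")
(report,) = run_pipeline(cfg)
for allele in report.alleles:
    print(allele.key, allele.n_support, f"{allele.vaf:.4f}")
```

Lower-level building blocks (`build_reference_context`, `smith_waterman`,
`rescue_soft_clips`, `realign_over_pathogenic`, `normalize_indel_placement`,
`translate_with_variants`, `assess_read`, `aggregate_alleles`) are exported
from the package root.

## Synthetic data

`revertscan.fixtures` generates complete, deterministic test data sets
(FASTA + .fai, SAM with deliberately naive alignments, VCF, transcript TSV,
truth JSON) with planted pathogenic and reversion alleles:

```python
from revertscan.fixtures import default_spec, generate_fixture
truth = generate_fixture(default_spec(seed=1, n_alleles=10, depth=1000), "fx/")
```

## Tests and acceptance report

```sh
python -m pytest -q tests/          # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates seeded synthetic data, re-runs the full
pipeline and verifies the worked misalignment correction
(`10M1D140M` → `4M2D6M1D140M`) and exact recovery of 10 planted low-VAF
alleles; it writes an empty JSON target object, as no published numeric
result is reproducible without external patient data.
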