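# hgblkit

Integrated genomic profiling of diffuse large B-cell lymphoma (DLBCL) with
abnormal *MYC* status. DLBCL with *MYC* alteration falls into three groups:

* **DHL/THL** — double/triple-hit lymphoma: *MYC* rearrangement (*MYC*-R)
  plus *BCL2*-R and/or *BCL6*-R;
* **SHL** — single-hit lymphoma: *MYC*-R without *BCL2*-R or *BCL6*-R;
* **MCAD** — DLBCL with *MYC*-cluster amplification: no *MYC*-R but more
  than 10 *MYC* FISH signals per cell in an above-threshold cell fraction.

`hgblkit` re-implements, as a tested reusable pipeline, the analysis chain
used to characterise these groups from three assays — break-apart/fusion
FISH, whole-genome copy-number segments, and targeted panel sequencing —
together with a synthetic cohort generator that emulates the three groups,
so every stage runs and is verifiable without patient data.

## What the pipeline computes

1. **FISH classification** (`hgblkit.fish`). Probes are scored over ≥100
   cells with a 10% positivity threshold; amplification requires >10 *MYC*
   signals per cell in ≥10% of cells. Probe calls map to the subtype
   (DHL/THL/SHL/MCAD). IHC positivity (>30% of tumor cells) feeds the Hans
   CD10/BCL6/MUM1 tree for cell of origin.
2. **Consensus variant filtering** (`hgblkit.variants`). Per-caller VCFs
   (5 callers) are merged on (chrom, pos, ref, alt); only variants seen by
   ≥3 callers survive. *BCL6* candidates are restricted to covered exons
   3–10. Survivors are classified into *mutation* / *likely SNP* / *SNP* /
   *likely non-functional*: a variant is a **mutation** if it is a COSMIC
   somatic, a literature-described driver, truncating (frameshift, splice,
   stop gained), or a missense judged damaging by ≥2 of 4 predictors
   (PolyPhen2, SIFT, CADD, Mutation Assessor). The per-sample **mutation
   burden** is the number of panel genes (panel size 115) with ≥1 selected
   mutation — not a per-megabase rate.
3. **Copy-number MCRs** (`hgblkit.cna`). Segments are called gain/loss at
   ±0.3 log2 (or CN ≥3 / ≤1); per-group altered-sample count profiles yield
   **minimal common regions**: peak plateaus (strict local maxima of the
   count profile) and broad above-threshold regions, each labeled by
   cytoband (e.g. `+8q24`, `-1p36.32-q21.1`) with its recurrence frequency.
4. **Integration and statistics** (`hgblkit.stats`). A gene × sample
   alteration matrix (mutation / gain / loss / combined) supports per-gene
   Fisher exact group comparisons (raw p primary, BH q alongside);
   Mann–Whitney U compares burdens; Kaplan–Meier + log-rank compare the
   *favorable* (CR to first-course chemotherapy, no relapse) vs *adverse*
   prognosis groups.

## Worked example

Simulate the study-sized cohort (10 DHL/THL, 10 SHL, 3 MCAD) and run the
full pipeline:

```bash
hgblkit simulate --seed 7 --out demo
hgblkit run --in demo --out demo_out --seed 7
```

The run log summarises every stage:

```
classify-fish: {'n_cases': 23, 'subtypes': {'SHL': 10, 'THL': 6, 'DHL': 4, 'MCAD': 3}}
call-filter:   {'n_samples': 23, 'n_selected_mutations': 305, 'mean_burden': 13.26}
cna-mcr:       {'n_segments': 460, 'n_mcrs': 27, 'n_significant_bins': 465}
integrate:     {'n_genes': 115, 'n_samples': 23, 'n_altered_cells': 844}
compare:       {'burden_mannwhitney_p': 0.00085}
survival:      {'favorable': 8, 'adverse': 15}
```

All 23 cases classify into the subtype the generator drew; the mean burden
(13.3) mixes the three group means. `demo_out/mcr.tsv` holds the per-group
minimal common regions, e.g. for DHL/THL:

```
group    chrom  start     end        direction  frequency  label      peak
DHL_THL  chr12  0         20000000   gain       0.7        +12p12.2   True
DHL_THL  chr3   70000000  100000000  gain       0.6        +3q29      True
DHL_THL  chr8   75000000  100000000  gain       0.5        +8q24      True
```

`demo_out/mutation_comparison.tsv` compares mutated-case fractions between
DHL/THL and SHL; in this draw *BCL2* is mutated in 9/10 DHL/THL vs 0/10 SHL
(Fisher p = 1.2e-4), while *DTX1* leans toward SHL — the group structure
the templates encode. `demo_out/survival.json` contains the Kaplan–Meier
curves and the favorable-vs-adverse log-rank test (here chi² = 5.10,
p = 0.024).

Individual stages are also exposed as subcommands (`classify-fish`,
`call-filter`, `cna-mcr`, `compare`, `survival`) over the same file
formats: VCF v4.2, IGV SEG, BED, UCSC cytoBand, TSV, JSON.

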