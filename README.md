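# repscope

Offline analysis toolkit for antibody heavy-chain repertoire sequencing
(Rep-seq) data: clonotyping, repertoire feature extraction, somatic
hypermutation (SHM) profiling, group comparison with public-clone detection,
antibody annotation with disease enrichment, and sequence query — plus a
synthetic V(D)J repertoire simulator so every stage can be exercised with
known ground truth and no external downloads.

It is aimed at immunologists and bioinformaticians who have clone tables
from an upstream aligner (AIRR Rearrangement TSV, a MiXCR export subset, or
this package's native TSV) and want reproducible, scriptable repertoire
statistics.

## What it computes

**Clonotypes.** Records sharing the same V gene, J gene, C gene (optional,
on by default) and identical CDR3 nucleotide sequence are clustered into a
clone; the clone's read count is the sum of its records' duplicate counts,
and its isotype (IGHM/IGHD/IGHG/IGHA/IGHE/NA) comes from the best-scoring
C-gene hit.

**Repertoire features.** V/D/J gene usage and CDR3 length distributions are
clone-count based. Junction diversity summarizes exonucleolytic deletions at
the four trim sites (V3′, D5′, D3′, J5′) and non-templated insertions at the
V–D and D–J joints, with insertions and deletions at the same joint treated
as mutually exclusive events. Clonal diversity uses read-weighted clone
frequencies *p&#8321;…p&#8342;*:

- Shannon index: −Σᵢ pᵢ ln pᵢ
- Simpson index: Σᵢ pᵢ²
- D50: the percentage of distinct clones whose cumulative reads first reach
  50% of the total (low D50 = clonal expansion)
- top-100 clone fraction: summed frequency of the 100 most abundant clones

**SHM profile.** Per-position mutation frequencies over FR1–FR3 of the
germline V, computed with the clone as the basic unit (fraction of a clone's
nonredundant reads carrying each event, then an unweighted mean over
clones), stratified by isotype. Positions are classified as silent /
replacement / composite loci by enumerating the three possible
substitutions, tagged with canonical hotspot (WRCY/RGYW, WA/TW) and coldspot
(SYC/GRS) motifs, and rates are cross-tabulated by locus class × motif tag
alongside a 4×4 germline→observed transition matrix.

**Group comparison.** An experimental group is compared to a reference
group selected from a catalog by exact metadata match; each feature category
is summarized by the reference five-number summary with the experimental
samples overlaid. CDR3s (or clone keys) shared by at least two samples are
reported as intragroup (experimental-only) or intergroup (spanning both
groups) public clones.

**Annotation and query.** Clones are annotated by exact CDR3 amino-acid
identity to database antibodies; disease over-representation among annotated
clones is tested with the hypergeometric upper tail P(X ≥ k) and
Benjamini–Hochberg FDR control (adjusted p < 0.05 flagged). Sequence query
returns exact amino-acid matches and ≥ 90%-identity nucleotide matches
(semi-global alignment; identity = matches / alignment columns).

## Worked example

```python
from repscope.simulate import SimulationParams, simulate_repertoire
from repscope.features import diversity_indices, gene_usage

result = simulate_repertoire(SimulationParams(seed=7, n_clones=1000), sample_id="demo")
rep = result.repertoire
idx = diversity_indices(rep)
print(f"clones: {len(rep.clones)}  reads: {rep.total_reads}")
print(f"Shannon: {idx.shannon:.4f}  Simpson: {idx.simpson:.4f}  "
      f"D50: {idx.d50:.1f}%  top-100: {idx.top100_fraction:.4f}")
for gene, frac in gene_usage(rep, "V").freq.items():
    print(f"V usage  {gene}: {frac:.3f}")
```

prints

```
clones: 1000  reads: 10000
Shannon: 5.1893  Simpson: 0.0293  D50: 2.4%  top-100: 0.6928
V usage  IGHV1-2: 0.481
V usage  IGHV3-7: 0.334
V usage  IGHV4-34: 0.185
```

The Shannon index sits below ln 1000 ≈ 6.91 and D50 is low because clone
abundances follow a rank power law: the top 100 of 1000 clones already carry
69% of the reads. The V-usage fractions recover the simulator's planted
priors (0.5 / 0.3 / 0.2) up to binomial sampling error.

The same pipeline runs from the shell:

```bash
repscope simulate --outdir data --seed 7 --n-clones 1000
repscope all --config config.yaml       # analyze + compare + annotate
repscope query --config config.yaml --sequence CARGYGMDVW --mode aa
```

where `config.yaml` points at the clone tables, germline FASTA + boundary
YAML, optional reference catalog and antibody database; every run writes a
`manifest.json` listing its output tables.

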