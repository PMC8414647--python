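# Methods

This note records the statistical definitions the package implements, the
modelling choices behind the synthetic repertoire generator, and the
numerical conventions that matter when interpreting output.

## Clone definition and counting bases

A clone is the set of aligned records sharing (V gene, J gene, C gene,
CDR3 nucleotide sequence). Gene calls are collapsed to gene level (the
allele name truncated at `*`) before grouping because allele-level calls are
unstable across aligners, while usage statistics are conventionally reported
per gene. The C gene is part of the key by default; `use_c_gene=False`
reproduces the looser V/J/CDR3nt definition used when isotype switching
within a lineage should not split clones.

Two counting bases coexist deliberately:

- **clone-count based** — gene usage and CDR3 length distributions: every
  clone weighs 1, because these features describe the diversity of
  *recombination products*, not of sequencing depth;
- **read-weighted** — Shannon, Simpson, D50 and the top-100 clone fraction:
  clone frequency = readCount / totalReads, because these indices describe
  *clonal expansion*.

The CDR3/junction convention includes the conserved Cys codon and the final
Trp codon, so printed CDR3aa strings look like `CARGYGMDVW`.

## Junction diversity

Deletion lengths are tracked at V3′, D5′, D3′ and J5′; non-templated
insertion lengths at the V–D and D–J joints. Only clones with complete
V/D/J junction information contribute. Insertions and deletions at the
same joint are treated as mutually exclusive: a clone with a positive
insertion contributes length 0 to that joint's deletion tallies, and a clone
with a positive deletion contributes 0 to that joint's insertion tally (a
clone carrying both contributes 0 to both). The rule is applied **per
joint** by default — a V–D insertion does not silence D–J deletions — with a
`exclusivity="clone"` switch for the global reading, since the narrower
per-joint scope follows from the fact that the V3/D5 deletions and the VD
insertion describe the same physical joint.

Deletion lengths are derived from aligner output: for the MiXCR-export
dialect they come from the `refPoints` read coordinates combined with the
germline segment boundaries (V's FR3 end, J's FR4 start, D's length plus the
germline alignment start carried in a documented extension slot); the native
dialect carries them as explicit columns. All internal coordinates are
0-based half-open; AIRR's 1-based closed fields are converted at the reader
boundary.

## D50 and tie handling

Clones are ranked by descending read count; D50 = 100·m/R where m is the
smallest number of top clones whose cumulative frequency reaches ≥ 0.5
(a clone carrying exactly half the reads gives m = 1). Descending sorts
break ties by clone key, so every ranked statistic is reproducible.

## SHM profile

The clone is the basic unit. Within a clone, the mutation frequency at
position p is the fraction of the clone's distinct supporting reads carrying
a mutation there (duplicate counts are ignored inside SHM — reads are
treated as nonredundant sequences). Clone-level values are then averaged
over clones with equal weight, separately per isotype. Only FR1–FR3 of the
germline V is considered; positions are keyed per (V gene, position) because
no cross-gene alignment (e.g. unified numbering) is imposed — pooled
region rates average clone-level region means instead.

Locus classes enumerate the three alternative bases of each coding position:
all substitutions synonymous → silent, none synonymous → replacement
(a stop codon counts as a non-silent outcome), mixed → composite. Motif
tags follow the canonical SHM spots with IUPAC matching (W=A/T, R=A/G,
Y=C/T, S=C/G): WRCY tags its C, RGYW its G, WA its A, TW its T (hotspots);
SYC its C, GRS its G (coldspots). Overlapping motif hits are all recorded,
and a position may carry several tags. Transition frequencies are reported
as the mean per-position event rate per germline base, so each row of the
4×4 matrix sums to that base's total mutation frequency.

## Group comparison and public clones

Reference selection is exact metadata matching (tissue, health condition,
amplification strategy, primer locations, read length, isotype, age, sex);
unspecified criteria match everything. Feature comparisons use
linear-interpolation quantiles for the reference five-number summary;
categories absent from one group count as 0 for distribution features.
Public-clone detection counts a sharing key once per sample, with the CDR3
amino-acid sequence as the default key (CDR3nt and V|J|CDR3nt offered),
and a minimum of two carrying samples.

## Enrichment

The annotation universe N is the set of database records carrying at least
one disease tag (configurable to the whole database); K counts records
tagged with the disease, n counts annotated clones carrying any tag, and k
counts annotated clones carrying the disease (a multi-tag clone counts once
per disease, so Σk may exceed n). The p-value is the hypergeometric upper
tail P(X ≥ k) = 1 − CDF(k−1), the standard over-representation convention.
BH adjustment runs across the diseases observed in one sample. Note that BH
step-up adjusted values are *not* a fixed point of re-adjustment (re-running
BH on adjusted values re-multiplies by m/rank); what is idempotent is the
monotone-cap enforcement step, and the tests check exactly that plus
agreement with the statsmodels implementation.

## Sequence query

Amino-acid queries are exact full-string matches. Nucleotide queries use a
shared-k-mer prefilter with a pigeonhole-safe seed length (no true hit at
the 90% identity threshold can be filtered out) followed by semi-global
alignment (edlib), so the whole query is aligned against the best subject
substring; identity = matched columns / alignment columns including gaps,
and the ≥ 90% threshold is applied to that ratio. Because the full query is
aligned, query coverage is 100% by construction. Hits sort by identity,
then subject id.

## Synthetic repertoire generator

The generator emulates the statistical structure the analysis stack
measures, with every latent variable recorded as ground truth:

- **gene usage**: categorical priors over the bundled 3 V / 2 D / 2 J
  germline (defaults 0.5/0.3/0.2, 0.6/0.4, 0.7/0.3) — skewed, as real
  repertoires are;
- **junction**: truncated geometric deletions per trim site (p = 0.3–0.35,
  max 6–9 nt) and truncated geometric insertions per joint (p = 0.25,
  max 12 nt), uniform random inserted bases. These one-parameter forms are a
  modelling convenience, not a biological claim. The D–J insertion is
  extended by 0–2 nt to keep the junction in frame; the V–D insertion is
  never adjusted, so its distribution is exactly the sampled one and is the
  one used in parameter-recovery checks. Junctions are not screened for
  stop codons, so a realistic minority of clones is unproductive;
- **SHM**: i.i.d. per-read, per-position Bernoulli mutations over FR1–FR3 at
  a 1% base rate, multiplied at hotspot (default ×3) and coldspot (default
  ×0.3) positions, with a uniform choice among the three alternative bases.
  There is no lineage structure — sufficient to exercise the clone-as-unit
  estimator, but not a model of affinity maturation;
- **abundance**: read counts proportional to rank^(−a) (default a = 1), a
  power law producing the low-D50, high-top-100 profile of expanded
  repertoires; distinct reads per clone are 1 + Poisson(1), and duplicate
  counts are distributed multinomially;
- **isotypes**: a fixed six-way categorical (M .35, D .03, G .37, A .18,
  E .02, NA .05).

Planted public clones bypass the recombination model: a requested CDR3aa is
encoded with a fixed codon table and injected into exactly the listed
samples with a fixed V/J/C context, so sharing-detection recovery can be
asserted exactly. Per-sample seeds are derived from the master seed via a
seed sequence, making groups independent but reproducible.

**What passing tests do not show about real data**: the simulator has no
sequencing error, no UMI structure, no allele-level variation, no lineage
trees, and a tiny germline; agreement between measured and planted
parameters validates the estimators' correctness, not their behaviour on
full-size biological repertoires.

## Numerical conventions and degenerate inputs

- Frequency vectors must sum to 1 within 1e-9; violations raise rather than
  renormalize silently.
- 0·ln 0 := 0 in the Shannon index.
- Empty repertoires, empty isotype strata, and zero V/D/J-complete clones
  return empty results with a logged warning rather than raising, matching
  how partial data arrives in practice.
- Problem sizes in the test suite (up to 10,000 clones for parameter
  recovery, 100,000 for junction-rule checks, 20 samples × 1,000 clones for
  public-clone oracles) were chosen so that 3·SE bounds are decisive while
  the whole suite runs in a couple of minutes on one CPU.

## Known limitations

- No fuzzy clonotyping (CDR3 similarity clustering) or lineage inference.
- No rarefaction/Chao-type richness estimators or Hill numbers.
- SHM analysis ignores indels and fits no k-mer targeting model.
- The MiXCR dialect consumes a documented subset of export columns; exports
  lacking the junction slots load with junction fields unavailable.
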