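# Methods

This note documents the models and procedures implemented in scpepkit,
the assumptions behind them, the parameters that matter, and what the
simulation-based tests do and do not demonstrate.

## In-silico digestion

Classic trypsin specificity: cleavage C-terminal to K or R, suppressed
when the next residue is P.  A K/R followed by P is not a cleavage site
and therefore never counts as a missed cleavage.  Coordinates are
1-based inclusive throughout, matching site notation ("Ser 67").
Non-canonical residues X and U are accepted in sequences but are never
cleavage sites and never satisfy a variant reference check.  The
initiator methionine is retained by default; `digest_with_met_clipping`
adds Met-clipped N-terminal forms for workflows that need them.
Default reporting bounds are 7–30 residues (the typically detectable
tryptic range); the engine itself accepts any bounds.  Semi-tryptic and
nonspecific digestion are out of scope.

The engine is verified against an independent brute-force oracle
(enumerate all substrings; keep those whose boundaries are termini or
cleavage sites and whose internal site count is within budget) and
cross-checked against pyteomics' `cleave` with the same rule.

## Variant windowing

"All mutated-sequence tryptic peptides containing the variant residue
with total missed cleavages ≤ 2" is the implemented interpretation of a
two-missed-cleavage window around a substituted residue.  It is the
minimal peptide set guaranteeing that any engine configured with ≤ 2
missed cleavages can match the variant; a window defined as "two
cleavage sites upstream and downstream" reduces to the same peptide set
after engine-side digestion.  Digestion runs on the *mutated* sequence,
so substitutions that create or destroy cleavage sites (ref or alt in
{K, R, P}) change the window correctly — property-tested against the
brute-force oracle.

Augmented databases append one entry per variant *peptide* (header
`accession|pPOSrefALT|sap`) rather than per mutated protein, so protein
inference does not conflate variant evidence with the reference entry;
a whole-protein mode exists behind a flag.  Variant length bounds
default to 7–45.  The wild-type counterpart of a variant peptide is the
reference peptide with the same boundaries when those are preserved,
else the fully cleaved reference peptide covering the coordinate.
Duplicate peptides arising from distinct variants are kept (for
traceability) and flagged.

## Report ingestion

The reader accepts a long-format precursor table in a DIA-NN-style
dialect (configurable column map) and rejects other modified-sequence
notations rather than guessing.  Modification tags use `(UniMod:N)`
with the vocabulary {1: acetyl, 21: phospho, 34/36/37: mono/di/
trimethyl, 35: oxidation, 122: formyl}; a tag before the first residue
is protein/peptide N-terminal acetylation.  Rows above the q-value
threshold (default 0.01) are dropped and counted; malformed rows abort
with row numbers.

Peptide matrix: log2 of summed intensity across charge states per run.
Protein matrix: log2 of the top-3 raw peptide intensity sum per run,
using only unmodified, non-SAP, unambiguously assigned peptides
(shared peptides count for detection, never quantitation).  Top-3 was
chosen over MaxLFQ-style quantitation because it is deterministic,
testable, and preserves the relative group differences that the
downstream DE/PCA analyses consume.  Zero intensities are treated as
missing; missingness is always "absent", never zero.

Normalization subtracts each sample's median of observed log2 values
and adds back the global pre-normalization median — a stand-in for the
global cross-run normalization an engine applies — leaving
within-sample differences untouched.

## PTM sites and the histone activity ratio

A modification at peptide position *i* on a peptide located (uniquely)
at protein start *s* maps to protein coordinate *s + i − 1*; the
residue is checked against the reference.  The mapping is invariant to
which missed-cleavage form carries the modification.  Peptides that
occur more than once in their protein, or map to multiple proteins,
are excluded from site tables (no way to place the site uniquely).
Site-localization scoring is engine-level and out of scope: a reported
site is taken as reported.

Histone coordinates are mature-protein coordinates (initiator Met
removed), the convention behind H3 K14/K23/K27/K79 labels.  The
activity ratio per cell is
`log2((Σ activating + ε)/(Σ repressing + ε))` on raw intensities, with
activating {K79me, K79me2, K14ac, K23ac} and repressing {K27me, K27me2,
K27me3, K79fo}; both sets are configuration-driven.  Missing marks
contribute zero to their sum.  The default pseudocount ε is half the
smallest observed positive mark intensity in the cell (configurable;
0 gives the strict, scale-invariant ratio, undefined when a side is
empty).  The ratio is scale-invariant at ε = 0 and monotone in every
mark.

## Statistics

* Student's *t*: equal-variance two-sample test (df = n₁ + n₂ − 2),
  chosen over Welch because the analysis convention being reproduced
  names Student's t.  Tests run on observed values only; imputing for
  testing would fabricate variance.
* Benjamini–Hochberg step-up over the tested (non-filtered) features of
  one comparison; verified against an independent step-up
  implementation and calibrated by a 10,000-replicate null simulation
  (type-I error within [0.045, 0.055] at α = 0.05).
* Differential expression: the ≥ 25 % quantification filter is applied
  over *all* samples (not per group); fold-change is computed from
  log-space group means; calls need |FC| > 2 and adjusted p < 0.01.
* PCA: features observed in ≥ 70 % of samples, remaining gaps imputed
  at the feature minimum (a conservative "censored at detection limit"
  reading of dropout), features centered, SVD scores, each component's
  sign fixed by making its largest-magnitude loading positive.
* Treatment comparison: per-site and per-protein t-tests between
  conditions at α = 0.05; a site significant while its parent protein
  is not is flagged as a site-specific (drug-like) effect.

## Interaction networks

Edge lists are undirected, deduplicated, self-loop-free; gene symbols
are the node identity.  The kinase subnetwork is the induced subgraph
on detected genes restricted to edges incident to at least one kinase;
its largest connected component is returned (ties by lexicographically
smallest member).  Dense regions come from greedy modularity
maximization with deterministic tie-breaking, filtered to ≥ 4 members
and ordered by internal edge density; the clustering method used in the
original network visualizations is unnamed, so greedy modularity is a
declared stand-in.  Reproducing release-dependent interactome node and
edge counts is a non-goal.

## The simulator: what it emulates, and what it does not

`synthetic_data` generates the whole study design from one seed:

* **Abundance.** Per-protein base log2 abundance ~ N(13, 2); group
  effects added on top; per-cell loading offset ~ N(0, 0.3); residual
  noise N(0, 0.4) per protein per cell.  A housekeeping-flagged 13 % of
  proteins get a +1.5 log2 boost (constitutively abundant machinery).
* **Peptides.** Fully cleaved peptides of 7–30 residues; per-protein
  intensity shares drawn once from a symmetric Dirichlet; peptide raw
  intensity = 2^(protein log2) × share.  Peptide sequences occurring in
  more than one protein are emitted with all parent accessions joined,
  as a search engine reports ambiguous precursors.
* **Dropout.** Logistic in log2 peptide intensity (midpoint 10, slope
  1), depending on abundance only — sufficient to emulate the
  missingness structure; hydrophobicity/charge effects are not modeled.
* **Chromatography.** Fixed per-peptide RT centers U(5, 35) min with
  N(0, 0.6 min) jitter, ion-mobility centers U(0.7, 1.3) with
  N(0, 0.017) jitter — chosen to land median CVs near the low-percent
  reproducibility a well-behaved timsTOF single-cell run shows.
* **Groups.** Default design: one normal group and three cancer-line
  groups, 50 cells each.  30 proteins up and 30 down at ±2 log2 in all
  cancer groups (the DE truth), plus 100 proteins per line at ±1.2
  (distinct per-line proteotypes; roughly 10 % of the proteome per
  line, conservative for real cell lines, and what makes each line its
  own PCA cluster).
* **Variants.** KRAS-like G12D (carriers HuCCT-1/EGI-1), CCT8-like
  A488T (carrier RBE), one cleavage-site-removing R→T and one plain
  substitution on random proteins; variant peptides are emitted only in
  carrier-group cells at detection probability 0.9.
* **PTMs.** The eight H3 marks in every cell at stoichiometry 0.25 and
  detection probability 0.8; "active" cells (half, by default) carry
  activating marks ×4; four nucleolin-like phosphosites at sparse
  detection (0.3).  The single-nucleus treatment design (15 control vs
  15 treated, `nucleus_config`) scales K27me3 to 40 % in treated nuclei
  and leaves total H3 untouched.
* **q-values.** True rows uniform on [0, 0.01]; 5 % decoy rows with q
  in (0.01, 0.5] so the filter path is always exercised.

Fixture proteins (KRAS-like, CCT8-like, histone-H3-like,
nucleolin-like) are synthetic constructions that reproduce only the
local tryptic context needed for their worked examples; they are not
database sequences, and their accessions carry a `_SYN` suffix.

**What passing tests show.** Parameter recovery on this generator
demonstrates that the pipeline's arithmetic, filters and statistics are
correct and calibrated under a log-normal, logistic-dropout,
group-shift world with known truth.  It does not demonstrate
performance on real spectra: interference, co-elution, transfer of
identifications, batch structure, peptide-specific ionization and
nonlinear detector response are all absent, so real-data effect-size
and FDR behavior will differ.

## Problem sizes

The default simulated study is 1,000 background proteins across 200
cells (~1 M report rows); the end-to-end acceptance checks run at that
scale.  The treatment-signature power analysis uses 100 replicate
nucleus simulations with 40 background proteins each — the tested
quantities involve only the histone fixture, so background proteome
size does not enter the comparison.  QC jitter recovery uses three
40-cell / 120-protein replicates.  The CLI demo defaults to 60 proteins
and 48 cells so a full pipeline pass takes seconds.

## Known limitations

* Only single-residue substitutions; indels, splice variants and
  fusions are out of scope.
* Top-3 protein quantitation is a deterministic stand-in for engine
  quantitation; absolute protein values are not comparable to MaxLFQ.
* Site tables require unambiguous peptide placement; modified peptides
  from repeated regions are dropped rather than fractionally assigned.
* The histone ratio aggregates summed intensities; it does not model
  per-mark ionization efficiency, so it is comparable across cells, not
  across marks.
* BH control is per comparison; no control across multiple contrasts.
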