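# scpepkit

Post-processing toolkit for single-cell and single-nucleus proteomics by
data-independent acquisition (diaPASEF-style) mass spectrometry.  It
covers the bespoke computational stages that sit *around* the search
engine: building variant-peptide search databases, parsing precursor
reports, mapping post-translational modifications (PTMs) to protein
coordinates, scoring histone-mark transcriptional activity, single-cell
QC and differential-expression statistics, and kinase-network detection
overlays.  A ground-truth simulator emulating search-engine reports
makes every stage testable without raw mass-spectrometry data.

**Who it is for.** Proteomics analysts who have a DIA-NN-style long
precursor report from single cells (or nuclei) and want reproducible,
scripted answers to: *which somatic variant peptides are detectable, and
in which cells?  which PTM sites, at which protein coordinates?  is the
histone-mark balance of each cell activating or repressing?  which
proteins differ between groups, and does a drug shift a site without
shifting its protein?*

## The core computations

**Variant-peptide windowing.** A single amino-acid polymorphism (SAP)
at position *p* of protein *P* is searchable only through tryptic
peptides containing *p*.  `variant_peptides` digests the *mutated*
sequence (classic trypsin: cleave after K/R, not before P) and emits
every peptide that covers *p* with at most two missed cleavages — the
minimal set a search engine configured with ≤ 2 missed cleavages can
match, and robust to cleavage-site gain or loss caused by the
substitution.  For example, KRAS G12D yields `LVVVGADGVGK` (wild-type
counterpart `LVVVGAGGVGK`), and CCT8 A488T yields `NVGLDIEAEVPTVK`.

**PTM site mapping.** A modification at peptide position *i* of a
peptide starting at protein position *s* sits at protein coordinate
*s + i − 1*; residues are checked against the reference so isoform or
coordinate drift fails loudly.  Site labels follow field convention
(`S67`, `K27me3`, `Nt-ac`).

**Histone activity ratio.** Per cell, with raw mark intensities,

    ratio = log2( (Σ activating + ε) / (Σ repressing + ε) )

with activating = {K79me, K79me2, K14ac, K23ac} and repressing =
{K27me, K27me2, K27me3, K79fo} on histone H3.  Higher values indicate a
more transcriptionally active chromatin state.

**Statistics.** Equal-variance two-sample Student's *t* on observed
values only (missing values are never imputed for testing),
Benjamini–Hochberg adjustment across the tested family, and
up/down calls at |fold-change| > 2 with adjusted *p* < 0.01 on proteins
quantified in ≥ 25 % of samples.  PCA retains features observed in
≥ 70 % of samples, imputes the rest at the feature minimum, and uses an
SVD with a deterministic sign convention.

## Worked example

The bundled demo simulates a four-group experiment (one normal
cholangiocyte-like group, three cancer-line-like groups, 12 cells each,
60 background proteins plus four designated fixture proteins), then runs
every stage:

```bash
scpepkit demo --seed 5 --n-proteins 60 --out demo_out
```

The log tells the story end to end:

```
simulate: 64 proteins, 4 variants, 11828 report rows (11265 true + 563 decoy)
build-db: 64 reference entries + 20 variant entries
ingest:   11265 observations -> 616 peptides x 48 samples, 63 proteins
qc:       {'median_rt_cv_percent': 3.16, 'median_im_cv_percent': 1.65,
           'mean_proteins_per_sample': 53.1, 'housekeeping_fraction': 0.109}
de:       63 features (down=8, filtered=2, ns=45, up=8)
pca:      explained variance fractions 0.309, 0.099
ptm:      12 sites across 48 samples
histone:  48 cells, median ratio 1.474
network:  largest component 63 nodes / 413 edges, 1 dense clusters
```

Reading those numbers: 563 decoy rows were removed at the q ≤ 0.01
filter; retention-time reproducibility (median CV 3.16 %) and ion
mobility (1.65 %) recover the jitter injected by the simulator; the 8
up- and 8 down-called proteins are exactly the planted differential
set; the 12 mapped sites are the eight H3 marks plus four
nucleolin-like phosphosites; and the positive median activity ratio
(1.47) reflects the simulated excess of activating marks in "active"
cells.  Each stage writes TSV/JSON/GraphML artifacts plus a manifest
recording parameters and seed; rerunning with the same seed reproduces
every file byte-for-byte.

The same stages run individually (`scpepkit simulate | build-db |
ingest | qc | de | pca | ptm | histone | treatment | network`) against
your own FASTA / SNV table / report files; column names are remappable
via the report dialect.

## Layout

```
src/scpepkit/
  digestion.py       tryptic cleavage + peptide enumeration, FASTA I/O
  variant_db.py      SAP windowing, augmented FASTA, detection patterns
  report_ingest.py   report parsing, UniMod notation, matrix assembly
  matrix.py          features x samples log2 container
  ptm_sites.py       site mapping, site tables, histone activity ratio
  sc_stats.py        CV/QC, housekeeping, t/BH, DE, PCA, treatment tests
  network.py         kinase subnetworks, detection overlay, clustering
  synthetic_data.py  ground-truth simulator of precursor reports
  fixtures.py        synthetic designated fixture proteins
  cli.py             click-based orchestration (`scpepkit ...`)
docs/methods.md      model, assumptions, parameter rationale
```
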