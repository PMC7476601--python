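# Methods

## Problem and model

Glycopeptide searches against composition databases report, per
peptide-spectrum match (PSM), the peptide sequence with bracketed Δ masses
at modified residues, the glycan's monosaccharide composition, a score,
the MS2 scan number, and the calculated m/z — but no abundance.  A
precursor-area export links each MS2 scan to the MS1 chromatographic peak
area (AUC) of its precursor.  `glycoquant` joins the two by scan number
and models glycoform abundance purely at the composition level: a glycan
is a multiset over {HexNAc, Hex, Fuc/dHex, NeuAc, NeuGc, Pent, Sulfo,
Phospho}; linkage, branching, and isotopic fine structure are outside the
model.

Quantities reported per (protein, anchor, sample): glycoform proportions
with and without the unglycosylated peptidoform in the denominator, and
occupancy = glycosylated AUC / total AUC.  Both rest on the assumption
that glycosylation status does not change detection efficiency — a known
simplification (glycopeptides ionize and fragment differently, and
glycopeptide-enriched samples under-represent unglycosylated forms), so
occupancies from enriched data should be read as relative, not absolute.

## Pipeline steps and their rules

1. **Identification parsing.** The UniProtKB accession is extracted from
   the free-text protein name with the published accession pattern,
   bounded so it cannot fire inside entry names; when nothing matches, the
   whole protein name becomes the grouping id, which also merges isoform
   entries (`P01857-2` → `P01857`).  Decoy rows (`>Reverse` convention)
   and contaminants (configurable marker list, default
   "common contaminant") are removed before any grouping.  Scan numbers
   are accepted as bare integers, `Scan 12345`, or the dotted
   `file.start.end.charge` spectrum-title dialect (the repeated scan field
   is taken).
2. **Glycan mass and site assignment.** The theoretical glycan mass is the
   sum of monoisotopic residue masses, stored at full double precision
   (HexNAc 203.079372520, Hex 162.052823418, Fuc 146.057908799, NeuAc
   291.095416506, NeuGc 307.090331126, Pent 132.042258735, Sulfo
   79.956814859, Phospho 79.966330521 Da).  The modified residue whose Δ
   mass lies within a tolerance of that sum is the glycosite; exports
   print Δ masses rounded to ~4 decimals, so the default tolerance is
   0.05 Da (configurable).  When two mods fall within tolerance the closer
   one wins; an exact tie is an error and flags the row.  Non-glycan mods
   (oxidation, deamidation, carbamidomethyl, pyro-Glu) are untouched.
   Rows listing several glycans are parsed but flagged `multi_glycan`:
   site-specific quantification excludes them (the supported search
   setting allows one glycan per peptide); peptide mode quantifies them
   under the combined composition.
3. **Join and filter.** Areas attach by scan; rows with no area (including
   areas of exactly 0, which mark failed integration) and rows below the
   score cutoff (default 200) are dropped, with per-stage counts logged.
   Duplicate area entries for one scan collapse to the maximum, mirroring
   the max-area unique-PSM rule and avoiding double counting.
4. **Unique PSM selection.** Group key: sample, protein id, unmodified
   sequence, composition, calculated m/z (rounded to 4 decimals for float
   stability), plus assigned site(s) in site mode.  The maximum-area
   record wins; ties break by higher score, then lower scan, making the
   outcome invariant to input order.
5. **Aggregation.** Unique-PSM areas are summed per anchor: in site mode
   all peptide variants covering an assigned residue merge (charge states,
   missed cleavages, non-glycan-mod forms); peptide mode keeps proteolytic
   forms separate.  An unglycosylated peptide enters site mode only at
   sites observed glycosylated somewhere in the experiment and spanned by
   its protein coordinates — unglycosylated stretches with no known site
   are not quantifiable anchors.  Summation order is fixed (by scan) so
   outputs are byte-stable.
6. **Output.** Wide tables (one row per glycoform, per-sample column
   blocks for AUC and both proportions; a separate occupancy table) with
   deterministic row order and 6-significant-digit float formatting.
   Anchors unobserved in a sample stay blank — missing, never zero, and
   never imputed.

## Two-group comparison

Unpaired two-tailed t-test per row on per-sample values (default: the
glycosylated-only proportions), Student equal-variance by default — the
usual choice for small balanced designs such as n = 3 per group — with
Welch by flag.  No multiple-testing correction is applied; the
`significant` column flags raw p < 0.05 and downstream users are expected
to apply their own error control when screening many rows.  Rows with
fewer than two values in a group are reported with an `insufficient n`
note; rows with zero pooled variance get `degenerate variance` and no
p-value.  Proportions are tested untransformed; a logit transform would be
defensible but changes the estimand and is left to downstream analysis.

## Synthetic-data generator

The generator plants a complete truth — proteins, sites, per-condition
glycoform distributions (Dirichlet-drawn in the default model) and
occupancies, per-site total abundance — and writes the exact export
dialects the readers parse.  Per sample, each glycoform's total AUC is
`base_auc × occupancy × proportion × LogNormal(0, σ)`, split 70/30 across
charge states 2 and 3 (exercising aggregation across m/z), and each
precursor is emitted `redundancy` times with halving areas (exercising
max-area deduplication).  Decoy, contaminant, missing-area, and
sub-cutoff rows are injected from an independent random stream with
disjoint scan numbers, so their rates never perturb the signal rows; all
of them are rows a correct pipeline discards, which is what makes
"proportions invariant to nuisance rates" a testable property.

Defaults: 3 proteins × 2 sites (two N-linked proteins, one O-linked),
2–4 glycoforms per site from small built-in N- (15 compositions) and
O-glycan (8 compositions) libraries, occupancy in [0.55, 0.95], two
conditions × 3 replicates, σ = 0.25 (realistic replicate scatter for
label-free areas), redundancy 2, decoy rate 0.1, contaminant/missing-area/
sub-cutoff rates 0.05, scores uniform in [250, 600] against the 200
cutoff.  Validation and acceptance runs use σ = 0 because the planted
truth is then recoverable exactly (to ~1e-16; asserted at 1e-9).

What passing on fixtures does *not* show: robustness to real
chromatographic integration errors, chimeric spectra, wrong
identifications, or shared peptides between proteins — the generator
plants none of these, and the score column is uninformative noise.  The
fixtures validate the algebra and the plumbing, not search quality.

## Numerical and design notes

- Residue masses are fixed constants derived from elemental monoisotopic
  masses; tests cross-check them against an independent elemental-formula
  oracle to 1e-6 Da.  Mass additivity holds to 1e-9 Da by construction.
- Canonical composition rendering (HexNAc, Hex, Fuc, NeuAc, NeuGc, then
  others alphabetically) makes equal compositions render identically;
  the empty composition renders as the empty string and is labelled
  "Unglycosylated" in tables.
- Calculated m/z values in fixtures come from standard peptide-mass
  computation (pyteomics) plus the glycan mass over charge; the pipeline
  itself never recomputes peptide masses — m/z is only an identity key.
- The glycans column name implies a one-letter shorthand dialect in some
  exports; only the long-form `Name(count)` syntax is parsed, and a
  shorthand cell fails loudly with the offending token rather than being
  guessed at.
- Scan numbers are assumed unique per (sample, scan) in the area map but
  not in the identification file (chimeric spectra may repeat them).
- Empty inputs degrade gracefully: an empty identification file yields
  header-only outputs and exit 0; only configuration errors (missing
  files, duplicate sample labels, unknown mode) abort a run.

## Problem sizes

The default planted experiment (6 sites, ~20–25 glycoform rows, 6
samples, ~2,000 export rows total) runs the full pipeline in about a
second; the t-test calibration uses 10,000 simulated null replicates at
n = 3 per group.  These sizes were chosen so the whole validation suite
exercises every code path while remaining instant to iterate on; all of
them scale by configuration.
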