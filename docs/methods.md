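# Methods

## Scope

`lipidbridge` implements an integrated untargeted/targeted lipidomics
workflow for SWATH-type data-independent acquisition (DIA) LC-MS/MS data:

1. rule-based in-silico MS/MS spectral libraries for algal lipid classes
   (betaine lipids, oxidized phospholipids, glycolipids, lyso-species);
2. untargeted annotation of chromatographic features that enumerates *every*
   library candidate above the score cut-off, not only the best match;
3. an automatic bridge that turns those candidates into an MRM-style
   transition reference library with quantifier/qualifier roles;
4. targeted quantification on product-ion MS/MS chromatograms with a
   posterior confidence score — the stage that resolves co-eluted isomers
   which share a precursor m/z and therefore collapse into a single MS1
   peak.

A seeded synthetic SWATH/DDA run generator provides ground truth for every
stage.

## Formula and ion arithmetic

Monoisotopic atomic masses are hard-coded to six decimals (C 12.000000,
H 1.007825, N 14.003074, O 15.994915, P 30.973762, S 31.972071).  Ion m/z
applies the electron-mass correction (0.000549 Da per charge): a cation is
lighter than its radical-sum, an anion heavier.  Without this correction
several published diagnostic-ion values are missed by ~0.0005 Da in the
wrong direction.  Published tables mix rounding and truncation at the third
decimal, so printed-value comparisons use a ±0.0015 Da band rather than
string equality.  Two values in the source table are treated as typos: the
phosphatidylmethanol head ion prints 167.012 where C4H8O5P− computes to
167.011 (kept, inside the band), and the glucuronosyldiacylglycerol class
ion prints formula "C9H13O7" where only C9H13O8− reproduces the printed
249.062 (formula corrected).

## Lipid composition model

A lipid is a glycerol backbone (C3H8O3) carrying esterified acyl chains and
a class head group.  A chain `c:d+xO` contributes the free fatty acid
CcH(2c−2d)O(2+x); each ester bond loses one water.  The head-group table in
`lipids.py` stores the *net* formula the head adds after its own
condensation loss; entries were derived so that the known neutral formulas
and published fragment ions of each class are reproduced exactly (e.g. the
DGCC head delta C7H15NO4 recovers the neutral-loss series 538.374 /
520.363 / 518.405 / 500.395 for DGCC 18:0-20:4 [M+H]+).  Supported adducts
are [M+H]+, [M−H]− and [M+HCOO]−; formate adducts fragment through the
demethylated [M−CH3]− anion (loss of CH3 + HCOOH, 60.021 Da).  The
phosphatidylserine/lysophosphatidylserine class loss is implemented as
C3H5NO2 (87.032 Da, serine − H2O), which is the loss that reproduces the
published 437.267 fragment of LPS 18:0.

Fragment abundances are template-based, because the experimental libraries
this emulates derived abundances from instrument-specific conditions that
are not published as numbers: first class ion 100, further class ions 50,
chain ions 40, dehydrated chain ions 20, rarely-detected minor ions
(doubly dehydrated oxidized chains) 5, rescaled so the base peak is 100.
The template is overridable per call.  DGTS and DGTA share diagnostic ions
(144.102, 236.149) and map to one library entry named "DGTS/DGTA".

## Acquisition model and simulator

DIA runs repeat a cycle of one MS1 scan plus 21-Da isolation windows
stepped every 20 Da (1 Da overlap) over m/z 100–1250; precursors on an
overlap belong to the higher window (half-open intervals).  The cycle-time
presets are 0.73 s (DIA) and 0.65 s (DDA).  mzML reading and writing is
namespace-agnostic, cvParam-accession-driven, and deterministic: a fixed
simulator seed yields byte-identical files.

The simulator plants Gaussian elution peaks (default σ = 0.05 min, about a
dozen points across the peak at the DIA cycle time) with per-compound MS1
and MS/MS scale factors, multiplicative Gaussian intensity noise, optional
additive baseline noise, and an optional MS/MS saturation ceiling that
emulates the narrower linear range of SWATH channels relative to MS1.  It
does **not** model isotope envelopes, chimeric DDA spectra, adduct
co-elution, retention-time drift between samples, or mass-accuracy drift —
so passing tests demonstrate correctness of the algorithms under the stated
noise model, not performance on real instrument data.

The `dgdg_showcase` scenario plants the three DGDG 34:3 isomers
(16:2–18:1, 16:1–18:2, 16:0–18:3; identical precursor m/z 913.589) at
retention offsets within ±0.02 min in nine pseudo-samples named after algal
taxa.  The dominant-isomer pattern mirrors the phylum split reported for
those taxa; the mixing percentages themselves (60–75 % major) are synthetic
choices, as no composition numbers exist to copy, and the P. lutheri major
is an arbitrary choice among the common case.

## Peak detection

Smoothing is a linear-weighted (triangular) moving average with half-window
equal to the level; edges use a truncated renormalized kernel, so constant
traces are preserved exactly.  Untargeted defaults: level 3, minimum width
5 scans, minimum height 1000; targeted defaults: level 1, minimum height
200 — the lower level keeps closely co-eluting peaks separate, the higher
one stabilizes automated edge detection.

Apexes are local maxima with topographic prominence of at least 5 % of the
apex; smaller bumps (noise on a peak flank) merge into their parent peak.
Edges descend through sub-prominence bumps to the flanking valleys and stop
early below 10 % of apex to prevent creep along noisy baselines.  These
thresholds are relative, so detection is invariant to uniform intensity
scaling.  Heights and trapezoidal areas are measured on the raw trace
between edges found on the smoothed one.  The reported apex retention time
is the intensity-weighted centroid of the smoothed trace above half-max,
which has far less jitter than the raw argmax.  MS1 feature spotting slices
the observed m/z values into 0.1-Da bins and peak-picks the per-bin XICs.
Alignment is greedy centroid clustering (0.05 min / 0.015 Da defaults);
blank filtering flags rows whose sample maximum is below 5× the mean blank
height but retains them tagged.

## Annotation scoring

Measured and library fragments pair greedily by nearest m/z within the MS2
tolerance (0.05 Da for identification).  The dot product uses square-root
intensity weighting over the union of peaks; the reverse dot product
restricts the measured sum to paired peaks; the diagnostic fraction is the
matched share of class-diagnostic ions (1.0 when a reference has none).
Total score = 0.4·dot + 0.3·reverse + 0.2·(100·diagnostic fraction) +
0.1·closeness, where closeness is a Gaussian penalty on precursor m/z and
retention-time deviation scaled by their tolerances.  The 70 % cut-off
applies to the total score, and *all* passing candidates are returned
ranked (ties: higher diagnostic fraction, then smaller precursor error).
The DIA spectrum associated with a feature is the average of its isolation
window's scans across the feature's RT span, baseline-subtracted by the
per-channel minimum — a deliberate simple stand-in for full spectral
deconvolution, sufficient because the co-elution information is recovered
downstream from the MS/MS chromatograms rather than the spectra.  DDA
features use the average of triggered scans matching the precursor within
0.01 Da inside the RT span.

## Transition building and targeted quantification

Each candidate becomes one reference entry.  The quantifier is its most
intense chain-diagnostic fragment at least 2× the MS2 tolerance away from
every fragment of every co-candidate in the same SWATH window (ties go to
the lowest m/z, which selects the SN1 acyl anion for the common
shorter-chain-first compositions); class ions become presence-only
qualifiers ("Q"); remaining products carry library abundances rescaled to
quantifier = 100.  Entries with no unique chain fragment fall back to the
most intense fragment with a warning.  The text format is one row per
(entry, product): name, RT (2 decimals, minutes), precursor m/z, product
m/z (4 decimals), ratio-or-Q; the fixed precision makes round trips
byte-exact.

Quantification extracts the quantifier XIC in the entry's window, smooths
at level 1, picks peaks, and takes the peak nearest the reference RT within
0.1 min.  All product traces share that peak's edges (peak group).  Product
heights are least-squares amplitudes of the quantifier peak shape fitted to
each raw product trace — using every point in the group instead of one
noisy apex sample.  The posterior is
exp(−(Δrt/σ_rt)²)·exp(−(Δamp/σ_amp)²)·1{qualifiers present} with σ_rt =
0.1 min and σ_amp = 15 percent points; detection requires posterior ≥ 0.7.
"Q"-flagged qualifiers are checked for presence (height above the minimum
peak height) but exempt from the amplitude rule.  This functional form is
this package's own stand-in for the published targeted-scoring method it
emulates; the thresholds are the workflow's standard parameters and the
form is configurable.  Co-eluted groups are resolved by quantifying each
entry independently on its unique quantifier trace and normalizing the
quantifier heights within the group; the merged MS1 height is reported
alongside for contrast.

## Problem sizes and numerical choices

The acceptance checks run the nine-sample co-elution scenario at 5 %
multiplicative noise over three seeds (27 runs of ~80 DIA cycles × 59
scans), chosen as a compact but fully representative exercise of the whole
pipeline; the diagnostic-ion mass checks are closed-form.  Degenerate
inputs are defined: empty chain enumerations warn and return an empty
library; features without an MS/MS spectrum are skipped; a missing
quantifier peak yields a detected=false result rather than an error;
plateau maxima take the leftmost scan as apex.

## Known limitations

Stereochemistry, double-bond positions and sn-position isomers beyond the
hyphen notation are not resolved (a platform-level limitation, not a
software one).  Ceramide nomenclature, isotope-pattern prediction,
charge > 1 adducts, FDR estimation for annotations and vendor file formats
are out of scope.  The MS2 composite spectrum is not a deconvolution; with
more than a handful of co-eluted precursors per window its candidate lists
will grow noisy, which is precisely why the targeted stage quantifies on
unique product-ion chromatograms.
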