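# Methods

## Modification model

*O*-2-hydroxyglutarylation is modelled as a single net elemental adduct,
C5H6O4 (+130.0266 Da monoisotopic), on Ser/Thr/Tyr hydroxyls: the free acid
(C5H8O5, 148.0372 Da) minus the water released on ester formation. Which of
the two 2HG carboxyls forms the ester is indistinguishable by mass and is
not modelled. D- and L-2HG are mass-identical; chirality exists only in the
experimental design labels of the quantification stage, never in any mass.

Two diagnostic neutral-loss channels follow from ester-bond cleavage during
collisional fragmentation:

* **channel A**, loss of C5H6O4 (130.0266 Da) — the backbone is restored, so
  a channel-A fragment coincides exactly with the unmodified fragment;
* **channel B**, loss of C5H8O5 (148.0372 Da) — the intact acid leaves,
  producing a dehydro residue 18.0106 Da (one water) below channel A.

The d4 isotopologue (C5H2D4O4) replaces four backbone hydrogens with
deuterium, shifting the adduct — and therefore every modification-bearing
ion — by 4.0251 Da per labelled site. Because both loss channels eject the
labelled adduct, loss-variant ions are *unshifted* between heavy and light
spectra; the isotope-pair validator accounts for this.

All masses derive from a fixed internal table of monoisotopic atomic masses
(CODATA/NIST, ≥9 decimals) committed to the repository, so results are
bit-reproducible offline. Masses are reported at 4 decimal places.
Carbamidomethylation of cysteine (+57.0215 Da, from chloroacetamide
alkylation) is a fixed modification, on by default.

## Digestion

Cleavage is purely positional: cut C-terminal to `cleave_after` residues
unless the next residue is in `suppress_before`. Trypsin uses the Keil rule
(K/R, not before P; a no-Keil variant is provided), GluC cuts after E in
bicarbonate buffer and after E and D in phosphate buffer. Because the
sequential protocol adds phosphate buffer before GluC, trypsin→GluC defaults
to the phosphate rule. Missed-cleavage products are all runs of at most
`max_missed + 1` adjacent fully cleaved fragments (default 2 per enzyme, the
common search-engine setting; the upstream protocol does not state one).
Coordinates are 0-based half-open internally; user-facing site labels are
1-based ("S719" style). Correctness is checked against a brute-force
position-wise cutter on random sequences.

The re-digest loss analysis re-cleaves a modified peptide with a second
protease and flags the modification-bearing fragment when it is shorter than
7 residues (the practical detectability floor used throughout) or contains
no K/R/H and hence no basic site for protonation. Both conditions predict
loss of the site from a sequential-digest dataset.

## Fragmentation and matching

Only b/y series are generated (charge 1, plus 2 for multiply charged
precursors), matching what annotated spectra of this modification class
show; a-ions and internal ions are omitted. Loss variants are emitted only
for ions whose residue span covers a modified site. Precursor-level losses
are treated as pseudo-fragments at precursor − 130.0266 and − 148.0372 so
the diagnostics scoring handles precursor and fragment losses uniformly.

The matcher is deliberately compact — a validation tool for this pipeline,
not a general search engine. Peaks are matched greedily to theoretical ions
within a ppm tolerance (default 10 ppm, TIMS-TOF-class accuracy), each peak
used once; the score is Σ log(1 + intensity/base peak) over matched ions.
Ties break toward fewer modifications, then lexicographically smaller
sequence, so results are deterministic.

Site localization is Ascore-like: for each candidate site, the
site-determining ions (ions whose m/z differs between site hypotheses, loss
variants included) are counted among the matched peaks; the margin between
best and runner-up site is the confidence (`delta`), with +inf as the
sentinel for a single candidate site and 0 meaning ambiguous. A site is
considered well localized at delta ≥ 1.

Neutral-loss detection checks the precursor-loss positions at every charge
up to the precursor charge plus all fragment loss variants, and records the
maximum observed loss-peak intensity as a fraction of the base peak
(base-peak normalization is a package decision; the upstream abundance
baseline is unstated). Cohort summaries bin per-channel abundances as
high (>5%], mid (1–5%], low (0–1%], or absent; the boundaries are
upper-inclusive, so exactly 5% bins as mid.

Isotope-pair validation accepts a light/heavy duo when (i) precursor
neutral masses differ by 4.0251 Da per labelled site within tolerance,
(ii) retention times agree within 1 min (deuteration does not move
reversed-phase elution at this resolution), and (iii) the matched ladders
show identical fragmentation: mod-free backbone ions must be matched on both
sides at equal m/z, mod-bearing backbone ions must shift by 4.0251/z, and
loss variants must be unshifted. Pairing is greedy on (mass error, RT error)
with each spectrum joining at most one pair, which makes it symmetric under
swapping the light and heavy inputs. The d4 reagent is racemic, so pairs
validate modification chemistry, not chirality.

## Quantification

Peak areas are normalized to total ion current (column sum by default, or
supplied TICs) and rescaled by the median TIC. A peptide responds to a
treatment when fold change (mean treated / mean control on normalized
areas) exceeds 1.2 **and** the two-tailed two-sample t-test gives p < 0.05,
with no multiple-testing adjustment (a Benjamini–Hochberg option exists but
is off by default, matching the unadjusted upstream rule). Welch's
(unequal-variance) test is the default; the pooled-variance classical test
is available via `equal_var=True`. At n = 3 per group Welch is measurably
conservative (empirical type-I ≈ 0.033 at nominal 0.05), which is the
safer direction for discovery but matters when checking calibration — the
calibration test in this package therefore uses the pooled test as the
exactly calibrated reference and asserts Welch is no more liberal.

A peptide is assigned to an enantiomer series when that series — and not the
other — responds: at least `min_passing_doses` (default 2) dose levels pass
the FC/p gate against vehicle and the fold changes are non-decreasing with
dose. "Non-decreasing" allows dips within a 10% relative tolerance: with
lognormal replicate noise at CV 0.15 and n = 3, the standard deviation of a
ratio of adjacent dose fold-change estimates is ≈ 12%, so a strict ordering
would reject a substantial fraction of genuine responders on noise alone.
Both series responding yields "shared"; neither, "ambiguous".

High-confidence filtering retains peptides with the same non-ambiguous call
in ≥ 2 independent dataset groups and drops cross-group enantiomer
conflicts. This is a deliberately simple cross-validation stand-in for a
more elaborate multi-group workflow whose details are not public.

Occupancy is modified/(modified + unmodified) peak area — semi-quantitative,
since modification can change ionization efficiency. The retention-time
shift of modified peptides is tested with a paired two-tailed t-test on
(modified − unmodified) RT deltas; zero-variance deltas are flagged
degenerate rather than tested.

## Synthetic data generator

The generator emulates a chiral metabolite-feeding study: dose gradient
0/5/10/20 (arbitrary units mirroring mM) for each enantiomer plus vehicle,
3 biological replicates, lognormal replicate noise with CV 0.15, planted
modification sites drawn so marginal S:T:Y usage matches 0.6:0.3:0.1, and
enantiomer labels D/L/shared at 0.45/0.45/0.10.

Planted top-dose fold changes are drawn uniformly from [2, 4]. This default
follows from a power analysis of the classification rule itself: with
FC > 1.2, p < 0.05, n = 3 and CV 0.15, per-dose power is only ≈ 0.55 at a
true fold change of 1.5 and ≈ 0.87 at 2.0, so reliably recoverable planted
effects must sit at 2 or above — consistent with the several-fold increases
a 20 mM exogenous metabolite feed produces. The dose-response shape is
linear in log(1 + dose) between 1 at dose 0 and the true fold change at the
top dose; the factor is applied only to the matching enantiomer series
(both for "shared").

Abundance matrices include, besides each planted peptide's modified row and
its unmodified counterpart (baseline ratio set by the occupancy parameter,
default 0.10), optional non-responding background rows from the rest of the
digest. The background matters: in a real measurement the bulk proteome
dominates every sample's TIC, so normalization is nearly neutral; a matrix
containing only responding peptides would let the planted effects inflate
the treated samples' TIC and attenuate every fold change by construction.

Spectra contain the full b/y ladder (unit base intensity, lognormal jitter
CV 0.2), neutral-loss peaks per channel with emission probabilities 0.9/0.7
at log-uniform relative abundance in [0.005, 0.2] (so the cohort spans the
high/mid/low diagnostic bins), and 20% spurious uniform peaks. Retention
time is a Kyte–Doolittle hydropathy surrogate mapped onto a 2–58 min
gradient plus a fixed +1.5 min shift for modified peptides — qualitatively
reproducing the increased hydrophobicity of the esterified residue without
attempting quantitative logP modelling.

All randomness flows from one seed through named substreams, so identical
configurations produce byte-identical FASTA/MGF/table files. The
ground-truth ledger is written alongside the data but is read only by test
harnesses and recovery reports, never by analysis stages.

### What the generator does not emulate

Chromatographic peak shapes, isotope envelopes beyond the single d4
variant, ion-mobility dimensions, chimeric spectra, missing values, and
between-replicate batch effects. Passing tests therefore demonstrate the
correctness of the analytic chain under the stated statistical structure,
not instrument-grade realism; real-data performance will be dominated by
search-engine and chromatography effects the generator abstracts away.

## Numerical choices and degenerate inputs

* ppm windows are relative to the theoretical m/z; nearest-peak ties go to
  the smaller error, matching order is deterministic.
* Empty spectra score 0; spectra with no precursor-compatible candidate are
  dropped and reported, not errored.
* Zero control means flag a peptide as unclassifiable rather than producing
  an infinite fold change; zero/negative TICs raise with the sample named.
* Noiseless (CV 0) simulations make the t-test degenerate (NaN p); the
  noiseless recovery checks therefore gate on fold change only.
* Problem sizes in the shipped tests and the acceptance script (≈200
  planted peptides for recovery, 1000 null peptides for calibration, 200
  random sequences for the digestion oracle, 10–25 spectra per spectral
  check) were chosen as the smallest sizes at which the binomial tolerances
  of the assertions are meaningful.

## Known limitations

The matcher has no FDR model and is not meant for open searches; the
high-confidence filter is a stand-in; occupancy ignores ionization-
efficiency differences between modified and unmodified forms; K/C/D/E
esterification targets are representable in `ModificationSpec` but the
shipped registry covers S/T/Y only.
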