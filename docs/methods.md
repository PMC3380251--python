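# Methods

## Scope and model

`hrmscreen` implements qualitative screening of small molecules (the bundled
demo database is a pesticide panel) from LC coupled to single-stage
high-resolution MS acquiring two continuously alternating full-scan events:
event 1 without fragmentation and event 2 with all-ion (HCD) fragmentation
of everything in the source, both over m/z 55–1,000 at a 1 Hz overall rate.
Detection is database-driven: for each analyte the primary diagnostic ion
(an electrospray adduct of the neutral molecule) and a secondary diagnostic
ion (an isotope of the adduct, measured in event 1, or a fragment cation,
measured in event 2) are extracted as ±ppm ion chromatograms and tested for
a coincident chromatographic peak.

## Diagnostic-ion chemistry

Monoisotopic masses are sums of the lightest isotope masses (for the
elements in scope — C, H, N, O, P, S, F, Cl, Br, I, Na — the lightest
isotope is also the most abundant, so the two conventions coincide).  Ion
m/z is `(mass(neutral + delta) − n_e·m_e)/z` with the electron mass
m_e = 0.00054858 Da subtracted once per removed electron; the supported
species are [M+H]+, [M+NH4]+, [M+Na]+, isotope-shifted protonated molecules
("(M+2)+H", "(M+4)+H" for analytes whose monoisotopic ion is not the most
abundant), and bare fragment cations.

Isotope patterns are computed by exact polynomial expansion: for each
element the n-atom distribution over integer nominal shifts is built by
convolving the single-atom distribution, and element distributions are then
convolved together, tracking per-shift probability and probability-weighted
mass.  All fine structure within one nominal shift (e.g. 13C2 vs 34S at
M+2) is aggregated into a single centroid, which matches acquisition at
resolving power 50,000 where that fine structure is unresolved.  The
aggregation by integer shift `round(m_isotope − m_lightest)` is equivalent
to a ±0.3 Da mass-defect window around `monoisotopic + k·1.00336` for these
elements.  The computation is exact (no Gaussian approximation, no pruning)
and linear in atom count, so no practical size bound applies to
small-molecule formulas.  Isotope masses and abundances are pinned to one
compilation (CIAAW 2013, `data/isotopes.csv`); other compilations can move
computed masses in the 5th decimal.

The most abundant isotope (shift k ≥ 1 maximising relative abundance, ties
toward smaller k) is the recommended secondary ion where no good fragment
is known: M+2 for Cl/Br-containing molecules and for S-rich ones, M+1
otherwise.

## mzML representation

Standard mzML has no concept of alternating scan events, so event-2 spectra
are written and read as MS-level-2 scans with no precursor selection; event
1 as MS level 1.  Runs are centroid-only (profile input is rejected), and
run-level metadata (run id, matrix label, scan range, scan period) travels
as a JSON userParam.  The reader accepts standard centroid mzML with 32- or
64-bit float arrays, zlib-compressed or not.  All times are minutes
internally.

## Peak detection and screening

Extracted ion chromatograms sum all centroid intensities within a symmetric
multiplicative ±ppm window (default 5 ppm) around the *theoretical* m/z,
one point per spectrum of the chosen event; multiple in-window centroids in
one scan are summed and their intensity-weighted mean m/z is kept for
mass-error reporting.

Peak detection within the ±0.5 min retention-time window: the baseline is
the lower quartile of the (3-point smoothed) in-window trace; a peak
requires at least 3 consecutive raw points above max(baseline, noise
floor), so a single-scan spike is never a peak.  The noise floor
(`min_height`, default 100 intensity units) represents the instrument
noise level below which single centroids are not meaningful.  Regions with
several local maxima of prominence ≥ half the floor are split at their
interior minima — this resolves an analyte eluting on the shoulder of a
larger near-isobaric interference, up to the point where the merged trace
genuinely has no second maximum.  Areas are trapezoidal integrals
(intensity × minutes) over the peak bounds extended one scan each side.

Screening strategies:

* **max-scan one-ion** — report the most intense in-window scan of the
  primary ion; no peak requirement.  This reproduces the high
  false-positive behaviour of naive automated screening (spikes and
  spectral-leakage artifacts all count).  Its "response" is the scan
  intensity; ties at the maximum take the first scan in time.
* **peak one-ion** — the primary ion must form a chromatographic peak; the
  response is the peak area.
* **response thresholds** — hits are kept when response is strictly greater
  than either a fixed global cutoff or a per-analyte threshold set at half
  the lowest response observed for that analyte across the reference
  matrices at one spike level.
* **two-ion** — primary peak (event 1) and secondary peak (its designated
  event) with apex retention times within 0.05 min.  Among multiple peak
  pairings the one minimising the apex difference is chosen.  The ±30 s
  window is applied to peak apexes.

The secondary isotope m/z is the aggregated-pattern centroid of the full
ion composition, not `monoisotopic + k·1.00336`.

## Identification

Identification requires two diagnostic ions including at least one
fragment, primary-ion mass accuracy ≤ 5 ppm, an ion ratio (fragment area
from event 2 over precursor area from event 1) within tolerance of a
reference ratio, and a relative-retention-time (RRT) criterion against an
internal reference compound (diuron in the demo panel, chosen for its
median, stable retention).  Isotope-only detections are reportable but
never identifiable.

Two ratio-tolerance schemes: the EU tiered scheme — reference ratio
(in percent) in (50, ∞] → ±20 %, (20, 50] → ±25 %, (10, 20] → ±30 %,
(0, 10] → ±50 % — and a generic flat ±50 %.  Boundary values take the wider
tolerance, and the tier is decided by the *reference* ratio, not the
observed one.  Ratios above 1 (fragments more intense than the precursor,
which happens) are accepted into the >50 % tier.  The printed tier table
nominally defines the ratio as "lower ion over higher"; this package uses
the fragment/precursor orientation throughout because that is the ratio the
two-event acquisition actually measures, and records it per result.  The
reference ratio source is configurable (solvent-standard mean by default;
a matrix mean is more representative when fragment ratios are attenuated in
matrix, and the choice can move an analyte across the 10 % tier boundary).
RRT deviation is `100·|RRT_obs − RRT_exp|/RRT_exp`; both the established
±2.5 % criterion and the stricter ±1.0 % are available.  If the reference
compound is not detected in a run, the RRT criterion is skipped for that
run rather than failing every analyte.

## Validation statistics

Over a design of N ≥ 20 commodities × (blank + spike levels), per-analyte
statistics use the 95 %-confidence rule `ceil(0.95·N)` detections (19 of
20, 20 of 21; the integer rule for N ≠ 20 is this package's conservative
reading and is configurable in effect through N).  The screening detection
limit (SDL) is the lowest level meeting that rule on the detected flags;
the limit of identification (LOI) the same on the identified flags, so
LOI ≥ SDL always.  False positives are detections in blank runs of analytes
not present (a detection at a wrong retention time in a blank still
counts); false negatives are spiked combinations with no detection.  Spike
levels are compared as exact decimals.

## The synthetic-data generator

The generator emulates the statistical structure reported for real
vegetable/fruit screening data, and is the ground-truth oracle for every
screening/identification/validation test:

* Gaussian chromatographic peaks (σ = 3 s default; optional split-peak mode
  emulating early-eluting shape degradation) sampled on the 1 Hz
  alternating grid.
* Response factors log-spaced over a factor of 600 across the panel — the
  observed sensitivity spread — at areas-per-mg/kg chosen so that the
  weakest analytes straddle the detection floor at 0.01–0.20 mg/kg under
  matrix suppression, which is what makes SDLs informative.
* Matrix suppression per commodity, log-uniform in 1–10.
* Isotope envelopes as theoretical pattern × an instrument bias factor:
  M+1 bias 0.47 at C5 rising linearly to 1.0 at C41+, M+2 bias uniform in
  0.8–1.0; per-run ratio noise lognormal at 8 % RSD.
* Event-2 fragment ions at the solvent fragment/precursor ratio × a matrix
  attenuation factor (mean 0.83) × lognormal noise at 20 % RSD, plus a
  residual precursor.
* Mass errors per centroid, Gaussian σ = 1.5 ppm truncated at ±5 ppm, so a
  ±5 ppm extraction window never loses a planted ion.
* Matrix artifacts: near-isobaric interferences (within ±3 ppm of a target
  analyte, no secondary ion), single-scan spike artifacts at analyte
  masses, spectral-leakage satellites flanking intense event-1 ions
  (±0.0165 Da at 0.2 % of the parent), and sparse exponential baseline
  noise (mean 30 counts, ~15 centroids per spectrum).
* All randomness flows from one seed through a `SeedSequence` spawn per
  run; identical seeds give bit-identical runs.

What it does **not** emulate: real electrospray physics, retention-time
drift between runs, correlated matrix chemistry, peak tailing beyond the
simple options, or the composition of a real 556-compound database (a
12-compound catalogue of real pesticides with their published retention
times, formulas, and diagnostic ions stands in).  Passing tests therefore
demonstrate the correctness and the qualitative behaviour of the screening
logic under the stated statistical structure, not instrument-level
performance on real extracts.

### Detectability oracle

Tests compare pipeline results against expectations derived from the
planted truth.  Because planted chromatography is fully known, the expected
two-ion outcome is computed from the noise-free analytic traces (analyte
Gaussian plus any co-eluting interference inside the primary mass window,
evaluated on the scan grid) passed through the same detection rule.  This
correctly predicts the two dominant false-negative mechanisms: signals
below the noise floor, and interference-merged peaks whose displaced apex
breaks the 0.05-min coincidence.  Residual disagreement comes from baseline
noise rescuing or sinking signals within a few counts of the floor, which
is why end-to-end agreement is asserted at the 95 % level rather than
exactly.

## Problem sizes

The default simulated experiment is 21 commodities × (blank + 0.01, 0.05,
0.20 mg/kg) = 84 runs of 20 min at 1 Hz (2,400 spectra each) over a
10-analyte panel; it generates in ~10 s and screens in a few seconds, so
the whole test suite runs in a few minutes on one core.  These sizes were
chosen to exercise every mechanism (floor-limited SDLs, interference
collisions, tier-boundary ratios) at desk scale; the screening chain itself
is linear in spectra × analytes and handles larger databases unchanged.

## Numerical choices

* Strict ">" for response thresholds.
* ppm windows are inclusive at the boundary; tier boundaries take the wider
  tolerance.
* Coincident centroids (< 1e-7 Da apart) are merged when assembling
  simulated spectra so m/z stays strictly ascending.
* Retention-time ties between multiple max-intensity scans: first in time.
* Degenerate inputs raise: empty runs, profile spectra, unknown elements,
  zero formula counts, negative ion compositions, levels < 0, panels or
  designs below the minimum size.
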