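# Methods

## The problem and the approach

Untargeted LC-MS of plant extracts acquired in DIA mode (alternating
low-energy and high-energy scans, e.g. Waters MS<sup>E</sup> or Orbitrap
AIF) records every precursor *and* every fragment as continuous
chromatographic signal, but with no precursor isolation the link between
the two channels is lost. For glycosylated flavonoids that link is highly
structured: the fragment channel carries aglycone diagnostic ions whose
mass difference to the precursor is a glycosyl neutral loss. diaflav
exploits this by treating the MS² channel as a first-class feature stream
— the identical detection chain runs on both channels — and then
reconstructing precursor–fragment relationships from co-elution and peak
shape alone.

## Fragmentation model

All fragment m/z values are on the deprotonated [M − H]⁻ basis, negative
mode, with the electron mass ignored (deprotonation delta = proton mass
1.007276 Da). This convention reproduces the tabulated reference ppm
errors to better than 0.1 ppm, which is why it was retained over the
electron-corrected alternative.

* Heterolytic O-cleavage: fragment = M(aglycone) − 1.007276. The neutral
  loss is the intact glycosyl residue (condensed sugar: glucose − H₂O =
  162.0528, etc.).
* Homolytic O-cleavage: fragment = heterolytic − 1.007825 (one hydrogen
  *atom*), the radical anion [Agly − 2H]˙⁻. The neutral loss is the
  glycosyl mass + 1.007825, because the hydrogen migrates to the sugar.
  Sugar matching applies this correction whenever the matched fragment is
  the radical species; C-entries are never radical-corrected, as
  C-glycosides do not undergo homolytic cleavage at a C–C bond in this
  model.
* C-glycoside cross-ring cleavage: the aglycone retains +42.0106 Da
  (C₂H₂O) or +72.0211 Da (C₃H₄O₂) per C-bound sugar; for two sugars the
  residue sums {84.0211, 114.0317, 144.0423} are enumerated and
  deduplicated, giving 7 fragment records per aglycone (2 O-type + 5
  C-type). The corresponding partial losses per sugar are 120.0423/90.0317
  (hexosyl) and 90.0317/60.0211 (pentosyl); di-C losses are sums of two
  partials, with the 210.0739 Da (90 + 120) combination named explicitly
  because it is the diagnostic schaftoside-type loss. Generation stops at
  two sugars — di-C-glycosides are the practical ceiling for these
  databases.

The +42.0106 reading of the "C₂H₃O residue" convention is deliberate: on
the deprotonated-ion basis it reproduces the reference fragments
311.0555/353.0673, while a neutral-residue reading does not.

The default fragment database covers the backbones kaempferol (sharing a
formula with datiscetin and luteolin), quercetin, catechin(/epicatechin),
apigenin, taxifolin, naringenin and myricetin. Exact-mass isomers are
represented once: formula-level m/z cannot separate them, and isomer
discrimination is delegated to fragmentation-pattern comparison
(`annotate.jaccard_isomer_score`, the Jaccard index of matched fragment
sets) rather than to wishful naming.

Adducts for the MS¹ search: [M − H]⁻, [M + Cl]⁻, [M + Br]⁻ and
[M + FA]⁻ (read as formate, [M + HCOO]⁻, delta +44.99820 — the standard
convention for formic-acid mobile phases), expanded to 2 molecules/cluster
and charge 2 for deprotonation.

## Detection parameters

Defaults follow a published MZmine-style parameter set for 10-minute UPLC
gradients; every value is a `DetectionConfig` field. The MS² variant
differs only in the minimum absolute height.

| stage | parameter | MS¹ default | MS² |
| --- | --- | --- | --- |
| mass detection | noise level | 3×10² | same |
| EIC builder | min consecutive scans | 5 | same |
| | min intensity (consecutive) | 8×10² | same |
| | min absolute height | 8×10³ | 4×10³ |
| | m/z tolerance | 0.005 Da or 10 ppm (max of both) | same |
| resolver | chromatographic threshold | 0.85 | same |
| | min RT search range | 0.035 min | same |
| | min top/edge ratio | 1.8 | same |
| | peak duration | 0–2 min, ≥ 5 scans | same |
| ¹³C filter | m/z 0.003 Da/5 ppm, RT 0.05 min, z ≤ 1 | | same |
| join aligner | m/z 0.007 Da/12 ppm (w=3), RT 0.045 min (w=2) | | same |
| gap filling | intensity tol 0.2, m/z 0.005 Da/7 ppm, RT 0.04 min, ≥ 4 scans | | same |

The MS² noise level is not separately specified in the source parameter
set; it stays at 3×10².

Interpretation choices where the originals are under-specified (all
configurable):

* Dual tolerances ("0.005 m/z or 10 ppm") use the **maximum** of the
  absolute and relative windows, matching MZmine semantics.
* The EIC builder approximates ADAP with deterministic intensity-seeded
  greedy grouping: seeds descend by intensity, extend scan-by-scan in both
  directions to the nearest unused centroid within the window, tolerating
  one missing scan. Only centroids reaching the minimum absolute height
  seed (a chromatogram that never reaches it is discarded anyway);
  equivalence is asserted against exhaustive grouping on toy runs, not
  against MZmine internals.
* "Chromatographic threshold 0.85" is read as a baseline quantile: points
  below the 15th intensity percentile of the EIC bound peak regions.
  Within a region, splits occur at retention-time-windowed local minima
  (the minimum of its ± half-search-range window).
* Gap-fill "intensity tolerance 0.2" is read as the maximum relative
  violation of monotonicity along a flank of the re-integrated profile.
* Peak area is trapezoidal integration over minutes; feature m/z is the
  intensity-weighted mean of its trace centroids.
* Alignment is greedy best-score first (score
  `3·(1−|Δm/z|/tol) + 2·(1−|ΔRT|/tol)`), ties by smaller |Δm/z| then input
  order; deterministic by construction.

## Linking and assignment

Precursor–fragment linking formalizes what is otherwise manual inspection:
candidate MS¹ rows within 0.045 min (the aligner RT tolerance; no separate
value exists) of an annotated MS² row, peak-shape similarity = Pearson
correlation of the two traces interpolated onto their shared RT grid,
default threshold 0.8 (a choice with no stated reference value; it is the
knob to lower for noisy real data). Fragments more intense than their
precursor are flagged, not discarded. Sugar candidates within 0.01 Da of
the expected loss (observed deviations in reference data reach ~0.003 Da)
are all retained, ranked by |Δloss|, and the best names the call;
ambiguous MS¹ candidate lists are reported in full, joined by "; ".
MS² aglycone features with no surviving precursor partner simply produce
no glycoside call (they remain visible in the MS² feature table).

## Synthetic cohorts: what they emulate and what they do not

`synthgen` emulates the features this pipeline actually consumes:
alternating-scan DIA structure, Gaussian elution profiles shared between a
precursor and its fragments (scaled by per-fragment yields 0.3–0.6), an
M + 1 isotope satellite at 1.1% per carbon, per-point Gaussian m/z jitter
(2 ppm), and a uniform-random noise floor (10 centroids/scan at ~200
counts). Study-condition defaults: 10-min runs, 10 Hz per channel, peak
sigma 0.02 min (plausible UPLC widths), spike heights 2×10⁴–2×10⁵, apexes
on a jittered grid across 1.5–6 min (the elution window of interest)
spaced well beyond the link tolerance.

Not emulated: chemical background and correlated matrix interference,
retention-time drift between samples, detector saturation, profile-mode
peaks, in-source fragmentation, and co-eluting isomers. Passing the
synthetic acceptance (≥ 90% recall and precision on a 20-spike, 3-sample
cohort) therefore demonstrates the *mechanics* — detection, alignment,
linking, loss arithmetic — are correct; it does not certify performance on
real chromatograms, where the correlation threshold and the databases do
the heavy lifting.

## Numerical and degenerate-input choices

* Element masses from the NIST table (via pyteomics); sugar dictionary
  entries validated against their compositions to 1e-4 Da.
* mzML written uncompressed as 64-bit little-endian floats so round-trips
  are bitwise; the reader accepts 32-bit and zlib payloads. RT unit is
  minutes everywhere (seconds converted on read).
* Empty spectra, empty feature lists and empty annotation sets flow
  through as empty results; undefined quantities (flavone:flavonol ratio
  with zero flavonols, correlation of a constant profile) raise or are
  excluded with a recorded reason rather than silently coerced.
* De-isotoping walks chains (M+1 anchors M+2) and can only ever remove
  features strictly less intense than their anchor, so the most intense
  member always survives.
* Determinism: a fixed seed fixes the cohort bit-for-bit; detection and
  alignment are seed-free and deterministic given identical input.

## Known limitations

* Formula-level annotation: exact-mass isomers are indistinguishable
  except by the Jaccard fragment-pattern score; attachment positions are
  out of scope by design.
* Negative mode only; positive-mode fragment rules are not modelled.
* The greedy EIC builder and aligner are faithful to the configured
  tolerances but are not drop-in re-implementations of ADAP/MZmine
  internals; agreement is at the level of detected features on clean
  signal, verified against brute-force oracles.
* No RT warping: cross-sample alignment relies on the join tolerance, so
  gradients must be reproducible to ~0.045 min.
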