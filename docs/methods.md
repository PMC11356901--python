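# Methods

## Model and procedure

The pipeline implements post-targeted screening: annotation proceeds from
a precomputed candidate list rather than from feature discovery. Its
stages and assumptions are:

1. **Exact-mass arithmetic.** Monoisotopic masses are sums over a shipped
   element table (C = 12 exactly, H = 1.00782503207, N = 14.0030740048,
   O = 15.9949146196 Da; `src/msescreen/data/element_masses.tsv`). Singly
   charged protonation adducts use the proton mass 1.00727646688 Da with
   the electron mass folded into the proton delta; this reproduces the
   leucine-enkephalin lock masses 556.2766/554.2620 at four decimals.
   The ppm sign convention is (observed − theoretical)/theoretical; the
   source table's printed error column is internally inconsistent (two
   rows share mass and formula yet print different signed errors) and is
   treated as non-normative provenance, never consumed by computation.

2. **CHNO decomposition.** An observed ion m/z is explained by exhaustive
   enumeration over bounded element counts (defaults C ≤ 40, H ≤ 80,
   N ≤ 1, O ≤ 8). N ≤ 1 reflects the chemistry in scope: the only
   nitrogenous class is the primary fatty amide. For each (C, N, O) the
   admissible hydrogen counts are solved directly from the mass window,
   so the search is complete over the bounds; candidates whose RDBE is
   negative or non-integral (impossible even-electron CHNO neutrals) or
   outside [0, 12] are dropped. Ranking is by |ppm error|, then fewer
   heteroatoms, then fewer atoms. Enumeration rather than heuristics was
   chosen because the bounds are small enough that equivalence to a
   brute-force oracle is provable (and is asserted in the tests).

3. **Screening.** Default tolerance ±7 ppm (precursor), ±0.01 Da
   (fragments). The fragment window is absolute, not ppm: printed
   high-energy fragment masses deviate from theory by up to ~50 ppm
   (e.g. the amide head ion printed 116.1123 vs theoretical 116.1070),
   so precursor-grade tolerance would reject genuine evidence.
   Confirmation requires ≥1 diagnostic fragment except for MFA/DFA,
   whose deprotonated molecule survives even high collision energy and
   may confirm alone (a config switch, `precursor_only_classes`).
   When several peaks match one target, the one with smallest |ppm error|
   is kept (ties to higher intensity), mirroring extracted-ion-
   chromatogram apexing. RT is never a gate — only isomer ordering uses
   it. The minimum-intensity threshold for calling presence is exposed as
   config with default 0, since the source protocol does not state one.

4. **Classification.** Decision order FAA → CAD → DFA → MFA: nitrogen
   content and aromatic-grade RDBE are unambiguous, so they go first; the
   oxygenated-DFA vs polyhydroxy-MFA boundary is the only contested one
   and is resolved last. A library hint, when present, adjudicates that
   boundary in both directions; fragment evidence (a matched dicarboxylic
   loss) decides only hint-free, and hint-free contested rows with no
   evidence are flagged ambiguous (2 of 166 on the packaged table).
   The CAD rule (N = 0, RDBE ≥ 4, 7 ≤ C ≤ 15) is deliberately broad so it
   covers benzoic acids, coumarin, syringaldehyde and abscisic acid; CAD
   membership is primarily library-driven in practice. A keto group
   cannot be distinguished from a double bond by formula alone, so
   `oxo` is set only from the library (compound name) or an explicit
   diagnostic, and moves one RDBE from the chain to the carbonyl count.
   Chain unsaturation = RDBE − carbonyls; oxygen excess = O − (2 MFA,
   4 DFA, 1 FAA). "Saturated" means zero chain C=C, zero excess oxygen
   and no keto flag.

5. **Chemometrics.** All multivariate summaries operate on the binary
   extracts × compounds matrix — occurrence is the only published data
   for the worked system. PCA column-centers but does not unit-variance
   scale (scaling binary columns explodes rare-compound influence; a
   switch exists). Constant columns are removed first; a single
   informative column yields the rank-one result rather than an error
   (zero informative columns is the degenerate case). Ward clustering
   uses scipy's variance-minimizing criterion on Euclidean distances
   (the squared-distance-updating, Ward.D2-style formulation); rows are
   sorted lexicographically first so ties and output are deterministic
   and permutation-invariant. Venn partitioning assigns each compound to
   the exact subset of extracts containing it; regions are disjoint and
   cover all compounds.

## The packaged identification table

`src/msescreen/data/ctl_identifications.tsv` transcribes the 166-row
identification table for the five supercritical-CO₂ extracts (CTL1-CTL5,
100-500 bar at 55 °C). Transcription policy:

* Unicode minus/dash variants and ion-notation variants are normalized at
  transcription; glued fragment lists are tokenized; duplicate printed
  names are disambiguated with a "(peak N)" suffix in the `label` column.
* A curated neutral `formula` column accompanies each row. For 157 rows
  it is the best 7-ppm decomposition of the printed observed mass that is
  consistent with the printed class. Nine rows (peaks 8, 13, 16, 17, 38,
  45, 50, 72, 87) print masses admitting no such composition — e.g.
  nonanamide's 158.1559 sits ~12 ppm from C₉H₁₉NO+H — and their formulas
  follow from the compound names instead. At run time the classifier
  always re-decomposes; the curated formula is used for screening and as
  a recorded fallback when decomposition fails.
* One presence cell is corrected: peak 103 (nonadecanedioic acid) prints
  "−" for CTL4, which contradicts two prose statements of the source
  (142 compounds common to all extracts; CTL4 richest in compounds).
  With that single cell set to "+", the common region is 142, CTL4's
  total (159) is strictly maximal, and every other published region
  count (CTL5 = 151; exclusives 1/1/1/3/0) matches. The verbatim printed
  flags are preserved per row in `printed_flags`; the correction is the
  only divergence, and a test pins that fact.
* Formula-driven bookkeeping trusts compositions over names: e.g. the
  row named "undecanedioic acid" at m/z 213.1128 decomposes to C₁₁H₁₈O₄
  (one chain double bond), and the 311.2224 "octadecanedioic" rows are
  octadecenedioic by composition. The saturation tallies (19 saturated
  MFA, 16 saturated FAA, 13 singly unsaturated DFA, 8 oxygenated DFA,
  28 saturated DFA) all derive from the formulas, not the names.

## Synthetic data: what it emulates and what it does not

The generator enumerates homologous series per class over a chain range
(default C9-C24) with 0-2 double bonds (0-1 for DFA) and a small aromatic
panel for CAD, then emits per-extract peak lists: precursor m/z with
Gaussian ppm noise (default s.d. 2 ppm — well inside the 7 ppm window, as
befits a calibrated Q-TOF), class-consistent diagnostic fragments with
Gaussian absolute noise (3 mDa), log-normal intensities, and retention
times linear in chain carbons (0.6 min/C) minus 0.4 min per double bond
with 0.02 min jitter — encoding the qualitative rule that saturated
homologs elute later the longer the chain. The presence design holds 80%
of compounds in every extract, Bernoulli cells elsewhere. Decoy peaks are
placed ≥ 25 ppm from every target.

Not emulated: chromatographic peak shapes, isotope envelopes, in-source
fragmentation, co-elution interference, intensity structure across
extracts. Passing end-to-end tests therefore demonstrates correctness of
the screening arithmetic and rule logic under realistic mass error — not
robustness to the full messiness of real acquisitions.

## Numerical choices

* Fragment/loss matching: absolute ±0.01 Da windows; first matching
  fragment per rule is recorded.
* Isomer labels: ascending RT; ties by descending intensity, then
  ascending m/z, making labels a pure function of the detection set.
* Decomposition ties: heteroatom count, then atom count, after |ppm|.
* All simulation randomness flows from one seeded generator; a fixed
  seed gives byte-identical output files.

## Known limitations

* The multivariate story on occurrence data differs from the published
  intensity-based one: with presence/absence, the least-rich extract
  (CTL5, 151/166 compounds) is necessarily the PCA/Ward outlier, whereas
  the intensity-based figures separate CTL4. The package reports the
  occurrence-based result and does not attempt to reconstruct
  intensities; the published per-mode variance percentages are likewise
  not reproducible from occurrence data and are not targeted.
* Out of scope by design: isotope-pattern scoring, multiply charged
  ions, adducts beyond (de)protonation, elements beyond CHNO, double-bond
  position/geometry, spectral-library matching, RT alignment across runs.
* The classifier separates keto from hydroxy oxygenation only via library
  knowledge or explicit diagnostics; formula alone cannot.
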