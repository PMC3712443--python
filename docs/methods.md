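# Methods

`floralsignals` analyses the convergence of floral signals between rewardless
flowers and the rewarding species they appear to imitate, from the viewpoint
of their shared pollinators. Four analyses are chained: (i) reflectance
spectra are mapped into the colour-hexagon space of trichromatic hymenopteran
vision; (ii) community colour structure is tested with a focal-species
distinctness permutation test and a UV-green group contrast; (iii) floral
outlines are compared by open-curve eigenshape morphometrics with canonical
variates discrimination; and (iv) the bee-UV-green colour state is mapped onto
phylogenies by parsimony to bracket its number of independent origins. A
synthetic-data module supplies spectra, outlines, and trees with known ground
truth, so every stage is testable end to end without field data.

## Colour-hexagon model of bee vision

A stimulus with reflectance S(λ), viewed under illuminant photon flux D(λ)
against an adaptation background I_B(λ), excites receptor class *i* (spectral
sensitivity S_i(λ)) with quantum catch

    P_i = R_i Σ_λ S(λ) S_i(λ) D(λ) Δλ,     R_i = 1 / Σ_λ I_B(λ) S_i(λ) D(λ) Δλ.

The von Kries factor R_i normalises each receptor to the background, which
therefore excites every class equally (P = 1). Phototransduction saturates as
E = P / (P + 1) ∈ [0, 1), and the three excitations (E_UV, E_B, E_G) place the
stimulus at

    x = (√3/2)(E_G − E_UV),     y = E_B − (E_UV + E_G)/2,

the hexagon chromaticity coordinates. Euclidean distance in (x, y) predicts a
bee's ability to discriminate two colours; behavioural work puts the reliable
discrimination threshold at 0.1 hexagon units, and `is_distinguishable` is
strict at that boundary (a distance of exactly 0.1 is *not* distinguishable).

Choices the model requires but field studies rarely report, all pluggable:

* **Receptor sensitivities** — default is a log-normal visual-pigment
  template (Gaussian in log wavelength, log-domain width 0.08, peak
  normalised to 1) at λ_max = 344, 436, 544 nm, a honeybee-like trichromat.
  Tabulated curves can be supplied as CSVs.
* **Illuminant** — a standard-daylight (D65-like) spectral power table,
  shipped at 10 nm resolution and converted to relative photon flux by
  multiplying with wavelength.
* **Background** — a green-leaf reflectance curve. The shipped
  `leaf_background_synthetic.csv` is parametric (UV/blue floor 0.045, green
  bump at 554 nm, chlorophyll absorption dip at 672 nm, red-edge onset), built
  to the qualitative shape of foliage spectra; it is synthetic, not a
  measured leaf.
* **Integration** — rectangle rule on a uniform 300–700 nm grid at 1 nm.
  At this density the rule's error is far below any biological effect.
* **Sectors** — hue angle θ = atan2(x, y), measured clockwise from the blue
  vertex, is binned into six 60° categories (blue, blue-green, green,
  UV-green, UV, UV-blue) with boundaries at odd multiples of 30°, half-open
  on the upper side. Hue is undefined near the centre, so loci within 0.05
  hexagon units of the origin are labelled achromatic; the radius only
  affects categorisation, never distances.

Because receptor curves, illuminant and background are not uniquely fixed by
any field study, absolute locus positions are configuration-dependent;
distances between loci computed under one configuration are internally
consistent, which is what the community statistics use.

## Community colour statistics

**Focal distinctness.** For focal species *f* in a community of *n* species
loci, the statistic is

    T = median{d(f, s) : s ≠ f} − median{d(s, s′) : s, s′ ≠ f, s < s′},

the excess of the focal species' typical distance over the community's
typical internal distance (medians use the midpoint convention). The null
distribution reassigns the focal role to one of the *other* n − 1 species
uniformly at random, n_boot times (default 1000), and p is the fraction of
replicates with T* ≥ T. Reassigning among the other species rather than all
n matters: replicates that redraw the observed focal would reproduce T
exactly and put a floor of about 1/(2n) under the p-value. This permutation
construction is exactly calibrated when the focal is exchangeable with the
community, which the acceptance suite verifies by simulation (rejection rate
at α = 0.05 within [0.03, 0.08] over 500 null communities). A variant that
additionally resamples the non-focal set with replacement
(`scheme="reassign-resample"`) is kept for sensitivity analysis; the extra
resampling variance makes it mildly conservative, which is why it is not the
default. Seeds are mandatory; results are reproducible bit for bit.

**UV-green group contrast.** Sample A collects all pairwise distances among
species classified bee-UV-green, sample B all pairwise distances among the
remaining species; a one-sided Welch t-test asks whether mean(A) < mean(B),
i.e. whether UV-green species cluster more tightly than the rest of the
community. Pairwise distances are not independent observations, so the
t-test is a descriptive convention; the caveat is carried in the result
metadata. Welch's form (unequal variances, fractional degrees of freedom) is
used throughout the package.

## Eigenshape morphometrics

An outline is an ordered open curve between two anchor landmarks. The
pipeline is:

1. **Semi-landmarks** — the polyline is resampled to m points (default 100)
   equally spaced by arc length; anchors are preserved exactly. m = 100 keeps
   sub-percent geometric error for smooth petal-scale curves while keeping
   the φ vectors short.
2. **φ function** — φ_j is the angle of segment j (unwrapped to remove 2π
   jumps) minus the angle of the start-to-end chord. Equal step lengths
   remove size; chord subtraction removes rotation deterministically and
   respects the anchors. A net-deviation variant that subtracts the mean
   angle instead (`variant="phi-star"`) is available. The representation is
   invariant to translation, rotation, and uniform scaling by construction,
   and the test suite verifies the whole outline→scores pipeline to 1e-8
   under similarity transforms.
3. **Decomposition** — the specimen-by-angle φ matrix is column-centred and
   factored by SVD; eigenvalues are singular values squared over (n − 1),
   identical to the eigendecomposition of the covariance matrix (the
   covariance, not correlation, matrix is the object decomposed). Scores are
   projections of centred rows on the orthonormal axes. Axes are retained to
   the smallest k whose cumulative variance fraction reaches 90% (configurable).
4. **Nearest-model distances** — for each non-model specimen, the Euclidean
   distance in retained-score space to the nearest specimen of the model
   family; a one-sided Welch t-test compares putative mimics against other
   taxa. Outlier exclusion is always an explicit caller-supplied list, never
   automatic.
5. **Two-group CVA** — the canonical axis is the Fisher discriminant
   w = S_w⁻¹(m₁ − m₀) with S_w the pooled within-group covariance;
   assignment thresholds the discriminant score at the pooled midpoint.
   With two groups there is exactly one canonical axis. When S_w is singular
   or ill-conditioned (retained axes ≥ specimens), ridge shrinkage
   S_w + λ·tr(S_w)/p·I with λ = 1e-8 (configurable) is applied and flagged.
   Both resubstitution and leave-one-out classification rates are reported;
   resubstitution is the default display, with LOO alongside, since the two
   can differ materially on small samples.

## Parsimony trait mapping

The binary bee-UV-green state is mapped by unweighted parsimony. The downpass
uses Hartigan's generalisation of Fitch's rule, so polytomies are treated as
hard (the input trees of interest are consensus trees with genuinely
unresolved nodes): each node keeps the states present in the largest number
of child state sets, and the score grows by (children − that count). Missing
tip states are fully ambiguous {0, 1}. A unit-cost Sankoff dynamic program
independently recomputes the score and, among reconstructions achieving it,
the minimum and maximum number of **origins** of state 1. An origin is a
0→1 change on an edge, *plus one* when the root itself is reconstructed in
state 1 — the state then arose on the stem lineage, and "the trait evolved k
times" should count that appearance. (Under pure edge-counting an all-1 tree
would show zero origins.) Root states are chosen to minimise total changes;
when both states tie at the root, both are explored and the reported bracket
covers them. `annotate_tree` emits one most-parsimonious reconstruction (the
one attaining the minimum origin count) as newick with per-node
`[&state=...]` comments, flagging nodes whose downpass set is ambiguous.
A genus-level summary (genera containing the state) is reported separately
from the tree-based bracket; the two counts answer different questions and
neither is adjudicated over the other.

## Synthetic data

The generators are pure functions of (parameters, seed) and define the study
conditions under which the package is tested.

**Spectra.** Parametric class templates, clipped to [0, 1] after optional
Gaussian noise (default sd 0.01, a typical field-spectrometer noise floor):
the *bee-uv-green-yellow* class is a sigmoid long-pass (inflection 520 nm,
slope 15 nm, amplitude 0.8) plus a Gaussian UV bump (centre 360 nm, sd 25 nm,
height 0.35) — long-wavelength reflectance that humans see as yellow combined
with UV reflectance, the signature that lands in the bee-UV-green sector.
*Blue* is a Gaussian band at 460 nm; *white* and *cream* are UV-absorbing
long-passes (390/420 nm) that land bee-blue-green, as most white flowers do;
*red-human* is a 610 nm long-pass landing bee-green. The default community
holds 20 species: 4 bee-UV-green (emulating mimic orchids together with
their rewarding models), 3 blue, 6 white, 4 cream, 3 red — making blue-green
the commonest bee-subjective colour, as in the tropical communities this
emulates. Template parameters are analytic so ground truth is exact; real
spectra have correlated noise, specular artefacts, and within-species
variation that these templates do not emulate, so passing tests demonstrate
correctness of the computations, not field realism.

**Outlines.** Curves from (0,0) to (1,0) displaced by Σ_k a_k sin(kπt) — a
half-period sine basis that pins the anchors exactly. Two groups share the
first harmonic (overall arching) and differ in higher harmonics; specimens
add Gaussian coefficient noise (default sd 0.02, n = 15 per group). The
default separation is large relative to the noise, so the default scenario
classifies perfectly; chance-level behaviour is exercised separately with
shuffled labels.

**Trees and characters.** Pure-birth (Yule) trees grown by splitting a
uniformly chosen tip, exponential edge lengths. In planted-gain mode
(default: 14 gains on a 200-tip tree, clade size ≤ 8% of tips), disjoint
clades are switched to state 1 and everything else stays 0. Clade placement
enforces a separation condition: any two planted clade roots must have at
least two all-zero subtrees hanging off the path between them. On a binary
tree this guarantees that every most-parsimonious reconstruction has exactly
the planted number of origins. Sketch: merging k planted clades into one
ancestral gain forces a loss on every all-zero subtree hanging off the
Steiner tree connecting them; with ≥ 2 such pendants between every pair, the
pendant count of any merged subset S is at least |S| (each cherry of the
Steiner tree contributes two private pendants), so the merged cost 1 + |pendants|
strictly exceeds the |S| separate gains. Disjointness alone is *not*
sufficient — two sister all-1 clades would collapse into a single cheaper
gain — which is why the generator rejects and redraws configurations that
violate the condition. Rate mode evolves the state as a two-state Markov
chain along branch lengths from a state-0 root and records the realised 0→1
edge count; homoplasy can then legitimately let parsimony infer fewer
origins, so rate mode is not used for exact-recovery tests.

## Problem sizes and numerical conventions

The test and acceptance runs use: 10⁴ random loci for the sector-classifier
oracle; 500 simulated 20-species communities (n_boot = 1000) for null
calibration and 150 per displacement level for the power curve; 20×50 φ
matrices for the SVD oracle; 200 label shuffles for the CVA chance baseline;
1000 random trees of ≤ 10 tips against exhaustive enumeration (2^internal
labelings); and 100 seeds of the 14-gain/200-tip recovery scenario in the
test suite (25 in the acceptance script). These sizes were chosen so each
check is statistically informative while the whole suite stays quick on one
CPU. Other conventions: reflectance slightly above 1 (≤ 1.05) is clipped as
white-standard noise, larger values rejected; replicate spectra are averaged
*before* colour transduction, so a species' locus is a function of one mean
spectrum; resampling never extrapolates; all RNGs are NumPy `default_rng`
with mandatory seeds, and the pipeline reproduces outputs byte-identically
for a fixed config.

## Known limitations

Only trichromatic vision with a single chromatic mechanism is modelled — no
receptor-noise-limited model, no achromatic/green-contrast channel, no
tetrachromats. The hexagon positions depend on receptor/illuminant/background
choices that published community studies generally do not report, so absolute
sector assignments for real spectra should be checked for sensitivity to
those inputs. The group-contrast t-test treats dependent pairwise distances
as observations, as is conventional in this literature; its p-values are
descriptive. CVA with midpoint thresholding assumes roughly equal group
covariances; heavily unbalanced or heteroscedastic score sets deserve the
regularisation flag's attention. Parsimony ignores branch lengths and cannot
distinguish a single ancestral origin plus losses from repeated origins when
their change counts tie; the reported min/max bracket makes that ambiguity
explicit rather than resolving it.
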