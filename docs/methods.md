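# Methods

## Model

The analysis treats the tumor–brain interface as a boundary between two
viscoelastic continua and asks where, in the tissue just outside the
tumor, elastic storage and viscous dissipation stop balancing. The
inputs per case are four volumes on one grid: storage modulus G′ (kPa),
loss modulus G″ (kPa), a binary tumor mask and a binary brain mask. All
computation happens in voxel space; per-axis spacing (mm) carries the
physical metric and the NIfTI affine is only propagated to outputs.

Regions are derived from the masks with an anisotropy-aware Euclidean
distance transform (`scipy.ndimage.distance_transform_edt` with
`sampling=spacing`), so every distance below is physical:

* **parenchyma** — brain minus tumor; for meningioma-group cases the
  brain mask is first eroded by one voxel (6-connectivity), a guard
  against partial-volume contamination at the cortical surface. The
  erosion must precede tumor subtraction: eroding (brain ∖ tumor) would
  also strip the peritumoral layer and empty the rim.
* **rim (r)** — the one-voxel layer immediately outside the tumor
  inside parenchyma (face-connected dilation; 26-connectivity is a
  config option). This is the reference region.
* **skull guard** — parenchyma within 2 mm of the brain-mask exterior
  ("skull" is operationalized as the brain-mask complement, since no
  skull image exists in the data contract).
* **shell (p)** — 0 < d ≤ 6 mm from the tumor, in parenchyma, outside
  the guard. The analysis domain; it includes the rim layer.
* **radial bins** — half-open 2 mm annuli (2(k−1), 2k], k = 1..6, under
  the same parenchyma/guard restriction. Distances are measured to
  tumor voxel centers, so with 3 mm voxels the first bin (0, 2] is
  structurally empty; the radial integral starts at the first occupied
  bin (leading and trailing empty bins truncate, interior gaps are
  linearly interpolated over bin centers).
* **analysis slice** — the axial slice of maximal tumor area (ties →
  lowest index); all 2D morphology lives there.

## Instability field

With tanδ = G″/G′ (NaN wherever either modulus is non-positive), rim
medians G″_r,med and (tanδ)_r,med are computed jointly over rim voxels
valid for both quantities, and

I(x) = ln(G″(x)/G″_r,med) · (tanδ(x) − (tanδ)_r,med)

on every valid shell voxel (invalid voxels stay NaN — excluded, never
clamped). The multiplicative structure makes I a *concurrence* detector:
either factor alone, however large, contributes nothing without the
other. A config switch (`reference_storage`) evaluates the log
denominator against the rim median of G′ instead — the literal printed
formula, retained for sensitivity analysis only; the text around the
formula makes G″ the intended reference.

The field is evaluated identically on the 0–12 mm band for radial
profiling. `pneg`, the fraction of valid shell voxels with I < 0,
summarizes how much of the interface remains elastically dominated.

## Descriptors and numerical choices

* **Median, p95, threshold fractions** over all valid shell voxels
  (negatives included). Primary cutoff τ = 0.02; sweep
  {0.015, 0.020, 0.025, 0.030}.
* **Entropy**: Shannon entropy of the I histogram, 32 bins on [0, 0.4],
  out-of-range voxels excluded, **base 2**. Base 2 is forced by the
  published group medians (≈3.9–4.0 bits), which exceed the natural-log
  ceiling ln 32 ≈ 3.47 of a 32-bin histogram.
* **Radial-AUC**: trapezoid of the per-bin mean I over bin centers
  (1, 3, …, 11 mm). The threshold sweep uses a suprathreshold variant
  (per-bin mean over I > τ voxels), which is the only reading under
  which the sweep's radial-AUC can depend on τ at all — and it then
  increases mildly with τ, matching the published robustness behavior.
  The τ-independent radial-AUC is what the group comparison uses.
* **Tail-AUC**: ∫₀^0.3 P(I > t) dt in closed form,
  mean(min(max(I, 0), 0.3)); cross-checked against numeric integration.
* **Slice morphology** on {I > τ} restricted to the 0–12 mm band of the
  analysis slice. Area pools all components; perimeter counts exposed
  pixel edges scaled by in-plane spacing (Crofton optional). IPR is
  reported in the complexity convention P²/(4πA): the printed formula
  4πA/P² is bounded by ~1 for any pixelated region, while the published
  medians run 8.7–18.1, which only the inverse convention can produce.
  Convexity = area / convex-hull area of suprathreshold pixel centers
  (NaN for < 3 non-collinear pixels).
* **Morphology domain**: restricting the slice maps to the shell proved
  degenerate at 3 mm voxels — the shell is a two-pixel annulus whose
  inner layer is pinned near I = 0 by rim-referencing, so every
  skeleton collapses to a one-pixel curve (length density ≡ 1, branch
  density ≡ 0) and the published magnitudes (length density 0.126–0.326)
  are unreachable. The default domain is therefore the 0–12 mm band
  (`morphology_domain` config; `shell` available).
* **Skeleton metrics**: 2D topology-preserving thinning
  (`skimage.morphology.skeletonize` followed by a `thin` pass that
  removes the rare residual 2×2 block), length density = skeleton px /
  region px, branch density = fraction of skeleton pixels with ≥ 3
  skeleton neighbors in 8-connectivity. Note the neighbor-count rule
  marks, for a plus-sign of two crossing lines, five pixels (the center
  plus the four arm pixels diagonally adjacent to the crossing arm),
  not one. An X-crossing of two diagonal filaments necessarily retains
  one 2×2 block: each of its four pixels is a cut vertex, so no
  topology-preserving thinning can remove it.
* **Opening robustness**: binary opening with an in-plane disc of
  radius round(1.5 mm / spacing), minimum one pixel. At 3 mm voxels the
  minimum representable opening is a full 3 mm — no longer "light".
* **Probability maps**: per case, {I > τ} on the analysis slice is
  cropped to a 120 × 120 mm patch centered on the tumor-slice centroid,
  nearest-neighbor resampled to 256 × 256, then skeletonized; branch
  pixels are marked where ≥ 3 skeleton segments converge. Group maps
  are exact voxelwise means; the N-map counts cases whose source voxel
  existed at a pixel. Radius normalization rescales the occupancy about
  the patch center by R*/R_eff (R_eff = √(tumor slice area/π),
  R* = 20 mm) and **recomputes** skeleton and branch maps, because
  rescaling a skeleton breaks its one-pixel width.
* **Statistics**: Kruskal–Wallis with tie correction (identical values
  → H = 0, p = 1); two-sided Mann–Whitney U of the first-listed group,
  exact when n₁n₂ ≤ 400 without ties; Cliff's δ = 1 − 2U/(n₁n₂)
  oriented as second group relative to first (the convention that
  reproduces all twelve published δ values from the published U
  statistics); Hodges–Lehmann = median of pairwise differences (first −
  second); BH step-up with external family size m = 21 (7 metrics — the
  six effect-size-table metrics plus tail-AUC — × 3 contrasts; m = 21
  uniquely reproduces the published q-values 0.015/0.034/0.049 from the
  published p-values). Pairwise significance is gated on the omnibus
  test (p < 0.05) and q < 0.05, but all rows are reported. The WHO II
  ordering bootstrap resamples cases with replacement within groups
  (10,000 iterations, seeded) and reports P(WHO II median strictly
  between the others, either direction) with 95% percentile CIs.

## Synthetic cohort: the stated world

`perimech.synthetic` builds phantoms on a 64 × 64 × 32 grid of 3 mm
voxels (the acquisition scale): an ellipsoidal brain (semiaxes
85/85/42 mm), a lobulated spherical tumor (radius drawn per case from
12–18 mm, low-order spherical-harmonic boundary perturbation of ±15%),
and three archetypes of peritumoral dissipation:

| archetype | emulates | elevation structure |
|---|---|---|
| compact | WHO I meningioma | isotropic exp(−d/4 mm), amplitude 5 |
| irregular | WHO II meningioma | compact field kept in a random 150° sector (10% elsewhere) + 2 filaments |
| branched | glioblastoma | short-range rim exp(−d/1.5 mm), amplitude 2.8, + 6 thin filaments (random walks, 3 mm steps, 20° jitter, bifurcation probability 0.35 at 60–100°) |

The elevation multiplies both G″ and tanδ by (1 + amplitude ·
pattern). Noise is multiplicative lognormal with CV 0.10 and 8 mm
correlation length, placed as independent fields on **G″ and tanδ**
with G′ := G″/tanδ — both moduli remain lognormal, and the two factors
of I become independent under the null, which is what makes the
amplitude-zero phantom sign-symmetric (pneg ≈ 0.5). Parenchymal
baselines are G′ ≈ 2.5 kPa, G″ ≈ 1.0 kPa (conventional brain-MRE
magnitudes, config-exposed, not claimed as measured values); tumor
interiors get a distinct G′ (stiff ×2 for the meningioma-like, soft
×0.6 for the GBM-like archetype); 1% of brain voxels are zeroed in G″
to exercise the positivity-exclusion rule. All randomness flows from
one seed through independent spawned streams, so a branched phantom
with zero filaments is byte-identical to the compact phantom with the
same tissue parameters.

Amplitudes deserve a remark, because rim-referencing makes them
non-obvious: the rim layer itself always sits at I ≈ 0 (it defines the
reference), so shell instability reflects the *gradient* of dissipation
between rim and shell, and the amplitudes above are sized so that the
resulting I values occupy the dynamic range the analysis constants
presuppose (cutoffs 0.015–0.03, histogram range 0–0.4, survival cap
0.30). Under an outward-decaying elevation the radial profile of I
*increases* with distance (the far field deviates most from the
elevated rim); radial-AUC still ranks coherence the same way —
compact ≫ irregular > branched.

What the generator does **not** emulate: anatomy (no ventricles, no
skull image, no white/gray contrast), wave physics and inversion
artifacts, registration error, 3D filament topology (filaments live in
the axial plane of the tumor-center slice, thickened by their 2 mm
half-width), and inter-subject covariance structure. A green cohort
test therefore establishes that the *pipeline* orders the archetypes
correctly and reproducibly — not that real tumors behave this way.

Two published-data properties are knowingly not met by this stated
world, and their acceptance-family tests are left red rather than
tuned: (1) convexity shows a real group effect in the phantoms (a
compact annulus and a fragmented filament field differ intrinsically in
convexity) whereas the patient cohort showed none; (2) the 1.5 mm
opening — one full pixel here — removes the one-pixel filaments that
define the branched archetype, shifting its median skeleton length
density by ~31%, beyond the stated 20% robustness band.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| shell radius / guard | 6 mm / 2 mm | analysis domain past the tumor, skull margin |
| radial extent / bin | 12 mm / 2 mm | persistence profiling range |
| τ (primary / sweep) | 0.02 / 0.015–0.03 | instability cutoff |
| entropy bins / range | 32 / [0, 0.4] | heterogeneity histogram |
| tail cap | 0.30 | survival-function integration limit |
| patch / grid / R* | 120 mm / 256 / 20 mm | probability-map geometry |
| bootstrap iterations | 10,000 | WHO II ordering resampling |
| BH family m | 21 | 7 metrics × 3 contrasts |

## Limitations

The index is scalar and interface-referenced: it omits directional and
anisotropic effects and says nothing absolute about stiffness. All
topology is 2D on one axial slice; at 3 mm voxels the morphological
metrics sit near their resolution floor, which is why the morphology
domain uses the 0–12 mm band and why opening robustness fails by
construction. Group statistics at n = (10, 5, 13) have little power for
the middle group; the bootstrap quantifies exactly that (the WHO II
intermediate-ordering probability is unstable for the skeleton
metrics).
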