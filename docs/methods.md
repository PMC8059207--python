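# Methods

## 1. Lattice model of DNA solutions with single-chain collapse

### Free energy

The solution is modelled on a lattice of coordination number `q` whose
sites hold either a solvent molecule or one of the `N` segments of a DNA
molecule. The total free energy is the Flory–Huggins mixing free energy of
whole molecules plus, per DNA molecule, an *internal* free energy that
describes the conformation of the single chain through its expansion
factor `α` (radius of gyration over the unperturbed θ-solvent value). Per
lattice site and in units of kT:

```
f(φ, α) = (1−φ) ln(1−φ) + (φ/N) ln φ + χ φ(1−φ) + (φ/N) g(α)
g(α)    = N[(χ−1) + B₂ω/(2^{3/2}α³) + B₃ω²/(2·3^{5/2}α⁶)]
          + (3/2)(α²−1) − 3 ln α
```

The internal part balances pairwise intramolecular segment contacts
(`B₂ = 1/2 − χ`, attractive in a poor solvent), triple contacts (`B₃`,
repulsive), the elastic stretching/compression energy, and the entropy of
deviating from the unperturbed coil. `ω` is the segment density of the
unperturbed coil (a flexibility measure): chains with larger ω gain more
contact energy upon compaction.

The extensive form (molecule numbers `n_solvent`, `n_DNA`; total volume
`V = V_s(n_solvent + n_DNA·N)`) is implemented only as a differentiation
target for validation; all production code works with the intensive form,
in which the unspecified solvent molecular volume `V_s` cancels.

### Chain descriptors and unit calibration

All descriptors derive from the molecular weight `M = 650·bp` g/mol:

| quantity | expression | value at 200 bp |
|---|---|---|
| ⟨h₀²⟩ (cm²) | `4·10⁻¹⁵ · M^{8/7}` | 2.80·10⁻⁹ |
| ω | `9π · M / (N_A · ρ · ⟨h₀²⟩^{3/2})` | 2.29·10⁻⁵ |
| N | `M / 4000` | 32.5 |

with ρ = 1.8 g/cm³ and one lattice segment corresponding to 4000 g/mol of
DNA (~6 bp). The carriers of these empirical expressions are
typeset-ambiguous in the literature they descend from, so they were fixed
by **calibration against two anchor predictions** of the same model at
χ = 0.7 — a dilute-branch coexistence concentration of roughly 160 mg/mL
for 200 bp DNA and roughly 0.3 µg/mL for 2.5 kb DNA:

- `N = M/4000` reproduces the 200 bp anchor essentially by itself
  (156.5 mg/mL, ratio 0.98), because a 200 bp chain does not collapse at
  χ = 0.7 and its binodal is pure Flory–Huggins.
- the 2.5 kb anchor is sensitive only to `ln ω` (the collapse free-energy
  gain is ω-independent at the stationary point; ω enters through the
  globule entropy `−3 ln α` with `α³ ∝ ω`). The reading
  `ω = 9π·⟨h₀²⟩^{−3/2}·M/(N_A ρ)` — prefactor **outside** the 3/2 power —
  lands at 0.153 µg/mL (ratio 0.51). Alternative readings fail: applying
  `(9/π)^{3/2}` gives 0.026 µg/mL (11× low), a Gaussian-density prefactor
  `(3/2π)^{3/2}` suppresses the 2.5 kb collapse entirely.
- the third virial coefficient is implemented as
  `B₃ = 1 + χ²/(2q) − χ³/(6q²)` with `q = 10`. The alternative grouping
  `1 + χ²q/2 − χ³q²/6` turns **negative** at χ ≈ 0.55, which makes
  `g(α) → −∞` as `α → 0` and the model unusable exactly in the χ-range of
  interest; the adopted grouping stays positive over the working range.
  Both are exposed as replaceable functions
  (`b3_default`, `b3_lattice_weighted`) so the comparison can be rerun.

The concentration separation between the two anchors comes out at 6.0
decades versus the anchors' 5.7.

### Collapse transition

Stationary points of `g(α)` are the positive real roots of the degree-8
polynomial `3α⁸ − 3α⁶ − N(3B₂ωα³/2^{3/2} + B₃ω²/3^{3/2})`, obtained from
the companion matrix (`numpy.roots`). The global minimum is selected among
the roots and the interval boundary `α_max = 1.5` (the `α → 0⁺` boundary
carries `g → +∞` for `B₃ > 0`). The transition is strongly first-order
here: α jumps from ≈ 1 to ≈ 10⁻² at a length-dependent χ. The collapse
boundary of a phase diagram is flagged at the first grid χ where α drops
below 0.5 or jumps by more than 0.2 between grid points (both thresholds
configurable; they coincide in practice because of the discontinuity).

### Binodal construction

Coexistence solves `μ_DNA(φ₁, α₁) = μ_DNA(φ₂, α₂)` and
`μ_solv(φ₁) = μ_solv(φ₂)` with

```
μ_DNA  = ln φ − (N−1)(1−φ) + χN(1−φ)² + g(α)
μ_solv = ln(1−φ) + (1−1/N) φ + χ φ²
```

The dilute phase uses the collapse solution `α₁` at the working χ; in the
dense phase intermolecular contacts replace the intramolecular ones that
drive collapse, so the unperturbed θ-solvent value `α₂` (χ = 0.5 solution,
≈ 1) is used — a configuration switch forces `α₂ = 1` exactly.

Because the α-terms are φ-independent, `μ_solv` retains the classic
Flory–Huggins structure: below the critical point
`χ_c = (1 + 1/√N)²/2` it is monotonic and no coexistence exists (the
solver returns a typed "no coexistence" result, not an error).

*Numerics.* Rather than a 2-D root-find, the system is solved as two
nested 1-D Brent solves: for a trial dilute fraction the solvent-potential
equality fixes the dense fraction uniquely on the decreasing branch beyond
the second spinodal (the spinodals are the roots of a quadratic), and the
remaining DNA-potential mismatch is a scalar function of `t = ln φ₁`,
bracketed by a 256-point scan and solved to `xtol = 10⁻¹³`. Working in
`ln φ₁` matters: for chromosome-scale chains the dilute branch lies at
log₁₀ φ₁ ~ −10⁵ and below, where φ itself underflows double precision. Once φ₁ underflows, the mismatch is exactly linear in `t`, so
the bracket is extended analytically and the returned `BinodalPoint`
carries a finite `log10_phi_dilute` alongside a `phi_dilute` that may be
0.0. Residuals of both potential equalities are checked against 10⁻¹⁰
(relative for the very large-N regime where μ itself is ~10⁷ kT and float
cancellation dominates).

Concentrations are `c = φ·ρ` (g/mL).

### Known model features and limitations

- **Re-entrant closure of the dilute branch.** Above χ ≈ 1 (for a 2.5 kb
  chain) the collapsed single-molecule state becomes so stable that the
  dilute-phase DNA potential stays below the dense-phase value for every
  φ₁ up to the spinodal: the construction returns "no coexistence". This
  is a genuine property of the collapse-vs-aggregation competition in
  this model prescription, not a solver failure.
- Gaussian-chain statistics throughout; no wormlike-chain stiffness
  corrections beyond the empirical ⟨h₀²⟩ ∝ M^{8/7} scaling, no sequence
  dependence, no spinodal computation.
- The dilute-branch concentration is non-monotonic in χ (collapse raises
  the solubility of single globules), so phase-diagram consumers should
  read the coexistence flag per grid point.

## 2. FRAP analysis

Raw traces are normalized affinely: pre-bleach mean → 1, first post-bleach
frame → 0, matching the model's `FRAP(0) = 0` (the normalization
convention is a package choice; an optional mono-exponential correction
for bleaching during acquisition sits behind a flag and is off by
default). The recovery model `a(1 − e^{−kt})` is fitted by bounded
trust-region least squares with `a ∈ [0, 1.2]` (slack above 1 tolerates
normalization noise) and `k ∈ [10⁻⁵, 10]` s⁻¹; initial guesses are the
plateau mean (last 10% of frames) and `ln 2 /` (time to half-plateau).
Fits landing on a bound are flagged, not rejected. `t½ = ln 2 / k` holds
exactly by construction. Any contribution of surface-stuck molecules
folds into the immobile fraction `1 − a`; no attempt is made to separate
it. Single-component recovery only — no diffusion-reaction modelling.

Default acquisition cadence everywhere: 300 frames at 0.8 s.

## 3. Morphology

Segmentation: Gaussian smoothing (σ = 1 px) → Otsu threshold → connected
components ≥ 20 px (all configurable); an optional distance-transform
watershed splits touching objects. The aspect ratio
`(R_max − R_min)/(R_max + R_min)` uses the maximum/minimum Euclidean
distance from the (intensity-weighted) centroid to the sub-pixel
marching-squares boundary contour. For an axis-aligned or rotated ellipse
these extrema are the semi-axes, giving 1/3 for a 2:1 ellipse; a disc
gives ≈ 0 within discretization error (< 0.05 at radius ≥ 30 px);
rotation/scale invariance holds within 0.03. Single-pixel masks return 0
with a degenerate flag.

Condition classification: per-condition mean aspect ratio and mean mobile
fraction are min–max scaled to [0, 1] (z-score available), clustered by
complete-linkage agglomerative clustering on Euclidean distances, and the
tree is cut at k = 3. Clusters map to regions I/II/III by decreasing mean
mobile fraction, ties broken by increasing mean aspect ratio — region I
is defined by its dynamics. Classification operates on per-condition
means by default (per-condensate tables can be aggregated upstream). A
fully degenerate input (all records identical) collapses to one cluster
mapped to region I, deterministically.

## 4. Flow stability

Frames are registered to frame 0 by integer-pixel phase cross-correlation
estimated on channel 0 and applied to both channels; sub-pixel
registration is deliberately omitted because the max-pixel statistic is
insensitive to sub-pixel error. Spots are detected in the first frame of
each channel with a robust threshold (median + max(6·MAD, 5% of dynamic
range) — Otsu fails when spot brightnesses span a wide range), and only
condensates whose centroids match across channels within 3 px are kept.
Per frame the statistic is max pixel inside the mask minus the mean of a
surrounding ring (mask dilated by 2 px to 5 px), which removes any
spatially uniform background exactly.

Decays are fitted with bounded least squares as single or double
exponentials, offset-free by default (an additive offset is available);
double-fit populations are reported fast-first. Model selection uses the
corrected Akaike criterion (AICc) under Gaussian errors. Molecule counts
are `I / I_dye / f_labeled`, reported as a continuous estimate with a
rounded convenience field; the single-dye intensity is the median over
calibration single-spot intensities. Ensemble decay curves are aggregated
by dividing each trace by the mean of its first 3 frames and reporting
mean ± SEM across condensates. No flow-physics (shear force) modelling.

## 5. Synthetic data

The generators define the study conditions and embed their ground truth:

- **FRAP**: `a(1 − e^{−kt})` + Gaussian noise (σ = 0.02 in normalized
  units by default) at 300 × 0.8 s. Presets cover the observed short-DNA
  regimes: a = 0.66/τ = 99 s (PEG/Mg condensation), 0.58/60 s (H1),
  0.40/69 s (chromatinized DNA + H1), and a ≈ 0.25 for long DNA near the
  critical concentration under H1.
- **Shapes**: non-touching discs (target AR 0), rotated ellipses
  (analytic AR `(r_a − r_b)/(r_a + r_b)`), and irregular blobs grown by
  seeded Eden aggregation with an anisotropy weight
  `exp(roughness·|cosθ|)` toward a random axis — roughness 0 gives
  compact quasi-round clusters, the default 1–2 spans AR ≈ 0.2–0.6.
  Blob ground truth is the aspect ratio measured on the generating mask.
  Packing beyond what rejection sampling can place raises an error.
- **Flow stacks**: two-channel disc spots with per-spot molecule numbers
  (default 2–50), per-channel labeled fractions, population-assigned
  single-exponential decays (mixtures emulate fast-minority/slow-majority
  disassembly), optional drift, Poisson shot noise and Gaussian read
  noise. Disc (top-hat) spots make the max-pixel statistic exact in the
  noise-free case.
- **Condition grids**: lengths 12 bp–48.5 kb × concentrations
  10 ng/mL–100 µg/mL; mobile fraction falls through a logistic inflection
  at 0.6 kb and aspect ratio rises through one at 6 kb (MF before AR,
  producing the I→II→III progression with length); the detection
  threshold concentration decreases with length, and sub-critical cells
  are flagged "no condensates". The default inflections are placed
  between grid lengths so that the programmed regions are exactly
  recoverable at zero noise.

Every generator is byte-deterministic under a fixed seed
(`numpy.random.default_rng`). What the generators do **not** emulate:
optics (no PSF convolution by default), condensate coarsening/fusion
dynamics, spatially varying backgrounds, or detector artefacts — so
passing recovery tests demonstrate correctness of the estimators under
the stated noise models, not robustness to microscope-specific
systematics.

## 6. Reproducibility

Pipeline runs are described by a validated YAML/dict config; unknown keys
fail fast by name. Each run echoes its effective config and stamps every
CSV with a provenance header (SHA-256 of the scientific config fields —
the output directory is excluded — plus seed and version). Identical
configs byte-reproduce all outputs; per-curve seeds are spawned from the
master seed via `SeedSequence`. Test-suite problem sizes (e.g. 200
Monte-Carlo FRAP curves per regime, 21-point χ grids, 40 decay
replicates) keep the full suite under ~15 s while holding Monte-Carlo
standard errors well below the asserted tolerances.
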