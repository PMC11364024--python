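# Methods note

This note records the models implemented in `secswaxs`, the parameter and
algorithm choices that are ours rather than forced by the physics, how the
synthetic generator relates to real SEC-SWAXS data, and the known
limitations.

## 1. Physical model

### Triple-detector composition

A two-component complex A:B eluting as a single SEC peak is observed in
three channels simultaneously:

```
A214 = L (eps_A cA + eps_B cB)                         (UV, Beer–Lambert)
dn   = [(dn/dc)_A M_A cA + (dn/dc)_B M_B cB] / 1000    (dRI)
I0   = n0 (f_t − rho_w V_t)^2                          (absolute SAXS)
```

with `cA, cB` molar concentrations (mol/l), `L` the capillary path length
(cm), `n0 = 10^-3 C N_Av / M_t` the complex number density (cm⁻³) at mass
concentration `C` (mg/ml), `f_t = (N_A E_A + N_B E_B) f_e` the total
scattering length (electron counts `E` times the Thomson length
`f_e = 2.8179·10⁻¹³ cm`), `V_t = N_A V_A + N_B V_B` the solvent-displaced
volume, and `rho_w = 9.42·10¹⁰ cm⁻²` the water scattering-length density.

The 2×2 UV/dRI system is solved exactly for `(cA, cB)`; its condition
number is reported and a value above 10⁶ raises (the two species' responses
are then collinear). The integer stoichiometry is found by scanning
`N_A = 1..6` with `N_B = round(χ N_A)` fixed by the measured molar ratio
`χ = cB/cA` and selecting the candidate whose predicted absolute `I0`
matches best; this works because at fixed composition `I0` is proportional
to `N_A` (factor-of-2 spacing between adjacent candidates), making the
discrimination robust. If no candidate comes within 30% relative, the
solver raises and attaches the full misfit table.

Species constants: `M` and `E` are sequence sums (residue masses/electrons
plus one terminal water), `V` the Jacrot (1976) residue-volume sum — or a
published override (see §5). Extinction coefficients at 214 nm and measured
dn/dc values for the SERF1a/NT17/Htt peptide family are bundled in
`species_data`.

The **aggregation number** is `N = I0 / I0_monomer(C)` with the denominator
the forward prediction for monomers at the same mass concentration: a rigid
dimer doubles the excess scattering length per particle and halves the
number density, hence N = 2. Given exact inputs the identity is exact;
through the pipeline it inherits the Guinier I0 bias (§3).

### Debye profiles

Theoretical profiles use the orientation-averaged Debye sum with
CRYSOL-style effective atomic amplitudes

```
g_i(q) = f_i(q) + nH_i f_H(q) − rho_s V_i r0 exp(−q² V_i^{2/3} / 4π)
```

— tabulated 4-Gaussian Cromer–Mann form factors (H/C/N/O/S/P), implicit
hydrogens from per-residue heavy-atom templates, Fraser displaced volumes,
solvent density 0.334 e/Å³, and a hydration layer of 1.5 Å dummy beads
placed on the rolling-probe (1.4 Å radius) accessible surface with
adjustable contrast `drho_shell`. Atoms are grouped by (element,
implicit-H count) and the pairwise structure sums `S_ab(q)` cached, so the
two-parameter (`r0`, `drho_shell`) fit costs O(groups² · nq) per
evaluation. Intensities are in cm² per molecule, so `I(0)` equals the
squared total excess scattering length exactly. Coarse bead models (one
bead per residue carrying the full residue electron count) use flat form
factors and no excluded-volume term, so `r0` is pinned to 1 when fitting
them — the parameter is degenerate there and a free fit would report a
meaningless grid-edge value.

### Guinier analysis

`autorg` scans all contiguous windows of ≥ 6 points within the leading
positive-intensity stretch, requiring `qmax·Rg ≤ 1.3` and `qmin·Rg ≤ 0.8`,
and selects the window maximizing `length × exp(−χ²_red)`. The χ² is taken
against an effective log-intensity uncertainty `sqrt((σ/I)² + 0.001²)` and
evaluated over *all* points from the start of the curve up to the window's
upper edge. Two deliberate choices live here:

- the 0.1% systematic floor makes curvature count against a window even
  for noiseless data. A plain length×R² score stretches to the `qRg = 1.3`
  bound and inherits the sphere's intrinsic +1.8% Guinier bias; with the
  floor the R = 30 Å sphere recovers Rg to +0.9% while exactly-Gaussian
  data still recover at machine precision (χ² = 0 selects the longest
  window).
- evaluating the fit down to q → 0 encodes that the Guinier law only
  improves toward zero angle; it vetoes short high-q windows whose small
  fitted Rg would otherwise satisfy both qRg bounds.

All window fits use prefix sums, so the full search is O(n²) in windows
with O(1) work per window.

### p(r) inversion

`pr_ift` solves `I(q) = 4π ∫ p(r) sinc(qr) dr` on a 101-bin histogram with
endpoint constraints `p(0) = p(dmax) = 0` and Tikhonov regularization of
the second difference; the weight is chosen at the L-curve corner over a
log-spaced grid scaled to the normal-matrix norm. Real-space moments give
Rg and I0. A solid sphere (closed-form p(r)) inverts to 1% in Rg and 2% in
I0.

### NSD

The normalized spatial discrepancy (Konarev's definition) is computed
after optimal rigid superposition: principal-axis initialization over all
four proper sign combinations, with the third axis sign tied to the
handedness product of the two SVD bases — omitting that product silently
misses half of all rotations — followed by iterated nearest-pair Kabsch
refinement, the enantiomer flip, and both alignment directions; the
minimum over all candidate poses (including the unaligned input) is
returned, which makes the result symmetric by construction. Identity
returns exactly 0; a rigidly rotated copy returns ~10⁻¹⁵.

## 2. Synthetic generator

The generator is the *exact forward model* of the analysis chain, so a
noiseless run is invertible stage by stage:

- single complex species, Gaussian elution peak (center 240 s, σ 30 s),
  2 s frames, apex concentration 0.25 mg/ml by default — the dilute regime
  of small-peptide SEC work, where interparticle structure factors are
  negligible;
- per-frame scattering `I(q,t) = I0(t) P(q) + b`, with `P(q)` the Debye
  form factor of a concrete coarse chain model (self-avoiding walk with
  3.8 Å virtual-Cα steps and 3.5 Å exclusion for coils; ideal helix
  geometry with 1.5 Å rise available) and `b = 0.0162 cm⁻¹` the flat water
  level at 283 K — the same constant the reduction uses as its
  absolute-intensity standard, closing the calibration loop;
- UV and dRI traces are Beer–Lambert / mass-weighted responses to the same
  concentration profile; the dRI detector sits downstream (5 s delay, 2 s
  Gaussian broadening, both applied analytically so Gaussian peaks stay
  Gaussian and the alignment stage has an exact target);
- optional noise `σ(q) = noise_scale · sqrt(I · b)` — the Poisson-like
  scaling of a photon-counting detector dominated by the buffer level;
- every exact pre-noise quantity (apex channel signals, per-frame I0 and C
  profiles, form factor, model Rg) is stored in `truth.derived` so tests
  have oracles that were never touched by the analysis code.

Deliberate simplifications: one species per run (no overlapping peaks),
flat buffer (no capillary-fouling drift), Gaussian peak shape (no
tailing), and geometric rather than Boltzmann-ensemble chains — the chains
only need realistic sizes and smooth form factors, not conformational
thermodynamics.

Trace alignment in the analysis direction fits a shift and Gaussian
broadening between each unit-area optical trace and the X-ray elution
proxy (grid search then Nelder–Mead), then removes them by
Wiener-regularized Fourier deconvolution (exact for Gaussian peaks, stable
for anything smooth; regularization 10⁻⁶). A trace with no peak rising 5
MAD above baseline raises rather than aligning noise.

## 3. Known accuracy limits

- Guinier extrapolation carries the usual shape-dependent bias:
  ≈ +0.3% in I0 for a compact coil, ≈ +2.6% for the elongated two-chain
  dimer model. The pipeline-level aggregation number is therefore 1.003
  (monomer) and 2.05 (dimer) — exact integers only after rounding — while
  the solver-level identity is exact to machine precision.
- The UV/dRI inversion for the SERF1a/NT17 pair amplifies channel noise
  ~7-fold in the derived concentrations: at 2% channel noise the molar
  ratio carries 15–30% error, so integer recovery is reliable as the
  *mode* over replicate frames/measurements, not per single frame. The
  tests use the modal statistic accordingly.
- Curves with a genuine low-q upturn (trace aggregation) are penalized by
  the down-to-zero Guinier evaluation; such data should be cropped before
  `autorg`.
- `merge_saxs_waxs` interpolates the WAXS curve onto the SAXS overlap
  grid; on strongly curved overlaps this biases the scale factor at the
  10⁻⁴ relative level.

## 4. Numerical choices

- All stochastic elements (chain builds, noise draws) flow from a single
  integer seed through `numpy.random.default_rng`; the full pipeline is
  byte-reproducible under a fixed config, and the run report records the
  config digest and seed.
- The Debye engine refuses > 50 000 centers (O(n²) pair-sum guard).
- Frame averaging is inverse-variance weighted with a leave-one-out
  reduced-χ² similarity test that rejects the worst offender per pass —
  testing each frame against a mean that still contains an outlier lets
  the outlier mask the good frames.
- Buffer subtraction and averaging require exactly matching q grids
  (tolerance 10⁻⁶); counting statistics are never silently interpolated.

## 5. The Jacrot volume discrepancy

Summing classical Jacrot (1976) residue volumes over the bundled
sequences gives 9094.5 ų for SERF1a (62 aa) and 2565.2 ų for NT17
(17 aa), while the published reference values for these species are 9719
and 3190 ų — an almost exactly constant offset of +625 ų per chain
(624.5 and 624.8 respectively). No variant residue-volume table can
produce a constant *additive* per-chain offset, so the provenance of the
extra term is unknown to us; it may reflect an end-group or hydration
convention not stated with the reference values. `species_from_sequence`
implements the plain documented sum; `builtin_species` returns the
published values by default (`use_published_volume=True`), since they are
measured inputs of the system and are what the stoichiometry chain
consumes. The acceptance tests compare the computed sums against the
published values honestly, and those two assertions fail; this is
recorded rather than tuned away.
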