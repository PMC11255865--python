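# Methods

`crystbio` re-implements, as a tested library, the four quantitative
analyses used to ask whether cumulative Asn→Asp deamidation perturbs a
two-domain γ-crystallin: chemical-shift-perturbation (CSP) mapping,
two-state chemical-denaturation thermodynamics, diffusion-interaction-
parameter (kD) estimation from DLS, and conformational-landscape /
residue-distance analysis of trajectories. No experimental raw data are
bundled; every analysis is exercised against seeded synthetic generators
whose ground truth is known exactly, with the published per-variant
parameters as the default study conditions.

## Chemical-shift perturbations

For each residue present in both peak lists the combined amide perturbation
is

    Δδ = sqrt(ΔδH² + (ΔδN/6)²)            ("plain", default)
    Δδ = sqrt((ΔδH² + (ΔδN/6)²) / 2)      ("half", Williamson convention)

The nitrogen difference is down-weighted by 1/6 to compensate for the ~6×
larger ¹⁵N shift dispersion. The two conventions differ only by a global
factor √2, so thresholding at k·SD flags the same residues either way; both
are offered because both weightings circulate in the literature, and the
default is the plain form. Residues present in only one list (prolines,
unassigned residues) are reported as unmatched and never imputed — an amide
CSP for a proline is undefined, and zero-filling would bias the SD
threshold downward. The significance threshold is k (default 1.0) sample
standard deviations of the matched Δδ values; substitution sites can be
excluded from the SD estimate via an option, but are included by default.
The additivity check reports per-residue residuals
Δδ_full − (Δδ_NTD + Δδ_CTD) and summary statistics only; it deliberately
encodes no pass/fail verdict because "additive" is a scientific judgement
about propagation across the domain boundary, not a fixed tolerance.

Because the combined CSP is a norm, additivity is exact only when the two
domain perturbation fields do not overlap residue-wise. The generator
spills perturbations onto sequence neighbours with an exponential decay
(default length 1.5 residues), so constructed NTD+CTD=full profiles show
residuals at the level of the overlapping tails (~10⁻⁴ ppm for default
geometry) rather than machine zero.

## Two-state unfolding (linear extrapolation model)

The unfolding free energy is assumed linear in denaturant concentration C:

    ΔG(C) = m (Cm − C),   fU(C) = 1 / (1 + exp(ΔG(C)/RT))

with R = 1.987×10⁻³ kcal/(mol·K) and T fixed at 298.15 K (samples
equilibrated at 25 °C). The observable is a population-weighted mix of two
sloping baselines,

    y(C) = (aN + bN·C)(1 − fU) + (aU + bU·C)·fU ,

fit by bounded nonlinear least squares in the six parameters
(Cm, m, aN, bN, aU, bU). The fit is parameterized in (Cm, m) rather than
(ΔG, m): the midpoint is pinned by the data while ΔG = m·Cm is a derived
product, and this conditioning avoids the strong (ΔG, m) correlation. ΔG
is therefore *identically* m·Cm in every fit. Because the model is affine
in the signal, any affine transform of the observable (raw intensity,
ratioed intensities, normalized signal) changes only the baselines, so the
fitted thermodynamics are agnostic to which transform the caller supplies.

Initialization is multi-start: Cm from the concentration whose mean signal
is nearest mid-range, m ∈ {1, 2, 4} kcal/mol/M, baselines from linear fits
through the three lowest/highest concentrations; the best-cost converged
start wins and total failure is a hard error listing the starts. A fitted
midpoint outside the sampled concentration range sets a warning flag rather
than failing, since extrapolated midpoints are legitimate but fragile.

95% intervals come from seeded residual-bootstrap percentiles (default
n_boot = 1000), or from the t distribution on the least-squares covariance
when n_boot = 0. On synthetic data the percentile intervals run slightly
below nominal (~92% observed coverage for Cm over 150 simulations at 1%
noise) while the t-based intervals are near-nominal (~95%); both satisfy
the ≥90% coverage bound the test suite enforces. Replicates enter the fit
jointly by default; per-concentration averaging (the common bench
workflow) is available and gives the same midpoint to well within its CI.

The published m-value column for these proteins prints values like
"2400 ± 300 kcal/mol/M", which is dimensionally inconsistent with
Cm = ΔG/m (7.4/2.4 ≈ 3.0 M); internally m is 2.4 kcal/mol/M and results
are emitted in both unit styles (`m` and `m_cal`).

## Diffusion interaction parameter

Concentration-dependent DLS is modelled as D = D0 (1 + kD·C). Ordinary
least squares of D on C (C converted from mg/mL to g/mL on read) gives
intercept D0 and slope D0·kD, hence kD = slope/intercept in mL/g. kD is a
ratio, so it is invariant to any rescaling of D and the absolute diffusion
unit is never interpreted. 95% intervals use the t distribution on the
regression; the kD interval follows by first-order propagation of the
(intercept, slope) covariance. Classification is by the interval: entirely
negative → attractive, entirely positive → repulsive, spanning zero →
indeterminate. Replicates enter as individual points by default (averaging
per concentration is an option). A two-point noiseless series fits exactly
but leaves zero degrees of freedom, so its intervals are NaN and its
classification indeterminate.

## Trajectory analysis

Superposition is a proper-rotation Kabsch fit over backbone heavy atoms
{N, CA, C, O} (OXT excluded) matched by residue index + atom name; the
minimized RMSD is evaluated directly from the transformed coordinates
because the eigenvalue-based residual loses precision to cancellation near
zero RMSD. The inter-domain orientation angle is the angle at the COM of a
vertex residue group (default residues 4+36) subtended by the COMs of two
arm residues (defaults 43 and 131), all COMs mass-weighted over backbone
heavy atoms. The angle is an internal coordinate computed on the
un-superposed frame; RMSD is computed after superposition.

Landscapes are 2D Gaussian product-kernel KDEs with per-dimension Scott
bandwidths (σ·n^(−1/6)), evaluated on a grid padded 5 bandwidths beyond the
samples and normalized over the grid. The separable kernel makes the
evaluation a pair of small matrix products. Mode finding merges plateaus of
exactly tied grid cells into a single mode at their centroid. Conformational
states are named rectangular regions of the (RMSD, angle) plane; the
defaults transcribe the approximate published coordinates (major: <2 Å,
15–30°; metastable: 2.4–3.2 Å, 12–18°; minor: 3.5–4.5 Å, <10°) and are
fully overridable since they are figure-derived. Frames outside every box
are labelled "other", so occupancies always sum to 1.

Residue-distance comparisons use per-residue all-heavy-atom COMs (backbone
plus sidechain), per the convention that distances consider both; the
orientation angle uses backbone only. Partners for the site-distance scan
default to the ASP/GLU residues found in the structure, not a hardcoded
list, so toy systems work unchanged. Representative frames for the
major/minor comparison are chosen nearest each state-box centroid in
standardized feature space — a stand-in for hand-picking frames from a
transition.

## Synthetic generators

All generators are pure functions of (parameters, seed), bit-reproducible,
and independently seed their sub-streams so that related calls compose:

- **Peak lists**: reference shifts uniform in amide windows (¹H 7–10 ppm,
  ¹⁵N 105–130 ppm); site perturbations of exact combined-CSP magnitude
  (default 0.15 ppm) in a per-site random ¹H/¹⁵N direction, decaying
  exponentially along the sequence; Gaussian baseline noise (default
  0.003 ppm ¹H, 6× on ¹⁵N — the scale of peak-picking reproducibility);
  ~4% of residues dropped as prolines. Per-site perturbation streams are
  keyed by (seed, site) so domain-confined and full-variant lists generated
  with one seed are exactly additive.
- **Isotherms**: 0–6 M in 0.25 M steps, 3 replicates, multiplicative
  Gaussian noise (default 1% — fluorescence detectors are
  signal-proportional), baselines (0.35, 0.005, 1.0, 0.015) giving an
  increasing signal on unfolding.
- **DLS series**: 5–25 mg/mL, triplicate, 0.5% multiplicative noise.
- **Trajectories**: two rigid pseudo-domains (default 36 residues each) on
  helical backbones (3.8 Å Cα spacing) joined by a 5-residue linker,
  hinging between two scripted orientation angles. Domain B is rotated
  rigidly about the vertex COM so the measured angle equals the scripted
  angle exactly before jitter; linker atoms interpolate between the
  anchors. Every 5th/7th residue is ASP/GLU with a single pseudo-sidechain
  atom so the all-heavy and backbone scopes genuinely differ. Per-frame
  state labels are Bernoulli draws at the requested minor occupancy;
  per-coordinate Gaussian jitter (default 0.2 Å) is added last. With the
  default geometry the scripted minor state sits ~3.6 Å backbone RMSD from
  the major reference, comparable to the landscape the analysis targets.

What the generators do *not* emulate: real NMR spectra (only peak lists),
scattering autocorrelation functions, and any actual molecular dynamics —
the toy trajectory has rigid domains, no internal fluctuations beyond
isotropic jitter, and no physics. Passing tests therefore demonstrate that
the estimators recover known ground truth under the stated noise models,
not that the pipeline is robust to the full pathology of real data
(baseline curvature, aggregation at high concentration, assignment errors,
force-field artifacts).

## Default study conditions

The published per-variant parameters in `crystbio.reference` — midpoints
3.0/2.4/2.6/2.4 M, m-values 2.4/1.9/1.8/1.9 kcal/mol/M, kD −3/−4/−5/−5
mL/g for wild-type / N-less / N-less NTD / N-less CTD, and D0 = 8×10⁻⁷
cm²/s — are the generator defaults for recovery tests and the acceptance
script. Because the generator is parameterized by (Cm, m), the implied
synthetic ΔG values are the products m·Cm (7.2, 4.56, 4.68, 4.56 kcal/mol),
which sit inside the published uncertainties of the rounded printed values.

Problem sizes used by the recovery checks: isotherms of 75 points (25
concentrations × 3 replicates), DLS series of 15 points (5 × 3), toy
trajectories of 2000 frames with 77 residues; bootstrap coverage is
estimated over 150 simulations of 300 resamples each. These are the scales
of the corresponding bench experiments and are comfortably stable for the
estimators involved.

## Known limitations

- Per-dataset fitting only; no global fits sharing baselines across
  variants, no three-state models, no thermal denaturation.
- The KDE grid normalization makes the landscape a proper density over the
  grid, not over the plane; with default 5-bandwidth padding the difference
  is < 10⁻⁶.
- Structure I/O assumes a single chain, takes the first altloc, and has no
  mmCIF support.
- State boxes are axis-aligned rectangles; a genuinely diagonal well would
  need caller-supplied bounds or a clustering step outside this package.
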