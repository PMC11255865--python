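# crystbio

A Python toolkit for the biophysical characterization of deamidation in
two-domain γ-crystallins — the eye-lens proteins whose aggregation causes
cataract. Asn→Asp deamidation is the most common age-related chemical
modification of lens proteins, and the question the toolkit addresses is
whether cumulative deamidation actually perturbs structure, stability,
colloidal behavior, or conformational dynamics. It provides four analysis
stages, each usable on its own from Python and each exercisable end-to-end
on synthetic data with known ground truth:

1. **NMR chemical-shift perturbations** — per-residue combined amide
   ¹H/¹⁵N differences, Δδ = √(ΔδH² + (ΔδN/6)²), with k·SD significance
   flagging and a domain-additivity check.
2. **Two-state chemical denaturation** — the linear extrapolation model
   ΔG(C) = m(Cm − C), fU = 1/(1+e^(ΔG/RT)), fit with sloping baselines to
   yield the midpoint Cm (M), m-value (kcal/mol/M) and ΔG°′ = m·Cm
   (kcal/mol) with bootstrap or t-based 95% CIs.
3. **Diffusion interaction parameter** — kD (mL/g) from the slope of
   D = D0(1 + kD·C) in concentration-dependent DLS; negative kD means
   weakly attractive protein–protein interactions.
4. **Trajectory conformational landscapes** — backbone RMSD to a reference
   (Kabsch superposition) vs an inter-domain orientation angle (the angle
   at the COM of vertex residues subtended by one arm residue per domain),
   2D product-kernel KDE landscapes, rectangular state assignment, and
   residue center-of-mass distance comparisons between conformations.

A synthetic-data module generates peak lists, isotherms, DLS series and
hinged two-domain toy trajectories with exact ground truth, and a pipeline
(`crystbio run`) wires all stages into one seeded, reproducible report.

## Worked example

```python
from crystbio import fit_isotherm, fit_dip, delta_delta_g
from crystbio.synth import gen_isotherm, gen_dls_series

# unfolding: wild-type vs fully deamidated, 1% noise
wt = fit_isotherm(gen_isotherm(Cm=3.0, m=2.4, noise_frac=0.01, seed=1), n_boot=500, seed=1)
nl = fit_isotherm(gen_isotherm(Cm=2.4, m=1.9, noise_frac=0.01, seed=1), n_boot=500, seed=1)
print(f"WT:     Cm={wt.Cm:.2f} M  dG={wt.dG:.2f} kcal/mol")
print(f"N-less: Cm={nl.Cm:.2f} M  dG={nl.dG:.2f} kcal/mol")
print("ddG = %.2f +/- %.2f kcal/mol" % delta_delta_g(wt, nl))

# colloidal stability from DLS
dip = fit_dip(gen_dls_series(kd=-3.0, noise_frac=0.005, seed=1))
print(f"kD = {dip.kd:.2f} mL/g, CI [{dip.ci95['kd'][0]:.2f}, {dip.ci95['kd'][1]:.2f}]")
```

prints

```
WT:     Cm=3.01 M  dG=7.04 kcal/mol
N-less: Cm=2.41 M  dG=4.48 kcal/mol
ddG = 2.56 +/- 0.51 kcal/mol
kD = -3.23 mL/g, CI [-3.64, -2.83]
```

The fitted midpoints and free energies recover the generating parameters
within their confidence intervals; the ~2.6 kcal/mol difference is the
destabilization imparted by replacing all seven Asn with Asp, and the
negative kD with a CI excluding zero classifies the protein–protein
interaction as weakly attractive. Each `examples/*.py` script walks one
capability the same way (CSP mapping, unfolding, DLS, trajectory
landscapes, the full pipeline).

## Command line

```bash
crystbio synth isotherm --cm 3.0 --m 2.4 --seed 1 --out data/
crystbio unfold fit --in data/isotherm.csv --boot 1000 --seed 1 --out fit.json
crystbio dip fit --in dls.csv --out dip.json
crystbio traj features --traj traj.pdb --ref ref.pdb --out feats.csv
crystbio run --config examples/demo_config.json --out results/
```

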