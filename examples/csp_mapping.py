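"""Map chemical-shift perturbations between a deamidation variant and a
reference protein, and check domain additivity.

Generates synthetic amide peak lists with perturbations localized at the
N-terminal-domain substitution sites (24, 33, 49), computes combined
1H/15N CSPs, flags residues above one standard deviation, and verifies
that the full variant's CSPs equal the sum of the two domain-confined
profiles.
"""

from crystbio import additivity_check, compute_csp, flag_significant
from crystbio.reference import CTD_SITES, NTD_SITES
from crystbio.synth import gen_peak_lists

SEED = 11

reference, variant = gen_peak_lists(sites=NTD_SITES, seed=SEED)
profile = flag_significant(compute_csp(variant, reference), k_sd=1.0)

print(f"matched residues : {profile.matched_count}")
print(f"threshold (1 SD) : {profile.threshold:.4f} ppm")
print(f"flagged residues : {sorted(profile.flagged)}")
# Flagged residues should cluster at and around the substitution sites;
# the threshold is the 1-SD line drawn on per-residue CSP plots.

kw = dict(baseline_noise=0.0, seed=SEED)
ref0, v_ntd = gen_peak_lists(sites=NTD_SITES, **kw)
_, v_ctd = gen_peak_lists(sites=CTD_SITES, **kw)
_, v_full = gen_peak_lists(sites=NTD_SITES + CTD_SITES, **kw)
_, summary = additivity_check(
    compute_csp(v_full, ref0), compute_csp(v_ntd, ref0), compute_csp(v_ctd, ref0)
)
print(f"additivity: max |residual| = {summary['max_abs_residual']:.2e} ppm, "
      f"r = {summary['pearson_r']:.6f}")
# Near-zero residuals and r ~ 1 mean perturbations in the two domains do
# not propagate across the domain boundary: the full variant's CSPs are
# the sum of the domain-confined ones.
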