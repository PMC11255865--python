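"""Chemical-shift perturbation (CSP) analysis.

Combined amide 1H/15N perturbations between a variant and a reference
protein, per residue, with the nitrogen difference down-weighted by 1/6 to
account for its larger shift range:

    plain:  ddelta = sqrt(dH^2 + (dN/6)^2)
    half:   ddelta = sqrt((dH^2 + (dN/6)^2) / 2)   (Williamson convention)

Residues present in only one list (prolines, unassigned) are reported as
unmatched and never imputed. Significance is flagged against a
k * sample-SD threshold over the matched residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fileio import PeakList

CONVENTIONS = ("plain", "half")


@dataclass
class CSPProfile:
    residues: np.ndarray  # matched residues, sorted
    delta_h: np.ndarray  # ppm, variant - reference
    delta_n: np.ndarray  # ppm
    delta: np.ndarray  # combined CSP, ppm, >= 0
    convention: str = "plain"
    threshold: float | None = None  # ppm
    flagged: frozenset = frozenset()
    unmatched: dict = field(default_factory=dict)
    variant_label: str = ""
    reference_label: str = ""

    def __post_init__(self):
        if (self.delta < 0).any():
            raise ValueError("combined CSP must be non-negative")
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if not set(self.flagged) <= set(self.residues.tolist()):
            raise ValueError("flagged residues must be matched residues")

    @property
    def matched_count(self) -> int:
        return len(self.residues)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "residue": self.residues,
                "delta_h": self.delta_h,
                "delta_n": self.delta_n,
                "csp": self.delta,
            }
        )
        df["flagged"] = df["residue"].isin(sorted(self.flagged))
        return df


def compute_csp(variant: PeakList, reference: PeakList, convention: str = "plain") -> CSPProfile:
    """Per-residue CSP between two peak lists, matched on residue index."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    common = np.intersect1d(variant.residues, reference.residues)
    if len(common) == 0:
        raise ValueError(
            f"no residue indices shared between {variant.label!r} and {reference.label!r}"
        )
    vi = {r: i for i, r in enumerate(variant.residues.tolist())}
    ri = {r: i for i, r in enumerate(reference.residues.tolist())}
    dh = np.array([variant.delta_h[vi[r]] - reference.delta_h[ri[r]] for r in common])
    dn = np.array([variant.delta_n[vi[r]] - reference.delta_n[ri[r]] for r in common])
    combined = np.sqrt(dh**2 + (dn / 6.0) ** 2)
    if convention == "half":
        combined = combined / math.sqrt(2.0)
    unmatched = {
        "variant_only": sorted(set(variant.residues.tolist()) - set(common.tolist())),
        "reference_only": sorted(set(reference.residues.tolist()) - set(common.tolist())),
    }
    return CSPProfile(
        residues=common,
        delta_h=dh,
        delta_n=dn,
        delta=combined,
        convention=convention,
        unmatched=unmatched,
        variant_label=variant.label,
        reference_label=reference.label,
    )


def flag_significant(profile: CSPProfile, k_sd: float = 1.0, exclude=()) -> CSPProfile:
    """Flag residues with CSP strictly above k_sd sample standard deviations.

    The SD is computed over all matched residues, optionally excluding
    ``exclude`` (e.g. substitution sites) from the threshold estimate; flags
    are still assigned over all matched residues.
    """
    if profile.matched_count < 2:
        raise ValueError("need at least 2 matched residues to estimate a threshold")
    keep = ~np.isin(profile.residues, np.asarray(list(exclude), dtype=int))
    vals = profile.delta[keep]
    if len(vals) < 2:
        raise ValueError("exclusion list leaves fewer than 2 residues for the SD")
    sd = float(np.std(vals, ddof=1))
    threshold = 0.0 if sd == 0.0 else float(k_sd) * sd
    flagged = frozenset(profile.residues[profile.delta > threshold].tolist())
    return replace(profile, threshold=threshold, flagged=flagged)


def additivity_check(full: CSPProfile, ntd: CSPProfile, ctd: CSPProfile):
    """Residuals of full-protein CSPs against the sum of the two
    domain-confined profiles.

    residual(i) = csp_full(i) - (csp_ntd(i) + csp_ctd(i)) over residues
    matched in all three profiles. Returns ``(table, summary)`` where summary
    holds ``max_abs_residual`` and ``pearson_r`` between the full profile and
    the domain sum. No verdict is encoded; the caller interprets.
    """
    labels = {full.reference_label, ntd.reference_label, ctd.reference_label}
    if len(labels - {""}) > 1:
        raise ValueError(f"profiles computed against different references: {sorted(labels)}")
    common = np.intersect1d(np.intersect1d(full.residues, ntd.residues), ctd.residues)
    if len(common) == 0:
        raise ValueError("no residues matched across all three profiles")

    def _at(profile, residues):
        idx = {r: i for i, r in enumerate(profile.residues.tolist())}
        return np.array([profile.delta[idx[r]] for r in residues])

    c_full = _at(full, common)
    c_sum = _at(ntd, common) + _at(ctd, common)
    residual = c_full - c_sum
    table = pd.DataFrame(
        {"residue": common, "csp_full": c_full, "csp_domain_sum": c_sum, "residual": residual}
    )
    if np.std(c_full) == 0 or np.std(c_sum) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(c_full, c_sum).statistic)
    summary = {
        "max_abs_residual": float(np.max(np.abs(residual))),
        "pearson_r": r,
        "n_residues": int(len(common)),
    }
    return table, summary
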