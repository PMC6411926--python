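"""Normalized chemical shift perturbations and the trimmed significance rule.

In the fast-exchange regime an amide cross-peak moves continuously from its
free to its bound position as ligand is added. The perturbation between two
states is summarized as the weighted Euclidean norm

    ddelta = sqrt(ddelta_H**2 + (w * ddelta_N)**2),   w = 0.20,

which down-weights the intrinsically wider 15N dimension so that both
dimensions contribute comparably in ppm units.

A resonance counts as significantly perturbed when its ddelta exceeds the
mean plus one standard deviation of the profile computed after trimming the
10% largest values — the trim keeps genuine binders from inflating their own
significance threshold, but trimmed residues themselves remain eligible to
be called significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import CSPError
from .peaks import PeakStatus, TitrationSeries

__all__ = ["CSPProfile", "normalized_csp", "csp_profile", "classify_significant"]

#: Default weight applied to the 15N shift change, matching the ratio of
#: amide 1H to 15N chemical shift ranges.
NITROGEN_WEIGHT = 0.20


def normalized_csp(
    dH_ref: float,
    dN_ref: float,
    dH_obs: float,
    dN_obs: float,
    nitrogen_weight: float = NITROGEN_WEIGHT,
    residue: int | str | None = None,
) -> float:
    """Weighted-norm shift change (ppm) between a reference and an observed
    peak position. Symmetric under swapping reference and observed."""
    if nitrogen_weight <= 0:
        raise ValueError("nitrogen_weight must be positive")
    vals = (dH_ref, dN_ref, dH_obs, dN_obs)
    if not all(math.isfinite(v) for v in vals):
        where = f" (residue {residue})" if residue is not None else ""
        raise CSPError(f"non-finite chemical shift{where}: {vals}")
    return math.hypot(dH_obs - dH_ref, nitrogen_weight * (dN_obs - dN_ref))


@dataclass
class CSPProfile:
    """Per-residue normalized shift changes between reference and endpoint.

    ``statuses`` distinguishes residues with a computed value (``ok``) from
    those broadened or missing at the endpoint (carried without a value) and
    those excluded outright (prolines, unassigned, absent from reference).
    """

    series_id: str
    endpoint_index: int
    values: dict[int, float]
    statuses: dict[int, str]
    labels: dict[int, str] = field(default_factory=dict)
    threshold: float | None = None
    significant: frozenset[int] = frozenset()

    def ok_values(self) -> dict[int, float]:
        return {r: v for r, v in self.values.items() if self.statuses[r] == "ok"}

    def to_frame(self) -> pd.DataFrame:
        residues = sorted(self.statuses)
        return pd.DataFrame(
            {
                "residue": residues,
                "label": [self.labels.get(r, str(r)) for r in residues],
                "dd_ppm": [self.values.get(r, math.nan) for r in residues],
                "status": [self.statuses[r] for r in residues],
                "significant": [r in self.significant for r in residues],
            }
        )


def csp_profile(
    series: TitrationSeries,
    endpoint_index: int | None = None,
    nitrogen_weight: float = NITROGEN_WEIGHT,
) -> CSPProfile:
    """Profile of normalized shift changes between the series reference and
    one endpoint.

    ddelta is computed for every residue observed at both points. Residues
    broadened or missing at the endpoint are carried with that status and no
    value; prolines and unassigned rows are excluded.
    """
    if endpoint_index is None:
        endpoint_index = series.endpoint_index
    if endpoint_index == series.reference_index:
        raise CSPError("endpoint must differ from the reference point")
    if not 0 <= endpoint_index < len(series.points):
        raise CSPError(f"endpoint_index {endpoint_index} out of range")

    ref = series.reference
    end = series.points[endpoint_index]
    values: dict[int, float] = {}
    statuses: dict[int, str] = {}
    labels: dict[int, str] = {}
    for idx, ref_peak in ref.peaks.items():
        labels[idx] = ref_peak.residue_label
        end_peak = end.peaks.get(idx)
        if ref_peak.status is not PeakStatus.OBSERVED:
            if ref_peak.status in (PeakStatus.PROLINE, PeakStatus.UNASSIGNED):
                continue
            statuses[idx] = "excluded"
            continue
        if end_peak is None or end_peak.status is PeakStatus.MISSING:
            statuses[idx] = "missing"
        elif end_peak.status is PeakStatus.BROADENED:
            statuses[idx] = "broadened"
        elif end_peak.status in (PeakStatus.PROLINE, PeakStatus.UNASSIGNED):
            continue
        else:
            values[idx] = normalized_csp(
                ref_peak.delta_H,
                ref_peak.delta_N,
                end_peak.delta_H,
                end_peak.delta_N,
                nitrogen_weight,
                residue=ref_peak.residue_label,
            )
            statuses[idx] = "ok"
    if not values:
        raise CSPError("no residue observed at both reference and endpoint")
    return CSPProfile(
        series_id=series.series_id,
        endpoint_index=endpoint_index,
        values=values,
        statuses=statuses,
        labels=labels,
    )


def trimmed_threshold(
    values: dict[int, float], trim_fraction: float = 0.10
) -> float:
    """Mean + 1 sample SD of the profile after discarding the
    ``ceil(trim_fraction * n)`` largest values.

    Ties among the largest values are broken by trimming the higher residue
    index first, which makes the threshold deterministic.
    """
    n = len(values)
    if n < 3:
        raise CSPError(f"need at least 3 observed residues, got {n}")
    # round() guards against 0.1 * 50 -> 5.000000000000001-style float dust
    k = math.ceil(round(trim_fraction * n, 9))
    order = sorted(values, key=lambda r: (values[r], r))
    kept = np.array([values[r] for r in order[: n - k]])
    if kept.size == 0:
        raise CSPError("trim_fraction removes every residue")
    sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return float(kept.mean()) + sd


def classify_significant(
    profile: CSPProfile, trim_fraction: float = 0.10
) -> CSPProfile:
    """Return a copy of ``profile`` with the trimmed threshold and the set of
    significantly perturbed residues filled in.

    All residues with an observed ddelta — including the trimmed ones — are
    compared (strictly) against the threshold. Broadened and missing
    residues never enter the statistics and are never marked significant.
    """
    ok = profile.ok_values()
    thr = trimmed_threshold(ok, trim_fraction)
    significant = frozenset(r for r, v in ok.items() if v > thr)
    return replace(profile, threshold=thr, significant=significant)
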