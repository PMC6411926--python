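"""Single-site binding under ligand depletion: forward model, per-residue
nonlinear fits, and outlier-filtered global-Kd aggregation.

When ligand and protein concentrations are comparable (here both in the
0.01-1 mM range) the free-ligand approximation fails and the bound fraction
must come from the exact quadratic solution of the 1:1 equilibrium:

    ddelta = ddelta_max * (([L]+[P]+Kd) - sqrt(([L]+[P]+Kd)**2 - 4[P][L])) / (2[P])

Each responsive residue is fit independently for (Kd, ddelta_max); the
reported global Kd is the mean over significantly perturbed residues after
a single pass removing per-residue Kd values more than ``outlier_sd``
standard deviations from the initial mean. If half or more of the residues
are removed the fits are mutually inconsistent and the result is reported
as a lower limit ("> x mM") instead of a point estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import AggregationError, FitError, NonBinderError

__all__ = [
    "ResidueFit",
    "GlobalKdResult",
    "predict_csp",
    "fit_residue",
    "aggregate_global_kd",
    "render_global_kd",
]

KD_BOUNDS_MM = (1e-6, 1e3)  # searchable Kd window, mM


def predict_csp(P, L, kd: float, dmax: float):
    """Normalized shift change predicted by the depletion isotherm.

    ``P`` (protein, mM) and ``L`` (ligand, mM) may be scalars or arrays and
    broadcast; ``kd`` (mM) and ``dmax`` (ppm) are scalars. The result lies
    in [0, dmax] and reduces to the hyperbola ``dmax*L/(L+kd)`` as P -> 0.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    P = np.asarray(P, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(P <= 0):
        raise ValueError("protein concentration must be positive")
    if np.any(L < 0):
        raise ValueError("ligand concentration must be non-negative")
    b = L + P + kd
    disc = b * b - 4.0 * P * L
    if np.any(disc < -1e-12 * np.maximum(b * b, 1.0)):
        raise FloatingPointError("negative discriminant in binding quadratic")
    disc = np.maximum(disc, 0.0)
    out = dmax * (b - np.sqrt(disc)) / (2.0 * P)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ResidueFit:
    """Per-residue (Kd, ddelta_max) estimate with fit diagnostics."""

    residue_index: int
    kd: float        # mM
    dmax: float      # ppm
    rss: float       # ppm^2
    n_points: int
    converged: bool


def _half_saturation_guess(L: np.ndarray, dd: np.ndarray) -> float:
    """Ligand concentration at which ddelta crosses half its observed
    maximum, by linear interpolation along the titration."""
    order = np.argsort(L)
    L, dd = L[order], dd[order]
    half = dd.max() / 2.0
    for i in range(1, len(L)):
        if dd[i] >= half:
            lo, hi = dd[i - 1], dd[i]
            if hi == lo:
                return float(L[i])
            frac = (half - lo) / (hi - lo)
            return float(L[i - 1] + frac * (L[i] - L[i - 1]))
    return float(L[-1])


def fit_residue(
    trajectory: Sequence[tuple[float, float, float]],
    residue_index: int = -1,
    ftol: float = 1e-10,
) -> ResidueFit:
    """Nonlinear least-squares fit of one residue's (P, L, ddelta) trajectory.

    Kd is optimized on a log10 scale within ``KD_BOUNDS_MM`` and dmax within
    (0, 10*max(ddelta)]. Initialization: Kd at the half-saturation ligand
    concentration, dmax at 1.2x the largest observed ddelta, with one
    fallback start at (10*Kd0, 2*dmax0) if the first attempt fails to
    converge. Deterministic for a given trajectory.
    """
    arr = np.asarray(trajectory, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise FitError("trajectory must be a sequence of (P, L, ddelta) triples")
    P, L, dd = arr[:, 0], arr[:, 1], arr[:, 2]
    usable = np.isfinite(dd)
    P, L, dd = P[usable], L[usable], dd[usable]
    if len(np.unique(L)) < 3:
        raise FitError(
            f"residue {residue_index}: need >= 3 points with distinct ligand "
            f"concentrations, got {len(np.unique(L))}"
        )
    dd_max_obs = float(dd.max())
    if dd_max_obs <= 1e-9:
        raise NonBinderError(
            f"residue {residue_index}: all shift changes below machine noise"
        )

    lo = (math.log10(KD_BOUNDS_MM[0]), 1e-12)
    hi = (math.log10(KD_BOUNDS_MM[1]), 10.0 * dd_max_obs)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return predict_csp(P, L, 10.0 ** theta[0], theta[1]) - dd

    kd0 = float(np.clip(_half_saturation_guess(L, dd), *KD_BOUNDS_MM))
    dmax0 = min(1.2 * dd_max_obs, hi[1])
    starts = [(math.log10(kd0), dmax0)]
    result = None
    for x0 in starts:
        res = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", ftol=ftol, xtol=1e-12
        )
        result = res
        if res.success:
            break
        # single multi-start fallback for non-converged fits
        starts = [
            (
                min(math.log10(kd0 * 10.0), hi[0]),
                min(2.0 * dmax0, hi[1]),
            )
        ] if len(starts) == 1 else []
    assert result is not None
    return ResidueFit(
        residue_index=residue_index,
        kd=float(10.0 ** result.x[0]),
        dmax=float(result.x[1]),
        rss=float(2.0 * result.cost),
        n_points=int(len(dd)),
        converged=bool(result.success),
    )


@dataclass(frozen=True)
class GlobalKdResult:
    """Outlier-filtered average of per-residue Kd estimates."""

    kd_mean: float  # mM
    kd_sd: float    # mM
    retained: frozenset[int]
    removed: frozenset[int]
    lower_limit: bool
    reported: str

    def __post_init__(self) -> None:
        if self.retained & self.removed:
            raise ValueError("retained and removed residue sets overlap")


def render_global_kd(kd_mean: float, kd_sd: float, lower_limit: bool) -> str:
    """Human-readable affinity: ``"0.7 ± 0.1 mM"`` or ``">0.7 mM"`` for a
    lower limit."""
    if lower_limit:
        return f">{kd_mean:.2g} mM"
    return f"{kd_mean:.2g} ± {kd_sd:.2g} mM"


def aggregate_global_kd(
    fits: Iterable[ResidueFit],
    significant: Iterable[int],
    outlier_sd: float = 2.0,
    lower_limit_fraction: float = 0.50,
) -> GlobalKdResult:
    """Average per-residue Kd values over the significantly perturbed set.

    Procedure: (i) mean and sample SD of Kd over converged fits of
    significant residues; (ii) one pass removing fits whose Kd deviates from
    that mean by more than ``outlier_sd`` of that SD; (iii) mean and SD
    recomputed over the retained fits; (iv) if the removed fraction reaches
    ``lower_limit_fraction`` the result is flagged and rendered as a lower
    limit.
    """
    significant = set(significant)
    usable = [f for f in fits if f.converged and f.residue_index in significant]
    if len(usable) < 2:
        raise AggregationError(
            f"need >= 2 converged fits among significant residues, got {len(usable)}"
        )
    kds = np.array([f.kd for f in usable])
    mean0, sd0 = float(kds.mean()), float(kds.std(ddof=1))
    out_mask = np.abs(kds - mean0) > outlier_sd * sd0
    removed = frozenset(f.residue_index for f, o in zip(usable, out_mask) if o)
    retained = frozenset(f.residue_index for f, o in zip(usable, out_mask) if not o)
    kept = kds[~out_mask]
    kd_mean = float(kept.mean())
    kd_sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    lower_limit = len(removed) >= lower_limit_fraction * len(usable)
    return GlobalKdResult(
        kd_mean=kd_mean,
        kd_sd=kd_sd,
        retained=retained,
        removed=removed,
        lower_limit=lower_limit,
        reported=render_global_kd(kd_mean, kd_sd, lower_limit),
    )
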