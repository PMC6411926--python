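"""Synthetic fast-exchange HSQC titrations with known ground truth.

The generator emulates a small (~50-residue) 15N-labelled reader domain at
0.05-0.10 mM titrated with ligand up to a 1:10 molar ratio. Under fast
exchange each responsive amide moves along a fixed direction in the
(1H, 15N) plane by an amount proportional to the bound fraction, which the
depletion isotherm supplies exactly; per-residue saturation amplitudes
(dmax) and directions are drawn once per series. Gaussian ppm noise is
added to every observed shift at every point, non-responsive residues move
only by noise, and a configurable number of responsive residues are lost to
exchange broadening at intermediate saturation (bound fraction 0.3-0.7),
mimicking peaks that broaden beyond detection mid-titration.

The per-residue direction is a unit vector in the *weighted* (dH, w*dN)
plane, so the normalized shift change equals the scalar forward model and
dmax is directly interpretable in normalized-ppm units.

Identical seeds produce bit-identical series (and, via
:func:`cspfit.io.write_series`, byte-identical files).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .binding import predict_csp
from .csp import NITROGEN_WEIGHT
from .peaks import PeakStatus, ResonancePeak, TitrationPoint, TitrationSeries

__all__ = ["SimulationConfig", "simulate_titration", "simulate_ternary"]

# amino acids with a backbone amide (proline excluded)
_AA = "ACDEFGHIKLMNQRSTVWY"

#: Reference-shift windows typical of a folded protein amide fingerprint.
H_WINDOW = (6.5, 10.5)
N_WINDOW = (103.0, 133.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one synthetic titration series.

    Defaults mirror a peptide titration into a ~49-resonance domain at
    0.1 mM with molar ratios 0-10; use ``ratios=(0, 0.25, 0.5, 1, 2)`` and a
    micromolar ``true_kd`` for a DNA-like high-affinity ligand.
    """

    true_kd: float = 0.7          # mM
    protein_conc: float = 0.1     # mM
    ratios: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 7.0, 10.0)
    n_residues: int = 49
    n_responsive: int = 30
    dmax_range: tuple[float, float] = (0.05, 0.25)  # ppm, normalized
    noise_H: float = 0.003        # ppm SD, 1H
    noise_N: float = 0.02         # ppm SD, 15N
    n_broadened: int = 2
    seed: int = 0
    series_id: str = "synthetic"
    ligand_name: str = "ligand"
    first_residue: int = 8        # numbering offset of the domain

    def __post_init__(self) -> None:
        if self.true_kd <= 0 or self.protein_conc <= 0:
            raise ValueError("true_kd and protein_conc must be positive")
        if not self.ratios or self.ratios[0] != 0:
            raise ValueError("ratios must start at 0 (the reference point)")
        if list(self.ratios) != sorted(self.ratios):
            raise ValueError("ratios must be non-decreasing")
        if not 0 <= self.n_responsive <= self.n_residues:
            raise ValueError("n_responsive must be within [0, n_residues]")
        if not 0 <= self.n_broadened <= self.n_responsive:
            raise ValueError("n_broadened must be within [0, n_responsive]")
        if self.noise_H < 0 or self.noise_N < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.dmax_range[0] <= 0 or self.dmax_range[1] < self.dmax_range[0]:
            raise ValueError("dmax_range must be positive and ordered")


#: Exchange-broadening window: bound fractions at which marked residues are
#: lost to intermediate exchange.
BROADENING_WINDOW = (0.3, 0.7)


def simulate_titration(
    config: SimulationConfig,
) -> tuple[TitrationSeries, dict[int, tuple[float, float]]]:
    """Generate one titration series plus its ground truth.

    Returns the series and a mapping ``residue_index -> (kd_mM, dmax_ppm)``
    for the responsive residues.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    indices = np.arange(config.first_residue, config.first_residue + n)
    letters = rng.choice(list(_AA), size=n)
    ref_H = rng.uniform(*H_WINDOW, size=n)
    ref_N = rng.uniform(*N_WINDOW, size=n)
    responsive = np.sort(rng.choice(n, size=config.n_responsive, replace=False))
    dmax = rng.uniform(*config.dmax_range, size=config.n_responsive)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=config.n_responsive)
    if config.n_broadened:
        broadened = set(
            responsive[rng.choice(config.n_responsive, size=config.n_broadened, replace=False)]
        )
    else:
        broadened = set()

    dmax_by_pos = dict(zip(responsive.tolist(), dmax.tolist()))
    phi_by_pos = dict(zip(responsive.tolist(), phi.tolist()))

    points: list[TitrationPoint] = []
    for ratio in config.ratios:
        L = ratio * config.protein_conc
        frac = (
            predict_csp(config.protein_conc, L, config.true_kd, 1.0) if L > 0 else 0.0
        )
        noise_H = rng.normal(0.0, config.noise_H, size=n) if config.noise_H else np.zeros(n)
        noise_N = rng.normal(0.0, config.noise_N, size=n) if config.noise_N else np.zeros(n)
        point = TitrationPoint(
            ratio=float(ratio), protein_conc=config.protein_conc, ligand_conc=float(L)
        )
        for pos in range(n):
            idx = int(indices[pos])
            label = f"{letters[pos]}{idx}"
            if pos in broadened and BROADENING_WINDOW[0] <= frac <= BROADENING_WINDOW[1]:
                point.add_peak(
                    ResonancePeak(idx, label, status=PeakStatus.BROADENED)
                )
                continue
            dd = dmax_by_pos[pos] * frac if pos in dmax_by_pos else 0.0
            dH = dd * math.cos(phi_by_pos[pos]) if pos in phi_by_pos else 0.0
            dN = (
                dd * math.sin(phi_by_pos[pos]) / NITROGEN_WEIGHT
                if pos in phi_by_pos
                else 0.0
            )
            point.add_peak(
                ResonancePeak(
                    idx,
                    label,
                    delta_H=float(ref_H[pos] + dH + noise_H[pos]),
                    delta_N=float(ref_N[pos] + dN + noise_N[pos]),
                    status=PeakStatus.OBSERVED,
                )
            )
        points.append(point)

    series = TitrationSeries(
        series_id=config.series_id,
        ligand_name=config.ligand_name,
        points=points,
        reference_index=0,
    )
    truth = {
        int(indices[pos]): (config.true_kd, dmax_by_pos[pos])
        for pos in responsive.tolist()
    }
    return series, truth


def simulate_ternary(
    config: SimulationConfig, reference_is_complex: bool = True
) -> tuple[TitrationSeries, dict[int, tuple[float, float]]]:
    """Titration into a pre-formed binary complex (e.g. peptide titrated
    into the DNA-bound domain).

    The forward model is unchanged — under fast exchange the second ligand
    perturbs the complex's resonances exactly as it would the free
    protein's — but the reference shifts now represent the pre-bound state
    and the series is labelled accordingly. With
    ``reference_is_complex=False`` this reduces exactly to
    :func:`simulate_titration`.
    """
    if not reference_is_complex:
        return simulate_titration(config)
    cfg = replace(
        config,
        series_id=f"{config.series_id}-ternary",
        ligand_name=f"{config.ligand_name} (into pre-bound complex)",
    )
    return simulate_titration(cfg)
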