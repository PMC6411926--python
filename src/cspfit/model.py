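"""Statsmodels-style front end: a model bound to a titration series whose
``fit()`` returns a results object carrying per-residue and global estimates.

Example
-------
>>> from cspfit import SimulationConfig, simulate_titration, TitrationKdModel
>>> series, truth = simulate_titration(SimulationConfig(true_kd=0.7, seed=1))
>>> res = TitrationKdModel(series).fit()
>>> round(res.kd, 2)  # doctest: +SKIP
0.7
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .binding import GlobalKdResult, ResidueFit, aggregate_global_kd, fit_residue, predict_csp
from .csp import NITROGEN_WEIGHT, CSPProfile, classify_significant, csp_profile
from .exceptions import FitError
from .io import read_series_manifest, write_results
from .peaks import PeakStatus, TitrationSeries

__all__ = ["TitrationKdModel", "TitrationKdResults"]

log = logging.getLogger(__name__)


class TitrationKdModel:
    """Global-Kd estimation from an assigned HSQC titration series.

    Parameters
    ----------
    series
        The titration data. The series' reference point defines the state
        against which perturbations are measured.
    endpoint_index
        Point used for the significance profile; defaults to the point with
        the highest ligand concentration.
    nitrogen_weight
        Weight on the 15N dimension in the normalized shift change.
    trim_fraction
        Fraction of the largest perturbations trimmed before computing the
        significance threshold (mean + 1 SD of the remainder).
    outlier_sd
        Per-residue Kd values deviating more than this many SDs from the
        initial mean are removed before averaging.
    lower_limit_fraction
        Removed fraction at or above which the global Kd is reported as a
        lower limit.
    """

    def __init__(
        self,
        series: TitrationSeries,
        endpoint_index: int | None = None,
        nitrogen_weight: float = NITROGEN_WEIGHT,
        trim_fraction: float = 0.10,
        outlier_sd: float = 2.0,
        lower_limit_fraction: float = 0.50,
    ) -> None:
        self.series = series
        self.endpoint_index = (
            series.endpoint_index if endpoint_index is None else endpoint_index
        )
        self.nitrogen_weight = nitrogen_weight
        self.trim_fraction = trim_fraction
        self.outlier_sd = outlier_sd
        self.lower_limit_fraction = lower_limit_fraction

    @classmethod
    def from_manifest(cls, path: str | Path, **kwargs) -> "TitrationKdModel":
        """Build the model directly from a YAML series manifest."""
        return cls(read_series_manifest(path), **kwargs)

    # ------------------------------------------------------------------

    def residue_trajectory(self, residue: int) -> list[tuple[float, float, float]]:
        """(P, L, ddelta) triples for one residue over every point where it
        and the reference are both observed. The reference contributes the
        (L_ref, 0) anchor."""
        ref = self.series.reference
        ref_peak = ref.peaks.get(residue)
        if ref_peak is None or ref_peak.status is not PeakStatus.OBSERVED:
            raise FitError(f"residue {residue} not observed in the reference point")
        triples = []
        from .csp import normalized_csp

        for i, pt in enumerate(self.series.points):
            peak = pt.peaks.get(residue)
            if peak is None or peak.status is not PeakStatus.OBSERVED:
                continue
            if i == self.series.reference_index:
                dd = 0.0
            else:
                dd = normalized_csp(
                    ref_peak.delta_H,
                    ref_peak.delta_N,
                    peak.delta_H,
                    peak.delta_N,
                    self.nitrogen_weight,
                    residue=residue,
                )
            # ligand added relative to the reference state drives the shift
            triples.append((pt.protein_conc, pt.ligand_conc - ref.ligand_conc, dd))
        return triples

    def fit(self) -> "TitrationKdResults":
        """Run the full pipeline: endpoint CSP profile, trimmed significance
        classification, per-residue depletion fits, global aggregation."""
        profile = csp_profile(self.series, self.endpoint_index, self.nitrogen_weight)
        profile = classify_significant(profile, self.trim_fraction)
        log.info(
            "series %s: threshold %.4f ppm, %d of %d residues significant",
            self.series.series_id,
            profile.threshold,
            len(profile.significant),
            len(profile.ok_values()),
        )
        fits: dict[int, ResidueFit] = {}
        fit_errors: list[FitError] = []
        for r in sorted(profile.significant):
            try:
                fits[r] = fit_residue(self.residue_trajectory(r), residue_index=r)
            except FitError as exc:
                fit_errors.append(exc)
                log.warning("residue %d skipped: %s", r, exc)
        if not fits and fit_errors:
            raise FitError(f"no residue could be fit: {fit_errors[0]}")
        global_kd = aggregate_global_kd(
            fits.values(),
            profile.significant,
            self.outlier_sd,
            self.lower_limit_fraction,
        )
        log.info(
            "series %s: global Kd %s (%d retained, %d removed%s)",
            self.series.series_id,
            global_kd.reported,
            len(global_kd.retained),
            len(global_kd.removed),
            ", lower limit" if global_kd.lower_limit else "",
        )
        return TitrationKdResults(self, profile, fits, global_kd)


class TitrationKdResults:
    """Estimates, diagnostics and output helpers from a fitted model."""

    def __init__(
        self,
        model: TitrationKdModel,
        profile: CSPProfile,
        residue_fits: dict[int, ResidueFit],
        global_kd: GlobalKdResult,
    ) -> None:
        self.model = model
        self.profile = profile
        self.residue_fits = residue_fits
        self.global_kd = global_kd

    # -- convenience accessors -----------------------------------------

    @property
    def kd(self) -> float:
        """Global Kd (mM), the outlier-filtered mean over retained residues."""
        return self.global_kd.kd_mean

    @property
    def kd_sd(self) -> float:
        return self.global_kd.kd_sd

    @property
    def lower_limit(self) -> bool:
        return self.global_kd.lower_limit

    def residue_table(self) -> pd.DataFrame:
        df = self.profile.to_frame()
        fits = self.residue_fits
        df["kd_mM"] = [fits[r].kd if r in fits else np.nan for r in df["residue"]]
        df["dmax_ppm"] = [fits[r].dmax if r in fits else np.nan for r in df["residue"]]
        df["rss"] = [fits[r].rss if r in fits else np.nan for r in df["residue"]]
        df["retained"] = [r in self.global_kd.retained for r in df["residue"]]
        return df

    def summary(self) -> str:
        """Plain-text report of the fit, one block per quantity of interest."""
        s = self.model.series
        g = self.global_kd
        lines = [
            "Titration global-Kd fit",
            "=" * 58,
            f"series:            {s.series_id} ({s.ligand_name})",
            f"points:            {len(s.points)}  (reference index {s.reference_index},"
            f" endpoint index {self.model.endpoint_index})",
            f"protein conc:      {s.reference.protein_conc:g} mM",
            f"max ligand conc:   {max(p.ligand_conc for p in s.points):g} mM",
            f"CSP threshold:     {self.profile.threshold:.4f} ppm"
            f" (trim fraction {self.model.trim_fraction:g})",
            f"significant:       {len(self.profile.significant)} of"
            f" {len(self.profile.ok_values())} observed residues",
            f"fits converged:    {sum(f.converged for f in self.residue_fits.values())}"
            f" of {len(self.residue_fits)}",
            f"Kd retained/removed: {len(g.retained)}/{len(g.removed)}"
            f" (outlier rule {self.model.outlier_sd:g} SD)",
            f"global Kd:         {g.reported}",
            "-" * 58,
        ]
        table = self.residue_table()
        fitted = table[table["significant"]]
        if not fitted.empty:
            lines.append(
                fitted[
                    ["residue", "label", "dd_ppm", "kd_mM", "dmax_ppm", "retained"]
                ].to_string(index=False, float_format=lambda x: f"{x:.4g}")
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> tuple[Path, Path]:
        """Write the per-residue TSV and global JSON summary."""
        return write_results(
            self.residue_fits.values(), self.global_kd, outdir, self.profile
        )

    # -- plotting ------------------------------------------------------

    def plot_profile(self, ax=None):
        """Bar plot of ddelta against residue number with the significance
        threshold; significant residues highlighted, broadened ones marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        df = self.profile.to_frame()
        ok = df[df["status"] == "ok"]
        colors = ["tab:blue" if s else "0.6" for s in ok["significant"]]
        ax.bar(ok["residue"], ok["dd_ppm"], color=colors)
        broad = df[df["status"] == "broadened"]
        if not broad.empty:
            ax.plot(broad["residue"], [0.0] * len(broad), "o", color="tab:blue", ms=4)
        ax.axhline(self.profile.threshold, ls="--", color="k", lw=0.8)
        ax.set_xlabel("residue")
        ax.set_ylabel(r"$\Delta\delta$ (ppm)")
        ax.set_title(f"{self.model.series.series_id}: CSP profile")
        return ax

    def plot_fit(self, residue: int, ax=None):
        """Observed ddelta versus ligand concentration for one residue with
        the fitted depletion isotherm."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fit = self.residue_fits[residue]
        traj = np.asarray(self.model.residue_trajectory(residue))
        ax.plot(traj[:, 1], traj[:, 2], "o", label="observed")
        grid = np.linspace(0.0, traj[:, 1].max(), 200)
        P = float(traj[:, 0].mean())
        curve = [predict_csp(P, l, fit.kd, fit.dmax) if l > 0 else 0.0 for l in grid]
        ax.plot(grid, curve, "-", label=f"fit: Kd={fit.kd:.3g} mM")
        ax.set_xlabel("[L] (mM)")
        ax.set_ylabel(r"$\Delta\delta$ (ppm)")
        ax.legend()
        return ax
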