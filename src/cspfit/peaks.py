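"""Domain containers for assigned HSQC titration data.

A titration series is an ordered set of :class:`TitrationPoint` objects, each
holding the assigned backbone-amide peak list recorded at one protein:ligand
molar ratio. One point (usually the first, ligand-free one) is the reference
state against which chemical shift perturbations are measured; for ternary
experiments the reference may instead be a pre-formed binary complex.

Units are ppm for chemical shifts and mM for concentrations throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["PeakStatus", "ResonancePeak", "TitrationPoint", "TitrationSeries"]


class PeakStatus(str, enum.Enum):
    """Observability of a backbone amide resonance at one titration point."""

    OBSERVED = "observed"
    BROADENED = "broadened"  # lost to exchange broadening during the titration
    MISSING = "missing"      # absent for an unspecified reason
    PROLINE = "proline"      # no backbone amide proton
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ResonancePeak:
    """One assigned amide cross-peak.

    ``delta_H`` / ``delta_N`` are finite if and only if the peak was actually
    observed; for broadened/missing/proline entries they are NaN placeholders.
    """

    residue_index: int
    residue_label: str
    delta_H: float = math.nan
    delta_N: float = math.nan
    status: PeakStatus = PeakStatus.OBSERVED

    def __post_init__(self) -> None:
        finite = math.isfinite(self.delta_H) and math.isfinite(self.delta_N)
        if self.status is PeakStatus.OBSERVED and not finite:
            raise ValueError(
                f"residue {self.residue_label}: observed peak requires finite shifts"
            )
        if self.status is not PeakStatus.OBSERVED and finite:
            raise ValueError(
                f"residue {self.residue_label}: non-observed peak must carry NaN shifts"
            )


@dataclass
class TitrationPoint:
    """Peak list plus concentrations at one molar ratio.

    Either the ratio or the ligand concentration may be derived from the
    other (``ligand_conc = ratio * protein_conc``). Peaks are keyed by
    residue index, which enforces uniqueness within the point.
    """

    ratio: float
    protein_conc: float  # mM
    ligand_conc: float   # mM
    peaks: dict[int, ResonancePeak] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protein_conc > 0:
            raise ValueError("protein_conc must be positive (mM)")
        if self.ligand_conc < 0:
            raise ValueError("ligand_conc must be non-negative (mM)")

    def add_peak(self, peak: ResonancePeak) -> None:
        if peak.residue_index in self.peaks:
            raise ValueError(f"duplicate residue_index {peak.residue_index}")
        self.peaks[peak.residue_index] = peak

    def observed(self) -> dict[int, ResonancePeak]:
        return {
            i: p for i, p in self.peaks.items() if p.status is PeakStatus.OBSERVED
        }


@dataclass
class TitrationSeries:
    """Ordered titration points sharing one residue universe."""

    series_id: str
    ligand_name: str
    points: list[TitrationPoint]
    reference_index: int = 0
    temperature: float = 25.0  # degrees C, metadata only

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("a titration series needs at least one point")
        if not 0 <= self.reference_index < len(self.points):
            raise ValueError(
                f"reference_index {self.reference_index} outside 0..{len(self.points) - 1}"
            )

    @property
    def reference(self) -> TitrationPoint:
        return self.points[self.reference_index]

    @property
    def endpoint_index(self) -> int:
        """Index of the point with the highest ligand concentration."""
        return max(range(len(self.points)), key=lambda i: self.points[i].ligand_conc)

    def residue_indices(self) -> list[int]:
        """Union of residue indices over all points, sorted."""
        out: set[int] = set()
        for pt in self.points:
            out.update(pt.peaks)
        return sorted(out)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[TitrationPoint]:
        return iter(self.points)
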