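"""Exception hierarchy for the titration pipeline.

Every stage raises a subclass of :class:`CspfitError` so the CLI can map
failures to a stage name and a nonzero exit status.
"""


class CspfitError(Exception):
    """Base class for all package errors."""


class PeaklistError(CspfitError, ValueError):
    """Malformed or inconsistent peak-list input."""


class ManifestError(CspfitError, ValueError):
    """Malformed titration-series manifest."""


class CSPError(CspfitError, ValueError):
    """Chemical-shift-perturbation computation failed (non-finite shifts,
    no shared residues, too few observed resonances)."""


class FitError(CspfitError, ValueError):
    """Per-residue binding-isotherm fit could not be performed."""


class NonBinderError(FitError):
    """All observed shift changes are indistinguishable from zero."""


class AggregationError(CspfitError, ValueError):
    """Global-Kd aggregation had fewer than two usable per-residue fits."""


class BedError(CspfitError, ValueError):
    """Malformed BED interval input."""
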