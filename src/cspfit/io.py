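"""Reading and writing peak lists, series manifests, and result tables.

Peak lists are Sparky-style whitespace/tab-separated text with one assigned
cross-peak per row::

    V10N-H    121.300000    8.450000

The default column order is assignment, 15N (ppm), 1H (ppm); pass
``shift_order=("H", "N")`` for lists written the other way round.

A titration series is described by one YAML manifest pointing at one peak
list per point::

    series_id: k27me3
    ligand_name: H3K27me3
    protein_conc_mM: 0.1
    temperature_C: 25
    reference: 0
    points:
      - {file: point_00.list, ratio: 0}
      - {file: point_01.list, ratio: 1, broadened: [L49]}
      - {file: point_05.list, ligand_conc_mM: 1.0}

Concentrations may be given in micromolar with ``_uM`` keys instead of
``_mM``; they are converted on read. Internally everything is mM and ppm.
"""

from __future__ import annotations

import json
import logging
import math
import re
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import yaml

from .exceptions import ManifestError, PeaklistError
from .peaks import PeakStatus, ResonancePeak, TitrationPoint, TitrationSeries

if TYPE_CHECKING:  # pragma: no cover
    from .binding import GlobalKdResult, ResidueFit
    from .csp import CSPProfile

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_series_manifest",
    "write_series",
    "write_results",
]

log = logging.getLogger(__name__)

# assignment labels like "V10N-H", "V10NH", "V10N-HN", or bare "V10"
_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)")


def _parse_label(label: str) -> tuple[int, str] | None:
    m = _LABEL_RE.match(label)
    if m is None:
        return None
    return int(m.group(2)), f"{m.group(1).upper()}{m.group(2)}"


def read_peaklist(
    path: str | Path,
    format: str = "sparky_tsv",
    shift_order: Sequence[str] = ("N", "H"),
) -> list[ResonancePeak]:
    """Read an assigned peak list; every parsed row has status ``observed``.

    Rows whose assignment label cannot be parsed into a residue index are
    kept with status ``unassigned`` (and a synthetic negative residue index
    so they never collide with real residues) and a warning is logged.
    """
    if format != "sparky_tsv":
        raise ValueError(f"unknown peak-list format {format!r}")
    path = Path(path)
    order = tuple(s.upper() for s in shift_order)
    if sorted(order) != ["H", "N"]:
        raise ValueError("shift_order must be a permutation of ('N', 'H')")

    peaks: list[ResonancePeak] = []
    seen: set[int] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if tokens[0].lower() == "assignment":  # Sparky header row
                continue
            if len(tokens) < 3:
                raise PeaklistError(
                    f"{path}:{lineno}: expected assignment and two shift columns"
                )
            try:
                w1, w2 = float(tokens[1]), float(tokens[2])
            except ValueError as exc:
                raise PeaklistError(
                    f"{path}:{lineno}: malformed numeric field: {exc}"
                ) from None
            shifts = dict(zip(order, (w1, w2)))
            parsed = _parse_label(tokens[0])
            if parsed is None:
                log.warning("%s:%d: unparseable assignment %r", path, lineno, tokens[0])
                peaks.append(
                    ResonancePeak(
                        residue_index=-lineno,
                        residue_label=tokens[0],
                        status=PeakStatus.UNASSIGNED,
                    )
                )
                continue
            idx, label = parsed
            if idx in seen:
                raise PeaklistError(f"{path}:{lineno}: duplicate residue_index {idx}")
            seen.add(idx)
            peaks.append(
                ResonancePeak(
                    residue_index=idx,
                    residue_label=label,
                    delta_H=shifts["H"],
                    delta_N=shifts["N"],
                    status=PeakStatus.OBSERVED,
                )
            )
    return peaks


def write_peaklist(peaks: Iterable[ResonancePeak], path: str | Path) -> None:
    """Write observed peaks in assignment / 15N / 1H order.

    Shifts are serialized with ``repr`` so a read/write round trip is
    bit-exact for any finite float.
    """
    path = Path(path)
    lines = ["# Assignment\tw1 (15N, ppm)\tw2 (1H, ppm)"]
    for p in sorted(peaks, key=lambda p: p.residue_index):
        if p.status is not PeakStatus.OBSERVED:
            continue
        lines.append(f"{p.residue_label}N-H\t{p.delta_N!r}\t{p.delta_H!r}")
    path.write_text("\n".join(lines) + "\n")


def _conc_from(mapping: dict, stem: str) -> float | None:
    """Fetch ``<stem>_mM`` or ``<stem>_uM`` (converted to mM) from a dict."""
    if f"{stem}_mM" in mapping:
        return float(mapping[f"{stem}_mM"])
    if f"{stem}_uM" in mapping:
        return float(mapping[f"{stem}_uM"]) / 1000.0
    return None


def read_series_manifest(path: str | Path) -> TitrationSeries:
    """Assemble a :class:`TitrationSeries` from a YAML manifest.

    Points are sorted by ligand concentration (ascending, stable). Residues
    present in the reference point but absent from another point are
    inserted there with status ``broadened`` when the manifest lists them
    under that point's ``broadened`` key, else ``missing``.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except OSError as exc:
        raise ManifestError(f"cannot read manifest {path}: {exc}") from None
    if not isinstance(doc, dict) or "points" not in doc:
        raise ManifestError(f"{path}: manifest must be a mapping with a 'points' list")

    default_p = _conc_from(doc, "protein_conc")
    entries = doc["points"]
    if not entries:
        raise ManifestError(f"{path}: empty points list")
    if "reference" not in doc:
        raise ManifestError(f"{path}: missing 'reference' point index")
    ref_entry = int(doc["reference"])
    if not 0 <= ref_entry < len(entries):
        raise ManifestError(
            f"{path}: reference point {ref_entry} not listed (have {len(entries)} points)"
        )

    points: list[tuple[TitrationPoint, list[str], bool]] = []
    for i, entry in enumerate(entries):
        p_conc = _conc_from(entry, "protein_conc")
        if p_conc is None:
            p_conc = default_p
        if p_conc is None:
            raise ManifestError(f"{path}: point {i}: no protein concentration given")
        l_conc = _conc_from(entry, "ligand_conc")
        ratio = entry.get("ratio")
        if l_conc is None and ratio is None:
            raise ManifestError(
                f"{path}: point {i}: neither ratio nor ligand_conc given"
            )
        if l_conc is None:
            l_conc = float(ratio) * p_conc
        if ratio is None:
            ratio = l_conc / p_conc
        if "file" not in entry:
            raise ManifestError(f"{path}: point {i}: missing peak-list file")
        peakfile = path.parent / entry["file"]
        if not peakfile.exists():
            raise ManifestError(f"{path}: point {i}: peak-list file {peakfile} not found")
        point = TitrationPoint(ratio=float(ratio), protein_conc=p_conc, ligand_conc=l_conc)
        for pk in read_peaklist(peakfile):
            point.add_peak(pk)
        points.append((point, list(entry.get("broadened", [])), i == ref_entry))

    # stable sort by ligand concentration; track where the reference lands
    points.sort(key=lambda t: t[0].ligand_conc)
    reference_index = next(i for i, t in enumerate(points) if t[2])

    # fill residues lost relative to the reference
    ref_point = points[reference_index][0]
    for i, (point, broad_labels, _) in enumerate(points):
        if i == reference_index:
            continue
        for idx, ref_peak in ref_point.peaks.items():
            if idx in point.peaks:
                continue
            status = (
                PeakStatus.BROADENED
                if ref_peak.residue_label in broad_labels
                else PeakStatus.MISSING
            )
            point.add_peak(
                ResonancePeak(
                    residue_index=idx, residue_label=ref_peak.residue_label, status=status
                )
            )

    series = TitrationSeries(
        series_id=str(doc.get("series_id", path.stem)),
        ligand_name=str(doc.get("ligand_name", "ligand")),
        points=[t[0] for t in points],
        reference_index=reference_index,
        temperature=float(doc.get("temperature_C", 25.0)),
    )
    min_l = min(pt.ligand_conc for pt in series.points)
    if series.reference.ligand_conc > min_l:
        # legitimate for ternary experiments where the reference is a complex
        log.info(
            "%s: reference point is not the lowest-ligand point (ternary reference?)",
            path,
        )
    return series


def write_series(
    series: TitrationSeries,
    outdir: str | Path,
    ground_truth: dict[int, tuple[float, float]] | None = None,
) -> Path:
    """Write one peak list per point plus a YAML manifest; returns the
    manifest path. Round-trips through :func:`read_series_manifest`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pt in enumerate(series.points):
        fname = f"point_{i:02d}.list"
        write_peaklist(pt.peaks.values(), outdir / fname)
        broadened = sorted(
            p.residue_label
            for p in pt.peaks.values()
            if p.status is PeakStatus.BROADENED
        )
        entry: dict = {
            "file": fname,
            "ratio": float(pt.ratio),
            "ligand_conc_mM": float(pt.ligand_conc),
            "protein_conc_mM": float(pt.protein_conc),
        }
        if broadened:
            entry["broadened"] = broadened
        entries.append(entry)
    doc = {
        "series_id": series.series_id,
        "ligand_name": series.ligand_name,
        "temperature_C": float(series.temperature),
        "reference": series.reference_index,
        "points": entries,
    }
    manifest = outdir / "series.yaml"
    manifest.write_text(yaml.safe_dump(doc, sort_keys=False))
    if ground_truth is not None:
        (outdir / "ground_truth.json").write_text(
            json.dumps(
                {
                    str(idx): {"kd_mM": kd, "dmax_ppm": dmax}
                    for idx, (kd, dmax) in sorted(ground_truth.items())
                },
                indent=1,
            )
        )
    return manifest


def write_results(
    fits: Iterable["ResidueFit"],
    global_result: "GlobalKdResult",
    outdir: str | Path,
    profile: "CSPProfile | None" = None,
) -> tuple[Path, Path]:
    """Write the per-residue fit table (TSV) and the global-Kd summary (JSON).

    Numbers are serialized with 8 significant digits so re-reading the table
    reproduces the in-memory values to well beyond experimental precision.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("write_results needs at least one residue fit")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from None

    def fmt(x: float) -> str:
        return "nan" if x is None or not math.isfinite(x) else f"{x:.8g}"

    fitted = {f.residue_index: f for f in fits}
    residues = sorted(
        set(fitted) | (set(profile.values) | set(profile.statuses) if profile else set())
    )
    rows = ["residue\tdd_endpoint_ppm\tsignificant\tkd_mM\tdmax_ppm\trss\tretained"]
    for r in residues:
        dd = profile.values.get(r, math.nan) if profile else math.nan
        sig = bool(profile and r in profile.significant)
        f = fitted.get(r)
        rows.append(
            "\t".join(
                [
                    str(r),
                    fmt(dd),
                    str(int(sig)),
                    fmt(f.kd) if f else "nan",
                    fmt(f.dmax) if f else "nan",
                    fmt(f.rss) if f else "nan",
                    str(int(r in global_result.retained)),
                ]
            )
        )
    table_path = outdir / "residue_fits.tsv"
    table_path.write_text("\n".join(rows) + "\n")

    summary = {
        "global_kd_mM": global_result.kd_mean,
        "kd_sd_mM": global_result.kd_sd,
        "n_retained": len(global_result.retained),
        "n_removed": len(global_result.removed),
        "lower_limit": global_result.lower_limit,
        "reported": global_result.reported,
    }
    summary_path = outdir / "global_kd.json"
    summary_path.write_text(json.dumps(summary, indent=1) + "\n")
    return table_path, summary_path
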