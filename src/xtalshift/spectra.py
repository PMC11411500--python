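"""Peak-list and correlation-set data model, delimited-text readers, and
DQ/SQ pair resolution.

Peak lists are taken as already picked: the inputs to inference are peak
positions, not raw spectra.  2D correlation sets are typed by experiment:

* ``HETCOR_SHORT`` - one-bond C-H cross peaks (short CP contact time);
  f1 is the 13C coordinate, f2 the 1H coordinate.
* ``HETCOR_LONG``  - multi-bond C-H cross peaks (long CP contact time).
* ``DQSQ``         - 1H-1H double-quantum/single-quantum correlation;
  f1 is the DQ coordinate (the sum of two proton shifts), f2 the SQ
  coordinate.

Default matching tolerances are half the typical linewidths at ultra-fast
MAS: 0.25 ppm for 1H and 0.5 ppm for 13C.  The DQ coordinate is a sum of
two uncertain shifts, so its tolerance is twice the SQ tolerance.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "TOL_H", "TOL_C",
    "Peak", "PeakList", "CorrelationSet", "ProtonPairContact",
    "read_peaklist", "read_correlations", "resolve_dq_pairs",
    "write_peaklist", "write_correlations",
]

logger = logging.getLogger(__name__)

TOL_H = 0.25  # ppm, default 1H matching tolerance
TOL_C = 0.50  # ppm, default 13C matching tolerance

EXPERIMENTS = ("HETCOR_SHORT", "HETCOR_LONG", "DQSQ")


@dataclass(frozen=True)
class Peak:
    peak_id: str
    shift: float
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift):
            raise ValueError(f"peak {self.peak_id}: shift must be finite")


@dataclass
class PeakList:
    nucleus: str  # "H1" or "C13"
    peaks: list[Peak]

    def __post_init__(self) -> None:
        if self.nucleus not in ("H1", "C13"):
            raise ValueError(f"unknown nucleus {self.nucleus!r}")
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError("peak_ids must be unique")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_id(self, peak_id: str) -> Peak:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        raise KeyError(peak_id)

    def nearest(self, shift: float, tolerance: float) -> Peak | None:
        best, dist = None, tolerance
        for p in self.peaks:
            d = abs(p.shift - shift)
            if d <= dist:
                best, dist = p, d
        return best


@dataclass
class CorrelationSet:
    experiment: str
    entries: list[tuple[float, float]]
    tolerance_f1: float
    tolerance_f2: float

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ProtonPairContact:
    """A resolved DQ/SQ contact between two proton peaks (equal ids give an
    autocorrelation peak on the 2:1 diagonal)."""

    peak_id_a: str
    peak_id_b: str
    dq_coordinate: float


def _dialect(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()
    return "\t" if head and "\t" in head[0] else ","


def read_peaklist(path: str | Path, nucleus: str) -> PeakList:
    """Read a 1D peak list from delimited text with header columns
    ``id, shift_ppm[, intensity]`` (comma or tab separated)."""
    path = Path(path)
    delim = _dialect(path)
    peaks = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        cols = [c.strip() for c in (reader.fieldnames or [])]
        if "id" not in cols or "shift_ppm" not in cols:
            raise ValueError(
                f"{path}: expected columns 'id, shift_ppm', got {cols}"
            )
        for row_no, row in enumerate(reader, start=1):
            row = {(k or "").strip(): (v or "").strip() for k, v in row.items()}
            try:
                shift = float(row["shift_ppm"])
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"{path}: non-numeric shift at row {row_no}: "
                    f"{row.get('shift_ppm')!r}"
                ) from exc
            inten = row.get("intensity") or None
            peaks.append(Peak(
                peak_id=row["id"],
                shift=shift,
                intensity=float(inten) if inten else None,
            ))
    return PeakList(nucleus=nucleus, peaks=peaks)


def read_correlations(
    path: str | Path,
    experiment: str,
    tolerance_f1: float | None = None,
    tolerance_f2: float | None = None,
) -> CorrelationSet:
    """Read a 2D correlation peak list with columns ``f1_ppm, f2_ppm``."""
    path = Path(path)
    if tolerance_f2 is None:
        tolerance_f2 = TOL_H
    if tolerance_f1 is None:
        tolerance_f1 = 2 * TOL_H if experiment == "DQSQ" else TOL_C
    delim = _dialect(path)
    entries = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        cols = [c.strip() for c in (reader.fieldnames or [])]
        if "f1_ppm" not in cols or "f2_ppm" not in cols:
            raise ValueError(
                f"{path}: expected columns 'f1_ppm, f2_ppm', got {cols}"
            )
        for row_no, row in enumerate(reader, start=1):
            row = {(k or "").strip(): (v or "").strip() for k, v in row.items()}
            try:
                f1 = float(row["f1_ppm"])
                f2 = float(row["f2_ppm"])
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"{path}: non-numeric coordinate at row {row_no}"
                ) from exc
            entries.append((f1, f2))
    return CorrelationSet(
        experiment=experiment,
        entries=entries,
        tolerance_f1=tolerance_f1,
        tolerance_f2=tolerance_f2,
    )


def resolve_dq_pairs(
    dqsq: CorrelationSet, h_peaks: PeakList
) -> list[ProtonPairContact]:
    """Resolve DQ/SQ entries into proton-peak pair contacts.

    For each entry ``(dq, sq)`` the SQ coordinate is matched to a proton
    peak ``p`` within the SQ tolerance; every peak ``q`` (including ``p``
    itself, giving an autocorrelation) with ``|shift_p + shift_q - dq|``
    within twice the SQ tolerance is emitted as a partner.  Entries whose
    SQ coordinate matches no peak are skipped with a warning.  Symmetric
    duplicates (the two cross peaks of one contact) are merged.
    """
    if dqsq.experiment != "DQSQ":
        raise ValueError("resolve_dq_pairs requires a DQSQ correlation set")
    tol_sq = dqsq.tolerance_f2
    tol_dq = 2 * tol_sq
    seen: dict[tuple[str, str, float], ProtonPairContact] = {}
    for dq, sq in dqsq.entries:
        p = h_peaks.nearest(sq, tol_sq)
        if p is None:
            logger.warning(
                "DQ/SQ entry (%.2f, %.2f): no SQ peak within %.2f ppm; skipped",
                dq, sq, tol_sq,
            )
            continue
        for q in h_peaks:
            if abs(p.shift + q.shift - dq) <= tol_dq:
                a, b = sorted((p.peak_id, q.peak_id))
                key = (a, b, round(dq, 6))
                seen.setdefault(
                    key, ProtonPairContact(a, b, dq_coordinate=dq)
                )
    return list(seen.values())


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "shift_ppm", "intensity"])
        for p in peaklist:
            w.writerow([p.peak_id, repr(p.shift),
                        "" if p.intensity is None else repr(p.intensity)])


def write_correlations(corr: CorrelationSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["f1_ppm", "f2_ppm"])
        for f1, f2 in corr.entries:
            w.writerow([repr(f1), repr(f2)])
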