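"""Per-site predicted-shift distributions and peak-site compatibility.

Each site gets a Gaussian prior over its chemical shift, typically centred
on the output of a shift predictor, with a standard deviation defaulting
to the predictor's published per-nucleus model error (4.53 ppm for 13C,
0.47 ppm for 1H).  Predicted shieldings sigma are converted to shifts via
the per-nucleus referencing offset, delta = offset - sigma; the conversion
is done in decimal arithmetic so that shift + shielding reproduces the
offset exactly at the printed precision.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

__all__ = [
    "SD_C", "SD_H", "WEIGHT_FLOOR", "Z_MAX",
    "ReferencingConstants", "ShiftPrior", "CandidateTable",
    "shielding_to_shift", "load_predictions", "candidate_table",
]

SD_C = 4.53  # ppm, default 13C prior width (predictor model error)
SD_H = 0.47  # ppm, default 1H prior width
Z_MAX = 4.0  # default candidate gate, in prior standard deviations
WEIGHT_FLOOR = 1e-30  # avoids zero-probability global assignments


@dataclass(frozen=True)
class ReferencingConstants:
    """Shielding-to-shift referencing offsets, fixed per predictor version."""

    offset_h: float = 30.78
    offset_c: float = 170.04

    def __post_init__(self) -> None:
        if self.offset_h <= 0 or self.offset_c <= 0:
            raise ValueError("referencing offsets must be positive")

    def offset(self, nucleus: str) -> float:
        if nucleus == "H1":
            return self.offset_h
        if nucleus == "C13":
            return self.offset_c
        raise ValueError(f"unknown nucleus {nucleus!r}")


@dataclass(frozen=True)
class ShiftPrior:
    site_label: str
    mean: float
    sd: float
    nucleus: str = ""

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"{self.site_label}: sd must be positive")

    def density(self, shift: float) -> float:
        z = (shift - self.mean) / self.sd
        return math.exp(-0.5 * z * z) / (self.sd * math.sqrt(2 * math.pi))


def shielding_to_shift(
    sigma: float, nucleus: str,
    constants: ReferencingConstants | None = None,
) -> float:
    """Convert an isotropic shielding to a chemical shift, offset - sigma.

    Decimal arithmetic keeps the identity shift + shielding = offset exact
    for values given at printed precision.
    """
    constants = constants or ReferencingConstants()
    offset = constants.offset(nucleus)
    return float(Decimal(str(offset)) - Decimal(str(sigma)))


def _nucleus_of_label(label: str) -> str:
    if label.startswith("H"):
        return "H1"
    if label.startswith("C"):
        return "C13"
    raise ValueError(f"cannot infer nucleus from site label {label!r}")


def load_predictions(
    path: str | Path,
    constants: ReferencingConstants | None = None,
    default_sd_h: float = SD_H,
    default_sd_c: float = SD_C,
    sites: list | None = None,
) -> list[ShiftPrior]:
    """Load a per-site prediction table into shift priors.

    The table is delimited text with columns ``site_label, value, kind``
    (kind in {shift, shielding}) and an optional ``sd`` column; shieldings
    are converted through the referencing offsets and missing sd values are
    replaced by the per-nucleus default.  If ``sites`` is given, labels are
    checked against the site model.
    """
    constants = constants or ReferencingConstants()
    path = Path(path)
    known = {s.label: s.nucleus for s in sites} if sites is not None else None
    head = path.read_text(encoding="utf-8").splitlines()
    delim = "\t" if head and "\t" in head[0] else ","
    priors: list[ShiftPrior] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        cols = [c.strip() for c in (reader.fieldnames or [])]
        for required in ("site_label", "value", "kind"):
            if required not in cols:
                raise ValueError(f"{path}: missing column {required!r}")
        for row_no, row in enumerate(reader, start=1):
            row = {(k or "").strip(): (v or "").strip() for k, v in row.items()}
            label = row["site_label"]
            if label in seen:
                raise ValueError(f"{path}: duplicate site label {label!r}")
            seen.add(label)
            if known is not None:
                if label not in known:
                    raise ValueError(
                        f"{path}: site label {label!r} not in site model"
                    )
                nucleus = known[label]
            else:
                nucleus = _nucleus_of_label(label)
            try:
                value = float(row["value"])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value at row {row_no}"
                ) from exc
            kind = row["kind"]
            if kind == "shielding":
                mean = shielding_to_shift(value, nucleus, constants)
            elif kind == "shift":
                mean = value
            else:
                raise ValueError(
                    f"{path}: row {row_no}: kind must be 'shift' or "
                    f"'shielding', got {kind!r}"
                )
            sd_text = row.get("sd") or ""
            if sd_text:
                sd = float(sd_text)
            else:
                sd = default_sd_h if nucleus == "H1" else default_sd_c
            priors.append(ShiftPrior(label, mean=mean, sd=sd, nucleus=nucleus))
    return priors


@dataclass
class CandidateTable:
    """Gated likelihood weights over (site, peak) pairs of matching nucleus.

    ``weights[site][peak_id]`` is the Gaussian prior density of the peak
    shift, floored to avoid underflow; a site's candidate set is the peaks
    within ``z_max`` prior standard deviations.  Sites whose candidate set
    is empty are flagged infeasible rather than silently dropped.
    """

    nuclei: dict[str, str]                  # site label -> nucleus
    weights: dict[str, dict[str, float]]    # site -> peak_id -> weight
    peak_shifts: dict[str, float]           # peak_id -> shift
    peak_nuclei: dict[str, str]             # peak_id -> nucleus
    infeasible: list[str] = field(default_factory=list)
    eliminations: list = field(default_factory=list)  # filled by propagation

    def candidates(self, site: str) -> set[str]:
        return set(self.weights[site])

    def is_singleton(self, site: str) -> bool:
        return len(self.weights[site]) == 1

    def copy(self) -> "CandidateTable":
        return CandidateTable(
            nuclei=dict(self.nuclei),
            weights={s: dict(w) for s, w in self.weights.items()},
            peak_shifts=dict(self.peak_shifts),
            peak_nuclei=dict(self.peak_nuclei),
            infeasible=list(self.infeasible),
            eliminations=list(self.eliminations),
        )

    def sites_with_candidate(self, peak_id: str) -> list[str]:
        return [s for s, w in self.weights.items() if peak_id in w]


def candidate_table(
    priors: list[ShiftPrior],
    peaklists: list,
    z_max: float = Z_MAX,
) -> CandidateTable:
    """Score peak-site compatibility under the Gaussian priors.

    Every site of each supplied nucleus must have a prior.  Peak ids must
    be unique across the supplied peak lists.
    """
    by_label = {p.site_label: p for p in priors}
    if len(by_label) != len(priors):
        raise ValueError("duplicate priors")
    peak_shifts: dict[str, float] = {}
    peak_nuclei: dict[str, str] = {}
    for pl in peaklists:
        for pk in pl:
            if pk.peak_id in peak_shifts:
                raise ValueError(f"duplicate peak id {pk.peak_id!r} across lists")
            peak_shifts[pk.peak_id] = pk.shift
            peak_nuclei[pk.peak_id] = pl.nucleus

    nuclei = {p.site_label: p.nucleus for p in priors}
    weights: dict[str, dict[str, float]] = {}
    infeasible: list[str] = []
    for prior in priors:
        row: dict[str, float] = {}
        for pid, shift in peak_shifts.items():
            if peak_nuclei[pid] != prior.nucleus:
                continue
            if abs(shift - prior.mean) <= z_max * prior.sd:
                row[pid] = max(prior.density(shift), WEIGHT_FLOOR)
        if not row:
            infeasible.append(prior.site_label)
        weights[prior.site_label] = row
    return CandidateTable(
        nuclei=nuclei,
        weights=weights,
        peak_shifts=peak_shifts,
        peak_nuclei=peak_nuclei,
        infeasible=infeasible,
    )
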