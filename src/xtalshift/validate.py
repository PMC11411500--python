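"""Structure validation by comparison of assigned and predicted shifts.

Given an assignment of experimental peaks to sites and a per-site
predicted-shift table for a candidate crystal structure, the validation
computes the per-site shift difference (delta = experiment - prediction),
the per-nucleus root-mean-square deviation, and a verdict: the structure
is validated when the RMSD of each nucleus is within the expected error of
the shift predictor and no site deviates by more than ``outlier_k`` times
that expected error.

Sites left ambiguous by the assignment (e.g. near-degenerate methyl
groups) are either excluded or included under the best-case pairing - the
injective pairing of ambiguous sites to their candidate peaks that
minimises the total squared deviation - and flagged as such.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from xtalshift.assign import AssignmentResult
from xtalshift.priors import ShiftPrior
from xtalshift.spectra import PeakList

__all__ = [
    "OUTLIER_K",
    "DeltaTable",
    "ValidationReport",
    "delta_table",
    "rmsd",
    "verdict",
]

OUTLIER_K = 3.0  # a site is an outlier beyond this many expected errors


@dataclass
class DeltaTable:
    """Per-site experimental vs predicted shift differences."""

    frame: pd.DataFrame  # site_label, nucleus, delta_exp, delta_pred, delta_diff, best_case

    def __len__(self) -> int:
        return len(self.frame)

    def rows(self, nucleus: str | None = None) -> pd.DataFrame:
        if nucleus is None:
            return self.frame
        return self.frame[self.frame.nucleus == nucleus]

    def to_csv(self, path: str | Path) -> None:
        """Scatter export (delta vs experimental shift) as delimited text."""
        self.frame.to_csv(path, index=False)


@dataclass
class ValidationReport:
    rmsd_c: float
    rmsd_h: float
    expected_err_c: float
    expected_err_h: float
    outliers: list[str]
    validated: bool
    n_sites_c: int = 0
    n_sites_h: int = 0
    best_case_sites: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "validated" if self.validated else "not_validated"

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "rmsd_c_ppm": self.rmsd_c,
            "rmsd_h_ppm": self.rmsd_h,
            "expected_err_c_ppm": self.expected_err_c,
            "expected_err_h_ppm": self.expected_err_h,
            "n_sites_c": self.n_sites_c,
            "n_sites_h": self.n_sites_h,
            "outliers": self.outliers,
            "best_case_sites": self.best_case_sites,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def summary(self) -> str:
        lines = [
            f"verdict: {self.verdict}",
            f"13C RMSD {self.rmsd_c:.2f} ppm (expected error "
            f"{self.expected_err_c:.2f} ppm, n={self.n_sites_c})",
            f"1H  RMSD {self.rmsd_h:.2f} ppm (expected error "
            f"{self.expected_err_h:.2f} ppm, n={self.n_sites_h})",
            f"outliers: {', '.join(self.outliers) if self.outliers else 'none'}",
        ]
        if self.best_case_sites:
            lines.append(
                "ambiguous sites included under best-case pairing: "
                + ", ".join(self.best_case_sites)
            )
        return "\n".join(lines)


def _best_case_pairing(
    sites: list[str],
    candidates: dict[str, list[str]],
    peak_shift: dict[str, float],
    pred: dict[str, float],
) -> dict[str, str]:
    """Injective pairing of ambiguous sites to candidate peaks minimising
    the total squared deviation from the predictions."""
    from scipy.optimize import linear_sum_assignment

    peaks = sorted({p for s in sites for p in candidates[s]})
    cost = np.full((len(sites), len(peaks)), 1e12)
    for i, s in enumerate(sites):
        for p in candidates[s]:
            j = peaks.index(p)
            cost[i, j] = (peak_shift[p] - pred[s]) ** 2
    rows, cols = linear_sum_assignment(cost)
    out = {}
    for i, j in zip(rows, cols):
        if cost[i, j] < 1e12:
            out[sites[i]] = peaks[j]
    return out


def delta_table(
    assignment: AssignmentResult,
    exp_peaks: list[PeakList],
    predictions: list[ShiftPrior],
    include_ambiguous: bool = True,
) -> DeltaTable:
    """One row per assigned site: experimental minus predicted shift.

    Mapped sites use their assigned peak.  With ``include_ambiguous`` the
    remaining sites are paired to their candidate peaks under the
    best-case pairing and flagged; otherwise they are excluded.  A mapped
    site without a prediction raises ``KeyError``.
    """
    pred = {p.site_label: p.mean for p in predictions}
    shift: dict[str, float] = {}
    nucleus_of_peak: dict[str, str] = {}
    for pl in exp_peaks:
        for pk in pl:
            shift[pk.peak_id] = pk.shift
            nucleus_of_peak[pk.peak_id] = pl.nucleus

    rows = []
    for site, pid in assignment.map.items():
        if site not in pred:
            raise KeyError(f"no prediction for mapped site {site}")
        rows.append({
            "site_label": site,
            "nucleus": nucleus_of_peak[pid],
            "delta_exp": shift[pid],
            "delta_pred": pred[site],
            "best_case": False,
        })
    if include_ambiguous and assignment.ambiguous_sites:
        amb = [s for s in assignment.ambiguous_sites if s in pred]
        used = set(assignment.map.values())
        candidates = {
            s: [p for p in assignment.marginals[s] if p not in used]
            for s in amb
        }
        amb = [s for s in amb if candidates[s]]
        pairing = _best_case_pairing(amb, candidates, shift, pred)
        for site, pid in pairing.items():
            rows.append({
                "site_label": site,
                "nucleus": nucleus_of_peak[pid],
                "delta_exp": shift[pid],
                "delta_pred": pred[site],
                "best_case": True,
            })
    frame = pd.DataFrame(
        rows,
        columns=["site_label", "nucleus", "delta_exp", "delta_pred", "best_case"],
    )
    frame["delta_diff"] = frame.delta_exp - frame.delta_pred
    frame = frame[
        ["site_label", "nucleus", "delta_exp", "delta_pred", "delta_diff",
         "best_case"]
    ].sort_values(["nucleus", "site_label"]).reset_index(drop=True)
    return DeltaTable(frame=frame)


def rmsd(table: DeltaTable, nucleus: str) -> float:
    """Root-mean-square deviation over the rows of one nucleus."""
    sub = table.rows(nucleus)
    if len(sub) == 0:
        raise ValueError(f"no rows for nucleus {nucleus}")
    return float(math.sqrt(np.mean(np.square(sub.delta_diff.to_numpy()))))


def verdict(
    rmsd_c: float,
    rmsd_h: float,
    expected_err_c: float,
    expected_err_h: float,
    table: DeltaTable,
    outlier_k: float = OUTLIER_K,
) -> ValidationReport:
    """Issue the validation verdict.

    Validated iff both per-nucleus RMSDs are within the expected predictor
    errors and no site deviates by more than ``outlier_k`` expected errors.
    """
    err = {"C13": expected_err_c, "H1": expected_err_h}
    frame = table.frame
    outliers = sorted(
        frame.loc[
            frame.apply(
                lambda r: abs(r.delta_diff) > outlier_k * err[r.nucleus], axis=1
            ),
            "site_label",
        ].tolist()
    ) if len(frame) else []
    validated = (
        rmsd_c <= expected_err_c and rmsd_h <= expected_err_h and not outliers
    )
    return ValidationReport(
        rmsd_c=rmsd_c,
        rmsd_h=rmsd_h,
        expected_err_c=expected_err_c,
        expected_err_h=expected_err_h,
        outliers=outliers,
        validated=validated,
        n_sites_c=int((frame.nucleus == "C13").sum()),
        n_sites_h=int((frame.nucleus == "H1").sum()),
        best_case_sites=sorted(frame.loc[frame.best_case, "site_label"].tolist()),
    )
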