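"""Packaged example data: the verinurad fixture.

Verinurad (2-[3-(4-cyanonaphthalen-1-yl)pyridin-4-yl]sulfanyl-2-
methylpropanoic acid) is a microcrystalline pharmaceutical with 20 carbon
and 12 proton sites.  The fixture bundles its published experimental peak
positions (20 13C and 12 1H shifts), the one-bond and long-range C-H
HETCOR and 1H-1H DQ/SQ cross peaks reported for it, Gaussian assignment
priors centred on the published site shifts (the two aromatic CH carbons
whose predicted shifts are published use those predictions as centres),
and the heavy-atom label map reproducing the published site numbering.

``predicted_shifts_synthetic.csv`` is a synthetic stand-in for the
full machine-learned predicted-shift table of the reference structure,
which is not redistributed here: per-site deviations from experiment were
drawn once (seed 20240717) and scaled so the per-nucleus RMSD equals the
predictor's published accuracy (3.1 ppm for 13C, 0.46 ppm for 1H), with
the two published predicted values kept verbatim.  It demonstrates the
validation workflow; it is not the original table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from xtalshift.molgraph import (
    BondDistanceMatrix,
    MolecularGraph,
    Site,
    bond_distance_matrix,
    build_sites,
    parse_structure,
)
from xtalshift.priors import ShiftPrior, load_predictions
from xtalshift.spectra import (
    CorrelationSet,
    PeakList,
    read_correlations,
    read_peaklist,
)

__all__ = ["VERINURAD_SMILES", "VerinuradFixture", "fixture_dir",
           "read_label_map", "load_verinurad"]

VERINURAD_SMILES = "n1cc(-c2ccc(C#N)c3ccccc23)c(SC(C)(C)C(=O)O)cc1"


def fixture_dir() -> Path:
    """Directory holding the packaged verinurad fixture files."""
    return Path(resources.files("xtalshift") / "data" / "verinurad")


def read_label_map(path: str | Path) -> dict[int, str]:
    """Read a two-column delimited label map (atom_id, label)."""
    out: dict[int, str] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if "atom_id" not in (reader.fieldnames or []) or "label" not in (
            reader.fieldnames or []
        ):
            raise ValueError(f"{path}: expected columns 'atom_id, label'")
        for row in reader:
            out[int(row["atom_id"])] = row["label"].strip()
    return out


@dataclass
class VerinuradFixture:
    graph: MolecularGraph
    sites: list[Site]
    bdm: BondDistanceMatrix
    label_map: dict[int, str]
    peaklists: dict[str, PeakList]          # nucleus -> peaks
    correlations: dict[str, CorrelationSet]  # experiment -> set
    priors: list[ShiftPrior]                # assignment priors
    predictions: list[ShiftPrior]           # synthetic predicted-shift table

    def peak_shift(self, peak_id: str) -> float:
        for pl in self.peaklists.values():
            for p in pl:
                if p.peak_id == peak_id:
                    return p.shift
        raise KeyError(peak_id)


def load_verinurad() -> VerinuradFixture:
    d = fixture_dir()
    label_map = read_label_map(d / "label_map.csv")
    graph = parse_structure(VERINURAD_SMILES)
    sites = build_sites(graph, label_map=label_map)
    bdm = bond_distance_matrix(sites, graph)
    peaklists = {
        "C13": read_peaklist(d / "peaks_13c.csv", "C13"),
        "H1": read_peaklist(d / "peaks_1h.csv", "H1"),
    }
    correlations = {
        "HETCOR_SHORT": read_correlations(d / "hetcor_short.csv", "HETCOR_SHORT"),
        "HETCOR_LONG": read_correlations(d / "hetcor_long.csv", "HETCOR_LONG"),
        "DQSQ": read_correlations(d / "dqsq.csv", "DQSQ"),
    }
    priors = load_predictions(d / "priors.csv", sites=sites)
    predictions = load_predictions(
        d / "predicted_shifts_synthetic.csv", sites=sites
    )
    return VerinuradFixture(
        graph=graph,
        sites=sites,
        bdm=bdm,
        label_map=label_map,
        peaklists=peaklists,
        correlations=correlations,
        priors=priors,
        predictions=predictions,
    )
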