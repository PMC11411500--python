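"""Synthetic assignment instances for testing and recovery studies.

An instance bundles a molecule, a hidden true site-to-shift map, Gaussian
shift priors biased away from the truth, resolution-limited 1D peak lists,
and correlation sets consistent with the molecular graph up to a missing-
peak rate.  Everything derives from one explicit seed, and instances can
round-trip through the same delimited formats the readers consume, so
generator output exercises the real I/O path.

Small real molecular graphs are shipped as templates - correlation
topology, not size, drives the difficulty of an instance - and a random-
molecule generator (tree growth plus ring insertion respecting valence)
is provided for property tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from xtalshift.assign import HH_WINDOW, LONG_RANGE_WINDOW, AssignmentResult
from xtalshift.molgraph import (
    Atom,
    BondDistanceMatrix,
    MolecularGraph,
    Site,
    bond_distance_matrix,
    build_sites,
    parse_structure,
)
from xtalshift.priors import SD_C, SD_H, ShiftPrior
from xtalshift.spectra import (
    CorrelationSet,
    Peak,
    PeakList,
    TOL_C,
    TOL_H,
    write_correlations,
    write_peaklist,
)

__all__ = [
    "TEMPLATES",
    "SHIFT_RANGES",
    "SyntheticInstance",
    "generate",
    "recovery_score",
    "random_molecule",
]

#: nucleus-typical chemical-shift ranges (ppm) for drawing true shifts
SHIFT_RANGES = {"H1": (0.0, 16.0), "C13": (10.0, 180.0)}

#: small real molecules as SMILES; their ring topology gives realistic
#: correlation structure
TEMPLATES = {
    "verinurad": "n1cc(-c2ccc(C#N)c3ccccc23)c(SC(C)(C)C(=O)O)cc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "pyridine": "c1ccncc1",
    "lutidine": "Cc1cccc(C)n1",
    "quinoline": "c1ccc2ncccc2c1",
    "toluic_acid": "Cc1ccc(C(=O)O)cc1",
}

_VALENCE = {"C": 4, "N": 3, "O": 2}


@dataclass
class SyntheticInstance:
    graph: MolecularGraph
    sites: list[Site]
    bdm: BondDistanceMatrix
    true_shifts: dict[str, float]          # site label -> true shift (ppm)
    true_assignment: dict[str, str]        # site label -> peak id
    priors: list[ShiftPrior]
    peaklists: dict[str, PeakList]         # nucleus -> peak list
    correlations: dict[str, CorrelationSet]
    params: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Serialise through the standard delimited formats plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_peaklist(self.peaklists["H1"], outdir / "peaks_1h.csv")
        write_peaklist(self.peaklists["C13"], outdir / "peaks_13c.csv")
        for key, name in (
            ("HETCOR_SHORT", "hetcor_short.csv"),
            ("HETCOR_LONG", "hetcor_long.csv"),
            ("DQSQ", "dqsq.csv"),
        ):
            write_correlations(self.correlations[key], outdir / name)
        with (outdir / "priors.csv").open("w", encoding="utf-8") as fh:
            fh.write("site_label,value,kind,sd\n")
            for p in self.priors:
                fh.write(f"{p.site_label},{p.mean!r},shift,{p.sd!r}\n")
        manifest = {
            "params": self.params,
            "true_shifts": self.true_shifts,
            "true_assignment": self.true_assignment,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )


def random_molecule(
    n_heavy: int,
    seed: int | np.random.Generator,
    p_ring: float = 0.3,
    p_hetero: float = 0.15,
) -> MolecularGraph:
    """Random connected molecule: heavy-atom tree growth with ring
    insertion, hydrogens filling the remaining valences.

    Carbons keep at most three hydrogens so rotor collapsing stays
    realistic; ring closure only joins atoms with free valence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_heavy < 2:
        raise ValueError("need at least two heavy atoms")
    elements = ["C"]
    for _ in range(n_heavy - 1):
        elements.append(
            "C" if rng.random() > p_hetero else ("N" if rng.random() < 0.6 else "O")
        )
    edges: list[tuple[int, int]] = []
    degree = [0] * n_heavy
    for i in range(1, n_heavy):
        choices = [j for j in range(i) if degree[j] < _VALENCE[elements[j]]]
        if not choices:
            choices = [i - 1]
        j = int(rng.choice(choices))
        edges.append((j, i))
        degree[i] += 1
        degree[j] += 1
    # ring insertion: close a few extra edges where valence allows
    n_rings = rng.binomial(max(n_heavy // 5, 1), p_ring)
    for _ in range(n_rings):
        free = [i for i in range(n_heavy) if degree[i] < _VALENCE[elements[i]]]
        rng.shuffle(free)
        for a in free:
            partners = [
                b for b in free
                if b != a and (min(a, b), max(a, b)) not in
                {(min(x, y), max(x, y)) for x, y in edges}
                and degree[b] < _VALENCE[elements[b]]
            ]
            if partners:
                b = int(rng.choice(partners))
                edges.append((a, b))
                degree[a] += 1
                degree[b] += 1
                break
    atoms = [Atom(i, elements[i], tuple()) for i in range(n_heavy)]
    bonds = [(a, b, 1.0) for a, b in edges]
    next_id = n_heavy
    full_atoms = []
    for i in range(n_heavy):
        n_h = _VALENCE[elements[i]] - degree[i]
        if elements[i] == "C":
            n_h = min(n_h, 3)
        full_atoms.append(Atom(i, elements[i], tuple(
            j for a, b, _ in bonds for j in ((b,) if a == i else (a,) if b == i else ())
        )))
        for _ in range(n_h):
            full_atoms.append(Atom(next_id, "H", (i,)))
            bonds.append((i, next_id, 1.0))
            next_id += 1
    return MolecularGraph(atoms=full_atoms, bonds=bonds)


def _resolve_template(template) -> MolecularGraph:
    if isinstance(template, MolecularGraph):
        return template
    if isinstance(template, str):
        if template in TEMPLATES:
            return parse_structure(TEMPLATES[template])
        return parse_structure(template)
    raise TypeError("template must be a MolecularGraph, template name or SMILES")


def _merged_peaks(
    labels: list[str],
    shifts: np.ndarray,
    resolution: float,
    prefix: str,
) -> tuple[list[Peak], dict[str, str]]:
    """Merge peaks closer than the overlap resolution to their mean.

    Returns the observed peak list (descending shift, ids like C01) and
    the site-to-peak-id truth map."""
    order = np.argsort(-shifts)
    clusters: list[list[int]] = []
    for idx in order:
        if clusters and abs(
            shifts[idx] - np.mean([shifts[i] for i in clusters[-1]])
        ) < resolution and resolution > 0:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    peaks: list[Peak] = []
    truth: dict[str, str] = {}
    for k, cluster in enumerate(clusters):
        pid = f"{prefix}{k + 1:02d}"
        peaks.append(Peak(pid, float(np.mean([shifts[i] for i in cluster]))))
        for i in cluster:
            truth[labels[i]] = pid
    return peaks, truth


def generate(
    template,
    seed: int,
    prior_sd_h: float = SD_H,
    prior_sd_c: float = SD_C,
    missing_rate: float = 0.1,
    overlap_resolution: float = 0.0,
    long_range_window: int = LONG_RANGE_WINDOW,
    hh_window: int = HH_WINDOW,
    min_separation_h: float = 0.15,
    min_separation_c: float = 1.0,
) -> SyntheticInstance:
    """Generate a synthetic instance on a molecular template.

    True shifts are drawn uniformly from nucleus-typical ranges with a
    minimum separation (rejection sampling) emulating resolved spectra;
    priors are the true shifts plus Gaussian bias of the stated standard
    deviation; short-range correlations cover every bonded C-H site pair
    and long-range ones every pair within the 2..window bond-distance
    band, each independently dropped with ``missing_rate``; DQ/SQ entries
    cover proton pairs within ``hh_window`` bonds.
    """
    if prior_sd_h < 0 or prior_sd_c < 0:
        raise ValueError("prior sd must be non-negative")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    graph = _resolve_template(template)
    sites = build_sites(graph)
    bdm = bond_distance_matrix(sites, graph)

    true_shifts: dict[str, float] = {}
    for nucleus, min_sep in (("C13", min_separation_c), ("H1", min_separation_h)):
        labels = [s.label for s in sites if s.nucleus == nucleus]
        lo, hi = SHIFT_RANGES[nucleus]
        for _ in range(200):
            draws = rng.uniform(lo, hi, size=len(labels))
            if len(draws) < 2 or np.min(np.diff(np.sort(draws))) >= min_sep:
                break
        for lab, val in zip(labels, draws):
            true_shifts[lab] = float(round(val, 3))

    priors = []
    for s in sites:
        sd = prior_sd_h if s.nucleus == "H1" else prior_sd_c
        bias = rng.normal(0.0, sd) if sd > 0 else 0.0
        priors.append(ShiftPrior(
            s.label,
            mean=float(true_shifts[s.label] + bias),
            sd=max(sd, 1e-6),
            nucleus=s.nucleus,
        ))

    peaklists: dict[str, PeakList] = {}
    truth: dict[str, str] = {}
    for nucleus, prefix in (("C13", "C"), ("H1", "H")):
        labels = [s.label for s in sites if s.nucleus == nucleus]
        shifts = np.array([true_shifts[lab] for lab in labels])
        peaks, tmap = _merged_peaks(labels, shifts, overlap_resolution, prefix)
        peaklists[nucleus] = PeakList(nucleus=nucleus, peaks=peaks)
        truth.update(tmap)

    peak_shift = {
        pid: pk.shift
        for pl in peaklists.values() for pid, pk in ((p.peak_id, p) for p in pl)
    }

    def observed(label: str) -> float:
        return peak_shift[truth[label]]

    c_sites = [s for s in sites if s.nucleus == "C13"]
    h_sites = [s for s in sites if s.nucleus == "H1"]
    short_entries, long_entries, dq_entries = [], [], []
    for c in c_sites:
        for h in h_sites:
            d = bdm[c.label, h.label]
            if d == 1:
                if rng.random() >= missing_rate:
                    short_entries.append((observed(c.label), observed(h.label)))
            elif 2 <= d <= long_range_window:
                if rng.random() >= missing_rate:
                    long_entries.append((observed(c.label), observed(h.label)))
    for i, a in enumerate(h_sites):
        for b in h_sites[i + 1:]:
            if bdm[a.label, b.label] <= hh_window:
                if rng.random() >= missing_rate:
                    dq = observed(a.label) + observed(b.label)
                    dq_entries.append((dq, observed(a.label)))
                    dq_entries.append((dq, observed(b.label)))

    correlations = {
        "HETCOR_SHORT": CorrelationSet(
            "HETCOR_SHORT", short_entries, tolerance_f1=TOL_C, tolerance_f2=TOL_H
        ),
        "HETCOR_LONG": CorrelationSet(
            "HETCOR_LONG", long_entries, tolerance_f1=TOL_C, tolerance_f2=TOL_H
        ),
        "DQSQ": CorrelationSet(
            "DQSQ", dq_entries, tolerance_f1=2 * TOL_H, tolerance_f2=TOL_H
        ),
    }
    params = {
        "seed": seed,
        "prior_sd_h": prior_sd_h,
        "prior_sd_c": prior_sd_c,
        "missing_rate": missing_rate,
        "overlap_resolution": overlap_resolution,
        "long_range_window": long_range_window,
        "hh_window": hh_window,
    }
    return SyntheticInstance(
        graph=graph,
        sites=sites,
        bdm=bdm,
        true_shifts=true_shifts,
        true_assignment=truth,
        priors=priors,
        peaklists=peaklists,
        correlations=correlations,
        params=params,
    )


def recovery_score(
    instance: SyntheticInstance,
    result: AssignmentResult,
    strict: bool = True,
) -> float:
    """Fraction of sites whose assignment recovers the hidden truth.

    Under strict scoring only sites in the unambiguous map can count as
    correct.  With ``strict=False`` an ambiguous site also counts when the
    true peak is inside its tied top-marginal set (ties within 1e-9).
    """
    n_total = len(instance.sites)
    n_good = 0
    for site in instance.sites:
        truth = instance.true_assignment[site.label]
        mapped = result.map.get(site.label)
        if mapped is not None:
            n_good += mapped == truth
        elif not strict:
            row = result.marginals.get(site.label, {})
            if row:
                top = max(row.values())
                tied = {p for p, v in row.items() if abs(v - top) <= 1e-9}
                n_good += truth in tied
    return n_good / n_total if n_total else 0.0
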