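"""End-to-end orchestration: configuration, assignment and validation runs.

``assign_dataset`` is the in-memory core used everywhere (fixtures,
synthetic studies, file runs): candidate gating under the Gaussian priors,
Poisson count evidence, HETCOR and DQ/SQ constraints, propagation and
global marginalization.  ``run_assignment`` / ``run_validation`` wrap it
with file I/O and write deterministic artifacts (tables are formatted with
repr floats and sorted keys, so identical config and seed reproduce
byte-identical outputs).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from xtalshift import assign as _assign
from xtalshift.assign import (
    AssignmentResult,
    apply_count_evidence,
    constraints_from_hetcor,
    contacts_to_evidence,
    expected_correlation_score,
    global_marginals,
    observed_long_range_counts,
)
from xtalshift.datasets import read_label_map
from xtalshift.molgraph import (
    BondDistanceMatrix,
    Site,
    bond_distance_matrix,
    build_sites,
    parse_structure,
)
from xtalshift.priors import SD_C, SD_H, Z_MAX, candidate_table, load_predictions
from xtalshift.spectra import (
    CorrelationSet,
    PeakList,
    read_correlations,
    read_peaklist,
    resolve_dq_pairs,
)
from xtalshift.validate import (
    OUTLIER_K,
    ValidationReport,
    delta_table,
    rmsd,
    verdict,
)

__all__ = ["AssignOptions", "RunConfig", "assign_dataset",
           "run_assignment", "run_validation"]

logger = logging.getLogger(__name__)


class AssignOptions(BaseModel):
    """Tunable parameters of the assignment engine."""

    tol_h: float = 0.25
    tol_c: float = 0.50
    long_range_window: int = _assign.LONG_RANGE_WINDOW
    hh_window: int = _assign.HH_WINDOW
    hh_reward: float = _assign.HH_REWARD
    z_max: float = Z_MAX
    unambiguity_threshold: float = _assign.UNAMBIGUITY_THRESHOLD
    max_enum: int = _assign.MAX_ENUM
    method: str = "auto"  # auto | enumerate | gibbs
    seed: int | None = None
    strict_bijection: bool = True
    #: detection probabilities by bond distance grade every observed
    #: long-range entry with the odds of its assigned pair (exact
    #: presence/absence cross-peak evidence); the coarser Poisson
    #: count-matching term can be enabled instead
    detection_by_distance: dict[int, float] = Field(
        default_factory=lambda: dict(_assign.DETECTION_BY_DISTANCE)
    )
    use_detection_odds: bool = True
    use_count_evidence: bool = False
    gibbs_sweeps: int = 4000
    gibbs_burn_in: int = 500


class RunConfig(BaseModel):
    """File-level configuration of an end-to-end run."""

    structure: str                      # SMILES text or path to a MOL file
    label_map: str | None = None
    peaks_h: str = ""
    peaks_c: str = ""
    hetcor_short: str | None = None
    hetcor_long: str | None = None
    dqsq: str | None = None
    predictions: str = ""               # prior table for assignment
    validation_predictions: str | None = None
    default_sd_h: float = SD_H
    default_sd_c: float = SD_C
    expected_err_h: float = SD_H
    expected_err_c: float = SD_C
    outlier_k: float = OUTLIER_K
    options: AssignOptions = Field(default_factory=AssignOptions)
    outdir: str = "run_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cfg = cls.model_validate(data)
        base = Path(path).resolve().parent
        for name in ("label_map", "peaks_h", "peaks_c", "hetcor_short",
                     "hetcor_long", "dqsq", "predictions",
                     "validation_predictions"):
            value = getattr(cfg, name)
            if value:
                p = Path(value)
                if not p.is_absolute():
                    setattr(cfg, name, str(base / p))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True),
            encoding="utf-8",
        )


def assign_dataset(
    sites: list[Site],
    bdm: BondDistanceMatrix,
    peaklists: dict[str, PeakList],
    correlations: dict[str, CorrelationSet],
    priors: list,
    options: AssignOptions | None = None,
) -> AssignmentResult:
    """Run the full assignment engine on in-memory inputs.

    ``correlations`` may contain any subset of HETCOR_SHORT, HETCOR_LONG
    and DQSQ sets; missing experiments simply contribute no constraints.
    """
    opts = options or AssignOptions()
    table = candidate_table(
        priors, list(peaklists.values()), z_max=opts.z_max
    )
    constraints = []
    short = correlations.get("HETCOR_SHORT")
    long_ = correlations.get("HETCOR_LONG")
    dqsq = correlations.get("DQSQ")
    if short is not None:
        constraints += constraints_from_hetcor(
            short, sites, bdm, peaklists["C13"], peaklists["H1"],
            window=opts.long_range_window,
        )
    if long_ is not None:
        constraints += constraints_from_hetcor(
            long_, sites, bdm, peaklists["C13"], peaklists["H1"],
            window=opts.long_range_window,
            detection=(opts.detection_by_distance
                       if opts.use_detection_odds else None),
        )
        if opts.use_count_evidence:
            expected = expected_correlation_score(
                sites, bdm, window=opts.long_range_window,
                detection=opts.detection_by_distance,
            )
            observed = observed_long_range_counts(long_, peaklists["C13"])
            table = apply_count_evidence(table, expected, observed)
    if dqsq is not None:
        contacts = resolve_dq_pairs(dqsq, peaklists["H1"])
        constraints += contacts_to_evidence(
            contacts, sites, bdm,
            hh_window=opts.hh_window, reward=opts.hh_reward,
        )
    return global_marginals(
        table,
        constraints,
        method=opts.method,
        seed=opts.seed,
        max_enum=opts.max_enum,
        unambiguity_threshold=opts.unambiguity_threshold,
        strict_bijection=opts.strict_bijection,
        gibbs_sweeps=opts.gibbs_sweeps,
        gibbs_burn_in=opts.gibbs_burn_in,
    )


def _load_inputs(config: RunConfig):
    structure_text = config.structure
    p = Path(structure_text)
    if p.suffix.lower() in (".mol", ".sdf", ".smi", ".txt") or (
        p.exists() and not p.is_dir()
    ):
        if not p.exists():
            raise FileNotFoundError(f"structure file not found: {p}")
        structure_text = p.read_text(encoding="utf-8")
    graph = parse_structure(structure_text)
    label_map = None
    if config.label_map:
        _require(config.label_map, "label map")
        label_map = read_label_map(config.label_map)
    sites = build_sites(graph, label_map=label_map)
    bdm = bond_distance_matrix(sites, graph)
    _require(config.peaks_h, "1H peak list")
    _require(config.peaks_c, "13C peak list")
    peaklists = {
        "H1": read_peaklist(config.peaks_h, "H1"),
        "C13": read_peaklist(config.peaks_c, "C13"),
    }
    opts = config.options
    correlations: dict[str, CorrelationSet] = {}
    if config.hetcor_short:
        _require(config.hetcor_short, "short-range HETCOR")
        correlations["HETCOR_SHORT"] = read_correlations(
            config.hetcor_short, "HETCOR_SHORT", opts.tol_c, opts.tol_h
        )
    if config.hetcor_long:
        _require(config.hetcor_long, "long-range HETCOR")
        correlations["HETCOR_LONG"] = read_correlations(
            config.hetcor_long, "HETCOR_LONG", opts.tol_c, opts.tol_h
        )
    if config.dqsq:
        _require(config.dqsq, "DQ/SQ")
        correlations["DQSQ"] = read_correlations(
            config.dqsq, "DQSQ", 2 * opts.tol_h, opts.tol_h
        )
    _require(config.predictions, "prediction table")
    priors = load_predictions(
        config.predictions,
        default_sd_h=config.default_sd_h,
        default_sd_c=config.default_sd_c,
        sites=sites,
    )
    return graph, sites, bdm, peaklists, correlations, priors


def _require(path: str, what: str) -> None:
    if not Path(path).exists():
        raise FileNotFoundError(f"{what} file not found: {path}")


def _write_assignment_artifacts(
    result: AssignmentResult, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "marginals.csv").open("w", encoding="utf-8") as fh:
        fh.write("site,peak_id,probability\n")
        for site in sorted(result.marginals):
            row = result.marginals[site]
            for pid in sorted(row):
                fh.write(f"{site},{pid},{row[pid]!r}\n")
    with (outdir / "map.csv").open("w", encoding="utf-8") as fh:
        fh.write("site,peak_id\n")
        for site in sorted(result.map):
            fh.write(f"{site},{result.map[site]}\n")
    with (outdir / "eliminations.log").open("w", encoding="utf-8") as fh:
        for e in result.eliminations:
            fh.write(f"{e.site}\t{e.peak_id}\t{e.reason}\n")
    payload = {
        "map": dict(sorted(result.map.items())),
        "ambiguous_sites": result.ambiguous_sites,
        "marginals": {
            s: dict(sorted(result.marginals[s].items()))
            for s in sorted(result.marginals)
        },
        "components": [sorted(c) for c in result.components],
    }
    (outdir / "assignment.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
    )


def run_assignment(config: RunConfig) -> AssignmentResult:
    """Load inputs, run the assignment engine, write artifacts.

    Deterministic given config and seed.  Artifacts: marginals.csv,
    map.csv, eliminations.log (one replayable line per pruned candidate,
    naming the triggering constraint) and assignment.json.
    """
    try:
        inputs = _load_inputs(config)
    except Exception as exc:
        raise type(exc)(f"[input stage] {exc}") from exc
    _, sites, bdm, peaklists, correlations, priors = inputs
    result = assign_dataset(
        sites, bdm, peaklists, correlations, priors, config.options
    )
    _write_assignment_artifacts(result, Path(config.outdir))
    logger.info(
        "assignment: %d sites mapped, %d ambiguous",
        len(result.map), len(result.ambiguous_sites),
    )
    return result


def run_validation(
    config: RunConfig, assignment: AssignmentResult
) -> ValidationReport:
    """Compare assigned shifts with the validation prediction table and
    write the delta table and verdict report."""
    if not assignment.map:
        raise ValueError("assignment map is empty; nothing to validate")
    if not config.validation_predictions:
        raise FileNotFoundError("no validation prediction table configured")
    _require(config.validation_predictions, "validation prediction table")
    _, sites, _, peaklists, _, _ = _load_inputs(config)
    predictions = load_predictions(
        config.validation_predictions,
        default_sd_h=config.default_sd_h,
        default_sd_c=config.default_sd_c,
        sites=sites,
    )
    table = delta_table(
        assignment, list(peaklists.values()), predictions,
        include_ambiguous=True,
    )
    report = verdict(
        rmsd(table, "C13"),
        rmsd(table, "H1"),
        config.expected_err_c,
        config.expected_err_h,
        table,
        outlier_k=config.outlier_k,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "delta_table.csv")
    report.to_json(outdir / "validation_report.json")
    return report
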