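"""Constraint construction, propagation, and marginal posteriors over
global site-to-peak assignments.

The probability of a global assignment (one injective site-to-peak map per
nucleus) is proportional to the product of per-site prior likelihood
weights, restricted to assignments satisfying every hard constraint, and
multiplied by the soft-evidence terms:

* one-bond HETCOR entries are hard: the carbon peak and proton peak of a
  cross peak must be assigned to a directly bonded C-H site pair;
* long-range HETCOR entries are hard outside the bond-distance window
  (2-3 bonds by default) and graded inside it: each observed entry carries
  the detection odds of the assigned pair's bond distance, which is the
  exact presence-and-absence evidence of a Bernoulli cross-peak detection
  model (two-bond cross peaks are far more probable than three-bond ones);
* proton-proton DQ/SQ contacts are soft, because they may be
  intermolecular: assignments placing the two peaks on intramolecularly
  proximate sites are rewarded, all others are left unpenalised;
* alternatively, expected long-range correlation counts per carbon site
  can be matched to observed counts per carbon peak through a Poisson
  term (a coarser, identity-blind form of the same absence evidence).

Absence of a cross peak is never a hard elimination, since correlations
can be missing for dynamics or transfer-efficiency reasons.

Marginals are computed exactly by depth-first enumeration within the
independent ambiguity components left after constraint propagation, or by
seeded Gibbs sampling when a component is too large to enumerate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from xtalshift.molgraph import BondDistanceMatrix, Site
from xtalshift.priors import CandidateTable, WEIGHT_FLOOR
from xtalshift.spectra import CorrelationSet, PeakList, ProtonPairContact

__all__ = [
    "Constraint",
    "AssignmentResult",
    "Elimination",
    "InfeasibleAssignment",
    "constraints_from_hetcor",
    "contacts_to_evidence",
    "expected_correlation_score",
    "observed_long_range_counts",
    "apply_count_evidence",
    "propagate",
    "global_marginals",
    "LONG_RANGE_WINDOW",
    "HH_WINDOW",
    "HH_REWARD",
    "UNAMBIGUITY_THRESHOLD",
    "MAX_ENUM",
    "DETECTION_BY_DISTANCE",
]

logger = logging.getLogger(__name__)

LONG_RANGE_WINDOW = 3        # max bond distance for long-range C-H cross peaks
HH_WINDOW = 3                # max bond distance for an intramolecular H-H contact
HH_REWARD = 2.0              # soft multiplier for an intramolecularly explained contact
UNAMBIGUITY_THRESHOLD = 0.95  # top marginal needed for map membership
MAX_ENUM = 9                 # largest component enumerated exactly by default
#: cross-peak detection probability by bond distance, used for the
#: expected-correlation-count evidence (two-bond transfers are much more
#: efficient than three-bond ones)
DETECTION_BY_DISTANCE = {2: 0.7, 3: 0.2}


class InfeasibleAssignment(Exception):
    """No globally consistent assignment exists."""


class Elimination(NamedTuple):
    site: str
    peak_id: str
    reason: str


@dataclass(frozen=True, eq=False)
class Constraint:
    """A typed assignment constraint derived from one 2D cross peak.

    ``allowed_site_pairs`` holds the (C site, H site) label pairs - or
    (H, H) pairs for DQ/SQ contacts - that the two peaks may jointly be
    assigned to.  One-bond and long-range HETCOR constraints are hard;
    proton-proton contacts are soft with multiplier ``weight``.

    ``pair_weights`` optionally grades the allowed pairs: a long-range
    cross peak is much more likely to arise from a two-bond pair than a
    three-bond one, so an observed entry multiplies the posterior by the
    detection odds p(d)/(1-p(d)) of the assigned pair's bond distance d.
    Because the factors of unobserved in-window pairs form a constant
    across assignments, this odds weighting is exactly the joint
    presence-and-absence (missing cross peak) evidence of a Bernoulli
    detection model.
    """

    kind: str  # ONE_BOND_CH | LONG_RANGE_CH | HH_CONTACT
    c_peak_id: str | None
    h_peak_ids: tuple[str, ...]
    allowed_site_pairs: frozenset[tuple[str, str]]
    hard: bool = True
    weight: float = 1.0
    pair_weights: dict | None = None  # (site, site) -> multiplier

    @property
    def peak_ids(self) -> tuple[str, ...]:
        if self.c_peak_id is None:
            return self.h_peak_ids
        return (self.c_peak_id, *self.h_peak_ids)

    def describe(self) -> str:
        return f"{self.kind}({', '.join(self.peak_ids)})"


def constraints_from_hetcor(
    corr: CorrelationSet,
    sites: list[Site],
    bdm: BondDistanceMatrix,
    c_peaks: PeakList,
    h_peaks: PeakList,
    window: int = LONG_RANGE_WINDOW,
    detection: dict[int, float] | None = None,
) -> list[Constraint]:
    """Turn HETCOR cross peaks into hard constraints.

    A short-range entry requires the carbon peak at f1 and the proton peak
    at f2 to be assigned to a directly bonded C-H site pair; a long-range
    entry requires the assigned pair to lie 2 to ``window`` bonds apart.
    With a ``detection`` map {bond distance: probability} the long-range
    constraints additionally carry the detection odds of each allowed
    pair, implementing presence-and-absence cross-peak evidence (see
    ``Constraint``).  Entries whose coordinates match no picked peak
    within tolerance are skipped with a warning.
    """
    if corr.experiment not in ("HETCOR_SHORT", "HETCOR_LONG"):
        raise ValueError(f"not a HETCOR correlation set: {corr.experiment}")
    c_sites = [s for s in sites if s.nucleus == "C13"]
    h_sites = [s for s in sites if s.nucleus == "H1"]
    pair_weights: dict | None = None
    if corr.experiment == "HETCOR_SHORT":
        kind = "ONE_BOND_CH"
        pairs = frozenset(
            (c.label, h.label)
            for c in c_sites for h in h_sites
            if bdm[c.label, h.label] == 1
        )
    else:
        kind = "LONG_RANGE_CH"
        pairs = frozenset(
            (c.label, h.label)
            for c in c_sites for h in h_sites
            if 2 <= bdm[c.label, h.label] <= window
        )
        if detection is not None:
            pair_weights = {}
            for c, h in pairs:
                p = min(detection.get(bdm[c, h], 0.5), 0.95)
                pair_weights[(c, h)] = p / (1.0 - p)
    out: list[Constraint] = []
    for f1, f2 in corr.entries:
        cp = c_peaks.nearest(f1, corr.tolerance_f1)
        hp = h_peaks.nearest(f2, corr.tolerance_f2)
        if cp is None or hp is None:
            logger.warning(
                "%s entry (%.2f, %.2f) matches no picked peak; skipped",
                corr.experiment, f1, f2,
            )
            continue
        out.append(Constraint(
            kind=kind,
            c_peak_id=cp.peak_id,
            h_peak_ids=(hp.peak_id,),
            allowed_site_pairs=pairs,
            hard=True,
            pair_weights=pair_weights,
        ))
    return out


def contacts_to_evidence(
    contacts: list[ProtonPairContact],
    sites: list[Site],
    bdm: BondDistanceMatrix,
    hh_window: int = HH_WINDOW,
    reward: float = HH_REWARD,
) -> list[Constraint]:
    """Turn DQ/SQ proton-pair contacts into soft constraints.

    Contacts may be intermolecular, so they never prune: an assignment in
    which the two proton peaks land on sites within ``hh_window`` bonds is
    multiplied by ``reward``; any other assignment keeps weight 1 (the
    intermolecular escape).  Autocorrelation contacts are compatible with
    any single site and impose no restriction.
    """
    h_sites = [s for s in sites if s.nucleus == "H1"]
    out: list[Constraint] = []
    for contact in contacts:
        if contact.peak_id_a == contact.peak_id_b:
            continue
        pairs = frozenset(
            (a.label, b.label)
            for a in h_sites for b in h_sites
            if a.label != b.label and bdm[a.label, b.label] <= hh_window
        )
        out.append(Constraint(
            kind="HH_CONTACT",
            c_peak_id=None,
            h_peak_ids=(contact.peak_id_a, contact.peak_id_b),
            allowed_site_pairs=pairs,
            hard=False,
            weight=reward,
        ))
    return out


def expected_correlation_score(
    sites: list[Site],
    bdm: BondDistanceMatrix,
    window: int = LONG_RANGE_WINDOW,
    detection: dict[int, float] | None = None,
) -> dict[str, float]:
    """Expected long-range correlation partner count per carbon site.

    With ``detection`` omitted this is the plain number of proton sites
    within ``window`` bonds.  A ``detection`` map {bond distance:
    probability} weights each proton site by the probability that its
    cross peak is actually observed, giving the expected *observed* count
    used as Poisson count evidence.
    """
    h_sites = [s for s in sites if s.nucleus == "H1"]
    out: dict[str, float] = {}
    for c in sites:
        if c.nucleus != "C13":
            continue
        lam = 0.0
        for h in h_sites:
            d = bdm[c.label, h.label]
            if 1 <= d <= window:
                lam += detection.get(d, 0.0) if detection is not None else 1.0
        out[c.label] = lam
    return out


def observed_long_range_counts(
    corr_long: CorrelationSet, c_peaks: PeakList
) -> dict[str, int]:
    """Number of long-range cross peaks observed at each carbon peak."""
    counts = {p.peak_id: 0 for p in c_peaks}
    for f1, _ in corr_long.entries:
        cp = c_peaks.nearest(f1, corr_long.tolerance_f1)
        if cp is not None:
            counts[cp.peak_id] += 1
    return counts


def apply_count_evidence(
    candidates: CandidateTable,
    expected: dict[str, float],
    observed: dict[str, int],
    floor: float = 1e-6,
) -> CandidateTable:
    """Fold Poisson count evidence into the candidate weights.

    The weight of (carbon site, carbon peak) is multiplied by the Poisson
    probability of seeing the peak's observed long-range correlation count
    given the site's expected count.  The factor is floored so that count
    evidence stays soft and can never eliminate a candidate outright.
    """
    from scipy.stats import poisson

    table = candidates.copy()
    for site, row in table.weights.items():
        if table.nuclei[site] != "C13" or site not in expected:
            continue
        lam = expected[site]
        for pid in row:
            if pid not in observed:
                continue
            factor = float(poisson.pmf(observed[pid], lam)) if lam > 0 else (
                1.0 if observed[pid] == 0 else 0.0
            )
            row[pid] = max(row[pid] * max(factor, floor), WEIGHT_FLOOR)
    return table


# ---------------------------------------------------------------------------
# constraint propagation


def propagate(
    candidates: CandidateTable, constraints: list[Constraint]
) -> CandidateTable:
    """Prune candidates to arc consistency under the hard constraints.

    Two rules are iterated to a fixed point: (i) a candidate (site, peak)
    is removed when some hard constraint on that peak has no compatible
    counterpart candidate left; (ii) when a site's candidate set becomes a
    singleton, that peak is removed from every other site of the same
    nucleus.  All eliminations are logged with the triggering constraint.
    A site whose candidate set empties raises ``InfeasibleAssignment``
    naming the site and the last constraint involved.
    """
    table = candidates.copy()
    if table.infeasible:
        raise InfeasibleAssignment(
            f"sites with empty candidate sets: {table.infeasible}"
        )
    hard = [c for c in constraints if c.hard]
    weights = table.weights
    nuclei = table.nuclei

    def remove(site: str, pid: str, reason: str) -> None:
        del weights[site][pid]
        table.eliminations.append(Elimination(site, pid, reason))
        if not weights[site]:
            raise InfeasibleAssignment(
                f"candidate set of site {site} emptied; last constraint: {reason}"
            )

    changed = True
    while changed:
        changed = False
        # (i) arc consistency on every hard pairwise constraint
        for con in hard:
            pc, ph = con.peak_ids
            c_holders = [s for s, w in weights.items() if pc in w]
            h_holders = [s for s, w in weights.items() if ph in w]
            allowed = con.allowed_site_pairs
            for s in list(c_holders):
                if not any((s, t) in allowed for t in h_holders if t != s):
                    remove(s, pc, con.describe())
                    changed = True
            h_holders = [s for s, w in weights.items() if ph in w]
            c_holders = [s for s, w in weights.items() if pc in w]
            for t in list(h_holders):
                if not any((s, t) in allowed for s in c_holders if s != t):
                    remove(t, ph, con.describe())
                    changed = True
        # (ii) singleton exclusion (alldifferent propagation)
        singles: dict[str, str] = {}
        for s, w in weights.items():
            if len(w) == 1:
                pid = next(iter(w))
                other = singles.get(pid)
                if other is not None:
                    raise InfeasibleAssignment(
                        f"sites {other} and {s} both forced onto peak {pid}"
                    )
                singles[pid] = s
        for pid, owner in singles.items():
            for s in list(weights):
                if s != owner and nuclei[s] == nuclei[owner] and pid in weights[s]:
                    remove(s, pid, f"peak {pid} forced onto {owner}")
                    changed = True
    return table


# ---------------------------------------------------------------------------
# global marginals


@dataclass
class AssignmentResult:
    """Marginal site-to-peak probabilities and the unambiguous map.

    ``marginals[site][peak_id]`` sums to one over each site's row; ``map``
    contains the sites whose top marginal reaches the unambiguity
    threshold (injective per nucleus); everything else is listed in
    ``ambiguous_sites``.
    """

    marginals: dict[str, dict[str, float]]
    map: dict[str, str]
    ambiguous_sites: list[str]
    eliminations: list[Elimination] = field(default_factory=list)
    components: list[list[str]] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def top(self, site: str) -> tuple[str, float]:
        row = self.marginals[site]
        pid = max(row, key=row.get)
        return pid, row[pid]

    def to_frame(self, nucleus: str | None = None):
        import pandas as pd

        rows = {
            s: r for s, r in self.marginals.items()
        }
        frame = pd.DataFrame(rows).T.fillna(0.0)
        if nucleus is not None:
            keep = [s for s in frame.index
                    if (nucleus == "H1") == s.startswith("H")]
            frame = frame.loc[keep]
        return frame.sort_index()


class _Component:
    """One independent ambiguity component prepared for search."""

    def __init__(
        self,
        site_labels: list[str],
        table: CandidateTable,
        constraints: list[Constraint],
    ) -> None:
        self.sites = site_labels
        self.site_index = {s: i for i, s in enumerate(site_labels)}
        peaks = sorted({p for s in site_labels for p in table.weights[s]})
        self.peaks = peaks
        self.peak_index = {p: i for i, p in enumerate(peaks)}
        self.nuclei = [table.nuclei[s] for s in site_labels]
        self.peak_nuclei = [table.peak_nuclei[p] for p in peaks]
        # candidate masks and log-weights
        self.cand_mask = [0] * len(site_labels)
        self.logw = [dict() for _ in site_labels]
        for s in site_labels:
            si = self.site_index[s]
            for pid, w in table.weights[s].items():
                pi = self.peak_index[pid]
                self.cand_mask[si] |= 1 << pi
                self.logw[si][pi] = math.log(w)
        # per-peak site masks (which sites may take a peak)
        self.peak_sites = [0] * len(peaks)
        for si in range(len(site_labels)):
            m = self.cand_mask[si]
            while m:
                pi = (m & -m).bit_length() - 1
                self.peak_sites[pi] |= 1 << si
                m &= m - 1
        # constraints fully inside the component, indexed by peak
        self.pair_cons: list[tuple[int, int, bool, float, list[int], dict]] = []
        self.cons_by_peak: dict[int, list[int]] = {}
        for con in constraints:
            pids = [p for p in con.peak_ids if p in self.peak_index]
            if len(con.peak_ids) != 2 or len(pids) != 2:
                continue
            pa, pb = (self.peak_index[p] for p in con.peak_ids)
            # allowed partner-site masks: entry [site index of side A] ->
            # bitmask of compatible side-B sites (and vice versa packed
            # symmetrically into one lookup keyed on (peak, site))
            allowed_ab = [0] * len(site_labels)
            pair_logw: dict[tuple[int, int], float] = {}
            for (a, b) in con.allowed_site_pairs:
                ia, ib = self.site_index.get(a), self.site_index.get(b)
                if ia is None or ib is None:
                    continue
                allowed_ab[ia] |= 1 << ib
                if not con.hard and con.kind == "HH_CONTACT":
                    allowed_ab[ib] |= 1 << ia
                if con.pair_weights is not None:
                    w = con.pair_weights.get((a, b), 1.0)
                    if w != 1.0:
                        pair_logw[(ia, ib)] = math.log(w)
            self.pair_cons.append(
                (pa, pb, con.hard, math.log(con.weight) if con.weight != 1.0 else 0.0,
                 allowed_ab, pair_logw)
            )
            ci = len(self.pair_cons) - 1
            self.cons_by_peak.setdefault(pa, []).append(ci)
            self.cons_by_peak.setdefault(pb, []).append(ci)

    def pair_ok_or_bonus(
        self, owner_of: list[int | None], pa: int, pb: int, hard: bool,
        log_bonus: float, allowed_ab: list[int],
        pair_logw: dict | None = None,
    ) -> tuple[bool, float]:
        sa, sb = owner_of[pa], owner_of[pb]
        if sa is None or sb is None:
            return True, 0.0
        ok = bool((allowed_ab[sa] >> sb) & 1) or bool((allowed_ab[sb] >> sa) & 1)
        if hard:
            if not ok or not pair_logw:
                return ok, 0.0
            return True, pair_logw.get((sa, sb), pair_logw.get((sb, sa), 0.0))
        return True, (log_bonus if ok else 0.0)


def _enumerate_component(comp: _Component, strict: bool) -> tuple[dict, int]:
    """Exact marginals by depth-first enumeration with forward checking.

    Returns (marginals keyed by (site, peak) index pairs, number of
    feasible global assignments found).
    """
    n_sites = len(comp.sites)
    n_peaks = len(comp.peaks)
    if strict and n_sites != n_peaks:
        raise InfeasibleAssignment(
            f"component {comp.sites} has {n_sites} sites but {n_peaks} "
            "candidate peaks under strict bijection"
        )
    owner_of: list[int | None] = [None] * n_peaks
    assigned_peak: list[int | None] = [None] * n_sites
    used_mask = 0
    live_sites_mask = (1 << n_sites) - 1

    acc = [[0.0] * n_peaks for _ in range(n_sites)]
    scale_ref = [-math.inf]  # running max log-weight
    total = [0.0]
    n_feasible = [0]

    def leaf(logw: float) -> None:
        n_feasible[0] += 1
        ref = scale_ref[0]
        if logw > ref:
            factor = math.exp(ref - logw) if ref > -math.inf else 0.0
            for row in acc:
                for j in range(n_peaks):
                    row[j] *= factor
            total[0] *= factor
            scale_ref[0] = logw
            ref = logw
        w = math.exp(logw - ref)
        total[0] += w
        for si in range(n_sites):
            acc[si][assigned_peak[si]] += w

    def dfs(logw: float, live_sites: int) -> None:
        nonlocal used_mask
        if live_sites == 0:
            leaf(logw)
            return
        # MRV: pick the live site with the fewest remaining candidates
        best_si, best_mask, best_n = -1, 0, 1 << 30
        m = live_sites
        while m:
            si = (m & -m).bit_length() - 1
            m &= m - 1
            dom = comp.cand_mask[si] & ~used_mask
            n = dom.bit_count()
            if n == 0:
                return  # dead branch
            if n < best_n:
                best_si, best_mask, best_n = si, dom, n
                if n == 1:
                    break
        si = best_si
        dom = best_mask
        while dom:
            pi = (dom & -dom).bit_length() - 1
            dom &= dom - 1
            # incremental hard-constraint check / soft bonus
            owner_of[pi] = si
            bonus = 0.0
            ok = True
            for ci in comp.cons_by_peak.get(pi, ()):
                pa, pb, hard, log_bonus, allowed, pw = comp.pair_cons[ci]
                good, b = comp.pair_ok_or_bonus(owner_of, pa, pb, hard,
                                                log_bonus, allowed, pw)
                if not good:
                    ok = False
                    break
                bonus += b
            if ok:
                # forward check: in strict mode no unassigned peak may lose
                # all of its potential sites
                used_mask |= 1 << pi
                next_live = live_sites & ~(1 << si)
                feasible = True
                if strict:
                    rem = ~used_mask & ((1 << n_peaks) - 1)
                    mm = rem
                    while mm:
                        qi = (mm & -mm).bit_length() - 1
                        mm &= mm - 1
                        if comp.peak_sites[qi] & next_live == 0:
                            feasible = False
                            break
                if feasible:
                    assigned_peak[si] = pi
                    dfs(logw + comp.logw[si][pi] + bonus, next_live)
                    assigned_peak[si] = None
                used_mask &= ~(1 << pi)
            owner_of[pi] = None

    dfs(0.0, live_sites_mask)
    if n_feasible[0] == 0:
        raise InfeasibleAssignment(
            f"no feasible assignment for component {comp.sites}"
        )
    marg: dict[tuple[int, int], float] = {}
    for si in range(n_sites):
        z = sum(acc[si])
        for pi in range(n_peaks):
            if acc[si][pi] > 0:
                marg[(si, pi)] = acc[si][pi] / z
    return marg, n_feasible[0]


def _first_feasible(comp: _Component, strict: bool) -> list[int] | None:
    """One feasible assignment (site index -> peak index) via DFS."""
    n_sites = len(comp.sites)
    n_peaks = len(comp.peaks)
    owner_of: list[int | None] = [None] * n_peaks
    out: list[int | None] = [None] * n_sites

    def dfs(live_sites: int, used: int) -> bool:
        if live_sites == 0:
            return True
        best_si, best_n = -1, 1 << 30
        m = live_sites
        while m:
            si = (m & -m).bit_length() - 1
            m &= m - 1
            n = (comp.cand_mask[si] & ~used).bit_count()
            if n == 0:
                return False
            if n < best_n:
                best_si, best_n = si, n
        si = best_si
        dom = comp.cand_mask[si] & ~used
        while dom:
            pi = (dom & -dom).bit_length() - 1
            dom &= dom - 1
            owner_of[pi] = si
            ok = True
            for ci in comp.cons_by_peak.get(pi, ()):
                pa, pb, hard, lb, allowed, pw = comp.pair_cons[ci]
                good, _ = comp.pair_ok_or_bonus(owner_of, pa, pb, hard, lb,
                                                allowed, pw)
                if not good:
                    ok = False
                    break
            if ok:
                out[si] = pi
                if dfs(live_sites & ~(1 << si), used | (1 << pi)):
                    return True
                out[si] = None
            owner_of[pi] = None
        return False

    if dfs((1 << n_sites) - 1, 0):
        return [p for p in out]  # type: ignore[misc]
    return None


def _gibbs_component(
    comp: _Component,
    strict: bool,
    rng: np.random.Generator,
    sweeps: int,
    burn_in: int,
) -> tuple[dict, dict]:
    """Marginals by Metropolis transposition sampling with block repair.

    The sampler walks over feasible injective assignments by proposing
    peak swaps between two same-nucleus sites.  Because one-bond
    constraints tie each proton peak to its carbon partner, a bare swap
    is usually hard-infeasible; the proposal is then deterministically
    extended with the induced swap of the partner peaks' owners (a
    symmetric repair, so detailed balance is preserved).  The feasible
    set is assumed connected under these block transpositions.  Returns
    (marginals, standard errors) keyed by (site, peak) index pairs;
    standard errors are batch means with a binomial floor.
    """
    state = _first_feasible(comp, strict)
    if state is None:
        raise InfeasibleAssignment(
            f"no feasible assignment for component {comp.sites}"
        )
    n_sites = len(comp.sites)
    owner_of: list[int | None] = [None] * len(comp.peaks)
    for si, pi in enumerate(state):
        owner_of[pi] = si

    def local_log(peaks: set[int]) -> tuple[float, list[int]]:
        """Site terms of the owners of the given peaks plus the
        constraint terms touching them; also returns the violated hard
        constraints."""
        lw = 0.0
        violated: list[int] = []
        for pi in peaks:
            si = owner_of[pi]
            if si is not None:
                lw += comp.logw[si].get(pi, -math.inf)
        cis = set()
        for pi in peaks:
            cis.update(comp.cons_by_peak.get(pi, ()))
        for ci in cis:
            qa, qb, hard, lb, allowed, pw = comp.pair_cons[ci]
            good, b = comp.pair_ok_or_bonus(owner_of, qa, qb, hard, lb,
                                            allowed, pw)
            if not good:
                violated.append(ci)
            else:
                lw += b
        return lw, violated

    def apply(block: dict[int, int]) -> None:
        for si, pi in block.items():
            state[si] = pi
            owner_of[pi] = si

    def build_block(sa: int, sb: int) -> tuple[dict, dict] | None:
        """Base swap of sa and sb, iteratively extended with the induced
        swaps of constraint-partner owners while the move stays
        hard-infeasible (e.g. swapping two protons of different CH2
        groups drags both carbon peaks and then the geminal partners
        along).  The cascade is deterministic, so the proposal is
        symmetric.  Returns (block, reverse_block) or None if the move
        cannot be repaired with pairwise extensions."""
        pa, pb = state[sa], state[sb]
        if pb not in comp.logw[sa] or pa not in comp.logw[sb]:
            return None
        block = {sa: pb, sb: pa}
        reverse = {sa: pa, sb: pb}
        apply(block)
        ok = False
        for _ in range(len(comp.sites)):
            _, violated = local_log({reverse[si] for si in block})
            if not violated:
                ok = True
                break
            moved_peaks = set(block.values()) | set(reverse.values())
            partners = set()
            for ci in violated:
                qa, qb, hard, *_ = comp.pair_cons[ci]
                ends = {qa, qb}
                outside = ends - moved_peaks
                if len(outside) != 1:
                    partners = set()
                    break
                partners.update(outside)
            if len(partners) != 2:
                break
            q1, q2 = sorted(partners)
            o1, o2 = owner_of[q1], owner_of[q2]
            if (o1 is None or o2 is None or o1 in block or o2 in block
                    or comp.nuclei[o1] != comp.nuclei[o2]
                    or q2 not in comp.logw[o1] or q1 not in comp.logw[o2]):
                break
            block.update({o1: q2, o2: q1})
            reverse.update({o1: q1, o2: q2})
            apply({o1: q2, o2: q1})
        apply(reverse)
        return (block, reverse) if ok else None

    nuc_groups: dict[str, list[int]] = {}
    for si, nuc in enumerate(comp.nuclei):
        nuc_groups.setdefault(nuc, []).append(si)
    swap_pool = [g for g in nuc_groups.values() if len(g) >= 2]
    if not swap_pool:
        marg = {(si, state[si]): 1.0 for si in range(n_sites)}
        return marg, {k: 0.0 for k in marg}

    counts = np.zeros((n_sites, len(comp.peaks)))
    n_batches = 20
    batch_counts = np.zeros((n_batches, n_sites, len(comp.peaks)))
    kept = 0

    total = sweeps + burn_in
    for sweep in range(total):
        for _ in range(n_sites):
            group = swap_pool[rng.integers(len(swap_pool))]
            a, b = rng.choice(len(group), size=2, replace=False)
            sa, sb = group[a], group[b]
            proposal = build_block(sa, sb)
            if proposal is None:
                continue
            block, reverse = proposal
            affected = {state[si] for si in block}
            old, old_violated = local_log(affected)
            if old_violated:  # cannot happen from a feasible state
                continue
            apply(block)
            new, new_violated = local_log(affected)
            if new_violated or math.log(rng.random()) > new - old:
                apply(reverse)
        if sweep >= burn_in:
            kept += 1
            bi = (sweep - burn_in) * n_batches // sweeps
            for si in range(n_sites):
                counts[si, state[si]] += 1
                batch_counts[bi, si, state[si]] += 1

    marg_arr = counts / kept
    batch_means = batch_counts / (kept / n_batches)
    se_arr = batch_means.std(axis=0, ddof=1) / math.sqrt(n_batches)
    # binomial floor keeps the error estimate positive for saturated entries
    laplace = (counts + 1) / (kept + 2)
    floor = np.sqrt(laplace * (1 - laplace) / kept)
    se_arr = np.maximum(se_arr, floor)

    marg: dict[tuple[int, int], float] = {}
    se: dict[tuple[int, int], float] = {}
    for si in range(n_sites):
        for pi in range(len(comp.peaks)):
            if comp.cand_mask[si] >> pi & 1:
                marg[(si, pi)] = float(marg_arr[si, pi])
                se[(si, pi)] = float(se_arr[si, pi])
    return marg, se


def _fold_unary_soft_evidence(
    table: CandidateTable, constraints: list[Constraint]
) -> None:
    """Fold pairwise evidence whose one peak is already owned by a forced
    site into the contested side's candidate weights.

    This covers soft contact rewards and the graded pair weights of hard
    constraints.  When both peaks are forced the factor is a constant and
    irrelevant to the marginals; when both are contested the term stays
    pairwise and is handled during component search.
    """

    def forced_owner(pid: str) -> str | None:
        holders = [s for s, w in table.weights.items() if pid in w]
        if len(holders) == 1 and len(table.weights[holders[0]]) == 1:
            return holders[0]
        return None

    for con in constraints:
        if len(con.peak_ids) != 2:
            continue
        if con.hard and con.pair_weights is None:
            continue
        pa, pb = con.peak_ids
        for fixed_pid, open_pid in ((pa, pb), (pb, pa)):
            owner = forced_owner(fixed_pid)
            if owner is None or forced_owner(open_pid) is not None:
                continue
            for t in list(table.weights):
                if open_pid not in table.weights[t] or t == owner:
                    continue
                allowed = (owner, t) in con.allowed_site_pairs or (
                    t, owner
                ) in con.allowed_site_pairs
                if not allowed:
                    continue
                if con.pair_weights is not None:
                    factor = con.pair_weights.get(
                        (owner, t), con.pair_weights.get((t, owner), 1.0)
                    )
                else:
                    factor = con.weight
                table.weights[t][open_pid] *= factor
            break


def _components(
    table: CandidateTable, constraints: list[Constraint]
) -> list[list[str]]:
    """Independent ambiguity components among the non-singleton sites.

    Sites are joined when they share a candidate peak or appear on the two
    sides of a constraint (hard or soft) whose both peaks are still
    contested."""
    multi = [s for s, w in table.weights.items() if len(w) > 1]
    parent = {s: s for s in multi}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    holders: dict[str, list[str]] = {}
    for s in multi:
        for pid in table.weights[s]:
            holders.setdefault(pid, []).append(s)
    for sites_of_peak in holders.values():
        for other in sites_of_peak[1:]:
            union(sites_of_peak[0], other)
    for con in constraints:
        pids = [p for p in con.peak_ids if p in holders]
        if len(pids) == 2:
            union(holders[pids[0]][0], holders[pids[1]][0])
    groups: dict[str, list[str]] = {}
    for s in multi:
        groups.setdefault(find(s), []).append(s)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])


def global_marginals(
    candidates: CandidateTable,
    constraints: list[Constraint],
    method: str = "auto",
    seed: int | None = None,
    max_enum: int = MAX_ENUM,
    unambiguity_threshold: float = UNAMBIGUITY_THRESHOLD,
    strict_bijection: bool = True,
    gibbs_sweeps: int = 4000,
    gibbs_burn_in: int = 500,
) -> AssignmentResult:
    """Marginal posterior over global assignments.

    The posterior weight of a global injective assignment is the product
    of candidate weights over sites, times the soft-constraint
    multipliers, restricted to hard-feasible assignments.  Marginals are
    exact (component-wise enumeration) when a component has at most
    ``max_enum`` sites or ``method='enumerate'``; larger components use
    seeded Gibbs sampling (``method='gibbs'`` forces sampling).  The
    unambiguous map contains the sites whose top marginal reaches the
    threshold; it is injective per nucleus by construction.
    """
    if method not in ("auto", "enumerate", "gibbs"):
        raise ValueError(f"unknown method {method!r}")
    table = propagate(candidates, constraints)
    if strict_bijection:
        for nuc in ("H1", "C13"):
            n_sites = sum(1 for s, n in table.nuclei.items() if n == nuc)
            n_peaks = sum(1 for p, n in table.peak_nuclei.items() if n == nuc)
            if n_sites and n_sites != n_peaks:
                raise InfeasibleAssignment(
                    f"strict bijection: {n_sites} {nuc} sites vs "
                    f"{n_peaks} {nuc} peaks"
                )

    marginals: dict[str, dict[str, float]] = {}
    for s, w in table.weights.items():
        if len(w) == 1:
            marginals[s] = {next(iter(w)): 1.0}

    _fold_unary_soft_evidence(table, constraints)
    components = _components(table, constraints)
    diagnostics: dict = {"gibbs": {}, "n_feasible": {}}
    rng = np.random.default_rng(seed) if seed is not None else None

    for comp_sites in components:
        comp = _Component(comp_sites, table, constraints)
        use_gibbs = method == "gibbs" or (
            method == "auto" and len(comp_sites) > max_enum
        )
        if use_gibbs and len(comp_sites) > 1:
            if rng is None:
                raise InfeasibleAssignment(
                    f"component {comp_sites} has {len(comp_sites)} sites "
                    f"(max_enum={max_enum}) and sampling is disabled "
                    "(no seed given)"
                )
            marg, se = _gibbs_component(
                comp, strict_bijection, rng, gibbs_sweeps, gibbs_burn_in
            )
            diagnostics["gibbs"][tuple(comp_sites)] = {
                (comp.sites[si], comp.peaks[pi]): se[(si, pi)]
                for (si, pi) in se
            }
        else:
            marg, n_feas = _enumerate_component(comp, strict_bijection)
            diagnostics["n_feasible"][tuple(comp_sites)] = n_feas
        for (si, pi), p in marg.items():
            marginals.setdefault(comp.sites[si], {})[comp.peaks[pi]] = p

    # renormalise rows (guards the sum-to-one invariant against rounding)
    for s, row in marginals.items():
        z = sum(row.values())
        for pid in row:
            row[pid] /= z

    # build the unambiguous map, injective per nucleus
    order = sorted(
        marginals,
        key=lambda s: -max(marginals[s].values()),
    )
    assignment_map: dict[str, str] = {}
    taken: set[str] = set()
    ambiguous: list[str] = []
    for s in order:
        row = marginals[s]
        pid = max(row, key=row.get)
        if row[pid] >= unambiguity_threshold and pid not in taken:
            assignment_map[s] = pid
            taken.add(pid)
        else:
            ambiguous.append(s)
    return AssignmentResult(
        marginals=marginals,
        map=assignment_map,
        ambiguous_sites=sorted(ambiguous),
        eliminations=list(table.eliminations),
        components=components,
        diagnostics=diagnostics,
    )
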