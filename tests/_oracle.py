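"""Naive all-permutations reference for global assignment marginals.

Independent of the production path: no constraint propagation, no
component decomposition, no bitmask search, no log-space scaling - just
every injective site-to-peak map per nucleus, weighted in linear space.
"""

from itertools import permutations


def _constraint_factor(con, owner):
    """Weight multiplier of one constraint under a full assignment."""
    pids = con.peak_ids
    owners = [owner.get(p) for p in pids]
    if any(o is None for o in owners):
        return 1.0
    a, b = owners
    allowed = (a, b) in con.allowed_site_pairs or (
        b, a
    ) in con.allowed_site_pairs
    if con.hard:
        if not allowed:
            return 0.0
        if con.pair_weights is not None:
            return con.pair_weights.get(
                (a, b), con.pair_weights.get((b, a), 1.0)
            )
        return 1.0
    return con.weight if allowed else 1.0


def brute_force_marginals(table, constraints):
    """Exact marginals over all feasible global assignments.

    ``table`` is a CandidateTable (its gated weights are the per-site
    likelihood terms); missing (site, peak) entries have weight zero.
    Assumes a strict per-nucleus bijection.
    """
    marginals = {s: {} for s in table.weights}
    by_nucleus = {}
    for s, nuc in table.nuclei.items():
        by_nucleus.setdefault(nuc, []).append(s)
    peaks_by_nucleus = {}
    for p, nuc in table.peak_nuclei.items():
        peaks_by_nucleus.setdefault(nuc, []).append(p)
    nuclei = sorted(by_nucleus)
    site_groups = [sorted(by_nucleus[n]) for n in nuclei]
    peak_groups = [sorted(peaks_by_nucleus[n]) for n in nuclei]
    for sites, peaks in zip(site_groups, peak_groups):
        if len(sites) != len(peaks):
            raise ValueError("strict bijection requires equal counts")

    total = 0.0
    perm_groups = [list(permutations(g)) for g in peak_groups]

    def weight(owner, assignment):
        w = 1.0
        for s, p in assignment.items():
            w *= table.weights[s].get(p, 0.0)
            if w == 0.0:
                return 0.0
        for con in constraints:
            w *= _constraint_factor(con, owner)
            if w == 0.0:
                return 0.0
        return w

    def recurse(gi, owner, assignment):
        nonlocal total
        if gi == len(site_groups):
            w = weight(owner, assignment)
            if w > 0.0:
                total += w
                for s, p in assignment.items():
                    marginals[s][p] = marginals[s].get(p, 0.0) + w
            return
        sites = site_groups[gi]
        for perm in perm_groups[gi]:
            for s, p in zip(sites, perm):
                owner[p] = s
                assignment[s] = p
            recurse(gi + 1, owner, assignment)
            for s, p in zip(sites, perm):
                del owner[p]
                del assignment[s]

    recurse(0, {}, {})
    if total == 0.0:
        raise ValueError("no feasible assignment")
    for s in marginals:
        for p in marginals[s]:
            marginals[s][p] /= total
    return marginals
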