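"""Constraints, propagation, and global marginal posteriors."""

import math

import pytest

from _oracle import brute_force_marginals
from xtalshift.assign import (
    InfeasibleAssignment,
    constraints_from_hetcor,
    contacts_to_evidence,
    expected_correlation_score,
    global_marginals,
    propagate,
)
from xtalshift.molgraph import bond_distance_matrix, build_sites, parse_structure
from xtalshift.priors import ShiftPrior, candidate_table
from xtalshift.spectra import (
    CorrelationSet,
    Peak,
    PeakList,
    ProtonPairContact,
    resolve_dq_pairs,
)
from xtalshift.synthetic import generate, random_molecule


class TestConstraintsFromHetcor:
    def test_short_range_allows_bonded_pairs_only(self, verinurad):
        fx = verinurad
        short = CorrelationSet("HETCOR_SHORT", [(132.8, 6.63)], 0.5, 0.25)
        (con,) = constraints_from_hetcor(
            short, fx.sites, fx.bdm, fx.peaklists["C13"], fx.peaklists["H1"]
        )
        assert con.hard and con.kind == "ONE_BOND_CH"
        assert ("C9", "H9") in con.allowed_site_pairs
        assert all(fx.bdm[c, h] == 1 for c, h in con.allowed_site_pairs)

    def test_long_range_window(self, verinurad):
        fx = verinurad
        long_ = CorrelationSet("HETCOR_LONG", [(109.7, 6.63)], 0.5, 0.25)
        (con,) = constraints_from_hetcor(
            long_, fx.sites, fx.bdm, fx.peaklists["C13"], fx.peaklists["H1"]
        )
        assert ("C10", "H9") in con.allowed_site_pairs  # 2 bonds
        assert ("C23", "H24") in con.allowed_site_pairs  # 2 bonds
        assert ("C16", "H9") not in con.allowed_site_pairs  # 4 bonds
        assert all(
            2 <= fx.bdm[c, h] <= 3 for c, h in con.allowed_site_pairs
        )

    def test_detection_odds(self, verinurad):
        fx = verinurad
        long_ = CorrelationSet("HETCOR_LONG", [(131.4, 7.86)], 0.5, 0.25)
        (con,) = constraints_from_hetcor(
            long_, fx.sites, fx.bdm, fx.peaklists["C13"], fx.peaklists["H1"],
            detection={2: 0.7, 3: 0.2},
        )
        assert con.pair_weights[("C11", "H12")] == pytest.approx(0.7 / 0.3)
        assert con.pair_weights[("C11", "H15")] == pytest.approx(0.25)

    def test_unmatched_entry_skipped(self, verinurad, caplog):
        fx = verinurad
        long_ = CorrelationSet("HETCOR_LONG", [(500.0, 6.63)], 0.5, 0.25)
        with caplog.at_level("WARNING"):
            cons = constraints_from_hetcor(
                long_, fx.sites, fx.bdm,
                fx.peaklists["C13"], fx.peaklists["H1"],
            )
        assert cons == []
        assert "matches no picked peak" in caplog.text


class TestContactsToEvidence:
    def test_soft_with_intramolecular_reward_set(self, verinurad):
        fx = verinurad
        contacts = [ProtonPairContact("H09", "H04", 14.7)]  # 6.63 + 8.07
        (con,) = contacts_to_evidence(contacts, fx.sites, fx.bdm)
        assert not con.hard and con.weight > 1.0
        assert ("H9", "H8") in con.allowed_site_pairs or (
            "H8", "H9"
        ) in con.allowed_site_pairs
        # an intermolecular hydrogen bond has no intramolecular
        # explanation: the pair is simply not rewarded, never forbidden
        assert ("H2", "H24") not in con.allowed_site_pairs
        assert ("H24", "H2") not in con.allowed_site_pairs

    def test_autocorrelation_imposes_nothing(self, verinurad):
        contacts = [ProtonPairContact("H09", "H09", 13.26)]
        assert contacts_to_evidence(
            contacts, verinurad.sites, verinurad.bdm
        ) == []

    def test_empty(self, verinurad):
        assert contacts_to_evidence([], verinurad.sites, verinurad.bdm) == []


class TestExpectedCorrelationScore:
    def test_window_one_counts_bonded_protons(self, verinurad):
        scores = expected_correlation_score(
            verinurad.sites, verinurad.bdm, window=1
        )
        by_label = {s.label: s for s in verinurad.sites}
        for label, lam in scores.items():
            n_bonded = 0 if by_label[label].is_quaternary else 1
            assert lam == n_bonded

    def test_benzene_symmetric(self):
        g = parse_structure("c1ccccc1")
        sites = build_sites(g)
        bdm = bond_distance_matrix(sites, g)
        scores = expected_correlation_score(sites, bdm, window=3)
        assert len(set(scores.values())) == 1

    def test_isolated_quaternary_minimal(self, verinurad):
        """The naphthalene ipso carbon bonded to one CH only has the
        smallest in-window proton neighbourhood among the candidates the
        peak with a single long-range correlation could go to."""
        scores = expected_correlation_score(
            verinurad.sites, verinurad.bdm, window=2
        )
        assert scores["C7"] <= min(scores["C3"], scores["C16"], scores["C11"])


def toy_table(priors, peaks_by_nucleus):
    peaklists = []
    for nucleus, shifts in peaks_by_nucleus.items():
        prefix = "c" if nucleus == "C13" else "h"
        peaklists.append(PeakList(nucleus, [
            Peak(f"{prefix}{i}", s) for i, s in enumerate(shifts)
        ]))
    return candidate_table(priors, peaklists)


class TestPropagate:
    def test_fixed_point_when_all_singletons(self):
        priors = [
            ShiftPrior("C1", 20.0, 1.0, "C13"),
            ShiftPrior("C2", 170.0, 1.0, "C13"),
        ]
        table = toy_table(priors, {"C13": [20.0, 170.0]})
        out = propagate(table, [])
        assert out.weights == table.weights
        assert out.eliminations == []

    def test_pigeonhole_infeasible(self):
        priors = [
            ShiftPrior("C1", 20.0, 1.0, "C13"),
            ShiftPrior("C2", 20.1, 1.0, "C13"),
        ]
        table = toy_table(priors, {"C13": [20.0, 170.0]})
        # both sites can only take the 20 ppm peak
        with pytest.raises(InfeasibleAssignment):
            propagate(table, [])

    def test_singleton_cascade_and_log(self, verinurad):
        fx = verinurad
        table = candidate_table(fx.priors, list(fx.peaklists.values()))
        cons = []
        for key in ("HETCOR_SHORT", "HETCOR_LONG"):
            cons += constraints_from_hetcor(
                fx.correlations[key], fx.sites, fx.bdm,
                fx.peaklists["C13"], fx.peaklists["H1"],
            )
        out = propagate(table, cons)
        # characteristic-shift sites are forced outright
        for site, shift in (("C23", 175.9), ("C18", 49.1), ("H24", 15.91)):
            (pid,) = out.candidates(site)
            assert fx.peak_shift(pid) == shift
        assert out.eliminations
        assert all(e.reason for e in out.eliminations)

    def test_never_eliminates_truth(self, verinurad):
        """On the fixture and on clean synthetic instances the true
        assignment survives arc consistency."""
        fx = verinurad
        table = candidate_table(fx.priors, list(fx.peaklists.values()))
        cons = []
        for key in ("HETCOR_SHORT", "HETCOR_LONG"):
            cons += constraints_from_hetcor(
                fx.correlations[key], fx.sites, fx.bdm,
                fx.peaklists["C13"], fx.peaklists["H1"],
            )
        out = propagate(table, cons)
        truth = {
            "C9": 132.8, "C10": 109.7, "C7": 140.8, "C3": 134.2,
            "C16": 132.5, "C11": 131.4, "C4": 152.1, "H2": 9.09,
            "H6": 8.67, "H8": 8.07, "H9": 6.63,
        }
        for site, shift in truth.items():
            assert shift in {
                fx.peak_shift(p) for p in out.candidates(site)
            }

    def test_added_constraint_never_grows_candidates(self, verinurad):
        fx = verinurad
        table = candidate_table(fx.priors, list(fx.peaklists.values()))
        cons = constraints_from_hetcor(
            fx.correlations["HETCOR_SHORT"], fx.sites, fx.bdm,
            fx.peaklists["C13"], fx.peaklists["H1"],
        ) + constraints_from_hetcor(
            fx.correlations["HETCOR_LONG"], fx.sites, fx.bdm,
            fx.peaklists["C13"], fx.peaklists["H1"],
        )
        prev = propagate(table, cons[:4])
        more = propagate(table, cons)
        for site in table.weights:
            assert more.candidates(site) <= prev.candidates(site)


class TestGlobalMarginals:
    def test_symmetric_methyl_pair_stays_ambiguous(self):
        priors = [
            ShiftPrior("C1", 26.0, 4.53, "C13"),
            ShiftPrior("C2", 26.0, 4.53, "C13"),
        ]
        table = toy_table(priors, {"C13": [27.0, 25.1]})
        res = global_marginals(table, [])
        for site in ("C1", "C2"):
            for p in res.marginals[site].values():
                assert p == pytest.approx(0.5, abs=1e-12)
        assert res.map == {}
        assert sorted(res.ambiguous_sites) == ["C1", "C2"]

    def test_rows_sum_to_one_and_map_injective(self, verinurad_result):
        for row in verinurad_result.marginals.values():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)
        mapped = list(verinurad_result.map.values())
        assert len(mapped) == len(set(mapped))

    def test_enumeration_matches_bruteforce_five_site_component(self):
        """Exact enumeration equals the naive 120-permutation oracle."""
        mol = random_molecule(5, seed=7)
        inst = generate(mol, seed=7, prior_sd_c=9.0, prior_sd_h=1.2,
                        missing_rate=0.2)
        table = candidate_table(inst.priors, list(inst.peaklists.values()))
        cons = constraints_from_hetcor(
            inst.correlations["HETCOR_LONG"], inst.sites, inst.bdm,
            inst.peaklists["C13"], inst.peaklists["H1"],
            detection={2: 0.7, 3: 0.2},
        )
        res = global_marginals(table, cons, method="enumerate")
        oracle = brute_force_marginals(propagate(table, cons), cons)
        for site, row in oracle.items():
            for pid, p in row.items():
                assert res.marginals[site].get(pid, 0.0) == pytest.approx(
                    p, abs=1e-12
                )

    def test_gibbs_agrees_with_enumeration(self):
        inst = generate(random_molecule(5, seed=3), seed=3,
                        prior_sd_c=10.0, prior_sd_h=1.5)
        table = candidate_table(inst.priors, list(inst.peaklists.values()))
        exact = global_marginals(table, [], method="enumerate")
        sampled = global_marginals(
            table, [], method="gibbs", seed=11,
            gibbs_sweeps=4000, gibbs_burn_in=400,
        )
        for comp, se_map in sampled.diagnostics["gibbs"].items():
            for (site, pid), se in se_map.items():
                diff = abs(
                    sampled.marginals[site][pid]
                    - exact.marginals[site].get(pid, 0.0)
                )
                assert diff <= 4 * se + 1e-9

    def test_noise_free_recovery(self):
        """Well-separated priors with complete correlations recover the
        truth with near-certain marginals."""
        inst = generate("quinoline", seed=5, prior_sd_c=0.5,
                        prior_sd_h=0.05, missing_rate=0.0)
        table = candidate_table(inst.priors, list(inst.peaklists.values()))
        cons = []
        for key in ("HETCOR_SHORT", "HETCOR_LONG"):
            cons += constraints_from_hetcor(
                inst.correlations[key], inst.sites, inst.bdm,
                inst.peaklists["C13"], inst.peaklists["H1"],
            )
        res = global_marginals(table, cons, method="enumerate")
        for site, truth_pid in inst.true_assignment.items():
            assert res.marginals[site][truth_pid] >= 0.999
            assert res.map[site] == truth_pid

    def test_large_component_without_seed_errors(self):
        priors = [
            ShiftPrior(f"C{i}", 100.0, 50.0, "C13") for i in range(6)
        ]
        table = toy_table(
            priors, {"C13": [90.0, 95.0, 100.0, 105.0, 110.0, 115.0]}
        )
        with pytest.raises(InfeasibleAssignment, match="sampling is disabled"):
            global_marginals(table, [], method="auto", max_enum=3, seed=None)

    def test_strict_bijection_count_mismatch(self):
        priors = [ShiftPrior("C1", 100.0, 2.0, "C13")]
        table = toy_table(priors, {"C13": [100.0, 105.0]})
        with pytest.raises(InfeasibleAssignment, match="strict bijection"):
            global_marginals(table, [])
        # surplus peaks (impurities) are allowed in non-strict mode
        res = global_marginals(table, [], strict_bijection=False)
        assert res.map["C1"] == "c0"

    def test_soft_contact_breaks_tie(self):
        """An H-H contact shifts mass toward the intramolecularly
        explained assignment without forbidding the alternative."""
        g = parse_structure("CCO")  # ethanol: CH3, CH2(a/b), OH
        sites = build_sites(g)
        bdm = bond_distance_matrix(sites, g)
        h_sites = [s for s in sites if s.nucleus == "H1"]
        # with a 2-bond window the geminal CH2 pair is the only
        # intramolecular explanation for a contact
        close = {
            frozenset((a.label, b.label))
            for a in h_sites for b in h_sites
            if a.label != b.label and bdm[a.label, b.label] <= 2
        }
        assert len(close) == 1
        (pair,) = close
        priors = [ShiftPrior(s.label, 3.0, 5.0, "H1") for s in h_sites]
        shifts = [1.0, 2.0, 3.0, 4.0][: len(h_sites)]
        table = toy_table(priors, {"H1": shifts})
        contact = ProtonPairContact("h0", "h1", shifts[0] + shifts[1])
        cons = contacts_to_evidence(
            [contact], sites, bdm, hh_window=2, reward=5.0
        )
        res = global_marginals(table, cons, method="enumerate")
        flat = global_marginals(table, [], method="enumerate")
        joint = sum(res.marginals[a].get("h0", 0) for a in pair)
        joint_flat = sum(flat.marginals[a].get("h0", 0) for a in pair)
        assert joint > joint_flat

    def test_marginal_mass_conserved_per_peak(self, verinurad_result):
        """Strict bijection: each peak's total marginal mass is one."""
        mass: dict[str, float] = {}
        for row in verinurad_result.marginals.values():
            for pid, p in row.items():
                mass[pid] = mass.get(pid, 0.0) + p
        for pid, m in mass.items():
            assert m == pytest.approx(1.0, abs=1e-6)
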