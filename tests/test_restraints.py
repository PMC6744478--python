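"""Restraint construction, evaluation and the brute-force distance oracle."""

import numpy as np
import pytest

from xlcal.fixtures import lobster_model, make_crosslink_table, make_helix_model
from xlcal.restraints import (
    DistanceRestraint,
    RestraintPolicy,
    build_restraints,
    evaluate_restraints,
    summarize,
)
from xlcal.structure import Atom, Residue, StructureModel
from xlcal.xlms import ResiduePair


def _pair(pa, a, pb, b, kind):
    return ResiduePair(protein_a=pa, pos_a=a, protein_b=pb, pos_b=b, kind=kind, psm_count=1)


def _model_with_nz(d_nz, d_ca=None, drop_nz=False):
    """Two lysines with NZ atoms d_nz apart (and optionally only CAs d_ca apart)."""
    atoms1 = [Atom("CA", "C", [0, 0, 0])]
    atoms2 = [Atom("CA", "C", [d_ca if d_ca is not None else d_nz, 0, 0])]
    if not drop_nz:
        atoms1.append(Atom("NZ", "N", [0, 1, 0]))
        atoms2.append(Atom("NZ", "N", [d_nz, 1, 0]))
    return StructureModel(
        "m", {"A": [Residue("A", 1, "LYS", atoms1), Residue("A", 9, "LYS", atoms2)]}
    )


class TestBuild:
    def test_intra_bounds(self):
        (r,) = build_restraints([_pair("P", 86, "P", 93, "intra")], chain_map={"P": "A"})
        assert (r.lower, r.upper) == (0.0, 10.0)
        assert r.policy_tag == "intra"
        assert (r.chain_a, r.res_a, r.chain_b, r.res_b) == ("A", 86, "A", 93)

    def test_inter_bounds(self):
        (r,) = build_restraints(
            [_pair("R7BP", 5, "RGS7", 40, "inter")], chain_map={"R7BP": "A", "RGS7": "B"}
        )
        assert (r.lower, r.upper) == (10.0, 20.0)

    def test_empty_pairs(self):
        assert build_restraints([]) == []

    def test_missing_protein_in_chain_map(self):
        with pytest.raises(KeyError, match="RGS7"):
            build_restraints([_pair("R7BP", 1, "RGS7", 2, "inter")], chain_map={"R7BP": "A"})


class TestEvaluate:
    @pytest.mark.parametrize(
        "d,satisfied,violation", [(8.0, True, 0.0), (12.0, False, 2.0), (10.0, True, 0.0)]
    )
    def test_upper_bound_arithmetic(self, d, satisfied, violation):
        model = _model_with_nz(d)
        restraints = build_restraints([_pair("A", 1, "A", 9, "intra")])
        (rep,) = evaluate_restraints(model, restraints)
        assert rep.atom_used == "primary"
        assert rep.satisfied is satisfied
        assert rep.violation == pytest.approx(violation)

    def test_calpha_fallback_widens_bounds(self):
        # no NZ atoms; Ca-Ca = 21 against widened bound 10 + 13 = 23
        model = _model_with_nz(0, d_ca=21.0, drop_nz=True)
        restraints = build_restraints([_pair("A", 1, "A", 9, "intra")])
        (rep,) = evaluate_restraints(model, restraints)
        assert rep.atom_used == "fallback"
        assert rep.distance == pytest.approx(21.0)
        assert rep.satisfied

    def test_fallback_still_violated_beyond_pad(self):
        model = _model_with_nz(0, d_ca=25.0, drop_nz=True)
        restraints = build_restraints([_pair("A", 1, "A", 9, "intra")])
        (rep,) = evaluate_restraints(model, restraints)
        assert rep.atom_used == "fallback"
        assert rep.violation == pytest.approx(2.0)

    def test_missing_atoms_are_data(self):
        model = _model_with_nz(5.0)
        restraints = build_restraints([_pair("A", 1, "A", 999, "intra")])
        (rep,) = evaluate_restraints(model, restraints)
        assert rep.atom_used == "missing"
        assert rep.distance is None
        assert not rep.satisfied

    def test_inter_lower_bound_flagged(self):
        model = StructureModel(
            "m",
            {
                "A": [Residue("A", 1, "LYS", [Atom("NZ", "N", [0, 0, 0])])],
                "B": [Residue("B", 1, "LYS", [Atom("NZ", "N", [5, 0, 0])])],
            },
        )
        restraints = build_restraints([_pair("A", 1, "B", 1, "inter")])
        (rep,) = evaluate_restraints(model, restraints)
        assert rep.violated_bound == "lower"
        assert rep.violation == pytest.approx(5.0)

    def test_order_independence(self, lobster, lobster_restraints):
        fwd = evaluate_restraints(lobster, lobster_restraints)
        rev = evaluate_restraints(lobster, lobster_restraints[::-1])
        assert [r.distance for r in rev] == [r.distance for r in fwd[::-1]]


class TestOracleAgreement:
    def test_matches_brute_force_on_random_fixtures(self):
        """Restraint distances equal independent pairwise-distance computation to 1e-9 Å."""
        rng = np.random.default_rng(42)
        policy = RestraintPolicy()
        for _ in range(100):
            n_lys = rng.integers(4, 10)
            positions = sorted(rng.choice(np.arange(1, 40), size=n_lys, replace=False))
            coords = {p: rng.uniform(-30, 30, size=3) for p in positions}
            model = StructureModel(
                "r",
                {
                    "A": [
                        Residue("A", int(p), "LYS", [Atom("NZ", "N", coords[p])])
                        for p in positions
                    ]
                },
            )
            pairs = [
                _pair("A", int(positions[i]), "A", int(positions[j]), "intra")
                for i in range(n_lys)
                for j in range(i + 1, n_lys)
            ]
            reports = evaluate_restraints(model, build_restraints(pairs), policy)
            for rep, pair in zip(reports, pairs):
                expected = float(
                    np.sqrt(np.sum((coords[pair.pos_a] - coords[pair.pos_b]) ** 2))
                )
                assert abs(rep.distance - expected) < 1e-9

    def test_monotonicity_in_upper_bound(self):
        """Raising the upper bound never decreases the satisfied count."""
        rng = np.random.default_rng(3)
        model = lobster_model()
        table = make_crosslink_table(model, n_pairs=10, seed=5)
        pairs = [
            _pair(r.protein_a, int(r.link_pos_a), r.protein_b, int(r.link_pos_b), "intra")
            for r in table.drop_duplicates(["link_pos_a", "link_pos_b"]).itertuples()
        ]
        prev = -1
        for upper in [0.5, 2.0, 5.0, 8.0, 10.0, 15.0, 50.0]:
            policy = RestraintPolicy(intra_max=upper)
            s = summarize(evaluate_restraints(model, build_restraints(pairs, policy), policy))
            assert s.n_satisfied >= prev
            prev = s.n_satisfied


class TestSummarize:
    def test_all_satisfied(self, lobster, lobster_restraints):
        s = summarize(evaluate_restraints(lobster, lobster_restraints))
        assert s.n_total == s.n_evaluated == s.n_satisfied == 14
        assert s.fraction_satisfied == 1.0
        assert s.sum_violations == 0.0

    def test_partial_satisfaction(self):
        model = _model_with_nz(12.5)
        restraints = build_restraints(
            [_pair("A", 1, "A", 9, "intra")] * 3 + [_pair("A", 1, "A", 9, "intra")]
        )
        # make 3 of 4 satisfied by mixing two models' reports
        good = evaluate_restraints(_model_with_nz(8.0), restraints[:3])
        bad = evaluate_restraints(model, restraints[3:])
        s = summarize(good + bad)
        assert s.fraction_satisfied == pytest.approx(0.75)
        assert s.max_violation == pytest.approx(2.5)

    def test_zero_evaluated(self):
        model = _model_with_nz(5.0)
        restraints = build_restraints([_pair("A", 100, "A", 200, "intra")])
        s = summarize(evaluate_restraints(model, restraints))
        assert s.n_evaluated == 0
        assert s.fraction_satisfied is None


def test_policy_validation():
    with pytest.raises(ValueError):
        RestraintPolicy(intra_max=0.0)
    with pytest.raises(ValueError):
        RestraintPolicy(inter_min=25.0, inter_max=20.0)
    with pytest.raises(ValueError):
        DistanceRestraint(
            pair=_pair("A", 1, "A", 2, "intra"), lower=5, upper=1,
            chain_a="A", res_a=1, chain_b="A", res_b=2, policy_tag="intra",
        )
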