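"""Junction criterion, clash detection, compatibility accounting, optimizer."""

import itertools
import math

import numpy as np
import pytest

from crosscoil.assembly import (
    STRAND_RATE,
    JunctionReport,
    clash_scan,
    compatibility_report,
    junction_check,
    optimize_assembly,
    _random_rotation,
)
from crosscoil.coilgen import build_helix
from crosscoil.distances import DEFAULT_VDW, validate
from crosscoil.structure import AssemblyModel, FragmentModel, Junction, ResidueCoords
from crosscoil.synth import LinkSimSpec, simulate_crosslinks
from crosscoil.xlink import CrossLinkSet


def ca_only(pid, idx, xyz, aa="A"):
    return ResidueCoords(pid, idx, aa, {"CA": np.array(xyz, float)})


def gapped_assembly(endpoint_distance, n_omitted):
    res1 = {("P", i): ca_only("P", i, (3.8 * i, 0, 0)) for i in range(1, 6)}
    start2 = 5 + n_omitted + 1
    res2 = {
        ("P", start2 + k): ca_only("P", start2 + k, (19.0 + endpoint_distance + 3.8 * k, 0, 0))
        for k in range(5)
    }
    frags = [
        FragmentModel("f1", [("P", 1, 5, "+")], res1),
        FragmentModel("f2", [("P", start2, start2 + 4, "+")], res2),
    ]
    return AssemblyModel(frags)


class TestJunctionCheck:
    def test_helical_rate_gap_passes(self):
        reports = junction_check(gapped_assembly(6.0, 4))
        (rep,) = reports
        assert rep.per_residue == pytest.approx(1.5)
        assert rep.passes

    def test_overstretched_gap_fails(self):
        (rep,) = junction_check(gapped_assembly(30.0, 2))
        assert rep.per_residue == pytest.approx(15.0)
        assert not rep.passes  # 30 > 2 x 3.4 + 2

    @pytest.mark.parametrize("distance", [5.0, 12.0, 25.0, 40.0])
    def test_pass_is_monotone_in_omitted_residues(self, distance):
        verdicts = [
            junction_check(gapped_assembly(distance, n))[0].passes
            for n in range(1, 15)
        ]
        # once a gap passes at some n_omitted it passes for every larger one
        assert verdicts == sorted(verdicts)

    def test_boundary_arithmetic(self):
        n = 4
        limit = n * STRAND_RATE + 2.0
        assert junction_check(gapped_assembly(limit - 0.01, n))[0].passes
        assert not junction_check(gapped_assembly(limit + 0.01, n))[0].passes


class TestClashScan:
    def test_close_ca_pair_in_different_fragments_reported(self):
        frags = [
            FragmentModel("a", [("P", 1, 1, None)], {("P", 1): ca_only("P", 1, (0, 0, 0))}),
            FragmentModel("b", [("Q", 1, 1, None)], {("Q", 1): ca_only("Q", 1, (1.0, 0, 0))}),
        ]
        clashes = clash_scan(AssemblyModel(frags))
        assert len(clashes) == 1

    def test_ideal_helix_is_clash_free(self):
        assert clash_scan(AssemblyModel([build_helix("A" * 30)])) == []

    def test_adjacent_residues_excluded(self):
        res = {
            ("P", 1): ca_only("P", 1, (0, 0, 0)),
            ("P", 2): ca_only("P", 2, (1.0, 0, 0)),
        }
        frag = FragmentModel("f", [("P", 1, 2, None)], res)
        assert clash_scan(AssemblyModel([frag])) == []

    def test_matches_all_pairs_oracle_on_jittered_assembly(self):
        rng = np.random.default_rng(8)
        residues = {}
        for i in range(1, 40):
            base = rng.uniform(0, 25, 3)
            residues[("P", i)] = ResidueCoords(
                "P", i, "A",
                {"CA": base, "N": base + rng.normal(0, 1.2, 3), "O": base + rng.normal(0, 1.2, 3)},
            )
        assembly = AssemblyModel([FragmentModel("f", [], residues)])
        coords, keys = assembly.atom_table()
        tol = 0.6
        expected = set()
        for i, j in itertools.combinations(range(len(coords)), 2):
            ki, kj = keys[i], keys[j]
            if ki[0] == kj[0] and abs(ki[1] - kj[1]) <= 1:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if d < DEFAULT_VDW[ki[3]] + DEFAULT_VDW[kj[3]] - tol:
                expected.add(frozenset((ki[:3], kj[:3])))
        got = {frozenset((a, b)) for a, b, _ in clash_scan(assembly, tol)}
        assert got == expected


class TestCompatibilityReport:
    def test_counts_partition_total(self, scaffold, scaffold_links):
        assembly, _, domains = scaffold
        summary = compatibility_report(scaffold_links, assembly, domains)
        assert (
            summary.explicit_total
            + summary.implicit
            + summary.incompatible
            + summary.unplaced
            == summary.total
            == len(scaffold_links)
        )

    def test_truth_links_fully_accommodated(self, scaffold):
        assembly, _, domains = scaffold
        links = simulate_crosslinks(assembly, LinkSimSpec(seed=21))
        summary = compatibility_report(links, assembly, domains)
        assert summary.incompatible == 0
        assert summary.incorporated == summary.total
        for stats in summary.stats.values():
            assert stats["mean"] <= 27.4

    def test_missing_fragment_yields_implicit_links(self, scaffold, scaffold_links):
        assembly, _, domains = scaffold
        half = AssemblyModel([assembly.fragments[0].copy()])
        summary = compatibility_report(scaffold_links, half, domains)
        assert summary.implicit > 0
        # both-endpoint-missing links with short sequence gaps count implicit
        assert summary.explicit_total + summary.implicit + summary.incompatible + summary.unplaced == summary.total


class TestOptimizer:
    def test_feasible_input_returned_unchanged(self, scaffold):
        assembly, _, _ = scaffold
        links = simulate_crosslinks(assembly, LinkSimSpec(seed=2))
        frag = assembly.fragments[0]
        sub_links = CrossLinkSet(
            l for l in links
            if l.a.protein_id == l.b.protein_id == frag.segments[0][0]
        )
        best, diag = optimize_assembly([frag], sub_links, seed=1, n_iter=200)
        assert diag["objective"] == 0.0
        for key, res in frag.residues.items():
            assert np.allclose(best.get(*key).ca, res.ca)

    def test_same_seed_gives_identical_poses(self, three_fragment_scaffold, scaffold_links):
        assembly, _, _ = three_fragment_scaffold
        frags = [f.copy() for f in assembly.fragments]
        for f in frags[1:]:
            f.transform(np.eye(3), np.array([6.0, -4.0, 3.0]))
        runs = []
        for _ in range(2):
            best, _ = optimize_assembly(
                [f.copy() for f in frags], scaffold_links, seed=42, n_iter=300
            )
            runs.append(np.concatenate([f.ca_array() for f in best.fragments]))
        assert np.array_equal(runs[0], runs[1])

    def test_recovers_scrambled_three_fragment_assembly(self, three_fragment_scaffold):
        truth, _, _ = three_fragment_scaffold
        all_links = list(
            simulate_crosslinks(truth, LinkSimSpec(seed=11, detection_probability=1.0))
        )
        rng = np.random.default_rng(7)
        chosen = rng.choice(len(all_links), 30, replace=False)
        links = CrossLinkSet(all_links[i] for i in sorted(chosen))

        frags = [f.copy() for f in truth.fragments]
        for i, frag in enumerate(frags[1:], start=1):
            r = np.random.default_rng(100 + i)
            rot = _random_rotation(r, math.radians(25))
            centroid = frag.ca_array().mean(axis=0)
            frag.transform(np.eye(3), -centroid)
            frag.transform(rot, centroid + r.uniform(-8, 8, 3))

        best, diag = optimize_assembly(frags, links, seed=5, n_iter=6000)
        counts = validate(links, best).counts()
        assert counts["accommodated"] / len(links) >= 0.95

    def test_best_objective_trace_is_non_increasing(self, three_fragment_scaffold, scaffold_links):
        assembly, _, _ = three_fragment_scaffold
        frags = [f.copy() for f in assembly.fragments]
        for f in frags:
            f.transform(np.eye(3), np.random.default_rng(0).uniform(-5, 5, 3))
        _, diag = optimize_assembly(frags, scaffold_links, seed=3, n_iter=500)
        trace = diag["trace"]
        assert all(a >= b for a, b in zip(trace, trace[1:]))
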