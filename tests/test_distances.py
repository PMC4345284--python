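"""Euclidean and solvent-accessible-surface distance machinery."""

import heapq
import itertools
import math

import numpy as np
import pytest

from crosscoil.distances import (
    SASGridParams,
    Unmeasurable,
    Unreachable,
    ca_distance,
    sas_distance,
    validate,
)
from crosscoil.structure import AssemblyModel, FragmentModel, ResidueCoords
from crosscoil.synth import LinkSimSpec, simulate_crosslinks
from crosscoil.xlink import CrossLink, CrossLinkSet, ResidueLocus


def point_residue(pid, idx, ca, cb=None, aa="K"):
    atoms = {"CA": np.array(ca, float)}
    if cb is not None:
        atoms["CB"] = np.array(cb, float)
    return ResidueCoords(pid, idx, aa, atoms)


def assembly_of(*residues):
    return AssemblyModel(
        [FragmentModel("f", [], {(r.protein_id, r.residue_index): r for r in residues})]
    )


LINK_15 = CrossLink(ResidueLocus("P", 1), ResidueLocus("P", 5))


class TestCaDistance:
    def test_identical_coordinates(self):
        asm = assembly_of(
            point_residue("P", 1, [1, 2, 3]), point_residue("P", 5, [1, 2, 3])
        )
        assert ca_distance(LINK_15, asm) == 0.0

    def test_three_four_five(self):
        asm = assembly_of(
            point_residue("P", 1, [0, 0, 0]), point_residue("P", 5, [3, 4, 0])
        )
        assert ca_distance(LINK_15, asm) == pytest.approx(5.0)

    def test_missing_endpoint_reported(self):
        asm = assembly_of(point_residue("P", 1, [0, 0, 0]))
        result = ca_distance(LINK_15, asm)
        assert result == Unmeasurable("one_endpoint_missing")
        assert ca_distance(
            CrossLink(ResidueLocus("P", 7), ResidueLocus("P", 9)), asm
        ) == Unmeasurable("both_missing")


def wall_assembly():
    """Two endpoints separated by a solid wall with no usable aperture."""
    residues = [
        point_residue("P", 1, [0, 0, 0], [0, 0, 0.1]),
        point_residue("P", 5, [10, 0, 0], [10, 0, 0.1]),
    ]
    k = 20
    for y in range(-8, 9):
        for z in range(-8, 9):
            if abs(y) <= 1 and abs(z - 6) <= 1:
                continue
            residues.append(point_residue("W", k, [5.0, float(y), float(z)], aa="A"))
            k += 1
    return assembly_of(*residues)


def oracle_sas(assembly, link, spacing=1.0, probe=1.4, cutoff=40.0, shell=3):
    """Exhaustive Dijkstra (plain heapq) over an enumerated voxel graph.

    Voxel blocking is evaluated densely with numpy; the path search itself
    is an independent textbook implementation.
    """
    vdw = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
    ra = assembly.get(link.a.protein_id, link.a.residue_index)
    rb = assembly.get(link.b.protein_id, link.b.residue_index)
    cb_a, cb_b = ra.cb(), rb.cb()
    margin = cutoff / 2.0 + 2.0 * spacing
    lo = np.minimum(cb_a, cb_b) - margin
    hi = np.maximum(cb_a, cb_b) + margin
    shape = tuple(int(math.floor((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    ends = {(link.a.protein_id, link.a.residue_index),
            (link.b.protein_id, link.b.residue_index)}

    cells = np.array(list(itertools.product(*(range(s) for s in shape))))
    centres = lo + cells * spacing
    in_shell = (np.linalg.norm(centres - cb_a, axis=1) <= shell) | (
        np.linalg.norm(centres - cb_b, axis=1) <= shell
    )
    blocked = np.zeros(len(cells), dtype=bool)
    for res in assembly:
        is_end = (res.protein_id, res.residue_index) in ends
        for name, xyz in res.atoms.items():
            hit = np.linalg.norm(centres - xyz, axis=1) <= vdw[name[0]] + probe
            if is_end:
                hit &= ~in_shell
            blocked |= hit
    free = {tuple(c) for c in cells[~blocked]}

    def nearest(cb):
        idx = np.flatnonzero(~blocked)
        d = np.linalg.norm(centres[idx] - cb, axis=1)
        best = idx[np.argmin(d)]
        return tuple(cells[best]), float(d.min())

    start, ds = nearest(cb_a)
    goal, dg = nearest(cb_b)
    dist = {start: 0.0}
    heap = [(0.0, start)]
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    while heap:
        d, cell = heapq.heappop(heap)
        if d > dist.get(cell, np.inf) or d > cutoff:
            continue
        if cell == goal:
            break
        for off in offsets:
            nb = tuple(cell[k] + off[k] for k in range(3))
            if nb not in free:
                continue
            nd = d + spacing * math.sqrt(sum(o * o for o in off))
            if nd < dist.get(nb, np.inf):
                dist[nb] = nd
                heapq.heappush(heap, (nd, nb))
    if goal not in dist or dist[goal] + ds + dg > cutoff:
        return None
    return dist[goal] + ds + dg


class TestSASDistance:
    def test_free_space_matches_straight_line(self):
        asm = assembly_of(
            point_residue("P", 1, [0, 0, 0], [0, 0, 0.1]),
            point_residue("P", 5, [10, 0, 0], [10, 0, 0.1]),
        )
        d = sas_distance(LINK_15, asm, cutoff=20.0)
        assert isinstance(d, float)
        assert d == pytest.approx(10.0, abs=0.8)

    def test_path_never_shorter_than_euclidean(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            pa, pb = rng.uniform(-5, 5, 3), rng.uniform(-5, 5, 3)
            obstacles = [
                point_residue("W", 20 + i, rng.uniform(-6, 6, 3), aa="A")
                for i in range(5)
            ]
            asm = assembly_of(
                point_residue("P", 1, pa, pa + [0, 0, 0.1]),
                point_residue("P", 5, pb, pb + [0, 0, 0.1]),
                *obstacles,
            )
            d = sas_distance(LINK_15, asm, cutoff=30.0)
            if isinstance(d, float):
                straight = np.linalg.norm(
                    asm.get("P", 1).cb() - asm.get("P", 5).cb()
                )
                assert d >= straight - 1e-9

    def test_wall_detour_matches_bruteforce_oracle(self):
        asm = wall_assembly()
        d = sas_distance(LINK_15, asm, cutoff=32.0)
        expected = oracle_sas(asm, LINK_15, cutoff=32.0)
        assert isinstance(d, float) and expected is not None
        assert d == pytest.approx(expected, abs=1e-6)
        # the detour is substantially longer than the straight line
        assert d > 2 * ca_distance(LINK_15, asm)

    def test_tight_cutoff_reports_unreachable(self):
        asm = wall_assembly()
        assert sas_distance(LINK_15, asm, cutoff=14.0) == Unreachable(
            "no_path_within_cutoff"
        )

    def test_refining_grid_never_lengthens_path_by_more_than_one_step(self):
        asm = wall_assembly()
        coarse = sas_distance(LINK_15, asm, SASGridParams(spacing=1.0))
        fine = sas_distance(LINK_15, asm, SASGridParams(spacing=0.5))
        assert isinstance(coarse, float) and isinstance(fine, float)
        assert fine <= coarse + math.sqrt(3) * 1.0

    def test_missing_endpoint(self):
        asm = assembly_of(point_residue("P", 1, [0, 0, 0], [0, 0, 0.1]))
        assert sas_distance(LINK_15, asm) == Unreachable("endpoint_missing")


class TestValidate:
    def test_counts_partition_link_set(self, scaffold, scaffold_links):
        assembly, _, _ = scaffold
        report = validate(scaffold_links, assembly)
        counts = report.counts()
        assert sum(counts.values()) == len(scaffold_links)

    def test_simulated_truth_has_no_incompatible_links(self, scaffold):
        assembly, _, _ = scaffold
        links = simulate_crosslinks(
            assembly, LinkSimSpec(seed=9, detection_probability=1.0)
        )
        report = validate(links, assembly)
        assert report.counts()["incompatible"] == 0

    def test_dropping_a_fragment_creates_implicit_links(self, scaffold, scaffold_links):
        assembly, _, _ = scaffold
        half = AssemblyModel([assembly.fragments[0].copy()])
        report = validate(scaffold_links, half)
        counts = report.counts()
        assert counts["implicit"] > 0
        assert counts["unmeasurable"] > 0
        assert sum(counts.values()) == len(scaffold_links)

    def test_report_statistics_invariant_to_link_order(self, scaffold, scaffold_links, smc_domains):
        assembly, _, domains = scaffold
        links = list(scaffold_links)
        fwd = validate(CrossLinkSet(links), assembly)
        rev = validate(CrossLinkSet(links[::-1]), assembly)
        assert fwd.counts() == rev.counts()
        s1, s2 = fwd.category_stats(domains), rev.category_stats(domains)
        assert s1.keys() == s2.keys()
        for cat in s1:
            assert s1[cat]["mean"] == pytest.approx(s2[cat]["mean"])

    def test_histogram_covers_all_measurable(self, scaffold, scaffold_links):
        assembly, _, _ = scaffold
        report = validate(scaffold_links, assembly)
        counts, edges = report.histogram()
        assert counts.sum() == len(report.measurable_ca())
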