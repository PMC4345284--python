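"""Assembly-level quality checks and a rigid-fragment optimizer.

A disjointed multi-fragment model is acceptable when (a) every gap between
consecutively modelled fragments can be spanned by the residues omitted in
it — the *junction criterion* — (b) fragments do not interpenetrate, and
(c) the cross-link restraints are satisfied.  The junction criterion is
formalized as

    endpoint_distance <= n_omitted × 3.4 Å + 2.0 Å

where 3.4 Å/residue is the extended (β-strand) per-residue span, 1.5
Å/residue the helical reference rate, and the 2 Å allowance is a deliberate
offset acknowledging the limits of rigid-fragment modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from crosscoil.distances import (
    DEFAULT_VDW,
    SASGridParams,
    ValidationReport,
    ValidationThresholds,
    validate,
)
from crosscoil.structure import AssemblyModel, FragmentModel, Junction, junctions
from crosscoil.xlink import CrossLinkSet, DomainTable, classify

__all__ = [
    "JunctionReport",
    "CompatibilitySummary",
    "junction_check",
    "clash_scan",
    "compatibility_report",
    "optimize_assembly",
    "HELIX_RATE",
    "STRAND_RATE",
]

#: Per-residue axial span references (Å/residue).
HELIX_RATE = 1.5
STRAND_RATE = 3.4


@dataclass(frozen=True)
class JunctionReport:
    junction: Junction
    endpoint_distance: float | None  # None when an endpoint lacks a CA
    offset_allowance: float

    @property
    def per_residue(self) -> float | None:
        if self.endpoint_distance is None:
            return None
        return self.endpoint_distance / self.junction.n_omitted

    @property
    def passes(self) -> bool:
        if self.endpoint_distance is None:
            return False
        return (
            self.endpoint_distance
            <= self.junction.n_omitted * STRAND_RATE + self.offset_allowance
        )

    @property
    def unmeasurable(self) -> bool:
        return self.endpoint_distance is None


def junction_check(
    assembly: AssemblyModel, offset_allowance: float = 2.0
) -> list[JunctionReport]:
    """One report per junction; the per-residue metric supports spannable-gap plots."""
    reports = []
    for junc in junctions(assembly):
        a = assembly.get(junc.protein_id, junc.last_modelled)
        b = assembly.get(junc.protein_id, junc.next_modelled)
        if a is None or b is None or "CA" not in a.atoms or "CA" not in b.atoms:
            dist = None
        else:
            dist = float(np.linalg.norm(a.ca - b.ca))
        reports.append(JunctionReport(junc, dist, offset_allowance))
    return reports


def clash_scan(
    assembly: AssemblyModel, overlap_tolerance: float = 0.6
) -> list[tuple[tuple, tuple, float]]:
    """Atom pairs of non-adjacent residues with vdW overlap beyond tolerance.

    A pair clashes when its distance is below vdW_i + vdW_j − tolerance.
    Atoms within one residue, or in sequence-adjacent residues of the same
    protein, are excluded (they are covalently constrained).
    """
    coords, keys = assembly.atom_table()
    if len(coords) == 0:
        return []
    radii = np.array([DEFAULT_VDW.get(k[3], 1.7) for k in keys])
    max_cut = 2.0 * radii.max() - overlap_tolerance
    tree = cKDTree(coords)
    clashes = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        ki, kj = keys[i], keys[j]
        if ki[0] == kj[0] and abs(ki[1] - kj[1]) <= 1:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < radii[i] + radii[j] - overlap_tolerance:
            clashes.append((ki[:3], kj[:3], d))
    return clashes


@dataclass
class CompatibilitySummary:
    """Category-resolved accounting of how a model fits its link set.

    ``explicit`` counts accommodated links per category; ``implicit`` are
    links that cannot be contradicted by the model (exactly one endpoint
    modelled, or neither modelled with a small sequence separation);
    ``incorporated`` is the complement of the incompatible links
    (total − incompatible), the most inclusive compatibility figure.
    """

    explicit: dict[str, int]
    implicit: int
    incompatible: int
    unplaced: int  # both endpoints missing and far apart in sequence
    total: int
    stats: dict[str, dict[str, float]]
    histogram: tuple[np.ndarray, np.ndarray]
    report: ValidationReport = field(repr=False)

    @property
    def explicit_total(self) -> int:
        return sum(self.explicit.values())

    @property
    def incorporated(self) -> int:
        return self.total - self.incompatible


def compatibility_report(
    links: CrossLinkSet,
    assembly: AssemblyModel,
    domains: DomainTable,
    thresholds: ValidationThresholds = ValidationThresholds(),
    mode: str = "ca_only",
    grid: SASGridParams = SASGridParams(),
    implicit_max_gap: int = 5,
) -> CompatibilitySummary:
    """Validate the links and aggregate the accounting per category."""
    report = validate(links, assembly, thresholds, mode, grid)
    explicit: dict[str, int] = {}
    implicit = incompatible = unplaced = 0
    for res in report.results:
        if res.status == "accommodated":
            cat = classify(res.link, domains).category
            explicit[cat] = explicit.get(cat, 0) + 1
        elif res.status == "implicit":
            implicit += 1
        elif res.status == "incompatible":
            incompatible += 1
        else:
            if res.sequence_gap is not None and res.sequence_gap <= implicit_max_gap:
                implicit += 1
            else:
                unplaced += 1
    return CompatibilitySummary(
        explicit=explicit,
        implicit=implicit,
        incompatible=incompatible,
        unplaced=unplaced,
        total=len(report.results),
        stats=report.category_stats(domains),
        histogram=report.histogram(),
        report=report,
    )


# ---------------------------------------------------------------------------
# Rigid-fragment optimizer

def _random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _objective(
    assembly: AssemblyModel,
    links: CrossLinkSet,
    thresholds: ValidationThresholds,
    offset_allowance: float,
    clash_cutoff: float = 3.0,
    w_link: float = 10.0,
    w_junction: float = 5.0,
    w_clash: float = 1.0,
) -> float:
    broken = 0
    soft = 0.0
    for link in links:
        ra = assembly.get(link.a.protein_id, link.a.residue_index)
        rb = assembly.get(link.b.protein_id, link.b.residue_index)
        if ra is None or rb is None:
            continue
        d = float(np.linalg.norm(ra.ca - rb.ca))
        if d > thresholds.ca_max:
            broken += 1
            soft += (d - thresholds.ca_max) / thresholds.ca_max
    junction_viol = 0
    junction_soft = 0.0
    for rep in junction_check(assembly, offset_allowance):
        if not rep.passes:
            junction_viol += 1
            if rep.endpoint_distance is not None:
                limit = rep.junction.n_omitted * STRAND_RATE + offset_allowance
                junction_soft += (rep.endpoint_distance - limit) / limit
    # CA-level steric proxy: inter-fragment CA pairs closer than the cutoff
    clash_count = 0
    arrays = [f.ca_array() for f in assembly.fragments]
    trees = [cKDTree(a) for a in arrays]
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            clash_count += int(
                trees[i].count_neighbors(trees[j], clash_cutoff)
            )
    return (
        w_link * (broken + soft)
        + w_junction * (junction_viol + junction_soft)
        + w_clash * clash_count
    )


def optimize_assembly(
    fragments: list[FragmentModel],
    links: CrossLinkSet,
    thresholds: ValidationThresholds = ValidationThresholds(),
    seed: int = 0,
    n_iter: int = 4000,
    max_translation: float = 2.0,
    max_rotation_deg: float = 5.0,
    t_start: float = 3.0,
    t_end: float = 0.01,
    offset_allowance: float = 2.0,
) -> tuple[AssemblyModel, dict]:
    """Seeded simulated annealing over rigid-body fragment poses.

    The objective counts broken links (with a soft distance excess term),
    junction violations and inter-fragment Cα contacts; moves are small
    random rotations about a fragment's centroid plus translations.  Atoms
    never move within a fragment.  Deterministic for a fixed seed.  Returns
    the best assembly found and diagnostics including the best-objective
    trace (non-increasing by construction).
    """
    rng = np.random.default_rng(seed)
    current = AssemblyModel([f.copy() for f in fragments])
    obj = _objective(current, links, thresholds, offset_allowance)
    best = current.copy()
    best_obj = obj
    trace = [best_obj]
    if obj == 0.0:  # already feasible: leave the poses untouched
        return best, {"objective": 0.0, "trace": trace, "iterations": 0}
    max_rot = math.radians(max_rotation_deg)
    cooling = (t_end / t_start) ** (1.0 / max(n_iter - 1, 1))
    temp = t_start
    for _ in range(n_iter):
        k = int(rng.integers(len(current.fragments)))
        frag = current.fragments[k]
        saved = {
            key: {n: xyz.copy() for n, xyz in r.atoms.items()}
            for key, r in frag.residues.items()
        }
        centroid = frag.ca_array().mean(axis=0)
        rot = _random_rotation(rng, max_rot)
        trans = rng.uniform(-max_translation, max_translation, size=3)
        frag.transform(np.eye(3), -centroid)
        frag.transform(rot, centroid + trans)
        current.reindex()
        new_obj = _objective(current, links, thresholds, offset_allowance)
        delta = new_obj - obj
        if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-9)):
            obj = new_obj
            if obj < best_obj:
                best_obj = obj
                best = current.copy()
        else:
            for key, atoms in saved.items():
                frag.residues[key].atoms = atoms
            current.reindex()
        trace.append(best_obj)
        temp *= cooling
        if best_obj == 0.0:
            break
    return best, {"objective": best_obj, "trace": trace, "iterations": len(trace) - 1}
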