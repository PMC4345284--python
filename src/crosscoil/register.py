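"""Cross-link-constrained register inference for anti-parallel helix pairs.

Because sliding one helix of a coiled-coil by a whole heptad often yields a
comparably stable structure, the axial register of a heterodimeric coil is
ambiguous from sequence alone.  Cross-links break the ambiguity: a set of
lysine–lysine restraints is scored against pair models built at candidate
registers, and the register satisfying the most restraints wins.  The
companion shift-sensitivity test quantifies how diagnostic a link set is: a
one-heptad shift (7 residues ≈ 10.5 Å) typically breaks few links, whereas
a two-heptad shift (≈ 21 Å) breaks most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from crosscoil.coilgen import CANONICAL, CrickParams, build_antiparallel_pair
from crosscoil.distances import ca_distance
from crosscoil.structure import AssemblyModel, FragmentModel
from crosscoil.xlink import CrossLink, CrossLinkSet

__all__ = [
    "RegisterProfile",
    "ShiftSensitivity",
    "score_register",
    "scan_registers",
    "shift_sensitivity",
    "DEFAULT_OFFSETS",
]

#: Heptad-preserving candidate registers.
DEFAULT_OFFSETS = (-21, -14, -7, 0, 7, 14, 21)


@dataclass(frozen=True)
class RegisterProfile:
    offsets: tuple[int, ...]
    satisfied: tuple[int, ...]
    best_offset: int
    ties: tuple[int, ...]


@dataclass(frozen=True)
class ShiftSensitivity:
    shift: int
    previously_satisfied: int
    broken: int

    @property
    def fraction_broken(self) -> float:
        if self.previously_satisfied == 0:
            return 0.0
        return self.broken / self.previously_satisfied


def _pair_assembly(
    seq_a: str,
    seq_b: str,
    params: CrickParams,
    offset: int,
    protein_a: str,
    protein_b: str,
    start_a: int,
    start_b: int,
) -> AssemblyModel:
    frag = build_antiparallel_pair(
        seq_a, seq_b, params, register_offset=offset,
        protein_a=protein_a, protein_b=protein_b,
        start_a=start_a, start_b=start_b,
    )
    return AssemblyModel([frag])


def score_register(
    links: CrossLinkSet,
    seq_a: str,
    seq_b: str,
    params: CrickParams = CANONICAL,
    offset: int = 0,
    threshold: float = 30.0,
    protein_a: str = "A",
    protein_b: str = "B",
    start_a: int = 1,
    start_b: int = 1,
) -> int:
    """Links with Cα–Cα ≤ threshold on the pair built at ``offset``."""
    assembly = _pair_assembly(
        seq_a, seq_b, params, offset, protein_a, protein_b, start_a, start_b
    )
    satisfied = 0
    for link in links:
        d = ca_distance(link, assembly)
        if isinstance(d, float) and d <= threshold:
            satisfied += 1
    return satisfied


def scan_registers(
    links: CrossLinkSet,
    seq_a: str,
    seq_b: str,
    params: CrickParams = CANONICAL,
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
    threshold: float = 30.0,
    protein_a: str = "A",
    protein_b: str = "B",
    start_a: int = 1,
    start_b: int = 1,
) -> RegisterProfile:
    """Score every candidate register and pick the best.

    Ties are broken toward the smaller absolute offset, then toward the
    negative one.  With no measurable link the register is unidentifiable
    and an error is raised.
    """
    if len(links) == 0:
        raise ValueError("register is unidentifiable without measurable links")
    scores = tuple(
        score_register(
            links, seq_a, seq_b, params, off, threshold,
            protein_a, protein_b, start_a, start_b,
        )
        for off in offsets
    )
    best_score = max(scores)
    ties = tuple(o for o, s in zip(offsets, scores) if s == best_score)
    best = min(ties, key=lambda o: (abs(o), o))
    return RegisterProfile(tuple(offsets), scores, best, ties)


def _fragment_axis(fragment: FragmentModel) -> np.ndarray:
    ca = fragment.ca_array()
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[0]


def _signed_axis(fragment: FragmentModel) -> np.ndarray:
    """Principal axis oriented N→C along the fragment's first segment."""
    axis = _fragment_axis(fragment)
    pid, start, end, _ = fragment.segments[0]
    direction = fragment.residues[(pid, end)].ca - fragment.residues[(pid, start)].ca
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis


def _shift_groups(assembly: AssemblyModel, pair_max: float = 15.0):
    """Identify the strand to translate for every coiled-coil unit.

    Fragments that carry both strands (two covered segments) shift their
    second segment.  Single-segment fragments — typical after a PDB
    round-trip, where every strand becomes its own chain — are paired
    geometrically with the nearest anti-parallel fragment, and the partner
    is shifted whole.  Yields (residues_to_shift, group_ca_array) tuples.
    """
    singles = []
    for fragment in assembly.fragments:
        if len(fragment.segments) >= 2:
            pid, start, end, _ = fragment.segments[1]
            residues = [fragment.residues[(pid, i)] for i in range(start, end + 1)]
            yield residues, fragment.ca_array()
        elif fragment.segments:
            singles.append(fragment)
        else:
            warnings.warn(
                f"fragment {fragment.fragment_id} declares no segments; skipped",
                stacklevel=3,
            )
    paired: set[str] = set()
    info = [(f, _signed_axis(f), f.ca_array().mean(axis=0)) for f in singles]
    for i, (fa, axis_a, cen_a) in enumerate(info):
        if fa.fragment_id in paired:
            continue
        best = None
        for fb, axis_b, cen_b in info[i + 1:]:
            if fb.fragment_id in paired or np.dot(axis_a, axis_b) > -0.5:
                continue
            gap = float(np.linalg.norm(cen_b - cen_a))
            if gap < pair_max and (best is None or gap < best[1]):
                best = (fb, gap)
        if best is None:
            warnings.warn(
                f"fragment {fa.fragment_id} has no anti-parallel partner "
                "strand; skipped",
                stacklevel=3,
            )
            continue
        fb = best[0]
        paired.update((fa.fragment_id, fb.fragment_id))
        yield list(fb.residues.values()), np.vstack([fa.ca_array(), fb.ca_array()])


def shift_sensitivity(
    assembly: AssemblyModel,
    links: CrossLinkSet,
    shift: int,
    rise: float = 1.5,
    threshold: float = 30.0,
) -> ShiftSensitivity:
    """Fraction of satisfied links broken by an axial register shift.

    For every coiled-coil unit, one anti-parallel strand is rigidly
    translated by ``shift × rise`` along the unit's principal axis; links
    already over threshold before the shift are excluded from the
    denominator.  Strands without an anti-parallel partner are skipped with
    a warning.
    """
    before: dict[tuple, float] = {}
    for link in links:
        d = ca_distance(link, assembly)
        if isinstance(d, float) and d <= threshold:
            before[link.key] = d
    shifted = assembly.copy()
    any_shifted = False
    for residues, group_ca in _shift_groups(shifted):
        centred = group_ca - group_ca.mean(axis=0)
        axis = np.linalg.svd(centred)[2][0]
        delta = axis * shift * rise
        for res in residues:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + delta
        any_shifted = True
    if not any_shifted and shift != 0:
        warnings.warn("no fragment was shifted", stacklevel=2)
    shifted.reindex()

    broken = 0
    for link in links:
        if link.key not in before:
            continue
        d = ca_distance(link, shifted)
        if not (isinstance(d, float) and d <= threshold):
            broken += 1
    return ShiftSensitivity(shift, len(before), broken)
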