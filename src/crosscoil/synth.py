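"""Synthetic ground truths for every pipeline stage.

The generator emulates the geometry the pipeline is built for: two SMC-like
proteins, each folded back into an intramolecular anti-parallel coiled-coil
(segments d2 and d4 joined by an unmodelled linker), the two coils lying
side by side in a rod.  Lysines are placed at outward-facing heptad
positions (b, c, e, f, g) only — buried a/d residues cannot react with an
amine-reactive cross-linker.  Simulated link sets apply a detection
probability to every lysine pair within a Cα–Cα capture radius (default
27.4 Å, the empirical BS3 reach) and optionally add uniform false positives
from the non-reachable pairs.

All generators are pure functions of (spec, seed): the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from crosscoil.breakpoints import MSA, BreakpointParams, SSPredictionSet
from crosscoil.coilgen import CANONICAL, CrickParams, build_antiparallel_pair, heptad_assign
from crosscoil.structure import AssemblyModel
from crosscoil.xlink import (
    CrossLink,
    CrossLinkSet,
    DomainTable,
    ProteinDef,
    ProteinRegistry,
    ResidueLocus,
)

__all__ = [
    "ScaffoldSpec",
    "LinkSimSpec",
    "make_dimer_scaffold",
    "simulate_crosslinks",
    "make_register_task",
    "make_breakpoint_task",
]

#: Outward-facing heptad positions where lysines may sit.
SURFACE_POSITIONS = frozenset("bcefg")

# polar surface alphabet (no Ala/Gly/Pro: Ala would fake hydrophobic
# stretches, Gly/Pro are parsing residues reserved for injected disruptions)
_SURFACE_ALPHABET = "EQSRN"


@dataclass(frozen=True)
class ScaffoldSpec:
    """Geometry and sequence rules for the two-coil rod scaffold."""

    coil_length: int = 70  # residues per strand (10 heptads)
    linker_length: int = 5  # unmodelled residues between d2 and d4
    spacing: float = 15.0  # centre-to-centre distance of the two coils, Å
    lysine_density: float = 0.25  # fraction of surface positions carrying K
    params: CrickParams = CANONICAL
    protein_ids: tuple[str, str] = ("SMCA", "SMCB")
    seed: int = 0

    def __post_init__(self):
        if self.coil_length < 14:
            raise ValueError("coil length must be at least two heptads")
        min_spacing = 2.0 * (self.params.superhelix_radius + self.params.helix_radius)
        if self.spacing <= min_spacing:
            raise ValueError(
                f"spacing {self.spacing} Å guarantees clashes; needs > "
                f"{min_spacing:.1f} Å for these Crick parameters"
            )


@dataclass(frozen=True)
class LinkSimSpec:
    """Noise model for simulated BS3 cross-link capture."""

    capture_radius: float = 27.4  # Cα–Cα, Å
    detection_probability: float = 0.8
    false_positive_rate: float = 0.0  # per non-reachable lysine pair
    seed: int = 0

    def __post_init__(self):
        if self.capture_radius < 0:
            raise ValueError("capture radius must be >= 0")
        if not 0 <= self.detection_probability <= 1:
            raise ValueError("detection probability must be in [0, 1]")
        if not 0 <= self.false_positive_rate <= 1:
            raise ValueError("false positive rate must be in [0, 1]")


def _coil_sequence(length: int, density: float, rng: np.random.Generator,
                   params: CrickParams) -> str:
    out = []
    for i in range(1, length + 1):
        letter = heptad_assign(i, params)
        if letter in "ad":
            out.append("L")
        elif rng.random() < density:
            out.append("K")
        else:
            out.append(_SURFACE_ALPHABET[rng.integers(len(_SURFACE_ALPHABET))])
    return "".join(out)


def make_dimer_scaffold(
    spec: ScaffoldSpec = ScaffoldSpec(),
) -> tuple[AssemblyModel, ProteinRegistry, DomainTable]:
    """Two side-by-side anti-parallel coiled-coils with surface lysines.

    Each protein contributes both strands of its own coil: residues
    1..L run N→C up (segment d2), a linker of unmodelled glycines follows,
    and the return strand (segment d4) runs back down.  The second coil is
    the same construction translated sideways by ``spacing``.
    """
    rng = np.random.default_rng(spec.seed)
    L, linker = spec.coil_length, spec.linker_length
    registry = ProteinRegistry()
    domains = DomainTable()
    fragments = []
    for k, pid in enumerate(spec.protein_ids):
        seq_up = _coil_sequence(L, spec.lysine_density, rng, spec.params)
        seq_down = _coil_sequence(L, spec.lysine_density, rng, spec.params)
        start_down = L + linker + 1
        frag = build_antiparallel_pair(
            seq_up,
            seq_down,
            spec.params,
            register_offset=0,
            protein_a=pid,
            protein_b=pid,
            start_a=1,
            start_b=start_down,
            fragment_id=f"coil_{pid}",
        )
        if k == 1:
            for res in frag.residues.values():
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + np.array([spec.spacing, 0.0, 0.0])
        fragments.append(frag)
        registry.add(ProteinDef(pid, seq_up + "G" * linker + seq_down))
        domains.add(pid, "d2", 1, L, "coil")
        domains.add(pid, "d4", start_down, start_down + L - 1, "coil")
    return AssemblyModel(fragments), registry, domains


def _lysine_loci(assembly: AssemblyModel) -> list:
    return [res for res in assembly if res.amino_acid == "K"]


def simulate_crosslinks(
    assembly: AssemblyModel, spec: LinkSimSpec = LinkSimSpec()
) -> CrossLinkSet:
    """Noisy capture of lysine pairs on a truth structure.

    Every lysine pair with Cα–Cα ≤ capture radius is emitted with the
    detection probability; pairs beyond the radius are emitted at the false
    positive rate.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    lys = sorted(_lysine_loci(assembly), key=lambda r: (r.protein_id, r.residue_index))
    links = CrossLinkSet()
    for i in range(len(lys)):
        for j in range(i + 1, len(lys)):
            a, b = lys[i], lys[j]
            d = float(np.linalg.norm(a.ca - b.ca))
            reachable = d <= spec.capture_radius
            p = spec.detection_probability if reachable else spec.false_positive_rate
            if p > 0 and rng.random() < p:
                links.add(
                    CrossLink(
                        ResidueLocus(a.protein_id, a.residue_index, "K"),
                        ResidueLocus(b.protein_id, b.residue_index, "K"),
                        confidence="high",
                        source_label="simulated" if reachable else "simulated_fp",
                    )
                )
    return links


def make_register_task(
    true_offset: int,
    n_links: int,
    seed: int,
    spec: ScaffoldSpec = ScaffoldSpec(),
    capture_radius: float = 27.4,
) -> tuple[str, str, CrossLinkSet, int]:
    """A register-recovery problem: sequences, links simulated at the truth.

    Builds one anti-parallel pair between two proteins at ``true_offset``
    and samples ``n_links`` inter-strand lysine pairs within the capture
    radius.
    """
    if abs(true_offset) > 21:
        raise ValueError("true offset must be within ±21 residues")
    rng = np.random.default_rng(seed)
    L = spec.coil_length
    seq_a = _coil_sequence(L, spec.lysine_density, rng, spec.params)
    seq_b = _coil_sequence(L, spec.lysine_density, rng, spec.params)
    frag = build_antiparallel_pair(
        seq_a, seq_b, spec.params, register_offset=true_offset,
        protein_a="A", protein_b="B",
    )
    assembly = AssemblyModel([frag])
    lys = sorted(_lysine_loci(assembly), key=lambda r: (r.protein_id, r.residue_index))
    eligible = []
    for a in lys:
        for b in lys:
            if a.protein_id == "A" and b.protein_id == "B":
                d = float(np.linalg.norm(a.ca - b.ca))
                if d <= capture_radius:
                    eligible.append((a, b))
    if not eligible:
        return seq_a, seq_b, CrossLinkSet(), true_offset
    chosen = rng.choice(len(eligible), size=min(n_links, len(eligible)), replace=False)
    links = CrossLinkSet()
    for idx in sorted(chosen):
        a, b = eligible[idx]
        links.add(
            CrossLink(
                ResidueLocus("A", a.residue_index, "K"),
                ResidueLocus("B", b.residue_index, "K"),
                source_label="simulated",
            )
        )
    return seq_a, seq_b, links, true_offset


@dataclass(frozen=True)
class DisruptionSpec:
    start: int  # 1-based reference residue where the disruption begins
    length: int = 5
    kind: str = "gp_insert"  # gp_insert | polar_run


def make_breakpoint_task(
    n_homologs: int = 8,
    identity: float = 0.8,
    disruptions: tuple[DisruptionSpec, ...] = (),
    seed: int = 0,
    length: int = 105,
    ss_methods: int = 4,
    ss_error: float = 0.05,
) -> tuple[MSA, SSPredictionSet, list[tuple[int, int]]]:
    """A break-point calling problem with known truth intervals.

    The reference is an ideal heptad repeat (Leu at a/d, polar surface);
    disruptions substitute windows with Gly/Pro parsing runs or polar runs.
    Homologues are seeded point substitutions of the reference that
    preserve residue class (so columns keep their polar/hydrophobic
    character); disruption windows are conserved across homologues.
    Secondary-structure tracks predict H with a small per-residue error and
    C across disruptions.
    """
    if not 0.3 < identity <= 1:
        raise ValueError("identity must be in (0.3, 1]")
    rng = np.random.default_rng(seed)
    params = BreakpointParams()

    ref = list(_coil_sequence(length, 0.2, rng, CANONICAL))
    truth: list[tuple[int, int]] = []
    for dis in disruptions:
        lo = dis.start - 1
        hi = min(lo + dis.length, length)
        if dis.kind == "gp_insert":
            for k in range(lo, hi):
                ref[k] = "GP"[(k - lo) % 2]
        elif dis.kind == "polar_run":
            for k in range(lo, hi):
                ref[k] = "DEKRN"[(k - lo) % 5]
        else:
            raise ValueError(f"unknown disruption kind {dis.kind!r}")
        truth.append((lo + 1, hi))
    ref_seq = "".join(ref)

    protected = np.zeros(length, dtype=bool)
    for lo, hi in truth:
        protected[lo - 1 : hi] = True

    hydro = sorted(params.hydrophobic_set - {"A", "C"})
    polar = sorted(params.polar_set)
    rows = {"ref": ref_seq}
    for h in range(n_homologs - 1):
        seq = list(ref_seq)
        for k in range(length):
            if protected[k] or rng.random() < identity:
                continue
            pool = hydro if ref_seq[k] in params.hydrophobic_set else polar
            seq[k] = pool[rng.integers(len(pool))]
        rows[f"hom{h}"] = "".join(seq)

    tracks = {}
    for m in range(ss_methods):
        track = []
        for k in range(length):
            if protected[k]:
                track.append("C")
            else:
                track.append("C" if rng.random() < ss_error else "H")
        tracks[f"method{m}"] = "".join(track)

    return MSA(rows, "ref"), SSPredictionSet(tracks), truth
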