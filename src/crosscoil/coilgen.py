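"""Parametric ideal α-helices and two-stranded anti-parallel coiled-coils.

A coiled-coil is described in Crick's parameterization: each α-helix (the
*minor* helix, radius ``r1``) is wound left-handed about a common
superhelical axis at radius ``r0`` with pitch ``P``.  The canonical coil
has a 3.5-residue periodicity in the supercoiling frame (exactly two minor
turns per 7-residue heptad), an axial rise of 1.5 Å per residue, ``r0`` ≈
5.0 Å and ``P`` ≈ 140 Å.  Hydrophobic residues at heptad positions a and d
form the buried interface; here the a/d face is oriented toward the
superhelical axis.

The module generates Cα traces from the Crick equations and completes the
backbone (N, C, O and Cβ) with constant offsets expressed in an intrinsic
per-residue frame, calibrated once from an ideal straight α-helix built
with standard internal coordinates (φ = −57°, ψ = −47°, ω = 180°).

``measure`` inverts the construction: it recovers rise, superhelical pitch,
radius and heptad axial span from coordinates alone, exploiting the exact
cancellation of the minor helix under a 7-residue moving average (the minor
phase advances 4π per heptad, so seven consecutive Cα positions average
onto the local helix axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from crosscoil.structure import FragmentModel, ResidueCoords, virtual_cb

__all__ = [
    "CrickParams",
    "GeometryMeasurement",
    "CANONICAL",
    "BECLIN_LIKE",
    "build_helix",
    "build_antiparallel_pair",
    "measure",
    "heptad_assign",
]

HEPTAD_LETTERS = "abcdefg"

#: Minor-helix angular step per residue in the rotating superhelix frame:
#: exactly two turns per heptad (3.5-residue periodicity).
OMEGA1 = 2.0 * math.pi * 2.0 / 7.0

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class CrickParams:
    """Geometry of an ideal (coiled-coil) helix.

    superhelix_radius
        r0 in Å; 0 gives a straight helix.
    superhelix_pitch
        P in Å, the axial distance over which a strand completes one full
        left-handed turn about the common axis.
    helix_radius
        r1, the minor α-helix radius in Å.
    rise_per_residue
        Axial translation per residue in Å.
    periodicity
        Residues per minor-helix turn relative to the supercoiling frame;
        3.5 for the canonical heptad.
    heptad_phase
        Heptad letter of residue 1.
    """

    superhelix_radius: float = 5.0
    superhelix_pitch: float = 140.0
    helix_radius: float = 2.26
    rise_per_residue: float = 1.5
    periodicity: float = 3.5
    heptad_phase: str = "a"
    orientation: str = "antiparallel"
    handedness: str = "left"

    def __post_init__(self):
        if self.superhelix_radius < 0:
            raise ValueError("superhelix radius must be >= 0")
        if self.superhelix_pitch <= 0:
            raise ValueError("superhelix pitch must be > 0")
        if self.rise_per_residue <= 0:
            raise ValueError("rise per residue must be > 0")
        if self.heptad_phase not in HEPTAD_LETTERS:
            raise ValueError(f"heptad phase must be one of {HEPTAD_LETTERS!r}")
        if self.handedness != "left":
            raise ValueError("only left-handed supercoils are supported")

    @property
    def omega0(self) -> float:
        """Superhelix phase step per residue (negative: left-handed)."""
        if self.superhelix_radius == 0.0:
            return 0.0
        return -2.0 * math.pi * self.rise_per_residue / self.superhelix_pitch

    @property
    def omega1(self) -> float:
        """Minor-helix phase step per residue in the rotating frame."""
        return 2.0 * math.pi / self.periodicity

    @property
    def pitch_angle(self) -> float:
        """Signed tilt of the minor-helix axis against the superhelix axis."""
        if self.superhelix_radius == 0.0:
            return 0.0
        return -math.atan2(
            2.0 * math.pi * self.superhelix_radius, self.superhelix_pitch
        )


#: Canonical two-stranded coiled-coil geometry.
CANONICAL = CrickParams()

#: Alternative preset mimicking the long anti-parallel coiled-coil of
#: Beclin-1 (13 heptads, ~127 Å pitch) used as a comparison geometry.
BECLIN_LIKE = replace(CANONICAL, superhelix_pitch=127.0)


@dataclass(frozen=True)
class GeometryMeasurement:
    rise_per_residue: float
    superhelix_pitch: float  # math.inf for a straight helix
    superhelix_radius: float
    heptad_axial_span: float


def heptad_assign(residue_index: int, params: CrickParams) -> str:
    """Heptad letter (a–g) of a 1-based residue index."""
    phase0 = HEPTAD_LETTERS.index(params.heptad_phase)
    return HEPTAD_LETTERS[(phase0 + residue_index - 1) % 7]


# ---------------------------------------------------------------------------
# Ideal straight-helix calibration (NeRF construction)

_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
_ANG_CA_C_O = 120.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d from three predecessors by internal coordinates."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _ideal_straight_helix(n_res: int) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O backbone of an ideal α-helix via sequential NeRF."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANG_CA_C_N, _PSI)
        ca = _nerf(prev["CA"], prev["C"], n, _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        c = _nerf(prev["C"], n, ca, _BOND_CA_C, _ANG_N_CA_C, _PHI)
        res.append({"N": n, "CA": ca, "C": c})
    for i in range(n_res - 1):
        # carbonyl O anti to the next amide N
        res[i]["O"] = _nerf(
            res[i + 1]["N"], res[i]["CA"], res[i]["C"], _BOND_C_O, _ANG_CA_C_O, 180.0
        )
    res[-1]["O"] = _nerf(res[-2]["N"], res[-1]["CA"], res[-1]["C"], _BOND_C_O, _ANG_CA_C_O, 180.0)
    return res


def _intrinsic_frame(ca_prev: np.ndarray, ca: np.ndarray, ca_next: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (rows) from three consecutive Cα."""
    e1 = ca_next - ca_prev
    e1 = e1 / np.linalg.norm(e1)
    v = 0.5 * (ca_prev + ca_next) - ca
    v = v - np.dot(v, e1) * e1
    e2 = v / np.linalg.norm(v)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3])


def _backbone_offsets() -> dict[str, np.ndarray]:
    """Constant N/C/O offsets from Cα in the intrinsic frame."""
    helix = _ideal_straight_helix(9)
    i = 4
    frame = _intrinsic_frame(helix[i - 1]["CA"], helix[i]["CA"], helix[i + 1]["CA"])
    return {
        name: frame @ (helix[i][name] - helix[i]["CA"]) for name in ("N", "C", "O")
    }


_OFFSETS = _backbone_offsets()


# ---------------------------------------------------------------------------
# Crick CA traces

def _ca_trace(
    params: CrickParams,
    axial_params: np.ndarray,
    minor_phases: np.ndarray,
    phi0: float,
) -> np.ndarray:
    """Cα positions from the Crick equations.

    ``axial_params`` s gives the axial progression in residue units (z ≈
    s·rise); ``minor_phases`` the per-residue minor-helix phase measured
    from the outward radial direction.
    """
    r0, r1 = params.superhelix_radius, params.helix_radius
    h = params.rise_per_residue
    w0 = params.omega0
    alpha = params.pitch_angle
    phi_c = phi0 + w0 * axial_params
    cosc, sinc_ = np.cos(phi_c), np.sin(phi_c)
    cosh_, sinh_ = np.cos(minor_phases), np.sin(minor_phases)
    x = r0 * cosc + r1 * (cosc * cosh_ - math.cos(alpha) * sinc_ * sinh_)
    y = r0 * sinc_ + r1 * (sinc_ * cosh_ + math.cos(alpha) * cosc * sinh_)
    z = h * axial_params - r1 * math.sin(alpha) * sinh_
    return np.stack([x, y, z], axis=1)


def _phase_of_first_residue(params: CrickParams, down: bool) -> float:
    """Minor phase of residue 1 putting the a/d midpoint on the inward face."""
    p0 = HEPTAD_LETTERS.index(params.heptad_phase)
    w1 = params.omega1
    if not down:
        # phases of a and d are phi_a and phi_a - 2*pi/7; midpoint at pi
        phi_a = math.pi + math.pi / 7.0
        return phi_a + p0 * w1
    phi_a = math.pi - math.pi / 7.0
    return phi_a - p0 * w1


def _build_strand(
    sequence: str,
    params: CrickParams,
    protein_id: str,
    start_index: int,
    phi0: float,
    axial_offset: float,
    down: bool,
) -> dict[tuple[str, int], ResidueCoords]:
    """Place one strand; ``down`` strands run N→C toward −z."""
    sequence = sequence.upper()
    bad = set(sequence) - _VALID_AA
    if bad:
        raise ValueError(f"not amino-acid letters: {sorted(bad)}")
    n = len(sequence)
    t = np.arange(-1, n + 1, dtype=float)  # phantom neighbours for frames
    if down:
        s = (n - 1) - t + axial_offset
        phases = _phase_of_first_residue(params, down=True) - params.omega1 * t
    else:
        s = t + axial_offset
        phases = _phase_of_first_residue(params, down=False) + params.omega1 * t
    ca = _ca_trace(params, s, phases, phi0)

    residues: dict[tuple[str, int], ResidueCoords] = {}
    for i in range(n):
        j = i + 1  # index into ca (phantom at 0)
        frame = _intrinsic_frame(ca[j - 1], ca[j], ca[j + 1])
        atoms = {"CA": ca[j]}
        for name, off in _OFFSETS.items():
            atoms[name] = ca[j] + frame.T @ off
        aa = sequence[i]
        if aa != "G":
            atoms["CB"] = virtual_cb(atoms["N"], atoms["CA"], atoms["C"])
        residues[(protein_id, start_index + i)] = ResidueCoords(
            protein_id, start_index + i, aa, atoms
        )
    return residues


def build_helix(
    sequence: str,
    params: CrickParams = CANONICAL,
    start_index: int = 1,
    protein_id: str = "A",
    fragment_id: str | None = None,
) -> FragmentModel:
    """Build a single ideal helix (supercoiled when r0 > 0).

    Consecutive Cα–Cα distances come out at ≈ 3.8 Å.  Glycine residues are
    emitted without a Cβ; :meth:`ResidueCoords.cb` supplies a virtual one
    on demand.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    residues = _build_strand(
        sequence, params, protein_id, start_index, phi0=0.0, axial_offset=0.0, down=False
    )
    end = start_index + len(sequence) - 1
    return FragmentModel(
        fragment_id or f"{protein_id}_{start_index}",
        [(protein_id, start_index, end, "+")],
        residues,
    )


def build_antiparallel_pair(
    seq_a: str,
    seq_b: str,
    params: CrickParams = CANONICAL,
    register_offset: int = 0,
    protein_a: str = "A",
    protein_b: str = "B",
    start_a: int = 1,
    start_b: int = 1,
    fragment_id: str = "pair",
) -> FragmentModel:
    """Two helices wound left-handed about a common axis, anti-parallel.

    Strand A runs N→C along +z at superhelix phase 0; strand B runs N→C
    along −z on the opposite side of the axis.  ``register_offset`` shifts
    strand B axially by ``offset × rise_per_residue`` (positive toward
    strand A's C-terminus); one heptad (offset 7) is ≈ 10.5 Å.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    if abs(register_offset) >= min(len(seq_a), len(seq_b)):
        raise ValueError("register offset larger than the shorter strand")
    res_a = _build_strand(
        seq_a, params, protein_a, start_a, phi0=0.0, axial_offset=0.0, down=False
    )
    res_b = _build_strand(
        seq_b, params, protein_b, start_b, phi0=math.pi,
        axial_offset=float(register_offset), down=True,
    )
    residues = dict(res_a)
    for key, val in res_b.items():
        if key in residues:
            raise ValueError(f"strands overlap at {key}")
        residues[key] = val
    segments = [
        (protein_a, start_a, start_a + len(seq_a) - 1, "+"),
        (protein_b, start_b, start_b + len(seq_b) - 1, "-"),
    ]
    return FragmentModel(fragment_id, segments, residues)


# ---------------------------------------------------------------------------
# Geometry measurement

def _strand_traces(fragment: FragmentModel) -> list[np.ndarray]:
    traces = []
    for pid, start, end, _ in fragment.segments:
        traces.append(
            np.array([fragment.residues[(pid, i)].ca for i in range(start, end + 1)])
        )
    return traces


def _heptad_centres(trace: np.ndarray) -> np.ndarray:
    """7-residue moving average of a Cα trace: the local minor-helix axis."""
    kernel = np.full(7, 1.0 / 7.0)
    return np.stack(
        [np.convolve(trace[:, k], kernel, mode="valid") for k in range(3)], axis=1
    )


def measure(fragment: FragmentModel) -> GeometryMeasurement:
    """Recover rise, pitch, radius and heptad span from coordinates.

    The superhelical axis is the principal axis of the minor-helix centres
    (7-residue moving averages of each strand's Cα trace).  Rise is the
    absolute slope of a per-strand linear fit of axial coordinate against
    residue index; pitch comes from the angular progression of the centres
    about the axis; radius is the mean centre–axis distance with a
    first-order correction for the smoothing of superhelical curvature by
    the moving average.  A straight helix (radius ≈ 0) reports infinite
    pitch.
    """
    traces = _strand_traces(fragment)
    for tr in traces:
        if len(tr) < 14:
            raise ValueError("measure needs >= 2 full heptads per strand")
    centres = [_heptad_centres(tr) for tr in traces]
    all_centres = np.concatenate(centres)
    mean = all_centres.mean(axis=0)
    _, _, vt = np.linalg.svd(all_centres - mean)
    axis = vt[0]

    rises, spans = [], []
    for tr in traces:
        z = (tr - mean) @ axis
        idx = np.arange(len(z))
        rises.append(abs(np.polyfit(idx, z, 1)[0]))
        spans.append(np.mean(np.abs(z[7:] - z[:-7])))
    rise = float(np.mean(rises))
    span = float(np.mean(spans))

    radial = all_centres - mean - np.outer((all_centres - mean) @ axis, axis)
    radius_raw = float(np.mean(np.linalg.norm(radial, axis=1)))
    if radius_raw < 0.5:
        return GeometryMeasurement(rise, math.inf, radius_raw, span)

    # pitch: unwrap azimuth of centres about the axis per strand
    ref = np.zeros(3)
    ref[np.argmin(np.abs(axis))] = 1.0
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    slopes = []
    for cen in centres:
        d = cen - mean
        z = d @ axis
        theta = np.unwrap(np.arctan2(d @ v, d @ u))
        slopes.append(np.polyfit(z, theta, 1)[0])
    dtheta_dz = float(np.mean(np.abs(slopes)))
    pitch = 2.0 * math.pi / dtheta_dz if dtheta_dz > 0 else math.inf

    # correct the radius shrinkage from averaging over the superhelix arc
    omega = 2.0 * math.pi * rise / pitch if math.isfinite(pitch) else 0.0
    factor = float(np.mean(np.cos(omega * np.arange(-3, 4))))
    radius = radius_raw / factor if factor > 0 else radius_raw

    return GeometryMeasurement(rise, pitch, radius, span)
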