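"""Disjointed multi-fragment coordinate models and PDB round-trip.

An :class:`AssemblyModel` holds rigid fragments, each covering one or more
residue ranges of one or more proteins.  Gaps between the covered ranges of
a protein are *junctions*: runs of residues deliberately left unmodelled
between consecutively placed fragments.  Junction bookkeeping is what lets
a disjointed model be scored against the spannable-gap criterion.

Coordinates are in Å.  Residue numbering is 1-based and identical to the
sequence numbering — nothing is renumbered on read or write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np
import yaml

__all__ = [
    "ResidueCoords",
    "FragmentModel",
    "AssemblyModel",
    "Junction",
    "read_assembly",
    "write_assembly",
    "residues_modelled",
    "junctions",
    "virtual_cb",
    "load_chain_map",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from backbone N/CA/C (tetrahedral geometry).

    Used for glycine, which has no real Cβ, whenever a Cβ-based operation
    (e.g. a solvent-accessible-surface path endpoint) needs one.
    """
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_vec + ca


@dataclass
class ResidueCoords:
    """Backbone coordinates for one residue (CA mandatory)."""

    protein_id: str
    residue_index: int
    amino_acid: str = "A"
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if "CA" not in self.atoms:
            raise ValueError(
                f"{self.protein_id}:{self.residue_index} has no CA atom"
            )
        for name, xyz in self.atoms.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(f"bad coordinates for atom {name}")
            self.atoms[name] = xyz

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def cb(self) -> np.ndarray:
        """Real Cβ, or a virtual one built from N/CA/C."""
        if "CB" in self.atoms:
            return self.atoms["CB"]
        if "N" in self.atoms and "C" in self.atoms:
            return virtual_cb(self.atoms["N"], self.ca, self.atoms["C"])
        raise ValueError(
            f"{self.protein_id}:{self.residue_index}: no CB and not enough "
            "backbone atoms to construct a virtual one"
        )


@dataclass
class FragmentModel:
    """One rigid fragment: residue coordinates plus the segments it covers.

    ``segments`` lists (protein_id, start, end, direction) with direction
    ``'+'`` for N→C along the fragment axis, ``'-'`` for the reverse, or
    ``None`` when unknown (e.g. models read from file).
    """

    fragment_id: str
    segments: list[tuple[str, int, int, str | None]] = field(default_factory=list)
    residues: dict[tuple[str, int], ResidueCoords] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[str, list[tuple[int, int]]] = {}
        for pid, start, end, _ in self.segments:
            if start > end:
                raise ValueError(f"segment {pid}:{start}-{end} inverted")
            for s, e in seen.get(pid, ()):
                if start <= e and s <= end:
                    raise ValueError(
                        f"overlapping segments of {pid} within fragment "
                        f"{self.fragment_id}"
                    )
            seen.setdefault(pid, []).append((start, end))
        for pid, start, end, _ in self.segments:
            for i in range(start, end + 1):
                if (pid, i) not in self.residues:
                    raise ValueError(
                        f"fragment {self.fragment_id} declares {pid}:{i} "
                        "but has no coordinates for it"
                    )

    def ca_array(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues.values()])

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply a rigid-body transform in place (x' = R x + t)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        for res in self.residues.values():
            for name in res.atoms:
                res.atoms[name] = rotation @ res.atoms[name] + translation

    def copy(self) -> "FragmentModel":
        return FragmentModel(
            self.fragment_id,
            list(self.segments),
            {
                key: ResidueCoords(
                    r.protein_id,
                    r.residue_index,
                    r.amino_acid,
                    {n: xyz.copy() for n, xyz in r.atoms.items()},
                )
                for key, r in self.residues.items()
            },
        )


class AssemblyModel:
    """A set of fragments sharing one coordinate frame.

    No residue of a protein may appear in two fragments.
    """

    def __init__(self, fragments: Iterable[FragmentModel] = (), chain_map: Mapping[str, str] | None = None):
        self.fragments: list[FragmentModel] = []
        self.chain_map: dict[str, str] = dict(chain_map or {})
        self._index: dict[tuple[str, int], ResidueCoords] = {}
        for frag in fragments:
            self.add_fragment(frag)

    def add_fragment(self, fragment: FragmentModel) -> None:
        for key in fragment.residues:
            if key in self._index:
                raise ValueError(
                    f"residue {key[0]}:{key[1]} appears in two fragments"
                )
        self.fragments.append(fragment)
        self._index.update(fragment.residues)

    def reindex(self) -> None:
        """Rebuild the residue lookup (after transforming fragments)."""
        self._index = {}
        for frag in self.fragments:
            self._index.update(frag.residues)

    def get(self, protein_id: str, residue_index: int) -> ResidueCoords | None:
        return self._index.get((protein_id, residue_index))

    def has_residue(self, protein_id: str, residue_index: int) -> bool:
        return (protein_id, residue_index) in self._index

    def __iter__(self) -> Iterator[ResidueCoords]:
        for frag in self.fragments:
            yield from frag.residues.values()

    def proteins(self) -> list[str]:
        return sorted({pid for frag in self.fragments for pid, *_ in frag.segments}
                      | {r.protein_id for r in self})

    def atom_table(self) -> tuple[np.ndarray, list[tuple[str, int, str, str]]]:
        """All atoms as an (n, 3) array plus (protein, residue, atom, element) keys."""
        coords, keys = [], []
        for res in self:
            for name, xyz in res.atoms.items():
                coords.append(xyz)
                keys.append((res.protein_id, res.residue_index, name, name[0]))
        if not coords:
            return np.empty((0, 3)), []
        return np.array(coords), keys

    def copy(self) -> "AssemblyModel":
        return AssemblyModel([f.copy() for f in self.fragments], self.chain_map)


@dataclass(frozen=True)
class Junction:
    """A gap of unmodelled residues between consecutive covered ranges."""

    protein_id: str
    last_modelled: int
    next_modelled: int

    @property
    def n_omitted(self) -> int:
        return self.next_modelled - self.last_modelled - 1

    def __post_init__(self):
        if self.n_omitted < 1:
            raise ValueError("a junction must omit at least one residue")


def _covered_ranges(assembly: AssemblyModel, protein_id: str) -> list[tuple[int, int]]:
    indices = sorted(
        idx for (pid, idx) in assembly._index if pid == protein_id
    )
    if not indices:
        return []
    ranges = []
    start = prev = indices[0]
    for idx in indices[1:]:
        if idx == prev + 1:
            prev = idx
        else:
            ranges.append((start, prev))
            start = prev = idx
    ranges.append((start, prev))
    return ranges


def residues_modelled(assembly: AssemblyModel, protein_id: str) -> tuple[int, list[tuple[int, int]]]:
    """Count of residues with coordinates and their maximal covered ranges."""
    ranges = _covered_ranges(assembly, protein_id)
    if not ranges:
        warnings.warn(f"no residues of {protein_id!r} in the assembly", stacklevel=2)
    count = sum(end - start + 1 for start, end in ranges)
    return count, ranges


def junctions(assembly: AssemblyModel, protein_id: str | None = None) -> list[Junction]:
    """Junctions per protein (termini are not junctions)."""
    proteins = [protein_id] if protein_id else assembly.proteins()
    out: list[Junction] = []
    for pid in proteins:
        ranges = _covered_ranges(assembly, pid)
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            out.append(Junction(pid, last_modelled=e1, next_modelled=s2))
    return out


def load_chain_map(path: str | Path) -> dict[str, str]:
    """Chain-id → protein-id map from YAML (``{A: SMC2, B: SMC4}``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {str(k): str(v) for k, v in raw.items()}


def read_assembly(path: str | Path, chain_map: Mapping[str, str]) -> AssemblyModel:
    """Read a PDB file into an :class:`AssemblyModel`.

    Each chain must be assigned to a protein via ``chain_map``.  Fragments
    are inferred from chain boundaries and residue-number gaps within a
    chain.  Alternate locations keep the first conformer; insertion codes
    are rejected (they would break the sequence-numbering contract);
    residues without a CA are dropped with a warning.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        return AssemblyModel(chain_map=dict(chain_map))
    model = st[0]

    unknown = [ch.name for ch in model if ch.name not in chain_map]
    if unknown:
        raise ValueError(f"chains not in the chain map: {unknown}")

    fragments: list[FragmentModel] = []
    for chain in model:
        pid = chain_map[chain.name]
        current: list[ResidueCoords] = []
        prev_idx: int | None = None

        def flush():
            if current:
                frag_id = f"{chain.name}_{current[0].residue_index}"
                seg = (pid, current[0].residue_index, current[-1].residue_index, None)
                fragments.append(
                    FragmentModel(
                        frag_id,
                        [seg],
                        {(r.protein_id, r.residue_index): r for r in current},
                    )
                )

        for residue in chain:
            seqid = residue.seqid
            if seqid.icode not in (" ", "", "\x00"):
                raise ValueError(
                    f"insertion code {seqid.icode!r} at {chain.name} "
                    f"{seqid.num} is not supported"
                )
            idx = seqid.num
            atoms: dict[str, np.ndarray] = {}
            for atom in residue:
                if atom.name in BACKBONE_ATOMS and atom.name not in atoms:
                    # gemmi orders altlocs; keeping the first occurrence keeps
                    # the first conformer
                    atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if "CA" not in atoms:
                warnings.warn(
                    f"residue {pid}:{idx} has no CA atom and was dropped",
                    stacklevel=2,
                )
                continue
            aa = _THREE_TO_ONE.get(residue.name.upper(), "X")
            if prev_idx is not None and idx != prev_idx + 1:
                flush()
                current = []
            current.append(ResidueCoords(pid, idx, aa, atoms))
            prev_idx = idx
        flush()

    return AssemblyModel(fragments, chain_map=dict(chain_map))


def write_assembly(assembly: AssemblyModel, path: str | Path) -> dict[str, str]:
    """Write an assembly to PDB, one chain per contiguous protein segment.

    Residues are serialized in ascending index order regardless of the
    spatial direction of the fragment.  Returns the chain-id → protein-id
    map needed to read the file back; coordinates round-trip at PDB
    precision (3 decimals).
    """
    st = gemmi.Structure()
    st.name = "crosscoil"
    model = gemmi.Model("1")

    chain_map: dict[str, str] = {}
    chain_counter = 0
    for frag in assembly.fragments:
        for pid, start, end, _ in sorted(frag.segments):
            if chain_counter >= len(_CHAIN_ALPHABET):
                raise ValueError("more than 62 chains: PDB chain ids exhausted")
            cid = _CHAIN_ALPHABET[chain_counter]
            chain_counter += 1
            chain_map[cid] = pid
            chain = gemmi.Chain(cid)
            for idx in range(start, end + 1):
                res = frag.residues[(pid, idx)]
                residue = gemmi.Residue()
                residue.name = _ONE_TO_THREE.get(res.amino_acid, "ALA")
                residue.seqid = gemmi.SeqId(idx, " ")
                for name in BACKBONE_ATOMS:
                    if name not in res.atoms:
                        continue
                    atom = gemmi.Atom()
                    atom.name = name
                    atom.element = gemmi.Element(name[0])
                    xyz = res.atoms[name]
                    atom.pos = gemmi.Position(*xyz)
                    atom.occ = 1.0
                    atom.b_iso = 0.0
                    residue.add_atom(atom)
                chain.add_residue(residue)
            model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))
    return chain_map
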