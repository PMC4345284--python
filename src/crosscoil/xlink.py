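"""Cross-link data model, parsing and domain classification.

A cross-link is an unordered pair of residue loci captured by an
amine-reactive reagent (BS3 in the experiments this package models).  Links
are classified against a per-protein segmentation into head / coiled-coil /
hinge segments (the d1–d5 convention used for SMC proteins):

* ``intradomain`` — both residues in the same segment of one protein;
* ``interdomain_intramolecular`` — different segments of one protein
  (for SMC proteins these are typically links between the two anti-parallel
  helices of the folded-back coiled-coil);
* ``intermolecular`` — residues on two different proteins, or the same
  residue position on two copies of one protein (a self-pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "ProteinDef",
    "ProteinRegistry",
    "DomainTable",
    "ResidueLocus",
    "CrossLink",
    "CrossLinkSet",
    "LinkCategory",
    "load_fasta_registry",
    "load_domain_table",
    "load_crosslinks",
    "classify",
    "partition_counts",
    "export_map",
    "UNASSIGNED",
]

#: Segment marker used when a residue falls outside every declared segment.
UNASSIGNED = "unassigned"

CATEGORIES = ("intradomain", "interdomain_intramolecular", "intermolecular")


@dataclass(frozen=True)
class ProteinDef:
    """A protein entry: short name plus its one-letter sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class ProteinRegistry:
    """Mapping of protein id to :class:`ProteinDef` with unique ids."""

    def __init__(self, proteins: Iterable[ProteinDef] = ()):
        self._proteins: dict[str, ProteinDef] = {}
        for p in proteins:
            self.add(p)

    def add(self, protein: ProteinDef) -> None:
        if protein.id in self._proteins:
            raise ValueError(f"duplicate protein id {protein.id!r}")
        self._proteins[protein.id] = protein

    def __getitem__(self, pid: str) -> ProteinDef:
        return self._proteins[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self._proteins

    def __iter__(self) -> Iterator[ProteinDef]:
        return iter(self._proteins.values())

    def __len__(self) -> int:
        return len(self._proteins)


def load_fasta_registry(path: str | Path) -> ProteinRegistry:
    """Build a registry from a FASTA file; record ids become protein ids."""
    reg = ProteinRegistry()
    for rec in SeqIO.parse(str(path), "fasta"):
        reg.add(ProteinDef(id=rec.id, sequence=str(rec.seq).upper()))
    return reg


@dataclass(frozen=True)
class Segment:
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    kind: str  # head | coil | hinge

    def __contains__(self, residue_index: int) -> bool:
        return self.start <= residue_index <= self.end


@dataclass
class DomainTable:
    """Ordered, non-overlapping d1–d5 style segments per protein.

    ``disruptions`` records annotated not-coiled-coil interruptions inside a
    coil segment, e.g. a Pro-rich insertion, as (start, end, label) triples.
    """

    segments: dict[str, list[Segment]] = field(default_factory=dict)
    disruptions: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def add(self, protein_id: str, name: str, start: int, end: int, kind: str) -> None:
        if start > end:
            raise ValueError(f"segment {name}: start {start} > end {end}")
        segs = self.segments.setdefault(protein_id, [])
        if segs and start <= segs[-1].end:
            raise ValueError(
                f"segment {name} of {protein_id} overlaps or is out of order "
                f"(starts at {start}, previous ends at {segs[-1].end})"
            )
        segs.append(Segment(name, start, end, kind))

    def segment_of(self, protein_id: str, residue_index: int) -> str:
        """Name of the segment containing the residue, or ``unassigned``."""
        for seg in self.segments.get(protein_id, ()):
            if residue_index in seg:
                return seg.name
        return UNASSIGNED

    def validate_against(self, registry: ProteinRegistry) -> None:
        for pid, segs in self.segments.items():
            if pid not in registry:
                raise ValueError(f"domain table references unknown protein {pid!r}")
            length = registry[pid].length
            for seg in segs:
                if seg.end > length:
                    raise ValueError(
                        f"{pid} segment {seg.name} ends at {seg.end} but the "
                        f"sequence has only {length} residues"
                    )


def load_domain_table(path: str | Path) -> DomainTable:
    """Read a domain table from YAML.

    Layout::

        SMC2:
          segments:
            - {name: d1, start: 1, end: 167, kind: head}
            ...
          disruptions:
            - {start: 1035, end: 1067, label: pro_rich}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table = DomainTable()
    for pid, entry in raw.items():
        for seg in entry.get("segments", []):
            table.add(pid, seg["name"], int(seg["start"]), int(seg["end"]), seg.get("kind", "coil"))
        for dis in entry.get("disruptions", []) or []:
            table.disruptions.setdefault(pid, []).append(
                (int(dis["start"]), int(dis["end"]), str(dis.get("label", "")))
            )
    return table


@dataclass(frozen=True, order=True)
class ResidueLocus:
    """One cross-linked residue: protein id plus 1-based residue index."""

    protein_id: str
    residue_index: int
    amino_acid: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.residue_index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.residue_index}")


@dataclass(frozen=True)
class CrossLink:
    """An unordered residue-pair restraint.

    ``self_pair_flag`` marks a link between the same residue position on two
    copies of one protein — chemically impossible within a single chain, so
    such links are classified intermolecular.
    """

    a: ResidueLocus
    b: ResidueLocus
    confidence: str = "high"
    source_label: str = ""
    self_pair_flag: bool = False

    def __post_init__(self):
        if self.confidence not in ("high", "low"):
            raise ValueError(f"confidence must be 'high' or 'low', got {self.confidence!r}")
        if not self.self_pair_flag and self.a == self.b:
            object.__setattr__(self, "self_pair_flag", True)

    @property
    def key(self) -> tuple:
        """Order-independent pair identity used for deduplication."""
        ka = (self.a.protein_id, self.a.residue_index)
        kb = (self.b.protein_id, self.b.residue_index)
        return (min(ka, kb), max(ka, kb))

    def is_intramolecular(self) -> bool:
        return self.a.protein_id == self.b.protein_id and not self.self_pair_flag


class CrossLinkSet:
    """Deduplicated collection of cross-links with stable insertion order."""

    def __init__(self, links: Iterable[CrossLink] = ()):
        self._links: dict[tuple, CrossLink] = {}
        for link in links:
            self.add(link)

    def add(self, link: CrossLink) -> None:
        self._links.setdefault(link.key, link)

    def __iter__(self) -> Iterator[CrossLink]:
        return iter(self._links.values())

    def __len__(self) -> int:
        return len(self._links)

    def __contains__(self, link: CrossLink) -> bool:
        return link.key in self._links

    def filter(self, predicate) -> "CrossLinkSet":
        return CrossLinkSet(l for l in self if predicate(l))


@dataclass(frozen=True)
class LinkCategory:
    molecularity: str  # intramolecular | intermolecular
    category: str  # intradomain | interdomain_intramolecular | intermolecular
    domain_pair: tuple[str, str]


_LINK_COLUMNS = ("Protein1", "Residue1", "Protein2", "Residue2", "Score", "Source")

# Accepted header aliases (case-insensitive) for the link table columns.
_COLUMN_ALIASES = {
    "protein1": "Protein1",
    "proteina": "Protein1",
    "residue1": "Residue1",
    "pos1": "Residue1",
    "protein2": "Protein2",
    "proteinb": "Protein2",
    "residue2": "Residue2",
    "pos2": "Residue2",
    "score": "Score",
    "confidence": "Score",
    "source": "Source",
    "source_label": "Source",
    "selfpair": "SelfPair",
    "self_pair": "SelfPair",
}


def _resolve_locus(pid: str, idx: int, registry: ProteinRegistry) -> ResidueLocus:
    if pid not in registry:
        raise ValueError(f"cross-link references unknown protein {pid!r}")
    prot = registry[pid]
    if not 1 <= idx <= prot.length:
        raise ValueError(
            f"residue {pid}:{idx} outside sequence of length {prot.length}"
        )
    return ResidueLocus(pid, idx, prot.sequence[idx - 1])


def load_crosslinks(path: str | Path, registry: ProteinRegistry) -> CrossLinkSet:
    """Load a delimited link table into a deduplicated :class:`CrossLinkSet`.

    The table must name protein/residue columns in its header (xiNET-style
    ``Protein1,Residue1,Protein2,Residue2`` with optional ``Score`` holding
    the high/low confidence class and ``Source`` the free-text provenance).
    Unknown proteins and out-of-range residues are hard errors; an amino-acid
    column disagreeing with the registry sequence only warns, because residue
    numbers may come from a slightly different database isoform.
    """
    df = pd.read_csv(path, comment="#")
    rename = {}
    for col in df.columns:
        canon = _COLUMN_ALIASES.get(col.strip().lower().replace(" ", ""))
        if canon:
            rename[col] = canon
    df = df.rename(columns=rename)
    missing = {"Protein1", "Residue1", "Protein2", "Residue2"} - set(df.columns)
    if missing:
        raise ValueError(f"link table is missing columns: {sorted(missing)}")

    links = CrossLinkSet()
    for row in df.itertuples(index=False):
        a = _resolve_locus(str(row.Protein1), int(row.Residue1), registry)
        b = _resolve_locus(str(row.Protein2), int(row.Residue2), registry)
        for col in ("AminoAcid1", "AminoAcid2"):
            if col in df.columns:
                locus = a if col.endswith("1") else b
                stated = str(getattr(row, col)).upper()
                if stated and stated != "NAN" and stated != locus.amino_acid:
                    warnings.warn(
                        f"{locus.protein_id}:{locus.residue_index} is "
                        f"{locus.amino_acid} in the registry but {stated} in the "
                        "link table (possible isoform drift)",
                        stacklevel=2,
                    )
        confidence = str(getattr(row, "Score", "high")).strip().lower()
        if confidence not in ("high", "low"):
            confidence = "high"
        source = str(getattr(row, "Source", "") or "")
        if source.lower() == "nan":
            source = ""
        self_pair = bool(getattr(row, "SelfPair", False)) or a == b
        links.add(CrossLink(a, b, confidence, source, self_pair))
    return links


def classify(link: CrossLink, domains: DomainTable) -> LinkCategory:
    """Classify a link against the segment partition.

    Symmetric in the two endpoints.  Residues outside every declared segment
    carry the ``unassigned`` marker but still classify (an unassigned residue
    can never share a segment, so such intramolecular links fall in the
    interdomain class).
    """
    seg_a = domains.segment_of(link.a.protein_id, link.a.residue_index)
    seg_b = domains.segment_of(link.b.protein_id, link.b.residue_index)
    pair_a = (link.a.protein_id, link.a.residue_index, seg_a)
    pair_b = (link.b.protein_id, link.b.residue_index, seg_b)
    first, second = sorted([pair_a, pair_b])
    domain_pair = (first[2], second[2])

    if link.a.protein_id != link.b.protein_id or link.self_pair_flag:
        return LinkCategory("intermolecular", "intermolecular", domain_pair)
    if seg_a == seg_b and seg_a != UNASSIGNED:
        return LinkCategory("intramolecular", "intradomain", domain_pair)
    return LinkCategory("intramolecular", "interdomain_intramolecular", domain_pair)


def partition_counts(links: CrossLinkSet, domains: DomainTable) -> dict[str, int]:
    """Counts per category; always sums to ``len(links)``."""
    counts = {c: 0 for c in CATEGORIES}
    for link in links:
        counts[classify(link, domains).category] += 1
    return counts


def per_protein_counts(links: CrossLinkSet, domains: DomainTable) -> dict[str, dict[str, int]]:
    """Intramolecular category counts resolved by protein."""
    out: dict[str, dict[str, int]] = {}
    for link in links:
        cat = classify(link, domains).category
        if cat == "intermolecular":
            continue
        per = out.setdefault(link.a.protein_id, {c: 0 for c in CATEGORIES[:2]})
        per[cat] += 1
    return out


def export_map(
    links: CrossLinkSet,
    registry: ProteinRegistry,
    domains: DomainTable | None,
    path: str | Path,
) -> None:
    """Write an xiNET-style link list plus a domain annotation track.

    The link table round-trips through :func:`load_crosslinks`.  When a
    domain table is given, a companion ``<path>.domains.csv`` annotation
    track is written with one row per segment.
    """
    rows = []
    for link in links:
        rows.append(
            {
                "Protein1": link.a.protein_id,
                "Residue1": link.a.residue_index,
                "Protein2": link.b.protein_id,
                "Residue2": link.b.residue_index,
                "Score": link.confidence,
                "Source": link.source_label,
                "SelfPair": link.self_pair_flag,
            }
        )
    pd.DataFrame(rows, columns=list(_LINK_COLUMNS) + ["SelfPair"]).to_csv(path, index=False)

    if domains is not None:
        ann = [
            {"Protein": pid, "Segment": s.name, "Start": s.start, "End": s.end, "Kind": s.kind}
            for pid, segs in domains.segments.items()
            for s in segs
        ]
        pd.DataFrame(ann).to_csv(str(path) + ".domains.csv", index=False)
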