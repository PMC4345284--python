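"""Sequence heuristics for locating coiled-coil break-points.

Long coiled-coils are interrupted by loops, stutters and stammers that are
hard to predict; fragmenting a model at such *break-points* is safer than
forcing one continuous ideal coil through them.  Five heuristics over a
homologue alignment and per-residue secondary-structure predictions flag
candidate break-points:

i.   five or more consecutive alignment positions dominated by highly polar
     residues;
ii.  helix prediction disrupted according to three or more secondary
     structure prediction methods;
iii. four or more consecutive positions featuring only hydrophobic
     residues (a buried or non-surface-like patch foreign to a 3.5-residue
     amphipathic rhythm);
iv.  secondary-structure "parsing" residues (Pro/Gly) or alignment gaps in
     more than one third of the homologues;
v.   disruption of the heptad repeat pattern itself, detected by a
     sliding-window heptad-phase score: the best of the seven phases is
     kept per window, and a phase jump (necessarily a non-multiple of
     seven) or a score collapse marks a disruption.

A break-point call is a maximal run of residues where at least one
criterion fires; nearby runs are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import AlignIO

__all__ = [
    "MSA",
    "SSPredictionSet",
    "BreakpointParams",
    "BreakpointCall",
    "criterion_masks",
    "call_breakpoints",
    "heptad_periodicity_profile",
]

GAP_CHARS = set("-.")

CRITERIA = ("i", "ii", "iii", "iv", "v")


@dataclass
class MSA:
    """Aligned homologue set with a designated reference row."""

    rows: dict[str, str]
    reference: str

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.reference not in self.rows:
            raise ValueError(f"reference row {self.reference!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def reference_sequence(self) -> str:
        return "".join(
            c for c in self.rows[self.reference] if c not in GAP_CHARS
        )

    def reference_columns(self) -> np.ndarray:
        """Column index of each reference residue (1:1, ungapped positions)."""
        ref = self.rows[self.reference]
        return np.array([i for i, c in enumerate(ref) if c not in GAP_CHARS])

    @classmethod
    def from_file(cls, path: str | Path, reference: str | None = None, fmt: str = "fasta") -> "MSA":
        aln = AlignIO.read(str(path), fmt)
        rows = {rec.id: str(rec.seq).upper() for rec in aln}
        return cls(rows, reference or next(iter(rows)))


@dataclass
class SSPredictionSet:
    """Per-method secondary-structure strings over the reference residues."""

    methods: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.methods.values()}
        if len(lengths) > 1:
            raise ValueError("prediction tracks differ in length")
        for name, track in self.methods.items():
            bad = set(track) - set("HEC")
            if bad:
                raise ValueError(f"track {name!r} has states {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.methods)

    @property
    def n_residues(self) -> int:
        return len(next(iter(self.methods.values())))


@dataclass(frozen=True)
class BreakpointParams:
    polar_set: frozenset = frozenset("DEKRNQSTH")
    hydrophobic_set: frozenset = frozenset("AVILMFWYC")
    parsing_set: frozenset = frozenset("PG")
    min_polar_run: int = 5
    polar_dominance: float = 0.6
    min_hydrophobic_run: int = 4
    min_ss_methods: int = 3
    parsing_fraction: float = 1.0 / 3.0
    heptad_window: int = 21
    heptad_score_threshold: float = 0.4
    merge_gap: int = 2


@dataclass(frozen=True)
class BreakpointCall:
    """1-based inclusive reference-residue range and the criteria fired."""

    start: int
    end: int
    criteria: frozenset

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)


def _runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Keep only True-runs of at least ``min_len``."""
    out = np.zeros_like(mask)
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def heptad_periodicity_profile(
    sequence: str, params: BreakpointParams = BreakpointParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window heptad score and best phase per residue.

    For each window the score under a phase is the hydrophobic fraction at
    the implied a/d positions minus the hydrophobic fraction elsewhere; the
    best of the seven phases is reported.  An ideal Leu-zipper style repeat
    scores 1.0 with a constant phase; a scrambled sequence hovers near 0.
    """
    w = params.heptad_window
    n = len(sequence)
    if n < w:
        raise ValueError(f"sequence shorter than the {w}-residue window")
    hydro = np.array([c in params.hydrophobic_set for c in sequence], dtype=float)
    pos = np.arange(n)
    scores = np.empty(n)
    phases = np.empty(n, dtype=int)
    half = w // 2
    for i in range(n):
        lo = min(max(0, i - half), n - w)
        sl = slice(lo, lo + w)
        best_score, best_phase = -np.inf, 0
        for phase in range(7):
            ad = ((pos[sl] + phase) % 7 == 0) | ((pos[sl] + phase) % 7 == 3)
            s_ad = hydro[sl][ad].mean() if ad.any() else 0.0
            s_other = hydro[sl][~ad].mean() if (~ad).any() else 0.0
            s = s_ad - s_other
            if s > best_score:
                best_score, best_phase = s, phase
        scores[i] = best_score
        phases[i] = best_phase
    return scores, phases


def criterion_masks(
    msa: MSA,
    sspreds: SSPredictionSet | None,
    params: BreakpointParams = BreakpointParams(),
) -> dict[str, np.ndarray | None]:
    """Boolean mask per criterion over the reference residues.

    Criterion ii is ``None`` (not evaluable) when fewer than
    ``min_ss_methods`` prediction tracks are supplied.
    """
    ref_cols = msa.reference_columns()
    n_ref = len(ref_cols)
    n_cols = msa.n_columns
    rows = list(msa.rows.values())

    polar_frac = np.zeros(n_cols)
    all_hydrophobic = np.zeros(n_cols, dtype=bool)
    parsing_frac = np.zeros(n_cols)
    for j in range(n_cols):
        col = [r[j] for r in rows]
        non_gap = [c for c in col if c not in GAP_CHARS]
        if non_gap:
            polar_frac[j] = sum(c in params.polar_set for c in non_gap) / len(non_gap)
            all_hydrophobic[j] = all(c in params.hydrophobic_set for c in non_gap)
        parsing_frac[j] = sum(
            c in params.parsing_set or c in GAP_CHARS for c in col
        ) / len(col)

    col_i = _runs(polar_frac >= params.polar_dominance, params.min_polar_run)
    col_iii = _runs(all_hydrophobic, params.min_hydrophobic_run)
    col_iv = parsing_frac > params.parsing_fraction

    masks: dict[str, np.ndarray | None] = {
        "i": col_i[ref_cols],
        "iii": col_iii[ref_cols],
        "iv": col_iv[ref_cols],
    }

    if sspreds is None or len(sspreds) < params.min_ss_methods:
        masks["ii"] = None
    else:
        if sspreds.n_residues != n_ref:
            raise ValueError(
                "prediction tracks do not cover the reference segment"
            )
        not_h = np.zeros(n_ref, dtype=int)
        for track in sspreds.methods.values():
            not_h += np.array([c != "H" for c in track], dtype=int)
        masks["ii"] = not_h >= params.min_ss_methods

    ref_seq = msa.reference_sequence
    if len(ref_seq) >= params.heptad_window:
        scores, phases = heptad_periodicity_profile(ref_seq, params)
        collapse = scores < params.heptad_score_threshold
        jump = np.zeros(n_ref, dtype=bool)
        jump[1:] = phases[1:] != phases[:-1]
        masks["v"] = collapse | jump
    else:
        masks["v"] = np.zeros(n_ref, dtype=bool)

    return masks


def call_breakpoints(
    masks: Mapping[str, np.ndarray | None],
    params: BreakpointParams = BreakpointParams(),
) -> list[BreakpointCall]:
    """Maximal runs where ≥ 1 criterion fires, merged across small gaps."""
    usable = {k: m for k, m in masks.items() if m is not None}
    if not usable:
        return []
    n = len(next(iter(usable.values())))
    combined = np.zeros(n, dtype=bool)
    for m in usable.values():
        combined |= m

    ranges: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if combined[i]:
            j = i
            while j < n and combined[j]:
                j += 1
            ranges.append((i, j - 1))
            i = j
        else:
            i += 1

    merged: list[tuple[int, int]] = []
    for start, end in ranges:
        if merged and start - merged[-1][1] - 1 <= params.merge_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    calls = []
    for start, end in merged:
        fired = frozenset(
            k for k, m in usable.items() if m[start : end + 1].any()
        )
        calls.append(BreakpointCall(start + 1, end + 1, fired))
    return calls
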