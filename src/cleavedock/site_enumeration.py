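"""Candidate cleavage-site enumeration under trypsin-like specificity.

Trypsin-like serine proteases cleave C-terminal to basic residues; in
Schechter–Berger nomenclature the residue N-terminal to the scissile bond is
P1 and its N-terminal neighbour is P2. The default rule set encodes the
specificity reported for TMPRSS2: P1 must be Arg or Lys, Arg is preferred
over Lys, and a Lys at P2 is incompatible with cleavage. Candidates failing
the P2 rule are flagged as excluded but kept in the output so that reports
can show every basic residue in a region.

Sequences carry author numbering (``start_number`` + index). The one-letter
code 'X' is accepted as an *unknown* residue placeholder for regions whose
sequence is only partially published; an X is never a P1 candidate and never
triggers the P2 exclusion rule.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .exceptions import MutantParseError, ValidationError

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
UNKNOWN_AA = "X"

__all__ = [
    "SubstrateSequence",
    "MutantSpec",
    "CleavageCandidate",
    "SpecificityRules",
    "apply_mutations",
    "parse_mutant_name",
    "enumerate_candidates",
    "docking_windows",
    "candidates_to_frame",
]


@dataclass(frozen=True)
class SubstrateSequence:
    """A substrate (fragment) sequence with author numbering."""

    identifier: str
    residues: str
    start_number: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - CANONICAL_AA - {UNKNOWN_AA}
        if bad:
            raise ValidationError(
                f"{self.identifier}: non-canonical residue code(s) {sorted(bad)}"
            )

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.residues) - 1

    def __len__(self) -> int:
        return len(self.residues)

    def contains(self, position: int) -> bool:
        return self.start_number <= position <= self.end_number

    def residue_at(self, position: int) -> str:
        if not self.contains(position):
            raise ValidationError(
                f"position {position} outside sequence span "
                f"{self.start_number}-{self.end_number}"
            )
        return self.residues[position - self.start_number]

    def segment(self, start: int, end: int) -> str:
        """Residues in the closed author-number interval [start, end]."""
        if start < self.start_number or end > self.end_number or start > end:
            raise ValidationError(
                f"interval {start}-{end} outside sequence span "
                f"{self.start_number}-{self.end_number}"
            )
        i = start - self.start_number
        return self.residues[i : i + (end - start + 1)]

    @classmethod
    def from_fasta(cls, path: str | Path, start_number: int = 1) -> "SubstrateSequence":
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(identifier=record.id, residues=str(record.seq).upper(),
                   start_number=start_number)


@dataclass(frozen=True)
class MutantSpec:
    """A set of point substitutions defining a mutant construct."""

    substitutions: tuple[tuple[int, str, str], ...]
    label: str = ""

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.substitutions]
        if len(positions) != len(set(positions)):
            raise ValidationError(f"{self.label or 'mutant'}: duplicate positions")

    def canonical_label(self) -> str:
        return ";".join(
            f"{f}{p}{t}" for p, f, t in sorted(self.substitutions)
        )


@dataclass(frozen=True)
class SpecificityRules:
    """Trypsin-like P1/P2 rules: which residues may sit in S1, and vetoes."""

    p1_allowed: frozenset[str] = frozenset({"R", "K"})
    p1_preference_order: tuple[str, ...] = ("R", "K")
    p2_forbidden: frozenset[str] = frozenset({"K"})
    rule_provenance: str = (
        "TMPRSS2 prefers Arg over Lys at P1; Lys at P2 is incompatible"
    )

    def __post_init__(self) -> None:
        if not self.p1_allowed:
            raise ValidationError("p1_allowed must not be empty")

    def preference_rank(self, residue: str) -> int:
        try:
            return self.p1_preference_order.index(residue)
        except ValueError:
            return len(self.p1_preference_order)


@dataclass(frozen=True)
class CleavageCandidate:
    """A candidate P1 residue with specificity annotation and docking window."""

    p1_position: int
    p1_residue: str
    p2_residue: str
    excluded: bool = False
    exclusion_reason: str = ""
    window: str = ""
    window_span: tuple[int, int] = (0, 0)


def apply_mutations(seq: SubstrateSequence, spec: MutantSpec) -> SubstrateSequence:
    """Return a new sequence with the spec's substitutions applied."""
    residues = list(seq.residues)
    for position, from_aa, to_aa in spec.substitutions:
        found = seq.residue_at(position)
        if found != from_aa:
            raise ValidationError(
                f"{spec.label or spec.canonical_label()}: expected {from_aa} at "
                f"position {position} but wild-type sequence has {found}"
            )
        residues[position - seq.start_number] = to_aa
    label = f"{seq.identifier}_{spec.label}" if spec.label else seq.identifier
    return replace(seq, identifier=label, residues="".join(residues))


_ITEM_RE = re.compile(r"^([A-Z]+)(\d+)([A-Z]+)$")


def parse_mutant_name(label: str, seq: SubstrateSequence) -> MutantSpec:
    """Parse a construct name like ``RKRK178AAAA;K168A`` into a mutant spec.

    Each item is ``X<pos>Y`` (single substitution) or a run
    ``X..X<pos>Y..Y``. Published construct names anchor the printed number
    inconsistently — sometimes at the first residue of the run, sometimes at
    the last — so both anchorings are tried against the wild-type sequence
    and the one that matches is used; if both or neither match, the item is
    rejected.
    """
    substitutions: list[tuple[int, str, str]] = []
    items = [part.strip() for part in re.split(r"[;+]", label) if part.strip()]
    if not items:
        raise MutantParseError(f"empty mutant name {label!r}")
    for item in items:
        match = _ITEM_RE.match(item)
        if not match or len(match.group(1)) != len(match.group(3)):
            raise MutantParseError(
                f"item {item!r} does not follow the X<pos>Y / X..X<pos>Y..Y grammar"
            )
        from_run, pos, to_run = match.group(1), int(match.group(2)), match.group(3)
        n = len(from_run)
        anchorings = []
        for start in {pos, pos - n + 1}:  # first-residue vs last-residue anchor
            end = start + n - 1
            if seq.contains(start) and seq.contains(end) and seq.segment(start, end) == from_run:
                anchorings.append(start)
        if len(anchorings) != 1:
            kind = "ambiguously (both anchorings)" if anchorings else "nowhere"
            raise MutantParseError(
                f"item {item!r}: run {from_run} matches the wild-type sequence {kind}"
            )
        start = anchorings[0]
        substitutions.extend(
            (start + i, from_run[i], to_run[i]) for i in range(n)
        )
    spec = MutantSpec(substitutions=tuple(substitutions), label=label)
    # validate against wild type (also catches duplicate positions)
    apply_mutations(seq, spec)
    return spec


def _window_for(seq: SubstrateSequence, p1: int,
                n_upstream: int = 3, n_downstream: int = 2) -> tuple[str, tuple[int, int]]:
    """P4–P2′ window around P1, truncated (with a warning) at sequence ends."""
    start = p1 - n_upstream
    end = p1 + n_downstream
    t_start = max(start, seq.start_number)
    t_end = min(end, seq.end_number)
    if (t_start, t_end) != (start, end):
        warnings.warn(
            f"docking window for P1 {p1} truncated to {t_start}-{t_end} "
            f"at sequence boundary",
            stacklevel=2,
        )
    return seq.segment(t_start, t_end), (t_start, t_end)


def enumerate_candidates(
    seq: SubstrateSequence,
    region: tuple[int, int] | None = None,
    rules: SpecificityRules | None = None,
    window_policy: str = "p1_centered",
) -> list[CleavageCandidate]:
    """Enumerate candidate P1 positions in an author-number region.

    One candidate is produced per allowed P1 residue (default Arg/Lys) in the
    region; a forbidden P2 residue flags the candidate as excluded without
    removing it. Windows follow the P4–P2′ convention (6-mer for a full
    context), truncated at sequence termini.
    """
    rules = rules or SpecificityRules()
    if region is None:
        region = (seq.start_number, seq.end_number)
    start, end = region
    if start < seq.start_number or end > seq.end_number:
        raise ValidationError(
            f"region {start}-{end} outside sequence span "
            f"{seq.start_number}-{seq.end_number}"
        )
    candidates = []
    for position in range(start, end + 1):
        residue = seq.residue_at(position)
        if residue not in rules.p1_allowed:
            continue
        p2 = seq.residue_at(position - 1) if seq.contains(position - 1) else ""
        excluded = p2 in rules.p2_forbidden
        reason = (
            f"P2 residue {p2} at {position - 1} is forbidden for cleavage"
            if excluded
            else ""
        )
        window, span = _window_for(seq, position)
        candidates.append(
            CleavageCandidate(
                p1_position=position,
                p1_residue=residue,
                p2_residue=p2,
                excluded=excluded,
                exclusion_reason=reason,
                window=window,
                window_span=span,
            )
        )
    return candidates


def docking_windows(
    candidates: Sequence[CleavageCandidate],
    policy: str = "p1_centered",
    anchors: Iterable[tuple[int, str]] | None = None,
    merge_distance: int = 6,
) -> list[tuple[str, tuple[int, int]]]:
    """Derive deduplicated 6-mer docking windows from candidates.

    ``p1_centered`` emits each candidate's own P4–P2′ window. ``region_based``
    assigns candidates to literal anchor windows supplied as
    ``(start_position, window_string)`` pairs, merging candidates that fall
    within ``merge_distance`` residues of an anchor span; candidates beyond
    reach of every anchor fall back to their own window with a warning.
    """
    windows: list[tuple[str, tuple[int, int]]] = []
    seen: set[tuple[str, tuple[int, int]]] = set()

    def _add(window: str, span: tuple[int, int]) -> None:
        key = (window, span)
        if key not in seen:
            seen.add(key)
            windows.append(key)

    if policy == "p1_centered":
        for cand in candidates:
            _add(cand.window, cand.window_span)
        return windows
    if policy != "region_based":
        raise ValidationError(f"unknown window policy {policy!r}")
    if anchors is None:
        raise ValidationError("region_based policy requires anchor windows")
    anchor_spans = [
        (window, (start, start + len(window) - 1)) for start, window in anchors
    ]
    for cand in candidates:
        best = None
        for window, (a_start, a_end) in anchor_spans:
            if a_start <= cand.p1_position <= a_end:
                gap = 0
            else:
                gap = min(abs(cand.p1_position - a_start), abs(cand.p1_position - a_end))
            if gap < merge_distance and (best is None or gap < best[0]):
                best = (gap, window, (a_start, a_end))
        if best is None:
            warnings.warn(
                f"candidate P1 {cand.p1_position} is not near any anchor window; "
                "emitting its own P4-P2' window",
                stacklevel=2,
            )
            _add(cand.window, cand.window_span)
        else:
            _add(best[1], best[2])
    return windows


def candidates_to_frame(candidates: Sequence[CleavageCandidate]) -> pd.DataFrame:
    """Tabulate candidates (TSV-ready; one row per P1 position)."""
    return pd.DataFrame(
        [
            {
                "p1_position": c.p1_position,
                "p1_residue": c.p1_residue,
                "p2_residue": c.p2_residue,
                "excluded": c.excluded,
                "reason": c.exclusion_reason,
                "window": c.window,
                "window_span": f"{c.window_span[0]}-{c.window_span[1]}",
            }
            for c in candidates
        ]
    )
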