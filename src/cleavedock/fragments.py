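"""Mapping cleavage events to proteolytic fragments of a substrate.

One cleavage event after residue P1 splits a substrate into an N-terminal
and a C-terminal fragment; two events additionally release the intervening
segment — for the channel-activation case, the inhibitory tract whose
excision opens the channel. Fragment masses are unmodified average masses
(each hydrolysis adds one water, so fragment masses sum to the substrate
mass plus n_cuts × 18.015 Da). Glycosylation and other modifications are
deliberately ignored: apparent gel mobilities of real fragments will differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight

from .exceptions import ValidationError
from .site_enumeration import SubstrateSequence

WATER_MASS = 18.0153  # average, Da

__all__ = [
    "CleavageEvent",
    "Fragment",
    "FragmentSet",
    "TractReleaseResult",
    "fragment_map",
    "tract_release_check",
    "peptide_mass",
]


@dataclass(frozen=True)
class CleavageEvent:
    """Hydrolysis of the bond C-terminal to ``p1_position``."""

    p1_position: int
    label: str = ""


@dataclass(frozen=True)
class Fragment:
    span: tuple[int, int]
    sequence: str
    length: int
    mass: float
    role: str  # N-terminal | released-tract | C-terminal | intact


@dataclass
class FragmentSet:
    substrate_id: str
    fragments: list[Fragment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "span": f"{frag.span[0]}-{frag.span[1]}",
                    "length": frag.length,
                    "mass_Da": round(frag.mass, 2),
                    "role": frag.role,
                }
                for frag in self.fragments
            ]
        )


@dataclass(frozen=True)
class TractReleaseResult:
    status: str  # released | retained-partial | retained
    note: str = ""


def peptide_mass(sequence: str) -> float:
    """Unmodified average mass (Da) of a peptide, including one water.

    Returns NaN for sequences containing the unknown-residue placeholder X,
    since no mass can be assigned to unpublished residues.
    """
    if "X" in sequence:
        return float("nan")
    return float(molecular_weight(sequence, seq_type="protein", monoisotopic=False))


def fragment_map(
    seq: SubstrateSequence, events: Sequence[CleavageEvent]
) -> FragmentSet:
    """Split a substrate at one or two cleavage events.

    With two events the middle fragment is labelled ``released-tract``; with
    none the substrate is returned intact as a single fragment.
    """
    positions = [e.p1_position for e in events]
    if len(set(positions)) != len(positions):
        raise ValidationError("cleavage events must be at distinct positions")
    if sorted(positions) != positions:
        raise ValidationError("cleavage events must be sorted by position")
    if len(positions) > 2:
        raise ValidationError("at most two cleavage events are supported")
    for p in positions:
        if not seq.contains(p):
            raise ValidationError(
                f"cleavage position {p} outside substrate span "
                f"{seq.start_number}-{seq.end_number}"
            )
        if p == seq.end_number:
            raise ValidationError(
                f"cleavage after the C-terminal residue {p} is not a cleavage"
            )

    boundaries = [seq.start_number - 1, *positions, seq.end_number]
    if len(positions) == 0:
        roles = ["intact"]
    elif len(positions) == 1:
        roles = ["N-terminal", "C-terminal"]
    else:
        roles = ["N-terminal", "released-tract", "C-terminal"]

    fragments = []
    for (prev, last), role in zip(zip(boundaries, boundaries[1:]), roles):
        start, end = prev + 1, last
        segment = seq.segment(start, end)
        fragments.append(
            Fragment(
                span=(start, end),
                sequence=segment,
                length=len(segment),
                mass=peptide_mass(segment),
                role=role,
            )
        )
    return FragmentSet(substrate_id=seq.identifier, fragments=fragments)


def tract_release_check(
    events: Sequence[CleavageEvent],
    inhibitory_tract_span: tuple[int, int],
    key_span: tuple[int, int],
) -> TractReleaseResult:
    """Decide whether a set of cleavage events releases the inhibitory tract.

    The tract spans ``(proximal P1, distal P1]``: a cut at/before the tract
    start boundary plus a cut at/after its end releases it fully. A proximal
    cut falling *inside* the tract still counts as releasing when it removes
    at most the first residue of the key inhibitory span (the partial-
    activation case), reported with a truncation note; a cut deeper into the
    key span yields ``retained-partial``. Anything less than a bracketing
    pair retains the tract.
    """
    tract_start, tract_end = inhibitory_tract_span
    key_start, _key_end = key_span
    positions = sorted({e.p1_position for e in events})

    distal_ok = any(p >= tract_end for p in positions)
    proximal_full = any(p <= tract_start - 1 for p in positions)
    inside = [p for p in positions if tract_start <= p < tract_end]

    if distal_ok and proximal_full:
        return TractReleaseResult(status="released")
    if distal_ok and inside:
        proximal = min(inside)
        if proximal <= key_start:
            return TractReleaseResult(
                status="released",
                note="key sequence truncated at proximal end",
            )
        return TractReleaseResult(
            status="retained-partial",
            note=f"proximal cleavage after {proximal} falls inside the key span",
        )
    if inside and not distal_ok:
        return TractReleaseResult(
            status="retained",
            note="no distal cleavage; a single cut cannot excise the tract",
        )
    return TractReleaseResult(status="retained")
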