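"""Geometric selection criteria for docked peptide binding modes.

A binding mode is *productive* (compatible with proteolysis) when two
distance criteria hold simultaneously:

1. **S1 salt bridge** — the charged side-chain group of a basic P1 residue
   (Arg NH1/NH2/NE or Lys NZ) lies within ``salt_bridge_max`` of the
   S1-pocket aspartate carboxylate (minimum heavy-atom distance to OD1/OD2).
2. **Scissile-bond geometry** — the backbone carbonyl carbon of that same
   residue lies within ``scissile_max`` of the catalytic serine's hydroxyl
   oxygen (OG), as required for nucleophilic attack.

Both default thresholds are 4 Å, interpreted strictly (< 4 Å); the
``strict_inequality`` flag relaxes them to ≤ for sensitivity analysis.
When several basic residues satisfy criterion 1, the S1 occupant is the one
with the smallest salt-bridge distance, with ties broken by the P1
preference order (Arg before Lys) and then by position. Criterion 2 is
checked only for the occupant: the scissile bond is defined by the residue
actually sitting in S1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, StructureError
from .site_enumeration import SpecificityRules
from .structure_io import PeptidePose, PoseSet, ProteaseReceptor, min_group_distance

__all__ = [
    "SelectionCriteria",
    "PoseEvaluation",
    "evaluate_pose",
    "evaluate_pose_set",
    "evaluations_to_frame",
]

_CHARGED_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
_THREE_TO_ONE = {"ARG": "R", "LYS": "K"}


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds and atom conventions for the two selection criteria."""

    salt_bridge_max: float = 4.0
    scissile_max: float = 4.0
    arg_charged_atoms: tuple[str, ...] = ("NH1", "NH2", "NE")
    lys_charged_atoms: tuple[str, ...] = ("NZ",)
    asp_charged_atoms: tuple[str, ...] = ("OD1", "OD2")
    ser_hydroxyl_atom: str = "OG"
    strict_inequality: bool = True

    def __post_init__(self) -> None:
        if self.salt_bridge_max <= 0 or self.scissile_max <= 0:
            raise ValueError("distance thresholds must be positive")

    def passes(self, distance: float, threshold: float) -> bool:
        return distance < threshold if self.strict_inequality else distance <= threshold

    def charged_atoms(self, residue_name: str) -> tuple[str, ...]:
        if residue_name == "ARG":
            return self.arg_charged_atoms
        if residue_name == "LYS":
            return self.lys_charged_atoms
        return ()


@dataclass
class PoseEvaluation:
    """Outcome of the two criteria for one binding mode."""

    pose_id: int
    s1_occupant: int | None
    salt_bridge_distance: float | None
    scissile_distance: float | None
    selected: bool
    reason: str = ""
    per_residue_detail: list[dict] = field(default_factory=list)


def evaluate_pose(
    pose: PeptidePose,
    receptor: ProteaseReceptor,
    criteria: SelectionCriteria | None = None,
    rules: SpecificityRules | None = None,
) -> PoseEvaluation:
    """Apply both selection criteria to one binding mode.

    A peptide without basic residues is reported as not selected (reason
    "no basic residue"), not as an error. A basic residue whose charged
    side-chain atoms are absent from the model is skipped with a warning.
    """
    criteria = criteria or SelectionCriteria()
    rules = rules or SpecificityRules()
    oxygens = receptor.atom_coords(receptor.s1_anchor, criteria.asp_charged_atoms)
    og = receptor.atom_coords(receptor.triad[2], (criteria.ser_hydroxyl_atom,))

    detail: list[dict] = []
    basic_seen = False
    for resnum in pose.residue_numbers():
        resname = pose.residue_atoms(resnum)[0].residue_name
        charged_names = criteria.charged_atoms(resname)
        if not charged_names:
            continue
        basic_seen = True
        charged = pose.atom_coords(resnum, charged_names)
        if charged.size == 0:
            warnings.warn(
                f"pose {pose.pose_id}: basic residue {resnum} ({resname}) lacks "
                f"charged side-chain atoms {charged_names}; skipped",
                stacklevel=2,
            )
            continue
        carbonyl = pose.atom_coords(resnum, ("C",))
        sb = min_group_distance(charged, oxygens)
        sc = min_group_distance(carbonyl, og) if carbonyl.size else np.nan
        detail.append(
            {
                "residue_number": resnum,
                "residue": _THREE_TO_ONE.get(resname, resname),
                "salt_bridge_distance": sb,
                "scissile_distance": sc,
                "salt_bridge_ok": criteria.passes(sb, criteria.salt_bridge_max),
            }
        )

    if not basic_seen:
        return PoseEvaluation(
            pose_id=pose.pose_id,
            s1_occupant=None,
            salt_bridge_distance=None,
            scissile_distance=None,
            selected=False,
            reason="no basic residue",
            per_residue_detail=detail,
        )

    in_pocket = [row for row in detail if row["salt_bridge_ok"]]
    if not in_pocket:
        return PoseEvaluation(
            pose_id=pose.pose_id,
            s1_occupant=None,
            salt_bridge_distance=None,
            scissile_distance=None,
            selected=False,
            reason="no basic residue within salt-bridge distance of S1",
            per_residue_detail=detail,
        )
    # smallest salt-bridge distance wins; ties: P1 preference, then position
    occupant = min(
        in_pocket,
        key=lambda row: (
            row["salt_bridge_distance"],
            rules.preference_rank(row["residue"]),
            row["residue_number"],
        ),
    )
    if np.isnan(occupant["scissile_distance"]):
        raise StructureError(
            f"pose {pose.pose_id}: S1 occupant {occupant['residue_number']} lacks "
            "its backbone carbonyl carbon"
        )
    selected = criteria.passes(occupant["scissile_distance"], criteria.scissile_max)
    return PoseEvaluation(
        pose_id=pose.pose_id,
        s1_occupant=occupant["residue_number"],
        salt_bridge_distance=occupant["salt_bridge_distance"],
        scissile_distance=occupant["scissile_distance"],
        selected=selected,
        reason="" if selected else "scissile carbon too far from catalytic serine",
        per_residue_detail=detail,
    )


def evaluate_pose_set(
    poses: PoseSet,
    receptor: ProteaseReceptor,
    criteria: SelectionCriteria | None = None,
    rules: SpecificityRules | None = None,
) -> list[PoseEvaluation]:
    """Evaluate every pose in an ensemble, preserving pose order."""
    if len(poses) == 0:
        raise EmptyInputError(
            f"ensemble '{poses.peptide_label}' contains no poses"
        )
    evaluations = []
    for pose in poses:
        try:
            evaluations.append(evaluate_pose(pose, receptor, criteria, rules))
        except StructureError as err:
            raise StructureError(
                f"ensemble '{poses.peptide_label}', pose {pose.pose_id}: {err}"
            ) from err
    return evaluations


def evaluations_to_frame(evaluations: list[PoseEvaluation]) -> pd.DataFrame:
    """One row per pose: occupant, both distances, selected flag."""
    return pd.DataFrame(
        [
            {
                "pose_id": ev.pose_id,
                "s1_occupant": ev.s1_occupant,
                "salt_bridge_distance": ev.salt_bridge_distance,
                "scissile_distance": ev.scissile_distance,
                "selected": ev.selected,
                "reason": ev.reason,
            }
            for ev in evaluations
        ]
    )
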