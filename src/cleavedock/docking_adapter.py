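"""Bridge to an external docking engine (AutoDock-Vina-style campaigns).

The engine itself is never a dependency: this module plans a campaign
(grid box centred on the catalytic triad, ten runs of nine modes each by
default), writes the engine's plain-text configuration, and normalises
engine output — per-run multi-model PDB or PDBQT files — into the package's
:class:`~cleavedock.structure_io.PoseSet` so the geometric criteria can be
applied unchanged to real docking output.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import EmptyInputError, PoseFormatError
from .structure_io import (
    Atom,
    PeptidePose,
    PoseSet,
    ProteaseReceptor,
    read_pose_ensemble,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DockingCampaign",
    "plan_campaign",
    "write_engine_config",
    "ingest_engine_output",
    "run_campaign",
]


@dataclass
class DockingCampaign:
    """Configuration of one docking campaign for one peptide window."""

    grid_center: tuple[float, float, float]
    grid_dims: tuple[float, float, float] = (40.0, 25.0, 25.0)
    runs: int = 10
    modes_per_run: int = 9
    seed_list: tuple[int, ...] | None = None
    engine_path: str | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid dimensions must be positive")
        if self.runs < 1 or self.modes_per_run < 1:
            raise ValueError("runs and modes_per_run must be >= 1")

    @property
    def expected_poses(self) -> int:
        return self.runs * self.modes_per_run


def plan_campaign(receptor: ProteaseReceptor, **overrides) -> DockingCampaign:
    """Default campaign: grid centred on the triad-CA centroid, 10×9 modes."""
    if "grid_center" in overrides:
        center = tuple(overrides.pop("grid_center"))
    else:
        cas = [receptor.atom_coords(res, ("CA",)) for res in receptor.triad]
        cas = np.vstack([c for c in cas if c.size])
        center = tuple(float(x) for x in cas.mean(axis=0))
    return DockingCampaign(grid_center=center, **overrides)


def write_engine_config(
    campaign: DockingCampaign,
    receptor_path: str | Path,
    ligand_path: str | Path,
    out_path: str | Path,
    run_index: int = 0,
) -> Path:
    """Write a Vina-style text config for one run (engine defaults elsewhere)."""
    out_path = Path(out_path)
    lines = [
        f"receptor = {receptor_path}",
        f"ligand = {ligand_path}",
        f"center_x = {campaign.grid_center[0]:.3f}",
        f"center_y = {campaign.grid_center[1]:.3f}",
        f"center_z = {campaign.grid_center[2]:.3f}",
        f"size_x = {campaign.grid_dims[0]:.1f}",
        f"size_y = {campaign.grid_dims[1]:.1f}",
        f"size_z = {campaign.grid_dims[2]:.1f}",
        f"num_modes = {campaign.modes_per_run}",
    ]
    if campaign.seed_list is not None:
        lines.append(f"seed = {campaign.seed_list[run_index]}")
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


def ingest_engine_output(
    paths: Sequence[str | Path],
    campaign: DockingCampaign,
    peptide_label: str,
    residue_offset: int = 0,
    receptor_ref: str = "",
) -> PoseSet:
    """Concatenate per-run engine output into one ordered :class:`PoseSet`.

    Pose ids are assigned lexicographically by (run index, mode index) in the
    order the paths are given, regardless of filesystem ordering. A pose
    count differing from the campaign's expectation warns but does not fail.
    """
    if not paths:
        raise EmptyInputError("no engine output files supplied")
    poses: list[PeptidePose] = []
    for run_index, path in enumerate(paths):
        path = Path(path)
        if path.suffix.lower() == ".pdbqt":
            run_poses = _read_pdbqt_models(path, peptide_label, residue_offset)
        else:
            run_poses = read_pose_ensemble(
                path, peptide_label, residue_offset=residue_offset
            ).poses
        for pose in run_poses:
            pose.pose_id = len(poses) + 1
            pose.source = f"{path}#run{run_index + 1}"
            poses.append(pose)
    if len(poses) != campaign.expected_poses:
        warnings.warn(
            f"campaign expected {campaign.expected_poses} poses but "
            f"{len(poses)} were ingested",
            stacklevel=2,
        )
    return PoseSet(receptor_ref=receptor_ref, peptide_label=peptide_label, poses=poses)


# PDBQT: PDB-like ATOM records with partial charge + AutoDock atom type in
# the trailing columns; no installed parser covers it, so the minimal subset
# (MODEL blocks, ATOM/HETATM coordinates, VINA RESULT remarks) is read here.
_AD_TYPE_TO_ELEMENT = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "O": "O", "SA": "S", "S": "S", "P": "P", "H": "H", "HD": "H", "HS": "H",
    "F": "F", "CL": "CL", "BR": "BR", "I": "I",
}


def _read_pdbqt_models(
    path: Path, peptide_label: str, residue_offset: int
) -> list[PeptidePose]:
    models: list[list[Atom]] = []
    scores: list[float | None] = []
    current: list[Atom] | None = None
    score: float | None = None
    for line in path.read_text().splitlines():
        record = line[:6].strip()
        if record == "MODEL":
            current = []
            score = None
        elif record == "ENDMDL":
            if current is None:
                raise PoseFormatError(f"{path}: ENDMDL without MODEL")
            models.append(current)
            scores.append(score)
            current = None
        elif line.startswith("REMARK VINA RESULT:"):
            try:
                score = float(line.split()[3])
            except (IndexError, ValueError):
                score = None
        elif record in ("ATOM", "HETATM"):
            if current is None:  # single-model file without MODEL records
                current = []
                models.append(current)
                scores.append(None)
            try:
                ad_type = line[77:79].strip().upper()
                element = _AD_TYPE_TO_ELEMENT.get(ad_type, ad_type or "C")
                if element == "H":
                    continue
                current.append(
                    Atom(
                        name=line[12:16].strip(),
                        element=element,
                        coords=(
                            float(line[30:38]),
                            float(line[38:46]),
                            float(line[46:54]),
                        ),
                        residue_number=int(line[22:26]) + residue_offset,
                        residue_name=line[17:20].strip(),
                        chain_id=line[21].strip() or "A",
                    )
                )
            except ValueError as err:
                raise PoseFormatError(f"{path}: malformed ATOM record: {line!r}") from err
    if current is not None and current:
        models.append(current)
        scores.append(score)
    if not models:
        raise PoseFormatError(f"{path}: no MODEL/ATOM records found")
    return [
        PeptidePose(
            pose_id=i + 1,
            peptide_label=peptide_label,
            atoms=atoms,
            source=str(path),
            engine_score=scores[i],
        )
        for i, atoms in enumerate(models)
    ]


def run_campaign(
    campaign: DockingCampaign,
    receptor_path: str | Path,
    ligand_path: str | Path,
    workdir: str | Path,
    peptide_label: str,
    residue_offset: int = 0,
) -> PoseSet:
    """Invoke the external engine for every run, then ingest its output.

    Only usable when ``campaign.engine_path`` points at an installed engine
    executable; every invocation is logged verbatim for provenance.
    """
    if not campaign.engine_path or not shutil.which(campaign.engine_path):
        raise EmptyInputError(
            "no docking engine configured; set campaign.engine_path"
        )
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out_paths = []
    for run_index in range(campaign.runs):
        config = write_engine_config(
            campaign, receptor_path, ligand_path,
            workdir / f"run_{run_index + 1:02d}.conf", run_index,
        )
        out = workdir / f"run_{run_index + 1:02d}_out.pdbqt"
        cmd = [campaign.engine_path, "--config", str(config), "--out", str(out)]
        logger.info("docking run %d: %s", run_index + 1, " ".join(cmd))
        subprocess.run(cmd, check=True, capture_output=True)
        out_paths.append(out)
    return ingest_engine_output(
        out_paths, campaign, peptide_label, residue_offset=residue_offset
    )
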