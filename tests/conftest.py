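import pytest

from cleavedock import (
    SubstrateSequence,
    SyntheticEnsembleConfig,
    make_ensemble,
    make_mock_receptor,
)

# The distal region of the gamma-subunit assembled from its published
# segments (K168, 169-GKARDF-174, 175-FTGR-178, 177-GRKRKV-182,
# 187-IHKASN-192); residues 183-186 are not published and are represented
# by the unknown placeholder X.
DISTAL_REGION = "KGKARDFFTGRKRKVXXXXIHKASN"
DISTAL_START = 168

# Residues 134-192 assembled the same way, adding the furin-region segment
# 135-RKRR-138 and the key inhibitory 11-mer 153-RFSHRIPLLIF-163.
def _full_residues() -> str:
    residues = ["X"] * (192 - 134 + 1)

    def put(start: int, segment: str) -> None:
        for i, aa in enumerate(segment):
            residues[start + i - 134] = aa

    put(135, "RKRR")
    put(153, "RFSHRIPLLIF")
    put(168, DISTAL_REGION[: 193 - 168])
    return "".join(residues)


@pytest.fixture(scope="session")
def mock_receptor():
    return make_mock_receptor()


@pytest.fixture(scope="session")
def distal_seq():
    return SubstrateSequence("gamma_distal", DISTAL_REGION, start_number=DISTAL_START)


@pytest.fixture(scope="session")
def full_seq():
    return SubstrateSequence("gamma_134_192", _full_residues(), start_number=134)


@pytest.fixture(scope="session")
def small_ensemble(mock_receptor):
    """30-pose GKARDF ensemble, 40% productive, occupant R172, seed 7."""
    config = SyntheticEnsembleConfig(
        peptide_window="GKARDF",
        peptide_start=169,
        occupant_position=172,
        n_poses=30,
        productive_fraction=0.4,
        seed=7,
    )
    pose_set, labels = make_ensemble(config, mock_receptor)
    return config, pose_set, labels
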