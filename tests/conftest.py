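import numpy as np
import pytest

from sterolsites import (
    Atom,
    PlantedMotif,
    Pose,
    PoseEnsemble,
    VdwRadiiTable,
    make_tetramer,
)


@pytest.fixture(scope="session")
def vdw() -> VdwRadiiTable:
    return VdwRadiiTable()


@pytest.fixture(scope="session")
def tetramer():
    """Small C4 tetramer with one planted CRAC motif (V440–Y443–R445)."""
    structure, truth = make_tetramer(
        res_per_helix=30,
        motif_spec=[PlantedMotif("CRAC", 440, 2, 1, letters=("V", "Y", "R"))],
        seed=7,
    )
    return structure, truth


def single_atom_pose(position, element="C", label="probe") -> Pose:
    return Pose(atoms=[Atom(1, element.upper() + "1", element, np.asarray(position, float))], label=label)


def multi_atom_pose(coords, label="pose", energy=None, lgfe=None) -> Pose:
    atoms = [Atom(i + 1, f"C{i + 1}", "C", np.asarray(c, float)) for i, c in enumerate(coords)]
    return Pose(atoms=atoms, energy=energy, lgfe=lgfe, label=label)


def ensemble_from_coords(coord_sets, energies=None, lgfes=None) -> PoseEnsemble:
    poses = []
    for i, coords in enumerate(coord_sets):
        poses.append(
            multi_atom_pose(
                coords,
                label=f"p{i}",
                energy=None if energies is None else energies[i],
                lgfe=None if lgfes is None else lgfes[i],
            )
        )
    return PoseEnsemble(ligand_name="LIG", poses=poses)
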