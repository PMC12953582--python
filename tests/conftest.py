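import numpy as np
import pytest

from glycomem import AtomRecord, Frame, Trajectory


def make_atom(aid, name="CA", resname="ALA", resnum=1, chain="A",
              pos=(0.0, 0.0, 0.0), b=None):
    return AtomRecord(aid, name, resname, resnum, chain, np.asarray(pos, float),
                      b_factor=b)


def make_traj(frames_atoms, times=None):
    """Build a Trajectory from a list of per-frame atom lists."""
    frames = [
        Frame(index=i, atoms=atoms,
              time_ns=None if times is None else times[i])
        for i, atoms in enumerate(frames_atoms)
    ]
    return Trajectory(frames)


@pytest.fixture
def bilayer_traj():
    """Two frames, four phosphates at z = ±20, plus a glycan axis."""
    def frame_atoms(tilt_vec):
        atoms = [
            make_atom(1, "P", "DSP", 1, "M", (0, 0, 20.0)),
            make_atom(2, "P", "DSP", 2, "M", (10, 0, 20.0)),
            make_atom(3, "P", "DSP", 3, "M", (0, 10, -20.0)),
            make_atom(4, "P", "DSP", 4, "M", (10, 10, -20.0)),
            make_atom(5, "C1", "GAL", 5, "G", (5, 5, 20.0)),
            make_atom(6, "C2", "SIA", 6, "G", np.array([5, 5, 20.0]) + tilt_vec),
            make_atom(7, "C3", "SIA", 6, "G", np.array([5, 5, 20.0]) + tilt_vec),
        ]
        return atoms

    return make_traj([frame_atoms(np.array([0, 0, 5.0])),
                      frame_atoms(np.array([0, 3.0, 4.0]))])
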