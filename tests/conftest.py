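"""Shared fixtures: hand-built molecular fragments and generated data."""

import numpy as np
import pytest

from chelastab.geometry import ComplexStructure


def _hexagon_ring(attach: np.ndarray, outward: np.ndarray, side: float = 1.39):
    """Vertices of a regular hexagon: first vertex at ``attach``, ring center
    displaced along ``outward``.  Returns the five remaining vertices."""
    outward = outward / np.linalg.norm(outward)
    # in-plane tangent perpendicular to outward (ring in the z=0-like plane)
    t = np.cross(outward, [0.0, 0.0, 1.0])
    if np.linalg.norm(t) < 1e-8:
        t = np.cross(outward, [0.0, 1.0, 0.0])
    t /= np.linalg.norm(t)
    center = attach + side * outward
    verts = []
    for k in range(1, 6):
        ang = k * np.pi / 3
        verts.append(center + side * (-np.cos(ang) * outward + np.sin(ang) * t))
    return verts


@pytest.fixture
def mixed_donor_complex():
    """La center with one donor of each rule-covered class, hand-placed.

    Donors: carboxylate O (acetate-like O-C(-O) fragment), water O,
    amine N (three methyl C), pyridine N (full six-ring), amide O
    (O on a C bonded to N), ether O (two C neighbours).
    """
    syms = ["La"]
    crd = [np.zeros(3)]
    expected = {}

    # carboxylate along +x: O1 at 2.50; C at 3.79; terminal O2 off-axis
    expected[len(syms)] = "O_carboxylate"
    syms += ["O", "C", "O"]
    crd += [np.array([2.50, 0, 0]), np.array([3.79, 0, 0]),
            np.array([3.79 + 0.625, 1.0825, 0])]

    # water along +y
    expected[len(syms)] = "O_water"
    syms += ["O", "H", "H"]
    h = 0.96
    a = np.radians(52.25)
    crd += [np.array([0, 2.60, 0]),
            np.array([h * np.sin(a), 2.60 + h * np.cos(a), 0]),
            np.array([-h * np.sin(a), 2.60 + h * np.cos(a), 0])]

    # amine along -x: N + three C, lone pair toward metal
    expected[len(syms)] = "N_amine"
    syms += ["N", "C", "C", "C"]
    npos = np.array([-2.75, 0, 0])
    th = np.radians(70.5)
    crd.append(npos)
    for az in (0, 2 * np.pi / 3, 4 * np.pi / 3):
        d = np.array([-np.cos(th), np.sin(th) * np.cos(az), np.sin(th) * np.sin(az)])
        crd.append(npos + 1.47 * d)

    # pyridine along -y: N plus five ring C
    expected[len(syms)] = "N_pyridine"
    npy = np.array([0, -2.65, 0])
    syms += ["N"] + ["C"] * 5
    crd += [npy] + _hexagon_ring(npy, np.array([0.0, -1.0, 0.0]))

    # amide O along +z: O-C(-N), N capped with two H
    expected[len(syms)] = "O_amide"
    syms += ["O", "C", "N", "H", "H"]
    crd += [np.array([0, 0, 2.55]), np.array([0, 0, 3.78]),
            np.array([1.16, 0, 4.45]), np.array([1.2, 0, 5.45]),
            np.array([2.0, 0, 3.9])]

    # ether O along -z: O with two C
    expected[len(syms)] = "O_ether"
    syms += ["O", "C", "C"]
    crd += [np.array([0, 0, -2.58]), np.array([1.16, 0, -3.25]),
            np.array([-1.16, 0, -3.25])]

    return ComplexStructure("mixed", tuple(syms), np.vstack(crd), 0), expected


@pytest.fixture
def xyz_file(tmp_path):
    """A minimal valid 3-atom XYZ file with a La center."""
    p = tmp_path / "lao.xyz"
    p.write_text("3\nminimal\nLa 0 0 0\nO 2.5 0 0\nH 3.3 0.8 0\n")
    return p
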