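import numpy as np
import pytest

from tetrelscan import HelixSpec, build_backbone, default_calibration_model


def pdb_line(
    serial,
    name,
    resname,
    chain,
    resseq,
    xyz,
    element=None,
    altloc=" ",
    hetatm=False,
    occupancy=1.00,
    icode=" ",
):
    record = "HETATM" if hetatm else "ATOM  "
    element = element or name[0]
    x, y, z = xyz
    return (
        f"{record}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}{resseq:>4}"
        f"{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00"
        f"          {element:>2}"
    )


def make_residue_lines(resseq, resname, origin, chain="A", serial_start=1,
                       hetatm=False, skip=()):
    """Four backbone atoms of one residue at plausible relative positions."""
    ox, oy, oz = origin
    coords = {
        "N": (ox, oy, oz),
        "CA": (ox + 1.458, oy, oz),
        "C": (ox + 2.0, oy + 1.4, oz),
        "O": (ox + 2.0, oy + 1.4, oz + 1.231),
    }
    lines = []
    serial = serial_start
    for name in ("N", "CA", "C", "O"):
        if name in skip:
            continue
        lines.append(
            pdb_line(serial, name, resname, chain, resseq, coords[name],
                     hetatm=hetatm)
        )
        serial += 1
    return lines


@pytest.fixture
def three_ala_pdb():
    lines = []
    serial = 1
    for i in range(3):
        res = make_residue_lines(i + 1, "ALA", (i * 3.8, 0.0, 0.0),
                                 serial_start=serial)
        serial += len(res)
        lines += res
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture
def table1_points_2_to_6():
    """(ρ×100, ΔE) pairs of the reference complexes entering the regression."""
    return [
        ("2", 0.63, -1.7),
        ("3", 0.60, -1.4),
        ("4", 0.69, -1.9),
        ("5", 0.50, -0.9),
        ("6", 0.61, -1.7),
    ]


@pytest.fixture(scope="session")
def default_model():
    return default_calibration_model()


@pytest.fixture(scope="session")
def ideal_helix_frame():
    return build_backbone(HelixSpec(n_residues=12))


def random_carbonyl_frame(rng, n, spread=8.0):
    """Random frame of well-formed carbonyls inside a box (test helper)."""
    from tetrelscan import BackboneCarbonyl

    frame = []
    for i in range(n):
        c = rng.uniform(-spread, spread, 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        o = c + 1.231 * direction
        frame.append(
            BackboneCarbonyl(
                chain_id="A",
                residue_number=i + 1,
                residue_name="ALA",
                c_coord=c,
                o_coord=o,
                ca_coord=c + rng.normal(scale=0.5, size=3),
            )
        )
    return frame
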