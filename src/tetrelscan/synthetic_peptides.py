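"""Synthetic backbone structures and ensembles with controlled helicity.

Frames are built in internal coordinates (NeRF-style) from φ/ψ/ω dihedrals
and fixed standard peptide geometry.  With the default dihedrals
(φ = −57°, ψ = −47°, ω = 180°) and zero noise the chain is an ideal
α helix (rise ≈ 1.5 Å per residue, ≈ 3.6 residues per turn), whose
consecutive O(i)···C(i+1) separations fall in the tetrel-bonding range.
Per-residue Gaussian noise on φ and ψ broadens the conformational
distribution; large noise (σ ≈ 40°) produces coil-like ensembles with broad
carbonyl-distance distributions.  The noise model is deliberately simple
(independent Gaussian perturbations, not Ramachandran-basin sampling) and
is non-physical; it exists to create a controllable ordered/disordered
contrast.

Ensembles are deterministic: frame ``i`` of an ensemble uses a sub-seed
derived from ``spec.seed`` and ``i`` through a splitmix-style mixer, so
regenerating or extending an ensemble reproduces identical coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .structure_io import BackboneCarbonyl, StructureEnsemble

__all__ = [
    "HelixSpec",
    "GEOMETRY",
    "build_backbone",
    "build_ensemble",
    "ensemble_to_pdb",
    "mix_seed",
]

#: Standard peptide backbone geometry (bond lengths in Å, angles in degrees).
GEOMETRY = {
    "bond_N_CA": 1.458,
    "bond_CA_C": 1.525,
    "bond_C_N": 1.329,
    "bond_C_O": 1.231,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.2,
    "angle_C_N_CA": 121.7,
    "angle_CA_C_O": 120.8,
}


@dataclass(frozen=True)
class HelixSpec:
    """Backbone dihedral specification for a synthetic peptide ensemble."""

    n_residues: int = 12
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0
    noise_sigma: float = 0.0  # degrees, sd of per-residue Gaussian dihedral noise
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def mix_seed(seed: int, index: int) -> int:
    """Derive a per-frame sub-seed via a splitmix64-style finalizer."""
    z = (seed + 0x9E3779B97F4A7C15 * (index + 1)) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0x7FFFFFFF


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """Position atom d from reference atoms a-b-c and internal coordinates."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(dihedral) * np.sin(angle),
            bond * np.sin(dihedral) * np.sin(angle),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(spec: HelixSpec, rng: np.random.Generator | None):
    """Return (N, CA, C, O) coordinate arrays, each (n_residues, 3)."""
    g = GEOMETRY
    n = spec.n_residues
    if rng is not None and spec.noise_sigma > 0:
        phis = spec.phi + rng.normal(0.0, spec.noise_sigma, size=n)
        psis = spec.psi + rng.normal(0.0, spec.noise_sigma, size=n)
    else:
        phis = np.full(n, spec.phi)
        psis = np.full(n, spec.psi)

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))

    # first residue: N at origin, CA on x, C in the xy plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g["bond_N_CA"], 0.0, 0.0)
    ang = np.radians(180.0 - g["angle_N_CA_C"])
    C[0] = CA[0] + g["bond_CA_C"] * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(n):
        # carbonyl O is planar with the next amide N: dihedral N-CA-C-O = ψ+180
        O[i] = _place_atom(
            N[i], CA[i], C[i], g["bond_C_O"], g["angle_CA_C_O"], psis[i] + 180.0
        )
        if i == n - 1:
            break
        N[i + 1] = _place_atom(
            N[i], CA[i], C[i], g["bond_C_N"], g["angle_CA_C_N"], psis[i]
        )
        CA[i + 1] = _place_atom(
            CA[i], C[i], N[i + 1], g["bond_N_CA"], g["angle_C_N_CA"], spec.omega
        )
        C[i + 1] = _place_atom(
            C[i], N[i + 1], CA[i + 1], g["bond_CA_C"], g["angle_N_CA_C"], phis[i + 1]
        )
    return N, CA, C, O


def build_backbone(spec: HelixSpec, frame_seed: int | None = None,
                   model_index: int = 0) -> list[BackboneCarbonyl]:
    """Build one frame of backbone carbonyls from dihedral specifications.

    Deterministic: the same spec and ``frame_seed`` give bit-identical
    coordinates.  With ``frame_seed=None`` and ``noise_sigma=0`` the frame is
    the noise-free ideal chain.
    """
    rng = None
    if frame_seed is not None and spec.noise_sigma > 0:
        rng = np.random.default_rng(frame_seed)
    N, CA, C, O = _build_chain(spec, rng)
    return [
        BackboneCarbonyl(
            chain_id="A",
            residue_number=i + 1,
            residue_name="ALA",
            c_coord=C[i],
            o_coord=O[i],
            ca_coord=CA[i],
            model_index=model_index,
        )
        for i in range(spec.n_residues)
    ]


def build_ensemble(spec: HelixSpec) -> StructureEnsemble:
    """Generate ``spec.n_frames`` independent frames as a StructureEnsemble."""
    frames = [
        build_backbone(spec, frame_seed=mix_seed(spec.seed, i), model_index=i)
        for i in range(spec.n_frames)
    ]
    label = (
        f"synthetic(n={spec.n_residues}, phi={spec.phi}, psi={spec.psi}, "
        f"sigma={spec.noise_sigma}, frames={spec.n_frames}, seed={spec.seed})"
    )
    return StructureEnsemble(frames=frames, source_label=label)


def ensemble_to_pdb(spec: HelixSpec) -> str:
    """Render the ensemble of a spec as multi-model PDB text (N/CA/C/O atoms)."""
    arrays = []
    for i in range(spec.n_frames):
        rng = None
        seed = mix_seed(spec.seed, i)
        if spec.noise_sigma > 0:
            rng = np.random.default_rng(seed)
        N, CA, C, O = _build_chain(spec, rng)
        n_res = spec.n_residues
        atoms = bst.AtomArray(4 * n_res)
        coords = np.empty((4 * n_res, 3))
        for r in range(n_res):
            coords[4 * r: 4 * r + 4] = [N[r], CA[r], C[r], O[r]]
        atoms.coord = coords
        atoms.chain_id = np.full(4 * n_res, "A")
        atoms.res_id = np.repeat(np.arange(1, n_res + 1), 4)
        atoms.res_name = np.full(4 * n_res, "ALA")
        atoms.atom_name = np.tile(np.array(["N", "CA", "C", "O"]), n_res)
        atoms.element = np.tile(np.array(["N", "C", "C", "O"]), n_res)
        arrays.append(atoms)
    stack = bst.stack(arrays)
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    buffer = io.StringIO()
    pdb_file.write(buffer)
    return buffer.getvalue()
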