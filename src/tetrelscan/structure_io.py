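"""Reading multi-model PDB structures and writing contact reports.

The unit of interest is the backbone carbonyl: the C and O atoms of one
residue, plus the Cα when present.  Extraction is atom-name based ("C" and
"O"), not residue-name based, so non-natural residues used in stapled
peptides (MK8, 0EH, 2JH, ...) and protonation variants (HIE) are captured
alongside the twenty standard amino acids.  Waters and monoatomic het
groups are excluded.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

import numpy as np
from biotite.structure.io.pdb import PDBFile

from .exceptions import (
    EmptyStructureError,
    MissingAtomWarning,
    ParseError,
    RosterMismatchWarning,
)

__all__ = [
    "BackboneCarbonyl",
    "StructureEnsemble",
    "parse_structure",
    "write_contacts",
    "contacts_from_json",
]

# Residue names that never yield a backbone carbonyl.
_EXCLUDED_RESNAMES = {"HOH", "WAT"}

# Plausible C=O bond length window (Å); records outside are rejected.
_CO_BOND_MIN = 1.0
_CO_BOND_MAX = 1.6


@dataclass(frozen=True)
class BackboneCarbonyl:
    """One residue's C=O unit with coordinates and residue identity.

    ``residue_number`` keeps the author numbering of the source file;
    an insertion code, when present, is concatenated into the textual
    label but kept separately for sorting.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    c_coord: np.ndarray
    o_coord: np.ndarray
    ca_coord: np.ndarray | None = None
    model_index: int = 0
    insertion_code: str = ""

    def __post_init__(self):
        object.__setattr__(self, "c_coord", np.asarray(self.c_coord, dtype=float))
        object.__setattr__(self, "o_coord", np.asarray(self.o_coord, dtype=float))
        if self.ca_coord is not None:
            object.__setattr__(self, "ca_coord", np.asarray(self.ca_coord, dtype=float))
        bond = float(np.linalg.norm(self.c_coord - self.o_coord))
        if not (_CO_BOND_MIN < bond < _CO_BOND_MAX):
            raise ValueError(
                f"C=O bond of {self.residue_name} {self.chain_id}{self.residue_number}"
                f" is {bond:.3f} Å, outside ({_CO_BOND_MIN}, {_CO_BOND_MAX})"
            )

    @property
    def residue_label(self) -> str:
        """Author residue number with any insertion code appended."""
        return f"{self.residue_number}{self.insertion_code}"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class StructureEnsemble:
    """An ordered set of frames, each a list of backbone carbonyls.

    Frames are expected to share a carbonyl roster; if they do not, the
    intersection roster is used and a :class:`RosterMismatchWarning` is
    emitted.
    """

    frames: list[list[BackboneCarbonyl]]
    source_label: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def shared_roster(self) -> list[tuple[str, int, str]]:
        """Keys of carbonyls present in every frame, in first-frame order."""
        common = set(c.key for c in self.frames[0])
        for frame in self.frames[1:]:
            common &= {c.key for c in frame}
        return [c.key for c in self.frames[0] if c.key in common]


def _validate_pdb_lines(text: str) -> None:
    """Cheap structural validation so errors carry a line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError("coordinate record truncated", lineno)
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError:
            raise ParseError("unparsable coordinates in record", lineno) from None


def parse_structure(pdb_source: str | Path | TextIO) -> StructureEnsemble:
    """Read a (possibly multi-model) PDB file into a :class:`StructureEnsemble`.

    One frame is produced per MODEL record (a single frame if the file has
    none).  Every residue possessing atoms named ``C`` and ``O`` yields a
    :class:`BackboneCarbonyl` regardless of residue name; HETATM records are
    included when the atom names match, so stapled-peptide residues are kept.
    Altloc conflicts resolve to the highest-occupancy conformer (ties broken
    by altloc letter).

    Raises
    ------
    ParseError
        On malformed ATOM/HETATM records, naming the line number.
    EmptyStructureError
        If no carbonyl at all can be extracted.
    """
    if isinstance(pdb_source, Path):
        text = pdb_source.read_text()
        label = pdb_source.name
    elif isinstance(pdb_source, str):
        if "\n" in pdb_source or pdb_source.startswith(("ATOM", "HETATM", "MODEL")):
            text = pdb_source
            label = "<string>"
        else:
            text = Path(pdb_source).read_text()
            label = pdb_source
    else:
        text = pdb_source.read()
        label = getattr(pdb_source, "name", "<stream>")

    _validate_pdb_lines(text)

    pdb_file = PDBFile.read(io.StringIO(text))
    try:
        n_models = pdb_file.get_model_count()
    except Exception as exc:  # pragma: no cover - biotite internals
        raise ParseError(str(exc)) from exc

    frames: list[list[BackboneCarbonyl]] = []
    for model in range(1, n_models + 1):
        try:
            atoms = pdb_file.get_structure(model=model, altloc="occupancy")
        except Exception as exc:
            raise ParseError(f"model {model}: {exc}") from exc
        frames.append(_extract_carbonyls(atoms, model_index=model - 1))

    if all(len(frame) == 0 for frame in frames):
        raise EmptyStructureError(f"no backbone carbonyls found in {label}")

    rosters = [frozenset(c.key for c in frame) for frame in frames]
    if len(set(rosters)) > 1:
        warnings.warn(
            "frames differ in carbonyl roster; analyses will use the intersection",
            RosterMismatchWarning,
            stacklevel=2,
        )

    return StructureEnsemble(frames=frames, source_label=label)


def _extract_carbonyls(atoms, model_index: int) -> list[BackboneCarbonyl]:
    carbonyls: list[BackboneCarbonyl] = []
    seen: set[tuple[str, int, str]] = set()
    ins = (
        atoms.ins_code
        if "ins_code" in atoms.get_annotation_categories()
        else np.full(atoms.array_length(), "", dtype="U1")
    )

    # Group atom indices by residue identity, preserving file order.
    order: list[tuple[str, int, str, str]] = []
    groups: dict[tuple[str, int, str, str], dict[str, np.ndarray]] = {}
    counts: dict[tuple[str, int, str, str], int] = {}
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]), str(ins[i]).strip(),
               str(atoms.res_name[i]))
        if key not in groups:
            groups[key] = {}
            counts[key] = 0
            order.append(key)
        counts[key] += 1
        name = str(atoms.atom_name[i])
        if name in ("C", "O", "CA") and name not in groups[key]:
            groups[key][name] = atoms.coord[i]

    for chain, resnum, icode, resname in order:
        if resname in _EXCLUDED_RESNAMES:
            continue
        key4 = (chain, resnum, icode, resname)
        if counts[key4] == 1:  # monoatomic het group (ions)
            continue
        found = groups[key4]
        if "C" not in found or "O" not in found:
            warnings.warn(
                f"residue {resname} {chain}{resnum}{icode} lacks C or O; skipped",
                MissingAtomWarning,
                stacklevel=3,
            )
            continue
        ident = (chain, resnum, icode)
        if ident in seen:
            raise ParseError(
                f"duplicate residue {chain}{resnum}{icode} in model {model_index}"
            )
        seen.add(ident)
        try:
            carbonyls.append(
                BackboneCarbonyl(
                    chain_id=chain,
                    residue_number=resnum,
                    residue_name=resname,
                    c_coord=found["C"],
                    o_coord=found["O"],
                    ca_coord=found.get("CA"),
                    model_index=model_index,
                    insertion_code=icode,
                )
            )
        except ValueError as exc:
            warnings.warn(str(exc), MissingAtomWarning, stacklevel=3)
    return carbonyls


# ---------------------------------------------------------------------------
# contact report output

_CONTACT_COLUMNS = [
    "chain_i", "res_i", "name_i",
    "chain_j", "res_j", "name_j",
    "d_OC", "theta", "separation", "rho_est", "dE_est",
]


def _contact_row(contact) -> dict:
    donor, acceptor = contact.donor, contact.acceptor
    return {
        "chain_i": donor.chain_id,
        "res_i": donor.residue_label,
        "name_i": donor.residue_name,
        "chain_j": acceptor.chain_id,
        "res_j": acceptor.residue_label,
        "name_j": acceptor.residue_name,
        "d_OC": f"{contact.d_OC:.3f}",
        "theta": f"{contact.theta_BD:.1f}",
        "separation": "" if contact.separation is None else str(contact.separation),
        "rho_est": "" if contact.rho_est is None else f"{contact.rho_est:.2f}",
        "dE_est": "" if contact.dE_est is None else _fmt_energy(contact.dE_est),
    }


def _fmt_energy(value: float) -> str:
    # one decimal, halves away from zero, matching table precision
    import decimal

    return str(
        decimal.Decimal(repr(value)).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )


def write_contacts(contacts: list, format_choice: str = "tsv") -> str:
    """Serialize detected contacts to TSV or JSON text.

    Column order is fixed; distances are rendered to 3 decimals and energies
    to 1 decimal.  An empty contact list yields a header-only TSV (or an
    empty JSON array).
    """
    rows = [_contact_row(c) for c in contacts]
    if format_choice == "tsv":
        lines = ["\t".join(_CONTACT_COLUMNS)]
        lines += ["\t".join(row[col] for col in _CONTACT_COLUMNS) for row in rows]
        return "\n".join(lines) + "\n"
    if format_choice == "json":
        return json.dumps(rows, indent=1)
    raise ValueError(f"unknown output format {format_choice!r}; use 'tsv' or 'json'")


def contacts_from_json(text: str) -> list[dict]:
    """Parse a JSON contact report back into its row dictionaries."""
    return json.loads(text)
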