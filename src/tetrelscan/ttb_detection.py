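"""Geometric detection of C=O···C=O tetrel-bond contacts.

A contact pairs a donor carbonyl, whose oxygen supplies the lone pair, with
an acceptor carbonyl, whose carbon exposes the π-hole.  Two criteria apply:
the O···C distance must fall under a cutoff (default 3.6 Å, slightly above
the largest tetrel-bond distance seen in helical peptides and near the O/C
van-der-Waals sum), and the O···C=O approach angle must lie inside a window
around the Bürgi–Dunitz trajectory (~107°; default window 95–125°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import BackboneCarbonyl

__all__ = [
    "TtBContact",
    "DEFAULT_CUTOFF",
    "DEFAULT_ANGLE_WINDOW",
    "detect_contacts",
    "pairwise_consecutive_distances",
    "approach_angle",
]

DEFAULT_CUTOFF = 3.6  # Å
DEFAULT_ANGLE_WINDOW = (95.0, 125.0)  # degrees
CHAIN_BREAK_CA_DISTANCE = 4.5  # Å; Cα(i)-Cα(i+1) beyond this flags a break


@dataclass
class TtBContact:
    """A detected O(i)···C(j) contact.

    ``separation`` is the acceptor-minus-donor residue offset along the
    chain (None for inter-chain contacts); its sign records the direction
    of donation, positive meaning the oxygen donates into a *subsequent*
    carbonyl, the canonical helical direction.
    """

    donor: BackboneCarbonyl
    acceptor: BackboneCarbonyl
    d_OC: float
    theta_BD: float
    separation: int | None
    model_index: int = 0
    rho_est: float | None = None
    dE_est: float | None = None


def approach_angle(o_donor: np.ndarray, c_acc: np.ndarray, o_acc: np.ndarray) -> float:
    """Angle O_donor···C_acceptor=O_acceptor in degrees.

    Degenerate (zero-length) vectors are treated via the colinear limit and
    return 0° or 180° without division by zero.
    """
    v1 = np.asarray(o_donor, float) - np.asarray(c_acc, float)
    v2 = np.asarray(o_acc, float) - np.asarray(c_acc, float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 180.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def detect_contacts(
    frame: list[BackboneCarbonyl],
    cutoff: float = DEFAULT_CUTOFF,
    angle_window: tuple[float, float] = DEFAULT_ANGLE_WINDOW,
    min_separation: int = 1,
) -> list[TtBContact]:
    """Find every ordered donor→acceptor carbonyl pair forming a contact.

    Each pair must satisfy ``d(O_donor, C_acceptor) <= cutoff``, an approach
    angle inside ``angle_window`` and ``|separation| >= min_separation`` for
    same-chain pairs.  Both directions of a geometric pair are examined and
    reported independently.  The result is sorted by donor chain, donor
    residue, then acceptor chain and residue.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lo, hi = angle_window
    if not (0.0 < lo < hi < 180.0):
        raise ValueError("angle_window must be an interval inside (0, 180)")

    contacts: list[TtBContact] = []
    for donor in frame:
        for acceptor in frame:
            if donor is acceptor or donor.key == acceptor.key:
                continue
            if donor.chain_id == acceptor.chain_id:
                separation = acceptor.residue_number - donor.residue_number
                if abs(separation) < min_separation:
                    continue
            else:
                separation = None
            d = float(np.linalg.norm(donor.o_coord - acceptor.c_coord))
            if d > cutoff:
                continue
            theta = approach_angle(donor.o_coord, acceptor.c_coord, acceptor.o_coord)
            if not (lo <= theta <= hi):
                continue
            contacts.append(
                TtBContact(
                    donor=donor,
                    acceptor=acceptor,
                    d_OC=d,
                    theta_BD=theta,
                    separation=separation,
                    model_index=donor.model_index,
                )
            )
    contacts.sort(
        key=lambda c: (
            c.donor.chain_id,
            c.donor.residue_number,
            c.donor.insertion_code,
            c.acceptor.chain_id,
            c.acceptor.residue_number,
            c.acceptor.insertion_code,
        )
    )
    return contacts


def pairwise_consecutive_distances(
    frame: list[BackboneCarbonyl],
    return_flags: bool = False,
):
    """O(i)···C(i+1) distances for consecutive residue pairs of each chain.

    Returns a mapping ``"{res_i}-{res_j}" -> distance`` (labels prefixed with
    the chain id when the frame spans several chains).  With
    ``return_flags=True`` a set of labels whose Cα(i)–Cα(i+1) distance
    exceeds 4.5 Å (a chain break) is returned as well.
    """
    chains: dict[str, list[BackboneCarbonyl]] = {}
    for cb in frame:
        chains.setdefault(cb.chain_id, []).append(cb)
    multi_chain = len(chains) > 1

    distances: dict[str, float] = {}
    breaks: set[str] = set()
    for chain_id, members in chains.items():
        members = sorted(members, key=lambda c: (c.residue_number, c.insertion_code))
        for a, b in zip(members, members[1:]):
            label = f"{a.residue_label}-{b.residue_label}"
            if multi_chain:
                label = f"{chain_id}:{label}"
            distances[label] = float(np.linalg.norm(a.o_coord - b.c_coord))
            if (
                a.ca_coord is not None
                and b.ca_coord is not None
                and np.linalg.norm(a.ca_coord - b.ca_coord) > CHAIN_BREAK_CA_DISTANCE
            ):
                breaks.add(label)
    if return_flags:
        return distances, breaks
    return distances
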