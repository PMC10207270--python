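"""Distance distributions and RMSD clustering over structural ensembles.

The per-residue-pair distribution of consecutive O(i)···C(i+1) distances
across frames distinguishes ordered (narrow, short-centered) from
disordered (broad) ensembles.  Frames can additionally be grouped by
agglomerative average-linkage clustering on pairwise best-fit RMSD with an
ε distance stop, the usual treatment of MD trajectory frames; clusters are
reported most-populated first (cluster 0 = largest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .structure_io import StructureEnsemble
from .exceptions import TetrelScanError

__all__ = [
    "EnsembleDistribution",
    "ClusterConfig",
    "ClusterResult",
    "distance_distributions",
    "cluster_frames",
    "superpose_rmsd",
]


@dataclass
class EnsembleDistribution:
    """Distance samples of one consecutive residue pair over an ensemble.

    Frames in which the pair is missing are counted in ``n_absent`` rather
    than contributing zeros.
    """

    pair_label: str
    distances: list[float]
    n_absent: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.distances, [25, 75])
        return float(q3 - q1)

    @property
    def narrowness(self) -> float:
        """IQR relative to the median; small values mean a narrow distribution."""
        return self.iqr / self.median


@dataclass(frozen=True)
class ClusterConfig:
    """Frame-clustering parameters: ε merge threshold and atom selection."""

    epsilon: float = 2.0  # Å
    atom_selection: str = "CA"  # "CA" or "CA+CB"
    linkage: str = "average"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.atom_selection not in ("CA", "CA+CB"):
            raise ValueError("atom_selection must be 'CA' or 'CA+CB'")


@dataclass
class ClusterResult:
    cluster_id: int
    members: list[int]  # frame indices
    centroid: int  # frame index minimizing summed RMSD to co-members

    @property
    def size(self) -> int:
        return len(self.members)


def distance_distributions(
    ensemble: StructureEnsemble, weighting: str = "uniform"
) -> list[EnsembleDistribution]:
    """Per-consecutive-pair O(i)···C(i+1) distance distributions.

    Every frame carries identical weight (no ensemble reweighting).  Pairs
    are taken from the roster shared by all frames; a pair contributes one
    sample per frame in which both residues are present.
    """
    if weighting != "uniform":
        raise ValueError("only uniform frame weighting is supported")
    if ensemble.n_frames < 1:
        raise ValueError("ensemble must contain at least one frame")
    if not ensemble.shared_roster():
        raise TetrelScanError("frames share no carbonyls; roster intersection empty")

    # consecutive pairs over the union roster: a pair missing from a frame is
    # recorded as absent there rather than silently dropped everywhere
    union: set[tuple[str, int, str]] = set()
    for frame in ensemble.frames:
        union.update(cb.key for cb in frame)
    by_chain: dict[str, list[tuple[str, int, str]]] = {}
    for key in sorted(union, key=lambda k: (k[0], k[1], k[2])):
        by_chain.setdefault(key[0], []).append(key)
    pairs = []
    for chain_keys in by_chain.values():
        pairs.extend(zip(chain_keys, chain_keys[1:]))

    # index frames by carbonyl key once
    frame_maps = [{cb.key: cb for cb in frame} for frame in ensemble.frames]

    out = []
    for key_i, key_j in pairs:
        distances: list[float] = []
        n_absent = 0
        label = None
        for fmap in frame_maps:
            a = fmap.get(key_i)
            b = fmap.get(key_j)
            if a is None or b is None:
                n_absent += 1
                continue
            if label is None:
                label = (
                    f"{a.residue_name} {a.residue_label} – "
                    f"{b.residue_name} {b.residue_label}"
                )
            distances.append(float(np.linalg.norm(a.o_coord - b.c_coord)))
        out.append(
            EnsembleDistribution(
                pair_label=label or f"{key_i[1]}-{key_j[1]}",
                distances=distances,
                n_absent=n_absent,
            )
        )
    return out


def superpose_rmsd(
    frame_a: np.ndarray, frame_b: np.ndarray, superposition: bool = True
) -> float:
    """Least-squares best-fit RMSD between two ordered coordinate sets.

    With ``superposition=True`` (default) the sets are centered and the
    optimal proper rotation (Kabsch-type, reflections excluded) is applied
    before measuring; the result is symmetric in its arguments.  With
    ``superposition=False`` the raw coordinate RMSD is returned.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need at least 3 atoms of shape (n, 3)")
    if not superposition:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    # align_vectors solves the orthogonal Procrustes problem with a proper
    # rotation (the reflection guard for degenerate/planar sets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exact alignments warn about rank
        rot, _ = Rotation.align_vectors(a, b)
    residual = rot.apply(b) - a
    return float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))


def _frame_coordinates(ensemble: StructureEnsemble, config: ClusterConfig):
    """Stack the selected atom coordinates of each frame over the shared roster."""
    roster = ensemble.shared_roster()
    if not roster:
        raise TetrelScanError("frames share no carbonyls; cannot cluster")
    if config.atom_selection == "CA+CB":
        # the carbonyl model carries no Cβ; degrade to Cα with notice
        warnings.warn(
            "CB atoms unavailable in carbonyl frames; falling back to CA-only RMSD",
            UserWarning,
            stacklevel=3,
        )
    frames = []
    bad = []
    for idx, frame in enumerate(ensemble.frames):
        fmap = {cb.key: cb for cb in frame}
        coords = []
        for key in roster:
            cb = fmap[key]
            if cb.ca_coord is None:
                bad.append(idx)
                break
            coords.append(cb.ca_coord)
        else:
            frames.append(np.asarray(coords))
    if bad:
        raise TetrelScanError(f"frames lacking Cα coordinates: {bad}")
    counts = {f.shape[0] for f in frames}
    if len(counts) > 1:
        raise TetrelScanError(f"mismatched atom counts across frames: {sorted(counts)}")
    return frames


def cluster_frames(
    ensemble: StructureEnsemble, config: ClusterConfig | None = None
) -> list[ClusterResult]:
    """Agglomerative average-linkage clustering of frames by best-fit RMSD.

    Merging stops once the minimum inter-cluster (average-linkage) distance
    exceeds ``config.epsilon``.  Clusters are sorted by size descending and
    re-labelled 0, 1, 2, ...; each cluster's centroid is the member frame
    minimizing the summed RMSD to its co-members.
    """
    config = config or ClusterConfig()
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames to cluster")
    coords = _frame_coordinates(ensemble, config)
    n = len(coords)

    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = superpose_rmsd(coords[i], coords[j])

    z = linkage(squareform(dmat, checks=False), method=config.linkage)
    labels = fcluster(z, t=config.epsilon, criterion="distance")

    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx)

    results = []
    for members in sorted(clusters.values(), key=lambda m: (-len(m), m[0])):
        sub = dmat[np.ix_(members, members)]
        centroid = members[int(np.argmin(sub.sum(axis=0)))]
        results.append(ClusterResult(cluster_id=len(results), members=members,
                                     centroid=centroid))
    return results
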