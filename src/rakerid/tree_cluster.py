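"""Neighbor-joining trees, bootstrap supports, cluster calls and the gap summary.

The tree side of the pipeline: build an unrooted NJ tree from a K2P distance
matrix, attach bipartition-frequency bootstrap supports, carve out
single-species monophyletic clusters, assign queries by best identity against
a reference panel, and summarise intra- vs inter-specific divergence ranges.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .barcode_core import (
    BarcodeError,
    DistanceMatrix,
    ReferencePanel,
    SaturationError,
    SequenceRecord,
    UNKNOWN,
    encode_panel,
    identity_fraction,
    pairwise_counts,
)

UNRESOLVED = "UNRESOLVED"
UNASSIGNED = "UNASSIGNED"

#: Genus whose species cannot be separated by either marker; calls are
#: reported with a complex-level caveat flag instead of being refined.
COMPLEX_GENERA = ("Manta",)


class TreeError(ValueError):
    pass


@dataclass
class TreeNode:
    """Node of a rooted representation of an unrooted tree.

    ``children`` pairs each child with the length of the edge above it;
    ``support`` is the bootstrap percentage of that same edge (internal
    edges only).
    """

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal rooting."""

    root: TreeNode

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(self.root.leaves())

    def splits(self) -> dict[frozenset[str], float | None]:
        """Nontrivial bipartitions keyed by the side excluding the smallest leaf.

        Anchoring on the lexicographically smallest leaf name makes keys
        comparable across trees over the same leaf set regardless of input
        order. Values are the bootstrap support of the corresponding edge
        (None if unannotated).
        """
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out: dict[frozenset[str], float | None] = {}
        for node, _parent in _edges(self.root):
            side = frozenset(node.leaves())
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            key = side if anchor not in side else all_leaves - side
            out[key] = node.support
        return out

    def clades(self) -> list[tuple[frozenset[str], float]]:
        """Both sides of every edge, paired with that edge's support.

        Unannotated edges and trivial (single-leaf / full-complement) sides
        are included; leaf edges and the full leaf set get support 100 by
        convention (they are splits the data cannot contradict).
        """
        all_leaves = frozenset(self.leaf_names)
        out: list[tuple[frozenset[str], float]] = [(all_leaves, 100.0)]
        for node, _parent in _edges(self.root):
            side = frozenset(node.leaves())
            other = all_leaves - side
            if len(side) == 1 or len(other) == 1:
                sup = 100.0
            else:
                sup = node.support if node.support is not None else 100.0
            out.append((side, sup))
            if other:
                out.append((other, sup))
        return out

    def to_newick(self) -> str:
        return _newick(self.root) + ";"


def _edges(root: TreeNode):
    """Yield (child, parent) over every edge of the rooted representation."""
    stack = [root]
    while stack:
        node = stack.pop()
        for child, _ in node.children:
            yield child, node
            stack.append(child)


def _newick(node: TreeNode) -> str:
    if node.is_leaf:
        return node.name
    inner = ",".join(f"{_newick(c)}:{ln:.6f}" for c, ln in node.children)
    label = "" if node.support is None else f"{node.support:g}"
    return f"({inner}){label}"


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining on the Q-criterion.

    Ties on the Q-criterion are broken by the lexicographically smallest
    index pair in the current matrix. Negative branch lengths are clamped to
    zero with the deficit moved to the sibling edge so path lengths through
    the joined pair are preserved.
    """
    D = np.asarray(dm.d, dtype=float).copy()
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise TreeError("need at least 2 taxa")
    if not np.allclose(D, D.T) or not np.all(np.isfinite(D)):
        raise TreeError("distance matrix must be symmetric and finite")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    if n == 2:
        half = D[0, 1] / 2.0
        root = TreeNode(children=[(nodes[0], half), (nodes[1], half)])
        return PhyloTree(root)

    while len(nodes) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Qc = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Qc[iu]
        k = int(np.argmin(flat))  # first minimum = lexicographically smallest (i, j)
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[: m - 2, m - 2] = dnew[keep]
        D2[m - 2, : m - 2] = dnew[keep]
        D2[m - 2, m - 2] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [new]

    # terminal trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    l0, l1, l2 = _clamp_trio(l0, l1, l2)
    root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return PhyloTree(root)


def _clamp_pair(a: float, b: float) -> tuple[float, float]:
    if a < 0:
        b = max(b + a, 0.0)
        a = 0.0
    elif b < 0:
        a = max(a + b, 0.0)
        b = 0.0
    return a, b


def _clamp_trio(a: float, b: float, c: float) -> tuple[float, float, float]:
    vals = [a, b, c]
    for idx in range(3):
        if vals[idx] < 0:
            deficit = vals[idx]
            vals[idx] = 0.0
            other = max(range(3), key=lambda x: vals[x])
            vals[other] = max(vals[other] + deficit, 0.0)
    return tuple(vals)  # type: ignore[return-value]


def bootstrap_support(
    records: Sequence[SequenceRecord], replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """Reference NJ tree annotated with bipartition-frequency supports.

    Alignment columns are resampled with replacement per replicate; a
    replicate whose resampled matrix yields an undefined (saturated or
    incomparable) distance is discarded and counted, with a warning if more
    than 10% are lost.
    """
    if replicates < 1:
        raise TreeError("replicates must be >= 1")
    from .barcode_core import distance_matrix  # local import avoids cycle at module load

    ref_dm = distance_matrix(records)
    ref_tree = neighbor_joining(ref_dm)
    ids = tuple(r.id for r in records)
    codes = encode_panel(records)
    L = codes.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in ref_tree.splits()}
    used = 0
    discarded = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        try:
            dm = _matrix_from_codes(codes[:, cols], ids)
            tree = neighbor_joining(dm)
        except (SaturationError, BarcodeError):
            discarded += 1
            continue
        used += 1
        for split in tree.splits():
            if split in counts:
                counts[split] += 1
    if used == 0:
        raise TreeError("all bootstrap replicates produced undefined distances")
    if discarded > 0.1 * replicates:
        warnings.warn(
            f"{discarded}/{replicates} bootstrap replicates discarded "
            "(undefined distances)",
            stacklevel=2,
        )
    all_leaves = frozenset(ids)
    anchor = min(all_leaves)
    for node, _parent in _edges(ref_tree.root):
        side = frozenset(node.leaves())
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        key = side if anchor not in side else all_leaves - side
        node.support = 100.0 * counts[key] / used
    return ref_tree


def _matrix_from_codes(codes: np.ndarray, ids: tuple[str, ...]) -> DistanceMatrix:
    n_sites, ts, tv = pairwise_counts(codes)
    n = codes.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(n_sites[off] == 0):
        raise BarcodeError("no comparable sites in resampled pair")
    safe = np.where(n_sites == 0, 1, n_sites)
    P = np.where(off, ts / safe, 0.0)
    Q = np.where(off, tv / safe, 0.0)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if np.any((w1 <= 0.0) | (w2 <= 0.0)):
        raise SaturationError("K2P distance undefined (saturation)")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d, n_sites, P, Q)


@dataclass(frozen=True)
class ClusterAssignment:
    cluster_id: str
    members: tuple[str, ...]
    species_call: str
    support: float
    complex_caveat: bool = False


def _is_complex(species: str) -> bool:
    genus = species.split("_")[0].split(" ")[0]
    return genus in COMPLEX_GENERA


def extract_clusters(
    tree: PhyloTree, refs: ReferencePanel, min_support: float = 99.0
) -> list[ClusterAssignment]:
    """Maximal single-species monophyletic clusters at a support threshold.

    Every side of every edge whose references are all one species and whose
    edge support reaches ``min_support`` is a candidate; maximal candidates
    (not nested inside another) become clusters named for that species.
    Leaves outside all clusters form a trailing UNRESOLVED cluster.
    """
    species_of = refs.species_map()
    leaf_names = tree.leaf_names
    if not any(l in species_of for l in leaf_names):
        raise TreeError("tree contains no reference leaves")
    candidates: list[tuple[frozenset[str], str, float]] = []
    for side, sup in tree.clades():
        ref_species = {species_of[l] for l in side if l in species_of}
        if len(ref_species) == 1 and sup >= min_support:
            candidates.append((side, next(iter(ref_species)), sup))
    candidates.sort(key=lambda c: -len(c[0]))
    chosen: list[tuple[frozenset[str], str, float]] = []
    for side, sp, sup in candidates:
        if any(side <= taken for taken, _, _ in chosen):
            continue
        chosen.append((side, sp, sup))
    clusters = []
    covered: set[str] = set()
    for k, (side, sp, sup) in enumerate(
        sorted(chosen, key=lambda c: (-len(c[0]), c[1]))
    ):
        clusters.append(
            ClusterAssignment(
                cluster_id=f"C{k + 1}",
                members=tuple(sorted(side)),
                species_call=sp,
                support=sup,
                complex_caveat=_is_complex(sp),
            )
        )
        covered |= side
    leftovers = tuple(sorted(set(leaf_names) - covered))
    if leftovers:
        clusters.append(
            ClusterAssignment(
                cluster_id=f"C{len(clusters) + 1}",
                members=leftovers,
                species_call=UNRESOLVED,
                support=0.0,
            )
        )
    return clusters


@dataclass(frozen=True)
class IdentityAssignment:
    species: str
    identity: float
    best_ref: str | None = None
    tied_refs: tuple[str, ...] = ()
    complex_caveat: bool = False


def assign_by_identity(
    query: SequenceRecord, refs: ReferencePanel, min_identity: float = 0.99
) -> IdentityAssignment:
    """Best-identity species call against the panel (local BLAST stand-in).

    Identity is matching/compared sites under pairwise deletion. Ties on the
    best identity are broken by panel order and reported in ``tied_refs``.
    """
    panel_records = refs.records(query.marker)
    best: SequenceRecord | None = None
    best_ident = -1.0
    tied: list[str] = []
    for ref in panel_records:
        ident = identity_fraction(query, ref)
        if ident > best_ident + 1e-12:
            best, best_ident, tied = ref, ident, []
        elif abs(ident - best_ident) <= 1e-12 and best is not None:
            tied.append(ref.id)
    assert best is not None
    if best_ident < min_identity:
        return IdentityAssignment(UNASSIGNED, best_ident, best.id, tuple(tied))
    sp = refs.species_of(best.id)
    return IdentityAssignment(sp, best_ident, best.id, tuple(tied), _is_complex(sp))


@dataclass(frozen=True)
class GapSummary:
    """Intra-/inter-specific K2P distance ranges for one marker, in % (100·d)."""

    intra_min: float
    intra_max: float
    inter_min: float
    inter_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.intra_min <= self.intra_max):
            raise ValueError("intra range invalid")
        if not (0 <= self.inter_min <= self.inter_max):
            raise ValueError("inter range invalid")

    @property
    def gap_exists(self) -> bool:
        return self.intra_max < self.inter_min


def barcoding_gap(dm: DistanceMatrix, labels: Mapping[str, str]) -> GapSummary:
    """Within- vs between-species distance ranges; UNKNOWN ids are excluded."""
    known = [
        (i, labels[lab])
        for i, lab in enumerate(dm.labels)
        if labels.get(lab, UNKNOWN) != UNKNOWN
    ]
    if not known:
        raise TreeError("all ids are UNKNOWN; cannot summarise the barcoding gap")
    intra: list[float] = []
    inter: list[float] = []
    for a in range(len(known)):
        for b in range(a + 1, len(known)):
            i, sp_i = known[a]
            j, sp_j = known[b]
            (intra if sp_i == sp_j else inter).append(dm.d[i, j])
    if not intra or not inter:
        raise TreeError(
            "need at least one within-species and one between-species pair"
        )
    return GapSummary(
        intra_min=float(100.0 * min(intra)),
        intra_max=float(100.0 * max(intra)),
        inter_min=float(100.0 * min(inter)),
        inter_max=float(100.0 * max(inter)),
    )
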