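"""Unrefined four-step assembly: sort, split, all-pairs alignment, OLC.

The layout is greedy best-edge-first: significant pairwise overlaps are
processed in order of increasing p-value and merged with a union-find
structure that carries each molecule's coordinate transform (orientation
and offset) into its component's frame.  An edge that contradicts an
existing placement by more than ``placement_tolerance_bp`` is rejected.
The consensus step clusters the member molecules' label positions in the
contig frame and keeps clusters supported by a sufficient fraction of the
local molecule coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .align import AlignParams, PairAlignment, ScoreNull, align_pair, DEFAULT_MAX_SKIP
from .io_formats import MapContig, Molecule, MoleculeSet

PLACEMENT_TOLERANCE_BP = 2000.0
MERGE_RADIUS_BP = 800.0
MIN_OCCURRENCE_FRAC = 0.25


@dataclass(frozen=True)
class Placement:
    contig_id: int
    offset_bp: float
    orientation: str  # "+" | "-"


@dataclass
class AssemblyResult:
    """Contigs plus the placement or singleton status of every molecule."""

    contigs: list[MapContig]
    placements: dict[int, Placement]
    singletons: set[int]
    params: object | None = None

    def conservation_ok(self, filtered: MoleculeSet) -> bool:
        return set(self.placements) | self.singletons == set(filtered.ids) and not (
            set(self.placements) & self.singletons
        )


# ---------------------------------------------------------------------------
# steps 1-3: filter, sort, split, all-pairs
# ---------------------------------------------------------------------------

def filter_molecules(
    ms: MoleculeSet, min_length_kbp: float, min_labels: int
) -> MoleculeSet:
    """Keep molecules with length >= min_length_kbp and labels >= min_labels
    (both inclusive); order preserved."""
    kept = [
        m
        for m in ms.molecules
        if m.length_bp >= min_length_kbp * 1000.0 and m.n_labels >= min_labels
    ]
    return MoleculeSet(kept, dict(ms.metadata))


def sort_molecules(ms: MoleculeSet) -> MoleculeSet:
    """Stable sort by descending length, ties by ascending id."""
    kept = sorted(ms.molecules, key=lambda m: (-m.length_bp, m.molecule_id))
    return MoleculeSet(kept, dict(ms.metadata))


def split_molecules(ms: MoleculeSet, n_chunks: int) -> list[MoleculeSet]:
    """Round-robin split over the given (sorted) order, balancing total
    length across chunks."""
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    chunks: list[list[Molecule]] = [[] for _ in range(n_chunks)]
    for i, m in enumerate(ms.molecules):
        chunks[i % n_chunks].append(m)
    return [MoleculeSet(c, dict(ms.metadata)) for c in chunks]


def all_pairs_overlaps(
    chunks: Sequence[MoleculeSet],
    p: AlignParams,
    null: ScoreNull,
    max_skip: int = DEFAULT_MAX_SKIP,
) -> list[PairAlignment]:
    """Align every unordered molecule pair (within and across chunks) and
    keep alignments with p-value <= ``p.pvalue_threshold``.

    The result is independent of the chunking: pairs are enumerated in a
    canonical id order, so any chunk layout yields the same set.
    """
    mols: dict[int, Molecule] = {}
    for chunk in chunks:
        for m in chunk:
            if m.molecule_id in mols:
                raise ValueError(f"molecule {m.molecule_id} in more than one chunk")
            mols[m.molecule_id] = m
    retained: list[PairAlignment] = []
    for id_a, id_b in combinations(sorted(mols), 2):
        al = align_pair(mols[id_a], mols[id_b], p, max_skip=max_skip)
        if al is None:
            continue
        pv = null.pvalue(al.score)
        if pv <= p.pvalue_threshold:
            retained.append(al.with_pvalue(pv))
    return retained


# ---------------------------------------------------------------------------
# step 4: overlap-layout-consensus
# ---------------------------------------------------------------------------

class _Frames:
    """Union-find over molecules carrying affine transforms x -> s*x + t
    from each molecule's native coordinates into its root's frame."""

    def __init__(self, ids: Iterable[int]):
        self.parent = {i: i for i in ids}
        self.rank = {i: 0 for i in ids}
        self.sign = {i: 1 for i in ids}
        self.shift = {i: 0.0 for i in ids}

    def find(self, x: int) -> tuple[int, int, float]:
        """Returns (root, s, t) with root_coord = s * x_coord + t."""
        path = []
        while self.parent[x] != x:
            path.append(x)
            x = self.parent[x]
        # accumulate transforms root-ward, then compress the path
        s_acc: dict[int, tuple[int, float]] = {x: (1, 0.0)}
        for node in reversed(path):
            ps, pt = s_acc[self.parent[node]]
            s_acc[node] = (ps * self.sign[node], ps * self.shift[node] + pt)
        for node in path:
            self.parent[node] = x
            self.sign[node], self.shift[node] = s_acc[node]
        if path:
            first = path[0]
            return x, self.sign[first], self.shift[first]
        return x, 1, 0.0

    def transform(self, x: int) -> tuple[int, int, float]:
        root, _, _ = self.find(x)
        if x == root:
            return root, 1, 0.0
        return root, self.sign[x], self.shift[x]

    def union(self, ra: int, rb: int, s: int, t: float) -> None:
        """Attach root rb under root ra with x_ra = s * x_rb + t."""
        if self.rank[ra] < self.rank[rb]:
            # attach ra under rb with the inverse transform
            ra, rb = rb, ra
            s, t = s, -s * t  # inverse of x -> s x + t is x -> s x - s t
        self.parent[rb] = ra
        self.sign[rb] = s
        self.shift[rb] = t
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def _edge_transform(al: PairAlignment, len_b: float) -> tuple[int, float]:
    """Mapping from b's native coordinates into a's frame implied by the
    alignment: x_a = s * x_b + t."""
    if al.orientation == "forward":
        return 1, al.offset_bp
    return -1, al.offset_bp + len_b


def _cluster_labels(
    coords: np.ndarray,
    mol_of: np.ndarray,
    radius: float,
) -> list[tuple[float, int, np.ndarray]]:
    """Single-linkage chains split at their largest internal gaps until each
    cluster spans at most 2*radius.  Returns (mean position, #distinct
    molecules, member indices) per cluster."""
    order = np.argsort(coords, kind="stable")
    coords, mol_of = coords[order], mol_of[order]
    out: list[tuple[float, int, np.ndarray]] = []

    def emit(lo: int, hi: int) -> None:  # [lo, hi)
        if hi - lo == 0:
            return
        width = coords[hi - 1] - coords[lo]
        if width > 2.0 * radius and hi - lo > 1:
            gaps = np.diff(coords[lo:hi])
            cut = lo + 1 + int(np.argmax(gaps))
            emit(lo, cut)
            emit(cut, hi)
            return
        members = np.arange(lo, hi)
        out.append(
            (
                float(np.mean(coords[lo:hi])),
                len(set(mol_of[lo:hi].tolist())),
                members,
            )
        )

    start = 0
    for k in range(1, coords.size + 1):
        if k == coords.size or coords[k] - coords[k - 1] > radius:
            emit(start, k)
            start = k
    out.sort(key=lambda c: c[0])
    return out


def assemble_olc(
    ms: MoleculeSet,
    overlaps: Sequence[PairAlignment],
    placement_tolerance_bp: float = PLACEMENT_TOLERANCE_BP,
    merge_radius_bp: float = MERGE_RADIUS_BP,
    min_occurrence_frac: float = MIN_OCCURRENCE_FRAC,
    params: object | None = None,
) -> AssemblyResult:
    """Greedy overlap-layout-consensus over significant pairwise overlaps.

    Edges are applied best (lowest p-value) first; an edge whose implied
    placement contradicts the current layout by more than
    ``placement_tolerance_bp`` is rejected.  Components of one molecule
    are singletons.  Consensus labels are cluster means of the member
    molecules' transformed labels; a cluster is kept when the number of
    distinct molecules observing it reaches
    ``max(1, ceil(min_occurrence_frac x local coverage))``.
    """
    mols = ms.by_id()
    for al in overlaps:
        if al.id_a not in mols or al.id_b not in mols:
            raise ValueError(f"overlap references unknown molecule {al.id_a}/{al.id_b}")

    frames = _Frames(mols)
    accepted: set[int] = set()
    edge_order = sorted(
        overlaps,
        key=lambda al: (al.pvalue, -al.score, min(al.id_a, al.id_b), max(al.id_a, al.id_b)),
    )
    for al in edge_order:
        s_e, t_e = _edge_transform(al, mols[al.id_b].length_bp)
        ra, sa, ta = frames.transform(al.id_a)
        rb, sb, tb = frames.transform(al.id_b)
        # b-native -> ra-frame via the edge: x_ra = sa*(s_e*x_b + t_e) + ta
        s_new, t_new = sa * s_e, sa * t_e + ta
        if ra == rb:
            if s_new == sb and abs(t_new - tb) <= placement_tolerance_bp:
                accepted.add(al.id_a)
                accepted.add(al.id_b)
            continue
        # express rb-native in ra-frame: x_b = sb*x_rb + ... invert b->rb
        # x_rb = sb * x_b - sb * tb  =>  x_b = sb * x_rb + sb * (-tb) ... careful:
        # b->rb: x_rb = sb*x_b + tb  =>  x_b = sb*(x_rb - tb) = sb*x_rb - sb*tb
        s_r = s_new * sb
        t_r = -s_new * sb * tb + t_new
        frames.union(ra, rb, s_r, t_r)
        accepted.add(al.id_a)
        accepted.add(al.id_b)

    # group members by root
    components: dict[int, list[int]] = {}
    for mol_id in mols:
        root, _, _ = frames.transform(mol_id)
        components.setdefault(root, []).append(mol_id)

    # multi-member components become contigs; a member joins a component
    # only through an accepted union, so every member sits on an accepted edge
    spec_list = [(root, members) for root, members in components.items() if len(members) >= 2]

    contig_data = []
    for root, members in spec_list:
        # transforms into root frame
        tf = {m: frames.transform(m)[1:] for m in members}
        # re-anchor: longest member forward, leftmost molecule start at 0
        anchor = max(members, key=lambda m: (mols[m].length_bp, -m))
        if tf[anchor][0] == -1:
            tf = {m: (-s, -t) for m, (s, t) in tf.items()}
        starts = []
        for m in members:
            s, t = tf[m]
            ends = (t, s * mols[m].length_bp + t)
            starts.append(min(ends))
        shift = min(starts)
        tf = {m: (s, t - shift) for m, (s, t) in tf.items()}
        intervals = {}
        coords_all, mol_all = [], []
        for m in members:
            s, t = tf[m]
            e0, e1 = t, s * mols[m].length_bp + t
            intervals[m] = (min(e0, e1), max(e0, e1))
            pos = s * np.asarray(mols[m].labels_bp) + t
            coords_all.append(pos)
            mol_all.append(np.full(pos.size, m))
        coords = np.concatenate(coords_all)
        mol_of = np.concatenate(mol_all)
        length = max(hi for _, hi in intervals.values())
        clusters = _cluster_labels(coords, mol_of, merge_radius_bp)

        lo_arr = np.array([intervals[m][0] for m in members])
        hi_arr = np.array([intervals[m][1] for m in members])
        labels, occ, cov = [], [], []
        tol = merge_radius_bp
        for pos, n_mols, _ in clusters:
            coverage = int(np.sum((lo_arr - tol <= pos) & (pos <= hi_arr + tol)))
            coverage = max(coverage, n_mols)
            need = max(1, math.ceil(min_occurrence_frac * coverage))
            if n_mols < need:
                continue
            labels.append(pos)
            occ.append(n_mols)
            cov.append(coverage)
        # round to the output precision, then drop collisions so positions
        # stay strictly increasing
        rounded = [round(x, 1) for x in labels]
        keep_i = [0] if rounded else []
        for i in range(1, len(rounded)):
            if rounded[i] > rounded[keep_i[-1]]:
                keep_i.append(i)
        contig_data.append(
            (
                length,
                tuple(rounded[i] for i in keep_i),
                tuple(occ[i] for i in keep_i),
                tuple(cov[i] for i in keep_i),
                tf,
                members,
            )
        )

    # contig ids in descending length
    contig_data.sort(key=lambda c: -c[0])
    contigs: list[MapContig] = []
    placements: dict[int, Placement] = {}
    for cid, (length, labels, occ, cov, tf, members) in enumerate(contig_data, start=1):
        contigs.append(MapContig(cid, float(round(length, 1)), labels, occ, cov))
        for m in members:
            s, t = tf[m]
            offset = t if s == 1 else t - mols[m].length_bp
            placements[m] = Placement(cid, float(offset), "+" if s == 1 else "-")

    singletons = {mol_id for mol_id in mols if mol_id not in placements}
    return AssemblyResult(contigs, placements, singletons, params)
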