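"""Independent oracles shared across test modules.

Everything here is deliberately written the slow, obvious way (nested loops,
full enumeration) so it stays independent of the library's vectorised code
paths.
"""

from __future__ import annotations

import numpy as np

from plastec.encoding import ROISearchSpace, SubRegion, SubRegionalPair


def fake_srp(nc1: int, nc2: int, size_a: int = 2, size_b: int = 2) -> SubRegionalPair:
    """A sub-regional pair with given counts and arbitrary geometry."""
    sub_a = SubRegion(roi_name="A", root_voxel=(0, 0, 0), members=np.arange(size_a))
    sub_b = SubRegion(roi_name="B", root_voxel=(0, 0, 0), members=np.arange(size_b))
    return SubRegionalPair(subA=sub_a, subB=sub_b, NC1=nc1, NC2=nc2)


def srp_from_members(members_a, members_b, **kw) -> SubRegionalPair:
    sub_a = SubRegion(roi_name="A", root_voxel=(0, 0, 0), members=np.asarray(members_a))
    sub_b = SubRegion(roi_name="B", root_voxel=(0, 0, 0), members=np.asarray(members_b))
    return SubRegionalPair(subA=sub_a, subB=sub_b, **kw)


def bh_stepup_oracle(pvalues, q):
    """Literal Benjamini-Hochberg step-up enumeration."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * q / m:
            k_star = rank
    if k_star == 0:
        return [False] * m
    threshold = p[order[k_star - 1]]
    return [pi <= threshold for pi in p]


def fitness_oracle(nc1, nc2, tc):
    """Direct transcription of the binomial z-score objective."""
    p1 = nc1 / tc
    p1 = min(max(p1, 0.5 / tc), 1 - 0.5 / tc)
    ec2 = p1 * tc
    sd = (tc * p1 * (1 - p1)) ** 0.5
    if nc2 == nc1:
        return 0.0
    return abs((nc2 - ec2) / sd)


def is_six_connected(voxels: np.ndarray) -> bool:
    """Union-find check that a voxel set forms one 6-connected component."""
    voxels = [tuple(int(c) for c in v) for v in np.asarray(voxels)]
    index = {v: i for i, v in enumerate(voxels)}
    parent = list(range(len(voxels)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for v in voxels:
        for off in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in index:
                ri, rj = find(index[v]), find(index[w])
                parent[ri] = rj
    return len({find(i) for i in range(len(voxels))}) == 1


def enumerate_decoded_pairs(space_a: ROISearchSpace, space_b: ROISearchSpace):
    """All distinct decodable sub-region member sets per ROI.

    Returns (sets_a, sets_b) as lists of index arrays; every decodable
    sub-regional pair is the cross product.
    """

    def subregion_sets(space):
        seen = {}
        for root in range(len(space.roi)):
            order = space.bfs_order(root)
            for L in space.lattice.values:
                members = order[: L + 1]
                seen.setdefault(frozenset(members.tolist()), members)
        return list(seen.values())

    return subregion_sets(space_a), subregion_sets(space_b)


def brute_force_max_fitness(sets_a, sets_b, m1, m2):
    """Exhaustive maximum of the objective over all decodable pairs."""
    best = 0.0
    for ma in sets_a:
        row1 = m1[ma].sum(axis=0)
        row2 = m2[ma].sum(axis=0)
        for mb in sets_b:
            nc1 = int(row1[mb].sum())
            nc2 = int(row2[mb].sum())
            best = max(best, fitness_oracle(nc1, nc2, len(ma) * len(mb)))
    return best


def truth_tagged_set(block) -> frozenset:
    return frozenset(("A", int(v)) for v in block.a_members) | frozenset(
        ("B", int(v)) for v in block.b_members
    )
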