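"""Independent brute-force reference implementations used as oracles.

These deliberately use the most literal formulation of each operation
(explicit loops, all 27 periodic images, all-pairs comparisons) and
share no code with the package internals beyond numpy.
"""

from __future__ import annotations

import itertools

import numpy as np

DIST_RESOLUTION = 1e-9   # Å; threshold comparison resolution (matches package)
ANGLE_RESOLUTION = 1e-7  # degrees


def min_image_27(a: np.ndarray, b: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Displacement b-a minimised over all 27 explicit image shifts."""
    best = None
    best_n = np.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        shift = np.array([sx, sy, sz]) * lengths
        d = (b + shift) - a
        n = float(np.dot(d, d))
        if n < best_n:
            best_n = n
            best = d
    return best


def brute_msd(pos: np.ndarray, max_frames: int, stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Literal double loop over origins and lags.  pos: (T, M, 3)."""
    T, M, _ = pos.shape
    values = np.zeros(max_frames)
    counts = np.zeros(max_frames, dtype=int)
    for m in range(1, max_frames + 1):
        total = 0.0
        n = 0
        for t0 in range(0, T - m, stride):
            for mol in range(M):
                d = pos[t0 + m, mol] - pos[t0, mol]
                total += float(d @ d)
                n += 1
        values[m - 1] = total / n
        counts[m - 1] = n
    return values, counts


def _angle(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def brute_hbonds(coords, topology, lengths, max_ha=2.8, min_donor=120.0, min_acceptor=90.0):
    """Literal triple loop over (donor, hydrogen, acceptor) with the same
    geometric tests (same threshold resolution) as the detector."""
    found = set()
    for h in np.flatnonzero(topology.donor_h):
        heavies = topology.heavy_neighbors(h)
        assert len(heavies) == 1
        d = int(heavies[0])
        for a in np.flatnonzero(topology.acceptor):
            a = int(a)
            if a == d or a == h:
                continue
            if topology.molecule_ids[d] == topology.molecule_ids[a]:
                if topology.species[d] == "water":
                    continue
                if topology.bond_path_within(d, a, 3):
                    continue
            ha = min_image_27(coords[h], coords[a], lengths)
            if not float(np.linalg.norm(ha)) < max_ha - DIST_RESOLUTION:
                continue
            hd = min_image_27(coords[h], coords[d], lengths)
            if _angle(hd, ha) < min_donor - ANGLE_RESOLUTION:
                continue
            ok = True
            for x in topology.heavy_neighbors(a):
                ax = min_image_27(coords[a], coords[int(x)], lengths)
                if _angle(-ha, ax) < min_acceptor - ANGLE_RESOLUTION:
                    ok = False
                    break
            if ok:
                found.add((d, int(h), a))
    return found


def brute_clusters(opos: np.ndarray, lengths: np.ndarray, cutoff: float) -> set[frozenset]:
    """All-pairs union-find over minimum-image O-O distances."""
    n = len(opos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = min_image_27(opos[i], opos[j], lengths)
            if float(np.linalg.norm(d)) <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}
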