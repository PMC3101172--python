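"""Shared fixtures and an independent random-tree oracle for the suite."""

from __future__ import annotations

import numpy as np
import pytest

from mosaicscreen.msa import Alignment
from mosaicscreen.taxonomy import default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture()
def small_alignment():
    return Alignment.from_records([
        ("Euglena_gracilis",     "MKV-LSTAGA"),
        ("Galdieria_sulphuraria", "MKVALSTAGA"),
        ("Ostreococcus_tauri",   "MKVALSV-GA"),
        ("Synechocystis_sp",     "MRVALSVAGA"),
    ])


# ---------------------------------------------------------------------------
# Independent tree oracle: random binary trees as nested tuples, with
# brute-force leaf-to-leaf path distances.  Deliberately shares no code with
# the package's tree engine.
# ---------------------------------------------------------------------------

def random_binary_topology(rng: np.random.Generator, labels: list[str],
                           lo: float = 0.1, hi: float = 2.0):
    """Grow a random binary tree: ((name, length) leaves, tuple internals)."""
    nodes = [("leaf", lab, float(rng.uniform(lo, hi))) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(("node", (a, b), float(rng.uniform(lo, hi))))
    kind, content, _ = nodes[0]
    return nodes[0]


def _leaf_depths(node):
    kind, content, length = node
    if kind == "leaf":
        return [(content, length)]
    out = []
    for child in content:
        out.extend((lab, d + length) for lab, d in _leaf_depths(child))
    return out


def oracle_distance_matrix(root) -> tuple[list[str], np.ndarray]:
    """Path-length matrix by brute-force recursion over the tuple tree."""
    def pairs(node):
        kind, content, _ = node
        if kind == "leaf":
            return {}, [(content, 0.0)]
        dists: dict[tuple[str, str], float] = {}
        sides = []
        for child in content:
            sub_d, sub_l = pairs(child)
            dists.update(sub_d)
            ckind, ccontent, clength = child
            sides.append([(lab, d + clength) for lab, d in sub_l])
        for li in range(len(sides)):
            for lj in range(li + 1, len(sides)):
                for la, da in sides[li]:
                    for lb, db in sides[lj]:
                        key = tuple(sorted((la, lb)))
                        dists[key] = da + db
        merged = [x for side in sides for x in side]
        return dists, merged

    dists, leaves = pairs(root)
    labels = sorted(lab for lab, _ in leaves)
    n = len(labels)
    mat = np.zeros((n, n))
    for (la, lb), d in dists.items():
        i, j = labels.index(la), labels.index(lb)
        mat[i, j] = mat[j, i] = d
    return labels, mat


def oracle_bipartitions(root) -> set[frozenset]:
    """Internal splits of the tuple tree, canonicalised to the side not
    containing the lexicographically smallest leaf."""
    all_leaves = frozenset(lab for lab, _ in _leaf_depths(root))
    ref = min(all_leaves)
    n = len(all_leaves)
    splits: set[frozenset] = set()

    def walk(node, is_root):
        kind, content, _ = node
        if kind == "leaf":
            return frozenset((content,))
        below = frozenset()
        for child in content:
            below |= walk(child, False)
        if not is_root and 2 <= len(below) <= n - 2:
            side = below if ref not in below else all_leaves - below
            splits.add(side)
        return below

    walk(root, True)
    return splits
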