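import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from io import StringIO

import ecoassembly as ea


@pytest.fixture
def toy_tree():
    return TreeNode.read(StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def toy_dist(toy_tree):
    return ea.patristic_distances(toy_tree)


@pytest.fixture
def random_tree():
    def make(n_tips=20, seed=0):
        return ea.simulate_tree(n_tips, seed=seed)

    return make


@pytest.fixture
def small_table(tmp_path):
    """2 samples x 3 OTUs TSV on disk plus the expected frame."""
    df = pd.DataFrame(
        [[5, 0, 1], [0, 2, 2]], index=["s1", "s2"], columns=["o1", "o2", "o3"]
    )
    path = tmp_path / "table.tsv"
    df.to_csv(path, sep="\t")
    return path, df


def brute_force_patristic(tree):
    """Independent path-sum oracle: distance via paths to root."""
    paths = {}
    for tip in tree.tips():
        path = []
        node = tip
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[tip.name] = path
    names = sorted(paths)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa = {id(n) for n in paths[a]}
            shared = sum(n.length for n in paths[b] if id(n) in pa)
            d = (
                sum(n.length for n in paths[a])
                + sum(n.length for n in paths[b])
                - 2 * shared
            )
            out.loc[a, b] = out.loc[b, a] = d
    return out


def brute_force_mntd(community: pd.Series, dist: pd.DataFrame, weighted=True):
    comm = community[community > 0]
    names = list(comm.index)
    f = comm / comm.sum() if weighted else pd.Series(1 / len(names), index=names)
    total = 0.0
    for i in names:
        total += f[i] * min(dist.loc[i, j] for j in names if j != i)
    return total


def brute_force_bmntd(ck: pd.Series, cm: pd.Series, dist: pd.DataFrame):
    a, b = ck[ck > 0], cm[cm > 0]
    fa, fb = a / a.sum(), b / b.sum()
    s1 = sum(fa[i] * min(dist.loc[i, j] for j in b.index) for i in a.index)
    s2 = sum(fb[i] * min(dist.loc[i, j] for j in a.index) for i in b.index)
    return 0.5 * (s1 + s2)


@pytest.fixture
def oracles():
    return {
        "patristic": brute_force_patristic,
        "mntd": brute_force_mntd,
        "bmntd": brute_force_bmntd,
    }
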