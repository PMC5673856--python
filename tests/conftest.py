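import numpy as np
import pytest

from treedelim.treeio import RootedTree, TreeNode


def random_tree(rng: np.random.Generator, n_tips: int,
                max_bl: float = 1.0) -> RootedTree:
    """Random rooted binary tree with uniform branch lengths."""
    nodes = [
        TreeNode(label=f"t{i}", length=float(rng.uniform(0.01, max_bl)))
        for i in range(n_tips)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        a, b = nodes.pop(int(i)), nodes.pop(int(j))
        parent = TreeNode(length=float(rng.uniform(0.01, max_bl)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return RootedTree(root)


def brute_force_patristic(tree: RootedTree, a: str, b: str) -> float:
    """Independent oracle: d(i,j) = depth(i) + depth(j) - 2 * depth(mrca)."""
    na, nb = tree.tip(a), tree.tip(b)
    ancestors_a = [na] + list(na.ancestors())
    ids_a = {id(x) for x in ancestors_a}
    walker = nb
    while id(walker) not in ids_a:
        walker = walker.parent
    return na.depth() + nb.depth() - 2 * walker.depth()


def brute_force_mrca(tree: RootedTree, labels) -> TreeNode:
    """Independent oracle: first shared node in root-to-tip ancestor lists."""
    paths = []
    for lab in labels:
        node = tree.tip(lab)
        path = [node] + list(node.ancestors())
        paths.append(list(reversed(path)))
    deepest = paths[0][0]
    for rank in range(min(len(p) for p in paths)):
        candidate = paths[0][rank]
        if all(p[rank] is candidate for p in paths):
            deepest = candidate
        else:
            break
    return deepest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def example_tree():
    from treedelim.treeio import parse_newick

    return parse_newick("((A:1,B:1)90:0.5,C:1.5);")
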