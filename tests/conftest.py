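import numpy as np
import pytest

from mscarbon import MultiScaleTree, SynthConfig, generate_supply, generate_tree


def make_chain(n, length=1.0, year=4, leaf_area=0.0, gu_id=1):
    """Straight chain of n metamers along +x, bases at the parent tops."""
    t = MultiScaleTree({1: "plant", 2: "metamer"})
    t.add_vertex("P1", 1, top_xyz=(0.0, 0.0, 0.0))
    prev = None
    for k in range(1, n + 1):
        props = dict(
            organ_type="internode", year=year, gu_id=gu_id,
            top_xyz=(k * length, 0.0, 0.0), length=length, radius=0.01,
        )
        if leaf_area:
            props["leaf_area"] = leaf_area
        t.add_vertex(f"M{k}", 2, parent=prev, edge="<" if prev else None,
                     complex_id="P1", **props)
        prev = f"M{k}"
    return t.validate()


def random_tree(rng, n=60, max_len=0.3):
    """Random-topology tree with random edge lengths and 3-D jitter."""
    t = MultiScaleTree({1: "plant", 2: "metamer"})
    t.add_vertex("P1", 1, top_xyz=(0.0, 0.0, 0.0))
    pos = {None: np.zeros(3)}
    ids = []
    has_succ = set()
    for k in range(n):
        parent = None if k == 0 else ids[int(rng.integers(len(ids)))]
        if parent is None:
            edge = None
        elif parent in has_succ:
            edge = "+"
        else:
            edge = "<"
            has_succ.add(parent)
        length = float(rng.uniform(0.01, max_len))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        top = pos[parent] + direction * length
        vid = f"M{k}"
        t.add_vertex(vid, 2, parent=parent, edge=edge, complex_id="P1",
                     organ_type="internode", year=4, gu_id=1 + k // 7,
                     top_xyz=tuple(top), length=length, radius=0.01)
        pos[vid] = top
        ids.append(vid)
    return t.validate()


def brute_force_distance(tree, geom, i, j):
    """Independent path-walk oracle: explicit root paths, summed terms."""
    if i == j:
        return 0.0
    anc_i = list(tree.ancestors(i))
    anc_j = set(tree.ancestors(j))
    g = next(v for v in anc_i if v in anc_j)

    def path_to(x):
        out, v = [], x
        while v != g:
            out.append(v)
            v = tree.parent_of[v]
        return out  # x .. child-of-g

    semi, length = geom.semi_length, geom.length
    pi, pj = path_to(i), path_to(j)
    if g == i or g == j:
        deep = pj if g == i else pi
        internal = sum(length(v) for v in deep[1:])
        return semi(i) + semi(j) + internal
    internal = sum(length(v) for v in pi[1:]) + sum(length(v) for v in pj[1:])
    gap = float(np.linalg.norm(geom.base(pi[-1]) - geom.base(pj[-1])))
    return semi(i) + semi(j) + internal + gap


def brute_force_gca(tree, i, j):
    """Root-path intersection oracle."""
    path_i = list(tree.ancestors(i))
    path_j = set(tree.ancestors(j))
    return next(v for v in path_i if v in path_j)


@pytest.fixture(scope="session")
def apple_cfg():
    return SynthConfig(seed=7, branches_per_gu=3.0)


@pytest.fixture(scope="session")
def apple_tree(apple_cfg):
    return generate_tree(apple_cfg)


@pytest.fixture(scope="session")
def apple_supply(apple_cfg, apple_tree):
    return generate_supply(apple_tree, apple_cfg)
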