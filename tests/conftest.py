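import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from mfstab import (GeneratorConfig, build_design, build_reference_design,
                    generate_experiment)


@pytest.fixture(scope="session")
def reference_design():
    return build_reference_design()


@pytest.fixture(scope="session")
def small_design():
    """Complete-set design with 3+3 assemblages at richness 1 and 2."""
    return build_design(
        assemblages_per_richness={1: 3, 2: 3},
        set_treatments={"S1": (0, 0), "S2": (1, 0), "S3": (2, 0),
                        "S4": (0, 1), "S5": (1, 1), "S6": (2, 1)})


@pytest.fixture(scope="session")
def small_generator_config():
    return GeneratorConfig(
        seed=11, n_species_pool=8,
        assemblages_per_richness={1: 4, 2: 4, 4: 3},
        n_fauna_taxa=8, n_orders=3)


@pytest.fixture(scope="session")
def small_experiment(small_generator_config):
    return generate_experiment(small_generator_config)


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def unifrac_brute_force(tree: TreeNode, taxa: list[str],
                        u: np.ndarray, v: np.ndarray) -> float:
    """Independent per-branch summation oracle for normalized weighted
    UniFrac: sum over branches of length * |A_b - B_b| over the subtended
    relative abundances, normalized by length * (A_b + B_b)."""
    u = np.asarray(u, float) / np.sum(u)
    v = np.asarray(v, float) / np.sum(v)
    pos = {t: k for k, t in enumerate(taxa)}
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        tips = [t.name for t in node.tips()] or [node.name]
        a = sum(u[pos[t]] for t in tips if t in pos)
        b = sum(v[pos[t]] for t in tips if t in pos)
        num += length * abs(a - b)
        den += length * (a + b)
    return num / den


def enumerate_paths(edges: dict, source: str, target: str,
                    path=None) -> list[list[str]]:
    """Independent recursive DFS enumeration of all directed paths."""
    path = path or [source]
    if source == target:
        return [path]
    out = []
    for (s, t) in edges:
        if s == source and t not in path:
            out.extend(enumerate_paths(edges, t, target, path + [t]))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
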