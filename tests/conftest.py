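import dendropy
import numpy as np
import pytest

from phylosym.data_model import AsvTable, SampleInfo, read_newick


@pytest.fixture
def quartet_tree():
    """Balanced 4-tip tree with unit branch lengths."""
    return read_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture
def seven_tip_tree():
    """Fixed ultrametric 7-tip tree used for frozen-oracle comparisons."""
    return read_newick(
        "((a:0.2,b:0.2):0.8,((c:0.4,d:0.4):0.3,(e:0.5,(f:0.3,g:0.3):0.2):0.2):0.3);"
    )


@pytest.fixture
def small_table():
    counts = np.array([[6, 0, 2], [2, 2, 0], [1, 1, 1]])
    return AsvTable(counts, ["s1", "s2", "s3"], ["a", "b", "c"])


def make_meta(species_of: dict[str, str], controls: tuple[str, ...] = ()):
    """Metadata from a sample->species map plus optional control ids."""
    out = []
    for sid, sp in species_of.items():
        out.append(
            SampleInfo(
                sample_id=sid,
                host_species=sp,
                host_genus=f"g_{sp}",
                host_family="fam1",
                site="site1",
            )
        )
    for sid in controls:
        out.append(
            SampleInfo(
                sample_id=sid,
                host_species="",
                host_genus="",
                host_family="",
                site="lab",
                is_control=True,
            )
        )
    return out


def random_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random binary topology with iid uniform(0.1, 1) branch lengths."""
    from phylosym.phylosymbiosis import random_topology

    tree = random_topology([f"t{i}" for i in range(n_tips)], int(rng.integers(2**31)))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.1, 1.0))
    return tree


def random_table(n_samples: int, asv_ids: list[str], rng: np.random.Generator) -> AsvTable:
    """Random sparse count table with no empty samples."""
    n_asvs = len(asv_ids)
    counts = rng.integers(0, 20, size=(n_samples, n_asvs))
    counts[rng.random(counts.shape) < 0.3] = 0
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_asvs)] = rng.integers(1, 10)
    return AsvTable(counts, [f"s{i}" for i in range(n_samples)], asv_ids)
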