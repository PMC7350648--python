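import pytest

from implied_alignment import sigma0, sigma1, sigma3
from implied_alignment.pairwise import Context
from implied_alignment.tree import lift


@pytest.fixture(scope="session")
def s0():
    return sigma0()


@pytest.fixture(scope="session")
def s1():
    return sigma1()


@pytest.fixture(scope="session")
def s3():
    return sigma3()


def lift_str(text: str, metric) -> Context:
    """Lift a plain residue string into an initial context."""
    alpha = metric.alphabet
    return lift([1 << alpha.index(c) for c in text])


def random_instance(rng, n_leaves, max_len, min_len=1):
    """Random binary tree + random nucleotide sequences as input texts."""
    names = [f"t{i}" for i in range(n_leaves)]
    subtrees = list(names)
    while len(subtrees) > 1:
        j = rng.randrange(len(subtrees) - 1)
        right = subtrees.pop(j + 1)
        subtrees[j] = f"({subtrees[j]},{right})"
    newick = subtrees[0] + ";"
    fasta = "".join(
        f">{name}\n"
        + "".join(
            rng.choice("ACGT")
            for _ in range(rng.randint(min_len, max_len))
        )
        + "\n"
        for name in names
    )
    return newick, fasta


def flip_random_children(newick, rng, prob=0.5):
    """Transpose left/right children of random internal nodes."""
    from implied_alignment import parse_newick

    tree = parse_newick(newick)
    for node in tree.preorder():
        if not node.is_leaf and rng.random() < prob:
            node.left, node.right = node.right, node.left
    return tree.to_newick()
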