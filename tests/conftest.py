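import numpy as np
import pytest

from paralogdiverge.alignments import SubfamilyAlignment


def make_alignment(a_seqs, b_seqs):
    """Build a two-group alignment from equal-length strings."""
    ids = [f"A{i}" for i in range(len(a_seqs))] + \
          [f"B{i}" for i in range(len(b_seqs))]
    labels = ["A"] * len(a_seqs) + ["B"] * len(b_seqs)
    matrix = np.array([list(s) for s in list(a_seqs) + list(b_seqs)],
                      dtype="<U1")
    return SubfamilyAlignment(ids, labels, matrix)


@pytest.fixture
def toy_separating_alignment():
    """4+4 alignment: column 1 separates the groups, column 2 is constant,
    column 3 is noisy."""
    return make_alignment(
        ["KAW", "KAY", "KAW", "KAW"],
        ["TAW", "TAW", "TAY", "TAW"],
    )


def random_binary_newick(labels, rng):
    """Random binary topology over ``labels`` with uniform branch lengths."""
    nodes = [f"{lab}:{rng.uniform(0.1, 1.0):.3f}" for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 1.0):.3f}")
    return "(" + ",".join(n.rsplit(':', 1)[0] + ":" + n.rsplit(':', 1)[1]
                          for n in nodes) + ");"
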