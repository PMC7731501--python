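import numpy as np
import pytest

from hybridexpr import CountMatrix, GODag


@pytest.fixture
def toy_counts() -> CountMatrix:
    """6 transcripts x 2 samples with assorted magnitudes and one zero."""
    counts = np.array(
        [
            [100, 150],
            [200, 900],
            [35, 40],
            [0, 25],
            [1200, 1100],
            [60, 310],
        ]
    )
    return CountMatrix(
        transcript_ids=[f"t{i}" for i in range(6)],
        sample_ids=["s1", "s2"],
        counts=counts,
        lengths=np.array([500, 1000, 800, 600, 1500, 700]),
    )


@pytest.fixture
def chain_fixture():
    """root <- mid <- leaf DAG with signal genes only on the leaf.

    15 leaf genes carry small scores; the 15 genes directly on mid and
    the 30 on root carry an evenly spread null grid.  Classic KS should
    flag leaf and mid; elim should clear mid after eliminating the leaf.
    """
    dag = GODag.from_edges([("leaf", "mid"), ("mid", "root")])
    leaf_genes = [f"sig{i}" for i in range(15)]
    mid_genes = [f"mid{i}" for i in range(15)]
    root_genes = [f"bg{i}" for i in range(30)]
    direct = {g: {"leaf"} for g in leaf_genes}
    direct.update({g: {"mid"} for g in mid_genes})
    direct.update({g: {"root"} for g in root_genes})
    scores = {g: 0.001 * (i + 1) for i, g in enumerate(leaf_genes)}
    # interleave mid and root genes so the null score grid is exchangeable
    null = [
        g
        for i in range(15)
        for g in (mid_genes[i], root_genes[2 * i], root_genes[2 * i + 1])
    ]
    scores.update({g: (i + 1) / (len(null) + 1) for i, g in enumerate(null)})
    return dag, direct, scores
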