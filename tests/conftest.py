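import numpy as np
import pandas as pd
import pytest

import commphylo as cp


@pytest.fixture
def three_tip_tree():
    # ((A:1,B:1):3,C:4); hand cophenetic: AB=2, AC=BC=8
    return cp.tree_from_newick("((A:1,B:1):3,C:4);")


@pytest.fixture
def small_community():
    ab = pd.DataFrame([[1, 2, 0], [0, 1, 3]], index=["s1", "s2"],
                      columns=["A", "B", "C"])
    ab.index.name = "site"
    return cp.CommunityTable(ab, pd.Series([1.0, 2.0], index=["s1", "s2"]),
                             "wet", 2013)


@pytest.fixture
def small_traits():
    quant = pd.DataFrame({"body": [1.0, 2.0, np.nan],
                          "wing": [0.5, 1.5, 2.5]},
                         index=["A", "B", "C"])
    cat = pd.DataFrame({"strategy": ["endo", "para", "endo"]},
                       index=["A", "B", "C"])
    return cp.TraitTable(quant, cat)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
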