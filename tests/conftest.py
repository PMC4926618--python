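import numpy as np
import pytest

from barcodiv.phylo import parse_newick
from barcodiv.records import SequenceRecord
from barcodiv.simulate import SimConfig, sim_survey


@pytest.fixture(scope="session")
def small_survey():
    """A 6-species, 3-samples-per-species survey used across modules."""
    return sim_survey(SimConfig(n_species=6, samples_per_species=3,
                                seq_length=400, seed=11))


@pytest.fixture
def two_cluster_tree():
    """Two well-separated pairs: the canonical mixed-process toy tree."""
    return parse_newick("((A:0.01,B:0.01):0.99,(C:0.01,D:0.01):0.99);")


@pytest.fixture
def toy_records():
    return [
        SequenceRecord(id="s1", bases="ACGTACGTACGT", marker="cox1"),
        SequenceRecord(id="s2", bases="ACGTACGTACGT", marker="cox1"),
        SequenceRecord(id="s3", bases="ACGAACGTACGT", marker="cox1"),
    ]


def random_tree_newick(rng: np.random.Generator, n_tips: int,
                       ultrametric: bool = False) -> str:
    """Random binary topology with exponential branch lengths (coalescent
    ages when ultrametric)."""
    labels = [f"t{i}" for i in range(n_tips)]
    if ultrametric:
        frags = {lab: (lab, 0.0) for lab in labels}
        active = list(labels)
        age = 0.0
        k = n_tips
        while k > 1:
            age += rng.exponential(1.0 / k)
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a, b = active[i], active[j]
            (sa, ta), (sb, tb) = frags.pop(a), frags.pop(b)
            frags[f"n{k}"] = (f"({sa}:{age - ta:.8g},{sb}:{age - tb:.8g})",
                              age)
            active = [x for x in active if x not in (a, b)] + [f"n{k}"]
            k -= 1
        return frags[active[0]][0] + ";"
    frags = list(labels)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        a, b = frags[i], frags[j]
        frags = [x for k_, x in enumerate(frags) if k_ not in (i, j)]
        frags.append(f"({a}:{rng.exponential(0.1):.8g},"
                     f"{b}:{rng.exponential(0.1):.8g})")
    return frags[0] + ";"
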