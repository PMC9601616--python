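import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import barcodegap as bg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_metadata() -> bg.SpeciesLabelMap:
    return bg.SpeciesLabelMap(
        {
            "a1": "spA",
            "a2": "spA",
            "b1": "spB",
            "b2": "spB",
            "c1": "spC",
        }
    )


@pytest.fixture
def tiny_alignment(tiny_metadata) -> bg.MarkerAlignment:
    rows = {
        "a1": "ACGTACGTAC",
        "a2": "ACGTACGTAT",
        "b1": "ACGAACTTAC",
        "b2": "ACGAACTTCC",
        "c1": "TCGAACTTCC",
    }
    return bg.MarkerAlignment(
        "m1", list(rows), dict(tiny_metadata.entries), rows
    )


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with uniform branch lengths.

    Returns (newick, labels); used as the generating truth for NJ
    consistency checks.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    ids = list(range(n_taxa))
    text = {i: labels[i] for i in range(n_taxa)}
    next_id = n_taxa
    while len(ids) > 3:
        i, j = sorted(rng.choice(len(ids), size=2, replace=False))
        a, b = ids[i], ids[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        text[next_id] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
        ids[i] = next_id
        del ids[j]
        next_id += 1
    lens = rng.uniform(0.1, 1.0, size=len(ids))
    parts = ",".join(f"{text[k]}:{l:.10g}" for k, l in zip(ids, lens))
    return f"({parts});", labels
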