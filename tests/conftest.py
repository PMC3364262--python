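import numpy as np
import pandas as pd
import pytest

from furcula.phylo import parse_newick
from furcula.synthetic import simulate_tree


@pytest.fixture(scope="session")
def tree16():
    return simulate_tree(16, seed=3)


@pytest.fixture(scope="session")
def tree24():
    return simulate_tree(24, seed=5)


@pytest.fixture(scope="session")
def star20():
    return parse_newick("(" + ",".join(f"t{i}:1" for i in range(20)) + ");")


@pytest.fixture(scope="session")
def basic_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def five_class_dataset():
    """60-specimen, 5-class synthetic outline dataset (shared across tests)."""
    from furcula.synthetic import simulate_dataset

    return simulate_dataset(
        {"CF": 12, "FG": 12, "IB": 12, "S": 12, "PF": 12},
        bm_fraction=0.5,
        seed=11,
        noise_sd=0.005,
    )


@pytest.fixture(scope="session")
def five_class_scores(five_class_dataset):
    """First three eigenshape scores of the 5-class dataset's profile view."""
    from furcula.eigenshape import extended_eigenshape_fit
    from furcula.shapes_io import orient_standard, resample_equal_arclength

    curves = [c for c in five_class_dataset["outlines"] if c.view == "profile"]
    pls = [resample_equal_arclength(orient_standard(c), 100) for c in curves]
    model = extended_eigenshape_fit(pls)
    scores = pd.DataFrame(
        model.scores[:, :3],
        index=list(model.specimen_ids),
        columns=["es1", "es2", "es3"],
    )
    return model, scores


def random_polyline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Non-degenerate random open polyline (no duplicate consecutive points)."""
    steps = rng.standard_normal((n - 1, 2))
    norms = np.linalg.norm(steps, axis=1, keepdims=True)
    steps = steps / np.maximum(norms, 1e-6) * (0.2 + rng.random((n - 1, 1)))
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
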