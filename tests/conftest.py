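import math

import numpy as np
import pytest

from dualdistill import SyntheticSpec, generate_synthetic_dataset, stratified_split


def kl_oracle(p, q, eps=1e-12):
    """Brute-force relative entropy by direct per-term summation."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log(max(pi, eps) / max(qi, eps))
    return total


def js_oracle(p, q):
    """Brute-force JS via the KL oracle and the explicit mixture."""
    m = [(a + b) / 2 for a, b in zip(p, q)]
    return 0.5 * kl_oracle(p, m) + 0.5 * kl_oracle(q, m)


def random_distribution_pairs(n_pairs, n_classes, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_pairs):
        yield rng.dirichlet(np.ones(n_classes)), rng.dirichlet(np.ones(n_classes))


@pytest.fixture(scope="session")
def tiny_split():
    """A small, easy 10-class dataset split 7:2:1 (session-cached)."""
    items = generate_synthetic_dataset(
        SyntheticSpec(n_classes=10, per_class=20, size=32, seed=42)
    )
    return stratified_split(items, (0.7, 0.2, 0.1), seed=43)
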