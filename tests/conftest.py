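import numpy as np
import pandas as pd
import pytest

from refstab import CqPanel, ExpressionMatrix


def make_matrix(values, genes=None, samples=None, groups=None, scale="log2rq"):
    """Small ExpressionMatrix builder for hand-written examples."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    groups = groups or {s: "all" for s in samples}
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), groups, scale
    )


def make_panel(values, genes=None, samples=None, groups=None):
    """CqPanel builder from a (gene, sample, replicate) array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    groups = groups or {s: "all" for s in samples}
    return CqPanel(genes=genes, samples=samples, groups=groups, values=values)


def random_cq_matrix(rng, k, n, two_groups=False):
    """Random complete Cq matrix: baselines + loading + noise."""
    base = rng.uniform(18, 30, k)
    loading = rng.normal(0, 0.5, n)
    noise = rng.normal(0, rng.uniform(0.1, 1.5, k)[:, None], (k, n))
    values = base[:, None] + loading[None, :] + noise
    samples = [f"s{j:02d}" for j in range(n)]
    if two_groups:
        groups = {s: ("a" if j < n // 2 else "b") for j, s in enumerate(samples)}
    else:
        groups = {s: "all" for s in samples}
    return make_matrix(values, samples=samples, groups=groups, scale="cq")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_panel():
    from refstab import study_scenario

    return study_scenario()
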