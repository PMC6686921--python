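import numpy as np
import pandas as pd
import pytest

from barypop.panel import ReferencePanel
from barypop.simulate import simulate_panel, simulate_subjects


def make_panel(p: np.ndarray, u: np.ndarray, epsilon: float = 1e-6) -> ReferencePanel:
    """Hand-built panel from explicit frequency arrays."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    s = p.shape[0]
    table = pd.DataFrame(
        {
            "snp_id": [f"rs{k}" for k in range(s)],
            "chrom": ["1"] * s,
            "pos": np.arange(1, s + 1) * 1000,
            "ref": ["A"] * s,
            "alt": ["G"] * s,
        }
    )
    return ReferencePanel(table=table, p=p, u=u, epsilon=epsilon)


@pytest.fixture(scope="session")
def small_panel() -> ReferencePanel:
    """400-SNP simulated panel shared across fast unit tests."""
    return simulate_panel(n_snps=400, seed=11)


@pytest.fixture(scope="session")
def pure_cohorts(small_panel):
    """30 subjects per pure anchor group on the small panel."""
    return simulate_subjects(
        small_panel,
        [(30, (1.0, 0.0, 0.0)), (30, (0.0, 1.0, 0.0)), (30, (0.0, 0.0, 1.0))],
        seed=12,
    )
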