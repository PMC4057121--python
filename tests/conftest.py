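import numpy as np
import pandas as pd
import pytest

from refstab.ct_data import CtTable


@pytest.fixture
def make_table():
    """Factory for small CtTables from a {gene: [cts]} dict."""

    def _make(cts, groups=None, efficiencies=None, samples=None, labels=None):
        genes = list(cts)
        n = len(next(iter(cts.values())))
        samples = samples or [f"s{i + 1}" for i in range(n)]
        values = pd.DataFrame(
            {g: pd.array(v, dtype=float) for g, v in cts.items()},
            index=pd.Index(samples, name="sample"),
        )
        info = pd.DataFrame({"group": groups or ["all"] * n}, index=samples)
        if labels:
            for k, v in labels.items():
                info[k] = v
        eff = pd.Series(efficiencies or {g: 2.0 for g in genes})
        return CtTable(values, info, eff)

    return _make


@pytest.fixture
def random_table(make_table):
    """Factory for random complete CtTables (genes x samples, seeded)."""

    def _make(n_genes, n_samples, seed, groups=None):
        rng = np.random.default_rng(seed)
        cts = {
            f"g{j}": list(20.0 + 5.0 * rng.random() + rng.normal(0, 1.0, n_samples))
            for j in range(n_genes)
        }
        eff = {g: float(rng.uniform(1.85, 2.1)) for g in cts}
        return make_table(cts, groups=groups, efficiencies=eff)

    return _make
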