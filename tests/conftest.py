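import numpy as np
import pytest

import kinscale as ks


@pytest.fixture
def noiseless_dataset() -> ks.MMDataset:
    """Exact hyperbolic data: k_cat=5 s^-1, K_M=20 g/L, E0=0.1 uM."""
    loads = [1, 2, 5, 10, 20, 50, 100]
    rates = [[0.1 * 5.0 * s / (s + 20.0)] for s in loads]
    return ks.MMDataset("EX", 0.1, loads, rates)


@pytest.fixture
def line_points() -> list[ks.KineticParams]:
    """20 enzymes exactly on ln k_cat = 1 + 0.74 ln K_M."""
    ln_km = np.linspace(0.0, 5.0, 20)
    return [
        ks.KineticParams(f"P{i:02d}", float(np.exp(1.0 + 0.74 * x)), float(np.exp(x)),
                         source="synthetic-truth")
        for i, x in enumerate(ln_km)
    ]


@pytest.fixture
def small_ensemble() -> ks.SyntheticEnsemble:
    return ks.generate_lfer_ensemble(ks.EnsembleSpec(n_enzymes=30, seed=11))


def pooled_arrays(ds: ks.MMDataset):
    loads = np.concatenate([np.full(len(r), s) for s, r in zip(ds.loads, ds.rates)])
    rates = np.concatenate([np.asarray(r, float) for r in ds.rates])
    return loads, rates


def ssr_of(ds: ks.MMDataset, k_cat: float, K_M: float) -> float:
    loads, rates = pooled_arrays(ds)
    return float(((ks.mm_rate(loads, ds.enzyme_conc, k_cat, K_M) - rates) ** 2).sum())


def grid_min_ssr(ds: ks.MMDataset, n: int = 400) -> float:
    """Brute-force SSR minimum over a log-spaced (k_cat, K_M) grid.

    Independent oracle for the nonlinear fit: evaluates the forward
    model directly on a 400x400 grid over [0.1,100] x [0.1,1000].
    """
    loads, rates = pooled_arrays(ds)
    kc = np.geomspace(0.1, 100.0, n)
    km = np.geomspace(0.1, 1000.0, n)
    KC, KM = np.meshgrid(kc, km, indexing="ij")
    model = ds.enzyme_conc * KC[..., None] * loads / (loads + KM[..., None])
    return float(((model - rates) ** 2).sum(axis=-1).min())
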