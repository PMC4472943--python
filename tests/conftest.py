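import numpy as np
import pandas as pd
import pytest

from episttp import SimulationParams, TtpFractionDist, simulate_experiment


def make_design(n_replicates=3, genotypes=("WT", "Dusp1KO", "Zfp36aa", "DoubleMut"),
                treatments=("untreated", "LPS"), timepoint="1h"):
    rows = []
    for g in genotypes:
        for t in treatments:
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_{t}_{timepoint}_r{r}",
                        "genotype": g,
                        "treatment": t,
                        "timepoint": timepoint,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


def make_matrix(design, values_by_group, default=100.0, probes=("p1",)):
    """Build a linear-intensity matrix from {(genotype, treatment): replicate values}."""
    data = {}
    for _, row in design.iterrows():
        key = (row["genotype"], row["treatment"])
        vals = values_by_group.get(key)
        col = (
            [default] * len(probes)
            if vals is None
            else [v[row["replicate"] - 1] if isinstance(v, (list, tuple)) else v for v in vals]
        )
        data[row["sample_id"]] = col
    m = pd.DataFrame(data, index=list(probes))
    m.index.name = "probe_id"
    return m


@pytest.fixture(scope="session")
def small_experiment():
    params = SimulationParams(n_genes=300, seed=42)
    return simulate_experiment(params)


@pytest.fixture(scope="session")
def responsive_params():
    """Every gene LPS-induced and DUSP1-responsive with a TTP-mediated share."""
    return SimulationParams(
        n_genes=600,
        frac_induced=1.0,
        frac_dusp1_responsive=1.0,
        ttp_fraction_dist=TtpFractionDist(point_mass_zero=0.0, beta_a=4.5, beta_b=5.5),
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1729)
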