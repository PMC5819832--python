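import pytest

import wormassay as wa


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Compile the Laplace kernel once so per-test timings are honest."""
    sc = wa.SimulationScenario(group_logits={"c": 0.0, "m": 1.0})
    ds = wa.simulate_assay_dataset(sc, wa.VarianceComponents(), 0)
    wa.fit_binomial_glmm(ds)


@pytest.fixture
def small_dataset() -> wa.AssayDataset:
    """3 strains x 6 plates over 3 days, moderate clustering, n=50."""
    scenario = wa.SimulationScenario(
        group_logits={"control": 0.0, "g1": 1.0, "g2": 0.0}
    )
    return wa.simulate_assay_dataset(
        scenario, wa.VarianceComponents(0.5, 0.2, 0.2), seed=1
    )


@pytest.fixture
def tiny_csv(tmp_path):
    path = tmp_path / "assays.csv"
    path.write_text(
        "strain,day,plate,n_total,n_dauer\n"
        "N2,d1,p1,20,10\n"
        "N2,d1,p2,20,0\n"
        "rict-1,d1,p3,20,20\n"
    )
    return path
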