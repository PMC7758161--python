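import pytest

import memokin as mk


@pytest.fixture(scope="session")
def spec_curve():
    """Body-water curve used in the closed-form worked examples."""
    return mk.BodyWaterCurve(f=0.015, delta=0.02, beta=0.005, tau=49.0)


@pytest.fixture(scope="session")
def cd4_median_params():
    """Published CD4 median rates as KineticParameters (per day)."""
    return mk.KineticParameters(**mk.reference_median_parameters("CD4"))


@pytest.fixture(scope="session")
def cd4_truth():
    return mk.default_true_parameters("CD4")


@pytest.fixture(scope="session")
def noisefree_design():
    return mk.StudyDesign(
        label_noise_sd=0.0, saliva_noise_sd=0.0, molecule_sd_bp=0.0
    )


@pytest.fixture(scope="session")
def noisefree_dataset(cd4_truth, noisefree_design):
    return mk.generate_volunteer(cd4_truth, noisefree_design, seed=1)


@pytest.fixture(scope="session")
def noisefree_fit(cd4_truth, noisefree_dataset):
    """Full-model fit to noise-free data at the CD4 median truth."""
    water = mk.BodyWaterModel(
        noisefree_dataset.saliva, tau=cd4_truth.curve.tau
    ).fit()
    model = mk.TurnoverModel(noisefree_dataset, water.curve)
    return model, model.fit()


def random_kinetic_parameters(rng, mr_min=1e-4):
    """Random within-bounds parameter set (mR bounded away from 0)."""
    return mk.KineticParameters(
        p1=rng.uniform(0.0, 0.02),
        z1s=rng.uniform(1e-4, 0.05),
        p2=rng.uniform(0.0, 0.02),
        z2s=rng.uniform(1e-4, 0.05),
        mR=rng.uniform(mr_min, 0.4),
    )


@pytest.fixture(scope="session")
def alt_recovery(cd4_truth):
    """200-replicate nested recovery study at the CD4 median truth."""
    return mk.recovery_experiment(
        200, truth=cd4_truth, seed=0, fit_constrained=True
    )


@pytest.fixture(scope="session")
def null_recovery():
    """200-replicate nested study under the p2 = 0 null."""
    return mk.recovery_experiment(
        200, truth=mk.default_true_parameters("CD4", p2=0.0),
        seed=0, fit_constrained=True,
    )
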