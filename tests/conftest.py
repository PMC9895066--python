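import numpy as np
import pytest

import amysustain as am

E3_ROIS = ("roi_a", "roi_b", "roi_c")


def toy3_model(sequences=(("roi_a", "roi_b", "roi_c"),), fractions=(1.0,),
               z_cut=(1.0, 1.0, 1.0), z_max=(3.0, 3.0, 3.0),
               sigma=(1.0, 1.0, 1.0)):
    """Three-event model small enough for exhaustive enumeration."""
    return am.SubtypeModel(sequences=list(sequences),
                           fractions=np.asarray(fractions, float),
                           z_cut=np.asarray(z_cut, float),
                           z_max=np.asarray(z_max, float),
                           sigma=np.asarray(sigma, float),
                           roi_names=E3_ROIS)


@pytest.fixture
def toy3():
    return toy3_model()


@pytest.fixture
def truth_model():
    """The generating two-subtype model of the default synthetic cohort."""
    return am.SubtypeModel(
        sequences=[am.SUBCORTEX_PRIORITY_SEQUENCE,
                   am.CORTEX_PRIORITY_SEQUENCE],
        fractions=[0.5, 0.5], z_cut=np.ones(11), z_max=3.0 * np.ones(11),
        sigma=np.ones(11))


def oracle_z(cohort):
    """Exact generator-scale z-scores of a cohort simulated without
    covariate effects (SUVR = 1 + 0.1 z)."""
    cols = [f"suvr_{r}" for r in am.ROI_NAMES]
    return (cohort[cols].to_numpy(dtype=float) - 1.0) / 0.1


def no_covariate_config(**kw):
    return am.default_config(covariate_effects=((0.0, 0.0, 0.0),) * 11, **kw)


@pytest.fixture(scope="session")
def recovery_fits():
    """Two-subtype fits on ten independently seeded default cohorts
    (n = 600, unit noise, 10 greedy restarts) plus ground truth — shared by
    the sequence-recovery and assignment-accuracy checks."""
    fits = []
    for seed in range(10):
        cfg = no_covariate_config(seed=seed, n_subjects=600)
        cohort, truth = am.generate_cohort(cfg)
        Z = oracle_z(cohort)
        model = am.fit_subtypes(Z, 2, z_cut=np.ones(11),
                                z_max=3.0 * np.ones(11), n_restarts=10,
                                seed=seed)
        fits.append({"seed": seed, "cohort": cohort, "truth": truth,
                     "Z": Z, "model": model})
    return fits
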