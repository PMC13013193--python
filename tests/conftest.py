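"""Shared heavyweight fixtures: phantom cohorts, prior bundle, trained nets.

Everything expensive is session-scoped so the property and acceptance
tests share one prior bundle, one trained 3D network and one trained 2D
network. All randomness is seeded; reruns are deterministic.
"""

import numpy as np
import pytest

from nigraseg.phantom import PhantomParams, generate_subject
from nigraseg.workflows import (DESK_EDGE, build_prior_bundle, desk_net3d_config,
                                desk_train_config, locate_cohort,
                                prepare_roi_case, train_midbrain_network,
                                train_sn_network)


@pytest.fixture(scope="session")
def phantom_params():
    return PhantomParams()


@pytest.fixture(scope="session")
def atlas_bundle(phantom_params):
    """Template + SPPM from five HC phantoms."""
    rng = np.random.default_rng(5)
    atlas = [generate_subject(phantom_params, "HC", rng, f"atlas{i}")
             for i in range(5)]
    return build_prior_bundle(atlas, subset_size=5, seed=0)


@pytest.fixture(scope="session")
def training_cohort(phantom_params):
    """20 phantoms (alternating HC/PD) for training/validation/held-out."""
    rng = np.random.default_rng(5)
    # consume the atlas draws so the stream continues deterministically
    for _ in range(5):
        generate_subject(phantom_params, "HC", rng, "skip")
    labels = ["HC", "PD"] * 10
    return [generate_subject(phantom_params, labels[i], rng, f"s{i}")
            for i in range(20)]


@pytest.fixture(scope="session")
def roi_cases(training_cohort, atlas_bundle):
    """(box, (image, sppm, label)) ROI crops for the training cohort."""
    return [prepare_roi_case(rec, atlas_bundle, edge=DESK_EDGE)
            for rec in training_cohort]


@pytest.fixture(scope="session")
def sn_model(roi_cases):
    """Desk-scale priority-gated attention network trained on 14 crops."""
    cases = [c for _, c in roi_cases]
    model, history = train_sn_network(
        cases[:14], cases[14:16],
        net_cfg=desk_net3d_config(dropout_rate=0.2, init_seed=1),
        train_cfg=desk_train_config(epochs=45, seed=0))
    model.history = history
    return model


@pytest.fixture(scope="session")
def heldout_cases(roi_cases, training_cohort):
    """Cases never touched by training or validation."""
    return [(training_cohort[i], roi_cases[i][0], roi_cases[i][1])
            for i in range(16, 20)]


@pytest.fixture(scope="session")
def mb_model(training_cohort):
    """Desk-scale 2D midbrain network trained on axial T1 slices."""
    model, history = train_midbrain_network(training_cohort[:7])
    model.history = history
    return model


@pytest.fixture(scope="session")
def eval_cohort(phantom_params):
    """30 HC + 30 PD phantoms for cohort-level discrimination."""
    from nigraseg.phantom import generate_cohort
    records, _ = generate_cohort(30, 30, phantom_params, seed=77)
    return records


@pytest.fixture(scope="session")
def eval_transforms(eval_cohort, atlas_bundle):
    """Template-to-case registrations, computed once per evaluation case."""
    return locate_cohort(eval_cohort, atlas_bundle)
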