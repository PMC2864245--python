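"""Shared fixtures: profiles, panels and a small synthetic survey scene."""

import numpy as np
import pytest

from chromomine import annotate, search, synthetic


@pytest.fixture(scope="session")
def rt_profile():
    return search.build_profile(synthetic.rt_int_seed_alignment())


@pytest.fixture(scope="session")
def domain_profiles():
    return annotate.default_domain_profiles()


@pytest.fixture(scope="session")
def reference_panel():
    return synthetic.reference_panel()


@pytest.fixture(scope="session")
def trna_panel():
    return synthetic.trna_panel()


@pytest.fixture(scope="session")
def small_scene():
    """300 kb genome, 2 families x 3 copies, one decayed copy per family."""
    genome, copies = synthetic.demo_scene(
        7, background_length=300_000, n_families=2, copy_number=3,
        decay_fraction=0.2)
    return genome, copies


@pytest.fixture(scope="session")
def small_scene_loci(small_scene, rt_profile, reference_panel):
    genome, _ = small_scene
    return search.mine_genome([genome], rt_profile, reference_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(20100408)
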