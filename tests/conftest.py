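import numpy as np
import pandas as pd
import pytest

import mmmp
from mmmp.phantom import (DEFAULT_ANTIBODIES, DEFAULT_BF_STAINS, CycleDef,
                          FeatureDef, PhantomSpec, default_cycles,
                          default_feature_set, default_signatures)


def small_panel_spec(n_if: int = 3, n_bf: int = 2, **kwargs) -> PhantomSpec:
    """A reduced-panel phantom spec (fewer cycles, small canvas) used to keep
    unit tests fast while exercising every modality."""
    ab = DEFAULT_ANTIBODIES[:n_if]
    bf = DEFAULT_BF_STAINS[:n_bf]
    defaults = dict(canvas_size=(160, 160),
                    feature_set=default_feature_set(),
                    signatures=default_signatures(antibodies=ab, bf_stains=bf),
                    noise_sd=5.0,
                    cycles=default_cycles(ab, bf),
                    seed=0)
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


def one_channel_spec(signature_value: float = 100.0,
                     noise_sd: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Minimal spec: one space-filling feature, one IF channel, no DAPI."""
    sig = pd.DataFrame({"marker": [signature_value]}, index=["tissue"])
    return PhantomSpec(canvas_size=(64, 64),
                       feature_set=(FeatureDef("tissue", "field"),),
                       signatures=sig, noise_sd=noise_sd,
                       cycles=(CycleDef(0, "IF", "marker", has_dapi=False),),
                       seed=seed)


def identity_stack(truth):
    """Wrap an undrifted phantom as a trivially registered stack (for tests
    whose subject is extraction or analysis, not registration)."""
    from mmmp.register import RegisteredStack
    from mmmp.transforms import RigidTransform

    cycles = list(truth.spec.cycles)
    ones = np.ones(truth.spec.canvas_size, dtype=bool)
    return RegisteredStack(
        images=truth.channel_stack, cycles=cycles,
        transforms=[RigidTransform.identity("IF0") for _ in cycles],
        validity_masks=[ones] * len(cycles))


@pytest.fixture(scope="session")
def small_truth():
    """Reduced-panel phantom shared by read-only tests."""
    return mmmp.make_phantom_core(small_panel_spec(seed=42))


@pytest.fixture(scope="session")
def registered_small(small_truth):
    spec = small_truth.spec
    return mmmp.register_series(small_truth.channel_stack, list(spec.cycles))


@pytest.fixture(scope="session")
def small_matrix(small_truth, registered_small):
    panel = mmmp.PanelConfig.from_cycles(list(small_truth.spec.cycles))
    fg = mmmp.compute_foreground(registered_small, tissue_threshold=0.05)
    return mmmp.build_matrix(registered_small, fg, panel)
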