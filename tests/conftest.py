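import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rendered_small_stack():
    """10-cell, 30-frame rendered stack with its trajectory ground truth."""
    import neutrokit as nk

    walk = nk.WalkParams(n_cells=10, n_frames=30, seed=11)
    ts = nk.gen_walk_population(walk)
    stack, truth = nk.render_stack(ts, nk.ImagingParams(seed=12))
    return walk, ts, stack, truth
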