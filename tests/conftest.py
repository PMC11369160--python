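import pytest

from spirocell.synthgen import (
    ParticleMixtureSpec,
    SynthCellSpec,
    render_cell_image,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def arc_cell():
    """Rendered default curved cell (r=0.4 µm, R_c=5.7 µm, L=5 µm) with
    ground-truth geometry."""
    spec = SynthCellSpec(centerline_kind="arc", curvature_radius=5.7,
                         length=5.0, half_width=0.4)
    stack, geom = render_cell_image(spec, seed=42)
    return spec, stack, geom


@pytest.fixture(scope="session")
def ribbon_cell():
    """Rendered arc cell with a 3× outer-curve ribbon."""
    spec = SynthCellSpec(centerline_kind="arc", curvature_radius=5.7,
                         length=5.0, half_width=0.4, ribbon_boost=3.0)
    stack, geom = render_cell_image(spec, seed=43)
    return spec, stack, geom


@pytest.fixture(scope="session")
def two_state_tracks():
    """Two-population Brownian mixture at the study's acquisition
    conditions (20-ms frames, 20-nm localization error)."""
    spec = ParticleMixtureSpec(
        populations=[(0.6, 0.0657), (0.4, 0.0191)],
        n_tracks=2000, frame_interval=0.02, localization_sd=0.02)
    return spec, simulate_tracks(spec, seed=7)
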