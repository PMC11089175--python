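"""Phantom generator: emission model, rendering contracts, pipeline recovery."""

import math

import numpy as np
import pytest

from ppixmap.colorimetry import extract_fluorescence
from ppixmap.masking import compute_mask
from ppixmap.phantom import (
    Lesion,
    PhantomSpec,
    load_spec,
    ppix_emission,
    render_phantom,
    save_spec,
)
from ppixmap.scenarios import SCENARIOS, scenario


def _one_lesion_spec(concentration, depth, **kw):
    return PhantomSpec(
        shape=(96, 96),
        lesions=[Lesion(center=(48.0, 48.0), radii=(28.0, 28.0),
                        concentration=concentration, depth=depth)],
        noise_sd=0.0,
        **kw,
    )


@pytest.mark.parametrize(
    "c, d, expected",
    [
        (0.0, 0.0, 0.0),                      # no fluorophore
        (0.0, 5.0, 0.0),
        (5.0, 0.0, 255 * (1 - math.exp(-2.5))),  # ~234.07, closed form
        (100.0, 2.0, 255 * (1 - math.exp(-50)) * math.exp(-1.2)),
    ],
)
def test_emission_closed_form(c, d, expected):
    assert ppix_emission(c, d) == pytest.approx(expected, abs=1e-9)


def test_emission_vanishes_at_infinite_depth():
    assert ppix_emission(100.0, 1e6) == pytest.approx(0.0, abs=1e-12)


def test_lesion_free_blue_image_has_no_red_excess():
    spec = PhantomSpec(shape=(64, 64), lesions=[], noise_sd=2.0, seed=3)
    _, blue, truth = render_phantom(spec)
    bg_r = 18  # translucent-yellowish blue-light background red level
    assert not truth.any()
    assert blue[:, :, 0].max() <= bg_r + 4 * spec.noise_sd


def test_surface_lesion_core_red_channel_from_closed_form():
    spec = _one_lesion_spec(5.0, 0.0)
    _, blue, truth = render_phantom(spec)
    assert blue[48, 48, 0] == 234  # round(255 * (1 - e^-2.5))
    assert blue[48, 48, 1] == 0 and blue[48, 48, 2] == 0


def test_rendering_is_bit_deterministic():
    spec = scenario("small_brain", seed=11)
    a = render_phantom(spec)
    b = render_phantom(scenario("small_brain", seed=11))
    for x, y in zip(a, b):
        assert np.array_equal(x, y)


def test_truth_labels_lesions_in_list_order():
    spec = scenario("coronal_section", seed=0)
    _, _, truth = render_phantom(spec)
    assert sorted(np.unique(truth).tolist()) == [0, 1, 2]
    # first lesion centered near row 80, second near row 180
    assert truth[80, 128] == 1 and truth[180, 128] == 2


def test_white_light_shows_no_fluorescence():
    spec = _one_lesion_spec(100.0, 0.0)
    white, _, truth = render_phantom(spec)
    bg = np.array([225, 205, 150])
    core = white[truth == 1].astype(int)
    # subtle texture only: within 15% of the background color, never red-shifted
    assert (np.abs(core - bg) <= 0.15 * bg + 1).all()


def test_overlapping_lesions_resolve_to_max_emission():
    spec = PhantomSpec(
        shape=(64, 64),
        lesions=[
            Lesion(center=(32.0, 28.0), radii=(12.0, 12.0), concentration=1.0, depth=0.0),
            Lesion(center=(32.0, 36.0), radii=(12.0, 12.0), concentration=50.0, depth=0.0),
        ],
        noise_sd=0.0,
    )
    _, blue, truth = render_phantom(spec)
    # overlap belongs to the stronger emitter and carries its emission
    assert truth[32, 32] == 2
    assert blue[32, 32, 0] == 255


def test_spec_yaml_round_trip(tmp_path):
    spec = scenario("half_brain_opaque", seed=5)
    save_spec(spec, tmp_path / "s.yaml")
    back = load_spec(tmp_path / "s.yaml")
    assert back == spec


def test_invalid_spec_fields_are_named():
    with pytest.raises(ValueError, match="k_sat"):
        PhantomSpec(k_sat=0.0)
    with pytest.raises(ValueError, match="background"):
        PhantomSpec(background="chartreuse")
    with pytest.raises(ValueError, match="concentration"):
        Lesion(center=(0, 0), radii=(5, 5), concentration=-1.0)


def test_lesion_outside_bounds_rejected():
    spec = PhantomSpec(shape=(32, 32), noise_sd=0.0)
    spec.lesions = [Lesion(center=(100.0, 10.0), radii=(4.0, 4.0), concentration=1.0)]
    with pytest.raises(ValueError, match="bounds"):
        render_phantom(spec)


def test_all_catalog_scenarios_render():
    for name in SCENARIOS:
        white, blue, truth = render_phantom(scenario(name, seed=1))
        assert white.shape == blue.shape
        assert truth.max() == len(scenario(name, seed=1).lesions)


def test_pipeline_mean_au_monotone_in_concentration():
    """At fixed depth, recovered mean au never decreases with concentration."""
    means = []
    for c in (0.5, 1.25, 5.0, 50.0, 100.0):
        _, blue, truth = render_phantom(_one_lesion_spec(c, 0.0))
        afi = extract_fluorescence(blue)
        means.append(afi[truth == 1].mean())
    assert all(b >= a for a, b in zip(means, means[1:]))
    assert means[2] > means[0]  # strictly increasing below camera saturation


def test_depth_confound_inverts_quantification():
    """A deep 100 µg/mL mass quantifies below a 50 µg/mL surface mass."""
    _, blue_deep, truth_deep = render_phantom(_one_lesion_spec(100.0, 2.5))
    _, blue_surf, truth_surf = render_phantom(_one_lesion_spec(50.0, 0.0))
    deep = extract_fluorescence(blue_deep)[truth_deep == 1].mean()
    surf = extract_fluorescence(blue_surf)[truth_surf == 1].mean()
    assert deep < surf


def test_mask_recovers_ground_truth_for_surface_lesions():
    """Noise-free surface lesions: recovered mask Jaccard >= 0.9 vs truth."""
    for c in (5.0, 50.0):
        _, blue, truth = render_phantom(_one_lesion_spec(c, 0.0))
        mask = compute_mask(extract_fluorescence(blue))
        gt = truth > 0
        jaccard = (mask & gt).sum() / (mask | gt).sum()
        assert jaccard >= 0.9
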