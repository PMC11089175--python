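"""Catalog of phantom scenes mirroring the bench acquisition sessions.

Four named scenes cover the acquisition setups used to validate the
pipeline on gel phantoms:

* ``small_brain``       — 1:25 scale model, high concentrations (50 and
  100 µg/mL), the more concentrated mass buried deeper so the depth
  confound inverts the quantification ordering.
* ``half_brain``        — 1:1 scale, four masses all at 5 µg/mL at
  different depths: equal concentration, unequal quantification.
* ``half_brain_opaque`` — the opaque pinkish 1:1 variant (reduced
  reflection), 1.25-5 µg/mL.
* ``coronal_section``   — a sectioned model with two surface masses (0.5
  and 5 µg/mL) at zero depth: quantification ordering follows
  concentration because nothing attenuates.

The same scenes ship as YAML files under ``fixtures/`` at the repository
root; this module is the programmatic source of truth.
"""

from __future__ import annotations

from .phantom import Lesion, PhantomSpec

__all__ = ["SCENARIOS", "scenario"]


def _small_brain(seed: int) -> PhantomSpec:
    return PhantomSpec(
        shape=(240, 320),
        background="translucent-yellowish",
        lesions=[
            Lesion(center=(80.0, 90.0), radii=(30.0, 24.0), angle=15.0,
                   concentration=50.0, depth=0.0),
            Lesion(center=(160.0, 220.0), radii=(26.0, 26.0), angle=0.0,
                   concentration=100.0, depth=0.5),
        ],
        n_highlights=3,
        seed=seed,
        model_scale="1:25",
    )


def _half_brain(seed: int) -> PhantomSpec:
    return PhantomSpec(
        shape=(256, 320),
        background="translucent-yellowish",
        lesions=[
            Lesion(center=(60.0, 230.0), radii=(24.0, 20.0), concentration=5.0, depth=0.0),
            Lesion(center=(120.0, 260.0), radii=(20.0, 20.0), concentration=5.0, depth=0.0),
            Lesion(center=(90.0, 70.0), radii=(26.0, 22.0), angle=-20.0,
                   concentration=5.0, depth=0.6),
            Lesion(center=(185.0, 110.0), radii=(22.0, 22.0), concentration=5.0, depth=0.6),
        ],
        n_highlights=2,
        seed=seed,
        model_scale="1:1",
    )


def _half_brain_opaque(seed: int) -> PhantomSpec:
    return PhantomSpec(
        shape=(256, 320),
        background="opaque-pinkish",
        lesions=[
            Lesion(center=(75.0, 85.0), radii=(26.0, 22.0), concentration=5.0, depth=0.3),
            Lesion(center=(170.0, 160.0), radii=(24.0, 24.0), concentration=2.5, depth=0.1),
            Lesion(center=(90.0, 245.0), radii=(22.0, 18.0), angle=30.0,
                   concentration=1.25, depth=0.0),
        ],
        seed=seed,
        model_scale="1:1",
    )


def _coronal_section(seed: int) -> PhantomSpec:
    return PhantomSpec(
        shape=(256, 256),
        background="opaque-pinkish",
        lesions=[
            Lesion(center=(80.0, 128.0), radii=(30.0, 26.0), concentration=5.0, depth=0.0),
            Lesion(center=(180.0, 128.0), radii=(26.0, 24.0), concentration=0.5, depth=0.0),
        ],
        seed=seed,
        model_scale="1:1",
    )


SCENARIOS = {
    "small_brain": _small_brain,
    "half_brain": _half_brain,
    "half_brain_opaque": _half_brain_opaque,
    "coronal_section": _coronal_section,
}


def scenario(name: str, seed: int = 0) -> PhantomSpec:
    """Return a named phantom scene; raises on unknown names."""
    try:
        make = SCENARIOS[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}") from None
    return make(seed)
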