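"""Shared scene factories for the test suite.

All fixtures build scenes programmatically; no image files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from guvquant.synthetic import GuvSpec, NoiseSpec, SceneSpec

TWO_PI = 2 * np.pi


def make_scene(contrast: dict[str, dict[str, float]] | None = None,
               phase_arcs: list | None = None,
               marker: dict[str, float] | None = None,
               noise: NoiseSpec | None = None,
               psf_sigma: float = 0.0,
               seed: int = 1,
               center: tuple[float, float] = (64.0, 64.0),
               radius: float = 20.0,
               image_shape: tuple[int, int] = (128, 128),
               solution: dict[str, float] | None = None) -> SceneSpec:
    """One-GUV scene with sensible defaults; noise/PSF off unless asked."""
    contrast = contrast or {"lectin_1": {"ld": 7.0}}
    solution = solution or {r: 100.0 for r in contrast}
    kwargs = {}
    if phase_arcs is not None:
        kwargs["phase_arcs"] = phase_arcs
    if marker is not None:
        kwargs["marker_rim_intensity"] = marker
    guv = GuvSpec(center_xy=center, radius=radius,
                  lectin_contrast=contrast, **kwargs)
    return SceneSpec(guvs=[guv], image_shape=image_shape,
                     solution_intensity=solution, psf_sigma=psf_sigma,
                     noise=noise, seed=seed)


def half_and_half_arcs() -> list[tuple[float, float, str]]:
    """ld on [0, pi), lo on [pi, 2*pi)."""
    return [(0.0, np.pi, "ld"), (np.pi, TWO_PI, "lo")]


@pytest.fixture
def clean_scene() -> SceneSpec:
    return make_scene()


@pytest.fixture
def phase_separated_scene() -> SceneSpec:
    return make_scene(
        contrast={"lectin_1": {"ld": 0.0, "lo": 7.0}},
        phase_arcs=half_and_half_arcs(),
        marker={"ld": 150.0, "lo": 37.5})
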