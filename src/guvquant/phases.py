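"""ld/lo phase discrimination along the rim from the membrane marker.

The marker (a BODIPY-type ld-phase lipid by default) is bright on
liquid-disordered arcs and dim on liquid-ordered arcs.  The angular marker
profile is split by a deterministic two-cluster 1-D k-means (centers
initialized at the 25th/75th percentiles); the brighter cluster gets the
marker's phase (``ld`` by default, configurable for lo-partitioning
markers).  The GUV is called ``uniform`` — a single phase — when the
bright/dim cluster-mean ratio falls below ``min_contrast_ratio`` or either
cluster covers less than ``min_arc_fraction`` of the bins.  Labels are
smoothed with a circular majority filter before arcs are summarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import QuantificationError
from .image import MARKER
from .rim import RimProfile


@dataclass
class PhaseConfig:
    min_contrast_ratio: float = 2.0
    min_arc_fraction: float = 0.05
    smooth_bins: int = 5
    marker_phase: str = "ld"    # phase the marker is bright in
    max_iter: int = 100


@dataclass
class PhaseLabeling:
    """Per-bin phase labels plus the phase-separated/uniform call.

    ``arcs`` lists circular runs as ``(start_bin, end_bin, label)`` with
    ``end_bin`` inclusive; a run may wrap past the last bin.
    """

    labels: np.ndarray          # array of "ld"/"lo" strings, one per bin
    mode: str                   # "phase_separated" | "uniform"
    arcs: list[tuple[int, int, str]]
    bright_dim_ratio: float

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    @property
    def phases_present(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def boundary_mask(self, halfwidth: int = 1) -> np.ndarray:
        """Bins within ``halfwidth`` bins of a label change (circular)."""
        mask = np.zeros(self.n_bins, dtype=bool)
        if self.mode == "uniform":
            return mask
        change = self.labels != np.roll(self.labels, 1)  # boundary before bin i
        for i in np.flatnonzero(change):
            for d in range(-halfwidth, halfwidth + 1):
                mask[(i + d) % self.n_bins] = True
                mask[(i - 1 + d) % self.n_bins] = True
        return mask


def _two_means_1d(values: np.ndarray, max_iter: int) -> np.ndarray:
    """Deterministic 1-D 2-means; returns a boolean 'bright' assignment."""
    lo_c, hi_c = np.percentile(values, [25, 75])
    if hi_c <= lo_c:
        return np.zeros(len(values), dtype=bool)
    for _ in range(max_iter):
        bright = np.abs(values - hi_c) < np.abs(values - lo_c)
        if not bright.any() or bright.all():
            break
        new_lo, new_hi = values[~bright].mean(), values[bright].mean()
        if np.isclose(new_lo, lo_c) and np.isclose(new_hi, hi_c):
            break
        lo_c, hi_c = new_lo, new_hi
    return np.abs(values - hi_c) < np.abs(values - lo_c)


def _majority_smooth(bright: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return bright
    n = len(bright)
    half = window // 2
    counts = np.zeros(n)
    for d in range(-half, half + 1):
        counts += np.roll(bright, d)
    return counts > window / 2


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Circular runs of equal labels as (start, end-inclusive, label)."""
    n = len(labels)
    if all(labels == labels[0]):
        return [(0, n - 1, str(labels[0]))]
    starts = np.flatnonzero(labels != np.roll(labels, 1))
    arcs = []
    for i, s in enumerate(starts):
        e = (starts[(i + 1) % len(starts)] - 1) % n
        arcs.append((int(s), int(e), str(labels[s])))
    return arcs


def segment_phases(profile: RimProfile,
                   cfg: PhaseConfig | None = None) -> PhaseLabeling:
    """Split the marker angular profile into ld and lo arcs.

    Raises :class:`QuantificationError` when the profile has no marker
    channel or fewer than 12 bins (too coarse to segment).
    """
    cfg = cfg or PhaseConfig()
    if MARKER not in profile.intensities:
        raise QuantificationError("profile has no marker channel")
    if profile.n_bins < 12:
        raise QuantificationError("need at least 12 angular bins to segment")

    values = np.asarray(profile.intensities[MARKER], dtype=float)
    bright_phase = cfg.marker_phase
    dim_phase = "lo" if bright_phase == "ld" else "ld"

    bright = _two_means_1d(values, cfg.max_iter)
    n = profile.n_bins
    uniform = False
    ratio = np.inf
    if not bright.any() or bright.all():
        uniform = True
    else:
        dim_mean = values[~bright].mean()
        bright_mean = values[bright].mean()
        ratio = bright_mean / dim_mean if dim_mean > 0 else np.inf
        frac = bright.mean()
        if ratio < cfg.min_contrast_ratio or min(frac, 1 - frac) < cfg.min_arc_fraction:
            uniform = True

    if uniform:
        labels = np.array([bright_phase] * n, dtype=object)
        return PhaseLabeling(labels=labels, mode="uniform",
                             arcs=[(0, n - 1, bright_phase)],
                             bright_dim_ratio=float(ratio) if np.isfinite(ratio) else float("nan"))

    bright = _majority_smooth(bright, cfg.smooth_bins)
    if not bright.any() or bright.all():     # smoothing collapsed one class
        labels = np.array([bright_phase if bright.all() else dim_phase] * n,
                          dtype=object)
        return PhaseLabeling(labels=labels, mode="uniform",
                             arcs=[(0, n - 1, str(labels[0]))],
                             bright_dim_ratio=float(ratio))
    labels = np.where(bright, bright_phase, dim_phase).astype(object)
    return PhaseLabeling(labels=labels, mode="phase_separated",
                         arcs=_runs(labels), bright_dim_ratio=float(ratio))
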