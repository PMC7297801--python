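"""The binding-efficiency contrast statistic and its per-phase variants.

Binding efficiency is the contrast between lectin bound at the GUV rim and
free lectin in solution::

    BE = (mean rim intensity - solution intensity) / solution intensity

A lectin that cannot bind gives a rim indistinguishable from the solution
and hence BE = 0; BE >= -1 always, because intensities are non-negative.
Being a ratio, BE is invariant under any positive rescaling of the channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import QuantificationError
from .phases import PhaseLabeling
from .rim import RimProfile


def compute_binding_efficiency(profile: RimProfile, solution: float,
                               channel: str,
                               bins: np.ndarray | None = None) -> float:
    """Contrast of the rim over the free-solution reference.

    Parameters
    ----------
    profile
        Rim profile holding per-bin intensities for ``channel``.
    solution
        Free-solution intensity (must be > 0; the statistic divides by it).
    bins
        Optional index array restricting the mean to a subset of bins
        (e.g. one phase); ``None`` uses all bins.
    """
    if solution <= 0:
        raise QuantificationError("solution intensity must be > 0")
    if channel not in profile.intensities:
        raise QuantificationError(f"profile has no channel {channel!r}")
    values = profile.intensities[channel]
    if bins is not None:
        bins = np.asarray(bins)
        if bins.size == 0:
            raise QuantificationError("empty bin subset")
        values = values[bins]
    return float((values.mean() - solution) / solution)


@dataclass
class BindingResult:
    """Per-GUV binding efficiencies, overall and per phase.

    ``per_phase`` maps lectin role -> {"ld": BE, "lo": BE}; a phase absent
    from the labeling is absent from the mapping.  ``n_bins_per_phase``
    counts the non-boundary bins each per-phase mean used.
    """

    guv_id: int
    binding_efficiency: dict[str, float]
    per_phase: dict[str, dict[str, float]]
    solution_intensity: dict[str, float]
    n_bins_per_phase: dict[str, int] = field(default_factory=dict)
    mode: str = "uniform"


def per_phase_binding(profile: RimProfile, labeling: PhaseLabeling,
                      solution: dict[str, float], guv_id: int = 0,
                      boundary_exclusion: int = 1) -> BindingResult:
    """Binding efficiency per lectin channel, overall and split by phase.

    Bins within ``boundary_exclusion`` bins of a phase boundary are
    excluded from the per-phase means (point-spread mixing at domain
    edges); the overall value uses every bin.
    """
    if labeling.n_bins != profile.n_bins:
        raise QuantificationError("labeling does not match the profile")
    lectins = [r for r in profile.intensities if r in solution]
    if not lectins:
        raise QuantificationError("no lectin channel with a solution reference")

    keep = ~labeling.boundary_mask(boundary_exclusion)
    overall: dict[str, float] = {}
    per_phase: dict[str, dict[str, float]] = {}
    n_bins: dict[str, int] = {}
    for phase in labeling.phases_present:
        sel = np.flatnonzero((labeling.labels == phase) & keep)
        n_bins[phase] = int(sel.size)
    for role in lectins:
        overall[role] = compute_binding_efficiency(profile, solution[role], role)
        per_phase[role] = {}
        for phase in labeling.phases_present:
            sel = np.flatnonzero((labeling.labels == phase) & keep)
            if sel.size:
                per_phase[role][phase] = compute_binding_efficiency(
                    profile, solution[role], role, bins=sel)
    return BindingResult(guv_id=guv_id, binding_efficiency=overall,
                         per_phase=per_phase,
                         solution_intensity={r: solution[r] for r in lectins},
                         n_bins_per_phase=n_bins, mode=labeling.mode)


@dataclass
class SegregationResult:
    """Pearson correlation of two lectins' angular profiles plus the raw
    two-channel table for circular-profile plots; ``nan`` correlation marks
    a zero-variance (undefined) case."""

    correlation: float
    table: pd.DataFrame


def segregation_profile(profile: RimProfile, lectin_a: str,
                        lectin_b: str) -> SegregationResult:
    """Quantify co- vs counter-localization of two lectins along the rim."""
    for role in (lectin_a, lectin_b):
        if role not in profile.intensities:
            raise QuantificationError(f"profile has no channel {role!r}")
    if profile.n_bins < 3:
        raise QuantificationError("need at least 3 bins for a correlation")
    a = profile.intensities[lectin_a]
    b = profile.intensities[lectin_b]
    table = pd.DataFrame({"angle_rad": profile.angles,
                          lectin_a: a, lectin_b: b})
    if np.std(a) == 0 or np.std(b) == 0:
        return SegregationResult(float("nan"), table)
    corr = float(np.corrcoef(a, b)[0, 1])
    return SegregationResult(corr, table)
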