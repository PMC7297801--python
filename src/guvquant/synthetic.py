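"""Forward simulation of GUV equatorial sections and polarized-cell stacks.

The generator is the ground-truth oracle for the quantification pipeline.
A GUV appears in an equatorial confocal section as a circular rim; the
membrane-marker channel carries rim signal only (bright on liquid-disordered
arcs, dim on liquid-ordered arcs, emulating a BODIPY-type ld marker), while
each lectin channel shows the free-lectin solution outside the vesicle, a
lectin-free lumen inside, and a rim whose centerline intensity is
``(1 + contrast) * solution`` — the generative inverse of the binding
efficiency statistic.

Signal formation, in order: analytic noise-free field sampled at pixel
centers -> Gaussian PSF blur -> Poisson shot noise on photon-scaled signal
-> additive Gaussian read noise -> clip at zero.  A single integer seed
drives one ``numpy.random.Generator`` for the whole scene, so a seed fully
determines the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import SceneError
from .image import MARKER, MultiChannelImage

TWO_PI = 2.0 * np.pi

#: margin (in units of rim_width) beyond the nominal radius that is treated
#: as belonging to the rim band when checking overlap / border contact
RIM_BAND_SIGMAS = 3.0


# ---------------------------------------------------------------------------
# scene specifications


@dataclass
class GuvSpec:
    """Geometry and photometry of one simulated vesicle.

    ``phase_arcs`` is a list of ``(start_rad, end_rad, label)`` with labels
    in {"ld", "lo"} that must partition [0, 2*pi).  ``lectin_contrast`` maps
    a lectin channel role to per-phase contrast values (>= -1); rim
    centerline intensity in that channel is ``(1 + contrast) * solution``.
    """

    center_xy: tuple[float, float]
    radius: float
    rim_width: float = 2.0
    phase_arcs: list[tuple[float, float, str]] = field(
        default_factory=lambda: [(0.0, TWO_PI, "ld")])
    marker_rim_intensity: dict[str, float] = field(
        default_factory=lambda: {"ld": 150.0, "lo": 37.5})
    lectin_contrast: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"lectin_1": {"ld": 7.0, "lo": 7.0}})

    def __post_init__(self) -> None:
        if not (self.radius > self.rim_width > 0):
            raise SceneError("need radius > rim_width > 0")
        arcs = sorted(self.phase_arcs, key=lambda a: a[0])
        cursor = 0.0
        for start, end, label in arcs:
            if label not in ("ld", "lo"):
                raise SceneError(f"unknown phase label {label!r}")
            if not np.isclose(start, cursor, atol=1e-9):
                raise SceneError("phase_arcs must partition [0, 2*pi) without "
                                 f"gaps/overlaps (gap at {cursor:.6f})")
            if end <= start:
                raise SceneError("phase arc must have end > start")
            cursor = end
        if not np.isclose(cursor, TWO_PI, atol=1e-9):
            raise SceneError("phase_arcs must cover the full circle")
        self.phase_arcs = arcs
        for role, per_phase in self.lectin_contrast.items():
            for phase, c in per_phase.items():
                if c < -1:
                    raise SceneError(
                        f"contrast {c} for {role}/{phase} is < -1 "
                        "(rim intensity cannot be negative)")

    def phase_at(self, theta: np.ndarray) -> np.ndarray:
        """Phase label index array for angles in [0, 2*pi): 0 = first arc."""
        theta = np.asarray(theta) % TWO_PI
        starts = np.array([a[0] for a in self.phase_arcs])
        return np.clip(np.searchsorted(starts, theta, side="right") - 1,
                       0, len(self.phase_arcs) - 1)

    def arc_labels(self) -> list[str]:
        return [a[2] for a in self.phase_arcs]


@dataclass
class NoiseSpec:
    """Poisson shot noise (``poisson_scale`` photons per a.u.; 0 disables)
    plus additive Gaussian read noise (a.u.; 0 disables)."""

    gaussian_sigma: float = 2.0
    poisson_scale: float = 5.0


@dataclass
class SceneSpec:
    """One simulated field of view with one or more GUVs."""

    guvs: list[GuvSpec]
    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1
    solution_intensity: dict[str, float] = field(
        default_factory=lambda: {"lectin_1": 100.0})
    background_offset: float = 0.0
    psf_sigma: float = 1.0
    noise: NoiseSpec | None = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for role, s in self.solution_intensity.items():
            if s <= 0:
                raise SceneError(f"solution_intensity for {role} must be > 0 "
                                 "(the binding statistic divides by it)")
        for guv in self.guvs:
            for role in guv.lectin_contrast:
                if role not in self.solution_intensity:
                    raise SceneError(f"GUV references lectin role {role!r} with "
                                     "no solution_intensity configured")

    @property
    def lectin_roles(self) -> list[str]:
        return sorted(self.solution_intensity)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GuvTruth:
    center_xy: tuple[float, float]
    radius: float
    rim_width: float
    phase_arcs: list[tuple[float, float, str]]
    marker_rim_intensity: dict[str, float]
    lectin_contrast: dict[str, dict[str, float]]
    border_touching: bool


@dataclass
class GroundTruthRecord:
    """JSON-serializable record of everything the simulator drew."""

    image_shape: tuple[int, ...]
    pixel_size: float
    solution_intensity: dict[str, float]
    background_offset: float
    psf_sigma: float
    noise: dict | None
    seed: int
    guvs: list[GuvTruth]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthRecord":
        raw = json.loads(Path(path).read_text())
        guvs = [GuvTruth(**{**g,
                            "center_xy": tuple(g["center_xy"]),
                            "phase_arcs": [tuple(a) for a in g["phase_arcs"]]})
                for g in raw.pop("guvs")]
        raw["image_shape"] = tuple(raw["image_shape"])
        return cls(guvs=guvs, **raw)


# ---------------------------------------------------------------------------
# GUV scene rendering


def _check_layout(scene: SceneSpec) -> list[bool]:
    """Reject rim-band overlaps; return per-GUV border_touching flags."""
    h, w = scene.image_shape
    border = []
    for i, a in enumerate(scene.guvs):
        band_a = a.radius + RIM_BAND_SIGMAS * a.rim_width
        cx, cy = a.center_xy
        border.append(not (band_a <= cx <= w - 1 - band_a
                           and band_a <= cy <= h - 1 - band_a))
        for b in scene.guvs[i + 1:]:
            band_b = b.radius + RIM_BAND_SIGMAS * b.rim_width
            dist = np.hypot(a.center_xy[0] - b.center_xy[0],
                            a.center_xy[1] - b.center_xy[1])
            if dist < band_a + band_b:
                raise SceneError(
                    "GUV rim bands overlap; the scene's ground truth would be "
                    f"ill-posed (centers {a.center_xy} and {b.center_xy})")
    return border


def _apply_noise(data: np.ndarray, noise: NoiseSpec | None,
                 rng: np.random.Generator) -> np.ndarray:
    if noise is None:
        return data
    out = data
    if noise.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.poisson_scale)
        out = out / noise.poisson_scale
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma, size=data.shape)
    return np.clip(out, 0.0, None)


def simulate_guv_image(scene: SceneSpec) -> tuple[MultiChannelImage, GroundTruthRecord]:
    """Render a multi-channel equatorial-section image plus its ground truth.

    Channel 0 is the membrane marker; lectin channels follow in sorted role
    order.  Raises :class:`SceneError` when two GUVs' rim bands overlap.
    """
    border_flags = _check_layout(scene)
    h, w = scene.image_shape
    lectins = scene.lectin_roles
    roles = {MARKER: 0, **{r: i + 1 for i, r in enumerate(lectins)}}

    yy, xx = np.indices((h, w), dtype=float)
    marker = np.full((h, w), scene.background_offset)
    lectin_imgs = {r: np.full((h, w), scene.solution_intensity[r]) for r in lectins}

    # lumens first (disks are disjoint by construction), then rim bumps
    for guv in scene.guvs:
        cx, cy = guv.center_xy
        r = np.hypot(xx - cx, yy - cy)
        inside = r < guv.radius
        for role in lectins:
            lectin_imgs[role][inside] = scene.background_offset

    for guv in scene.guvs:
        cx, cy = guv.center_xy
        r = np.hypot(xx - cx, yy - cy)
        theta = np.arctan2(yy - cy, xx - cx) % TWO_PI
        bump = np.exp(-0.5 * ((r - guv.radius) / guv.rim_width) ** 2)
        arc_idx = guv.phase_at(theta)
        labels = guv.arc_labels()
        marker_amp = np.choose(arc_idx,
                               [guv.marker_rim_intensity[l] for l in labels])
        marker += marker_amp * bump
        for role in lectins:
            per_phase = guv.lectin_contrast.get(role)
            if per_phase is None:
                continue
            amp = np.choose(arc_idx, [per_phase.get(l, 0.0) for l in labels])
            lectin_imgs[role] += amp * scene.solution_intensity[role] * bump

    # negative contrasts can push the lumen-side rim tail below zero;
    # physical intensities are non-negative
    data = np.clip(np.stack([marker] + [lectin_imgs[r] for r in lectins]),
                   0.0, None)
    if scene.psf_sigma > 0:
        data = np.stack([ndimage.gaussian_filter(c, scene.psf_sigma) for c in data])

    rng = np.random.default_rng(scene.seed)
    data = _apply_noise(data, scene.noise, rng)

    image = MultiChannelImage(data, roles, scene.pixel_size)
    truth = GroundTruthRecord(
        image_shape=scene.image_shape,
        pixel_size=scene.pixel_size,
        solution_intensity=dict(scene.solution_intensity),
        background_offset=scene.background_offset,
        psf_sigma=scene.psf_sigma,
        noise=asdict(scene.noise) if scene.noise else None,
        seed=scene.seed,
        guvs=[GuvTruth(center_xy=g.center_xy, radius=g.radius,
                       rim_width=g.rim_width, phase_arcs=list(g.phase_arcs),
                       marker_rim_intensity=dict(g.marker_rim_intensity),
                       lectin_contrast={k: dict(v)
                                        for k, v in g.lectin_contrast.items()},
                       border_touching=flag)
              for g, flag in zip(scene.guvs, border_flags)],
    )
    return image, truth


# ---------------------------------------------------------------------------
# polarized-cell stacks


@dataclass
class CellSceneSpec:
    """A polarized epithelial monolayer on a grid of rectangular cells.

    A fraction ``labeled_fraction`` of cells express the receptor and carry
    lectin signal: apical membrane voxels (top of the monolayer slab) at
    ``ap_intensity`` and basolateral voxels (bottom + lateral walls) at
    ``bl_intensity``, per lectin role.  This emulates receptor-positive
    cells diluted 1:10 into an unlabeled monolayer so that single labeled
    cells can be measured in isolation.
    """

    stack_shape: tuple[int, int, int] = (16, 160, 160)  # (Z, Y, X)
    n_cells: int = 100
    cell_size: int = 16
    membrane_thickness: int = 2
    ap_intensity: dict[str, float] = field(default_factory=lambda: {"lectin_1": 70.0})
    bl_intensity: dict[str, float] = field(default_factory=lambda: {"lectin_1": 10.0})
    labeled_fraction: float = 0.1
    background_offset: float = 0.0
    pixel_size: float = 0.25
    noise: NoiseSpec | None = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.labeled_fraction <= 1:
            raise SceneError("labeled_fraction must be in (0, 1]")
        for d in (self.ap_intensity, self.bl_intensity):
            for role, v in d.items():
                if v < 0:
                    raise SceneError("membrane intensities must be >= 0")
        z, y, x = self.stack_shape
        if self.capacity < self.n_cells:
            raise SceneError(f"{self.n_cells} cells do not fit a "
                             f"{y // self.cell_size}x{x // self.cell_size} grid")
        if z < 2 * self.membrane_thickness + 2:
            raise SceneError("stack too shallow for a monolayer")

    @property
    def capacity(self) -> int:
        _, y, x = self.stack_shape
        return (y // self.cell_size) * (x // self.cell_size)

    @property
    def lectin_roles(self) -> list[str]:
        return sorted(set(self.ap_intensity) | set(self.bl_intensity))


@dataclass
class CellTruth:
    cell_id: int
    row: int
    col: int
    bbox_xy: tuple[int, int, int, int]  # x0, y0, x1, y1 (exclusive)
    labeled: bool
    isolated: bool
    ap_intensity: dict[str, float]
    bl_intensity: dict[str, float]


@dataclass
class CellGroundTruth:
    """Per-cell truth plus apical/basolateral label stacks (cell_id + 1)."""

    stack_shape: tuple[int, int, int]
    pixel_size: float
    isolation_margin_um: float
    seed: int
    n_labeled: int
    cells: list[CellTruth]
    ap_labels: np.ndarray
    bl_labels: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload.pop("ap_labels")
        payload.pop("bl_labels")
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _rect_gap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    """Euclidean gap between two axis-aligned rectangles (0 if they touch)."""
    dx = max(b[0] - a[2], a[0] - b[2], 0)
    dy = max(b[1] - a[3], a[1] - b[3], 0)
    return float(np.hypot(dx, dy))


def simulate_cell_stack(scene: CellSceneSpec,
                        isolation_margin_um: float = 2.0
                        ) -> tuple[MultiChannelImage, CellGroundTruth]:
    """Render a 3-D polarized-monolayer stack and its per-cell ground truth.

    The seeded generator draws the labeled/unlabeled state of each cell
    first (``rng.random(n_cells) < labeled_fraction``), then the noise, so
    the labeled-cell draw is reproducible from the seed alone.
    """
    z, y, x = scene.stack_shape
    rng = np.random.default_rng(scene.seed)
    labeled = rng.random(scene.n_cells) < scene.labeled_fraction

    roles = {r: i for i, r in enumerate(scene.lectin_roles)}
    data = np.full((len(roles), z, y, x), scene.background_offset)
    ap_labels = np.zeros((z, y, x), dtype=np.int32)
    bl_labels = np.zeros((z, y, x), dtype=np.int32)

    t = scene.membrane_thickness
    z0, z1 = 1, z - 1                      # monolayer slab
    cols = x // scene.cell_size

    cells: list[CellTruth] = []
    for cid in range(scene.n_cells):
        row, col = divmod(cid, cols)
        x0, y0 = col * scene.cell_size, row * scene.cell_size
        x1, y1 = x0 + scene.cell_size, y0 + scene.cell_size
        if labeled[cid]:
            # label masks cover receptor-positive cells only: they are the
            # measurable units, and isolation is defined against them
            # apical: top slab of the footprint interior
            ap = (slice(z1 - t, z1), slice(y0 + 1, y1 - 1), slice(x0 + 1, x1 - 1))
            ap_labels[ap] = cid + 1
            # basolateral: bottom slab + lateral walls
            bl_labels[z0:z0 + t, y0:y1, x0:x1] = cid + 1
            wall = np.zeros((y, x), dtype=bool)
            wall[y0:y1, x0:x1] = True
            wall[y0 + 1:y1 - 1, x0 + 1:x1 - 1] = False
            bl_labels[z0 + t:z1 - t, wall] = cid + 1
        cells.append(CellTruth(
            cell_id=cid, row=row, col=col, bbox_xy=(x0, y0, x1, y1),
            labeled=bool(labeled[cid]), isolated=False,
            ap_intensity={r: (scene.ap_intensity.get(r, 0.0) if labeled[cid] else 0.0)
                          for r in roles},
            bl_intensity={r: (scene.bl_intensity.get(r, 0.0) if labeled[cid] else 0.0)
                          for r in roles},
        ))

    margin_px = isolation_margin_um / scene.pixel_size
    for c in cells:
        if not c.labeled:
            continue
        c.isolated = all(
            _rect_gap(c.bbox_xy, other.bbox_xy) > margin_px
            for other in cells
            if other.cell_id != c.cell_id and other.labeled)

    for c in cells:
        if not c.labeled:
            continue
        for role, ch in roles.items():
            data[ch][ap_labels == c.cell_id + 1] = c.ap_intensity[role]
            data[ch][bl_labels == c.cell_id + 1] = c.bl_intensity[role]

    data = _apply_noise(data, scene.noise, rng)
    image = MultiChannelImage(data, roles, scene.pixel_size)
    truth = CellGroundTruth(
        stack_shape=scene.stack_shape, pixel_size=scene.pixel_size,
        isolation_margin_um=isolation_margin_um, seed=scene.seed,
        n_labeled=int(labeled.sum()), cells=cells,
        ap_labels=ap_labels, bl_labels=bl_labels,
    )
    return image, truth
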