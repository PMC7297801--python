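"""Multi-channel image container and TIFF + sidecar-config I/O.

Conventions shared by every module in the package:

* pixel coordinates are 0-based, origin at the top-left, y increasing
  downwards; a point is addressed as ``(x, y)`` in that frame while arrays
  are indexed ``[y, x]`` (or ``[z, y, x]`` for stacks);
* angles are measured counter-clockwise from the +x axis in the
  mathematical sense, i.e. ``x = cx + r cos(theta)``,
  ``y = cy + r sin(theta)``, and live in ``[0, 2*pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import ConfigError

#: channel roles understood by the pipeline
MARKER = "marker"
LECTIN_1 = "lectin_1"
LECTIN_2 = "lectin_2"
KNOWN_ROLES = (MARKER, LECTIN_1, LECTIN_2)


@dataclass
class MultiChannelImage:
    """A stack of co-registered intensity channels with a role map.

    Parameters
    ----------
    data
        Array of shape ``(C, Y, X)`` for 2-D images or ``(C, Z, Y, X)`` for
        z-stacks, arbitrary units, non-negative.
    channel_roles
        Maps a role name (``marker``, ``lectin_1``, ``lectin_2``) to the
        channel index along the first axis.
    pixel_size
        Lateral pixel size in micrometres per pixel.
    """

    data: np.ndarray
    channel_roles: dict[str, int]
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ConfigError(
                f"expected (C, Y, X) or (C, Z, Y, X) data, got shape {self.data.shape}"
            )
        if np.any(self.data < 0):
            raise ConfigError("intensities must be non-negative")
        n_channels = self.data.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_channels:
                raise ConfigError(f"role {role!r} maps to channel {idx}, "
                                  f"but the image has {n_channels} channels")
        indices = list(self.channel_roles.values())
        if len(set(indices)) != len(indices):
            raise ConfigError("channel roles must map to distinct channels")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")

    # -- accessors ---------------------------------------------------------
    @property
    def is_stack(self) -> bool:
        return self.data.ndim == 4

    @property
    def shape(self) -> tuple[int, ...]:
        """Spatial shape, without the channel axis."""
        return self.data.shape[1:]

    @property
    def roles(self) -> list[str]:
        return list(self.channel_roles)

    @property
    def lectin_roles(self) -> list[str]:
        return [r for r in self.channel_roles if r.startswith("lectin")]

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise ConfigError(f"image has no channel with role {role!r}; "
                              f"available: {sorted(self.channel_roles)}")
        return self.data[self.channel_roles[role]]


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O


def write_image(image: MultiChannelImage, tiff_path: str | Path,
                sidecar_path: str | Path | None = None) -> Path:
    """Write one TIFF page per channel plus a YAML sidecar with the role map."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, image.data.astype(np.float32))
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".channels.yaml")
    meta = {
        "channel_roles": {k: int(v) for k, v in image.channel_roles.items()},
        "pixel_size_um": float(image.pixel_size),
    }
    Path(sidecar_path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return tiff_path


def read_image(tiff_path: str | Path,
               sidecar_path: str | Path | None = None,
               channel_roles: dict[str, int] | None = None,
               pixel_size: float | None = None) -> MultiChannelImage:
    """Read a multi-channel TIFF; roles come from the sidecar unless given."""
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if channel_roles is None or pixel_size is None:
        if sidecar_path is None:
            sidecar_path = tiff_path.with_suffix(".channels.yaml")
        sidecar_path = Path(sidecar_path)
        if not sidecar_path.exists():
            raise ConfigError(f"no channel-role sidecar found at {sidecar_path}")
        meta = yaml.safe_load(sidecar_path.read_text())
        if channel_roles is None:
            channel_roles = {str(k): int(v) for k, v in meta["channel_roles"].items()}
        if pixel_size is None:
            pixel_size = float(meta.get("pixel_size_um", 0.1))
    return MultiChannelImage(data, channel_roles, pixel_size)
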