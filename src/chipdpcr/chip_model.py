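"""Chip geometry and fluorescence-panel configuration.

The device modelled throughout this package is a microfluidic digital-PCR
chip: a rectangular array of cylindrical microchambers (each an isolated
sub-nanolitre reaction) fed by parallel fluid channels.  The default
geometry is a chip with 54 parallel channels serving 108 rows of 198
chambers each — 21,384 chambers in total — where every chamber is a
cylinder of 87 µm diameter and 120 µm height, i.e. about 0.71 nL.

Two configuration objects live here:

``ChipLayout``
    The geometric description of the chamber array.  It owns the two
    quantities that enter the Poisson quantification formula: the total
    chamber count ``n`` and the single-chamber volume ``Vd``.

``PanelConfig``
    The probe-to-fluorescence-channel assignment for multiplex mutation
    typing: one universal *reference* probe that responds to every target
    template (wild-type or mutant) plus up to three mutation-specific
    probes, each on its own colour channel.

Unit conventions (centralised here):

* lengths are micrometres (µm);
* chamber volume is carried in microlitres (µL) wherever it feeds the
  concentration estimate ``C = -ln(1 - d/n) / Vd`` (copies/µL), and in
  nanolitres for human-readable display.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ChipLayout",
    "PanelConfig",
    "DEFAULT_LAYOUT",
    "DEFAULT_PANEL",
    "total_chambers",
    "chamber_volume",
    "chamber_volume_ul",
    "grid_centres_um",
    "grid_centres_px",
    "grid_image_shape",
    "load_chip_config",
    "default_chip_config",
]

#: µm³ per nanolitre (1 nL = 1e6 µm³)
_UM3_PER_NL = 1.0e6
#: nanolitres per microlitre
_NL_PER_UL = 1.0e3


@dataclass(frozen=True)
class ChipLayout:
    """Geometric description of the chamber array.

    Parameters
    ----------
    n_channels : int
        Number of parallel fluid channels feeding the array.
    n_rows : int
        Number of chamber-array rows.
    chambers_per_row : int
        Chambers in each row.
    chamber_diameter, chamber_height : float
        Cylindrical chamber dimensions, µm.
    channel_width, channel_height : float
        Fluid-channel cross-section, µm (metadata; no effect on statistics).
    pitch_x, pitch_y : float
        Centre-to-centre chamber spacing, µm.  Used only for rendering and
        grid registration, never for counting or volume.
    """

    n_channels: int = 54
    n_rows: int = 108
    chambers_per_row: int = 198
    chamber_diameter: float = 87.0
    chamber_height: float = 120.0
    channel_width: float = 60.0
    channel_height: float = 55.0
    pitch_x: float = 110.0
    pitch_y: float = 110.0

    def __post_init__(self) -> None:
        for name in ("n_channels", "n_rows", "chambers_per_row"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in (
            "chamber_diameter",
            "chamber_height",
            "channel_width",
            "channel_height",
            "pitch_x",
            "pitch_y",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")

    @property
    def total_chambers(self) -> int:
        """Total chamber count ``n`` = n_rows x chambers_per_row."""
        return self.n_rows * self.chambers_per_row

    @property
    def chamber_volume_nl(self) -> float:
        """Single-chamber volume ``Vd`` in nanolitres (full precision)."""
        r = self.chamber_diameter / 2.0
        return math.pi * r * r * self.chamber_height / _UM3_PER_NL

    @property
    def chamber_volume_ul(self) -> float:
        """Single-chamber volume ``Vd`` in microlitres, as used by the
        Poisson concentration formula (copies/µL)."""
        return self.chamber_volume_nl / _NL_PER_UL

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChipLayout":
        return cls(**d)


def total_chambers(layout: ChipLayout) -> int:
    """Total number of microchambers on the chip (``n`` of the Poisson
    quantification formula)."""
    return layout.total_chambers


def chamber_volume(layout: ChipLayout) -> float:
    """Single-chamber volume in nanolitres.

    Computed as pi * (diameter/2)^2 * height with no internal rounding;
    round only for display (the default chip prints as 0.71 nL).
    """
    return layout.chamber_volume_nl


def chamber_volume_ul(layout: ChipLayout) -> float:
    """Single-chamber volume in microlitres (``Vd`` of the concentration
    estimate)."""
    return layout.chamber_volume_ul


@dataclass(frozen=True)
class PanelConfig:
    """Probe panel: which fluorescence channel carries which probe.

    A four-colour panel consists of a universal reference probe (detects
    every target template, mutant or wild-type) plus at most three
    mutation-specific probes.  Gating a mutation call on the reference
    channel excludes false positives from impurity interference: a chamber
    that lights up in a mutation channel but not in the reference channel
    cannot contain a genuine target template.

    Parameters
    ----------
    channels : tuple of str
        Ordered channel names (e.g. ``("Cy5", "FAM", "HEX", "ROX")``).
    reference_channel : str
        Channel carrying the universal reference probe.
    target_map : dict
        Mutation label -> channel name; each non-reference channel carries
        at most one mutation probe.
    """

    channels: tuple = ("Cy5", "FAM", "HEX", "ROX")
    reference_channel: str = "Cy5"
    target_map: dict = field(
        default_factory=lambda: {"G12S": "FAM", "G12D": "HEX", "G12V": "ROX"}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.reference_channel not in self.channels:
            raise ValueError(
                f"reference_channel {self.reference_channel!r} not in channels"
            )
        if len(self.target_map) > 3:
            raise ValueError("at most 3 mutation types per panel (one chip)")
        seen_channels = set()
        for mut, ch in self.target_map.items():
            if ch == self.reference_channel:
                raise ValueError(
                    f"mutation {mut!r} may not map to the reference channel"
                )
            if ch not in self.channels:
                raise ValueError(f"mutation {mut!r} maps to unknown channel {ch!r}")
            if ch in seen_channels:
                raise ValueError(f"channel {ch!r} carries more than one mutation probe")
            seen_channels.add(ch)

    @property
    def mutation_channels(self) -> dict:
        """Mutation label -> channel, in panel order."""
        return dict(self.target_map)

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "reference_channel": self.reference_channel,
            "target_map": dict(self.target_map),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelConfig":
        return cls(
            channels=tuple(d["channels"]),
            reference_channel=d["reference_channel"],
            target_map=dict(d.get("target_map", {})),
        )


#: The default chip: 54 channels, 108 rows x 198 chambers (21,384 total),
#: 87 µm x 120 µm cylinders (~0.71 nL).  Pitch 110 µm is a rendering
#: parameter only (chosen > diameter so drawn chambers do not touch).
DEFAULT_LAYOUT = ChipLayout()

#: Default 4-colour panel: Cy5 reference plus three codon-12 mutation probes.
DEFAULT_PANEL = PanelConfig()


# ---------------------------------------------------------------------------
# Grid geometry shared by the renderer and the image-analysis registration.
# ---------------------------------------------------------------------------

def grid_centres_um(layout: ChipLayout) -> np.ndarray:
    """Nominal chamber-centre coordinates in µm, row-major from top-left.

    Returns an (n, 2) array of (x, y) with x increasing along a row and
    y increasing down rows; a margin of one pitch surrounds the array.
    """
    cols = np.arange(layout.chambers_per_row)
    rows = np.arange(layout.n_rows)
    x = layout.pitch_x + cols * layout.pitch_x
    y = layout.pitch_y + rows * layout.pitch_y
    xx, yy = np.meshgrid(x, y)  # row-major: rows vary slowest
    return np.column_stack([xx.ravel(), yy.ravel()])


def grid_centres_px(layout: ChipLayout, pixel_scale: float) -> np.ndarray:
    """Nominal chamber centres in pixels (x right, y down, 0-based) for a
    given rendering scale in µm per pixel."""
    if not pixel_scale > 0:
        raise ValueError("pixel_scale must be > 0")
    return grid_centres_um(layout) / pixel_scale


def grid_image_shape(layout: ChipLayout, pixel_scale: float) -> tuple:
    """(height, width) in pixels of the rendered chip image, including the
    one-pitch margin on every side."""
    width_um = (layout.chambers_per_row - 1) * layout.pitch_x + 2 * layout.pitch_x
    height_um = (layout.n_rows - 1) * layout.pitch_y + 2 * layout.pitch_y
    return (
        int(math.ceil(height_um / pixel_scale)),
        int(math.ceil(width_um / pixel_scale)),
    )


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def load_chip_config(path) -> tuple:
    """Read a chip configuration (YAML or JSON) into (ChipLayout, PanelConfig).

    The file holds two top-level keys, ``layout`` and ``panel``; either may
    be omitted, in which case the default chip / default panel is used.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"chip config {path} must be a mapping")
    layout = (
        ChipLayout.from_dict(doc["layout"]) if "layout" in doc else DEFAULT_LAYOUT
    )
    panel = PanelConfig.from_dict(doc["panel"]) if "panel" in doc else DEFAULT_PANEL
    return layout, panel


def default_chip_config() -> tuple:
    """The bundled default chip configuration (layout, panel)."""
    ref = resources.files("chipdpcr").joinpath("data/default_chip.yaml")
    doc = yaml.safe_load(ref.read_text())
    return (
        ChipLayout.from_dict(doc["layout"]),
        PanelConfig.from_dict(doc["panel"]),
    )
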