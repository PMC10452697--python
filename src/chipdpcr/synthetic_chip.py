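"""Ground-truthed synthetic chips: Poisson loading, detection, rendering.

The simulator emulates what a chamber-array dPCR run produces: template
molecules distributed over the chambers at limiting dilution, end-point
amplification turning occupied chambers bright, and a four-channel
fluorescence reader imaging the array.

Loading model
-------------
Each template species ``s`` at in-chamber concentration ``C_s`` (copies/µL)
lands in a chamber of volume ``Vd`` (µL) as an independent Poisson draw
with mean ``lambda_s = C_s * Vd``; the expected positive fraction for a
single species is ``1 - exp(-lambda_s)``.  Independent per-chamber Poisson
draws are equivalent to multinomial assignment of a Poisson-distributed
total in the dilute limit, which is exactly the regime the inversion
formula ``C = -ln(1 - d/n)/Vd`` assumes.

Species whose label appears in the panel's ``target_map`` are mutant
templates (they light their mapped channel *and* the reference channel);
any other species is wild-type (reference channel only).

Stock versus in-chamber concentration
-------------------------------------
Concentrations are in-chamber (final reaction mix).  A serially diluted
stock enters the mix at a fixed volumetric ratio; the default
``dilution_factor`` of 3.5/31.7 reflects 3.5 µL of template in a
~31.7 µL reaction, so stock 2e4 copies/µL becomes ~2208 copies/µL in the
chamber.  Use :func:`stock_to_chamber` to convert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import disk as _draw_disk

from .chip_model import (
    ChipLayout,
    PanelConfig,
    DEFAULT_LAYOUT,
    DEFAULT_PANEL,
    grid_centres_px,
    grid_image_shape,
)

__all__ = [
    "DEFAULT_DILUTION_FACTOR",
    "ChannelIntensityModel",
    "SimulationConfig",
    "ChipTruth",
    "stock_to_chamber",
    "simulate_partition",
    "render_images",
    "simulate_mixture_series",
    "write_chip_outputs",
]

#: Template volume over total reaction-mix volume: 3.5 µL of serially
#: diluted template in a ~31.7 µL mix.
DEFAULT_DILUTION_FACTOR = 3.5 / 31.7


def stock_to_chamber(stock_concentration: float,
                     dilution_factor: float = DEFAULT_DILUTION_FACTOR) -> float:
    """In-chamber (final mix) concentration from a stock concentration."""
    if stock_concentration < 0:
        raise ValueError("stock concentration must be >= 0")
    if not 0 < dilution_factor <= 1:
        raise ValueError("dilution_factor must be in (0, 1]")
    return stock_concentration * dilution_factor


@dataclass(frozen=True)
class ChannelIntensityModel:
    """Bimodal end-point fluorescence model for one channel.

    Negative chambers draw one intensity from Normal(mu_neg, sigma_neg),
    positive chambers from Normal(mu_pos, sigma_pos); a ``rain_fraction``
    of positive chambers instead draw uniformly between mu_neg and mu_pos
    (partial amplification, "rain").  Units are arbitrary fluorescence
    counts on a 16-bit scale.
    """

    mu_neg: float = 5_000.0
    mu_pos: float = 30_000.0
    sigma_neg: float = 1_500.0
    sigma_pos: float = 1_500.0
    rain_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu_pos > self.mu_neg:
            raise ValueError("mu_pos must exceed mu_neg")
        if self.sigma_neg < 0 or self.sigma_pos < 0:
            raise ValueError("sigmas must be >= 0")
        if not 0 <= self.rain_fraction <= 1:
            raise ValueError("rain_fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Everything needed to simulate one chip.

    ``species_concentrations`` are in-chamber concentrations in copies/µL;
    ``seed`` is mandatory and echoed into every output.
    """

    species_concentrations: dict
    seed: int
    layout: ChipLayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    panel: PanelConfig = field(default_factory=lambda: DEFAULT_PANEL)
    dilution_factor: float = DEFAULT_DILUTION_FACTOR
    detection_efficiency: float = 1.0
    unfilled_fraction: float = 0.0
    intensity_models: dict = field(default_factory=dict)
    pixel_scale: float = 10.0  # µm per pixel
    background_level: float = 2_000.0
    background_noise_sd: float = 200.0
    max_image_dim: int = 8192  # pixels, per side

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        for s, c in self.species_concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for species {s!r}")
        for name in ("detection_efficiency", "unfilled_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be in (0, 1]")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be > 0")
        if self.background_noise_sd < 0 or self.background_level < 0:
            raise ValueError("background parameters must be >= 0")
        # fill in default intensity model for unconfigured channels
        models = dict(self.intensity_models)
        for ch in self.panel.channels:
            models.setdefault(ch, ChannelIntensityModel())
        self.intensity_models = models
        unknown = set(self.species_concentrations) - set(self.panel.target_map)
        mutants = set(self.species_concentrations) & set(self.panel.target_map)
        # anything not in the target map is wild-type (reference only)
        self._wild_species = sorted(unknown)
        self._mutant_species = sorted(mutants)

    @classmethod
    def from_stock(cls, stock_concentrations: dict, seed: int,
                   dilution_factor: float = DEFAULT_DILUTION_FACTOR,
                   **kwargs) -> "SimulationConfig":
        """Build a config from stock concentrations, applying the
        template-in-mix dilution factor."""
        chamber = {
            s: stock_to_chamber(c, dilution_factor)
            for s, c in stock_concentrations.items()
        }
        return cls(species_concentrations=chamber, seed=seed,
                   dilution_factor=dilution_factor, **kwargs)

    def to_dict(self) -> dict:
        return {
            "species_concentrations": dict(self.species_concentrations),
            "seed": int(self.seed),
            "layout": self.layout.to_dict(),
            "panel": self.panel.to_dict(),
            "dilution_factor": self.dilution_factor,
            "detection_efficiency": self.detection_efficiency,
            "unfilled_fraction": self.unfilled_fraction,
            "intensity_models": {
                ch: asdict(m) for ch, m in self.intensity_models.items()
            },
            "pixel_scale": self.pixel_scale,
            "background_level": self.background_level,
            "background_noise_sd": self.background_noise_sd,
        }


@dataclass
class ChipTruth:
    """Simulator ground truth for one chip.

    ``counts`` holds loaded molecules per chamber per species;
    ``detected`` the subset yielding signal after detection-efficiency
    thinning (equal to ``counts`` at efficiency 1).  ``positivity`` maps
    each panel channel to a boolean per-chamber array.  Unfilled chambers
    hold no reaction and are negative everywhere.
    """

    layout: ChipLayout
    panel: PanelConfig
    species: list
    counts: np.ndarray        # (n_chambers, n_species) int
    detected: np.ndarray      # (n_chambers, n_species) int
    filled: np.ndarray        # (n_chambers,) bool
    positivity: dict          # channel -> (n_chambers,) bool
    seed: int

    @property
    def n_chambers(self) -> int:
        return self.layout.total_chambers

    def positives(self, channel: str) -> int:
        """Number of true-positive chambers in a channel."""
        return int(self.positivity[channel].sum())

    def double_positives(self, mutation: str) -> int:
        """Chambers positive in both the reference channel and the
        mutation's channel."""
        ref = self.positivity[self.panel.reference_channel]
        mut = self.positivity[self.panel.target_map[mutation]]
        return int((ref & mut).sum())

    def to_dataframe(self, pixel_scale: float = 10.0) -> pd.DataFrame:
        """Per-chamber table: ids, grid position, pixel centre, molecule
        counts per species and true per-channel calls."""
        layout = self.layout
        n = self.n_chambers
        centres = grid_centres_px(layout, pixel_scale)
        rows = np.repeat(np.arange(layout.n_rows), layout.chambers_per_row)
        cols = np.tile(np.arange(layout.chambers_per_row), layout.n_rows)
        data = {
            "chamber_id": np.arange(n),
            "row": rows,
            "col": cols,
            "x_px": centres[:, 0],
            "y_px": centres[:, 1],
            "filled": self.filled,
        }
        for j, s in enumerate(self.species):
            data[f"count_{s}"] = self.counts[:, j]
        for ch in self.panel.channels:
            data[f"true_call_{ch}"] = self.positivity[ch]
        df = pd.DataFrame(data)
        df.attrs["seed"] = int(self.seed)
        return df


def simulate_partition(config: SimulationConfig) -> ChipTruth:
    """Poisson-load template molecules into the chambers of one chip.

    Each chamber's count for species ``s`` is an independent Poisson draw
    with mean ``C_s * Vd``; detection-efficiency thinning is binomial per
    molecule.  Channel positivity: the reference channel fires when any
    detected template of any species is present; a mutation channel fires
    when a detected molecule of its mapped mutant species is present.
    """
    layout, panel = config.layout, config.panel
    n = layout.total_chambers
    vd_ul = layout.chamber_volume_ul
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    species = sorted(config.species_concentrations)
    lam = np.array([config.species_concentrations[s] * vd_ul for s in species])
    counts = rng.poisson(lam[None, :], size=(n, len(species)))

    filled = rng.random(n) >= config.unfilled_fraction
    counts[~filled, :] = 0  # an unfilled chamber holds no reaction

    if config.detection_efficiency < 1.0:
        detected = rng.binomial(counts, config.detection_efficiency)
    else:
        detected = counts.copy()

    positivity = {}
    any_detected = detected.sum(axis=1) > 0
    for ch in panel.channels:
        if ch == panel.reference_channel:
            positivity[ch] = any_detected & filled
        else:
            pos = np.zeros(n, dtype=bool)
            for mut, mapped in panel.target_map.items():
                if mapped == ch and mut in species:
                    pos |= detected[:, species.index(mut)] > 0
            positivity[ch] = pos & filled

    return ChipTruth(layout=layout, panel=panel, species=species,
                     counts=counts, detected=detected, filled=filled,
                     positivity=positivity, seed=int(config.seed))


def _chamber_disk_offsets(layout: ChipLayout, pixel_scale: float):
    """Pixel offsets of one chamber disk relative to its centre."""
    radius = max(layout.chamber_diameter / 2.0 / pixel_scale, 1.0)
    rr, cc = _draw_disk((0, 0), radius)
    return rr, cc


def render_images(truth: ChipTruth, config: SimulationConfig):
    """Render one 16-bit grayscale image per channel.

    Chambers are drawn as filled disks at the nominal grid positions; each
    filled chamber gets a single intensity draw from its channel's bimodal
    model (so a noise-free configuration reproduces mu_neg / mu_pos
    exactly), and per-pixel Gaussian background noise is added on top.
    Unfilled chambers are not drawn.

    Returns
    -------
    images : dict
        channel name -> uint16 image.
    centres : pandas.DataFrame
        Ground-truth chamber centres in pixel coordinates
        (chamber_id, row, col, x_px, y_px).
    """
    layout = truth.layout
    shape = grid_image_shape(layout, config.pixel_scale)
    if max(shape) > config.max_image_dim:
        raise ValueError(
            f"rendered image {shape} exceeds the {config.max_image_dim}px cap; "
            "increase pixel_scale or the cap"
        )
    centres = grid_centres_px(layout, config.pixel_scale)
    rr0, cc0 = _chamber_disk_offsets(layout, config.pixel_scale)
    cy = np.round(centres[:, 1]).astype(int)
    cx = np.round(centres[:, 0]).astype(int)
    # (n_chambers, disk_px) flat pixel indices, precomputed once
    rows_idx = cy[:, None] + rr0[None, :]
    cols_idx = cx[:, None] + cc0[None, :]

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = truth.n_chambers
    images = {}
    for ch in truth.panel.channels:
        model = config.intensity_models[ch]
        pos = truth.positivity[ch]
        values = np.where(
            pos,
            rng.normal(model.mu_pos, model.sigma_pos, size=n),
            rng.normal(model.mu_neg, model.sigma_neg, size=n),
        )
        if model.rain_fraction > 0:
            rain = pos & (rng.random(n) < model.rain_fraction)
            values[rain] = rng.uniform(model.mu_neg, model.mu_pos,
                                       size=int(rain.sum()))
        img = np.full(shape, config.background_level, dtype=np.float64)
        if config.background_noise_sd > 0:
            img += rng.normal(0.0, config.background_noise_sd, size=shape)
        drawn = truth.filled
        img[rows_idx[drawn].ravel(), cols_idx[drawn].ravel()] = np.repeat(
            values[drawn], rr0.size
        )
        images[ch] = np.clip(img, 0, 65535).astype(np.uint16)

    rows = np.repeat(np.arange(layout.n_rows), layout.chambers_per_row)
    cols = np.tile(np.arange(layout.chambers_per_row), layout.n_rows)
    centre_table = pd.DataFrame({
        "chamber_id": np.arange(n),
        "row": rows,
        "col": cols,
        "x_px": centres[:, 0],
        "y_px": centres[:, 1],
    })
    return images, centre_table


def simulate_mixture_series(fractions, total_stock_concentration: float,
                            reps: int, seed: int,
                            mutation: str = "G12D",
                            wild_label: str = "WT",
                            layout: ChipLayout = DEFAULT_LAYOUT,
                            panel: PanelConfig = DEFAULT_PANEL,
                            dilution_factor: float = DEFAULT_DILUTION_FACTOR,
                            render: bool = False,
                            **config_kwargs):
    """Simulate chips over a series of mutation fractions.

    For each fraction ``f`` the mutant species gets in-chamber
    concentration ``f * total`` and the wild-type ``(1 - f) * total``,
    where ``total = total_stock_concentration * dilution_factor``.  The
    reference channel responds to both species, the mutation channel to
    the mutant only.

    Returns a list (per fraction) of lists (per replicate) of
    ``(ChipTruth, images_or_None)`` pairs.  Seeds are spawned
    deterministically from ``seed``.
    """
    fractions = list(fractions)
    for f in fractions:
        if not 0 <= f <= 1:
            raise ValueError(f"mutation fraction {f} outside [0, 1]")
    if total_stock_concentration < 0:
        raise ValueError("total concentration must be >= 0")
    if mutation not in panel.target_map:
        raise ValueError(f"mutation {mutation!r} not in panel")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    total = stock_to_chamber(total_stock_concentration, dilution_factor)
    # independent 32-bit seeds per (fraction, rep), reproducible from `seed`
    seed_rng = np.random.default_rng(int(seed))
    chip_seeds = seed_rng.integers(0, 2**31, size=(len(fractions), reps))

    out = []
    for i, f in enumerate(fractions):
        level = []
        for r in range(reps):
            cfg = SimulationConfig(
                species_concentrations={mutation: f * total,
                                        wild_label: (1.0 - f) * total},
                seed=int(chip_seeds[i, r]),
                layout=layout, panel=panel,
                dilution_factor=dilution_factor,
                **config_kwargs,
            )
            truth = simulate_partition(cfg)
            images = render_images(truth, cfg)[0] if render else None
            level.append((truth, images))
        out.append(level)
    return out


def write_chip_outputs(out_dir, chip_id: str, truth: ChipTruth,
                       images: dict, config: SimulationConfig) -> dict:
    """Write one chip's TIFFs, ground-truth CSV and config echo.

    Files: ``<chip_id>_<channel>.tif`` per channel, ``<chip_id>_truth.csv``
    and ``<chip_id>_config.yaml`` (with the seed echoed).  Returns the
    mapping of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ch, img in images.items():
        p = out_dir / f"{chip_id}_{ch}.tif"
        tifffile.imwrite(p, img)
        paths[f"image_{ch}"] = str(p)
    truth_df = truth.to_dataframe(pixel_scale=config.pixel_scale)
    p = out_dir / f"{chip_id}_truth.csv"
    truth_df.to_csv(p, index=False)
    paths["truth"] = str(p)
    p = out_dir / f"{chip_id}_config.yaml"
    p.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    paths["config"] = str(p)
    return paths
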