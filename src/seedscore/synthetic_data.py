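"""Synthetic single-seed tile generator with known ground truth.

Renders the phenotypes that make germination scoring hard to automate: a
dark ellipsoidal seed on a light noisy background, swelling slightly over
time as it takes up water; a protruding radicle once the seed germinates
(the germination signal); translucent mould speckle near and over the seed;
and broken seeds rendered as two displaced half-ellipses. Every image is a
pure function of the generator seed, the seed id and the time point, so
datasets are reproducible and appending seeds never changes existing
images.

Two presets bracket the difficulty range: ``easy`` (clear, long radicles,
no mould or breakage, low noise — the analogue of an optimised image set of
distinctly germinated-or-not seeds) and ``hard`` (short radicles, mould,
broken seeds, higher noise — the analogue of a non-ideal full dataset).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .dataset import make_label_table
from .seed_imaging import DEFAULT_TILE_SHAPE, SeedImage, write_tile

_SEED_COLOUR_TINT = np.array([22.0, 0.0, -26.0])  # brownish cast around base shade
_RADICLE_COLOUR = np.array([132.0, 120.0, 88.0])  # pale shoot, still darker than bg
_MOULD_COLOUR = np.array([138.0, 148.0, 126.0])  # grey-green speckle


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic dataset.

    Lengths are in pixels, shades in 0-255 grey levels. ``radicle_length_range``
    is the protrusion length at the germination time point;
    ``radicle_growth`` is added per subsequent time point.
    """

    n_seeds: int = 200
    n_timepoints: int = 4  # time 0 is the pre-test photograph
    germination_fraction: float = 0.5
    germination_time_range: tuple[int, int] = (1, 3)  # uniform integer, inclusive
    seed_major_axis_range: tuple[float, float] = (28.0, 42.0)  # semi-axis px
    seed_minor_axis_range: tuple[float, float] = (14.0, 22.0)
    seed_shade_range: tuple[float, float] = (45.0, 80.0)
    background_shade: float = 200.0
    noise_sd: float = 3.0
    swell_per_timepoint: float = 0.02  # fractional axis inflation per time point
    radicle_length_range: tuple[float, float] = (25.0, 45.0)
    radicle_growth: float = 15.0
    radicle_width_fraction: float = 0.25  # base radius as fraction of minor axis
    mould_probability: float = 0.0
    speckle_density: float = 0.0  # expected mould clusters per time point
    broken_probability: float = 0.0
    tile_shape: tuple[int, int] = DEFAULT_TILE_SHAPE
    rng_seed: int = 1234

    def __post_init__(self) -> None:
        for p in (
            self.germination_fraction,
            self.mould_probability,
            self.broken_probability,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.seed_minor_axis_range[0] < 2 or self.seed_major_axis_range[0] < 2:
            raise ValueError("seed semi-axes must be at least 2 px")
        if self.n_seeds < 1 or self.n_timepoints < 1:
            raise ValueError("need at least one seed and one time point")
        lo, hi = self.germination_time_range
        if not (1 <= lo <= hi):
            raise ValueError("germination times must be >= 1 (time 0 is pre-test)")
        # The seed plus its longest possible radicle must fit in the tile.
        max_axis = self.seed_major_axis_range[1] * (
            1.0 + self.swell_per_timepoint * (self.n_timepoints - 1)
        )
        max_radicle = (
            self.radicle_length_range[1]
            + self.radicle_growth * max(self.n_timepoints - 1 - lo, 0)
        )
        margin = 8.0 + 12.0  # centre jitter + border clearance
        if max_axis + max_radicle + margin > min(self.tile_shape) / 2:
            raise ValueError(
                "tile too small for the configured seed plus maximal radicle"
            )


@dataclass
class SeedParams:
    """Static per-seed phenotype drawn once from the seed's own substream."""

    seed_id: str
    center: tuple[float, float]  # (row, col)
    major: float
    minor: float
    angle: float
    shade: float
    germinates: bool
    germination_time: int  # 0 means never
    radicle_initial: float
    radicle_angle: float
    radicle_curve: float
    mouldy: bool
    broken: bool
    broken_gap: float


def _substream(config: GeneratorConfig, *parts: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed & 0x7FFFFFFF, *parts])


def _seed_tag(seed_id: str) -> int:
    return zlib.crc32(seed_id.encode())


def _germinator_flags(n_seeds: int, fraction: float) -> np.ndarray:
    # Deterministic count = round-half-up(n * fraction); flags are stable
    # under appending seeds (existing seeds keep their status).
    r = np.floor(np.arange(n_seeds + 1) * fraction + 0.5)
    return np.diff(r).astype(bool)


def seed_params(config: GeneratorConfig, index: int) -> SeedParams:
    """Draw the static phenotype of seed ``index`` from its keyed substream."""
    seed_id = f"s{index:04d}"
    rng = _substream(config, 1, _seed_tag(seed_id))
    h, w = config.tile_shape
    germinates = bool(_germinator_flags(config.n_seeds, config.germination_fraction)[index])
    lo, hi = config.germination_time_range
    hi = min(hi, config.n_timepoints - 1) if config.n_timepoints > 1 else lo
    t_germ = int(rng.integers(lo, max(hi, lo) + 1)) if germinates else 0
    return SeedParams(
        seed_id=seed_id,
        center=(
            (h - 1) / 2 + float(rng.uniform(-8, 8)),
            (w - 1) / 2 + float(rng.uniform(-8, 8)),
        ),
        major=float(rng.uniform(*config.seed_major_axis_range)),
        minor=float(rng.uniform(*config.seed_minor_axis_range)),
        angle=float(rng.uniform(0, np.pi)),
        shade=float(rng.uniform(*config.seed_shade_range)),
        germinates=germinates,
        germination_time=t_germ,
        radicle_initial=float(rng.uniform(*config.radicle_length_range)),
        radicle_angle=float(rng.uniform(-0.5, 0.5)),
        radicle_curve=float(rng.uniform(-0.004, 0.004)),
        mouldy=bool(rng.random() < config.mould_probability),
        broken=bool(rng.random() < config.broken_probability),
        broken_gap=float(rng.uniform(4.0, 9.0)),
    )


def radicle_length_at(config: GeneratorConfig, params: SeedParams, t: int) -> float:
    """Scheduled radicle length at time ``t`` (0 if not yet germinated)."""
    if not params.germinates or t < params.germination_time:
        return 0.0
    return params.radicle_initial + config.radicle_growth * (t - params.germination_time)


def _paint_disk(img: np.ndarray, r: float, c: float, radius: float,
                colour: np.ndarray, alpha: float = 1.0) -> None:
    h, w = img.shape[:2]
    r0, r1 = max(int(r - radius) - 1, 0), min(int(r + radius) + 2, h)
    c0, c1 = max(int(c - radius) - 1, 0), min(int(c + radius) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    m = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
    patch = img[r0:r1, c0:c1]
    patch[m] = (1 - alpha) * patch[m] + alpha * colour


def render_seed_tile(
    config: GeneratorConfig, params: SeedParams, time_index: int
) -> tuple[SeedImage, dict]:
    """Render one tile and its ground-truth row, deterministically.

    Time 0 shows the dry (unswollen) seed; later time points inflate the
    seed axes to mimic water uptake and add the radicle/mould/breakage the
    seed's phenotype schedules.
    """
    rng = _substream(config, 2, _seed_tag(params.seed_id), time_index)
    h, w = config.tile_shape
    bg = config.background_shade + np.array([3.0, 1.0, -4.0])
    img = np.tile(bg, (h, w, 1))
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=(h, w, 3))

    swell = 1.0 + config.swell_per_timepoint * time_index
    a, b = params.major * swell, params.minor * swell
    cr, cc = params.center
    cos_t, sin_t = np.cos(params.angle), np.sin(params.angle)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    xr = (xx - cc) * cos_t + (yy - cr) * sin_t  # along major axis
    yr = -(xx - cc) * sin_t + (yy - cr) * cos_t

    seed_colour = params.shade + _SEED_COLOUR_TINT
    if params.broken:
        # Two half-ellipses displaced along the minor axis by the gap.
        for side in (1.0, -1.0):
            off = side * params.broken_gap / 2.0
            mask = ((xr / a) ** 2 + ((yr - off) / b) ** 2 <= 1.0) & (
                side * (yr - off) >= 0
            )
            img[mask] = seed_colour
    else:
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        img[mask] = seed_colour
    # Seed-coat texture so the grey histogram is not a single spike.
    tex_mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    img[tex_mask] += rng.normal(0.0, 4.0, size=(int(tex_mask.sum()), 3))

    radicle_length = radicle_length_at(config, params, time_index)
    if radicle_length > 0:
        # Tapered protrusion from the ellipse apex, slightly bent.
        apex = np.array(
            [cr + a * sin_t * np.cos(params.radicle_angle),
             cc + a * cos_t * np.cos(params.radicle_angle)]
        )
        direction = np.array(
            [sin_t * np.cos(params.radicle_angle) + cos_t * np.sin(params.radicle_angle),
             cos_t * np.cos(params.radicle_angle) - sin_t * np.sin(params.radicle_angle)]
        )
        normal = np.array([direction[1], -direction[0]])
        r_base = max(b * config.radicle_width_fraction, 2.0)
        n_steps = max(int(radicle_length * 2), 2)
        for i in range(n_steps + 1):
            s = radicle_length * i / n_steps
            pos = apex + direction * s + normal * params.radicle_curve * s * s
            radius = max(r_base * (1.0 - 0.75 * s / radicle_length), 1.0)
            _paint_disk(img, pos[0], pos[1], radius, _RADICLE_COLOUR)

    has_mould = params.mouldy and time_index >= 1
    if has_mould:
        n_clusters = int(rng.poisson(config.speckle_density * time_index)) + 1
        for _ in range(n_clusters):
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0.6, 1.5) * a
            centre = np.array([cr + np.sin(ang) * dist, cc + np.cos(ang) * dist])
            for _ in range(int(rng.integers(15, 35))):
                dr, dc = rng.normal(0.0, 5.0, size=2)
                _paint_disk(
                    img,
                    centre[0] + dr,
                    centre[1] + dc,
                    rng.uniform(1.0, 2.2),
                    _MOULD_COLOUR,
                    alpha=float(rng.uniform(0.45, 0.8)),
                )

    image = SeedImage(
        pixels=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        seed_id=params.seed_id,
        dish_id="d0",
        time_index=time_index,
    )
    truth = {
        "seed_id": params.seed_id,
        "time_index": time_index,
        "germinated": int(radicle_length > 0),
        "radicle_length": radicle_length,
        "mould": int(has_mould),
        "broken": int(params.broken),
    }
    return image, truth


@dataclass
class SyntheticDataset:
    """Generated images plus the aligned ground truth and label tables."""

    config: GeneratorConfig
    images: list[SeedImage] | None
    labels: pd.DataFrame  # LabelTable schema, provenance "human"
    ground_truth: pd.DataFrame
    image_dir: Path | None = None


def ground_truth_table(config: GeneratorConfig) -> pd.DataFrame:
    """Ground truth for every (seed, time) without rendering any pixels."""
    rows = []
    for i in range(config.n_seeds):
        p = seed_params(config, i)
        for t in range(config.n_timepoints):
            length = radicle_length_at(config, p, t)
            rows.append(
                {
                    "seed_id": p.seed_id,
                    "time_index": t,
                    "germinated": int(length > 0),
                    "radicle_length": length,
                    "mould": int(p.mouldy and t >= 1),
                    "broken": int(p.broken),
                }
            )
    return pd.DataFrame(rows)


def iter_images(config: GeneratorConfig) -> Iterator[tuple[SeedImage, dict]]:
    """Lazily render every tile (seed-major, time-minor order)."""
    for i in range(config.n_seeds):
        p = seed_params(config, i)
        for t in range(config.n_timepoints):
            yield render_seed_tile(config, p, t)


def generate_dataset(
    config: GeneratorConfig,
    out_dir: str | Path | None = None,
    keep_images: bool = True,
) -> SyntheticDataset:
    """Render the full dataset; optionally write tiles + tables to disk.

    Ground-truth labels are monotone in time by construction (germination
    is irreversible), so the label table is already propagated.
    """
    images: list[SeedImage] | None = [] if keep_images else None
    truths = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for image, truth in iter_images(config):
        truths.append(truth)
        if out_path is not None:
            write_tile(image, out_path)
        if images is not None:
            images.append(image)
    truth_df = pd.DataFrame(truths)
    labels = make_label_table(
        truth_df.rename(columns={"germinated": "label"})[
            ["seed_id", "time_index", "label"]
        ],
        provenance="human",
    )
    if out_path is not None:
        truth_df.to_csv(out_path / "ground_truth.csv", index=False)
        labels.to_csv(out_path / "labels.csv", index=False)
        _write_config_toml(config, out_path / "config.toml")
    return SyntheticDataset(
        config=config,
        images=images,
        labels=labels,
        ground_truth=truth_df,
        image_dir=out_path,
    )


def _write_config_toml(config: GeneratorConfig, path: Path) -> None:
    lines = []
    for key, value in asdict(config).items():
        if isinstance(value, tuple):
            value = list(value)
        if isinstance(value, bool):
            rendered = "true" if value else "false"
        elif isinstance(value, str):
            rendered = f'"{value}"'
        else:
            rendered = repr(value)
        lines.append(f"{key} = {rendered}")
    path.write_text("\n".join(lines) + "\n")


def presets(
    n_seeds: int = 200, n_timepoints: int = 4, rng_seed: int = 1234
) -> dict[str, GeneratorConfig]:
    """Named study conditions.

    ``easy``: distinctly germinated-or-not seeds — long radicles, no mould,
    no broken seeds, low sensor noise (the optimised-subset analogue).
    ``hard``: short radicles barely beyond the swelling confound, mould
    speckle, broken seeds and higher noise (the non-ideal full-set
    analogue).
    """
    common = dict(n_seeds=n_seeds, n_timepoints=n_timepoints, rng_seed=rng_seed)
    return {
        # Clear images: uniform plump seeds, long thick unmistakable radicles.
        "easy": GeneratorConfig(
            germination_fraction=0.5,
            seed_major_axis_range=(32.0, 38.0),
            seed_minor_axis_range=(16.0, 20.0),
            noise_sd=3.0,
            radicle_length_range=(25.0, 45.0),
            radicle_growth=15.0,
            radicle_width_fraction=0.4,
            mould_probability=0.0,
            speckle_density=0.0,
            broken_probability=0.0,
            **common,
        ),
        "hard": GeneratorConfig(
            germination_fraction=0.5,
            noise_sd=8.0,
            radicle_length_range=(5.0, 12.0),
            radicle_growth=4.0,
            mould_probability=0.35,
            speckle_density=2.0,
            broken_probability=0.12,
            **common,
        ),
    }
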