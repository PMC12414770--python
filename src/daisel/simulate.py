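"""Synthetic multi-year two-treatment single-plant trials with known truth.

The generator emulates a randomized-complete-block switchgrass drought
screening: 404 genotypes grown in 3 blocks under a covered drought
treatment (CV, per-block grid of 7 rows × 58 columns) and an uncovered
irrigated control (UC, 14 × 29), repeated over four years. Per-plant dry
yield is built additively on the gram scale:

    y = mu + year_t + treatment + g_i + (GE)_it + spatial(row, col) + eps

with genotype effects g_i ~ N(0, Vg) drawn fresh per simulation but shared
across environments, a low-rank genotype-by-environment interaction built
from outer products of factor vectors (so AMMI axis recovery has known
truth), a smooth Gaussian-process-flavoured spatial surface per field, and
right-skewed residuals (shifted lognormal re-centred to mean zero with
variance Ve, matching the field data's right tail). Yields are clipped at
zero. Plants go missing at a fixed rate and their positions — plus grid
positions beyond the genotype count — are filled with non-study filler
plants, as real border management does.

Blocks are laid side by side along the column axis with a 2-column gap, so
(row, col) are unique global field coordinates.

Everything derives from one integer seed through spawned substreams, so a
(config, seed) pair regenerates the trial bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PlotRecord, Treatment

__all__ = ["SimConfig", "SimTruth", "simulate_trial"]

FILLER_ID = "AP13"  # upland cultivar used as border/filler plant


@dataclass(frozen=True)
class SimConfig:
    """Study-design and variance settings for one simulated trial."""

    n_genotypes: int = 404
    years: tuple[int, ...] = (2019, 2020, 2021, 2022)
    blocks: int = 3
    grid_cv: tuple[int, int] = (7, 58)  # rows × cols per block
    grid_uc: tuple[int, int] = (14, 29)
    mu: float = 1800.0  # grand mean dry yield, g·plant⁻¹
    treatment_effect: float = -250.0  # CV mean minus UC mean, halved each way
    year_effects: tuple[float, ...] = (300.0, 100.0, -100.0, -300.0)
    Vg: float = 400_000.0  # genetic variance, g²
    Ve: float = 300_000.0  # residual variance, g²
    gei_rank: int = 1
    gei_sd: float = 150.0  # SD of the interaction effect, g
    spatial_amplitude: float = 300.0  # g
    spatial_length_scale: float = 8.0  # plants
    skew: float = 0.8  # lognormal sigma of the residual shape; 0 = normal
    missing_rate: float = 0.05
    filler_rate: float = 0.005  # extra positions reserved for fillers
    dry_matter_range: tuple[float, float] = (0.30, 0.50)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.Vg < 0 or self.Ve < 0 or self.spatial_amplitude < 0:
            raise ValueError("variances and amplitudes must be >= 0")
        if not 0 <= self.missing_rate <= 1 or not 0 <= self.filler_rate <= 1:
            raise ValueError("rates must be probabilities")
        for name, (r, c) in (("grid_cv", self.grid_cv), ("grid_uc", self.grid_uc)):
            if r * c < self.n_genotypes:
                raise ValueError(f"{name} capacity {r * c} < {self.n_genotypes} genotypes")
        if len(self.year_effects) != len(self.years):
            raise ValueError("year_effects must match years")


@dataclass
class SimTruth:
    """Ground truth underlying one simulated trial."""

    genotype_ids: list[str]
    genotype_effects: np.ndarray  # (n_genotypes,) main effects, g
    gei: np.ndarray  # (n_genotypes, n_envs) interaction effects, g
    env_labels: list[str]
    env_means: np.ndarray  # mu + year + treatment per environment, g
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)  # per env: (n_plants,)
    surface_coords: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ge_matrix(self) -> np.ndarray:
        """Realized genotype × environment expected-yield matrix."""
        return (
            self.env_means[None, :]
            + self.genotype_effects[:, None]
            + self.gei
        )


def _smooth_surface(coords: np.ndarray, amplitude: float, length_scale: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Smooth random field: sum of a few random low-frequency cosines,
    standardized to SD = amplitude."""
    if amplitude == 0:
        return np.zeros(len(coords))
    n_waves = 6
    ang = rng.uniform(0, 2 * np.pi, n_waves)
    phase = rng.uniform(0, 2 * np.pi, n_waves)
    freq = rng.uniform(0.5, 1.5, n_waves) / length_scale
    w = rng.normal(size=n_waves)
    proj = coords @ np.vstack([np.cos(ang), np.sin(ang)])  # (n, n_waves)
    z = np.cos(2 * np.pi * proj * freq + phase) @ w
    sd = z.std()
    return amplitude * (z - z.mean()) / sd if sd > 0 else np.zeros(len(coords))


def _skewed_noise(n: int, ve: float, skew: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-zero residuals with variance ve; right-skewed when skew > 0."""
    if ve == 0:
        return np.zeros(n)
    if skew <= 0:
        return rng.normal(0.0, np.sqrt(ve), n)
    ln = rng.lognormal(mean=0.0, sigma=skew, size=n)
    ln_sd = np.sqrt((np.exp(skew**2) - 1) * np.exp(skew**2))
    return (ln - np.exp(skew**2 / 2)) * np.sqrt(ve) / ln_sd


def simulate_trial(cfg: SimConfig) -> tuple[list[PlotRecord], SimTruth]:
    """Draw one full trial; returns plot records and the generating truth.

    Records carry fresh weight and subsample masses consistent with the
    simulated dry yield (a uniform dry-matter fraction back-computes the
    fresh weight), so the dry-yield arithmetic can be exercised end to end.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_geno, ss_gei, ss_env = root.spawn(3)
    rng_g = np.random.default_rng(ss_geno)
    rng_gei = np.random.default_rng(ss_gei)

    gids = [f"G{i + 1:03d}" for i in range(cfg.n_genotypes)]
    geffects = (
        rng_g.normal(0.0, np.sqrt(cfg.Vg), cfg.n_genotypes)
        if cfg.Vg > 0
        else np.zeros(cfg.n_genotypes)
    )

    envs = [
        (trt, year, j)
        for trt in (Treatment.CV, Treatment.UC)
        for j, year in enumerate(cfg.years)
    ]
    env_labels = [f"{t.value}{y % 100:02d}" for t, y, _ in envs]
    env_means = np.array(
        [
            cfg.mu
            + cfg.year_effects[j]
            + (cfg.treatment_effect / 2 if t is Treatment.CV else -cfg.treatment_effect / 2)
            for t, _, j in envs
        ]
    )

    gei = np.zeros((cfg.n_genotypes, len(envs)))
    if cfg.gei_sd > 0 and cfg.gei_rank > 0:
        for _ in range(cfg.gei_rank):
            u = rng_gei.normal(size=cfg.n_genotypes)
            v = rng_gei.normal(size=len(envs))
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            gei += np.outer(u, v)
        # standardize total interaction to the requested per-cell SD
        gei *= cfg.gei_sd / gei.std()

    truth = SimTruth(
        genotype_ids=gids,
        genotype_effects=geffects,
        gei=gei,
        env_labels=env_labels,
        env_means=env_means,
    )

    records: list[PlotRecord] = []
    env_streams = ss_env.spawn(len(envs))
    for (trt, year, jy), label, stream in zip(envs, env_labels, env_streams):
        rng = np.random.default_rng(stream)
        jenv = env_labels.index(label)
        nrow, ncol = cfg.grid_cv if trt is Treatment.CV else cfg.grid_uc
        coords_all = []
        rows_all: list[PlotRecord] = []
        surface_vals = []
        for block in range(1, cfg.blocks + 1):
            col_offset = (block - 1) * (ncol + 2)
            positions = [(r, c) for r in range(1, nrow + 1) for c in range(1, ncol + 1)]
            # randomize genotype placement within the block
            perm = rng.permutation(len(positions))
            n_filler_extra = int(round(cfg.filler_rate * len(positions)))
            coords = np.array(
                [[r, c + col_offset] for r, c in positions], dtype=float
            )
            # one smooth surface per block keeps the field trend continuous
            # within a block while blocks stay independent
            surface = _smooth_surface(
                coords, cfg.spatial_amplitude, cfg.spatial_length_scale, rng
            )
            missing = rng.random(len(positions)) < cfg.missing_rate
            noise = _skewed_noise(len(positions), cfg.Ve, cfg.skew, rng)
            dm = rng.uniform(*cfg.dry_matter_range, len(positions))
            sub_fresh = rng.uniform(50.0, 300.0, len(positions))
            # study genotypes take the first slots of the random placement;
            # spare capacity and the reserved filler fraction stay filler
            n_study = min(cfg.n_genotypes, len(positions) - n_filler_extra)
            for slot, pos_idx in enumerate(perm):
                r, c = positions[pos_idx]
                gslot = slot  # genotype index if a study plant
                is_study = gslot < n_study and not missing[pos_idx]
                if is_study:
                    gid = gids[gslot]
                    y = (
                        env_means[jenv]
                        + geffects[gslot]
                        + gei[gslot, jenv]
                        + surface[pos_idx]
                        + noise[pos_idx]
                    )
                else:
                    gid = FILLER_ID
                    y = max(env_means[jenv] + surface[pos_idx] + noise[pos_idx], 0.0)
                y = max(float(y), 0.0)
                rows_all.append(
                    PlotRecord(
                        genotype_id=gid,
                        year=year,
                        treatment=trt,
                        block=block,
                        row=r,
                        col=c + col_offset,
                        fresh_weight=round(y / dm[pos_idx], 4) if y > 0 else 0.0,
                        subsample_fresh=round(float(sub_fresh[pos_idx]), 4),
                        subsample_dry=round(float(sub_fresh[pos_idx] * dm[pos_idx]), 4),
                        dry_yield=y,
                        is_filler=not is_study,
                    )
                )
            coords_all.append(coords)
            surface_vals.append(surface)
        truth.surfaces[label] = np.concatenate(surface_vals)
        truth.surface_coords[label] = np.vstack(coords_all)
        records.extend(rows_all)
    return records, truth
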