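"""Fermentation-like synthetic microbe and volatile tables with planted couplings.

The generator emits two compositional feature-by-sample tables (microbes and
volatiles) over a shared ordered time axis, an annotation table, and a planted
set of signed microbe-volatile couplings that serves as ground truth for
association-network recovery experiments.

Model
-----
Each foreground feature has a latent log-abundance trajectory

    l(t) = baseline + trend_amplitude * archetype(t) + jitter(t),

with the archetype drawn from {rising, falling, peaked, stable} on a normalized
time axis t in [0, 1] (rising = t, falling = 1 - t, peaked = triangular at
t = 0.5, stable = constant) and i.i.d. Gaussian jitter giving each feature an
identifiable rank signature. A coupled volatile's latent trajectory is a
strictly monotone transform of its partner microbe's latent (sign per planted
edge) plus Gaussian noise with sd ``noise_sd``; at ``noise_sd = 0`` every
planted pair is perfectly monotone on the emitted tables (|Spearman rho| = 1).

Ground-truth well-posedness
---------------------------
Two properties make the planted edge set *the* ground truth rather than merely
a subset of it:

1. **Rank-safe closure.** Per-sample closure (dividing by the sample total)
   would reshuffle cross-sample ranks whenever totals differ between samples.
   The generator therefore fixes every sample's pre-closure total to a constant
   by adding two explicit background features per table (ids ``*_BG1``,
   ``*_BG2``) that absorb the residual signal, so normalization is a global
   scalar and the rank structure of every generated feature survives closure
   exactly.
2. **Spurious-correlation control.** Independently drawn trajectories would
   collide by chance (at 8 timepoints roughly 5% of null pairs exceed the
   significance bound), so independent trajectories are rejection-sampled until
   every non-planted microbe-volatile pair stays at or below
   ``max_spurious_rho`` in absolute rank correlation; the background features
   are re-balanced the same way. With 4 timepoints only 24 rank patterns
   exist, so the cap is relaxed to "no exact rank collision" and recovery
   guarantees require >= 5 (in practice >= 6) timepoints.

All randomness derives from one seed through a fixed spawn tree, so adding
features never perturbs the draws of earlier features.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .tabular_io import (
    CATEGORIES,
    AbundanceTable,
    FeatureAnnotation,
    read_abundance_table,
    read_annotations,
    read_truth_edges,
    write_abundance_table,
    write_annotations,
    write_truth_edges,
)

ARCHETYPES = ("rising", "falling", "peaked", "stable")

_GENUS_PHYLUM = {
    "Virgibacillus": "Firmicutes",
    "Bacillus": "Firmicutes",
    "Loigolactobacillus": "Firmicutes",
    "Alkalibacillus": "Firmicutes",
    "Planococcus": "Firmicutes",
    "Pseudomonas": "Proteobacteria",
    "Halomonas": "Proteobacteria",
    "Sphingomonas": "Proteobacteria",
    "Agrobacterium": "Proteobacteria",
    "Zygosaccharomyces": "Ascomycota",
    "Debaryomyces": "Ascomycota",
    "Wickerhamiella": "Ascomycota",
    "Symmetrospora": "Basidiomycota",
    "Filobasidium": "Basidiomycota",
    "Sporobolomyces": "Basidiomycota",
}
_GENERA = sorted(_GENUS_PHYLUM)
_CATEGORY_LIST = sorted(CATEGORIES)


@dataclasses.dataclass
class SimConfig:
    """Study-design parameters of a synthetic fermentation dataset.

    Defaults mirror a multi-year fermented-vegetable survey: 4 sampling
    timepoints, a few dozen community members and volatiles, and a planted
    coupling for a subset of volatiles.
    """

    n_timepoints: int = 4
    n_microbes: int = 20
    n_volatiles: int = 50
    n_coupled_pairs: int = 30
    noise_sd: float = 0.25
    archetype_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "rising": 0.3,
            "falling": 0.3,
            "peaked": 0.2,
            "stable": 0.2,
        }
    )
    seed: int = 0
    # trajectory shape parameters (latent log scale)
    trend_amplitude: float = 1.5
    jitter_sd: float = 1.0
    baseline_sd: float = 0.3
    coupling_slope: float = 1.0
    # ground-truth well-posedness controls
    max_spurious_rho: float = 0.65
    max_redraws: int = 300
    background_fill: float = 0.8

    def __post_init__(self) -> None:
        for name in ("n_timepoints", "n_microbes", "n_volatiles"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_timepoints < 3:
            raise ConfigurationError("n_timepoints must be >= 3 for rank statistics")
        if self.n_coupled_pairs < 0:
            raise ConfigurationError("n_coupled_pairs must be >= 0")
        if self.n_coupled_pairs > self.n_volatiles:
            raise ConfigurationError(
                "n_coupled_pairs must be <= n_volatiles: each coupled volatile "
                "follows exactly one partner microbe (a volatile cannot be "
                "perfectly monotone in two independent trajectories)"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if set(self.archetype_mix) - set(ARCHETYPES):
            raise ConfigurationError(
                f"unknown archetypes: {sorted(set(self.archetype_mix) - set(ARCHETYPES))}"
            )
        props = np.array([self.archetype_mix.get(a, 0.0) for a in ARCHETYPES])
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("archetype_mix proportions must be >= 0 and sum to 1")
        if not 0 < self.max_spurious_rho <= 1:
            raise ConfigurationError("max_spurious_rho must be in (0, 1]")
        if not 0 < self.background_fill < 1:
            raise ConfigurationError("background_fill must be in (0, 1)")


@dataclasses.dataclass
class SyntheticDataset:
    """Generated tables, annotations, planted truth edges, and the seed."""

    microbe_table: AbundanceTable
    volatile_table: AbundanceTable
    annotations: list[FeatureAnnotation]
    truth_edges: set[tuple[str, str, int]]
    seed: int
    config: SimConfig | None = None

    def validate(self) -> None:
        mids = set(self.microbe_table.feature_ids)
        vids = set(self.volatile_table.feature_ids)
        for m, v, sign in self.truth_edges:
            if m not in mids or v not in vids:
                raise ValidationError(f"truth edge ({m}, {v}) references unknown feature")
            if sign not in (1, -1):
                raise ValidationError(f"truth edge ({m}, {v}) has invalid sign {sign}")
        if self.microbe_table.sample_ids != self.volatile_table.sample_ids:
            raise ValidationError("tables must share the identical ordered sample list")


# ---------------------------------------------------------------------------
# trajectory machinery
# ---------------------------------------------------------------------------

def _archetype_curve(name: str, t: np.ndarray) -> np.ndarray:
    if name == "rising":
        curve = t
    elif name == "falling":
        curve = 1.0 - t
    elif name == "peaked":
        curve = 1.0 - 2.0 * np.abs(t - 0.5)
    elif name == "stable":
        curve = np.zeros_like(t)
    else:  # pragma: no cover - guarded by SimConfig
        raise ConfigurationError(f"unknown archetype {name!r}")
    return curve - curve.mean()


def _std_ranks(v: np.ndarray) -> np.ndarray:
    """Standardized rank vector (zero mean, unit norm); continuous draws make
    ties a measure-zero event, so plain argsort ranks suffice here."""
    r = np.argsort(np.argsort(v)).astype(float)
    r -= r.mean()
    n = np.sqrt((r**2).sum())
    return r / n if n > 0 else r


def _max_abs_corr(candidate: np.ndarray, target_ranks: np.ndarray | None) -> float:
    if target_ranks is None or len(target_ranks) == 0:
        return 0.0
    return float(np.abs(target_ranks @ _std_ranks(candidate)).max())


def _decorrelation_active(config: SimConfig) -> bool:
    # With < 5 timepoints too few rank patterns exist (4! = 24) to decorrelate
    # dozens of features; the spurious-|rho| cap is only enforced for >= 5.
    return config.n_timepoints >= 5


def _draw_decorrelated(
    rng: np.random.Generator,
    shape: np.ndarray,
    config: SimConfig,
    target_ranks: np.ndarray | None,
) -> tuple[np.ndarray, float]:
    """Draw trend+jitter trajectories until the candidate's |rho| against all
    targets is at or below the cap; keep the best candidate on exhaustion."""
    tries = max(config.max_redraws, 1) if _decorrelation_active(config) else 1
    cap = config.max_spurious_rho
    best, best_score = None, np.inf
    for _ in range(tries):
        jitter = rng.normal(0.0, config.jitter_sd, size=len(shape))
        cand = config.trend_amplitude * shape + jitter
        score = _max_abs_corr(cand, target_ranks)
        if score <= cap or tries == 1:
            return cand, score
        if score < best_score:
            best, best_score = cand, score
    return best, best_score


def _balanced_backgrounds(
    rng: np.random.Generator,
    residual: np.ndarray,
    config: SimConfig,
    target_ranks: np.ndarray | None,
    max_redraws: int = 2000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Split the per-sample residual mass into two background trajectories,
    re-drawing the split until both decorrelate from the targets."""
    tries = max_redraws if _decorrelation_active(config) else 1
    cap = config.max_spurious_rho
    best, best_score = None, np.inf
    for _ in range(tries):
        logit = rng.normal(0.0, 2.5, size=len(residual))
        beta = 1.0 / (1.0 + np.exp(-logit))
        bg1 = residual * beta
        bg2 = residual - bg1
        score = max(_max_abs_corr(bg1, target_ranks), _max_abs_corr(bg2, target_ranks))
        if score <= cap or tries == 1:
            return bg1, bg2, score
        if score < best_score:
            best, best_score = (bg1, bg2), score
    return best[0], best[1], best_score


def _close_with_background(
    latents: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Exponentiate latents and rescale by a *global* constant so that per-sample
    foreground totals never exceed ``background_fill``; return (foreground
    relative values, per-sample residual mass). Because the rescale factor is
    shared by all samples, cross-sample ranks are exactly preserved."""
    expd = np.exp(latents)
    totals = expd.sum(axis=0)
    gamma = config.background_fill / totals.max()
    fg = expd * gamma
    residual = 1.0 - fg.sum(axis=0)
    return fg, residual


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a reproducible fermentation-like dataset with planted couplings."""
    T = config.n_timepoints
    t = np.linspace(0.0, 1.0, T)
    root = np.random.SeedSequence(config.seed)
    (
        ss_arch_m,
        ss_arch_v,
        ss_coupling,
        ss_microbes,
        ss_volatiles,
        ss_bg_m,
        ss_bg_v,
        ss_annot,
    ) = root.spawn(8)

    mix = np.array([config.archetype_mix.get(a, 0.0) for a in ARCHETYPES])
    arch_m_rng = np.random.default_rng(ss_arch_m)
    arch_v_rng = np.random.default_rng(ss_arch_v)
    microbe_arch = [
        ARCHETYPES[i] for i in arch_m_rng.choice(len(ARCHETYPES), size=config.n_microbes, p=mix)
    ]
    volatile_arch = [
        ARCHETYPES[i] for i in arch_v_rng.choice(len(ARCHETYPES), size=config.n_volatiles, p=mix)
    ]

    # planted couplings: each coupled volatile follows exactly one microbe
    coupling_rng = np.random.default_rng(ss_coupling)
    coupled_volatiles = sorted(
        coupling_rng.choice(config.n_volatiles, size=config.n_coupled_pairs, replace=False)
    )
    partners = coupling_rng.integers(0, config.n_microbes, size=config.n_coupled_pairs)
    signs = coupling_rng.choice([1, -1], size=config.n_coupled_pairs)
    coupling = {
        int(v): (int(m), int(s))
        for v, m, s in zip(coupled_volatiles, partners, signs)
    }

    worst_spurious = 0.0

    # microbes: sequential rejection against all previously accepted microbes
    microbe_streams = ss_microbes.spawn(config.n_microbes)
    microbe_latents: list[np.ndarray] = []
    microbe_ranks: list[np.ndarray] = []
    for i in range(config.n_microbes):
        rng = np.random.default_rng(microbe_streams[i])
        baseline = rng.normal(0.0, config.baseline_sd)
        shape = _archetype_curve(microbe_arch[i], t)
        targets = np.array(microbe_ranks) if microbe_ranks else None
        traj, score = _draw_decorrelated(rng, shape, config, targets)
        worst_spurious = max(worst_spurious, score)
        microbe_latents.append(baseline + traj)
        microbe_ranks.append(_std_ranks(traj))
    microbe_latents = np.array(microbe_latents)

    fg_m, residual_m = _close_with_background(microbe_latents, config)
    bg_m_rng = np.random.default_rng(ss_bg_m)
    m_bg1, m_bg2, score = _balanced_backgrounds(
        bg_m_rng, residual_m, config, np.array(microbe_ranks)
    )
    worst_spurious = max(worst_spurious, score)
    # bipartite decorrelation targets for the volatile side
    v_target_ranks = np.array(microbe_ranks + [_std_ranks(m_bg1), _std_ranks(m_bg2)])

    # volatiles: coupled ones track their partner; uncoupled ones are rejected
    # against every microbe-side trajectory
    volatile_streams = ss_volatiles.spawn(config.n_volatiles)
    volatile_latents: list[np.ndarray] = []
    for j in range(config.n_volatiles):
        rng = np.random.default_rng(volatile_streams[j])
        baseline = rng.normal(0.0, config.baseline_sd)
        if j in coupling:
            m_idx, sign = coupling[j]
            partner = microbe_latents[m_idx]
            centered = partner - partner.mean()
            noise = rng.normal(0.0, config.noise_sd, size=T) if config.noise_sd > 0 else 0.0
            traj = config.coupling_slope * sign * centered + noise
        else:
            shape = _archetype_curve(volatile_arch[j], t)
            traj, score = _draw_decorrelated(rng, shape, config, v_target_ranks)
            worst_spurious = max(worst_spurious, score)
        volatile_latents.append(baseline + traj)
    volatile_latents = np.array(volatile_latents)

    fg_v, residual_v = _close_with_background(volatile_latents, config)
    bg_v_rng = np.random.default_rng(ss_bg_v)
    v_bg1, v_bg2, score = _balanced_backgrounds(bg_v_rng, residual_v, config, v_target_ranks)
    worst_spurious = max(worst_spurious, score)

    cap = config.max_spurious_rho
    if worst_spurious > cap and _decorrelation_active(config):
        warnings.warn(
            f"could not fully decorrelate independent trajectories: worst "
            f"non-planted |rho| = {worst_spurious:.3f} > cap {cap:.3f}; "
            "planted-edge recovery may see spurious edges"
        )

    samples = [f"T{k}" for k in range(T)]
    m_ids = [f"M{i + 1:02d}" for i in range(config.n_microbes)] + ["M_BG1", "M_BG2"]
    v_ids = [f"V{j + 1:02d}" for j in range(config.n_volatiles)] + ["V_BG1", "V_BG2"]
    m_values = np.vstack([fg_m, m_bg1, m_bg2])
    v_values = np.vstack([fg_v, v_bg1, v_bg2])
    microbe_table = AbundanceTable(
        pd.DataFrame(m_values, index=m_ids, columns=samples), mode="relative"
    )
    volatile_table = AbundanceTable(
        pd.DataFrame(v_values, index=v_ids, columns=samples), mode="relative"
    )

    annot_rng = np.random.default_rng(ss_annot)
    annotations: list[FeatureAnnotation] = []
    for mid in m_ids:
        if mid.startswith("M_BG"):
            genus, phylum = "SyntheticBackground", "Unclassified"
        else:
            genus = _GENERA[annot_rng.integers(0, len(_GENERA))]
            phylum = _GENUS_PHYLUM[genus]
        annotations.append(
            FeatureAnnotation(feature_id=mid, role="microbe", code=mid,
                              genus=genus, phylum=phylum)
        )
    for vid in v_ids:
        category = _CATEGORY_LIST[annot_rng.integers(0, len(_CATEGORY_LIST))]
        annotations.append(
            FeatureAnnotation(feature_id=vid, role="volatile", code=vid,
                              category=category)
        )

    truth_edges = {
        (m_ids[m_idx], v_ids[v_idx], sign)
        for v_idx, (m_idx, sign) in coupling.items()
    }

    dataset = SyntheticDataset(
        microbe_table=microbe_table,
        volatile_table=volatile_table,
        annotations=annotations,
        truth_edges=truth_edges,
        seed=config.seed,
        config=config,
    )
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "microbes": "microbes.csv",
    "volatiles": "volatiles.csv",
    "annotations": "annotations.csv",
    "truth_edges": "truth_edges.csv",
    "meta": "meta.json",
}


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as a directory of CSV files (plus a small meta file).

    Round-trips losslessly through the tabular_io readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FIXTURE_FILES.items()}
    write_abundance_table(dataset.microbe_table, paths["microbes"])
    write_abundance_table(dataset.volatile_table, paths["volatiles"])
    write_annotations(dataset.annotations, paths["annotations"])
    write_truth_edges(dataset.truth_edges, paths["truth_edges"])
    meta = {"seed": dataset.seed}
    if dataset.config is not None:
        meta["config"] = dataclasses.asdict(dataset.config)
    paths["meta"].write_text(json.dumps(meta, indent=2) + "\n")
    return paths


def read_fixture(directory: str | Path) -> SyntheticDataset:
    """Read a fixture directory back into a :class:`SyntheticDataset`."""
    directory = Path(directory)
    paths = {k: directory / v for k, v in _FIXTURE_FILES.items()}
    meta = json.loads(paths["meta"].read_text())
    config = SimConfig(**meta["config"]) if "config" in meta else None
    dataset = SyntheticDataset(
        microbe_table=read_abundance_table(paths["microbes"], mode="relative"),
        volatile_table=read_abundance_table(paths["volatiles"], mode="relative"),
        annotations=read_annotations(paths["annotations"]),
        truth_edges=read_truth_edges(paths["truth_edges"]),
        seed=meta["seed"],
        config=config,
    )
    dataset.validate()
    return dataset
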