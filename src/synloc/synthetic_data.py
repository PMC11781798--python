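"""Synthetic volumes, puncta, group tables, and behavioral counts with
known ground truth.

The generator emulates the data the analysis expects: a two-channel
confocal-like stack of a neurite arbor whose membrane marker traces a
tube (bright shell, dimmer lumen) along a smooth random-walk centerline,
with the receptor channel riding on the membrane field times a
region-dependent enrichment factor; a punctum channel of 3D Gaussian
spots placed inside and outside the membrane; factorial group datasets
with programmed genotype x time effects; and per-second T-maze choice
counts.  Every output is a deterministic function of its seed.

Because the target channel is constructed as membrane x enrichment
(x noise), the programmed enrichment factors are exactly the quantities
the localization-index pipeline should recover, which closes the loop
for end-to-end parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .group_stats import BehavioralCounts
from .volume_io import GroupTable, RegionLabelMap, Volume

__all__ = [
    "NeuronVolumeParams",
    "SyntheticGroundTruth",
    "PunctumTruth",
    "generate_neuron_volume",
    "generate_group_dataset",
    "generate_behavior_counts",
    "fig8_like_effects",
]

logger = logging.getLogger(__name__)


@dataclass
class PunctumTruth:
    """Ground truth for one generated spot (voxel coordinates)."""

    position: tuple[float, float, float]
    in_cell: bool
    has_receptor_ring: bool
    amplitude: float
    sigma_um: float


@dataclass
class SyntheticGroundTruth:
    """Everything needed to verify what the pipeline recovers."""

    region_enrichment: dict[str, float]
    membrane_geometry: dict
    puncta_truth: list[PunctumTruth]
    noise: dict
    seed: int


@dataclass
class NeuronVolumeParams:
    """Parameters of the tubular-arbor volume generator.

    Defaults describe a plausible confocal acquisition of a neurite
    tract: 0.2 µm lateral / 0.4 µm axial voxels, a 1.5 µm-radius tube
    with a 0.3 µm membrane shell and a dimmer lumen, 10% multiplicative
    intensity noise plus additive detector noise at 2% of the membrane
    peak.  ``region_enrichment`` maps each compartment traversed by the
    centerline to its receptor enrichment factor; the default programs a
    2:1 contrast between two compartments.
    """

    shape: tuple[int, int, int] = (48, 192, 192)
    voxel_size: tuple[float, float, float] = (0.4, 0.2, 0.2)
    region_enrichment: dict[str, float] = field(
        default_factory=lambda: {"calyx": 1.0, "peduncle": 2.0}
    )
    tube_radius_um: float = 1.5
    shell_width_um: float = 0.3
    lumen_fraction: float = 0.35
    membrane_peak: float = 100.0
    multiplicative_cv: float = 0.10
    additive_sd_fraction: float = 0.02
    photon_like: bool = False
    noise_on_membrane: bool = True
    # punctum channel
    n_puncta_in: int = 0
    n_puncta_out: int = 0
    puncta_sigma_um: float = 0.3
    puncta_snr_range: tuple[float, float] = (5.0, 10.0)
    puncta_noise_sd: float = 2.0
    puncta_min_separation_um: float = 1.5
    receptor_ring_fraction: float = 0.0
    receptor_ring_amplitude: float = 1000.0


def _smooth_walk(n: int, rng: np.random.Generator, amplitude: float, smooth: float) -> np.ndarray:
    """Seeded smooth 1D random walk, zero-mean, max |value| = amplitude."""
    steps = rng.standard_normal(n)
    walk = gaussian_filter1d(np.cumsum(steps), smooth)
    walk -= walk.mean()
    peak = np.max(np.abs(walk))
    return walk * (amplitude / peak) if peak > 0 else walk


def _centerline_um(
    params: NeuronVolumeParams, rng: np.random.Generator, max_attempts: int = 10
) -> np.ndarray:
    """Centerline points in µm threading the volume along x.

    The tube must stay inside the volume with a margin of one full
    membrane support; if a draw exits, the wiggle amplitude is damped and
    the line regenerated (logged).
    """
    vs = np.asarray(params.voxel_size)
    extent = (np.asarray(params.shape) - 1) * vs
    margin = params.tube_radius_um + 3 * params.shell_width_um + 2 * max(vs)
    n = 256
    x = np.linspace(margin, extent[2] - margin, n)
    damp = 1.0
    for attempt in range(max_attempts):
        amp_y = (extent[1] / 2 - margin) * 0.6 * damp
        amp_z = (extent[0] / 2 - margin) * 0.5 * damp
        y = extent[1] / 2 + _smooth_walk(n, rng, amp_y, smooth=25)
        z = extent[0] / 2 + _smooth_walk(n, rng, amp_z, smooth=40)
        pts = np.stack([z, y, x], axis=1)
        if np.all(pts >= margin) and np.all(pts <= extent - margin):
            # resample to ~uniform arc-length spacing of 0.15 µm
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            n_fine = max(int(arc[-1] / 0.15), 2)
            return interp1d(arc, pts, axis=0)(np.linspace(0, arc[-1], n_fine))
        damp *= 0.7
        logger.info("centerline attempt %d exited the volume; damping wiggle", attempt + 1)
    raise RuntimeError("could not fit a tube centerline inside the volume")


def _apply_noise(
    clean: np.ndarray,
    rng: np.random.Generator,
    cv: float,
    additive_sd: float,
    photon_like: bool,
) -> np.ndarray:
    out = clean.copy()
    if cv > 0:
        out = out * (1.0 + cv * rng.standard_normal(out.shape))
    if photon_like:
        out = out + np.sqrt(np.maximum(clean, 0)) * rng.standard_normal(out.shape)
    if additive_sd > 0:
        out = out + additive_sd * rng.standard_normal(out.shape)
    return np.maximum(out, 0.0)


def _add_gaussian_spot(
    field: np.ndarray,
    pos_vox: np.ndarray,
    sigma_vox: np.ndarray,
    amplitude: float,
) -> None:
    """Accumulate one anisotropic 3D Gaussian into ``field`` (in place)."""
    reach = np.ceil(4 * sigma_vox).astype(int)
    lo = np.maximum(np.floor(pos_vox - reach).astype(int), 0)
    hi = np.minimum(np.ceil(pos_vox + reach).astype(int) + 1, field.shape)
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    q = sum(((g - p) / s) ** 2 for g, p, s in zip(grids, pos_vox, sigma_vox))
    field[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(-q / 2)


def _place_puncta(
    params: NeuronVolumeParams,
    tree: cKDTree,
    centerline: np.ndarray,
    rng: np.random.Generator,
) -> list[PunctumTruth]:
    """Sample spot positions: in-cell ones inside the tube, out-of-cell
    ones well clear of any membrane signal, all pairwise separated."""
    vs = np.asarray(params.voxel_size)
    extent = (np.asarray(params.shape) - 1) * vs
    edge = 4 * params.puncta_sigma_um + max(vs)
    out_clearance = params.tube_radius_um + 3 * params.shell_width_um + 1.2
    placed_um: list[np.ndarray] = []
    truths: list[PunctumTruth] = []

    def _admissible(pos: np.ndarray) -> bool:
        if np.any(pos < edge) or np.any(pos > extent - edge):
            return False
        return all(
            np.linalg.norm(pos - q) >= params.puncta_min_separation_um for q in placed_um
        )

    n_ring = int(round(params.receptor_ring_fraction * params.n_puncta_in))
    for k in range(params.n_puncta_in):
        for _ in range(2000):
            anchor = centerline[rng.integers(len(centerline))]
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = anchor + direction * rng.uniform(0, 0.6 * params.tube_radius_um)
            if _admissible(pos):
                break
        else:
            raise RuntimeError("could not place an in-cell punctum; volume too crowded")
        placed_um.append(pos)
        truths.append(
            PunctumTruth(
                position=tuple(pos / vs),
                in_cell=True,
                has_receptor_ring=k < n_ring,
                amplitude=float(rng.uniform(*params.puncta_snr_range) * params.puncta_noise_sd),
                sigma_um=params.puncta_sigma_um,
            )
        )
    for _ in range(params.n_puncta_out):
        for _ in range(5000):
            pos = rng.uniform(edge, extent - edge)
            if _admissible(pos) and tree.query(pos)[0] >= out_clearance:
                break
        else:
            raise RuntimeError("could not place an out-of-cell punctum; volume too crowded")
        placed_um.append(pos)
        truths.append(
            PunctumTruth(
                position=tuple(pos / vs),
                in_cell=False,
                has_receptor_ring=False,
                amplitude=float(rng.uniform(*params.puncta_snr_range) * params.puncta_noise_sd),
                sigma_um=params.puncta_sigma_um,
            )
        )
    return truths


def generate_neuron_volume(
    params: NeuronVolumeParams | None = None,
    seed: int = 0,
) -> tuple[Volume, RegionLabelMap, SyntheticGroundTruth]:
    """Generate a (membrane, rgfp[, brp]) volume with its label map and truth.

    The membrane channel is a smooth tube-shell field around a seeded
    random-walk centerline; the receptor channel equals membrane times
    the enrichment factor of the compartment each voxel belongs to, with
    multiplicative and additive noise applied independently per channel
    and clipped at zero; the punctum channel (present when puncta are
    requested) is a sum of Gaussian spots plus detector noise.  The label
    map partitions the tube into equal-arc-length compartments along the
    centerline.
    """
    params = params or NeuronVolumeParams()
    if not params.region_enrichment:
        raise ValueError("need at least one region")
    vs = np.asarray(params.voxel_size)
    if params.tube_radius_um < min(vs):
        raise ValueError("tube radius must be at least one voxel in the finest axis")
    rng = np.random.default_rng(seed)

    centerline = _centerline_um(params, rng)
    tree = cKDTree(centerline)
    region_names = list(params.region_enrichment)
    # equal-length partition of the centerline into compartments
    point_region = np.minimum(
        (np.arange(len(centerline)) * len(region_names)) // len(centerline),
        len(region_names) - 1,
    )

    # distance-to-centerline field, restricted to a bounding box around the tube
    support = params.tube_radius_um + 3 * params.shell_width_um
    lo = np.maximum(np.floor((centerline.min(axis=0) - support) / vs).astype(int), 0)
    hi = np.minimum(
        np.ceil((centerline.max(axis=0) + support) / vs).astype(int) + 1,
        params.shape,
    )
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    coords_um = np.stack([g.ravel() * s for g, s in zip(grids, vs)], axis=1)
    dist, nearest = tree.query(coords_um)
    dist = dist.reshape([h - l for l, h in zip(lo, hi)])
    nearest = nearest.reshape(dist.shape)

    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    r, w = params.tube_radius_um, params.shell_width_um
    shell = np.exp(-((dist - r) ** 2) / (2 * w**2))
    lumen = params.lumen_fraction * np.exp(-(dist**2) / (2 * (r / 2) ** 2))
    profile = np.where(dist <= support, shell + lumen, 0.0)

    membrane_clean = np.zeros(params.shape)
    membrane_clean[box] = params.membrane_peak * profile

    labels = np.zeros(params.shape, dtype=np.int32)
    region_of_voxel = point_region[nearest] + 1
    labels[box] = np.where(dist <= support, region_of_voxel, 0)

    factor_of_label = np.array([1.0] + [params.region_enrichment[n] for n in region_names])
    rgfp_clean = membrane_clean * factor_of_label[labels]

    puncta_truth: list[PunctumTruth] = []
    brp_clean = None
    if params.n_puncta_in or params.n_puncta_out:
        puncta_truth = _place_puncta(params, tree, centerline, rng)
        brp_clean = np.zeros(params.shape)
        for t in puncta_truth:
            _add_gaussian_spot(
                brp_clean, np.asarray(t.position), t.sigma_um / vs, t.amplitude
            )
            if t.has_receptor_ring:
                # receptor condensate: a shell of signal hugging the punctum
                # at ~2 sigma, i.e. inside the [sigma, 3*sigma] adjacency shell
                _add_ring(rgfp_clean, np.asarray(t.position), t.sigma_um, vs,
                          params.receptor_ring_amplitude)

    additive_sd = params.additive_sd_fraction * params.membrane_peak
    noise_args = dict(
        cv=params.multiplicative_cv,
        additive_sd=additive_sd,
        photon_like=params.photon_like,
    )
    membrane = (
        _apply_noise(membrane_clean, rng, **noise_args)
        if params.noise_on_membrane
        else membrane_clean
    )
    rgfp = _apply_noise(rgfp_clean, rng, **noise_args)

    # channel order matches the package-wide config default (rgfp, membrane, brp)
    channels = {"rgfp": rgfp, "membrane": membrane}
    if brp_clean is not None:
        brp = brp_clean + params.puncta_noise_sd * rng.standard_normal(params.shape)
        channels["brp"] = np.maximum(brp, 0.0)

    volume = Volume(channels=channels, voxel_size=tuple(params.voxel_size))
    label_map = RegionLabelMap(
        labels=labels, names={i + 1: n for i, n in enumerate(region_names)}
    )
    truth = SyntheticGroundTruth(
        region_enrichment=dict(params.region_enrichment),
        membrane_geometry={
            "centerline_um": centerline,
            "tube_radius_um": params.tube_radius_um,
            "shell_width_um": params.shell_width_um,
        },
        puncta_truth=puncta_truth,
        noise={
            "multiplicative_cv": params.multiplicative_cv,
            "additive_sd": additive_sd,
            "photon_like": params.photon_like,
            "puncta_noise_sd": params.puncta_noise_sd,
        },
        seed=seed,
    )
    return volume, label_map, truth


def _add_ring(
    field: np.ndarray,
    pos_vox: np.ndarray,
    sigma_um: float,
    voxel_size: np.ndarray,
    amplitude: float,
) -> None:
    """Add a spherical shell of intensity at radius 2*sigma (width 0.4*sigma)."""
    r_ring, w_ring = 2.0 * sigma_um, 0.4 * sigma_um
    reach_um = r_ring + 3 * w_ring
    reach = np.ceil(reach_um / voxel_size).astype(int)
    lo = np.maximum(np.floor(pos_vox).astype(int) - reach, 0)
    hi = np.minimum(np.ceil(pos_vox).astype(int) + reach + 1, field.shape)
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    d = np.sqrt(sum(((g - p) * s) ** 2 for g, p, s in zip(grids, pos_vox, voxel_size)))
    field[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(
        -((d - r_ring) ** 2) / (2 * w_ring**2)
    )


# ---------------------------------------------------------------------------
# factorial group datasets


def fig8_like_effects() -> dict[tuple[str, float], float]:
    """Preset cell means with a genotype x starvation-time crossover:
    one receptor rises with starvation while the other drifts down."""
    times = [0.0, 10.0, 24.0, 48.0]
    up = [1.0, 1.5, 1.6, 1.7]
    down = [1.0, 0.9, 0.85, 0.8]
    effects = {("Dop1R1", t): m for t, m in zip(times, up)}
    effects.update({("Dop2R", t): m for t, m in zip(times, down)})
    return effects


def generate_group_dataset(
    effects: Mapping[tuple[str, float], float] | None = None,
    sd: float = 0.3,
    n_per_cell: int = 10,
    seed: int = 0,
    region: str = "gamma5",
) -> GroupTable:
    """Normal draws around programmed genotype x time cell means.

    ``effects`` maps (genotype, time) -> mean; the default is the
    crossover preset of :func:`fig8_like_effects`.  With sd = 0 every
    measurement equals its cell mean exactly.
    """
    if n_per_cell < 2:
        raise ValueError("need n_per_cell >= 2")
    effects = dict(effects) if effects is not None else fig8_like_effects()
    rng = np.random.default_rng(seed)
    rows = []
    for (genotype, t), mean in effects.items():
        draws = mean + sd * rng.standard_normal(n_per_cell)
        for i, y in enumerate(draws):
            rows.append(
                {
                    "sample_id": f"{genotype}_t{t:g}_s{i}",
                    "genotype": genotype,
                    "starvation_hours": t,
                    "region": region,
                    "measurement": y,
                }
            )
    return GroupTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# behavioral counts


def generate_behavior_counts(
    true_li: float,
    n_flies: int = 50,
    seconds: int = 120,
    seed: int = 0,
) -> BehavioralCounts:
    """Binomial per-second T-maze arm allocation.

    Each second, every fly is in the CS- arm with probability
    (1 + true_li)/2 (aversive convention), independently across seconds
    — a simplification of real fly behavior, where positions are
    autocorrelated over time.
    """
    if not -1 <= true_li <= 1:
        raise ValueError(f"|true_li| must be <= 1, got {true_li}")
    if n_flies < 1:
        raise ValueError("need at least one fly")
    rng = np.random.default_rng(seed)
    p_minus = (1.0 + true_li) / 2.0
    n_minus = rng.binomial(n_flies, p_minus, size=seconds)
    return BehavioralCounts(
        n_cs_plus=n_flies - n_minus, n_cs_minus=n_minus, session_length=seconds
    )
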