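"""Synthetic inputs with known ground truth for every analysis stage.

Generators stand in for the microscopes and sequencers of a root-cell
study: a remodeling actin-filament network imaged as a time-lapse stack
(with an actin-stabilized, frozen control at remodeling rate 0), a
single-exponential FRAP recovery trace with pre-bleach scans, a field of
BFA-body-like disks with an exact per-body truth table, and per-site
allele-count tables for homozygous / heterozygous / absent variants under
a stated sequencing-error rate.

Every generator is a pure function of its parameter object, including the
seed: identical parameters give bitwise-identical output.  All randomness
flows through one ``numpy.random.Generator`` created per call; no global
state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as _disk
from skimage.draw import line_aa

from .dynamics import TimeLapseStack
from .frap import FrapTrace

__all__ = [
    "FilamentNetworkParams",
    "FrapSimParams",
    "BlobFieldParams",
    "VariantSimParams",
    "whole_cell_params",
    "make_filament_timelapse",
    "make_frap_trace",
    "make_bfa_image",
    "make_allele_counts",
]


# ---------------------------------------------------------------------------
# parameter objects


@dataclass(frozen=True)
class FilamentNetworkParams:
    """Parameters of the remodeling filament-network time-lapse.

    The default acquisition matches the study conditions this simulator
    emulates: one frame every 2.5 s over a 60 s time course (25 frames).
    ``remodeling_rate`` is the per-filament, per-frame probability of being
    torn down and replaced by a fresh random filament; 0 models an
    actin-stabilized (MBS-like) frozen cell.  ``bundling_factor`` b >= 1 is
    the number of co-localized filaments per bundle; a ``bundled_fraction``
    of filaments share paths in groups of b (bundled pixels carry ~b-fold
    intensity), the remainder run alone.  Filament orientations are drawn
    within ``orientation_spread`` radians of the cell's long axis,
    mimicking the predominantly axial cortical array of elongating root
    cells (and keeping chance filament crossings rare).  Per-filament
    brightness is lognormal with coefficient of variation
    ``intensity_cv``, emulating variable labeling and focal depth.
    """

    image_size: tuple[int, int] = (128, 128)
    n_filaments: int = 15
    length_range: tuple[float, float] = (30.0, 80.0)
    width: float = 2.0
    remodeling_rate: float = 0.2
    bundling_factor: int = 1
    bundled_fraction: float = 0.3
    orientation_spread: float = 0.35
    intensity_cv: float = 0.3
    noise_sigma: float = 2.0
    n_frames: int = 25
    frame_interval: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.remodeling_rate <= 1.0):
            raise ValueError("remodeling_rate must be in [0, 1]")
        if self.bundling_factor < 1:
            raise ValueError("bundling_factor must be >= 1")
        if not (0.0 <= self.bundled_fraction <= 1.0):
            raise ValueError("bundled_fraction must be in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_filaments < 1 or min(self.image_size) < 8:
            raise ValueError("n_filaments and image_size must be positive")
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("length_range must be positive and ordered")
        diag = math.hypot(*self.image_size)
        if self.length_range[1] > diag:
            raise ValueError(
                f"maximum filament length {self.length_range[1]} exceeds image "
                f"diagonal {diag:.1f}"
            )
        if self.noise_sigma < 0 or self.width < 0:
            raise ValueError("noise_sigma and width must be >= 0")
        if not (0.0 <= self.orientation_spread <= math.pi):
            raise ValueError("orientation_spread must be in [0, pi]")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")


@dataclass(frozen=True)
class FrapSimParams:
    """Parameters of a simulated FRAP recovery trace.

    Defaults mirror the emulated acquisition: three pre-bleach scans, then
    recovery recorded for 40 min at 1 frame/min.  Post-bleach intensity
    follows F(t) = F0 + Mf*(Fpre - F0)*(1 - exp(-t ln2 / t_half)) with
    F0 = Fpre*(1 - bleach_depth), attenuated by
    (1 - acquisition_bleach_rate)**frame_index.
    """

    pre_bleach_level: float = 100.0
    bleach_depth: float = 0.7
    mobile_fraction: float = 0.7
    t_half: float = 5.0
    n_prebleach: int = 3
    n_frames: int = 41
    frame_interval: float = 1.0
    noise_sigma: float = 0.0
    acquisition_bleach_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.bleach_depth <= 1.0):
            raise ValueError("bleach_depth must be in (0, 1]")
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.t_half <= 0:
            raise ValueError("t_half must be > 0")
        if self.n_prebleach < 1:
            raise ValueError("n_prebleach must be >= 1")
        if self.n_frames < 2 or self.frame_interval <= 0:
            raise ValueError("need >= 2 post-bleach frames at positive interval")
        if self.acquisition_bleach_rate < 0 or self.noise_sigma < 0:
            raise ValueError("rates and sigmas must be >= 0")
        if self.pre_bleach_level <= 0:
            raise ValueError("pre_bleach_level must be > 0")


@dataclass(frozen=True)
class BlobFieldParams:
    """Parameters of a synthetic BFA-body field: non-overlapping uniform
    disks on a uniform background."""

    image_size: tuple[int, int] = (256, 256)
    n_bodies: int = 12
    radius_range: tuple[int, int] = (3, 8)
    intensity_range: tuple[float, float] = (80.0, 150.0)
    background: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bodies < 0:
            raise ValueError("n_bodies must be >= 0")
        if self.radius_range[0] < 1 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radii must be >= 1 px and ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class VariantSimParams:
    """Parameters of a simulated per-site allele-count table.

    ``genotype_mix`` gives the fractions of truth-homozygous, heterozygous
    and absent (wild-type) sites; per-site depth is negative-binomial with
    the given mean and dispersion (size) parameter, and alt reads are
    binomial at 1-e / 0.5 / e for the three genotypes.
    """

    n_sites: int = 10_000
    genotype_mix: tuple[float, float, float] = (0.2, 0.3, 0.5)
    mean_depth: float = 30.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if abs(sum(self.genotype_mix) - 1.0) > 1e-9 or min(self.genotype_mix) < 0:
            raise ValueError("genotype_mix fractions must be >= 0 and sum to 1")
        if self.mean_depth < 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth >= 0 and depth_dispersion > 0 required")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")


def whole_cell_params(**overrides) -> FilamentNetworkParams:
    """Filament-network parameters at whole-cell field scale.

    The default :class:`FilamentNetworkParams` frame (128 px, 15
    filaments) is a time-lapse crop; architecture metrics — bundling
    skewness in particular — are distribution statistics and need a field
    holding on the order of a hundred filaments (a dozen bundles) for
    stable estimates, as a projected whole-cell image does.  This keeps
    the same areal density at a 384 px field with 135 filaments.
    """
    defaults = dict(image_size=(384, 384), n_filaments=135,
                    length_range=(40.0, 120.0))
    defaults.update(overrides)
    return FilamentNetworkParams(**defaults)


# ---------------------------------------------------------------------------
# filament time-lapse


def _random_path(rng: np.random.Generator, params: FilamentNetworkParams,
                 strip: tuple[int, int] | None = None) -> tuple:
    """One random line segment (r0, c0, r1, c1, amplitude) in the image.

    Orientation is near-axial within ``orientation_spread``; amplitude is
    lognormal around 100 with coefficient of variation ``intensity_cv``.
    When ``strip`` = (index, count) is given, the anchor row is stratified
    into that transverse strip — cortical arrays are roughly evenly
    spaced across the cell rather than thrown down uniformly at random.
    """
    h, w = params.image_size
    if strip is not None:
        idx, count = strip
        r0 = min((idx + rng.random()) * h / count, h - 1.0)
    else:
        r0 = rng.uniform(0, h - 1)
    c0 = rng.uniform(0, w - 1)
    theta = rng.uniform(-params.orientation_spread, params.orientation_spread)
    if rng.random() < 0.5:
        theta += math.pi
    length = rng.uniform(*params.length_range)
    r1 = min(max(r0 + length * math.sin(theta), 0.0), h - 1)
    c1 = min(max(c0 + length * math.cos(theta), 0.0), w - 1)
    if params.intensity_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.intensity_cv**2))
        amp = 100.0 * rng.lognormal(-sigma**2 / 2.0, sigma)
    else:
        amp = 100.0
    return (r0, c0, r1, c1, amp)


def _render_frame(paths: list[tuple], multiplicity: np.ndarray,
                  params: FilamentNetworkParams) -> np.ndarray:
    img = np.zeros(params.image_size, dtype=np.float64)
    for (r0, c0, r1, c1, amp), mult in zip(paths, multiplicity):
        if mult == 0:
            continue
        rr, cc, val = line_aa(int(round(r0)), int(round(c0)),
                              int(round(r1)), int(round(c1)))
        img[rr, cc] += amp * mult * val
    if params.width > 0:
        img = ndimage.gaussian_filter(img, sigma=params.width / 2.0)
    return img


def make_filament_timelapse(
    params: FilamentNetworkParams,
) -> tuple[TimeLapseStack, dict]:
    """Simulate a filament-network time-lapse with known remodeling rate.

    Each filament references a path; bundled filaments share one, so the
    rendered intensity on a bundle is ~b-fold.  Between frames, every
    filament is independently replaced by a fresh random filament (its own
    new path) with probability ``remodeling_rate``.  Gaussian read noise of
    ``noise_sigma`` is added per frame.

    Returns the stack and a ground-truth dict with the remodeling rate and
    bundling factor actually used.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_filaments
    b = params.bundling_factor

    # initial assignment: a bundled_fraction of filaments share paths in
    # groups of b; the rest are singletons.  Initial anchor rows are
    # stratified so the array starts evenly spaced across the cell.
    n_bundled = int(round(params.bundled_fraction * n)) if b > 1 else 0
    n_bundled -= n_bundled % b  # whole bundles only
    n_paths = n_bundled // b + (n - n_bundled)
    strip_order = rng.permutation(n_paths)
    paths: list[tuple] = []
    path_of = np.empty(n, dtype=np.intp)
    i = 0
    while i < n_bundled:
        paths.append(_random_path(rng, params,
                                  strip=(int(strip_order[len(paths)]), n_paths)))
        for _ in range(b):
            path_of[i] = len(paths) - 1
            i += 1
    while i < n:
        paths.append(_random_path(rng, params,
                                  strip=(int(strip_order[len(paths)]), n_paths)))
        path_of[i] = len(paths) - 1
        i += 1

    frames = np.empty((params.n_frames, *params.image_size), dtype=np.float64)
    for t in range(params.n_frames):
        if t > 0 and params.remodeling_rate > 0:
            reborn = rng.random(n) < params.remodeling_rate
            for j in np.flatnonzero(reborn):
                paths.append(_random_path(rng, params))
                path_of[j] = len(paths) - 1
        mult = np.bincount(path_of, minlength=len(paths))
        frames[t] = _render_frame(paths, mult, params)
        if params.noise_sigma > 0:
            frames[t] += rng.normal(0.0, params.noise_sigma, params.image_size)

    stack = TimeLapseStack(frames=frames, frame_interval=params.frame_interval,
                           condition="synthetic")
    truth = {"remodeling_rate": params.remodeling_rate,
             "bundling_factor": params.bundling_factor}
    return stack, truth


# ---------------------------------------------------------------------------
# FRAP trace


def make_frap_trace(params: FrapSimParams) -> tuple[FrapTrace, dict]:
    """Simulate a FRAP trace from the single-exponential recovery model.

    Pre-bleach points sit at negative times at ``pre_bleach_level``; the
    bleach happens at t = 0 and post-bleach frames follow the closed-form
    recovery, attenuated per frame by the acquisition-bleaching factor.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    fpre = params.pre_bleach_level
    f0 = fpre * (1.0 - params.bleach_depth)
    k = math.log(2.0) / params.t_half

    t_pre = np.arange(-params.n_prebleach, 0) * dt
    t_post = np.arange(params.n_frames) * dt
    recovery = f0 + params.mobile_fraction * (fpre - f0) * (1.0 - np.exp(-k * t_post))
    recovery *= (1.0 - params.acquisition_bleach_rate) ** np.arange(params.n_frames)

    times = np.concatenate([t_pre, t_post])
    intensities = np.concatenate([np.full(params.n_prebleach, fpre), recovery])
    if params.noise_sigma > 0:
        intensities = intensities + rng.normal(0.0, params.noise_sigma, times.size)

    trace = FrapTrace(times=times, intensities=intensities,
                      n_prebleach=params.n_prebleach, zone="synthetic")
    truth = {"mobile_fraction": params.mobile_fraction, "t_half": params.t_half}
    return trace, truth


# ---------------------------------------------------------------------------
# BFA-body field


def make_bfa_image(params: BlobFieldParams) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a field of non-overlapping uniform disks (BFA bodies).

    Returns the image (with noise, if requested) and a truth table with
    the exact rasterized pixel area and noiseless mean intensity of each
    disk.  Raises ``RuntimeError`` if the requested packing cannot be
    placed within a bounded number of rejection-sampling attempts.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    img = np.full((h, w), params.background, dtype=np.float64)

    rows, cols, radii, amps = [], [], [], []
    max_tries = 2000
    for _ in range(params.n_bodies):
        for attempt in range(max_tries):
            r = int(rng.integers(params.radius_range[0], params.radius_range[1] + 1))
            cy = rng.uniform(r + 1, h - r - 2)
            cx = rng.uniform(r + 1, w - r - 2)
            # keep at least a 2 px gap so bodies stay distinct under
            # 8-connectivity
            ok = all(
                math.hypot(cy - py, cx - px) > r + pr + 2.0
                for py, px, pr in zip(rows, cols, radii)
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not place {params.n_bodies} non-overlapping bodies of "
                f"radius {params.radius_range} in {params.image_size}"
            )
        rows.append(cy)
        cols.append(cx)
        radii.append(r)
        amps.append(rng.uniform(*params.intensity_range))

    records = []
    for i, (cy, cx, r, amp) in enumerate(zip(rows, cols, radii, amps), start=1):
        rr, cc = _disk((cy, cx), r + 0.5, shape=(h, w))
        img[rr, cc] += amp
        records.append({
            "body_id": i, "center_row": cy, "center_col": cx, "radius": r,
            "area_px": rr.size, "mean_intensity": params.background + amp,
        })
    truth = pd.DataFrame(
        records,
        columns=["body_id", "center_row", "center_col", "radius",
                 "area_px", "mean_intensity"],
    )
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    return img, truth


# ---------------------------------------------------------------------------
# allele counts


def make_allele_counts(
    params: VariantSimParams,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate per-site ref/alt read counts for a panel of SNP sites.

    Truth genotypes are drawn from ``genotype_mix`` in the order
    (homozygous, heterozygous, absent); per-site depth is negative-binomial
    (mean ``mean_depth``, size ``depth_dispersion``) and alt counts are
    binomial with success probability 1 - error_rate, 0.5 or error_rate.

    Returns a table (chrom, position, ref_count, alt_count) and the array
    of truth genotype labels.
    """
    rng = np.random.default_rng(params.seed)
    labels = np.array(["hom", "het", "absent"])
    genotypes = rng.choice(labels, size=params.n_sites, p=list(params.genotype_mix))

    size = params.depth_dispersion
    p_nb = size / (size + params.mean_depth)
    depth = rng.negative_binomial(size, p_nb, params.n_sites)

    p_alt = np.where(genotypes == "hom", 1.0 - params.error_rate,
                     np.where(genotypes == "het", 0.5, params.error_rate))
    alt = rng.binomial(depth, p_alt)
    table = pd.DataFrame({
        "chrom": "chr1",
        "position": np.arange(1, params.n_sites + 1) * 100,
        "ref_count": depth - alt,
        "alt_count": alt,
    })
    return table, genotypes
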