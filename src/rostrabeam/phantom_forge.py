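"""Parametric synthetic rostrum volumes with analytic ground truth.

Real museum CT scans of archosaur skulls are not redistributable, so this
module builds voxelized stand-ins: tapering, hollow, bilaterally symmetric
tubes whose transverse sections are hollow ellipses.  Every section then has
closed-form area and second moments, which makes the phantoms usable as exact
oracles for the image-based measurement pipeline.

Three classic snout morphotypes are provided:

* ``tube_morphotype`` — near-constant-width narrow tube (gharial-like),
* ``flat_wide_morphotype`` — broad, dorsoventrally flattened taper
  (alligator-like),
* ``tall_narrow_morphotype`` — tall, mediolaterally compressed taper with a
  bulbous tip rosette (spinosaur-like).

Also here: a deterministic paired-series builder that realizes an exact
signed-rank configuration, used to exercise the statistics module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy.stats import rankdata

from rostrabeam.section_engine import SectionProperties

__all__ = [
    "MorphotypeSpec",
    "VoxelVolume",
    "PairedSeries",
    "ResolutionError",
    "piecewise_linear",
    "generate_rostrum_volume",
    "analytic_ellipse_properties",
    "generate_paired_series",
    "positive_rank_sum_of",
    "tube_morphotype",
    "flat_wide_morphotype",
    "tall_narrow_morphotype",
    "morphotype_by_name",
    "write_volume",
    "read_volume",
]


class ResolutionError(ValueError):
    """Voxel size too coarse to resolve the thinnest wall of a phantom."""


Profile = Callable[[float], float]


def piecewise_linear(knots: Sequence[tuple[float, float]]) -> Profile:
    """Piecewise-linear profile through ``(z, value)`` knots, z in [0, 1].

    Constant extrapolation outside the knot range.  This is the only profile
    family the generator assumes, so each slice's geometry is exactly known.
    """
    pts = sorted(knots)
    zs = np.array([p[0] for p in pts], dtype=float)
    vs = np.array([p[1] for p in pts], dtype=float)
    if len(zs) < 1:
        raise ValueError("at least one knot required")

    def profile(z: float) -> float:
        return float(np.interp(z, zs, vs))

    return profile


def constant(value: float) -> Profile:
    return lambda z: float(value)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MorphotypeSpec:
    """Parametric description of a hollow-ellipse rostrum phantom.

    Profiles are functions of fractional axial position ``z`` (0 at the
    rostral tip, 1 at the posterior reference landmark) returning metres:
    ``width_profile`` the outer semi-width a(z), ``height_profile`` the outer
    semi-height b(z), ``wall_thickness_profile`` the wall t(z).
    ``rosette_bulge`` optionally multiplies a and b near the tip;
    ``naris_gap`` optionally opens the dorsal wall over an axial interval,
    producing open (C-shaped) sections there.
    """

    name: str
    skull_length: float
    rostral_span: float
    width_profile: Profile
    height_profile: Profile
    wall_thickness_profile: Profile
    rosette_bulge: Profile | None = None
    naris_gap: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.skull_length <= 0 or self.rostral_span <= 0:
            raise ValueError("skull_length and rostral_span must be positive")
        if self.rostral_span > self.skull_length:
            raise ValueError("rostral_span cannot exceed skull_length")
        for z in np.linspace(0.0, 1.0, 101):
            a, b, t = self.section_geometry(z)
            if a <= 0 or b <= 0:
                raise ValueError(f"outer semi-axes must be positive at z={z:.2f}")
            if not 0 < t <= min(a, b):
                raise ValueError(
                    f"wall thickness must satisfy 0 < t <= min(a, b) at z={z:.2f}"
                )

    def section_geometry(self, z: float) -> tuple[float, float, float]:
        """(a, b, t) in metres at fractional axial position z, bulge applied."""
        bulge = self.rosette_bulge(z) if self.rosette_bulge is not None else 1.0
        a = self.width_profile(z) * bulge
        b = self.height_profile(z) * bulge
        t = self.wall_thickness_profile(z)
        return a, b, t


@dataclass(frozen=True)
class VoxelVolume:
    """3D binary bone mask standing in for a segmented CT scan.

    ``mask`` axes: z (anteroposterior slice index), rows (dorsoventral y),
    cols (mediolateral x).  ``voxel_spacing`` is ``(dz, dy, dx)`` in metres.
    ``origin_landmarks`` gives the axial indices of the rostral tip and the
    posterior reference landmark.
    """

    mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    origin_landmarks: tuple[int, int]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {mask.shape}")
        object.__setattr__(self, "mask", mask)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacings must be positive: {self.voxel_spacing}")
        tip, post = self.origin_landmarks
        if not (0 <= tip < mask.shape[0] and 0 <= post < mask.shape[0]):
            raise ValueError("landmarks outside the stack")
        if not mask[min(tip, post) : max(tip, post) + 1].any():
            raise ValueError("mask empty between the landmarks")

    @property
    def sagittal_column(self) -> int:
        """Column index of the mid-sagittal plane (grids are odd-width)."""
        return (self.mask.shape[2] - 1) // 2


@dataclass(frozen=True)
class PairedSeries:
    """Two slice-matched measurement series for a paired test."""

    values_a: np.ndarray
    values_b: np.ndarray
    pairing_key: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        k = np.asarray(self.pairing_key, dtype=float)
        if not (len(a) == len(b) == len(k)):
            raise ValueError("paired series must have equal lengths")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        object.__setattr__(self, "pairing_key", k)


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------


def analytic_ellipse_properties(a: float, b: float, t: float = 0.0) -> SectionProperties:
    """Closed-form section properties of a solid or hollow ellipse.

    Solid ellipse (t = 0) about centroidal axes: ``Ix = pi*a*b**3/4``,
    ``Iy = pi*a**3*b/4``; the hollow case subtracts the inner ellipse with
    semi-axes ``(a - t, b - t)``.  ``J = Ix + Iy``.
    """
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if t < 0 or t > min(a, b):
        raise ValueError(f"wall thickness t={t} outside [0, min(a, b)={min(a, b)}]")
    ai, bi = a - t, b - t
    if t == 0:  # solid: no cavity to subtract
        ai = bi = 0.0
    area = math.pi * (a * b - ai * bi)
    Ix = math.pi / 4.0 * (a * b**3 - ai * bi**3)
    Iy = math.pi / 4.0 * (a**3 * b - ai**3 * bi)
    return SectionProperties(area=area, centroid=(0.0, 0.0), Ix=Ix, Iy=Iy, J=Ix + Iy)


# ---------------------------------------------------------------------------
# volume generation
# ---------------------------------------------------------------------------


def _symmetric_offsets(n: int) -> np.ndarray:
    # pixel-center offsets symmetric about 0; mirrored pairs are exact
    # negations so x**2 is bitwise identical across the midline
    return np.arange(n, dtype=float) - (n - 1) / 2.0


def _rasterize_section(
    a: float,
    b: float,
    t: float,
    voxel: float,
    height: int,
    width: int,
    naris_open: bool,
) -> np.ndarray:
    y = _symmetric_offsets(height)[:, None] * voxel
    x = _symmetric_offsets(width)[None, :] * voxel
    inside_outer = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    ai, bi = a - t, b - t
    if ai > 0 and bi > 0:
        inside_cavity = (x / ai) ** 2 + (y / bi) ** 2 < 1.0
    else:
        inside_cavity = np.zeros_like(inside_outer)
    mask = inside_outer & ~inside_cavity
    if naris_open:
        # breach the dorsal wall over the middle of the section: the lumen
        # connects to the exterior, so the slice becomes an open C-shape
        gap_half_width = 0.5 * max(ai, 0.25 * a)
        mask &= ~((y < 0) & (np.abs(x) <= gap_half_width))
    return mask


def generate_rostrum_volume(
    spec: MorphotypeSpec,
    voxel_size: float,
    noise_seed: int | None = None,
) -> VoxelVolume:
    """Rasterize a morphotype into an isotropic voxel volume.

    Each transverse slice is the hollow-ellipse section prescribed by the
    spec at that axial position; a pixel belongs to the section iff its
    center lies inside the outer boundary and outside the cavity.  The output
    is deterministic; a ``noise_seed`` adds reproducible boundary-voxel
    jitter only.  Walls thinner than 3 voxels anywhere raise
    :class:`ResolutionError` naming the offending axial position.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    n_slices = int(round(spec.rostral_span / voxel_size)) + 1
    if n_slices < 2:
        raise ResolutionError("voxel_size too coarse: fewer than 2 slices span the rostrum")
    zs = np.linspace(0.0, 1.0, n_slices)

    geoms = [spec.section_geometry(z) for z in zs]
    for z, (a, b, t) in zip(zs, geoms):
        if t < 3 * voxel_size:
            raise ResolutionError(
                f"wall thickness {t:.6g} m at axial position z={z:.3f} spans "
                f"fewer than 3 voxels at voxel_size={voxel_size:.6g} m"
            )
    a_max = max(g[0] for g in geoms)
    b_max = max(g[1] for g in geoms)
    half_w = int(math.ceil(a_max / voxel_size)) + 2
    half_h = int(math.ceil(b_max / voxel_size)) + 2
    width = 2 * half_w + 1  # odd: exact mid-sagittal column
    height = 2 * half_h + 1

    gap = spec.naris_gap
    stack = np.zeros((n_slices, height, width), dtype=bool)
    for k, (z, (a, b, t)) in enumerate(zip(zs, geoms)):
        naris_open = gap is not None and gap[0] <= z <= gap[1]
        stack[k] = _rasterize_section(a, b, t, voxel_size, height, width, naris_open)

    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        from scipy import ndimage

        for k in range(n_slices):
            sl = stack[k]
            boundary = sl & ~ndimage.binary_erosion(sl)
            flip = boundary & (rng.random(sl.shape) < 0.15)
            stack[k] = sl & ~flip

    return VoxelVolume(
        mask=stack,
        voxel_spacing=(voxel_size, voxel_size, voxel_size),
        origin_landmarks=(0, n_slices - 1),
    )


# ---------------------------------------------------------------------------
# morphotype presets
# ---------------------------------------------------------------------------


def tube_morphotype(skull_length: float = 0.86, name: str = "tube") -> MorphotypeSpec:
    """Narrow, near-constant-width hollow tube; circular sections."""
    r = 0.045 * skull_length
    return MorphotypeSpec(
        name=name,
        skull_length=skull_length,
        rostral_span=0.60 * skull_length,
        width_profile=piecewise_linear([(0.0, 0.85 * r), (1.0, r)]),
        height_profile=piecewise_linear([(0.0, 0.85 * r), (1.0, r)]),
        wall_thickness_profile=constant(0.35 * r),
    )


def flat_wide_morphotype(
    skull_length: float = 0.217, name: str = "flat_wide"
) -> MorphotypeSpec:
    """Broad, dorsoventrally flattened taper: a(z) > b(z) everywhere."""
    L = skull_length
    return MorphotypeSpec(
        name=name,
        skull_length=L,
        rostral_span=0.55 * L,
        width_profile=piecewise_linear([(0.0, 0.055 * L), (1.0, 0.16 * L)]),
        height_profile=piecewise_linear([(0.0, 0.025 * L), (1.0, 0.06 * L)]),
        wall_thickness_profile=piecewise_linear([(0.0, 0.016 * L), (1.0, 0.024 * L)]),
    )


def tall_narrow_morphotype(
    skull_length: float = 0.971, name: str = "tall_narrow"
) -> MorphotypeSpec:
    """Tall, mediolaterally compressed taper with a bulbous tip rosette."""
    L = skull_length
    return MorphotypeSpec(
        name=name,
        skull_length=L,
        rostral_span=0.55 * L,
        width_profile=piecewise_linear([(0.0, 0.022 * L), (1.0, 0.05 * L)]),
        height_profile=piecewise_linear([(0.0, 0.045 * L), (1.0, 0.12 * L)]),
        wall_thickness_profile=piecewise_linear([(0.0, 0.014 * L), (1.0, 0.02 * L)]),
        rosette_bulge=piecewise_linear([(0.0, 1.45), (0.07, 1.45), (0.18, 1.0), (1.0, 1.0)]),
    )


_MORPHOTYPES: dict[str, Callable[..., MorphotypeSpec]] = {
    "tube": tube_morphotype,
    "flat_wide": flat_wide_morphotype,
    "tall_narrow": tall_narrow_morphotype,
}


def morphotype_by_name(
    kind: str, skull_length: float | None = None, name: str | None = None
) -> MorphotypeSpec:
    """Look up a preset morphotype, optionally overriding length and label."""
    try:
        factory = _MORPHOTYPES[kind]
    except KeyError:
        raise ValueError(
            f"unknown morphotype {kind!r}; available: {sorted(_MORPHOTYPES)}"
        ) from None
    kwargs = {}
    if skull_length is not None:
        kwargs["skull_length"] = skull_length
    if name is not None:
        kwargs["name"] = name
    return factory(**kwargs)


# ---------------------------------------------------------------------------
# paired-series fixtures
# ---------------------------------------------------------------------------


def _ranks_summing_to(n: int, target: int) -> set[int]:
    # greedy largest-first over ranks 1..n always lands exactly on target
    remaining = target
    chosen: set[int] = set()
    for r in range(n, 0, -1):
        if remaining >= r:
            chosen.add(r)
            remaining -= r
    assert remaining == 0
    return chosen


def generate_paired_series(
    n: int, positive_rank_sum: int, seed: int
) -> PairedSeries:
    """Build two series realizing an exact signed-rank configuration.

    The pairwise differences ``a - b`` are all nonzero with distinct
    magnitudes, and the ranks (1 = smallest magnitude) of the positive
    differences sum exactly to ``positive_rank_sum``.  Reproducible for a
    given seed.
    """
    max_sum = n * (n + 1) // 2
    if not 0 <= positive_rank_sum <= max_sum:
        raise ValueError(
            f"positive_rank_sum must be in [0, {max_sum}] for n={n}, "
            f"got {positive_rank_sum}"
        )
    rng = np.random.default_rng(seed)
    positive_ranks = _ranks_summing_to(n, positive_rank_sum)

    # magnitude for rank r is r plus sub-unit jitter: distinct, order-preserving
    magnitudes = np.arange(1, n + 1) + rng.uniform(0.05, 0.45, size=n)
    signs = np.array([1.0 if r in positive_ranks else -1.0 for r in range(1, n + 1)])
    diffs = signs * magnitudes
    order = rng.permutation(n)  # scatter ranks along the slice axis
    diffs = diffs[order]

    values_b = rng.normal(0.0, 1.0, size=n)
    values_a = values_b + diffs
    key = np.arange(1, n + 1) / n
    return PairedSeries(values_a=values_a, values_b=values_b, pairing_key=key)


def positive_rank_sum_of(series: PairedSeries) -> float:
    """Audit: recompute the positive-difference rank sum from the series."""
    d = series.values_a - series.values_b
    if np.any(d == 0):
        raise ValueError("zero difference present; rank audit undefined")
    ranks = rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


# ---------------------------------------------------------------------------
# volume I/O: multipage TIFF or numbered PNG series + plain-text sidecar
# ---------------------------------------------------------------------------

_META_KEYS = ("dz", "dy", "dx", "tip_index", "posterior_index")


def _write_sidecar(path: Path, volume: VoxelVolume) -> None:
    dz, dy, dx = volume.voxel_spacing
    tip, post = volume.origin_landmarks
    lines = [
        f"dz = {dz!r}",
        f"dy = {dy!r}",
        f"dx = {dx!r}",
        f"tip_index = {tip}",
        f"posterior_index = {post}",
        f"sagittal_column = {volume.sagittal_column}",
    ]
    path.write_text("\n".join(lines) + "\n")


def _read_sidecar(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            meta[key.strip()] = float(val.strip())
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {path} missing keys: {missing}")
    return meta


def write_volume(volume: VoxelVolume, path, fmt: str = "tiff") -> Path:
    """Write a volume as 8-bit 0/255 slices plus a plain-text sidecar.

    ``tiff``: single multi-page TIFF at ``path`` with sidecar
    ``<path>.meta.txt``.  ``png``: directory of ``slice_0000.png`` files with
    ``meta.txt`` inside.  Returns the main path written.
    """
    path = Path(path)
    data = volume.mask.astype(np.uint8) * 255
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data)
        _write_sidecar(path.with_name(path.name + ".meta.txt"), volume)
        return path
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for k in range(data.shape[0]):
            iio.imwrite(path / f"slice_{k:04d}.png", data[k])
        _write_sidecar(path / "meta.txt", volume)
        return path
    raise ValueError(f"fmt must be 'tiff' or 'png', got {fmt!r}")


def read_volume(path, threshold: tuple[float, float] | None = None) -> VoxelVolume:
    """Read a volume written by :func:`write_volume` (either layout).

    By default pixels >= 128 count as bone (matching the 0/255 phantom
    encoding); pass ``threshold=(low, high)`` to binarize a grayscale stack
    with an inclusive window instead.
    """
    path = Path(path)
    if path.is_dir():
        meta = _read_sidecar(path / "meta.txt")
        files = sorted(path.glob("slice_*.png"))
        if not files:
            raise FileNotFoundError(f"no slice_*.png files in {path}")
        data = np.stack([iio.imread(f) for f in files])
    else:
        meta = _read_sidecar(path.with_name(path.name + ".meta.txt"))
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if threshold is None:
        mask = data >= 128
    else:
        low, high = threshold
        mask = (data >= low) & (data <= high)
    return VoxelVolume(
        mask=mask,
        voxel_spacing=(meta["dz"], meta["dy"], meta["dx"]),
        origin_landmarks=(int(meta["tip_index"]), int(meta["posterior_index"])),
    )
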