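"""Synthetic pulse-chase fluorescence fields with known ground truth.

Each field of view contains a few cells drawn as discs.  Per cell the
generator lays out binary organelle geometry — a plasma-membrane ring at the
cell boundary, a reticular ER texture filling the interior, a compact
perinuclear Golgi blob cluster, and disjoint endosome discs — then softens
each layer with a small Gaussian blur to emulate classifier-style
probability masks.  The lipid channel is rendered by distributing a known
total signal over the soft masks according to a compartment fraction
vector, adding a flat background and Poisson-Gaussian camera noise.

Because the per-compartment signal is known by construction, and the
fraction vectors can follow a kinetic trajectory, every downstream stage
(mask assignment, fraction quantification, rate fitting) can be validated
end to end without any real microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .kinetics import COMPARTMENTS, FractionTimeSeries, KineticParams, forward_model

__all__ = [
    "SceneConfig",
    "OrganelleMaskSet",
    "FieldImage",
    "SyntheticDataset",
    "generate_organelle_masks",
    "render_field",
    "generate_dataset",
]


class SceneConfigError(ValueError):
    """A scene configuration that cannot be realised geometrically."""


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, photon budget and noise of one synthetic field of view.

    Lengths are in pixels, intensities in photons.  ``total_signal`` is the
    integrated lipid signal per cell (split across compartments by the
    fraction vector at render time).  ``poisson_scale`` converts intensity to
    Poisson counts (0 disables shot noise); ``gaussian_sd`` is additive read
    noise.  The default geometry is deliberately chunky relative to the
    4-pixel analysis blur so that mask assignment of a blurred image remains
    faithful; see the methods note.
    """

    image_shape: tuple[int, int] = (384, 384)
    n_cells: int = 3
    pm_ring_px: float = 16.0
    er_density: float = 0.55
    golgi_blob_count: int = 3
    golgi_blob_radius_px: float = 8.0
    endosome_count: int = 3
    endosome_radius_px: tuple[float, float] = (8.0, 12.0)
    compartment_margin_px: float = 8.0
    background_level: float = 20.0
    poisson_scale: float = 1.0
    gaussian_sd: float = 2.0
    total_signal: float = 5.0e6
    mask_blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 64 or w < 64:
            raise SceneConfigError("image_shape dims must be >= 64 px")
        if self.n_cells < 1:
            raise SceneConfigError("n_cells must be >= 1")
        for name in ("pm_ring_px", "golgi_blob_radius_px", "mask_blur_sigma"):
            if getattr(self, name) <= 0:
                raise SceneConfigError(f"{name} must be strictly positive")
        if not (0.0 < self.er_density <= 1.0):
            raise SceneConfigError("er_density must be in (0, 1]")
        if self.golgi_blob_count < 0 or self.endosome_count < 0:
            raise SceneConfigError("object counts must be >= 0")
        rmin, rmax = self.endosome_radius_px
        if rmin <= 0 or rmax < rmin:
            raise SceneConfigError(
                "endosome_radius_px must satisfy 0 < min <= max"
            )
        if self.compartment_margin_px < 0:
            raise SceneConfigError("compartment_margin_px must be >= 0")
        if self.background_level < 0:
            raise SceneConfigError("background_level must be >= 0")
        if self.total_signal <= 0:
            raise SceneConfigError("total_signal must be > 0")
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise SceneConfigError("noise parameters must be >= 0")


@dataclass
class OrganelleMaskSet:
    """Soft probability maps per compartment plus the cell-covered area.

    ``masks`` maps each :data:`~lipidflux.kinetics.COMPARTMENTS` label to a
    float map in [0, 1]; supports lie inside ``cell_mask``.  ``n_objects``
    records how many discrete objects (per compartment) were placed, for use
    as a morphometry oracle on synthetic data.
    """

    masks: dict[str, np.ndarray]
    cell_mask: np.ndarray
    n_objects: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.cell_mask.shape
        for name, m in self.masks.items():
            if m.shape != shape:
                raise ValueError(f"mask {name!r} shape mismatch")
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"mask {name!r} values outside [0, 1]")

    def stacked(self) -> np.ndarray:
        return np.stack([self.masks[c] for c in COMPARTMENTS])


@dataclass
class FieldImage:
    """One lipid-channel acquisition with its metadata.

    ``true_signal`` holds the per-compartment integrated signal placed in the
    noise-free render (ground truth for assignment tests); ``provenance``
    accumulates processing records (e.g. subtracted background).
    """

    pixels: np.ndarray
    probe_id: str
    chase_time: float
    condition: str = "UV"
    seed: int = 0
    true_signal: dict[str, float] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.min() < 0:
            raise ValueError("pixel values must be >= 0")
        if self.condition not in ("UV", "no-UV"):
            raise ValueError("condition must be 'UV' or 'no-UV'")


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _cell_centers(config: SceneConfig) -> tuple[list[tuple[float, float]], float]:
    """Place cells on a jittered grid; returns centers and the cell radius."""
    h, w = config.image_shape
    n = config.n_cells
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    pitch = min(h / nrow, w / ncol)
    radius = 0.42 * pitch
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    centers = []
    k = 0
    for i in range(nrow):
        for j in range(ncol):
            if k >= n:
                break
            cy = (i + 0.5) * h / nrow + rng.uniform(-0.04, 0.04) * pitch
            cx = (j + 0.5) * w / ncol + rng.uniform(-0.04, 0.04) * pitch
            centers.append((cy, cx))
            k += 1
    return centers, radius


def generate_organelle_masks(config: SceneConfig) -> OrganelleMaskSet:
    """Build the per-compartment probability masks for one field of view.

    Deterministic given ``config.seed``.  Raises :class:`SceneConfigError`
    when the requested geometry cannot fit (e.g. endosomes larger than the
    cell interior).
    """
    shape = config.image_shape
    centers, radius = _cell_centers(config)
    interior_r = radius - config.pm_ring_px
    rmin, rmax = config.endosome_radius_px
    if interior_r <= rmax + 3:
        raise SceneConfigError(
            f"endosome_radius_px max {rmax} does not fit the cell interior "
            f"(radius {interior_r:.1f} px); reduce endosome_radius_px or "
            f"pm_ring_px, or enlarge image_shape"
        )
    if config.golgi_blob_count and interior_r <= config.golgi_blob_radius_px + 3:
        raise SceneConfigError(
            "golgi_blob_radius_px does not fit the cell interior"
        )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    pm = np.zeros(shape, dtype=bool)
    golgi = np.zeros(shape, dtype=bool)
    endo = np.zeros(shape, dtype=bool)
    cells = np.zeros(shape, dtype=bool)
    interior = np.zeros(shape, dtype=bool)
    n_endo_placed = 0
    n_golgi_placed = 0

    for cy, cx in centers:
        cell = _disc(shape, (cy, cx), radius)
        inner = _disc(shape, (cy, cx), interior_r)
        cells |= cell
        interior |= inner
        pm |= cell & ~inner

        # perinuclear Golgi: compact blob cluster offset from the centre
        placed: list[tuple[float, float, float]] = []
        if config.golgi_blob_count:
            ang = rng.uniform(0, 2 * np.pi)
            gr = config.golgi_blob_radius_px
            gcy = cy + 0.35 * interior_r * np.sin(ang)
            gcx = cx + 0.35 * interior_r * np.cos(ang)
            for _ in range(config.golgi_blob_count):
                jy = gcy + rng.uniform(-1.2, 1.2) * gr
                jx = gcx + rng.uniform(-1.2, 1.2) * gr
                golgi |= _disc(shape, (jy, jx), gr) & inner
                placed.append((jy, jx, gr))
            n_golgi_placed += 1  # one cluster per cell

        # endosomes: mutually disjoint discs avoiding the Golgi cluster
        for _ in range(config.endosome_count):
            r = rng.uniform(rmin, rmax)
            ok = False
            for _attempt in range(2000):
                rho = rng.uniform(0, interior_r - r - 3)
                ang = rng.uniform(0, 2 * np.pi)
                ey = cy + rho * np.sin(ang)
                ex = cx + rho * np.cos(ang)
                clear = all(
                    np.hypot(ey - py, ex - px) > r + pr + 4 for py, px, pr in placed
                )
                if clear:
                    ok = True
                    break
            if not ok:
                raise SceneConfigError(
                    "could not place disjoint endosomes: endosome_count/"
                    "endosome_radius_px too large for the cell interior"
                )
            endo |= _disc(shape, (ey, ex), r)
            placed.append((ey, ex, r))
            n_endo_placed += 1

    # reticular ER: thresholded smooth noise filling the remaining interior.
    # A signal-free margin separates the ER region from the PM ring and from
    # the Golgi/endosome objects so that, after the analysis blur, signal
    # spilling across a compartment boundary lands in unclaimed territory
    # (reported as unassigned) rather than in the neighbouring mask.
    margin = int(round(config.compartment_margin_px))
    organelle_zone = (
        ndimage.binary_dilation(golgi | endo, iterations=max(margin, 1))
    )
    er_core = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        er_core |= _disc(shape, (cy, cx), interior_r - margin)
    er_room = er_core & ~organelle_zone
    texture = ndimage.gaussian_filter(rng.normal(size=shape), 3.0)
    if er_room.any() and config.er_density < 1.0:
        cut = np.quantile(texture[er_room], 1.0 - config.er_density)
        er = er_room & (texture >= cut)
    else:
        er = er_room

    sigma = config.mask_blur_sigma
    pad = int(np.ceil(3 * sigma)) + 1
    cell_mask = ndimage.binary_dilation(cells, iterations=pad)

    def soften(b: np.ndarray) -> np.ndarray:
        s = ndimage.gaussian_filter(b.astype(np.float32), sigma)
        return np.clip(s, 0.0, 1.0) * cell_mask

    masks = {
        "PM": soften(pm),
        "ER": soften(er),
        "Golgi": soften(golgi),
        "Endo": soften(endo),
    }
    for name, binary in (("PM", pm), ("ER", er), ("Golgi", golgi), ("Endo", endo)):
        if binary.any() and not masks[name].any():
            raise SceneConfigError(f"mask {name} lost all mass during softening")
    n_objects = {
        "PM": len(centers),
        "ER": 1 if er.any() else 0,
        "Golgi": n_golgi_placed,
        "Endo": n_endo_placed,
    }
    return OrganelleMaskSet(masks=masks, cell_mask=cell_mask, n_objects=n_objects)


def _resolve_seed(config: SceneConfig, chase_time: float, condition: str,
                  override: int | None) -> int:
    if override is not None:
        return int(override)
    ss = np.random.SeedSequence(
        [config.seed, int(round(chase_time * 1000)), 1 if condition == "UV" else 0]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def render_field(
    masks: OrganelleMaskSet,
    fractions: Sequence[float],
    config: SceneConfig,
    chase_time: float,
    probe_id: str = "probe",
    condition: str = "UV",
    seed: int | None = None,
) -> FieldImage:
    """Render the lipid channel for one field.

    The noise-free expected signal integrated over compartment *o* equals
    ``total_signal * n_cells * fractions[o]``; background is added everywhere
    and Poisson-Gaussian noise applied with a seed derived from the config
    seed and the chase time (or the explicit ``seed``).  Fields in the
    ``no-UV`` control condition contain background and noise only — the probe
    is never crosslinked, so no lipid-specific signal survives fixation.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (4,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 4 nonnegative values summing to 1")
    total = config.total_signal * config.n_cells
    clean = np.full(config.image_shape, float(config.background_level))
    true_signal = dict.fromkeys(COMPARTMENTS, 0.0)
    if condition == "UV":
        for f, comp in zip(fr, COMPARTMENTS):
            m = masks.masks[comp].astype(np.float64)
            mass = m.sum()
            if f > 0 and mass == 0:
                raise ValueError(
                    f"cannot place signal in {comp}: mask has zero mass"
                )
            if mass > 0:
                clean += (f * total) * m / mass
                true_signal[comp] = f * total

    field_seed = _resolve_seed(config, chase_time, condition, seed)
    rng = np.random.default_rng(field_seed)
    img = clean
    if config.poisson_scale > 0:
        img = rng.poisson(clean * config.poisson_scale) / config.poisson_scale
    if config.gaussian_sd > 0:
        img = img + rng.normal(0.0, config.gaussian_sd, size=clean.shape)
    img = np.clip(img, 0.0, None)
    return FieldImage(
        pixels=img.astype(np.float64),
        probe_id=probe_id,
        chase_time=float(chase_time),
        condition=condition,
        seed=field_seed,
        true_signal=true_signal,
    )


@dataclass
class SyntheticDataset:
    """Fields plus their masks and the generating kinetic ground truth."""

    fields: list[tuple[FieldImage, OrganelleMaskSet]]
    truth_series: FractionTimeSeries
    truth_params: KineticParams
    probe_id: str

    def __len__(self) -> int:
        return len(self.fields)


def generate_dataset(
    config: SceneConfig,
    truth: KineticParams,
    times: Sequence[float],
    n_fields_per_time: int,
    probe_id: str = "probe",
    n_no_uv: int = 0,
) -> SyntheticDataset:
    """Simulate a pulse-chase time course for one probe.

    Compartment fractions at each chase time follow the forward kinetic
    model from an all-PM initial state at the first time point.  Every field
    gets its own geometry and noise via counter-derived sub-seeds, so the
    dataset is reproducible bit for bit from (config, truth, times).
    ``n_no_uv`` appends that many background-only control fields at the first
    chase time.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be nonempty and strictly increasing")
    if n_fields_per_time < 1:
        raise ValueError("n_fields_per_time must be >= 1")
    truth_series = forward_model(truth, times, method="expm")
    fields: list[tuple[FieldImage, OrganelleMaskSet]] = []
    for ti, t in enumerate(times):
        for fi in range(n_fields_per_time):
            sub = np.random.SeedSequence([config.seed, ti, fi]).generate_state(2)
            cfg_f = replace(config, seed=int(sub[0] % (2**31)))
            masks = generate_organelle_masks(cfg_f)
            img = render_field(
                masks,
                truth_series.fractions[ti],
                cfg_f,
                chase_time=t,
                probe_id=probe_id,
                condition="UV",
                seed=int(sub[1] % (2**31)),
            )
            fields.append((img, masks))
    for fi in range(n_no_uv):
        sub = np.random.SeedSequence([config.seed, len(times), fi]).generate_state(2)
        cfg_f = replace(config, seed=int(sub[0] % (2**31)))
        masks = generate_organelle_masks(cfg_f)
        img = render_field(
            masks,
            truth_series.fractions[0],
            cfg_f,
            chase_time=times[0],
            probe_id=probe_id,
            condition="no-UV",
            seed=int(sub[1] % (2**31)),
        )
        fields.append((img, masks))
    return SyntheticDataset(
        fields=fields, truth_series=truth_series, truth_params=truth, probe_id=probe_id
    )
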