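"""Seeded generator of phase-contrast-like cell scenes with exact ground truth.

The generator emulates the phenomenology of adherent-cell phase-contrast
micrographs: dark-toned cell bodies on a brighter fuzzy background, soft
bright halo rings around a fraction of cells (the out-of-focus artifact),
small bright debris specks, a smooth uneven-illumination vignette (bright
center, shading toward the corners), and additive Gaussian pixel noise.

Cell bodies are ellipses with a radial Fourier boundary perturbation so
outlines are irregular rather than trivially smooth.  The truth mask covers
exactly the rasterized cell-body pixels; halo rings and debris are *not* in
the truth — correct pipeline behavior is scored as excluding them, and the
scene keeps separate halo/debris bookkeeping masks for that purpose.

A single integer seed determines everything; corpora derive per-scene seeds
by stable hashing so they are order-independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .exceptions import GenerationError, ParameterError
from .imaging import BinaryMask, GrayImage


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    If ``confluence_target`` is set, cells are added until the truth-mask
    area fraction reaches it (bounded retries); otherwise exactly
    ``n_cells`` cells are placed.
    """

    width: int = 400
    height: int = 300
    n_cells: int = 15
    confluence_target: float | None = 0.35
    cell_radius_range: tuple[float, float] = (14.0, 30.0)
    cell_intensity: float = 85.0        # mean dark tone of cell bodies
    cell_intensity_spread: float = 12.0  # per-cell tone jitter (1 sd)
    background_intensity: float = 190.0  # mean bright tone of the background
    halo_fraction: float = 0.25          # fraction of cells with a halo ring
    halo_amplitude: float = 35.0         # peak halo brightness above background
    n_debris: int = 8
    debris_intensity: float = 240.0
    illumination_gradient_amp: float = 15.0  # vignette depth, intensity units
    noise_sigma: float = 4.0
    #: Cellular regions are inhomogeneous in phase contrast (organelles,
    #: granularity): amplitude (1 sd) and correlation length of the smooth
    #: intracellular texture field.
    texture_amplitude: float = 25.0
    texture_scale: float = 1.5
    #: Optical point-spread blur (1 sd, px) applied to the noiseless scene;
    #: real micrographs never have 1-px-sharp transitions.
    psf_sigma: float = 1.0
    boundary_wobble: float = 0.25        # max total radial excursion, fraction of radius
    n_harmonics_range: tuple[int, int] = (3, 6)
    aspect_range: tuple[float, float] = (0.6, 1.0)
    fixed_centers: tuple[tuple[float, float], ...] | None = None  # (row, col) pins
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ParameterError("scene dimensions must be >= 1")
        if not 0 <= self.cell_intensity <= 255 or not 0 <= self.background_intensity <= 255:
            raise ParameterError("intensity bands must lie inside [0, 255]")
        if self.cell_intensity >= self.background_intensity:
            raise ParameterError("cell tone must be strictly darker than the background tone")
        if self.confluence_target is not None and not 0 < self.confluence_target < 1:
            raise ParameterError("confluence_target must be in (0, 1)")
        lo, hi = self.cell_radius_range
        if lo <= 0 or hi < lo:
            raise ParameterError("cell_radius_range must satisfy 0 < min <= max")
        if not 0 <= self.halo_fraction <= 1:
            raise ParameterError("halo_fraction must be in [0, 1]")
        if self.boundary_wobble < 0 or self.boundary_wobble > 0.25:
            raise ParameterError("boundary_wobble must be in [0, 0.25]")


@dataclass
class SyntheticScene:
    """A rendered scene plus its exact ground truth and artifact bookkeeping."""

    image: GrayImage
    truth_mask: BinaryMask
    spec: SceneSpec
    true_area_fraction: float
    halo_mask: BinaryMask    # visible halo-ring pixels (not in truth)
    debris_mask: BinaryMask  # debris speck pixels (not in truth)


def _cell_geometry(rng, spec, h, w, center, radius):
    """Perturbed-ellipse membership field around ``center``.

    Returns the bounding-box slice bounds, the normalized radius ``u`` and
    the angular boundary function ``B(theta)``; the body is ``u <= B``.
    """
    aspect = rng.uniform(*spec.aspect_range)
    a, b = radius, radius * aspect
    angle = rng.uniform(0.0, np.pi)
    nh = int(rng.integers(spec.n_harmonics_range[0], spec.n_harmonics_range[1] + 1))
    amps = rng.uniform(0.0, 1.0, nh)
    total = amps.sum()
    if total > 0:
        amps = amps * (spec.boundary_wobble * rng.uniform(0.5, 1.0) / total)
    orders = np.arange(2, 2 + nh)
    phases = rng.uniform(0.0, 2.0 * np.pi, nh)

    cy, cx = center
    pad = radius * (1.0 + spec.boundary_wobble) + 8.0
    y0, y1 = max(0, int(cy - pad)), min(h, int(cy + pad) + 1)
    x0, x1 = max(0, int(cx - pad)), min(w, int(cx + pad) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    xr = (dx * ca + dy * sa) / a
    yr = (-dx * sa + dy * ca) / b
    u = np.hypot(xr, yr)
    theta = np.arctan2(yr, xr)
    boundary = 1.0 + sum(
        amp * np.cos(k * theta + ph) for amp, k, ph in zip(amps, orders, phases)
    )
    return (y0, y1, x0, x1), u, boundary


def _detached_cell_field(rng, spec, h, w, center):
    """Brightness field of a detached (out-of-focus) cell.

    Detached cells have left the focal plane: they appear as tiny bright
    circles wrapped in a diffuse halo, carry no dark adherent body, and do
    not count toward the growth area.
    """
    r = 0.5 * rng.uniform(*spec.cell_radius_range)
    halo_px = float(rng.integers(1, 4))
    bounds, u, boundary = _cell_geometry(rng, spec, h, w, center, r)
    d_out = (u - boundary) * r  # approximate px distance outside the rim
    field = np.where(
        u <= boundary,
        spec.halo_amplitude * (0.6 + 0.4 * u / np.maximum(boundary, 1e-9)),
        spec.halo_amplitude * np.exp(-((np.maximum(d_out, 0.0) / (halo_px + 1.0)) ** 2)),
    )
    return bounds, field


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one scene deterministically from its spec (seed fixes everything)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # Background: bright center, shading toward the corners, plus a mild tilt.
    canvas = np.full((h, w), spec.background_intensity, dtype=np.float64)
    if spec.illumination_gradient_amp > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        ry = (yy - (h - 1) / 2) / max(h / 2, 1)
        rx = (xx - (w - 1) / 2) / max(w / 2, 1)
        r2 = (ry**2 + rx**2) / 2.0  # 0 at center, ~1 at corners
        tilt = rng.uniform(-0.3, 0.3, 2)
        canvas -= spec.illumination_gradient_amp * r2
        canvas += spec.illumination_gradient_amp * (tilt[0] * rx + tilt[1] * ry) * 0.5

    truth = np.zeros((h, w), dtype=bool)
    body = np.zeros((h, w), dtype=np.float64)
    halo_field = np.zeros((h, w), dtype=np.float64)

    # smooth intracellular texture field, shared across the scene
    texture = np.zeros((h, w), dtype=np.float64)
    if spec.texture_amplitude > 0:
        from scipy import ndimage as _ndi

        raw = rng.normal(0.0, 1.0, (h, w))
        texture = _ndi.gaussian_filter(raw, spec.texture_scale)
        sd = texture.std()
        if sd > 0:
            texture *= spec.texture_amplitude / sd

    max_r = spec.cell_radius_range[1]
    needed = None
    if spec.confluence_target is not None:
        needed = spec.confluence_target * h * w
        max_attempts = 200 + 40 * int(needed / max(np.pi * spec.cell_radius_range[0] ** 2, 1.0))
    else:
        max_attempts = None

    placed = 0
    attempts = 0
    fixed = list(spec.fixed_centers) if spec.fixed_centers else None
    while True:
        if needed is None:
            if placed >= spec.n_cells:
                break
        else:
            if truth.sum() >= needed:
                break
            if attempts >= max_attempts:
                raise GenerationError(
                    f"confluence_target={spec.confluence_target} unreachable after "
                    f"{attempts} attempts with radii {spec.cell_radius_range} "
                    f"on a {w}x{h} frame"
                )
        attempts += 1
        if fixed is not None:
            if placed >= len(fixed):
                break
            center = fixed[placed]
        else:
            margin = min(max_r, h / 2 - 1, w / 2 - 1)
            center = (rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin))
        if fixed is None and rng.random() < spec.halo_fraction:
            # detached cell: bright fuzzy blob, no truth contribution
            (y0, y1, x0, x1), field = _detached_cell_field(rng, spec, h, w, center)
            sub_halo = halo_field[y0:y1, x0:x1]
            np.maximum(sub_halo, field, out=sub_halo)
            placed += 1
            continue
        radius = rng.uniform(*spec.cell_radius_range)
        (y0, y1, x0, x1), u, boundary = _cell_geometry(rng, spec, h, w, center, radius)
        inside = u <= boundary
        if not inside.any():
            continue
        # reject placements already fully covered (no new truth pixels)
        if truth[y0:y1, x0:x1][inside].all():
            continue
        tone = float(np.clip(rng.normal(spec.cell_intensity, spec.cell_intensity_spread),
                             20.0, spec.background_intensity - 50.0))
        sub_body = body[y0:y1, x0:x1]
        sub_body[inside] = tone + texture[y0:y1, x0:x1][inside]
        truth[y0:y1, x0:x1] |= inside
        placed += 1

    img = np.where(truth, body, canvas + halo_field)
    halo_visible = (halo_field > spec.halo_amplitude * 0.25) & ~truth

    debris = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_debris):
        for _try in range(20):
            dcy = rng.uniform(1, h - 2)
            dcx = rng.uniform(1, w - 2)
            if not truth[int(round(dcy)), int(round(dcx))]:
                break
        else:
            continue
        diam = rng.uniform(1.0, 4.0)
        rr = max(diam / 2.0, 0.6)
        y0, y1 = max(0, int(dcy - rr) - 1), min(h, int(dcy + rr) + 2)
        x0, x1 = max(0, int(dcx - rr) - 1), min(w, int(dcx + rr) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        speck = (yy - dcy) ** 2 + (xx - dcx) ** 2 <= rr**2
        speck &= ~truth[y0:y1, x0:x1]
        img[y0:y1, x0:x1][speck] = spec.debris_intensity + rng.normal(0.0, 3.0)
        debris[y0:y1, x0:x1] |= speck

    if spec.psf_sigma > 0:
        from scipy import ndimage as _ndi

        img = _ndi.gaussian_filter(img, spec.psf_sigma)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, (h, w))

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth_mask = np.where(truth, 255, 0).astype(np.uint8)
    return SyntheticScene(
        image=image,
        truth_mask=truth_mask,
        spec=spec,
        true_area_fraction=float(truth.sum()) / (h * w),
        halo_mask=np.where(halo_visible, 255, 0).astype(np.uint8),
        debris_mask=np.where(debris, 255, 0).astype(np.uint8),
    )


def _derived_seed_and_jitter(seed: int, index: int) -> tuple[int, float]:
    """Stable per-scene seed and confluence jitter factor in [0.8, 1.2]."""
    state = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),)).generate_state(2)
    child_seed = int(state[0] % (2**31))
    jitter = 0.8 + 0.4 * (float(state[1]) / 2**32)
    return child_seed, jitter


def generate_corpus(spec_template: SceneSpec, n: int, seed: int) -> list[SyntheticScene]:
    """Generate ``n`` scenes with per-scene derived seeds.

    Confluence (or the cell count, when no target is set) is jittered within
    +-20% of the template so the corpus spans low- and high-density regimes.
    """
    if n < 1:
        raise ParameterError(f"corpus size must be >= 1, got {n}")
    scenes = []
    for i in range(n):
        child_seed, jitter = _derived_seed_and_jitter(seed, i)
        if spec_template.confluence_target is not None:
            spec = dataclasses.replace(
                spec_template,
                seed=child_seed,
                confluence_target=spec_template.confluence_target * jitter,
            )
        else:
            spec = dataclasses.replace(
                spec_template,
                seed=child_seed,
                n_cells=max(1, round(spec_template.n_cells * jitter))
                if spec_template.n_cells > 0
                else 0,
            )
        try:
            scenes.append(generate_scene(spec))
        except GenerationError as exc:
            raise GenerationError(f"scene {i}: {exc}") from exc
    return scenes
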