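"""Simulated adipose tissue: lipid-droplet kinetics and frame rendering.

The plant stands in for the cultured 3T3-L1 adipocytes under the
microscope. Droplet radii grow linearly under insulin (lipogenesis) and
shrink under adrenaline (lipolysis), with a lower clamp; droplets belong
to clusters that drift across the field of view and occasionally jump —
the disturbance that, in the real system, carried clusters of droplets
out of the frame.

Rendering produces 8-bit grayscale frames: bright droplet lumens with a
darker rim band (phase-contrast-like boundary) over a smooth textured
background plus optional sensor noise. Everything is deterministic given
the state's seed and the stimulant schedule.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .stimulant import Stimulant

__all__ = [
    "Droplet",
    "LDPlantState",
    "make_plant",
    "random_droplet_field",
    "step_plant",
    "render_frame",
    "write_frames",
    "droplet_table",
    "analytic_index",
]

R_MIN = 1.0  # px, radii never shrink below this


@dataclasses.dataclass(frozen=True)
class Droplet:
    """One lipid droplet: center (x, y) in pixels, radius in pixels."""

    x: float
    y: float
    radius: float
    cluster_id: int = 0


@dataclasses.dataclass(frozen=True)
class LDPlantState:
    """Kinetic state of the simulated adipose field.

    Rates are in px/h; ``drift_velocity`` is the speed of each cluster's
    constant-velocity drift (direction fixed per cluster by the seed) and
    ``jump_rate`` the expected number of sudden cluster relocations per
    hour (Poisson). ``noise_sd`` is the additive rendering noise in 8-bit
    intensity units.
    """

    droplets: tuple[Droplet, ...]
    active_stimulant: Stimulant = Stimulant.INSULIN
    growth_rate: float = 0.4
    shrink_rate: float = 0.6
    drift_velocity: float = 0.0
    jump_rate: float = 0.0
    jump_scale: float = 80.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    time: float = 0.0
    frame_shape: tuple[int, int] = (480, 640)  # rows, cols

    def mean_radius(self) -> float:
        if not self.droplets:
            return 0.0
        return float(np.mean([d.radius for d in self.droplets]))


def random_droplet_field(
    n_droplets: int,
    frame_shape: tuple[int, int] = (480, 640),
    radius_range: tuple[float, float] = (5.0, 9.0),
    n_clusters: int = 6,
    min_separation: float = 4.0,
    margin: float = 15.0,
    seed: int = 0,
) -> tuple[Droplet, ...]:
    """Place non-overlapping droplets by rejection sampling.

    Droplets are assigned round-robin to ``n_clusters`` clusters so drift
    disturbances act on spatially arbitrary groups; separation is enforced
    between rims (center distance > r1 + r2 + min_separation).
    """
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    placed: list[Droplet] = []
    for i in range(n_droplets):
        for _attempt in range(200):
            r = float(rng.uniform(*radius_range))
            x = float(rng.uniform(margin, w - margin))
            y = float(rng.uniform(margin, h - margin))
            ok = all(
                (x - d.x) ** 2 + (y - d.y) ** 2
                > (r + d.radius + min_separation) ** 2
                for d in placed
            )
            if ok:
                placed.append(Droplet(x, y, r, cluster_id=i % n_clusters))
                break
        else:
            break  # field saturated; keep what fits
    return tuple(placed)


def make_plant(
    n_droplets: int = 150,
    frame_shape: tuple[int, int] = (240, 320),
    seed: int = 0,
    **state_kwargs,
) -> LDPlantState:
    """Convenience constructor: random field + default kinetics."""
    droplets = random_droplet_field(n_droplets, frame_shape=frame_shape, seed=seed)
    return LDPlantState(
        droplets=droplets, rng_seed=seed, frame_shape=frame_shape, **state_kwargs
    )


def _cluster_direction(seed: int, cluster_id: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7, cluster_id]))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])


def step_plant(
    state: LDPlantState, dt: float, stimulant: Stimulant | str | None = None
) -> LDPlantState:
    """Advance the plant by ``dt`` hours under ``stimulant``.

    Radii follow the linear rate law with clamping at ``R_MIN``; cluster
    centers translate at their drift velocity; jump events relocate whole
    clusters by ~``jump_scale`` px. Purely a function of (state, dt,
    stimulant): repeated calls with equal arguments return equal states.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    stim = Stimulant.parse(stimulant if stimulant is not None else state.active_stimulant)
    if stim is Stimulant.INSULIN:
        dr = state.growth_rate * dt
    else:
        dr = -state.shrink_rate * dt

    cluster_ids = sorted({d.cluster_id for d in state.droplets})
    shift = {
        c: _cluster_direction(state.rng_seed, c) * state.drift_velocity * dt
        for c in cluster_ids
    }
    if state.jump_rate > 0 and cluster_ids:
        # jump draws are keyed on quantized time so the schedule alone
        # (not call granularity) determines the event sequence
        key = int(round(state.time * 3600.0))
        rng = np.random.default_rng(np.random.SeedSequence([state.rng_seed, 11, key]))
        n_jumps = rng.poisson(state.jump_rate * dt)
        for _ in range(n_jumps):
            c = int(rng.choice(cluster_ids))
            vec = rng.normal(0.0, state.jump_scale, size=2)
            shift[c] = shift[c] + vec

    new_droplets = tuple(
        Droplet(
            x=d.x + float(shift[d.cluster_id][0]),
            y=d.y + float(shift[d.cluster_id][1]),
            radius=max(R_MIN, d.radius + dr),
            cluster_id=d.cluster_id,
        )
        for d in state.droplets
    )
    return dataclasses.replace(
        state, droplets=new_droplets, active_stimulant=stim, time=state.time + dt
    )


def _background(shape: tuple[int, int], seed: int) -> np.ndarray:
    """Smooth static texture (mean 100, sd ~8) fixed by the plant seed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), 4.0)
    sd = max(float(tex.std()), 1e-9)
    return 100.0 + 8.0 * tex / sd


def render_frame(
    state: LDPlantState,
    lumen_intensity: float = 150.0,
    rim_intensity: float = 40.0,
    rim_thickness: float = 2.0,
) -> np.ndarray:
    """Rasterize the droplet field to an 8-bit grayscale frame.

    The rim band is centered on each droplet's radius, so the thinned
    contour of the monitored image traces the true circumference.
    Off-frame droplets are silently clipped. Additive Gaussian noise
    (``noise_sd``) is seeded from (plant seed, quantized time) so a fixed
    schedule reproduces a bit-identical stack.
    """
    h, w = state.frame_shape
    img = _background((h, w), state.rng_seed).copy()
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    half = rim_thickness / 2.0
    for d in state.droplets:
        if (
            d.x < -d.radius - half
            or d.x > w + d.radius + half
            or d.y < -d.radius - half
            or d.y > h + d.radius + half
        ):
            continue
        # restrict to the droplet's bounding box for speed
        x0 = max(0, int(d.x - d.radius - half - 1))
        x1 = min(w, int(d.x + d.radius + half + 2))
        y0 = max(0, int(d.y - d.radius - half - 1))
        y1 = min(h, int(d.y + d.radius + half + 2))
        if x1 <= x0 or y1 <= y0:
            continue
        dist = np.hypot(yy[y0:y1, x0:x1] - d.y, xx[y0:y1, x0:x1] - d.x)
        patch = img[y0:y1, x0:x1]
        patch[dist < d.radius - half] = lumen_intensity
        patch[np.abs(dist - d.radius) <= half] = rim_intensity
    if state.noise_sd > 0:
        key = int(round(state.time * 3600.0))
        rng = np.random.default_rng(np.random.SeedSequence([state.rng_seed, 5, key]))
        img = img + rng.normal(0.0, state.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def analytic_index(state: LDPlantState) -> float:
    """Ground-truth index: 100 * sum of in-frame circumference / area.

    Droplets fully outside the frame contribute nothing; partial clipping
    is ignored (adequate for fields placed with a margin).
    """
    h, w = state.frame_shape
    total = 0.0
    for d in state.droplets:
        if -d.radius < d.x < w + d.radius and -d.radius < d.y < h + d.radius:
            total += 2.0 * np.pi * d.radius
    return 100.0 * total / (h * w)


def droplet_table(states: Sequence[LDPlantState]) -> pd.DataFrame:
    """Ground-truth droplet geometry per frame as a tidy table."""
    rows = []
    for frame_id, s in enumerate(states):
        for d in s.droplets:
            rows.append(
                {
                    "frame": frame_id,
                    "time_h": s.time,
                    "cluster_id": d.cluster_id,
                    "x": d.x,
                    "y": d.y,
                    "radius": d.radius,
                }
            )
    return pd.DataFrame(rows, columns=["frame", "time_h", "cluster_id", "x", "y", "radius"])


def write_frames(frames: Sequence[np.ndarray], out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Write a frame stack as zero-padded image files (frame_0001.png ...)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames, start=1):
        p = out / f"frame_{i:04d}.{fmt}"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths
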