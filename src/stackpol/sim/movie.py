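"""Synthetic centrifuge-force-microscope bead movies.

Renders a dissociation dataset as what the camera sees: dark (or bright)
circular microspheres on a uniform background with Gaussian camera noise.
A bead vanishes from its dissociation frame onward — its region reverts to
background + noise, which is exactly the variance drop the tracking arm
detects. Deliberately clustered bead pairs and irregular debris blobs are
injected as screening fixtures. Ground truth (positions, radii, true event
frames) is attached only as sidecar metadata, never encoded in the pixels,
so the tracking pipeline cannot cheat.

The camera noise model and bead polarity are unknowns of the real
instrument and are therefore plain configuration options here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from stackpol.datatypes import DissociationDataset, ImageStack


@dataclass(frozen=True)
class MovieParams:
    """Rendering parameters for a synthetic bead movie."""

    width: int = 256
    height: int = 256
    bead_radius: float = 4.0
    bead_contrast: float = 80.0
    background: float = 200.0
    noise_sigma: float = 5.0
    dark_beads: bool = True
    n_clustered: int = 0
    n_debris: int = 0
    min_separation_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bead_radius < 2:
            raise ValueError("bead_radius must be >= 2 px")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


class PlacementError(RuntimeError):
    """Could not place the requested objects without overlap."""


def _place_positions(
    rng: np.random.Generator,
    n: int,
    width: int,
    height: int,
    min_sep: float,
    margin: float,
    existing: list[tuple[float, float]],
    max_tries: int = 20000,
) -> list[tuple[float, float]]:
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n:
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} objects with separation {min_sep:.1f} px "
                f"in a {width}x{height} frame"
            )
        tries += 1
        x = rng.uniform(margin, width - margin)
        y = rng.uniform(margin, height - margin)
        ok = all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2
                 for px, py in placed + existing)
        if ok:
            placed.append((x, y))
    return placed


def _draw_disk(img: np.ndarray, x: float, y: float, radius: float,
               amplitude: float) -> None:
    """Add a soft-edged disk (~1 px edge roll-off) to ``img`` in place."""
    h, w = img.shape
    x0, x1 = max(int(x - radius - 2), 0), min(int(x + radius + 3), w)
    y0, y1 = max(int(y - radius - 2), 0), min(int(y + radius + 3), h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
    cover = np.clip(radius + 0.5 - r, 0.0, 1.0)
    img[y0:y1, x0:x1] += amplitude * cover


def _draw_debris(img: np.ndarray, rng: np.random.Generator, x: float, y: float,
                 radius: float, amplitude: float) -> None:
    """An irregular elongated blob: a short chain of overlapping small disks."""
    n_lobes = rng.integers(3, 6)
    angle = rng.uniform(0, 2 * np.pi)
    for j in range(n_lobes):
        step = (j - (n_lobes - 1) / 2) * radius * 0.9
        jx = x + step * np.cos(angle) + rng.normal(0, 0.5)
        jy = y + step * np.sin(angle) + rng.normal(0, 0.5)
        _draw_disk(img, jx, jy, radius * rng.uniform(0.4, 0.7), amplitude)


def render_bead_movie(
    dataset: DissociationDataset, params: MovieParams
) -> ImageStack:
    """Render a dissociation dataset as a noisy multi-frame movie.

    One frame per save-grid point on ``[time_zero, time_zero + t_end]``.
    The sidecar lists every rendered object (tethers, then cluster members,
    then debris) with its ground-truth event frame (``None`` for objects
    that never disappear).
    """
    if not np.isfinite(dataset.t_end):
        raise ValueError("movie rendering needs a finite t_end")
    if dataset.frame_interval <= 0:
        raise ValueError("movie rendering needs a positive frame_interval")
    rng = np.random.default_rng(params.seed)
    dt = dataset.frame_interval
    n_frames = int(round(dataset.t_end / dt)) + 1
    amp = -params.bead_contrast if params.dark_beads else params.bead_contrast

    r = params.bead_radius
    min_sep = params.min_separation_factor * r
    margin = 2 * r + 2

    n_tethers = dataset.n_total
    tether_pos = _place_positions(rng, n_tethers, params.width, params.height,
                                  min_sep, margin, [])
    cluster_anchor = _place_positions(rng, params.n_clustered, params.width,
                                      params.height, min_sep, margin,
                                      tether_pos)
    debris_pos = _place_positions(rng, params.n_debris, params.width,
                                  params.height, min_sep, margin,
                                  tether_pos + cluster_anchor)

    objects = []
    for (x, y), row in zip(tether_pos, dataset.events.itertuples()):
        event_frame = None
        if not row.censored:
            event_frame = int(round(row.time_s / dt))
        objects.append({"kind": "tether", "x": x, "y": y, "radius": r,
                        "tether_id": int(row.tether_id),
                        "event_frame": event_frame})
    for x, y in cluster_anchor:
        # a touching pair (centers 2 radii apart): an aggregation artifact
        ang = rng.uniform(0, 2 * np.pi)
        dx, dy = r * np.cos(ang), r * np.sin(ang)
        for sx, sy in ((x - dx, y - dy), (x + dx, y + dy)):
            objects.append({"kind": "cluster", "x": sx, "y": sy, "radius": r,
                            "tether_id": None, "event_frame": None})
    for x, y in debris_pos:
        objects.append({"kind": "debris", "x": x, "y": y, "radius": r,
                        "tether_id": None, "event_frame": None})

    frames = np.empty((n_frames, params.height, params.width), dtype=np.float32)
    base = np.full((params.height, params.width), params.background,
                   dtype=np.float64)
    for i in range(n_frames):
        img = base.copy()
        for obj in objects:
            ef = obj["event_frame"]
            if ef is not None and i >= ef:
                continue
            if obj["kind"] == "debris":
                # deterministic per-object shape: re-seed from position
                obj_rng = np.random.default_rng(
                    int(obj["x"] * 1000 + obj["y"]) % (2**31)
                )
                _draw_debris(img, obj_rng, obj["x"], obj["y"], obj["radius"],
                             amp)
            else:
                _draw_disk(img, obj["x"], obj["y"], obj["radius"], amp)
        if params.noise_sigma > 0:
            img += rng.normal(0.0, params.noise_sigma, size=img.shape)
        frames[i] = img.astype(np.float32)

    sidecar = {
        "objects": objects,
        "frame_interval_s": dt,
        "time_zero_s": dataset.time_zero,
        "bead_radius_px": r,
        "n_tethers": n_tethers,
        "n_clustered": params.n_clustered,
        "n_debris": params.n_debris,
    }
    return ImageStack(frames=frames, frame_interval=dt,
                      time_zero=dataset.time_zero, sidecar=sidecar)
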