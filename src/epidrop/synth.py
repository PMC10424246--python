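"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates one raw-data modality of an air–liquid-interface
bioprinting experiment — beating-cilia recordings, tight-junction boundary
images, LIVE/DEAD point fields, dextran time courses, per-cell infection
intensity tables and TEER time courses — and returns its output together
with a :class:`GroundTruth` record of the exact parameters used, so every
analysis operation can be validated by parameter recovery without any real
microscopy data.

All randomness flows through ``numpy.random.default_rng(seed)``:
regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from os import PathLike
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .barrier import DEFAULT_MEMBRANE_AREA_CM2, PermeabilitySeries, TEERRecord

__all__ = [
    "GroundTruth",
    "gen_cilia_stack",
    "gen_junction_image",
    "gen_livedead",
    "gen_dextran_series",
    "gen_infection_table",
    "gen_teer_course",
    "DEFAULT_TEER_TEMPLATE",
]


@dataclass(frozen=True)
class GroundTruth:
    """The parameters a generator actually used, for recovery tests."""

    generator: str
    parameters: dict[str, Any]
    seed: int

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(
            {"generator": self.generator, "parameters": self.parameters,
             "seed": self.seed},
            default=_jsonable, **kwargs,
        )

    def write(self, path: str | PathLike) -> None:
        """Serialize as a JSON sidecar next to the generated dataset."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json(indent=2))
            fh.write("\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def gen_cilia_stack(
    f0: float = 8.0,
    frame_rate: float = 100.0,
    n_frames: int = 1024,
    snr: float = 5.0,
    shape: tuple[int, int] = (32, 32),
    amplitude: float = 10.0,
    baseline: float = 100.0,
    phase_gradient: float = 0.05,
    second_harmonic: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Quasi-sinusoidal beating-cilia image stack.

    Per-pixel intensity is ``baseline + A·sin(2πf0·t + φ(x)) +
    second_harmonic·A·sin(4πf0·t + 2φ(x)) + noise`` where the phase
    φ(x) = ``phase_gradient``·x advances across columns like a metachronal
    wave, the second harmonic captures the asymmetric power/recovery
    stroke, and the Gaussian noise standard deviation is ``amplitude/snr``
    (SNR = oscillation amplitude over noise SD; ``snr=np.inf`` for a clean
    tone). Zero amplitude yields a flat stack on which spectral estimation
    fails cleanly.

    Defaults mirror the recording protocol the analysis targets: 100
    frames/s, 1024 frames (~10 s), beat frequencies in the 6–9 Hz range.
    """
    if not 0 <= f0 < frame_rate / 2.0:
        raise ValueError(f"f0={f0} must lie below Nyquist ({frame_rate / 2} Hz)")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    h, w = shape
    t = np.arange(n_frames) / frame_rate
    phase = phase_gradient * np.arange(w)
    arg = 2.0 * np.pi * f0 * t[:, None, None] + phase[None, None, :]
    stack = (
        baseline
        + amplitude * np.sin(arg)
        + second_harmonic * amplitude * np.sin(2.0 * arg)
    ) * np.ones((1, h, 1))
    if amplitude > 0 and np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        stack = stack + rng.normal(0.0, amplitude / snr, size=stack.shape)
    truth = GroundTruth(
        generator="cilia_stack",
        parameters={
            "f0": f0, "frame_rate": frame_rate, "n_frames": n_frames,
            "snr": snr, "shape": list(shape), "amplitude": amplitude,
            "baseline": baseline, "phase_gradient": phase_gradient,
            "second_harmonic": second_harmonic,
        },
        seed=seed,
    )
    return stack, truth


def _hex_lattice(shape: tuple[int, int], spacing_px: float) -> np.ndarray:
    """Hexagonal lattice of points covering ``shape`` with the given
    nearest-neighbour spacing, extended one ring beyond the border so that
    edge pixels have proper Voronoi neighbours."""
    h, w = shape
    dy = spacing_px * np.sqrt(3.0) / 2.0
    points = []
    row = 0
    y = -dy
    while y <= h + dy:
        offset = 0.5 * spacing_px if row % 2 else 0.0
        x = -spacing_px + offset
        while x <= w + spacing_px:
            points.append((y, x))
            x += spacing_px
        y += dy
        row += 1
    return np.asarray(points, dtype=float)


def _lloyd_relax(
    centers: np.ndarray, shape: tuple[int, int], iterations: int,
    grid_step: int = 2,
) -> np.ndarray:
    """Move each center to the centroid of its Voronoi cell (Lloyd step),
    evaluated on a subsampled pixel grid extended past the border."""
    h, w = shape
    pad = grid_step * 16
    rows, cols = np.mgrid[-pad : h + pad : grid_step, -pad : w + pad : grid_step]
    pixels = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    for _ in range(iterations):
        _, idx = cKDTree(centers).query(pixels)
        relaxed = centers.copy()
        for k in range(len(centers)):
            cell = pixels[idx == k]
            if len(cell):
                relaxed[k] = cell.mean(axis=0)
        centers = relaxed
    return centers


def gen_junction_image(
    mean_cell_diameter: float = 25.0,
    jitter: float = 0.2,
    um_per_pixel: float = 0.5,
    boundary_width: float = 1.0,
    snr: float = 10.0,
    shape: tuple[int, int] = (512, 512),
    relaxation_iters: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Polygonal cell-boundary fluorescence field (ZO-1-like).

    Cell centers sit on a hexagonal lattice with nearest-neighbour spacing
    ``mean_cell_diameter`` (µm), perturbed by isotropic Gaussian jitter of
    SD ``jitter × diameter`` and then relaxed by ``relaxation_iters`` Lloyd
    steps toward a centroidal Voronoi tessellation — the standard geometric
    model of epithelial cell packing, which keeps cell sizes uniform the
    way confluent junctional networks are. The lattice pins the mean center
    spacing to the requested diameter, with the regular-hexagon limit
    (itself centroidal) at zero jitter. Boundaries of the induced Voronoi
    tessellation are rendered as Gaussian ridges of width ``boundary_width``
    (µm) and unit amplitude; Gaussian noise of SD ``1/snr`` is added.
    ``boundary_width=0`` produces a blank (peak-free) field.
    """
    if mean_cell_diameter <= 0 or um_per_pixel <= 0:
        raise ValueError("mean_cell_diameter and um_per_pixel must be positive")
    if jitter < 0 or boundary_width < 0:
        raise ValueError("jitter and boundary_width must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    spacing_px = mean_cell_diameter / um_per_pixel
    centers = _hex_lattice((h, w), spacing_px)
    if jitter > 0:
        centers = centers + rng.normal(0.0, jitter * spacing_px, size=centers.shape)
        if relaxation_iters > 0:
            centers = _lloyd_relax(centers, (h, w), relaxation_iters)

    if boundary_width == 0:
        image = np.zeros((h, w), dtype=float)
    else:
        rows, cols = np.mgrid[0:h, 0:w]
        pixels = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
        dist, _ = cKDTree(centers).query(pixels, k=2)
        # Ridge height peaks where the two nearest centers are equidistant,
        # i.e. on Voronoi boundaries.
        margin = dist[:, 1] - dist[:, 0]
        sigma_px = boundary_width / um_per_pixel
        image = np.exp(-0.5 * (margin / sigma_px) ** 2).reshape(h, w)
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        image = image + rng.normal(0.0, 1.0 / snr, size=image.shape)

    truth = GroundTruth(
        generator="junction_image",
        parameters={
            "mean_cell_diameter": mean_cell_diameter, "jitter": jitter,
            "um_per_pixel": um_per_pixel, "boundary_width": boundary_width,
            "snr": snr, "shape": list(shape),
            "relaxation_iters": relaxation_iters, "n_centers": len(centers),
        },
        seed=seed,
    )
    return image, truth


def _scatter_spots(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_separation: float,
) -> np.ndarray:
    """Dart-throwing placement of ``n`` points with a minimum pairwise
    distance, keeping a half-separation margin from the border."""
    h, w = shape
    margin = min_separation / 2.0
    accepted: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while len(accepted) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} spots with separation "
                f"{min_separation} in a {h}×{w} field"
            )
        attempts += 1
        cand = (
            rng.uniform(margin, h - 1 - margin),
            rng.uniform(margin, w - 1 - margin),
        )
        if all(
            (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_separation**2
            for p in accepted
        ):
            accepted.append(cand)
    return np.asarray(accepted, dtype=float)


def _render_spots(
    points: np.ndarray, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    """Unit-amplitude Gaussian spots at the given (row, col) positions."""
    image = np.zeros(shape, dtype=float)
    if len(points):
        idx = np.round(points).astype(int)
        np.add.at(image, (idx[:, 0], idx[:, 1]), 1.0)
        image = ndimage.gaussian_filter(image, sigma) * (2.0 * np.pi * sigma**2)
    return image


def gen_livedead(
    n_cells: int = 500,
    viability_pct: float = 93.0,
    field_size: tuple[int, int] = (512, 512),
    spot_sigma: float = 2.0,
    min_separation: float = 10.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two-channel LIVE/DEAD point field.

    ``round(n_cells · viability_pct/100)`` cells are rendered as unit
    Gaussian spots in the live (calcein) channel, the remainder in the dead
    (ethidium) channel, at non-overlapping positions. Returns
    ``(live_image, dead_image, truth)``; the true live/dead counts are in
    the ground-truth parameters.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not 0.0 <= viability_pct <= 100.0:
        raise ValueError("viability_pct must be in [0, 100]")
    rng = np.random.default_rng(seed)
    n_live = int(round(n_cells * viability_pct / 100.0))
    n_dead = n_cells - n_live
    points = (
        _scatter_spots(rng, n_cells, field_size, min_separation)
        if n_cells
        else np.empty((0, 2))
    )
    order = rng.permutation(n_cells)
    live_pts, dead_pts = points[order[:n_live]], points[order[n_live:]]
    live = _render_spots(live_pts, field_size, spot_sigma)
    dead = _render_spots(dead_pts, field_size, spot_sigma)
    if noise_sd > 0:
        live = live + rng.normal(0.0, noise_sd, size=live.shape)
        dead = dead + rng.normal(0.0, noise_sd, size=dead.shape)
    truth = GroundTruth(
        generator="livedead",
        parameters={
            "n_cells": n_cells, "viability_pct": viability_pct,
            "n_live": n_live, "n_dead": n_dead,
            "field_size": list(field_size), "spot_sigma": spot_sigma,
            "min_separation": min_separation, "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return live, dead, truth


def gen_dextran_series(
    slope: float = 0.42,
    noise_sd: float = 0.02,
    n_timepoints: int = 4,
    dt_hours: float = 1.0,
    apical_concentration: float = 10.0,
    apical_volume_ml: float | None = 0.25,
    condition: str = "synthetic",
    seed: int = 0,
) -> tuple[PermeabilitySeries, GroundTruth]:
    """Monotone basal dextran accumulation, sampled hourly over 3 h by
    default (4 points at 0–3 h): ``amount(t) = slope·t + noise``."""
    if n_timepoints < 3:
        raise ValueError("need >= 3 time points")
    rng = np.random.default_rng(seed)
    times = np.arange(n_timepoints) * dt_hours
    amounts = slope * times + rng.normal(0.0, noise_sd, size=times.shape)
    series = PermeabilitySeries(
        times=times,
        basal_amounts=amounts,
        apical_concentration=apical_concentration,
        apical_volume_ml=apical_volume_ml,
        condition=condition,
    )
    truth = GroundTruth(
        generator="dextran_series",
        parameters={
            "slope": slope, "noise_sd": noise_sd,
            "n_timepoints": n_timepoints, "dt_hours": dt_hours,
            "apical_concentration": apical_concentration,
            "apical_volume_ml": apical_volume_ml, "condition": condition,
        },
        seed=seed,
    )
    return series, truth


def gen_infection_table(
    n_cells: int = 2000,
    infected_fraction: float = 0.106,
    dapi_log10: tuple[float, float] = (3.0, 0.15),
    gfp_neg_log10: tuple[float, float] = (1.0, 0.2),
    gfp_pos_log10: tuple[float, float] = (2.5, 0.25),
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell DAPI × GFP intensity table with a known infected fraction.

    All events are nuclei, so DAPI is a single log-normal; GFP is a
    two-component log-normal mixture (uninfected autofluorescence vs. viral
    reporter expression) — intensities are positive and right-skewed, which
    the log-normal captures. Exactly ``round(n_cells·infected_fraction)``
    cells are infected, so the design fraction is recovered up to gating
    error rather than binomial sampling noise.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= infected_fraction <= 1.0:
        raise ValueError("infected_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_inf = int(round(n_cells * infected_fraction))
    infected = np.zeros(n_cells, dtype=bool)
    infected[rng.permutation(n_cells)[:n_inf]] = True
    dapi = 10.0 ** rng.normal(dapi_log10[0], dapi_log10[1], size=n_cells)
    gfp = np.where(
        infected,
        10.0 ** rng.normal(gfp_pos_log10[0], gfp_pos_log10[1], size=n_cells),
        10.0 ** rng.normal(gfp_neg_log10[0], gfp_neg_log10[1], size=n_cells),
    )
    table = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "dapi_mean": dapi,
            "gfp_mean": gfp,
            "infected_truth": infected,
        }
    )
    truth = GroundTruth(
        generator="infection_table",
        parameters={
            "n_cells": n_cells, "infected_fraction": infected_fraction,
            "n_infected": n_inf, "dapi_log10": list(dapi_log10),
            "gfp_neg_log10": list(gfp_neg_log10),
            "gfp_pos_log10": list(gfp_pos_log10),
        },
        seed=seed,
    )
    return table, truth


#: Ω·cm² template of a differentiating culture: barrier resistance peaks
#: about a week into air-lift (~1000 Ω·cm²) and relaxes to ~250 Ω·cm² by
#: day 28 as the epithelium matures and sheds.
DEFAULT_TEER_TEMPLATE: dict[int, float] = {0: 500.0, 7: 1000.0, 14: 650.0,
                                           21: 400.0, 28: 255.0}


def gen_teer_course(
    template: dict[int, float] | None = None,
    replicate_sd: float = 30.0,
    n_reps: int = 3,
    blank_resistance: float = 120.0,
    membrane_area: float = DEFAULT_MEMBRANE_AREA_CM2,
    condition: str = "synthetic",
    seed: int = 0,
) -> tuple[list[TEERRecord], GroundTruth]:
    """Replicate TEER records following a rise-then-decline template.

    ``template`` maps ALI day to true Ω·cm²; each replicate reading adds
    Gaussian noise of SD ``replicate_sd`` (Ω·cm²) before being converted
    back to a raw chopstick reading (blank + value/area), so the analysis
    path exercises blank subtraction and area normalization.
    """
    if template is None:
        template = DEFAULT_TEER_TEMPLATE
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for day in sorted(template):
        true_value = template[day]
        for _ in range(n_reps):
            measured = true_value + rng.normal(0.0, replicate_sd)
            raw = max(0.0, blank_resistance + measured / membrane_area)
            records.append(
                TEERRecord(
                    raw_resistance=raw,
                    blank_resistance=blank_resistance,
                    membrane_area=membrane_area,
                    day=day,
                    condition=condition,
                )
            )
    truth = GroundTruth(
        generator="teer_course",
        parameters={
            "template": {str(k): v for k, v in template.items()},
            "replicate_sd": replicate_sd, "n_reps": n_reps,
            "blank_resistance": blank_resistance,
            "membrane_area": membrane_area, "condition": condition,
        },
        seed=seed,
    )
    return records, truth
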