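"""Synthetic Visium-like slides with known ground truth.

Generates hexagonal (Visium-style packing) or square spot lattices, plants
linear gradient fields of known direction, slope and noise inside disk
regions of chosen programs' loading maps, simulates factor-model counts
(Poisson sampling of a low-rank spots-by-genes rate matrix with
block-structured gene loadings), and plants a disk-shaped tumor region.
Every generator is a pure function of its parameters and seed, and the
planted truth serializes to JSON so recovery tests never re-derive it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .io import SpatialDataset

__all__ = [
    "PlantedGradient",
    "PlantedTruth",
    "simulate_layout",
    "plant_gradients",
    "opposed_pair",
    "simulate_counts",
    "plant_tumor_region",
    "sigma_for_window_r2",
    "make_default_slide",
]


@dataclass
class PlantedGradient:
    """One planted linear gradient: a planar loading field inside a disk.

    Inside the region the program's loading is
    ``max(0, a + s * ((x - cx) cos(theta) + (y - cy) sin(theta)) + eps)``
    with eps ~ Normal(0, sigma); outside, only baseline noise.
    """

    program: int
    center: tuple
    radius: float
    theta: float          # direction of increasing loading, radians
    slope: float
    intercept: float = 1.0
    sigma: float = 0.0


@dataclass
class PlantedTruth:
    """Everything a recovery test needs to score a synthetic slide.

    ``baseline_mean`` sets the flat activity every program carries outside
    its planted region.  It matters for count simulation: spots are
    mixtures, so a gradient is observable in the expression composition
    only against a non-trivial background of other programs' reads.
    """

    gradients: list
    n_programs: int
    baseline_sigma: float
    baseline_mean: float = 0.5
    tumor_center: Optional[tuple] = None
    tumor_radius: Optional[float] = None
    seed: int = 0

    def to_json(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        d["gradients"] = [PlantedGradient(**{**g, "center": tuple(g["center"])})
                          for g in d["gradients"]]
        if d.get("tumor_center") is not None:
            d["tumor_center"] = tuple(d["tumor_center"])
        return cls(**d)

    def in_region(self, coords: np.ndarray, g: PlantedGradient) -> np.ndarray:
        return np.linalg.norm(coords - np.asarray(g.center), axis=1) <= g.radius


def simulate_layout(n_spots: int, layout: str = "hex", pitch: float = 1.0,
                    seed: int = 0, jitter: float = 0.0) -> np.ndarray:
    """A compact patch of ``n_spots`` lattice points.

    ``hex`` mimics Visium spot packing (nearest-neighbor distance = pitch
    everywhere); ``square`` is a row-major square lattice.  Optional
    Gaussian jitter (sd = jitter * pitch) perturbs positions.
    """
    if n_spots < 25:
        raise ValueError("n_spots must be >= 25")
    if layout == "square":
        side = math.ceil(math.sqrt(n_spots))
        ij = [(i, j) for i in range(side) for j in range(side)][:n_spots]
        coords = np.array([(j * pitch, i * pitch) for i, j in ij], dtype=float)
    elif layout == "hex":
        # generous candidate patch, then the n nearest to a central lattice spot
        half = math.ceil(math.sqrt(n_spots)) + 2
        pts = []
        for i in range(-half, half + 1):
            for j in range(-half, half + 1):
                x = j * pitch + (i % 2) * pitch / 2.0
                y = i * pitch * math.sqrt(3) / 2.0
                pts.append((x, y))
        pts = np.array(pts, dtype=float)
        center = pts[np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1))]
        d = np.linalg.norm(pts - center, axis=1)
        order = np.lexsort((pts[:, 0], pts[:, 1], np.round(d, 9)))
        coords = pts[order[:n_spots]]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter * pitch, size=coords.shape)
    return coords


def plant_gradients(coords: np.ndarray, truth: PlantedTruth) -> np.ndarray:
    """Build the N x k planted spot-loading matrix from a truth spec.

    Outside planted regions every program sits at a flat baseline,
    ``max(0, baseline_mean + Normal(0, baseline_sigma))`` — spatially
    structureless activity that planted fields overwrite inside their
    regions.
    """
    coords = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(truth.seed)
    N = coords.shape[0]
    W = np.maximum(
        0.0,
        truth.baseline_mean
        + rng.normal(0.0, truth.baseline_sigma, size=(N, truth.n_programs)),
    )
    for g in truth.gradients:
        if not (0 <= g.program < truth.n_programs):
            raise ValueError(f"planted program {g.program} out of range")
        inside = truth.in_region(coords, g)
        rel = coords[inside] - np.asarray(g.center)
        proj = rel[:, 0] * math.cos(g.theta) + rel[:, 1] * math.sin(g.theta)
        noise = rng.normal(0.0, g.sigma, size=int(inside.sum())) if g.sigma > 0 else 0.0
        W[inside, g.program] = np.maximum(0.0, g.intercept + g.slope * proj + noise)
    return W


def opposed_pair(center, radius, theta, slope, programs=(0, 1),
                 intercept: float = 1.0, sigma: float = 0.0) -> list:
    """Two gradients sharing one region, pointing in opposite directions —
    the 'proximal yet opposite directed' scenario."""
    a, b = programs
    return [
        PlantedGradient(program=a, center=tuple(center), radius=radius,
                        theta=theta, slope=slope, intercept=intercept, sigma=sigma),
        PlantedGradient(program=b, center=tuple(center), radius=radius,
                        theta=theta + math.pi, slope=slope, intercept=intercept,
                        sigma=sigma),
    ]


def sigma_for_window_r2(slope: float, target_r2: float, Q: int = 25,
                        pitch: float = 1.0) -> float:
    """Noise sd that makes an in-window fit of a planted plane hit ~target R2.

    A Q-spot window on a hex lattice of the given pitch covers a disk of
    area Q * pitch^2 * sqrt(3)/2; the variance of the planar signal's
    projection over that disk is slope^2 * r^2 / 4.  Solving
    R2 = var_signal / (var_signal + sigma^2) for sigma.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    r2_disk = Q * pitch ** 2 * math.sqrt(3) / 2.0 / math.pi
    var_signal = slope ** 2 * r2_disk / 4.0
    return math.sqrt(var_signal * (1.0 - target_r2) / target_r2)


def simulate_counts(W_true: np.ndarray, G: int, seed: int = 0,
                    sparsity: float = 0.0, depth: float = 2000.0):
    """Poisson counts from a planted factor model.

    Gene loadings ``H_true`` get disjoint-leaning supports: genes are split
    evenly across programs, each gene loading mainly on its own program
    (uniform in [0.5, 1]) with cross-program leakage on a ``sparsity``
    fraction of entries (uniform in [0, 0.1]).  Counts are Poisson draws
    of ``c * W_true @ H_true`` with the single global constant ``c`` chosen
    so the mean spot depth equals ``depth``; the expected count matrix is
    therefore exactly rank k, and per-spot depth varies with total program
    activity as it does on a real slide.

    Returns ``(counts_csr, H_true)``.
    """
    W_true = np.asarray(W_true, dtype=float)
    if (W_true < 0).any():
        raise ValueError("W_true must be non-negative")
    rng = np.random.default_rng(seed)
    k = W_true.shape[1]
    H = np.zeros((k, G))
    owner = np.arange(G) % k
    H[owner, np.arange(G)] = rng.uniform(0.5, 1.0, size=G)
    if sparsity > 0:
        leak = rng.random((k, G)) < sparsity
        leak[owner, np.arange(G)] = False
        H[leak] = rng.uniform(0.0, 0.1, size=int(leak.sum()))
    rates = W_true @ H
    mean_total = rates.sum(axis=1).mean()
    if mean_total == 0:
        raise ValueError("planted loadings are identically zero")
    counts = rng.poisson(depth / mean_total * rates)
    return sp.csr_matrix(counts), H


def plant_tumor_region(coords: np.ndarray, center, radius: float) -> np.ndarray:
    """Boolean tumor flag: spots inside the disk."""
    coords = np.asarray(coords, dtype=float)
    return np.linalg.norm(coords - np.asarray(center, dtype=float), axis=1) <= radius


def make_default_slide(seed: int = 0, n_spots: int = 2000, n_programs: int = 5,
                       target_r2: float = 0.8, G: int = 200,
                       depth: float = 4000.0, with_counts: bool = True):
    """The reference synthetic slide used across tests and examples.

    A hex lattice of ~2000 spots with three planted gradient disks
    (programs 0-2, distinct directions, slope 0.3, noise calibrated to an
    in-window R2 of ~0.8), two pure-noise programs, and a tumor disk over
    the first gradient region.  Returns
    ``(dataset, truth, W_true, H_true)``; with ``with_counts=False`` the
    counts matrix is a placeholder of zeros and H_true is None (loadings-
    only studies).
    """
    coords = simulate_layout(n_spots, layout="hex", pitch=1.0, seed=seed)
    span = coords.max(axis=0) - coords.min(axis=0)
    lo = coords.min(axis=0)
    slope = 0.15
    sigma = sigma_for_window_r2(slope, target_r2)
    centers = [
        tuple(lo + span * (0.30, 0.30)),
        tuple(lo + span * (0.70, 0.35)),
        tuple(lo + span * (0.45, 0.72)),
    ]
    radius = 0.16 * float(min(span))
    # keep the planar field positive across the region so clipping at zero
    # does not bend it
    intercept = slope * radius + 0.1
    gradients = [
        PlantedGradient(program=i, center=centers[i], radius=radius,
                        theta=math.radians(ang), slope=slope,
                        intercept=intercept, sigma=sigma)
        for i, ang in enumerate((30.0, 150.0, 280.0))
    ]
    truth = PlantedTruth(
        gradients=gradients, n_programs=n_programs, baseline_sigma=0.05,
        baseline_mean=0.5,
        tumor_center=centers[0], tumor_radius=radius * 1.2, seed=seed,
    )
    W_true = plant_gradients(coords, truth)
    tumor = plant_tumor_region(coords, truth.tumor_center, truth.tumor_radius)
    if with_counts:
        counts, H_true = simulate_counts(W_true, G=G, seed=seed, depth=depth)
    else:
        counts, H_true = sp.csr_matrix((coords.shape[0], G), dtype=float), None
    dataset = SpatialDataset(
        spot_ids=[f"spot_{i:05d}" for i in range(coords.shape[0])],
        coords=coords,
        counts=counts,
        gene_ids=[f"g{j:04d}" for j in range(G)],
        tumor_flag=tumor,
    )
    return dataset, truth, W_true, H_true
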