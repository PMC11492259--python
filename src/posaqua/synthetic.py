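"""Deterministic fixture generators: liquid boxes and toy quantum systems.

Every generator is a pure function of its spec + seed, so fixtures are
reproducible bit-for-bit and nothing needs to be downloaded or stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import AVOGADRO
from .forcefield import embedded_parameters
from .liquid import LiquidConfiguration, minimum_image

__all__ = ["FixtureSpec", "make_lattice_box", "make_toy_quantum"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic liquid-box fixture."""
    name: str = "water-box"
    seed: int = 0
    n_waters: int = 125
    box_edge: float | None = None       # Å; None -> 0.997 g/cm^3 by mass
    jitter: float = 0.25                # Å, lattice displacement scale
    solute: str | None = None           # molecule name or None

    def __post_init__(self):
        if self.n_waters < 0:
            raise ValueError("n_waters must be >= 0")


MIN_OO_DISTANCE = 2.4  # Å, overlap guard for generated boxes


def make_lattice_box(spec: FixtureSpec) -> LiquidConfiguration:
    """Waters on a jittered cubic lattice at the target density, random
    orientations; the solute (if any) sits at the box center with lattice
    cells cleared around it.  Same spec + seed => bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    water = embedded_parameters("water")
    solute = embedded_parameters(spec.solute) if spec.solute else None

    mass = spec.n_waters * water.mass + (solute.mass if solute else 0.0)
    if spec.box_edge is not None:
        edge = float(spec.box_edge)
    elif spec.n_waters == 0:
        edge = 20.0
    else:
        target = 0.997  # g/cm^3
        edge = (mass / (target * AVOGADRO * 1e-24)) ** (1.0 / 3.0)

    center = np.full(3, edge / 2.0)
    solute_coords = None
    blocked_r = 0.0
    if solute is not None:
        solute_coords = solute.coords + center
        blocked_r = np.linalg.norm(solute.coords, axis=1).max() + 1.6

    # lattice sites, skipping a clearance sphere around the solute; if the
    # box cannot host the lattice with safe spacing, expand it a little
    # (the NpT stage re-equilibrates the volume anyway)
    min_cell = MIN_OO_DISTANCE + 0.15
    sites = None
    cell = edge
    for _ in range(40):
        m = max(1, int(edge / min_cell))
        cell = edge / m
        ii = (np.arange(m) + 0.5) * cell
        cand = np.array(np.meshgrid(ii, ii, ii)).reshape(3, -1).T
        if solute is not None:
            keep = np.linalg.norm(cand - center, axis=1) > blocked_r
            cand = cand[keep]
        if len(cand) >= spec.n_waters:
            sites = cand
            break
        if spec.box_edge is not None:
            break        # user-pinned box: do not silently expand
        edge *= 1.05
        center = np.full(3, edge / 2.0)
        if solute is not None:
            solute_coords = solute.coords + center
    if sites is None:
        raise ValueError("density implies overlaps that jitter cannot "
                         "resolve within the requested box")

    order = rng.permutation(len(sites))[:spec.n_waters]
    origins = sites[order]
    if spec.n_waters and spec.jitter > 0:
        max_jitter = max(0.0, (cell - MIN_OO_DISTANCE) / 2.0)
        amp = min(spec.jitter, max_jitter)
        origins = origins + rng.uniform(-amp, amp, size=origins.shape)

    rots = Rotation.random(max(spec.n_waters, 1), random_state=rng)
    water_coords = np.empty((spec.n_waters, len(water.sites), 3))
    for i in range(spec.n_waters):
        water_coords[i] = water.coords @ rots[i].as_matrix().T + origins[i]

    config = LiquidConfiguration(
        solute=solute, solute_coords=solute_coords,
        water=water, water_coords=water_coords, box_edge=edge,
        meta={"fixture": spec.name, "seed": spec.seed})

    if spec.n_waters > 1:
        oo = _min_oo_distance(config)
        if oo < MIN_OO_DISTANCE:
            raise ValueError(
                f"requested density leaves O–O contacts at {oo:.2f} Å that "
                f"jitter cannot resolve (need >= {MIN_OO_DISTANCE} Å)")
    return config


def _min_oo_distance(config: LiquidConfiguration) -> float:
    o = config.water_coords[:, 0, :]
    d = o[:, None, :] - o[None, :, :]
    d = minimum_image(d, config.box_edge)
    r = np.sqrt((d ** 2).sum(axis=-1))
    np.fill_diagonal(r, np.inf)
    return float(r.min())


def make_toy_quantum(name: str):
    """Small quantum fixtures with known properties (see qc registry)."""
    from .qc.fixtures import toy_quantum_registry
    registry = toy_quantum_registry()
    if name not in registry:
        raise KeyError(f"unknown toy system {name!r}; known: {sorted(registry)}")
    return registry[name]()
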