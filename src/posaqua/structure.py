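"""Solvation-shell statistics over configuration ensembles.

The central statistic is the minimum-distance distribution function
(MDDF): for every solvent molecule, the minimum over all solute-atom /
solvent-atom distances, histogrammed over the ensemble and normalized by
the same statistic for an ideal gas of solvent molecules at the same
density in the same box, so that the bulk plateau is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial.transform import Rotation

from .constants import KCAL_TO_KJ
from .liquid import LiquidConfiguration, RigidMolecule, minimum_image
from .mc import pair_energy

__all__ = ["MDDFResult", "min_distances", "mddf", "shell_population",
           "hbond_count", "HBondCriterion"]


@dataclass
class MDDFResult:
    r: np.ndarray              # bin centers, Å
    g: np.ndarray              # normalized MDDF
    g_raw: np.ndarray          # before smoothing (same normalization)
    cumulative: np.ndarray     # ensemble-average N(<r)
    first_peak: float | None
    first_minimum: float | None
    bulk_onset: float | None
    cavity_onset: float | None
    n_configurations: int


def min_distances(config: LiquidConfiguration) -> np.ndarray:
    """Per-water minimum solute-site/water-site distance (Å), min image."""
    if config.solute is None:
        raise ValueError("configuration has no solute")
    sol = config.solute_coords                     # (ns, 3)
    wat = config.water_coords                      # (nw, nws, 3)
    d = wat[:, :, None, :] - sol[None, None, :, :]
    d = minimum_image(d, config.box_edge)
    r = np.sqrt((d ** 2).sum(axis=-1))             # (nw, nws, ns)
    return r.reshape(r.shape[0], -1).min(axis=1)


def _ideal_histogram(config: LiquidConfiguration, edges, n_insert, rng):
    """Minimum-distance histogram for uniformly random solvent molecules
    (random position + orientation) at the same box size: the ideal-gas
    reference that self-normalizes the MDDF."""
    sol = config.solute_coords
    water = config.water
    origins = rng.uniform(0.0, config.box_edge, size=(n_insert, 3))
    rots = Rotation.random(n_insert, random_state=rng).as_matrix()
    sites = np.einsum("sj,nij->nsi", water.coords, rots) + origins[:, None, :]
    d = sites[:, :, None, :] - sol[None, None, :, :]
    d = minimum_image(d, config.box_edge)
    r = np.sqrt((d ** 2).sum(axis=-1)).reshape(n_insert, -1).min(axis=1)
    h, _ = np.histogram(r, bins=edges)
    return h


def mddf(ensemble: list[LiquidConfiguration], bin_width: float = 0.05,
         r_max: float | None = None, n_insert: int = 20000,
         seed: int = 0, smooth_window: int = 11) -> MDDFResult:
    """Compute the solute–solvent MDDF over an ensemble of configurations.

    Normalization uses an ideal-gas Monte-Carlo reference (``n_insert``
    random rigid-water insertions per configuration).  Shell landmarks are
    located on a Savitzky–Golay-smoothed curve; the raw curve is kept.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if r_max is None:
        r_max = min(c.box_edge for c in ensemble) / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    rng = np.random.default_rng(seed)
    h_real = np.zeros(len(centers))
    h_ref = np.zeros(len(centers))
    n_w = 0
    for config in ensemble:
        rmin = min_distances(config)
        h, _ = np.histogram(rmin, bins=edges)
        h_real += h
        n_w += config.n_waters
        h_ref += _ideal_histogram(config, edges, n_insert, rng)

    n_cfg = len(ensemble)
    mean_nw = n_w / n_cfg
    # per-configuration real counts vs reference counts, scaled to the same
    # number of "solvent molecules"
    with np.errstate(divide="ignore", invalid="ignore"):
        g_raw = np.where(h_ref > 0,
                         (h_real / n_cfg) / (h_ref / n_cfg / n_insert * mean_nw),
                         0.0)
    cumulative = np.cumsum(h_real) / n_cfg

    window = min(smooth_window, 2 * (len(centers) // 2) - 1)
    if window >= 5:
        g_smooth = savgol_filter(g_raw, window, 3)
        g_smooth = np.clip(g_smooth, 0.0, None)
    else:
        g_smooth = g_raw.copy()

    first_peak, first_min = _first_extrema(centers, g_smooth)
    bulk = _bulk_onset(centers, g_smooth)
    cavity = _cavity_onset(centers, g_raw)
    return MDDFResult(r=centers, g=g_smooth, g_raw=g_raw,
                      cumulative=cumulative, first_peak=first_peak,
                      first_minimum=first_min, bulk_onset=bulk,
                      cavity_onset=cavity, n_configurations=n_cfg)


def _first_extrema(r, g):
    """First local maximum with g>0.5, and the first-shell boundary: the
    minimum of the smoothed curve between that peak and the point where
    G recovers to the bulk level (robust for flat, deep valleys)."""
    peak = None
    for i in range(1, len(g) - 1):
        if g[i] > 0.5 and g[i] >= g[i - 1] and g[i] > g[i + 1]:
            peak = i
            break
    if peak is None:
        return None, None
    below = None
    for i in range(peak + 1, len(g)):
        if g[i] < 1.0:
            below = i
            break
    if below is None:
        return float(r[peak]), None
    limit = len(g)
    for i in range(below, len(g)):
        if g[i] >= 1.0:
            limit = i
            break
    if limit <= peak + 1:
        return float(r[peak]), None
    m = peak + 1 + int(np.argmin(g[peak + 1:limit]))
    if m >= len(g) - 1:
        return float(r[peak]), None
    # flat valleys: use the center of the near-minimal region rather than
    # the (tie-broken) argmin, which is stable under re-binning
    thr = g[m] + 0.05 * max(g[peak] - g[m], 1e-12)
    lo = m
    while lo > peak + 1 and g[lo - 1] <= thr:
        lo -= 1
    hi = m
    while hi < limit - 1 and g[hi + 1] <= thr:
        hi += 1
    return float(r[peak]), float(0.5 * (r[lo] + r[hi]))


def _bulk_onset(r, g, tol=0.1, run=10):
    """Smallest r beyond which |G-1| stays below tol for ``run`` bins."""
    ok = np.abs(g - 1.0) < tol
    for i in range(len(g) - run):
        if ok[i:i + run].all():
            return float(r[i])
    return None


def _cavity_onset(r, g_raw, threshold=0.01):
    """r where G first exceeds ``threshold``: the solute cavity radius."""
    idx = np.nonzero(g_raw > threshold)[0]
    return float(r[idx[0]]) if idx.size else None


def shell_population(result: MDDFResult, r_limit: float) -> float:
    """Ensemble-average number of solvent molecules with minimum distance
    below ``r_limit`` (linear interpolation inside the containing bin)."""
    r = result.r
    if not (r[0] - 1e-9 <= r_limit <= r[-1] + 1e-9):
        raise ValueError(f"r_limit {r_limit} outside MDDF grid "
                         f"[{r[0]:.2f}, {r[-1]:.2f}]")
    return float(np.interp(r_limit, r, result.cumulative))


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric (+ optional energetic) solute–water hydrogen-bond rule.

    distance: donor–acceptor heavy-atom separation limit (Å);
    angle: H–donor–acceptor angular deviation limit (degrees);
    energy: pair-interaction threshold (kcal/mol) applied when not None.
    """
    distance: float = 3.5
    angle: float = 30.0
    energy: float | None = -2.0


def hbond_count(config: LiquidConfiguration,
                criterion: HBondCriterion = HBondCriterion()):
    """Count solute<->water hydrogen bonds in one configuration.

    Returns (count, labels); labels are (role, solute_atom, water_index)
    with role "solute_donor" or "water_donor".
    """
    if config.solute is None:
        return 0, []
    solute = config.solute
    if not solute.hbond_donors and not solute.hbond_acceptors:
        raise ValueError("solute has no donor/acceptor annotations")
    water = config.water
    box = config.box_edge
    sol = config.solute_coords
    labels = []

    sol_mol = RigidMolecule(solute, sol)
    cosmax = math.cos(math.radians(criterion.angle))
    anchor = sol[solute.carboxylate_carbon
                 if solute.carboxylate_carbon is not None else 0]
    for iw in range(config.n_waters):
        wc = config.water_coords[iw]
        # image-shift the whole water molecule next to the solute
        d = wc[0] - anchor
        wc = wc + (minimum_image(d, box) - d)
        bonds_here = []
        # water as donor: O(w)-H(w) ... acceptor(solute)
        for acc in solute.hbond_acceptors:
            d_oa = np.linalg.norm(wc[0] - sol[acc])
            if d_oa > criterion.distance:
                continue
            for _, h in water.hbond_donors:
                v_oh = wc[h] - wc[0]
                v_oa = sol[acc] - wc[0]
                cosang = np.dot(v_oh, v_oa) / (
                    np.linalg.norm(v_oh) * np.linalg.norm(v_oa))
                if cosang >= cosmax:
                    bonds_here.append(("water_donor", acc, iw))
                    break
        # solute as donor: N-H ... O(water)
        for heavy, h in solute.hbond_donors:
            d_no = np.linalg.norm(sol[heavy] - wc[0])
            if d_no > criterion.distance:
                continue
            v_nh = sol[h] - sol[heavy]
            v_no = wc[0] - sol[heavy]
            cosang = np.dot(v_nh, v_no) / (
                np.linalg.norm(v_nh) * np.linalg.norm(v_no))
            if cosang >= cosmax:
                bonds_here.append(("solute_donor", heavy, iw))
        if bonds_here and criterion.energy is not None:
            wat_mol = RigidMolecule(water, config.water_coords[iw])
            e = pair_energy(sol_mol, wat_mol, box_edge=box)
            if e > criterion.energy * KCAL_TO_KJ:
                bonds_here = []
        labels.extend(bonds_here)
    return len(labels), labels
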