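"""Metropolis Monte-Carlo sampling of rigid solute + rigid waters (NpT).

The sampler follows standard isothermal–isobaric practice for rigid
molecules: single-molecule translation+rotation trial moves accepted on
exp(-beta dU), and volume moves accepted on
exp(-beta (dU + p dV) + M ln(V'/V)).  Electrostatics and LJ interactions
are truncated molecule-wise at a spherical cutoff on reference-site
distances (no Ewald), with the standard LJ long-range (tail) correction.
Step sizes are auto-tuned toward ~40% acceptance during equilibration and
frozen for production.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import ATM_TO_KJMOL_A3, KB_KJMOL
from .liquid import LiquidConfiguration, RigidMolecule

__all__ = ["MCParams", "TrajectorySample", "Trajectory", "pair_energy",
           "run_npt", "energy_autocorrelation", "select_uncorrelated"]

log = logging.getLogger(__name__)


@dataclass
class MCParams:
    """Monte-Carlo run parameters (defaults: water at ambient conditions)."""
    temperature: float = 298.15       # K
    pressure: float = 1.0             # atm
    n_steps: int = 1_000_000          # production steps (1 step = 1 trial move)
    n_equilibration: int = 200_000
    max_translation: float = 0.25     # Å, tuned during equilibration
    max_rotation: float = 0.35        # rad
    volume_amplitude: float = 80.0    # Å^3
    cutoff: float | None = None       # Å; None -> 0.49 x initial box edge
    volume_move_interval: int | None = None   # None -> one per molecule sweep
    sample_stride: int = 200
    config_stride: int = 5000
    seed: int = 2024
    tail_correction: bool = True
    reaction_field: bool = True   # conducting-boundary RF inside the cutoff
    move_solute: bool = False
    lj_on: bool = True
    coulomb_on: bool = True

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class TrajectorySample:
    step: int
    energy: float          # kJ/mol
    density: float         # g/cm^3
    box_edge: float        # Å


@dataclass
class Trajectory:
    """Output of :func:`run_npt`: scalar samples plus saved configurations."""
    samples: list[TrajectorySample]
    configurations: list[LiquidConfiguration]
    config_steps: list[int]
    acceptance: dict
    params: MCParams
    final: LiquidConfiguration

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.samples])

    @property
    def densities(self) -> np.ndarray:
        return np.array([s.density for s in self.samples])


def _flatten(config: LiquidConfiguration, params: MCParams):
    """Flat site arrays + molecule bookkeeping for the kernels."""
    specs = []
    if config.solute is not None:
        specs.append(config.solute)
    specs.extend([config.water] * config.n_waters)

    coords = config.flat_coords().copy()
    q, sig, ehalf, mstart, mend, ref = [], [], [], [], [], []
    pos = 0
    for spec in specs:
        n = len(spec.sites)
        mstart.append(pos)
        mend.append(pos + n)
        refsite = next((i for i, s in enumerate(spec.sites)
                        if s.element != "H"), 0)
        ref.append(pos + refsite)
        q.extend(spec.charges if params.coulomb_on else np.zeros(n))
        sig.extend(spec.sigmas)
        ehalf.extend(np.sqrt(spec.epsilons) if params.lj_on else np.zeros(n))
        pos += n
    arrays = dict(
        coords=coords,
        q=np.array(q), sig=np.array(sig), ehalf=np.array(ehalf),
        mstart=np.array(mstart, dtype=np.int64),
        mend=np.array(mend, dtype=np.int64),
        ref=np.array(ref, dtype=np.int64),
    )
    first_water = 1 if config.solute is not None else 0
    movable = np.arange(0 if params.move_solute else first_water,
                        len(specs), dtype=np.int64)
    arrays["movable"] = movable
    return arrays


def _tail_coefficients(config: LiquidConfiguration, params: MCParams):
    """Sum_ab N_a N_b 4 eps_ab sigma_ab^{12,6} over LJ-bearing site types."""
    if not (params.tail_correction and params.lj_on):
        return 0.0, 0.0
    sites = []
    if config.solute is not None:
        sites.extend(zip(config.solute.sigmas, config.solute.epsilons))
    for _ in range(config.n_waters):
        sites.extend(zip(config.water.sigmas, config.water.epsilons))
    sites = [(s, e) for s, e in sites if e > 0]
    c9 = c3 = 0.0
    for sa, ea in sites:
        for sb, eb in sites:
            sab = 0.5 * (sa + sb)
            eab = math.sqrt(ea * eb)
            c9 += 4.0 * eab * sab**12
            c3 += 4.0 * eab * sab**6
    return c9, c3


def pair_energy(mol_a: RigidMolecule, mol_b: RigidMolecule,
                box_edge: float | None = None,
                cutoff: float | None = None,
                reaction_field: bool = False) -> float:
    """Site–site 12-6 LJ + Coulomb energy (kJ/mol) between two rigid
    molecules, minimum image on the reference-site separation.
    """
    if box_edge is not None and cutoff is not None and cutoff > box_edge / 2:
        raise ValueError("cutoff exceeds half the box edge")
    na, nb = len(mol_a.spec.sites), len(mol_b.spec.sites)
    coords = np.concatenate([mol_a.coords, mol_b.coords], axis=0)
    q = np.concatenate([mol_a.spec.charges, mol_b.spec.charges])
    sig = np.concatenate([mol_a.spec.sigmas, mol_b.spec.sigmas])
    ehalf = np.sqrt(np.concatenate([mol_a.spec.epsilons, mol_b.spec.epsilons]))
    return float(_kernels.pair_energy_kernel(
        coords, q, sig, ehalf, 0, na, na, na + nb,
        mol_a.reference_site, na + mol_b.reference_site,
        box_edge if box_edge is not None else -1.0,
        cutoff**2 if cutoff is not None else -1.0,
        1.0 / (2.0 * cutoff**3) if (cutoff is not None and reaction_field)
        else 0.0))


def configuration_energy(config: LiquidConfiguration, params: MCParams) -> float:
    """Full potential energy (kJ/mol), including the tail correction."""
    arr = _flatten(config, params)
    rc = params.cutoff if params.cutoff is not None else 0.49 * config.box_edge
    krf = 1.0 / (2.0 * rc**3) if params.reaction_field else 0.0
    u = _kernels.total_energy(arr["coords"], arr["q"], arr["sig"],
                              arr["ehalf"], arr["mstart"], arr["mend"],
                              arr["ref"], config.box_edge, rc * rc, krf)
    c9, c3 = _tail_coefficients(config, params)
    if params.tail_correction:
        u += _kernels.tail_energy(config.box_edge**3, c9, c3, rc)
    return float(u)


def _unflatten(config: LiquidConfiguration, coords, box_edge) -> LiquidConfiguration:
    new = config.copy()
    new.box_edge = float(box_edge)
    pos = 0
    if config.solute is not None:
        n = len(config.solute.sites)
        new.solute_coords = coords[:n].copy()
        pos = n
    nw = config.n_waters
    ns = len(config.water.sites)
    new.water_coords = coords[pos:pos + nw * ns].reshape(nw, ns, 3).copy()
    return new


def run_npt(initial: LiquidConfiguration, params: MCParams) -> Trajectory:
    """Equilibrate (with step-size tuning) then sample the NpT ensemble.

    One MC step is one attempted move; a volume move replaces a particle
    move every ``volume_move_interval`` steps (default: once per molecule
    sweep).  Samples are emitted every ``sample_stride`` steps of the
    production stage, and full configurations every ``config_stride``.
    """
    arr = _flatten(initial, params)
    rc = params.cutoff if params.cutoff is not None else 0.49 * initial.box_edge
    if rc > initial.box_edge / 2 + 1e-9:
        raise ValueError("cutoff exceeds half the box edge")
    c9, c3 = _tail_coefficients(initial, params)
    krf = 1.0 / (2.0 * rc**3) if params.reaction_field else 0.0
    nmol = len(arr["mstart"])
    vol_int = (nmol if params.volume_move_interval is None
               else params.volume_move_interval)
    beta = 1.0 / (KB_KJMOL * params.temperature)
    p_kj = params.pressure * ATM_TO_KJMOL_A3
    mass = initial.total_mass
    from .constants import AVOGADRO

    dt, dang, dvol = (params.max_translation, params.max_rotation,
                      params.volume_amplitude)
    box_edge = initial.box_edge
    coords = arr["coords"]

    if params.n_equilibration > 0:
        out = _kernels.run_mc_chunk(
            coords, arr["q"], arr["sig"], arr["ehalf"], arr["mstart"],
            arr["mend"], arr["ref"], arr["movable"], box_edge, rc, beta,
            p_kj, params.n_equilibration, dt, dang, dvol, vol_int,
            max(params.n_equilibration // 200, 1), 0, c9, c3,
            True, params.seed % (2**31), params.tail_correction, krf)
        dt, dang, dvol, box_edge = out[7], out[8], out[9], out[10]
        acc_eq, att_eq = out[5], out[6]
        log.info("equilibration: acc(move)=%.2f acc(vol)=%.2f dt=%.3f "
                 "dang=%.3f dvol=%.1f", acc_eq[0] / max(att_eq[0], 1),
                 acc_eq[1] / max(att_eq[1], 1), dt, dang, dvol)

    out = _kernels.run_mc_chunk(
        coords, arr["q"], arr["sig"], arr["ehalf"], arr["mstart"],
        arr["mend"], arr["ref"], arr["movable"], box_edge, rc, beta,
        p_kj, params.n_steps, dt, dang, dvol, vol_int,
        params.sample_stride, params.config_stride, c9, c3,
        False, (params.seed + 1) % (2**31), params.tail_correction, krf)
    (energies, volumes, sample_steps, saved_coords, saved_edges,
     acc, att, dt, dang, dvol, box_edge, u_final) = out

    if not np.all(np.isfinite(energies)):
        raise RuntimeError("non-finite energy during production")
    if att[0] > 1000 and acc[0] == 0:
        raise RuntimeError("zero acceptance over production window; "
                           "step sizes are badly scaled")

    dens = mass / (AVOGADRO * volumes * 1e-24)
    samples = [TrajectorySample(int(s), float(e), float(d), float(v**(1 / 3)))
               for s, e, d, v in zip(sample_steps, energies, dens, volumes)]
    configs = [_unflatten(initial, saved_coords[i], saved_edges[i])
               for i in range(saved_coords.shape[0])]
    config_steps = [params.config_stride * (i + 1)
                    for i in range(len(configs))]
    acceptance = {
        "move": {"accepted": int(acc[0]), "attempted": int(att[0])},
        "volume": {"accepted": int(acc[1]), "attempted": int(att[1])},
        "max_translation": float(dt), "max_rotation": float(dang),
        "volume_amplitude": float(dvol),
    }
    log.info("production: acc(move)=%.2f acc(vol)=%.2f <rho>=%.4f g/cm^3",
             acc[0] / max(att[0], 1), acc[1] / max(att[1], 1),
             float(np.mean(dens)))
    return Trajectory(samples=samples, configurations=configs,
                      config_steps=config_steps, acceptance=acceptance,
                      params=params,
                      final=_unflatten(initial, coords, box_edge))


def energy_autocorrelation(series: np.ndarray, max_lag: int | None = None):
    """Normalized autocorrelation of an energy series and its integrated
    correlation interval (in sample units).

    The interval is 2.5*tau_int estimated with Sokal's automatic windowing
    (W = smallest lag with W >= 5*tau_int(W)); an exponential fit to the
    initial decay is reported alongside for diagnostics.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("series too short")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0:
        raise ValueError("constant series has no autocorrelation")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    acf = acov / acov[0]
    if max_lag is None:
        max_lag = n // 4
    acf = acf[:max_lag]

    tau = 0.5
    window = 1
    for w in range(1, len(acf)):
        tau = 0.5 + np.sum(acf[1:w + 1])
        window = w
        if w >= 5 * tau:
            break
    interval = max(1, int(np.ceil(2.5 * tau)))

    # exponential fit over the initial positive decay
    pos = np.nonzero(acf <= 0.05)[0]
    kmax = int(pos[0]) if pos.size else len(acf)
    tau_exp = np.nan
    if kmax >= 3:
        k = np.arange(1, kmax)
        with np.errstate(divide="ignore"):
            y = np.log(np.clip(acf[1:kmax], 1e-12, None))
        slope = np.polyfit(k, y, 1)[0]
        if slope < 0:
            tau_exp = -1.0 / slope
    return {"acf": acf, "tau_int": float(tau), "tau_exp": float(tau_exp),
            "interval": int(interval), "window": int(window),
            "method": "integrated-sokal"}


def select_uncorrelated(trajectory: Trajectory, n: int,
                        interval: int | None = None) -> list[LiquidConfiguration]:
    """Pick ``n`` evenly spaced configurations at least one correlation
    interval apart (interval estimated from the energy series if not given,
    converted to units of saved configurations)."""
    if interval is None:
        stats = energy_autocorrelation(trajectory.energies)
        steps = stats["interval"] * trajectory.params.sample_stride
        interval = max(1, int(np.ceil(steps / trajectory.params.config_stride)))
    configs = trajectory.configurations
    need = (n - 1) * interval + 1
    if len(configs) < need:
        raise ValueError(
            f"stream of {len(configs)} configurations cannot supply {n} "
            f"picks at spacing {interval}")
    stride = (len(configs) - 1) // (n - 1) if n > 1 else 1
    stride = max(stride, interval)
    picks = [configs[len(configs) - 1 - i * stride] for i in range(n)]
    return list(reversed(picks))
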