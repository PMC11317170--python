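"""Seeded generators for synthetic force-spectroscopy and AFM data.

Every generator is a pure function of its parameters and the seed in
:class:`SimulationConfig`: the same call yields bit-identical output.
The generators emulate the statistical structure the analysis assumes —
force-extension curves with Gaussian force noise of SD 0.37 pN (the
typical optical-trap force noise during the overstretch transition),
mono-exponential length relaxations after force or concentration jumps,
and normally distributed AFM contour lengths — without attempting a
physical simulation of strand unpeeling or sequence effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import ThermalConstants
from .errors import ConstructionError, InvalidParameterError, PoleError
from .afm_stats import ContourSample
from .fec_model import EmpiricalParams, ForceExtensionCurve, eval_empirical
from .perturbation_kinetics import KineticTrace, LinearRateParams
from .polymer_models import PolymerParams, ewlc_force, wlc_force

__all__ = [
    "SimulationConfig",
    "gen_fec_empirical",
    "gen_fec_polymer",
    "gen_fec_mechanistic",
    "gen_kinetic_trace",
    "gen_afm_sample",
    "DEFAULT_DS_PARAMS",
    "DEFAULT_SS_PARAMS",
]

#: Default dsDNA eWLC parameters for the mechanistic generator
#: (λ-phage contour length; canonical bare-DNA stiffness).
DEFAULT_DS_PARAMS = PolymerParams(lc_um=16.37, lp_nm=50.0, kappa_pn=1200.0)

#: Default ssDNA-branch eWLC parameters (post-overstretch behaviour).
DEFAULT_SS_PARAMS = PolymerParams(lc_um=27.0, lp_nm=1.0, kappa_pn=800.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs of all generators.

    Parameters
    ----------
    seed : int
        RNG seed; fixing it makes every generator bit-reproducible.
    force_noise_sd : float
        Gaussian force noise SD in pN.  Default 0.37 pN, the typical
        measured force noise of the instrument class being emulated.
    length_noise_sd : float
        Gaussian length noise SD in μm for kinetic traces (default 5 nm).
    extension_grid : array, optional
        Extension grid in μm for FEC generators; default 10-31 μm at
        10 nm spacing.
    """

    seed: int = 0
    force_noise_sd: float = 0.37
    length_noise_sd: float = 0.005
    extension_grid: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.force_noise_sd < 0 or self.length_noise_sd < 0:
            raise InvalidParameterError("noise SDs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def grid(self) -> np.ndarray:
        if self.extension_grid is not None:
            return np.asarray(self.extension_grid, dtype=float)
        return np.arange(10.0, 31.0, 0.01)


def gen_fec_empirical(
    p: EmpiricalParams,
    cfg: SimulationConfig = SimulationConfig(),
    **meta,
) -> ForceExtensionCurve:
    """FEC sampled from the empirical model plus Gaussian force noise."""
    x = cfg.grid()
    if x.max() >= p.p5:
        raise PoleError(
            f"extension grid reaches the pole P5 = {p.p5} μm; shorten it"
        )
    f = eval_empirical(x, p)
    if cfg.force_noise_sd > 0:
        f = f + cfg.rng().normal(0.0, cfg.force_noise_sd, size=x.size)
    return ForceExtensionCurve(extension=x, force=f, **meta)


def gen_fec_polymer(
    p: PolymerParams,
    cfg: SimulationConfig = SimulationConfig(),
    model: str = "ewlc",
    n_points: int = 500,
    force_max: float = 60.0,
    c: ThermalConstants = ThermalConstants(),
    **meta,
) -> ForceExtensionCurve:
    """FEC sampled from a WLC/eWLC model up to ``force_max`` (pN).

    The extension grid is ``n_points`` evenly spaced extensions between
    2% of the contour length and the extension at which the model force
    reaches ``force_max``; Gaussian force noise is added on top.
    """
    if model == "ewlc":
        fmodel = lambda z: ewlc_force(z, p, c)  # noqa: E731
        z_hi_cap = p.lc_um * (1.0 + force_max / p.kappa_pn)
    else:
        fmodel = lambda z: wlc_force(z, p, c)  # noqa: E731
        z_hi_cap = p.lc_um * (1.0 - 1e-9)
    z_hi = brentq(lambda z: fmodel(z) - force_max,
                  1e-6 * p.lc_um, z_hi_cap, xtol=1e-12)
    z = np.linspace(0.02 * p.lc_um, z_hi, n_points)
    f = np.array([fmodel(zi) for zi in z])
    if cfg.force_noise_sd > 0:
        f = f + cfg.rng().normal(0.0, cfg.force_noise_sd, size=z.size)
    return ForceExtensionCurve(extension=z, force=f, **meta)


def gen_fec_mechanistic(
    ds: PolymerParams = DEFAULT_DS_PARAMS,
    plateau_force: float = 65.0,
    plateau_slope: float = 2.0,
    ss: PolymerParams = DEFAULT_SS_PARAMS,
    cfg: SimulationConfig = SimulationConfig(),
    c: ThermalConstants = ThermalConstants(),
    **meta,
) -> ForceExtensionCurve:
    """Piecewise mechanistic FEC: dsDNA eWLC, linear plateau, ssDNA eWLC.

    The dsDNA branch runs until it reaches ``plateau_force``; from there
    a line of slope ``plateau_slope`` models the overstretch transition
    until it intersects the ssDNA eWLC branch, which takes over.  The
    construction is continuous by definition of the two joining points.

    Raises
    ------
    ConstructionError
        If the branches cannot be joined within the extension grid (for
        example a plateau force below the dsDNA branch, or an ssDNA
        branch that never crosses the plateau line).
    """
    if not ds.lc_um < ss.lc_um:
        raise ConstructionError("dsDNA contour length must be below ssDNA's")
    f_ds_check = ewlc_force(0.98 * ds.lc_um, ds, c)
    if plateau_force <= f_ds_check:
        raise ConstructionError(
            f"plateau force {plateau_force} pN does not exceed the dsDNA "
            f"branch ({f_ds_check:.1f} pN at 0.98 Lc)"
        )
    x = cfg.grid()
    # dsDNA branch end: extension where the ds eWLC reaches the plateau
    z_cap = ds.lc_um * (1.0 + plateau_force / ds.kappa_pn)
    z1 = brentq(lambda z: ewlc_force(z, ds, c) - plateau_force,
                1e-6 * ds.lc_um, z_cap, xtol=1e-12)

    def plateau(z):
        return plateau_force + plateau_slope * (z - z1)

    # ssDNA branch start: where it crosses the plateau line
    g = lambda z: ewlc_force(z, ss, c) - plateau(z)  # noqa: E731
    z_hi = min(x.max(), ss.lc_um * (1.0 + 2000.0 / ss.kappa_pn))
    if z_hi <= z1 or g(z1) >= 0:
        raise ConstructionError("ssDNA branch sits above the plateau line")
    if g(z_hi) < 0:
        raise ConstructionError(
            "ssDNA branch never crosses the plateau line within the grid"
        )
    z2 = brentq(g, z1, z_hi, xtol=1e-12)

    f = np.empty_like(x)
    for i, zi in enumerate(x):
        if zi <= z1:
            f[i] = ewlc_force(zi, ds, c)
        elif zi < z2:
            f[i] = plateau(zi)
        else:
            f[i] = ewlc_force(zi, ss, c)
    if cfg.force_noise_sd > 0:
        f = f + cfg.rng().normal(0.0, cfg.force_noise_sd, size=x.size)
    return ForceExtensionCurve(extension=x, force=f, **meta)


@dataclass(frozen=True)
class KineticScenario:
    """Protocol details of the kinetic-trace generator.

    The defaults emulate the instrument class being modelled: ~30 ms
    force ramps (5 pN steps), ~250 ms stage transfers for concentration
    jumps, 2 kHz length sampling, ~0.5 μm of length change per force
    step of which ~90% is instantaneous elastic response (so only the
    remaining fraction relaxes kinetically).
    """

    step_length_um: float = 0.5
    elastic_fraction: float = 0.9
    ramp_time_s: float = 0.03
    transfer_time_s: float = 0.25
    sample_dt_s: float = 5e-4
    min_duration_s: float = 0.25
    relax_durations: float = 5.0  # phase length in units of 1/k_obs
    baseline_um: float = 15.0
    jump_amplitude_um: float = 0.3  # concentration-jump equilibrium shift
    dx_off_nm: Optional[float] = None  # Bell distance of dissociation


def gen_kinetic_trace(
    protocol: str,
    rates: LinearRateParams,
    dx_nm: float,
    tmpyp_nm: float,
    forces: Sequence[float],
    cfg: SimulationConfig = SimulationConfig(),
    scenario: KineticScenario = KineticScenario(),
    c: ThermalConstants = ThermalConstants(),
) -> KineticTrace:
    """Synthetic force-jump or concentration-jump kinetic trace.

    Per phase the length relaxes mono-exponentially towards the phase
    equilibrium with ``k_obs = (k_on*C + k_off) * exp(F*dx/kBT)`` (high
    ligand) or ``k_obs = k_off * exp(F*dx_off/kBT)`` (zero ligand,
    concentration-jump returns; ``dx_off`` defaults to ``-dx``).
    Gaussian length noise is added per sample; the trace is seeded and
    reproducible.
    """
    forces = list(forces)
    if not forces:
        raise InvalidParameterError("forces list must not be empty")
    if protocol not in ("force_jump", "concentration_jump"):
        raise InvalidParameterError(f"unknown protocol {protocol!r}")
    if protocol == "force_jump" and np.any(np.diff(forces) <= 0):
        raise InvalidParameterError("forces must be increasing for force jumps")
    rng = cfg.rng()
    dt = scenario.sample_dt_s
    dx_off = scenario.dx_off_nm if scenario.dx_off_nm is not None else -dx_nm

    times, lengths, force_arr, labels = [], [], [], []
    t_now = 0.0
    L_now = scenario.baseline_um

    def k_obs(force, conc):
        if conc > 0:
            return (rates.k_on * conc + rates.k_off) * np.exp(
                force * dx_nm / c.kbt)
        return rates.k_off * np.exp(force * dx_off / c.kbt)

    def add_segment(t, L, F, label):
        times.append(t)
        lengths.append(L)
        force_arr.append(F)
        labels.extend([label] * t.size)

    if protocol == "force_jump":
        F_prev = 0.0
        for i, F in enumerate(forces):
            label = f"step{i:02d}"
            k = k_obs(F, tmpyp_nm)
            L_eq = scenario.baseline_um + (i + 1) * scenario.step_length_um
            L_elastic = L_now + scenario.elastic_fraction * (L_eq - L_now)
            # ramp: force and length move to the elastic point
            n_ramp = max(2, int(round(scenario.ramp_time_s / dt)))
            t_ramp = t_now + dt * np.arange(1, n_ramp + 1)
            frac = np.linspace(0.0, 1.0, n_ramp)
            add_segment(t_ramp, L_now + frac * (L_elastic - L_now),
                        F_prev + frac * (F - F_prev), label)
            t_now = t_ramp[-1]
            # relaxation towards equilibrium
            duration = max(scenario.relax_durations / k,
                           scenario.min_duration_s)
            n_rel = max(10, int(round(duration / dt)))
            t_rel = t_now + dt * np.arange(1, n_rel + 1)
            amp = L_eq - L_elastic
            add_segment(
                t_rel,
                L_eq - amp * np.exp(-k * (t_rel - t_now)),
                np.full(n_rel, float(F)),
                label,
            )
            t_now = t_rel[-1]
            L_now = L_eq
            F_prev = F
    else:  # concentration jump: high/zero alternation at each constant force
        for i, F in enumerate(forces):
            for phase_name, conc in (("high_tmpyp", tmpyp_nm),
                                     ("zero_tmpyp", 0.0)):
                label = f"{phase_name}_F{i:02d}"
                k = k_obs(F, conc)
                L_eq = scenario.baseline_um + (
                    scenario.jump_amplitude_um if conc > 0 else 0.0)
                duration = max(scenario.relax_durations / k,
                               scenario.min_duration_s)
                n = max(10, int(round(duration / dt)))
                t_seg = t_now + dt * np.arange(1, n + 1)
                amp = L_eq - L_now
                add_segment(
                    t_seg,
                    L_eq - amp * np.exp(-k * (t_seg - t_now)),
                    np.full(n, float(F)),
                    label,
                )
                t_now = t_seg[-1]
                L_now = L_eq
    time = np.concatenate(times)
    length = np.concatenate(lengths)
    force = np.concatenate(force_arr)
    if cfg.length_noise_sd > 0:
        length = length + rng.normal(0.0, cfg.length_noise_sd, size=length.size)
    if cfg.force_noise_sd > 0:
        force = force + rng.normal(0.0, cfg.force_noise_sd, size=force.size)
    return KineticTrace(
        time=time, length=length, force=force,
        phase=np.array(labels), tmpyp=tmpyp_nm, protocol=protocol,
    )


def gen_afm_sample(
    mean_nm: float,
    sd_nm: float,
    n: int,
    cfg: SimulationConfig = SimulationConfig(),
    target_lp_nm: float = 12.0,
    end_to_end_jitter: float = 0.2,
    label: str = "",
) -> ContourSample:
    """Normally distributed AFM contour sample (truncated at > 0).

    End-to-end distances are drawn around ``sqrt(4 * Lp_target * Lc)``
    per molecule with a relative jitter, clipped below each molecule's
    contour length, so the sample-level adsorbed-chain estimator
    recovers approximately ``target_lp_nm``.
    """
    if sd_nm < 0 or n < 2:
        raise InvalidParameterError("need sd >= 0 and n >= 2")
    rng = cfg.rng()
    contour = rng.normal(mean_nm, sd_nm, size=n)
    # truncate at > 0 by redrawing (means are many SDs above zero)
    for _ in range(100):
        bad = contour <= 0
        if not bad.any():
            break
        contour[bad] = rng.normal(mean_nm, sd_nm, size=int(bad.sum()))
    contour = np.abs(contour)  # last-resort guard
    r0 = np.sqrt(4.0 * target_lp_nm * contour)
    r = r0 * (1.0 + rng.normal(0.0, end_to_end_jitter, size=n))
    r = np.clip(r, 1e-3, 0.99 * contour)
    return ContourSample(contour_lengths=contour, end_to_end=r, label=label)
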