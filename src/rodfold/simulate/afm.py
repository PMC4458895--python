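"""Synthetic constant-velocity force-extension traces of a polyprotein.

Forward model: the cantilever base retracts at constant speed, z = v*t.
At every sample the force balance  F = k_c (z - x) = F_WLC(x; Lc, p)  is
solved for the protein extension x (quasi-static: the loading rate is
far below the chain relaxation rate).  Each folded domain unfolds with
the Bell hazard  k(F) = k0 * exp(F * xu / kBT); unfolding adds that
class's contour-length increment to Lc and the force relaxes along the
new WLC.  The trace ends when the force reaches the detachment
threshold.

Unfolding times are drawn by exact inhomogeneous-Poisson time-transform
sampling of the hazard along the deterministic force ramp (equivalent to
per-timestep Bernoulli thinning in the small-dt limit, but independent
of the sample grid).

Default per-class parameters reproduce the published pulling-speed
series for the SasG 13-domain construct: xu from the Bell-Evans slope of
mode force vs ln(speed), and k0 calibrated analytically so the modal
unfolding force at the requested speed matches the published mode (see
``bell_k0_for_modal_force``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..afm import ForceExtensionTrace
from ..constants import kbt
from ..reference import AFM_SPEED_TABLE, N_E, N_G5, bell_xu_from_speed_series
from ..wlc import wlc_extension, wlc_stiffness

DEFAULT_CANTILEVER_K = 30.0     # pN/nm, nominal spring constant
DEFAULT_SAMPLE_RATE = 10_000.0  # Hz
DEFAULT_DETACH_FORCE = 650.0    # pN
DEFAULT_FORCE_NOISE = 10.0      # pN
#: Folded contour length of the 13-domain construct (rigid model length).
DEFAULT_INITIAL_LC = 71.0       # nm


@dataclass(frozen=True)
class DomainClass:
    """One unfolding domain class of the polyprotein."""

    name: str
    n: int                   # copies in the construct
    k0: float                # s^-1, intrinsic unfolding rate
    xu: float                # nm, distance to the transition state
    dlc: float               # nm, contour-length increment on unfolding
    dlc_sd: float = 0.0      # nm, per-event scatter of the increment

    def __post_init__(self):
        if self.n < 0 or self.k0 <= 0 or self.xu <= 0 or self.dlc <= 0:
            raise ValueError("domain class parameters must be positive")


@dataclass
class AFMSimConfig:
    classes: tuple[DomainClass, ...]
    persistence: float = 0.4            # nm
    cantilever_k: float = DEFAULT_CANTILEVER_K   # pN/nm
    speed: float = 800.0                # nm/s
    sample_rate: float = DEFAULT_SAMPLE_RATE     # Hz
    force_noise_sd: float = DEFAULT_FORCE_NOISE  # pN
    temperature: float = 298.0          # K
    detachment_force: float = DEFAULT_DETACH_FORCE   # pN
    initial_lc: float = DEFAULT_INITIAL_LC       # nm
    seed: int = 0

    def __post_init__(self):
        if self.persistence <= 0:
            raise ValueError("persistence length must be positive")
        if self.cantilever_k <= 0:
            raise ValueError("cantilever stiffness must be positive")
        if self.speed <= 0 or self.sample_rate <= 0:
            raise ValueError("speed and sample rate must be positive")
        if self.initial_lc <= 0 or self.detachment_force <= 0:
            raise ValueError("initial Lc and detachment force must be "
                             "positive")


def loading_rate(force: float, lc: float, cantilever_k: float, speed: float,
                 p: float = 0.4, temperature_k: float = 298.0) -> float:
    """dF/dt (pN/s) at a given force: speed times the series stiffness of
    cantilever and WLC."""
    x = wlc_extension(force, lc, p, temperature_k)
    k_wlc = wlc_stiffness(x, lc, p, temperature_k)
    k_eff = 1.0 / (1.0 / cantilever_k + 1.0 / k_wlc)
    return speed * k_eff


def bell_k0_for_modal_force(modal_force: float, xu: float, speed: float,
                            lc_rep: float, cantilever_k: float = DEFAULT_CANTILEVER_K,
                            p: float = 0.4, temperature_k: float = 298.0,
                            multiplicity: float = 1.0) -> float:
    """Intrinsic rate k0 that puts the Bell modal force at ``modal_force``.

    Inverts the most-probable-rupture-force condition
    n * k0 * exp(F* xu / kBT) = r(F*) * xu / kBT  with the loading rate
    evaluated at a representative contour length.  ``multiplicity`` is
    the effective number of domains sharing the hazard (the geometric
    mean of the per-event folded counts for a pooled ensemble).
    """
    kt = kbt(temperature_k)
    r = loading_rate(modal_force, lc_rep, cantilever_k, speed, p,
                     temperature_k)
    return (r * xu / kt) * np.exp(-modal_force * xu / kt) / multiplicity


def _geometric_mean_multiplicity(n: int) -> float:
    """exp(mean(ln k) for k = n..1): effective parallel-domain count."""
    return float(np.exp(np.mean(np.log(np.arange(1, n + 1)))))


def table_calibrated_config(speed: float = 800.0, seed: int = 0,
                            **overrides) -> AFMSimConfig:
    """Generator conditions matching the published speed-series table.

    dLc truths (and their scatter) come straight from the table row for
    the requested speed; xu per class from the Bell-Evans speed-series
    slope; k0 per class from the analytic modal-force calibration at a
    mid-phase representative contour length (E domains unfold first,
    then G5).
    """
    row = AFM_SPEED_TABLE.get(int(speed))
    if row is None:
        raise ValueError(f"no published table row at {speed} nm/s; "
                         f"available: {sorted(AFM_SPEED_TABLE)}")
    dlc_e = row.dlc_e_a / 10.0     # A -> nm
    dlc_g5 = row.dlc_g5_a / 10.0
    xu_e = bell_xu_from_speed_series("E")
    xu_g5 = bell_xu_from_speed_series("G5")
    l0 = overrides.get("initial_lc", DEFAULT_INITIAL_LC)
    kc = overrides.get("cantilever_k", DEFAULT_CANTILEVER_K)
    p = overrides.get("persistence", 0.4)
    temp = overrides.get("temperature", 298.0)
    # representative Lc midway through each class's unfolding phase
    lc_rep_e = l0 + 0.5 * (N_E - 1) * dlc_e
    lc_rep_g5 = l0 + N_E * dlc_e + 0.5 * (N_G5 - 1) * dlc_g5
    k0_e = bell_k0_for_modal_force(
        row.force_e, xu_e, speed, lc_rep_e, kc, p, temp,
        multiplicity=_geometric_mean_multiplicity(N_E))
    k0_g5 = bell_k0_for_modal_force(
        row.force_g5, xu_g5, speed, lc_rep_g5, kc, p, temp,
        multiplicity=_geometric_mean_multiplicity(N_G5))
    classes = (
        DomainClass("E", N_E, k0_e, xu_e, dlc_e, row.dlc_e_sd / 10.0),
        DomainClass("G5", N_G5, k0_g5, xu_g5, dlc_g5, row.dlc_g5_sd / 10.0),
    )
    return AFMSimConfig(classes=classes, speed=speed, seed=seed, **overrides)


def _solve_extension_grid(z: np.ndarray, lc: float, kc: float, p: float,
                          temp: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bisection for x(z) from kc (z - x) = F_WLC(x)."""
    c = kbt(temp) / p
    lo = np.zeros_like(z)
    hi = np.minimum(z, lc) * (1.0 - 1e-12)
    for _ in range(55):
        mid = 0.5 * (lo + hi)
        u = mid / lc
        f_wlc = c * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
        g = kc * (z - mid) - f_wlc      # >0 when mid below the root
        below = g > 0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    x = 0.5 * (lo + hi)
    return x, kc * (z - x)


def simulate_afm_trace(cfg: AFMSimConfig
                       ) -> tuple[ForceExtensionTrace, pd.DataFrame]:
    """One retraction cycle plus the ground-truth event table.

    The truth table has one row per unfolding event plus a final
    detachment row, with columns: time_s, force_pN, class, lc_before_nm,
    lc_after_nm, sample_index.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.sample_rate
    kt = kbt(cfg.temperature)
    folded = {c.name: c.n for c in cfg.classes}
    by_name = {c.name: c for c in cfg.classes}

    lc = cfg.initial_lc
    t0, z0 = 0.0, 0.0
    times, exts, forces = [], [], []
    events = []
    guard = 0
    while True:
        guard += 1
        if guard > sum(c.n for c in cfg.classes) + 2:
            raise RuntimeError("event loop failed to terminate")
        # z range from here until the detachment force is reached at this Lc
        x_det = wlc_extension(cfg.detachment_force, lc, cfg.persistence,
                              cfg.temperature)
        z_det = x_det + cfg.detachment_force / cfg.cantilever_k
        n_max = int(np.ceil((z_det - z0) / (cfg.speed * dt))) + 2
        tt = t0 + dt * np.arange(1, n_max + 1)
        zz = z0 + cfg.speed * dt * np.arange(1, n_max + 1)
        xx, ff = _solve_extension_grid(zz, lc, cfg.cantilever_k,
                                       cfg.persistence, cfg.temperature)
        # total Bell hazard of all folded domains along the ramp
        hazard = np.zeros_like(ff)
        class_hazards = {}
        for name, n in folded.items():
            if n == 0:
                continue
            c = by_name[name]
            h = n * c.k0 * np.exp(np.minimum(ff * c.xu / kt, 700.0))
            class_hazards[name] = h
            hazard = hazard + h
        cum = np.cumsum(hazard) * dt
        detach_idx = int(np.argmax(ff >= cfg.detachment_force))
        if ff[detach_idx] < cfg.detachment_force:
            detach_idx = len(ff) - 1
        draw = rng.exponential() if class_hazards else np.inf
        event_idx = int(np.searchsorted(cum, draw))
        if event_idx >= detach_idx:
            # no unfolding before detachment: emit samples, detach, stop
            stop = detach_idx + 1
            times.append(tt[:stop])
            exts.append(xx[:stop])
            forces.append(ff[:stop])
            events.append(dict(time_s=tt[detach_idx],
                               force_pN=float(ff[detach_idx]),
                               domain_class="detachment",
                               lc_before_nm=lc, lc_after_nm=np.nan))
            t_end, z_end = tt[detach_idx], zz[detach_idx]
            break
        # an unfolding event at event_idx: pick the class by its hazard share
        names = list(class_hazards)
        weights = np.array([class_hazards[n][event_idx] for n in names])
        name = rng.choice(names, p=weights / weights.sum())
        c = by_name[name]
        stop = event_idx + 1
        times.append(tt[:stop])
        exts.append(xx[:stop])
        forces.append(ff[:stop])
        dlc = c.dlc if c.dlc_sd == 0 else max(
            rng.normal(c.dlc, c.dlc_sd), 0.2 * c.dlc)
        events.append(dict(time_s=tt[event_idx],
                           force_pN=float(ff[event_idx]),
                           domain_class=name,
                           lc_before_nm=lc, lc_after_nm=lc + dlc))
        folded[name] -= 1
        lc += dlc
        t0, z0 = tt[event_idx], zz[event_idx]

    # post-detachment tail: free cantilever, zero force
    n_tail = max(int(0.02 * cfg.sample_rate), 50)
    tail_t = t_end + dt * np.arange(1, n_tail + 1)
    tail_z = z_end + cfg.speed * dt * np.arange(1, n_tail + 1)
    times.append(tail_t)
    exts.append(tail_z)
    forces.append(np.zeros(n_tail))

    time = np.concatenate(times)
    ext = np.concatenate(exts)
    force = np.concatenate(forces)
    if cfg.force_noise_sd > 0:
        force = force + rng.normal(0.0, cfg.force_noise_sd, force.size)
    truth = pd.DataFrame(events)
    truth["sample_index"] = np.searchsorted(time, truth.time_s.values)
    trace = ForceExtensionTrace(time, ext, force, cfg.speed,
                                meta=dict(seed=cfg.seed,
                                          initial_lc=cfg.initial_lc))
    return trace, truth


def saturated_noiseless_config(seed: int = 0) -> AFMSimConfig:
    """A noiseless configuration in which every domain unfolds well below
    the detachment force (for exact event-count checks)."""
    cfg = table_calibrated_config(speed=800.0, seed=seed)
    classes = tuple(replace(c, dlc_sd=0.0) for c in cfg.classes)
    return replace(cfg, classes=classes, force_noise_sd=0.0,
                   detachment_force=650.0)
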