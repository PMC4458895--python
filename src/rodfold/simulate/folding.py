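"""Synthetic equilibrium denaturation curves and chevron rate data.

The denaturation generator inverts the two-state fitting model: signal
drawn from the two-state equation with linear baselines plus Gaussian
noise.  The chevron generator evaluates the two-limb rate law and
applies log-normal noise (rates are measured on a log scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..thermo import DenaturationCurve, two_state_signal


def _default_grid():
    return np.linspace(0.0, 8.0, 30)


@dataclass
class EqSimConfig:
    m: float = 1.4            # kcal mol^-1 M^-1
    d50: float = 4.4          # M
    a_n: float = 1.0          # native baseline intercept (signal units)
    b_n: float = -0.02        # native baseline slope (signal/M)
    a_d: float = 0.1          # denatured baseline intercept
    b_d: float = 0.005        # denatured baseline slope
    grid: np.ndarray = field(default_factory=_default_grid)   # M
    noise_sd: float = 0.018   # signal units (~2% of the amplitude)
    temperature: float = 298.0
    seed: int = 0
    construct: str = ""

    def __post_init__(self):
        if self.m <= 0 or self.d50 <= 0:
            raise ValueError("m and d50 must be positive")
        g = np.asarray(self.grid, dtype=float)
        if g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("denaturant grid must be strictly increasing")
        self.grid = g


def simulate_denaturation(cfg: EqSimConfig) -> DenaturationCurve:
    rng = np.random.default_rng(cfg.seed)
    y = two_state_signal(cfg.grid, cfg.m, cfg.d50, cfg.a_n, cfg.b_n,
                         cfg.a_d, cfg.b_d)
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, y.shape)
    return DenaturationCurve(cfg.grid.copy(), y, cfg.construct)


@dataclass
class ChevronSimConfig:
    kf0: float = 100.0        # s^-1, folding rate in water
    m_kf: float = 1.6         # M^-1
    ku0: float = 100.0 * np.exp(-6.3 / 0.592)   # s^-1; detailed balance
    m_ku: float = 1.4 / 0.592 - 1.6             # M^-1; matches eq m-value
    grid: np.ndarray = field(default_factory=_default_grid)   # M
    log_noise_sd: float = 0.05   # dimensionless (sd of ln kobs)
    seed: int = 0

    def __post_init__(self):
        if self.kf0 <= 0 or self.ku0 <= 0:
            raise ValueError("rate constants must be positive")
        if self.m_kf <= 0 or self.m_ku <= 0:
            raise ValueError("kinetic m-values must be positive")
        self.grid = np.asarray(self.grid, dtype=float)


def chevron_kobs(denaturant, kf0: float, m_kf: float, ku0: float,
                 m_ku: float):
    """Noiseless two-state observed rate kobs(D)."""
    d = np.asarray(denaturant, dtype=float)
    out = kf0 * np.exp(-m_kf * d) + ku0 * np.exp(m_ku * d)
    return float(out) if out.ndim == 0 else out


def chevron_minimum(kf0: float, m_kf: float, ku0: float,
                    m_ku: float) -> float:
    """Denaturant concentration of the noiseless chevron minimum:
    D* = ln(kf0 m_kf / (ku0 m_ku)) / (m_kf + m_ku)."""
    return float(np.log(kf0 * m_kf / (ku0 * m_ku)) / (m_kf + m_ku))


def simulate_chevron(cfg: ChevronSimConfig) -> pd.DataFrame:
    """Table of (denaturant_M, kobs_s) with log-normal rate noise."""
    rng = np.random.default_rng(cfg.seed)
    k = chevron_kobs(cfg.grid, cfg.kf0, cfg.m_kf, cfg.ku0, cfg.m_ku)
    if cfg.log_noise_sd > 0:
        k = k * np.exp(rng.normal(0.0, cfg.log_noise_sd, k.shape))
    return pd.DataFrame({"denaturant_M": cfg.grid, "kobs_s": k})
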