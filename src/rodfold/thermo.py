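"""Two-state folding thermodynamics, chevron kinetics and the interface
free-energy ledger.

Equilibrium urea denaturation of a two-state folder with linear
baselines:

    Y(D) = [(aN + bN*D) + (aD + bD*D) * K] / (1 + K),
    K(D) = exp(m * (D - d50) / RT)

so the unfolding free energy in water is dG = m * d50 (an identity, not
a fitted output).  Chevron plots are fitted either to the standard
two-state form  kobs = kf0*exp(-m_kf*D) + ku0*exp(m_ku*D)  or to a
sequential transition-state variant in which the unfolding limb is the
harmonic combination of two barriers (the rate-limiting barrier switches
with denaturant, curving the limb).

The ledger attributes multi-domain stability to per-domain terms plus
inter-domain interface terms, with explicit bound propagation: a bounded
input (the E domain is *at least* +2.5 kcal/mol unstable) always yields
a bounded, never an equality, output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import RT_KCAL_MOL


@dataclass
class DenaturationCurve:
    denaturant: np.ndarray   # M
    signal: np.ndarray
    construct: str = ""
    probe: str = "Tyr"

    def __post_init__(self):
        d = np.asarray(self.denaturant, float)
        y = np.asarray(self.signal, float)
        if d.size != y.size:
            raise ValueError("denaturant and signal must have equal length")
        if d.size < 10:
            raise ValueError("need >= 10 points")
        if np.any(d < 0):
            raise ValueError("denaturant must be non-negative")
        self.denaturant, self.signal = d, y


def two_state_signal(denaturant, m: float, d50: float, a_n: float,
                     b_n: float, a_d: float, b_d: float,
                     rt: float = RT_KCAL_MOL):
    """Observed signal of a two-state folder with linear baselines."""
    d = np.asarray(denaturant, dtype=float)
    k = np.exp(m * (d - d50) / rt)
    y = ((a_n + b_n * d) + (a_d + b_d * d) * k) / (1.0 + k)
    return float(y) if y.ndim == 0 else y


def fraction_unfolded(denaturant, m: float, d50: float,
                      rt: float = RT_KCAL_MOL):
    d = np.asarray(denaturant, dtype=float)
    k = np.exp(m * (d - d50) / rt)
    out = k / (1.0 + k)
    return float(out) if out.ndim == 0 else out


@dataclass
class TwoStateFit:
    m: float                 # kcal mol^-1 M^-1
    d50: float               # M
    a_n: float
    b_n: float
    a_d: float
    b_d: float
    m_se: float
    d50_se: float
    dg_se: float
    construct: str = ""
    covar: np.ndarray | None = field(default=None, repr=False)

    @property
    def dg(self) -> float:
        """Unfolding free energy in water, kcal/mol: dG = m * d50."""
        return self.m * self.d50


def fit_two_state(curve: DenaturationCurve,
                  rt: float = RT_KCAL_MOL) -> TwoStateFit:
    """Six-parameter least-squares fit of the two-state equation.

    Refuses curves with no detectable transition (signal range below
    three times the local noise estimate).
    """
    d, y = curve.denaturant, curve.signal
    noise = np.std(np.diff(y)) / np.sqrt(2.0)
    if np.ptp(y) < 3.0 * max(noise, 1e-12):
        raise ValueError("no transition detectable "
                         "(signal range < 3x noise)")
    # a straight line through the data leaves no sigmoidal signal to fit
    line = np.polyval(np.polyfit(d, y, 1), d)
    if np.std(y - line) < max(3.0 * noise, 1e-3 * np.ptp(y)):
        raise ValueError("no transition detectable (signal is linear "
                         "in denaturant)")

    # initial guesses: baselines from the curve ends, d50 from the
    # mid-signal crossing
    n_edge = max(3, d.size // 6)
    a_n0 = float(np.mean(y[:n_edge]))
    a_d0 = float(np.mean(y[-n_edge:]))
    mid = 0.5 * (a_n0 + a_d0)
    d50_0 = float(d[np.argmin(np.abs(y - mid))])
    d50_0 = min(max(d50_0, d[1]), d[-2])

    model = lmfit.Model(two_state_signal, independent_vars=["denaturant"])
    params = model.make_params(
        m=dict(value=1.0, min=1e-3),
        d50=dict(value=d50_0, min=float(d.min()), max=float(d.max())),
        a_n=a_n0, b_n=0.0, a_d=a_d0, b_d=0.0,
    )
    params["rt"] = lmfit.Parameter("rt", value=rt, vary=False)
    out = model.fit(y, params, denaturant=d)
    p = out.params

    def se(name):
        s = p[name].stderr
        return float(s) if s is not None else np.nan

    m, d50 = p["m"].value, p["d50"].value
    # dG = m*d50; delta-method error including the m-d50 covariance
    dg_se = np.nan
    if out.covar is not None and p["m"].stderr is not None:
        names = [n for n in p if p[n].vary]
        im, id50 = names.index("m"), names.index("d50")
        var = (d50 ** 2 * out.covar[im, im]
               + m ** 2 * out.covar[id50, id50]
               + 2 * m * d50 * out.covar[im, id50])
        dg_se = float(np.sqrt(max(var, 0.0)))
    return TwoStateFit(float(m), float(d50), float(p["a_n"].value),
                       float(p["b_n"].value), float(p["a_d"].value),
                       float(p["b_d"].value), se("m"), se("d50"), dg_se,
                       curve.construct, out.covar)


def ddg(fit_a, fit_b) -> tuple[float, float]:
    """Stability difference dG_a - dG_b (kcal/mol) with propagated error.

    Accepts TwoStateFit objects or (dg, se) tuples.
    """
    def unpack(f):
        if hasattr(f, "dg"):
            return f.dg, f.dg_se
        return float(f[0]), float(f[1])

    ga, sa = unpack(fit_a)
    gb, sb = unpack(fit_b)
    return ga - gb, float(np.hypot(sa, sb))


# ---------------------------------------------------------------------------
# Interface free-energy ledger


@dataclass(frozen=True)
class FreeEnergy:
    """A free energy carrying bound semantics (folding convention).

    bound: 'exact' (equality), 'ge' (true value >= ``value``) or 'le'.
    Internally represented as the interval [lo, hi].
    """

    value: float
    bound: str = "exact"     # 'exact' | 'ge' | 'le'

    @property
    def lo(self) -> float:
        return self.value if self.bound in ("exact", "ge") else -np.inf

    @property
    def hi(self) -> float:
        return self.value if self.bound in ("exact", "le") else np.inf

    @property
    def is_bound(self) -> bool:
        return self.bound != "exact"


@dataclass(frozen=True)
class InterfaceEstimate:
    """Derived interface contribution with its derivation rule.

    ``stabilization_min`` is the minimum free energy (kcal/mol) the
    interface must confer; ``exact`` is False whenever any input was a
    bound (bounds propagate, never collapsing to equalities).
    """

    name: str
    rule: str                # 'A:partition-additivity' | 'B:midpoint-shift'
    stabilization_min: float
    exact: bool


def interface_additivity(name: str, construct_folding: FreeEnergy,
                         parts: list[FreeEnergy]) -> InterfaceEstimate:
    """Rule A: dG_int(X-Y) = dG(XY) - dG(X) - dG(Y), folding convention.

    Interval arithmetic propagates any input bound to the output: the
    interface folding free energy lies in
    [c.lo - sum(p.hi), c.hi - sum(p.lo)], and the stabilization the
    interface must confer is minus the upper end.
    """
    hi = construct_folding.hi - sum(p.lo for p in parts)
    exact = (not construct_folding.is_bound
             and not any(p.is_bound for p in parts))
    return InterfaceEstimate(name, "A:partition-additivity",
                             float(-hi), exact)


def midpoint_shift_bound(name: str, m_domain: float, d50_construct: float,
                         d50_domain: float) -> InterfaceEstimate:
    """Rule B: stabilization of a domain inside a larger construct.

    If the construct unfolds at a higher denaturant midpoint than the
    isolated domain, the interface must stabilize the domain by at least
    m_domain * (d50_construct - d50_domain).  Always a bound: the
    construct midpoint only floors the stabilization.
    """
    return InterfaceEstimate(name, "B:midpoint-shift",
                             float(m_domain * (d50_construct - d50_domain)),
                             exact=False)


def sasg_interface_ledger(domains: dict[str, tuple[float, str]] | None = None,
                          eq_table=None) -> dict[str, InterfaceEstimate]:
    """The canonical ledger for the G5^1-E-G5^2 system.

    Uses the published per-domain folding stabilities and construct
    equilibrium fits (overridable).  Returns the E-G5^2 interface (rule
    A on the E-G5^2 construct partitioned into E and G5^2) and the
    G5^1-E interface (rule B on the G5^1 midpoint shift inside
    G5^1-E-G5^2).
    """
    from .reference import DOMAIN_FOLDING_DG, EQUILIBRIUM
    domains = domains or DOMAIN_FOLDING_DG
    eq = eq_table or EQUILIBRIUM
    fe = {k: FreeEnergy(v, b) for k, (v, b) in domains.items()}
    # construct folding dG = -(unfolding dG) = -(m * d50 printed column)
    construct_e_g52 = FreeEnergy(-eq["E-G5_2"].dg, "exact")
    rule_a = interface_additivity("E-G5_2 interface", construct_e_g52,
                                  [fe["E"], fe["G5_2"]])
    rule_b = midpoint_shift_bound("G5_1-E interface",
                                  eq["G5_1"].m,
                                  eq["G5_1-E-G5_2"].d50,
                                  eq["G5_1"].d50)
    return {"E-G5_2": rule_a, "G5_1-E": rule_b}


# ---------------------------------------------------------------------------
# Chevron analysis


@dataclass
class ChevronFit:
    kf0: float               # s^-1
    m_kf: float              # M^-1 (natural-log slope)
    ku0: float
    m_ku: float
    model: str               # 'two_state' | 'sequential_ts'
    ku2: float | None = None
    m_ku2: float | None = None
    redchi: float = np.nan
    partial: str | None = None   # 'folding'/'unfolding' if one limb only

    @property
    def kinetic_m_value(self) -> float:
        """Total kinetic m-value, kcal mol^-1 M^-1: RT*(m_kf + m_ku)."""
        return RT_KCAL_MOL * (self.m_kf + self.m_ku)

    @property
    def dg_kinetic(self) -> float:
        """RT * ln(kf0/ku0): the detailed-balance unfolding free energy."""
        return RT_KCAL_MOL * np.log(self.kf0 / self.ku0)


def chevron_rate(denaturant, fit: ChevronFit):
    """Observed relaxation rate kobs(D) for a fitted chevron model."""
    d = np.asarray(denaturant, dtype=float)
    kf = fit.kf0 * np.exp(-fit.m_kf * d)
    if fit.model == "sequential_ts":
        ku1 = fit.ku0 * np.exp(fit.m_ku * d)
        ku2 = fit.ku2 * np.exp(fit.m_ku2 * d)
        ku = 1.0 / (1.0 / ku1 + 1.0 / ku2)
    else:
        ku = fit.ku0 * np.exp(fit.m_ku * d)
    out = kf + ku
    return float(out) if out.ndim == 0 else out


def _log_kobs_two_state(d, ln_kf0, m_kf, ln_ku0, m_ku):
    return np.log(np.exp(ln_kf0 - m_kf * d) + np.exp(ln_ku0 + m_ku * d))


def _log_kobs_sequential(d, ln_kf0, m_kf, ln_ku1, m_ku1, ln_ku2, m_ku2):
    ku = 1.0 / (np.exp(-(ln_ku1 + m_ku1 * d))
                + np.exp(-(ln_ku2 + m_ku2 * d)))
    return np.log(np.exp(ln_kf0 - m_kf * d) + ku)


def fit_chevron(denaturant, kobs, model: str = "two_state") -> ChevronFit:
    """Fit log observed rates to a chevron model.

    model: 'two_state', 'sequential_ts' or 'auto' (residual comparison,
    preferring the simpler model unless the sequential fit reduces the
    reduced chi-square by >20%).  Data covering only one limb are fitted
    limb-only and flagged partial.
    """
    d = np.asarray(denaturant, dtype=float)
    k = np.asarray(kobs, dtype=float)
    if d.size < 8:
        raise ValueError("need >= 8 denaturant points")
    if np.any(k <= 0):
        raise ValueError("rates must be positive")
    logk = np.log(k)

    imin = int(np.argmin(logk))
    has_folding = imin >= 2
    has_unfolding = imin <= d.size - 3
    if not (has_folding and has_unfolding):
        # single-limb data: plain exponential fit on the available limb
        slope, inter = np.polyfit(d, logk, 1)
        if slope < 0:
            return ChevronFit(float(np.exp(inter)), float(-slope),
                              np.nan, np.nan, "two_state",
                              partial="folding")
        return ChevronFit(np.nan, np.nan, float(np.exp(inter)),
                          float(slope), "two_state", partial="unfolding")

    # limb-based starting guesses
    fold_sl, fold_in = np.polyfit(d[:max(imin, 2)], logk[:max(imin, 2)], 1)
    unf_sl, unf_in = np.polyfit(d[imin:], logk[imin:], 1)

    def run_two_state():
        m = lmfit.Model(_log_kobs_two_state, independent_vars=["d"])
        pars = m.make_params(ln_kf0=fold_in, m_kf=dict(value=max(-fold_sl, .1), min=0),
                             ln_ku0=unf_in, m_ku=dict(value=max(unf_sl, .1), min=0))
        return m.fit(logk, pars, d=d)

    def run_sequential():
        m = lmfit.Model(_log_kobs_sequential, independent_vars=["d"])
        pars = m.make_params(
            ln_kf0=fold_in, m_kf=dict(value=max(-fold_sl, .1), min=0),
            ln_ku1=unf_in - 1.0, m_ku1=dict(value=max(unf_sl * 1.5, .15), min=0),
            ln_ku2=unf_in + 1.0, m_ku2=dict(value=max(unf_sl * 0.5, .05), min=0),
        )
        return m.fit(logk, pars, d=d)

    if model == "two_state":
        out = run_two_state()
    elif model == "sequential_ts":
        out = run_sequential()
    elif model == "auto":
        out2 = run_two_state()
        outs = run_sequential()
        out = outs if outs.redchi < 0.8 * out2.redchi else out2
    else:
        raise ValueError(f"unknown chevron model {model!r}")

    p = out.params
    if "ln_ku1" in p:
        return ChevronFit(float(np.exp(p["ln_kf0"])), float(p["m_kf"]),
                          float(np.exp(p["ln_ku1"])), float(p["m_ku1"]),
                          "sequential_ts",
                          ku2=float(np.exp(p["ln_ku2"])),
                          m_ku2=float(p["m_ku2"]), redchi=float(out.redchi))
    return ChevronFit(float(np.exp(p["ln_kf0"])), float(p["m_kf"]),
                      float(np.exp(p["ln_ku0"])), float(p["m_ku"]),
                      "two_state", redchi=float(out.redchi))
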