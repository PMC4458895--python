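"""Coarse bead-chain shape models and model-level scattering observables.

A multi-domain rod is represented as a chain of uniform-weight beads
filling a cylinder; per-junction random tilts emulate inter-domain
flexing.  From bead coordinates the pair-distance distribution P(r) and
its support Dmax, the cross-sectional distance distribution, the Debye
scattering curve, Guinier and cross-sectional Guinier radii and the
Porod exponent are computed.  These are model-level analogues of the
solution-scattering observables used to characterize elongated
particles; no experimental curve fitting is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import linregress

#: Default per-domain lengths (nm), solved from the two printed rigid-model
#: anchors: 2*len_g5 + len_e = 17 (three domains) and
#: 7*len_g5 + 6*len_e = 71 (thirteen domains).
LEN_G5_NM = 6.2
LEN_E_NM = 4.6
DEFAULT_RADIUS_NM = 1.0
DEFAULT_BEADS_PER_NM = 2.0


@dataclass
class BeadChain:
    """Bead coordinates (nm) with per-bead domain indices."""

    coords: np.ndarray                 # (n, 3)
    domain_of_bead: np.ndarray         # (n,) int
    domain_lengths: np.ndarray         # per-domain axial length, nm
    radius: float
    ends: np.ndarray = None            # (2, 3): axis start / end points

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def end_to_end(self) -> float:
        """Distance between the chain-axis start and end points."""
        if self.ends is not None:
            return float(np.linalg.norm(self.ends[1] - self.ends[0]))
        return float(np.linalg.norm(self.coords[-1] - self.coords[0]))


_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _domain_block(length: float, beads_per_nm: float, radius: float):
    """Beads of one rigid domain in its local frame (+z from the origin).

    Axial stations every 1/beads_per_nm; each station carries a
    golden-angle sunflower disk of beads, which samples the circular
    cross-section with uniform area density (so the cross-sectional
    radius of gyration of the bead model matches a solid cylinder's
    a/sqrt(2)).
    """
    h = 1.0 / beads_per_nm
    n_ax = max(2, int(round(length / h)) + 1)
    zs = np.linspace(0.0, length, n_ax)
    if radius <= 0:
        return np.column_stack([np.zeros(n_ax), np.zeros(n_ax), zs])
    n_disk = max(1, int(round(np.pi * radius ** 2 / h ** 2)))
    i = np.arange(n_disk)
    rr = radius * np.sqrt((i + 0.5) / n_disk)
    phi = i * _GOLDEN_ANGLE
    disk = np.column_stack([rr * np.cos(phi), rr * np.sin(phi)])
    pts = np.empty((n_ax * n_disk, 3))
    for k, z in enumerate(zs):
        pts[k * n_disk:(k + 1) * n_disk, :2] = disk
        pts[k * n_disk:(k + 1) * n_disk, 2] = z
    return pts


def _assemble(blocks: list[np.ndarray], lengths: list[float],
              directions: list[np.ndarray]
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords = []
    dom = []
    origin = np.zeros(3)
    start = origin.copy()
    for i, (blk, length, u) in enumerate(zip(blocks, lengths, directions)):
        rot = _rotation_to(u)
        coords.append(blk @ rot.T + origin)
        dom.append(np.full(blk.shape[0], i))
        origin = origin + u * length
    ends = np.vstack([start, origin])
    return np.vstack(coords), np.concatenate(dom), ends


def _rotation_to(u: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +z to unit vector u (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    u = u / np.linalg.norm(u)
    v = np.cross(z, u)
    c = float(np.dot(z, u))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_chain(n_g5: int, n_e: int, len_g5: float = LEN_G5_NM,
                len_e: float = LEN_E_NM,
                beads_per_nm: float = DEFAULT_BEADS_PER_NM,
                radius: float = DEFAULT_RADIUS_NM) -> BeadChain:
    """Collinear rigid chain with alternating G5-(E-G5)^n composition."""
    if len_g5 <= 0 or len_e <= 0:
        raise ValueError("domain lengths must be positive")
    if n_g5 < 1 or n_e < 0 or n_g5 != n_e + 1:
        raise ValueError(
            "composition must alternate G5-(E-G5)^n, i.e. n_g5 == n_e + 1")
    lengths = []
    for i in range(n_g5 + n_e):
        lengths.append(len_g5 if i % 2 == 0 else len_e)
    blocks = [_domain_block(L, beads_per_nm, radius) for L in lengths]
    dirs = [np.array([0.0, 0.0, 1.0])] * len(lengths)
    coords, dom, ends = _assemble(blocks, lengths, dirs)
    return BeadChain(coords, dom, np.array(lengths), radius, ends)


def sample_flexed(chain_spec: dict, bend_sd_deg: float, n_samples: int,
                  seed: int) -> list[BeadChain]:
    """Ensemble of flexed chains: per-junction polar tilt ~ N(0, bend_sd),
    uniform azimuth; domains stay rigid.

    ``chain_spec`` holds the build_chain keyword arguments.
    """
    if bend_sd_deg < 0:
        raise ValueError("bend_sd must be non-negative")
    rng = np.random.default_rng(seed)
    spec = dict(n_g5=chain_spec["n_g5"], n_e=chain_spec["n_e"],
                len_g5=chain_spec.get("len_g5", LEN_G5_NM),
                len_e=chain_spec.get("len_e", LEN_E_NM),
                beads_per_nm=chain_spec.get("beads_per_nm",
                                            DEFAULT_BEADS_PER_NM),
                radius=chain_spec.get("radius", DEFAULT_RADIUS_NM))
    rigid = build_chain(**spec)
    lengths = list(rigid.domain_lengths)
    blocks = [_domain_block(L, spec["beads_per_nm"], spec["radius"])
              for L in lengths]
    out = []
    for _ in range(n_samples):
        dirs = [np.array([0.0, 0.0, 1.0])]
        for _j in range(len(lengths) - 1):
            tilt = np.deg2rad(rng.normal(0.0, bend_sd_deg))
            az = rng.uniform(0, 2 * np.pi)
            u_prev = dirs[-1]
            # tilt away from u_prev by |tilt| around a random azimuth
            perp = _any_perpendicular(u_prev)
            perp2 = np.cross(u_prev, perp)
            u_new = (np.cos(tilt) * u_prev
                     + np.sin(tilt) * (np.cos(az) * perp + np.sin(az) * perp2))
            dirs.append(u_new / np.linalg.norm(u_new))
        coords, dom, ends = _assemble(blocks, lengths, dirs)
        out.append(BeadChain(coords, dom, np.array(lengths),
                             spec["radius"], ends))
    return out


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    v = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, v)) > 0.9:
        v = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, v)
    return p / np.linalg.norm(p)


# ---------------------------------------------------------------------------
# Distance distributions


@dataclass
class PairDistribution:
    r: np.ndarray            # bin centres, nm
    p: np.ndarray            # normalized density, integral 1
    dmax: float              # exact max pairwise distance, nm
    bin_edges: np.ndarray = field(repr=False, default=None)


def _pairwise_distances(coords: np.ndarray, chunk: int = 2000) -> np.ndarray:
    n = coords.shape[0]
    if n <= chunk:
        return pdist(coords)
    parts = []
    for i in range(0, n, chunk):
        a = coords[i:i + chunk]
        parts.append(pdist(a))
        b = coords[i + chunk:]
        if b.size:
            parts.append(cdist(a, b).ravel())
    return np.concatenate(parts)


def pair_distribution(chain: BeadChain | np.ndarray,
                      n_bins: int = 100) -> PairDistribution:
    """Normalized histogram of all pairwise bead distances; Dmax is the
    exact maximum pairwise distance."""
    coords = chain.coords if isinstance(chain, BeadChain) else np.asarray(chain)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    dists = _pairwise_distances(coords)
    dmax = float(dists.max())
    edges = np.linspace(0.0, dmax, n_bins + 1)
    counts, _ = np.histogram(dists, edges)
    width = edges[1] - edges[0]
    p = counts / (counts.sum() * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PairDistribution(centers, p, dmax, edges)


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """Longest axis: dominant eigenvector of the gyration tensor.

    Ties are broken by eigenvalue order as returned by the symmetric
    eigensolver (coordinate order).
    """
    c = coords - coords.mean(axis=0)
    gyr = c.T @ c / c.shape[0]
    w, v = np.linalg.eigh(gyr)
    return v[:, -1]


def cross_section_distribution(chain: BeadChain | np.ndarray,
                               n_bins: int = 60) -> PairDistribution:
    """Pairwise-distance distribution of beads projected onto the plane
    normal to the principal (longest) axis."""
    coords = chain.coords if isinstance(chain, BeadChain) else np.asarray(chain)
    axis = principal_axis(coords)
    c = coords - coords.mean(axis=0)
    proj = c - np.outer(c @ axis, axis)
    # drop the axial component by expressing in an in-plane basis
    e1 = _any_perpendicular(axis)
    e2 = np.cross(axis, e1)
    plane = np.column_stack([proj @ e1, proj @ e2])
    dists = _pairwise_distances(plane)
    dmax = float(dists.max())
    if dmax == 0:
        return PairDistribution(np.array([0.0]), np.array([np.inf]), 0.0,
                                np.array([0.0, 0.0]))
    edges = np.linspace(0.0, dmax, n_bins + 1)
    counts, _ = np.histogram(dists, edges)
    width = edges[1] - edges[0]
    p = counts / (counts.sum() * width)
    return PairDistribution(0.5 * (edges[:-1] + edges[1:]), p, dmax, edges)


# ---------------------------------------------------------------------------
# Scattering


@dataclass
class ScatteringProfile:
    s: np.ndarray            # nm^-1, s = 4 pi sin(theta) / lambda
    intensity: np.ndarray


def debye_intensity(chain: BeadChain | np.ndarray, s) -> ScatteringProfile:
    """Debye scattering of uniform-weight beads:
    I(s) = sum_ij sinc(s * r_ij), evaluated through a fine pair-distance
    histogram (standard Debye histogram approximation)."""
    coords = chain.coords if isinstance(chain, BeadChain) else np.asarray(chain)
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s < 0):
        raise ValueError("s must be non-negative")
    n = coords.shape[0]
    if n == 1:
        return ScatteringProfile(s, np.ones_like(s))
    dists = _pairwise_distances(coords)
    dmax = dists.max()
    n_bins = min(4000, max(200, int(dmax / 0.02)))
    counts, edges = np.histogram(dists, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sr = np.outer(s, centers)
    with np.errstate(invalid="ignore"):
        sinc = np.where(sr == 0, 1.0, np.sin(sr) / np.where(sr == 0, 1, sr))
    intensity = n + 2.0 * sinc @ counts
    return ScatteringProfile(s, intensity)


def radius_of_gyration(coords: np.ndarray) -> float:
    """Direct second-moment Rg of bead coordinates."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


@dataclass
class GuinierResult:
    rg: float                # nm
    i0: float
    n_points: int
    nonlinear_warning: bool


def guinier_fit(profile: ScatteringProfile,
                s_range: tuple[float, float]) -> GuinierResult:
    """ln I vs s^2 regression; slope = -Rg^2/3.

    Sets a warning flag when the residuals show a strong systematic
    trend (fit outside the Guinier validity range).
    """
    mask = (profile.s >= s_range[0]) & (profile.s <= s_range[1]) \
        & (profile.intensity > 0)
    s2 = profile.s[mask] ** 2
    ln_i = np.log(profile.intensity[mask])
    if s2.size < 3:
        raise ValueError("need >= 3 points in the Guinier range")
    res = linregress(s2, ln_i)
    rg = float(np.sqrt(max(-3.0 * res.slope, 0.0)))
    resid = ln_i - (res.intercept + res.slope * s2)
    warn = bool(np.max(np.abs(resid)) > 0.05 * np.ptp(ln_i) + 1e-12) \
        if np.ptp(ln_i) > 0 else False
    return GuinierResult(rg, float(np.exp(res.intercept)), int(s2.size),
                         warn)


def cross_section_guinier(profile: ScatteringProfile,
                          s_range: tuple[float, float]) -> float:
    """Rc from the modified Guinier plot ln(I*s) vs s^2 (slope=-Rc^2/2)."""
    mask = (profile.s >= s_range[0]) & (profile.s <= s_range[1]) \
        & (profile.intensity > 0) & (profile.s > 0)
    s2 = profile.s[mask] ** 2
    ln_is = np.log(profile.intensity[mask] * profile.s[mask])
    if s2.size < 3:
        raise ValueError("need >= 3 points in the cross-section range")
    res = linregress(s2, ln_is)
    return float(np.sqrt(max(-2.0 * res.slope, 0.0)))


def porod_exponent(profile: ScatteringProfile,
                   s_range: tuple[float, float]) -> float:
    """Negative slope of log I vs log s over the mid-s range."""
    mask = (profile.s >= s_range[0]) & (profile.s <= s_range[1]) \
        & (profile.intensity > 0) & (profile.s > 0)
    if np.count_nonzero(mask) < 5:
        raise ValueError("need >= 5 points in the Porod range")
    res = linregress(np.log(profile.s[mask]),
                     np.log(profile.intensity[mask]))
    return float(-res.slope)


def ball_beads(radius: float, spacing: float) -> np.ndarray:
    """Uniform grid beads filling a sphere (test/reference geometry)."""
    g = np.arange(-radius, radius + spacing / 2, spacing)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return pts[(pts ** 2).sum(axis=1) <= radius ** 2]
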