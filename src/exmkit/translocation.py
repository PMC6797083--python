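"""Free-energy model for escape of a confined ideal chain through a wall pore.

A chromosome confined in a spherical cavity of radius ``R`` (smaller than the
chain's unconfined radius of gyration ``R_g``) can thread through a pore in the
wall.  With ``m`` Kuhn segments translocated, the free energy in units of
``k_B T`` is::

    F(m) = -ln[1 + (R/R_g) * sqrt(N / (pi * m))]
           + pi**2 * ((N - m) / N) * (R_g / R)**2
           + m * dmu

where ``N`` is the total number of Kuhn segments and ``dmu`` the per-segment
chemical-potential difference between outside and inside (negative values
favour the outside).  The first term is the conformational entropy of the
escaped half-chain, the second that of the confined half-chain, the third the
bulk driving term.

For an ideal chain ``R_g = sqrt(N/6) * l_K``, so with the confinement
parameter ``z_c = sqrt(6/pi) * (R / l_K)`` the profile reduces to::

    F(m) = -ln(1 + z_c / sqrt(m)) + pi * (N - m) / z_c**2 + m * dmu

Setting ``dF/dm = 0`` and substituting ``x = sqrt(m)`` yields the cubic

    2*c*x**3 + 2*c*z_c*x**2 - z_c = 0,      c = pi / z_c**2 - dmu,

whose positive root locates the entropic barrier ``m* = x**2``; note it
depends only on ``R / l_K`` and ``dmu``, not on ``N``.  The barrier vanishes
(``m* = 1``) at the critical potential::

    dmu_c = pi / z_c**2 - z_c / (2 * (1 + z_c))

All energies are expressed in units of ``k_B T``; lengths in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChainParams",
    "DerivedChain",
    "EnergyPoint",
    "BarrierResult",
    "CriticalPotential",
    "chain_quantities",
    "free_energy",
    "profile",
    "barrier",
    "critical_potential",
    "segments_to_bp",
    "round_half_away",
]


@dataclass(frozen=True)
class ChainParams:
    """Physical parameters of the confined chain.

    Defaults correspond to the E. coli chromosome in a cell of radius 1 um:
    4.7 Mbp at 0.34 nm/bp rise, Kuhn length 100 nm, DNA cross-section radius
    1 nm.
    """

    genome_bp: float = 4.7e6
    rise_nm_per_bp: float = 0.34
    kuhn_nm: float = 100.0
    cell_radius_nm: float = 1000.0
    cross_radius_nm: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "genome_bp",
            "rise_nm_per_bp",
            "kuhn_nm",
            "cell_radius_nm",
            "cross_radius_nm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.kuhn_nm < self.rise_nm_per_bp:
            raise ValueError("kuhn_nm must be >= rise_nm_per_bp")

    @property
    def r_over_lk(self) -> float:
        return self.cell_radius_nm / self.kuhn_nm


@dataclass(frozen=True)
class DerivedChain:
    contour_nm: float
    n_kuhn: float
    rg_nm: float
    confinement_ratio: float  # R / R_g
    volume_fraction: float  # DNA volume / cell volume


@dataclass(frozen=True)
class EnergyPoint:
    m: float
    dmu_kT: float
    f_kT: float
    df_kT: float  # F(m) - F(1)
    entropy_out_kT: float
    entropy_in_kT: float
    chem_kT: float


@dataclass(frozen=True)
class BarrierResult:
    m_star: float
    df_star_kT: float
    exists: bool


@dataclass(frozen=True)
class CriticalPotential:
    dmu_c_kT: float
    z_c: float


def _zc(r_over_lk: float) -> float:
    return math.sqrt(6.0 / math.pi) * r_over_lk


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def chain_quantities(p: ChainParams) -> DerivedChain:
    """Contour length, segment count, ideal-chain R_g, confinement ratio and
    intracellular volume fraction of the chain (cylinder in a sphere)."""
    contour = p.genome_bp * p.rise_nm_per_bp
    n = contour / p.kuhn_nm
    rg = math.sqrt(n / 6.0) * p.kuhn_nm
    vol_frac = (math.pi * p.cross_radius_nm**2 * contour) / (
        4.0 / 3.0 * math.pi * p.cell_radius_nm**3
    )
    if not 0.0 < vol_frac < 1.0:
        raise ValueError("volume fraction outside (0, 1); check parameters")
    return DerivedChain(
        contour_nm=contour,
        n_kuhn=n,
        rg_nm=rg,
        confinement_ratio=p.cell_radius_nm / rg,
        volume_fraction=vol_frac,
    )


def _f_terms(m, p: ChainParams, dmu_kT: float, derived: DerivedChain):
    m = np.asarray(m, dtype=float)
    n = derived.n_kuhn
    r_over_rg = derived.confinement_ratio
    out = -np.log(1.0 + r_over_rg * np.sqrt(n / (math.pi * m)))
    inside = math.pi**2 * ((n - m) / n) / r_over_rg**2
    chem = m * dmu_kT
    return out, inside, chem


def free_energy(
    m: float, p: ChainParams, dmu_kT: float = 0.0
) -> EnergyPoint:
    """Evaluate F(m)/k_BT and dF = F(m) - F(1) at a single (continuous) m."""
    derived = chain_quantities(p)
    if not 1.0 <= m <= derived.n_kuhn - 1.0:
        raise ValueError(f"m={m} outside [1, N-1]")
    out, inside, chem = _f_terms(m, p, dmu_kT, derived)
    f = float(out + inside + chem)
    o1, i1, c1 = _f_terms(1.0, p, dmu_kT, derived)
    return EnergyPoint(
        m=float(m),
        dmu_kT=dmu_kT,
        f_kT=f,
        df_kT=f - float(o1 + i1 + c1),
        entropy_out_kT=float(out),
        entropy_in_kT=float(inside),
        chem_kT=float(chem),
    )


def profile(p: ChainParams, dmu_kT: float, m_grid) -> list[EnergyPoint]:
    """Vectorized F(m) over a grid in (1, N-1)."""
    derived = chain_quantities(p)
    m_grid = np.asarray(m_grid, dtype=float)
    if m_grid.size == 0:
        return []
    if m_grid.min() < 1.0 or m_grid.max() > derived.n_kuhn - 1.0:
        raise ValueError("m grid outside [1, N-1]")
    out, inside, chem = _f_terms(m_grid, p, dmu_kT, derived)
    f = out + inside + chem
    o1, i1, c1 = _f_terms(1.0, p, dmu_kT, derived)
    f1 = float(o1 + i1 + c1)
    return [
        EnergyPoint(
            m=float(m_grid[i]),
            dmu_kT=dmu_kT,
            f_kT=float(f[i]),
            df_kT=float(f[i] - f1),
            entropy_out_kT=float(out[i]),
            entropy_in_kT=float(inside[i]),
            chem_kT=float(chem[i]),
        )
        for i in range(m_grid.size)
    ]


def _dfdm_at_one(z: float, dmu_kT: float) -> float:
    # dF/dm = z / (2 m^{3/2} + 2 z m) - pi/z^2 + dmu, evaluated at m = 1
    return z / (2.0 + 2.0 * z) - math.pi / z**2 + dmu_kT


def barrier(p: ChainParams, dmu_kT: float = 0.0) -> BarrierResult:
    """Interior maximum of F(m), solved from the cubic in x = sqrt(m).

    ``exists`` is False when the slope at m = 1 is non-positive (barrier has
    vanished; dmu <= dmu_c), in which case m_star = 1 and the height is 0.
    """
    derived = chain_quantities(p)
    z = _zc(p.r_over_lk)
    if _dfdm_at_one(z, dmu_kT) <= 0.0:
        return BarrierResult(m_star=1.0, df_star_kT=0.0, exists=False)
    c = math.pi / z**2 - dmu_kT
    if c <= 0.0:
        # dF/dm > 0 everywhere: no interior stationary point; clamp at the
        # right edge. Only reachable for dmu >= pi/z_c^2 > 0.
        m_star = derived.n_kuhn - 1.0
        return BarrierResult(
            m_star=m_star,
            df_star_kT=free_energy(m_star, p, dmu_kT).df_kT,
            exists=True,
        )

    def g(x: float) -> float:
        return 2.0 * c * x**3 + 2.0 * c * z * x**2 - z

    lo, hi = 1.0, math.sqrt(derived.n_kuhn - 1.0)
    if g(lo) >= 0.0 or g(hi) <= 0.0:
        raise RuntimeError("barrier root not bracketed; internal inconsistency")
    # bracketed bisection to relative tolerance 1e-10
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0.0:
            hi = mid
        else:
            lo = mid
        if (hi - lo) <= 1e-10 * hi:
            break
    x = 0.5 * (lo + hi)
    m_star = x * x
    # verify it is a maximum: slope positive just below, negative just above
    eps = max(1e-6, 1e-8 * m_star)
    f_lo = free_energy(max(1.0, m_star - eps), p, dmu_kT).f_kT
    f_hi = free_energy(min(derived.n_kuhn - 1.0, m_star + eps), p, dmu_kT).f_kT
    f_at = free_energy(m_star, p, dmu_kT)
    if f_at.f_kT + 1e-9 < max(f_lo, f_hi) - 1e-9:
        raise RuntimeError("stationary point is not a maximum")
    return BarrierResult(m_star=m_star, df_star_kT=f_at.df_kT, exists=True)


def critical_potential(p: ChainParams) -> CriticalPotential:
    """Chemical potential at which the entropic barrier vanishes (m* = 1)."""
    z = _zc(p.r_over_lk)
    dmu_c = math.pi / z**2 - z / (2.0 * (1.0 + z))
    return CriticalPotential(dmu_c_kT=dmu_c, z_c=z)


def segments_to_bp(m: float, p: ChainParams) -> float:
    """Base pairs spanned by m Kuhn segments."""
    if m < 0:
        raise ValueError("m must be non-negative")
    return m * p.kuhn_nm / p.rise_nm_per_bp
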