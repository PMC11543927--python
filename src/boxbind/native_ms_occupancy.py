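"""Native-MS binding stoichiometry, identical-sites null model, competition.

Native mass spectrometry resolves intact protein-ligand complexes as
separate mass species, so the intensity of the i-ligand species is a proxy
for its concentration (equal response factors across stoichiometries, the
standard native-MS assumption).  This module turns per-stoichiometry
intensities into occupancy statistics (fractions, average occupancy nu,
Scatchard coordinates nu/Lfree vs nu), tests them against the
non-interacting identical-sites null model -- under which the species
distribution is binomial in the per-site occupancy p and the Scatchard
plot is a straight line nu/Lfree = (n - nu)/Kd -- and solves the
two-ligand, one-site competition equilibrium used to measure mutual
displacement of adaptor peptides.

Concentrations in µM throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .errors import DataError, FitError, ModelError

DEFAULT_N_MAX = 4  # a fourth, possibly unspecific, binding event is observed
DEFAULT_N_SITES = 3  # the three specific boxes (Clathrin, Arrestin, W)


@dataclass
class SpeciesDistribution:
    """Intensities of the 0..n_max ligand-bound species at one titration point."""

    lt_uM: float
    pt_uM: float
    intensities: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise DataError("need intensities for stoichiometries 0..n_max, n_max >= 1")
        if np.any(self.intensities < 0):
            raise DataError("intensities must be non-negative")
        if not np.any(self.intensities > 0):
            raise DataError("at least one intensity must be positive")

    @property
    def n_max(self) -> int:
        return self.intensities.size - 1


@dataclass
class OccupancyResult:
    """Occupancy statistics derived from one species distribution."""

    fractions: np.ndarray
    nu: float
    lfree_uM: float
    scatchard_x: float
    scatchard_y: float | None  # None when Lfree <= 0 (point undefined)
    lfree_floored: bool = False


def occupancy(dist: SpeciesDistribution) -> OccupancyResult:
    """Fractions, average occupancy and the Scatchard point.

    nu = sum_i i * f_i; Lfree = Lt - nu * Pt (floored at zero with a
    warning, in which case the Scatchard point is undefined).
    """
    fractions = dist.intensities / dist.intensities.sum()
    nu = float(np.arange(fractions.size) @ fractions)
    lfree = dist.lt_uM - nu * dist.pt_uM
    floored = False
    if lfree < 0:
        warnings.warn(
            f"bound ligand ({nu * dist.pt_uM:.3g} uM) exceeds total "
            f"({dist.lt_uM:.3g} uM); Lfree floored at 0",
            stacklevel=2,
        )
        lfree, floored = 0.0, True
    if lfree > 0:
        scat_y = nu / lfree
    elif nu == 0:
        scat_y = 0.0
    else:
        scat_y = None
    return OccupancyResult(
        fractions=fractions,
        nu=nu,
        lfree_uM=float(lfree),
        scatchard_x=nu,
        scatchard_y=scat_y,
        lfree_floored=floored,
    )


def identical_sites_fractions(
    n_sites: int, kd_uM: float, pt_uM: float, lt_uM: float
) -> np.ndarray:
    """Expected species fractions under n non-interacting identical sites.

    With per-site occupancy p = Lfree / (Kd + Lfree) and ligand depletion
    Lfree = Lt - n p Pt, p is the root in [0, 1] of

        n Pt p^2 - (Kd + Lt + n Pt) p + Lt = 0

    and the fractions are binomial: f_i = C(n, i) p^i (1 - p)^(n - i).
    """
    if n_sites < 1:
        raise ModelError("n_sites must be >= 1")
    if kd_uM <= 0:
        raise ModelError("Kd must be positive")
    if pt_uM < 0 or lt_uM < 0:
        raise ModelError("concentrations must be non-negative")
    if lt_uM == 0:
        p = 0.0
    else:
        a = n_sites * pt_uM
        b = kd_uM + lt_uM + a
        if a == 0:
            p = lt_uM / (kd_uM + lt_uM)
        else:
            p = (b - math.sqrt(b * b - 4.0 * a * lt_uM)) / (2.0 * a)
    p = min(max(p, 0.0), 1.0)
    i = np.arange(n_sites + 1)
    comb = np.array([math.comb(n_sites, k) for k in i], dtype=float)
    return comb * p**i * (1.0 - p) ** (n_sites - i)


@dataclass
class IdenticalSitesFit:
    """Least-squares fit of the identical-sites model to a titration."""

    kd_uM: float
    deviation: float  # minimized sum of squared fraction residuals per dof
    n_sites: int
    dof: int
    ssr: float
    fractions_obs: list[np.ndarray] = field(default_factory=list)
    fractions_exp: list[np.ndarray] = field(default_factory=list)


def _observed_fractions(dist: SpeciesDistribution, n_sites: int) -> np.ndarray:
    """Observed fractions over stoichiometries 0..n_sites (renormalized)."""
    intens = dist.intensities
    if dist.n_max > n_sites:
        intens = intens[: n_sites + 1]
    total = intens.sum()
    if total <= 0:
        raise DataError("no intensity within stoichiometries 0..n_sites")
    frac = np.zeros(n_sites + 1)
    frac[: intens.size] = intens / total
    return frac


def fit_identical_sites(
    titration: list[SpeciesDistribution], n_sites: int = DEFAULT_N_SITES
) -> IdenticalSitesFit:
    """Fit a single Kd to the whole titration and report the misfit.

    Minimizes the sum over titration points and stoichiometries of
    (f_obs - f_exp)^2 over log10 Kd; the deviation statistic is the
    minimized sum per degree of freedom (n_points * n_sites - 1: each
    point's fractions sum to one, and one parameter is fitted).  Large
    deviations flag non-identical sites or cooperative binding; calibrate
    the null with :func:`null_deviation_quantile`.
    """
    if len(titration) < 3:
        raise FitError(f"need >= 3 titration points, got {len(titration)}")
    f_obs = [_observed_fractions(d, n_sites) for d in titration]
    if all(f[0] >= 1.0 - 1e-12 for f in f_obs):
        raise FitError("degenerate titration: all points are apo")

    def ssr_at(log10_kd: float) -> float:
        kd = 10.0 ** log10_kd
        s = 0.0
        for d, fo in zip(titration, f_obs):
            fe = identical_sites_fractions(n_sites, kd, d.pt_uM, d.lt_uM)
            s += float(((fo - fe) ** 2).sum())
        return s

    res = minimize_scalar(ssr_at, bounds=(-3.0, 6.0), method="bounded",
                          options={"xatol": 1e-8})
    kd_hat = 10.0 ** res.x
    ssr = float(res.fun)
    dof = len(titration) * n_sites - 1
    f_exp = [
        identical_sites_fractions(n_sites, kd_hat, d.pt_uM, d.lt_uM)
        for d in titration
    ]
    return IdenticalSitesFit(
        kd_uM=float(kd_hat),
        deviation=ssr / dof,
        n_sites=n_sites,
        dof=dof,
        ssr=ssr,
        fractions_obs=f_obs,
        fractions_exp=f_exp,
    )


def null_deviation_quantile(
    n_sites: int,
    kd_uM: float,
    pt_uM: float,
    lt_grid_uM,
    counts_n: int,
    n_sims: int = 200,
    seed: int = 0,
    q: float = 0.95,
) -> float:
    """Simulated null quantile of the deviation statistic.

    Parametric calibration: multinomial counts of size ``counts_n`` are
    drawn from the identical-sites fractions at each grid point, refitted,
    and the ``q`` quantile of the resulting deviation statistics returned.
    Small-count sampling noise is thereby represented exactly rather than
    through an asymptotic chi-square.
    """
    rng = np.random.default_rng(seed)
    devs = np.empty(n_sims)
    for s in range(n_sims):
        titr = []
        for lt in lt_grid_uM:
            probs = identical_sites_fractions(n_sites, kd_uM, pt_uM, lt)
            counts = rng.multinomial(counts_n, probs / probs.sum())
            if counts.sum() == 0 or not counts.any():
                counts[0] = 1
            titr.append(SpeciesDistribution(lt, pt_uM, counts.astype(float)))
        devs[s] = fit_identical_sites(titr, n_sites).deviation
    return float(np.quantile(devs, q))


def scatchard_points(
    titration: list[SpeciesDistribution],
) -> pd.DataFrame:
    """Scatchard coordinates (nu, nu/Lfree) for each titration point."""
    rows = []
    for d in titration:
        occ = occupancy(d)
        rows.append((d.lt_uM, occ.nu, occ.lfree_uM, occ.scatchard_y))
    return pd.DataFrame(rows, columns=["lt_uM", "nu", "lfree_uM", "nu_over_lfree"])


# ---------------------------------------------------------------------------
# Two-ligand, one-site competition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompetitionSystem:
    """P + A <-> PA and P + B <-> PB at a single shared site."""

    pt_uM: float
    at_uM: float
    bt_uM: float
    kda_uM: float
    kdb_uM: float

    def __post_init__(self):
        if min(self.pt_uM, self.at_uM, self.bt_uM) < 0:
            raise ModelError("concentrations must be non-negative")
        if self.kda_uM <= 0 or self.kdb_uM <= 0:
            raise ModelError("dissociation constants must be positive")


@dataclass
class CompetitionResult:
    """Equilibrium composition as fractions of total protein."""

    fraction_pa: float
    fraction_pb: float
    fraction_free: float
    pfree_uM: float
    afree_uM: float
    bfree_uM: float
    iterations: int


def solve_competition(
    sys: CompetitionSystem,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> CompetitionResult:
    """Damped fixed-point solution of the two-ligand mass-balance system.

    Iterates free concentrations

        Pfree = Pt / (1 + Afree/KdA + Bfree/KdB)
        Afree = At / (1 + Pfree/KdA)
        Bfree = Bt / (1 + Pfree/KdB)

    with damping 0.5 until the relative change drops below ``tol``; the
    returned composition conserves mass to better than 1e-10.
    """
    p, a, b = sys.pt_uM, sys.at_uM, sys.bt_uM
    for it in range(1, max_iter + 1):
        p_new = sys.pt_uM / (1.0 + a / sys.kda_uM + b / sys.kdb_uM)
        a_new = sys.at_uM / (1.0 + p_new / sys.kda_uM)
        b_new = sys.bt_uM / (1.0 + p_new / sys.kdb_uM)
        p_next = damping * p_new + (1.0 - damping) * p
        a_next = damping * a_new + (1.0 - damping) * a
        b_next = damping * b_new + (1.0 - damping) * b
        delta = max(
            abs(p_next - p) / max(p, 1e-30),
            abs(a_next - a) / max(a, 1e-30),
            abs(b_next - b) / max(b, 1e-30),
        )
        p, a, b = p_next, a_next, b_next
        if delta < tol:
            break
    else:
        raise ModelError(f"competition solver did not converge in {max_iter} iterations")
    # project onto exact ligand mass balance given the converged Pfree:
    # a + PA = At and b + PB = Bt hold to machine precision by construction
    a = sys.at_uM / (1.0 + p / sys.kda_uM)
    b = sys.bt_uM / (1.0 + p / sys.kdb_uM)
    pa = p * a / sys.kda_uM
    pb = p * b / sys.kdb_uM
    p = sys.pt_uM - pa - pb
    pt = sys.pt_uM if sys.pt_uM > 0 else 1.0
    return CompetitionResult(
        fraction_pa=pa / pt,
        fraction_pb=pb / pt,
        fraction_free=p / pt,
        pfree_uM=p,
        afree_uM=a,
        bfree_uM=b,
        iterations=it,
    )


def one_site_bound_fraction(pt_uM: float, lt_uM: float, kd_uM: float) -> float:
    """Closed-form 1:1 bound fraction of protein (quadratic with depletion)."""
    s = pt_uM + lt_uM + kd_uM
    pa = (s - math.sqrt(s * s - 4.0 * pt_uM * lt_uM)) / 2.0
    return pa / pt_uM if pt_uM > 0 else 0.0


def competition_curve(
    pt_uM: float,
    fixed_ligand: tuple[str, float, float],
    titrant: tuple[str, "list[float] | np.ndarray", float],
) -> pd.DataFrame:
    """Bound fractions along a titrant grid at constant competitor.

    ``fixed_ligand`` is ``(label, concentration_uM, Kd_uM)``; ``titrant``
    is ``(label, ascending concentration grid in µM, Kd_uM)``.  The fixed
    ligand's bound fraction is monotone non-increasing in the titrant.
    """
    fixed_label, fixed_conc, fixed_kd = fixed_ligand
    tit_label, grid, tit_kd = titrant
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise DataError("titrant grid must be non-negative and ascending")
    rows = []
    for c in grid:
        res = solve_competition(
            CompetitionSystem(pt_uM, at_uM=c, bt_uM=fixed_conc,
                              kda_uM=tit_kd, kdb_uM=fixed_kd)
        )
        rows.append((c, res.fraction_pa, res.fraction_pb, res.fraction_free))
    df = pd.DataFrame(
        rows,
        columns=[
            f"{tit_label}_uM",
            f"frac_bound_{tit_label}",
            f"frac_bound_{fixed_label}",
            "frac_free",
        ],
    )
    return df
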