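"""Bond-path electron-density profiles and (3,-1) critical-point location.

Along the straight path between a metal nucleus and a donor nucleus the
electron density shows two nuclear maxima and one interior minimum; in the
1-D sample that minimum is the bond critical point (the (3,-1) saddle of the
full 3-D density).  Its distance from the metal nucleus partitions the bond
length into atomic contributions, so comparing CP positions between the
complexes of two different metal ions probes their ionic-radius difference.

Profiles are 1-D samples (position in Angstrom from the metal nucleus,
density in atomic units).  A two-exponential promolecular model — the
superposition of two unrelaxed spherical atomic densities with tabulated
decay lengths — serves as a self-contained analytic test bed: its CP
position has a closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .atomdata import decay_length_A, density_amplitude
from .errors import ChelastabError, NoInteriorMinimumError

MIN_SAMPLES = 11


@dataclass(frozen=True)
class DensityProfile:
    """Sampled electron density along a metal-donor path, metal nucleus at 0."""

    positions: np.ndarray   # Angstrom, strictly increasing
    densities: np.ndarray   # atomic units, > 0
    metal: str
    donor: str
    donor_class: str | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        den = np.asarray(self.densities, dtype=float)
        if pos.ndim != 1 or pos.shape != den.shape:
            raise ChelastabError("positions and densities must be parallel 1-D arrays")
        if len(pos) < MIN_SAMPLES:
            raise ChelastabError(f"need >= {MIN_SAMPLES} samples, got {len(pos)}")
        if np.any(np.diff(pos) <= 0):
            raise ChelastabError("positions must be strictly increasing")
        if np.any(den <= 0):
            raise ChelastabError("densities must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "densities", den)


@dataclass(frozen=True)
class CriticalPoint:
    """Interior density minimum along a bond path."""

    position: float     # Angstrom from the metal nucleus
    density: float      # interpolated density at the minimum
    method: str


def read_profile(path: str | Path, metal: str = "", donor: str = "") -> DensityProfile:
    """Read a two-column (position_A, density_au) profile; '#' lines ignored."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ChelastabError(f"{path}: expected two columns (position_A, density_au)")
    return DensityProfile(data[:, 0], data[:, 1], metal=metal, donor=donor)


def write_profile(profile: DensityProfile, path: str | Path) -> None:
    header = f"position_A density_au  ({profile.metal}-{profile.donor} path)"
    np.savetxt(path, np.column_stack([profile.positions, profile.densities]),
               header=header)


def locate_cp(profile: DensityProfile) -> CriticalPoint:
    """Locate the bond critical point: grid minimum + quadratic refinement.

    The minimum must be interior to the sampled interval.  A plateau of
    equal minimal values yields the plateau midpoint with a warning.
    Refinement fits a parabola through the minimum and its two neighbours;
    if the three points are collinear the grid minimum is returned as-is.
    """
    x, y = profile.positions, profile.densities
    kmin = int(np.argmin(y))
    ties = np.flatnonzero(y == y[kmin])
    if len(ties) > 1:
        if ties[0] == 0 or ties[-1] == len(y) - 1:
            raise NoInteriorMinimumError("minimum plateau touches an endpoint")
        warnings.warn("plateau of equal minima; returning its midpoint")
        pos = 0.5 * (x[ties[0]] + x[ties[-1]])
        return CriticalPoint(float(pos), float(y[kmin]), "plateau_midpoint")
    if kmin == 0 or kmin == len(y) - 1:
        raise NoInteriorMinimumError(
            f"no interior CP: sampled minimum at endpoint x = {x[kmin]:.4f} A"
        )
    x0, x1, x2 = x[kmin - 1 : kmin + 2]
    y0, y1, y2 = y[kmin - 1 : kmin + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a <= 0:
        return CriticalPoint(float(x1), float(y1), "grid")
    xv = -b / (2 * a)
    xv = float(np.clip(xv, x0, x2))
    c = y1 - a * x1**2 - b * x1
    return CriticalPoint(xv, float(a * xv**2 + b * xv + c), "quadratic")


def cp_separation(ref: DensityProfile, cmp: DensityProfile) -> float:
    """cp(cmp).position - cp(ref).position, both with the metal at the origin.

    Positive when the comparison CP sits farther from the metal nucleus.
    """
    return locate_cp(cmp).position - locate_cp(ref).position


def promolecular_profile(
    elem_a: str,
    elem_b: str,
    bond_length: float,
    n_samples: int = 501,
) -> DensityProfile:
    """Two-exponential promolecular density along an A-B bond path.

    density(x) = c_A exp(-x/lambda_A) + c_B exp(-(d-x)/lambda_B), with the
    amplitudes c (atomic number) and decay lengths lambda (from first
    ionization energies) frozen in :mod:`chelastab.atomdata`.  Sampled
    uniformly on [0.2 d, 0.8 d], avoiding the nuclear cusp regions the
    exponential model does not represent.
    """
    if bond_length <= 0:
        raise ChelastabError("bond_length must be positive")
    if n_samples < 51:
        raise ChelastabError("n_samples must be >= 51")
    c_a, lam_a = density_amplitude(elem_a), decay_length_A(elem_a)
    c_b, lam_b = density_amplitude(elem_b), decay_length_A(elem_b)
    x = np.linspace(0.2 * bond_length, 0.8 * bond_length, n_samples)
    rho = c_a * np.exp(-x / lam_a) + c_b * np.exp(-(bond_length - x) / lam_b)
    return DensityProfile(x, rho, metal=elem_a, donor=elem_b)


def promolecular_cp_position(elem_a: str, elem_b: str, bond_length: float) -> float:
    """Closed-form CP of the two-exponential model (independent of sampling).

    Setting the derivative to zero: c_A/lambda_A e^{-x/lambda_A}
    = c_B/lambda_B e^{-(d-x)/lambda_B}, hence

        x* = [ln(c_A lambda_B / (c_B lambda_A)) + d/lambda_B]
             / (1/lambda_A + 1/lambda_B).
    """
    c_a, lam_a = density_amplitude(elem_a), decay_length_A(elem_a)
    c_b, lam_b = density_amplitude(elem_b), decay_length_A(elem_b)
    return (np.log(c_a * lam_b / (c_b * lam_a)) + bond_length / lam_b) / (
        1.0 / lam_a + 1.0 / lam_b
    )
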