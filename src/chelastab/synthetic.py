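"""Synthetic inputs for the whole pipeline, with ground truth attached.

The quantum-chemistry layer that would normally produce optimized geometries,
EDA tables and exchange free energies is replaced by generators whose outputs
carry their generating truth:

* paired nine/ten-donor coordination geometries whose metal-donor distances
  differ by a controlled offset, with donor-type-dependent noise (broader for
  amine N, whose flat potential-energy surfaces smear real distributions);
* EDA tables satisfying the decomposition identities by construction;
* random M/L/H equilibrium models together with a pM computed by a
  brute-force bisection oracle that shares no code with the Newton solver.

All generators are deterministic given (spec, seed); seeds and truth are
emitted alongside the data, never encoded only in filenames.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eda import EdaTerms
from .errors import ChelastabError, ConvergenceError, GenerationError
from .geometry import ComplexStructure, classify_donors
from .speciation import EquilibriumModel, Species

logger = logging.getLogger(__name__)

# Class-mean reference-metal distances (Angstrom), typical of nine-coordinate
# La3+ chelates: carboxylate O ~2.50, pyridine N ~2.65, amine N ~2.75,
# water O ~2.60.
DEFAULT_R_REF = {
    "O_carboxylate": 2.50,
    "N_pyridine": 2.65,
    "N_amine": 2.75,
    "O_water": 2.60,
}
DEFAULT_NOISE_SD = 0.02     # per-structure distance noise, Angstrom
AMINE_NOISE_FACTOR = 2.5    # amine N distributions are markedly broader


@dataclass(frozen=True)
class GeometryGenSpec:
    """Study conditions for paired-geometry generation.

    Defaults mirror the statistical structure of a 17-pair La/Ac comparison:
    true radial offset 0.059 A for the comparison metal, per-class Gaussian
    distance noise of 0.02 A (2.5x larger for amine N), and a tri-capped
    nonadentate donor set of 3 carboxylate O + 3 pyridine N + 3 amine N.
    """

    seed: int
    n_complexes: int = 17
    donor_counts: dict = field(
        default_factory=lambda: {"O_carboxylate": 3, "N_pyridine": 3, "N_amine": 3}
    )
    r_ref: dict = field(default_factory=lambda: dict(DEFAULT_R_REF))
    delta_r: float = 0.059
    noise_sd: dict = field(
        default_factory=lambda: {
            "default": DEFAULT_NOISE_SD,
            "N_amine": DEFAULT_NOISE_SD * AMINE_NOISE_FACTOR,
        }
    )
    ref_metal: str = "La"
    cmp_metal: str = "Ac"

    def __post_init__(self):
        if self.n_complexes < 1:
            raise ChelastabError("need at least one complex")
        if any(v < 0 for v in self.donor_counts.values()) or (
            sum(self.donor_counts.values()) < 1
        ):
            raise ChelastabError("donor counts must be >= 0 with at least one donor")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ChelastabError("noise sd must be >= 0")

    def sd_for(self, donor_class: str) -> float:
        return self.noise_sd.get(donor_class, self.noise_sd.get("default", 0.0))


@dataclass(frozen=True)
class EquilibriumGenSpec:
    """Random M/L/H model generation: species count and log-beta ranges."""

    seed: int
    n_species: int | None = None          # None: draw 1..8
    logbeta_complex: tuple[float, float] = (2.0, 30.0)
    prot_step: tuple[float, float] = (2.0, 11.0)    # stepwise ligand log K_H
    complex_prot_step: tuple[float, float] = (1.5, 5.0)

    def __post_init__(self):
        for rng_ in (self.logbeta_complex, self.prot_step, self.complex_prot_step):
            if not all(np.isfinite(rng_)) or rng_[0] > rng_[1]:
                raise ChelastabError(f"bad range {rng_}")
        if self.n_species is not None and not 1 <= self.n_species <= 8:
            raise ChelastabError("n_species must be in 1..8")


# ---------------------------------------------------------------------------
# Paired geometries
# ---------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci sphere)."""
    k = np.arange(n, dtype=float)
    phi = (1 + 5**0.5) / 2
    z = 1 - (2 * k + 1) / n
    theta = 2 * np.pi * k / phi
    r = np.sqrt(np.maximum(1 - z**2, 0.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _tangent_frame(u: np.ndarray, rot: float) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangents to u, rotated in-plane by ``rot`` radians."""
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(u, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    c, s = np.cos(rot), np.sin(rot)
    return c * t1 + s * t2, -s * t1 + c * t2


def _decoration(donor_class: str, u, t1, t2) -> list[tuple[str, np.ndarray]]:
    """Minimal substituent atoms (offsets from the donor) realizing a class."""
    if donor_class == "O_water":
        a = math.radians(52.25)  # half of the 104.5 deg H-O-H angle
        return [
            ("H", 0.96 * (math.cos(a) * u + math.sin(a) * t1)),
            ("H", 0.96 * (math.cos(a) * u - math.sin(a) * t1)),
        ]
    if donor_class == "O_carboxylate":
        c = 1.29 * u
        o2 = c + 1.25 * (math.cos(math.radians(60)) * u + math.sin(math.radians(60)) * t1)
        return [("C", c), ("O", o2)]
    if donor_class == "N_amine":
        a = math.radians(70.5)  # near-tetrahedral, lone pair toward the metal
        out = []
        for az in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            d = math.cos(a) * u + math.sin(a) * (np.cos(az) * t1 + np.sin(az) * t2)
            out.append(("C", 1.47 * d))
        return out
    if donor_class == "N_pyridine":
        s = 1.39  # aromatic C-C/C-N bond, also the circumradius of the hexagon
        center = s * u
        out = []
        for k in range(1, 6):
            ang = k * np.pi / 3
            out.append(("C", center + s * (-np.cos(ang) * u + np.sin(ang) * t1)))
        return out
    raise ChelastabError(f"no decoration template for class {donor_class!r}")


def _classification_ok(structure: ComplexStructure, intended: dict[int, str]) -> bool:
    """True iff the donor classifier recovers exactly the intended classes.

    This, not a hard-sphere margin, is the generator's acceptance criterion:
    decorations of neighbouring donors may approach each other (as substituents
    in real crowded chelates do), as long as no spurious contact changes any
    donor's perceived chemistry.
    """
    found = {c.atom_index: c.donor_class for c in classify_donors(structure)}
    return found == intended


def generate_paired_structures(
    spec: GeometryGenSpec,
) -> list[tuple[ComplexStructure, ComplexStructure, pd.DataFrame]]:
    """Generate (ref, cmp, truth) triples with identical atom ordering.

    Donors sit at quasi-uniform directions; the reference distance is
    r_ref(class) + N(0, sd^2) and the comparison distance adds the true
    offset ``delta_r`` plus independent noise.  Each donor carries the
    minimal substituent fragment that the donor classifier recognizes as the
    intended class.  Orientations are re-drawn (up to 100 attempts) whenever
    a spurious inter-donor contact changes any donor's perceived class.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_complexes)
    classes: list[str] = []
    for cls, cnt in spec.donor_counts.items():
        if cls not in DEFAULT_R_REF and cls not in spec.r_ref:
            raise ChelastabError(f"no reference distance for class {cls!r}")
        classes.extend([cls] * cnt)
    dirs = _fibonacci_directions(len(classes))

    out = []
    for ic, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        label = f"SYN{ic:02d}"
        for attempt in range(100):
            rots = rng.uniform(0, 2 * np.pi, size=len(classes))
            noise_ref = np.array([rng.normal(0, spec.sd_for(c)) for c in classes])
            noise_cmp = np.array([rng.normal(0, spec.sd_for(c)) for c in classes])
            syms: list[str] = [spec.ref_metal]
            crd_ref: list[np.ndarray] = [np.zeros(3)]
            crd_cmp: list[np.ndarray] = [np.zeros(3)]
            intended: dict[int, str] = {}
            truth_rows = []
            for k, cls in enumerate(classes):
                u = dirs[k]
                t1, t2 = _tangent_frame(u, rots[k])
                r0 = spec.r_ref[cls]
                d_ref = r0 + noise_ref[k]
                d_cmp = r0 + spec.delta_r + noise_cmp[k]
                donor_el = cls.split("_")[0]
                truth_rows.append(
                    {
                        "complex": label,
                        "atom_index": len(syms),
                        "donor_class": cls,
                        "r_ref_nominal": r0,
                        "d_ref": d_ref,
                        "d_cmp": d_cmp,
                        "delta_r_true": spec.delta_r,
                        "delta_realized": d_cmp - d_ref,
                    }
                )
                deco = _decoration(cls, u, t1, t2)
                intended[len(syms)] = cls
                syms.append(donor_el)
                crd_ref.append(d_ref * u)
                crd_cmp.append(d_cmp * u)
                for el, off in deco:
                    syms.append(el)
                    crd_ref.append(d_ref * u + off)
                    crd_cmp.append(d_cmp * u + off)
            coords_ref = np.vstack(crd_ref)
            coords_cmp = np.vstack(crd_cmp)
            ref = ComplexStructure(label, tuple(syms), coords_ref, 0)
            cmp_syms = (spec.cmp_metal,) + tuple(syms[1:])
            cmp_ = ComplexStructure(label, cmp_syms, coords_cmp, 0)
            if _classification_ok(ref, intended) and _classification_ok(cmp_, intended):
                break
        else:
            raise GenerationError(
                f"{label}: steric overlap between donor groups breaks donor "
                f"classification even after 100 orientation retries"
            )
        truth = pd.DataFrame(truth_rows)
        truth.attrs["seed"] = spec.seed
        truth.attrs["delta_r"] = spec.delta_r
        out.append((ref, cmp_, truth))
    return out


# ---------------------------------------------------------------------------
# EDA tables
# ---------------------------------------------------------------------------

def generate_eda_tables(
    n: int, seed: int, round_1dp: bool = False
) -> tuple[list[EdaTerms], list[EdaTerms]]:
    """Paired (Ac, La) EDA term lists whose identities hold by construction.

    Component magnitudes are drawn from ranges typical of trivalent
    metal-polyaminocarboxylate interactions (electrostatics dominant and
    attractive, Pauli repulsive, induction/dispersion large and opposing);
    E_pol and E_int are then *set* from the identities.  With
    ``round_1dp=True`` the output emulates one-decimal table truncation,
    after which identities hold only to ~0.15 kJ/mol.
    """
    if n < 1:
        raise ChelastabError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    ac, la = [], []
    for i in range(n):
        lig = f"L{i:02d}"
        e_elec = rng.uniform(-6000.0, -3000.0)
        e_pauli = rng.uniform(200.0, 500.0)
        e_ind = rng.uniform(-2000.0, -500.0)
        e_disp = rng.uniform(-600.0, -100.0)
        # Ac-minus-La offsets per component, spanning the observed sign patterns
        off = {
            "e_elec": rng.uniform(-650.0, 50.0),
            "e_pauli": rng.uniform(250.0, 320.0),
            "e_ind": rng.uniform(300.0, 1400.0),
            "e_disp": rng.uniform(-1250.0, -450.0),
        }
        def build(metal, base):
            e_e, e_p, e_i, e_d = base
            e_pol = e_i + e_d
            e_int = e_e + e_p + e_i + e_d
            vals = [e_int, e_e, e_p, e_i, e_d, e_pol]
            if round_1dp:
                vals = [round(v, 1) for v in vals]
            return EdaTerms(lig, metal, *vals)

        la.append(build("La", (e_elec, e_pauli, e_ind, e_disp)))
        ac.append(
            build(
                "Ac",
                (
                    e_elec + off["e_elec"],
                    e_pauli + off["e_pauli"],
                    e_ind + off["e_ind"],
                    e_disp + off["e_disp"],
                ),
            )
        )
    return ac, la


# ---------------------------------------------------------------------------
# Equilibrium cases and the brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_pm(
    model: EquilibriumModel,
    total_m: float = 1e-6,
    total_l: float = 1e-5,
    ph: float = 7.4,
    resid_tol: float = 1e-6,
) -> float:
    """pM by grid scan + bisection on (log10[M], log10[L]).

    Independent of the Newton solver: the mass balances are re-evaluated
    locally and each is driven to a relative residual below ``resid_tol``
    by a sign-change grid scan followed by bisection.  The inner loop
    solves the ligand balance for a trial free-metal value; the outer loop
    bisects the metal balance.
    """

    def totals(xm: float, xl: float) -> tuple[float, float]:
        tm, tl = 10.0**xm, 10.0**xl
        for sp in model.species:
            logc = sp.logbeta + sp.m * xm + sp.l * xl - sp.h * ph
            c = 10.0**logc if logc > -300 else 0.0
            tm += sp.m * c
            tl += sp.l * c
        return tm, tl

    def solve_l(xm: float) -> float:
        top = math.log10(total_l)
        if totals(xm, top)[1] - total_l <= resid_tol * total_l:
            return top
        lo, hi = None, top
        x = top
        for _ in range(90):
            x -= 0.5
            if totals(xm, x)[1] - total_l < 0:
                lo = x
                break
            hi = x
        if lo is None:
            raise ConvergenceError("oracle: ligand balance not bracketed")
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if totals(xm, mid)[1] - total_l < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def m_resid(xm: float) -> float:
        return totals(xm, solve_l(xm))[0] - total_m

    top = math.log10(total_m)
    if abs(m_resid(top)) <= resid_tol * total_m:
        xm = top
    else:
        lo, hi = None, top
        x = top
        for _ in range(90):
            x -= 0.5
            if m_resid(x) < 0:
                lo = x
                break
            hi = x
        if lo is None:
            raise ConvergenceError("oracle: metal balance not bracketed")
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if m_resid(mid) < 0:
                lo = mid
            else:
                hi = mid
        xm = 0.5 * (lo + hi)
    xl = solve_l(xm)
    tm, tl = totals(xm, xl)
    if abs(tm - total_m) > resid_tol * total_m or abs(tl - total_l) > resid_tol * total_l:
        raise ConvergenceError(
            f"oracle residuals too large: {abs(tm - total_m) / total_m:.2e}, "
            f"{abs(tl - total_l) / total_l:.2e}"
        )
    return -xm


def generate_equilibrium_case(spec: EquilibriumGenSpec) -> tuple[EquilibriumModel, float]:
    """Random M/L/H model plus its oracle pM.

    The model combines up to four cumulative ligand-protonation species with
    an ML complex and optional protonated-complex species.  If the oracle
    fails to bracket a balance the case is regenerated from the next
    substream (logged), so the returned pair is always solved.
    """
    root = np.random.SeedSequence(spec.seed)
    for sub in root.spawn(32):
        rng = np.random.default_rng(sub)
        n = spec.n_species if spec.n_species is not None else int(rng.integers(1, 9))
        n_prot = int(rng.integers(0, min(4, n) + 1))
        n_cplx = n - n_prot
        species: list[Species] = []
        # descending stepwise protonation constants, cumulated into log beta
        steps = np.sort(rng.uniform(*spec.prot_step, size=n_prot))[::-1]
        acc = 0.0
        for i, st in enumerate(steps, start=1):
            acc += float(st)
            species.append(Species(0, 1, i, acc))
        if n_cplx > 0:
            logk = float(rng.uniform(*spec.logbeta_complex))
            species.append(Species(1, 1, 0, logk))
            acc = logk
            for i in range(1, n_cplx):
                acc += float(rng.uniform(*spec.complex_prot_step))
                species.append(Species(1, 1, i, acc))
        model = EquilibriumModel(tuple(species), label=f"rand-{spec.seed}")
        try:
            return model, brute_force_pm(model)
        except ConvergenceError:
            logger.warning("oracle failed for a generated case; next substream")
            continue
    raise GenerationError("could not generate a solvable equilibrium case in 32 tries")
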