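"""Fixed-pH M/L/H equilibrium speciation and pM values.

A model is a set of species M_m L_l H_h with cumulative formation constants
log beta relative to free metal M, fully deprotonated ligand L and the
proton, so that

    [M_m L_l H_h] = 10^logbeta [M]^m [L]^l [H]^h .

At buffered pH the proton activity is fixed at [H] = 10^-pH (the proton
balance is not solved; h may be negative for hydroxo species) and the two
mass balances

    C_M = [M] + sum m [species],    C_L = [L] + sum l [species]

are solved for the free concentrations by damped Newton iteration in
(log10[M], log10[L]), which is robust against the stiff exponents of large
formation constants.

pM = -log10([M]free) at pH 7.4 with C_M = 1 uM and C_L = 10 uM is the
conventional conditional measure of metal sequestration: unlike log K it
accounts for ligand basicity (protonation competes with the metal at
physiological pH).

Constants are used at their reported ionic strengths as-is; no activity
corrections are applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChelastabError, ConvergenceError

logger = logging.getLogger(__name__)

PM_TOTAL_M = 1e-6
PM_TOTAL_L = 1e-5
PM_PH = 7.4

LN10 = np.log(10.0)


@dataclass(frozen=True)
class Species:
    """One species m M + l L + h H = M_m L_l H_h with cumulative log beta."""

    m: int
    l: int
    h: int
    logbeta: float

    def __post_init__(self):
        if not np.isfinite(self.logbeta):
            raise ChelastabError("log beta must be finite")

    @property
    def name(self) -> str:
        def part(sym, k):
            if k == 0:
                return ""
            if sym == "H" and k < 0:
                return f"(OH){-k}" if k < -1 else "(OH)"
            return sym if k == 1 else f"{sym}{k}"

        return (part("M", self.m) + part("L", self.l) + part("H", self.h)) or "free"


@dataclass(frozen=True)
class EquilibriumModel:
    """Species list over components (M, L, H); free M and L are implicit."""

    species: tuple[Species, ...]
    label: str = ""

    def __post_init__(self):
        stoich = [(s.m, s.l, s.h) for s in self.species]
        if len(set(stoich)) != len(stoich):
            raise ChelastabError("duplicate species stoichiometries")
        if any(st in ((1, 0, 0), (0, 1, 0)) for st in stoich):
            raise ChelastabError(
                "free components (1,0,0)/(0,1,0) are implicit; do not list them"
            )
        if any(s.m > 1 or s.l > 1 for s in self.species):
            warnings.warn("species with m>1 or l>1 are supported but untested "
                          "against reference speciation output")

    @classmethod
    def from_constants(
        cls,
        logK_ml: float,
        ligand_logKH: tuple[float, ...] = (),
        complex_logKH: tuple[float, ...] = (),
        label: str = "",
    ) -> "EquilibriumModel":
        """Build from stepwise constants.

        ``logK_ml`` is the ML stability constant; ``ligand_logKH`` are the
        stepwise ligand protonation constants (log K_H1, log K_H2, ...), and
        ``complex_logKH`` the stepwise protonation constants of the complex.
        Cumulative constants: beta(0,1,i) = sum_{j<=i} logK_Hj, and
        beta(1,1,i) = logK_ml + sum of complex steps.
        """
        sp = [Species(1, 1, 0, logK_ml)]
        acc = 0.0
        for i, lk in enumerate(ligand_logKH, start=1):
            acc += lk
            sp.append(Species(0, 1, i, acc))
        acc = logK_ml
        for i, lk in enumerate(complex_logKH, start=1):
            acc += lk
            sp.append(Species(1, 1, i, acc))
        return cls(tuple(sp), label=label)

    def solve(self, total_m: float, total_l: float, ph: float) -> "SpeciationResult":
        return solve_equilibrium(self, total_m, total_l, ph)

    def pm(self) -> float:
        return pM(self)


@dataclass(frozen=True)
class SpeciationResult:
    """Converged free concentrations and per-species concentrations (mol/L)."""

    free_m: float
    free_l: float
    ph: float
    total_m: float
    total_l: float
    concentrations: dict[Species, float]
    residual_m: float  # relative mass-balance residuals
    residual_l: float

    @property
    def pm(self) -> float:
        return -float(np.log10(self.free_m))

    def fractions_of_m(self) -> dict[str, float]:
        """Fraction of total metal in each M-containing species (plus free M)."""
        out = {"M": self.free_m / self.total_m}
        for sp, c in self.concentrations.items():
            if sp.m > 0:
                out[sp.name] = sp.m * c / self.total_m
        return out

    def summary(self) -> str:
        lines = [
            f"pH {self.ph:.2f}, C_M = {self.total_m:.3g} M, C_L = {self.total_l:.3g} M",
            f"free [M] = {self.free_m:.6g} M  (pM = {self.pm:.3f})",
            f"free [L] = {self.free_l:.6g} M",
            f"mass-balance residuals: {self.residual_m:.2e} (M), {self.residual_l:.2e} (L)",
        ]
        for sp, c in sorted(self.concentrations.items(), key=lambda kv: -kv[1]):
            lines.append(f"  [{sp.name}] = {c:.6g} M  (log beta {sp.logbeta:g})")
        return "\n".join(lines)


def _balances(model: EquilibriumModel, xm: float, xl: float, ph: float):
    """Totals and sensitivity sums at log10 free concentrations (xm, xl).

    Returns (T_M, T_L, concs, S_mm, S_ml, S_ll) where S_ab = sum of
    stoichiometry-weighted concentrations, so that d T_M / d xm =
    ln10 * S_mm etc.
    """
    cm = 10.0**xm
    cl = 10.0**xl
    tm, tl = cm, cl
    s_mm, s_ml, s_ll = cm, 0.0, cl
    concs = []
    for sp in model.species:
        logc = sp.logbeta + sp.m * xm + sp.l * xl - sp.h * ph
        c = 10.0**logc if logc > -300 else 0.0
        concs.append(c)
        tm += sp.m * c
        tl += sp.l * c
        s_mm += sp.m * sp.m * c
        s_ml += sp.m * sp.l * c
        s_ll += sp.l * sp.l * c
    return tm, tl, concs, s_mm, s_ml, s_ll


def solve_equilibrium(
    model: EquilibriumModel,
    total_m: float,
    total_l: float,
    ph: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> SpeciationResult:
    """Solve the two mass balances at fixed pH by damped Newton iteration.

    Unknowns are (log10[M], log10[L]).  The Newton residuals are the
    *logarithmic* balance errors log10(T/C): with cumulative constants
    spanning tens of orders of magnitude the linear residuals vary over an
    enormous range, while the log form keeps steps well scaled.

    When a single complex dominates both balances the Jacobian is nearly
    singular and the residual surface develops a long flat valley along the
    (d log[M], d log[L]) = (-1, +1) direction.  Each iteration therefore
    tries two step candidates, each rescaled to at most 20 log units and
    halved (at most 60 times) until the residual norm decreases: first the
    exact Newton step (which traverses the valley), then the rank-truncated
    pseudoinverse step (pure descent in the well-determined direction).
    Deterministic for fixed inputs.  Convergence: relative linear residuals
    |T/C - 1| below ``tol``.
    """
    if total_m <= 0 or total_l <= 0:
        raise ChelastabError("total concentrations must be positive")
    if not 0 <= ph <= 14:
        raise ChelastabError("pH must lie in [0, 14]")
    xm = float(np.log10(total_m)) - 3.0
    xl = float(np.log10(total_l)) - 3.0

    def evaluate(xm_, xl_):
        tm, tl, concs, s_mm, s_ml, s_ll = _balances(model, xm_, xl_, ph)
        f = np.array([np.log10(tm / total_m), np.log10(tl / total_l)])
        rel = np.array([tm / total_m - 1.0, tl / total_l - 1.0])
        jac = np.array([[s_mm / tm, s_ml / tm], [s_ml / tl, s_ll / tl]])
        return f, rel, jac, concs

    max_step = 20.0

    def line_search(step, norm0):
        big = float(np.max(np.abs(step)))
        if big == 0.0:
            return None
        if big > max_step:
            step = step * (max_step / big)
        lam = 1.0
        for _halve in range(60):
            xm_n, xl_n = xm + lam * step[0], xl + lam * step[1]
            f_n, rel_n, jac_n, concs_n = evaluate(xm_n, xl_n)
            if float(np.linalg.norm(f_n)) < norm0:
                return xm_n, xl_n, f_n, rel_n, jac_n, concs_n
            lam *= 0.5
        return None

    f, rel, jac, concs = evaluate(xm, xl)
    for _ in range(max_iter):
        if float(np.max(np.abs(rel))) < tol:
            break
        norm0 = float(np.linalg.norm(f))
        exact = np.linalg.lstsq(jac, -f, rcond=None)[0]
        truncated = np.linalg.lstsq(jac, -f, rcond=1e-6)[0]
        state = line_search(exact, norm0) or line_search(truncated, norm0)
        if state is None:
            raise ConvergenceError(
                "damping exhausted (60 halvings) without residual decrease",
                last_iterate={"log_m": xm, "log_l": xl, "residuals": rel.tolist()},
            )
        xm, xl, f, rel, jac, concs = state
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} Newton iterations",
            last_iterate={"log_m": xm, "log_l": xl, "residuals": rel.tolist()},
        )
    return SpeciationResult(
        free_m=10.0**xm,
        free_l=10.0**xl,
        ph=ph,
        total_m=total_m,
        total_l=total_l,
        concentrations=dict(zip(model.species, concs)),
        residual_m=abs(float(rel[0])),
        residual_l=abs(float(rel[1])),
    )


def pM(
    model: EquilibriumModel,
    total_m: float = PM_TOTAL_M,
    total_l: float = PM_TOTAL_L,
    ph: float = PM_PH,
) -> float:
    """pM = -log10([M]free) at pH 7.4, C_M = 1 uM, C_L = 10 uM (defaults)."""
    return solve_equilibrium(model, total_m, total_l, ph).pm


def speciation_curve(
    model: EquilibriumModel,
    total_m: float,
    total_l: float,
    ph_grid,
) -> pd.DataFrame:
    """Fractions of total metal in each M-containing species across a pH grid.

    Failed grid points are flagged in the ``converged`` column, not dropped.
    """
    ph_grid = np.asarray(ph_grid, dtype=float)
    if np.any(np.diff(ph_grid) <= 0):
        raise ChelastabError("pH grid must be strictly increasing")
    rows = []
    for ph in ph_grid:
        row: dict = {"pH": float(ph), "converged": True}
        try:
            res = solve_equilibrium(model, total_m, total_l, float(ph))
            row.update(res.fractions_of_m())
        except ConvergenceError:
            row["converged"] = False
            logger.warning("speciation_curve: no convergence at pH %.3f", ph)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model file I/O: "m l h logbeta" lines, in the spirit of equilibrium decks
# ---------------------------------------------------------------------------

def read_model(path: str | Path) -> EquilibriumModel:
    """Read a structured-text model: header line 'chelastab-model v1', then
    one 'm l h logbeta' line per species ('#' comments allowed)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines or not lines[0].startswith("chelastab-model"):
        raise ChelastabError(f"{path}: missing 'chelastab-model v1' header")
    sp = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 4:
            raise ChelastabError(f"{path}: bad species line {ln!r}")
        sp.append(Species(int(parts[0]), int(parts[1]), int(parts[2]), float(parts[3])))
    return EquilibriumModel(tuple(sp), label=Path(path).stem)


def write_model(model: EquilibriumModel, path: str | Path) -> None:
    out = ["chelastab-model v1", "# m l h logbeta"]
    for sp in model.species:
        out.append(f"{sp.m} {sp.l} {sp.h} {sp.logbeta:.6g}")
    Path(path).write_text("\n".join(out) + "\n")
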