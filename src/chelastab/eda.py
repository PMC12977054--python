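"""Energy-decomposition-analysis bookkeeping.

Houses per-complex EDA terms (kJ/mol) and enforces the two decomposition
identities of the density-based scheme used here:

    E_int = E_elec + E_pauli + E_pol          (three-term form)
    E_int = E_elec + E_pauli + E_ind + E_disp (with E_pol = E_ind + E_disp)

E_int is the gas-phase metal-ligand interaction energy E(ML) - [E(M) + E(L)];
it enters as an input quantity and is never recomputed here.  Relative terms
dE = E_Ac - E_La compare how each component shifts between the two ions:
negative values favour the Ac complex.

The default validation tolerance of 0.15 kJ/mol accommodates tables printed
to one decimal, where a four-term sum can disagree with the printed total by
pure rounding.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ChelastabError, FixtureIntegrityError

DEFAULT_TOL_KJMOL = 0.15
COMPONENTS = ("e_elec", "e_pauli", "e_ind", "e_disp")

_TABLE1_SHA256 = "34c19523a24ac37713091412dddb1c9210bb50377dc2383c1ccbfbe35ada545d"


@dataclass(frozen=True)
class EdaTerms:
    """Absolute EDA terms for one complex (kJ/mol)."""

    ligand: str
    metal: str
    e_int: float
    e_elec: float
    e_pauli: float
    e_ind: float
    e_disp: float
    e_pol: float


@dataclass(frozen=True)
class EdaDelta:
    """Ac-minus-La relative EDA terms for one ligand (kJ/mol)."""

    ligand: str
    de_int: float
    de_elec: float
    de_pauli: float
    de_ind: float
    de_disp: float
    de_pol: float


@dataclass(frozen=True)
class IdentityCheck:
    name: str
    residual: float
    tol: float

    @property
    def passed(self) -> bool:
        return abs(self.residual) <= self.tol


@dataclass(frozen=True)
class ValidationReport:
    ligand: str
    checks: tuple[IdentityCheck, ...]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        rows = [
            f"  {c.name}: residual {c.residual:+.3f} kJ/mol "
            f"({'pass' if c.passed else 'FAIL'} at {c.tol})"
            for c in self.checks
        ]
        return f"{self.ligand}:\n" + "\n".join(rows)


def _six(terms) -> tuple[float, float, float, float, float, float]:
    """(int, elec, pauli, ind, disp, pol) from either EdaTerms or EdaDelta."""
    if isinstance(terms, EdaTerms):
        keys = ("e_int", "e_elec", "e_pauli", "e_ind", "e_disp", "e_pol")
    elif isinstance(terms, EdaDelta):
        keys = ("de_int", "de_elec", "de_pauli", "de_ind", "de_disp", "de_pol")
    else:
        raise ChelastabError(f"expected EdaTerms or EdaDelta, got {type(terms).__name__}")
    vals = []
    for k in keys:
        v = getattr(terms, k, None)
        if v is None:
            raise ChelastabError(f"missing EDA field {k!r}")
        vals.append(float(v))
    return tuple(vals)  # type: ignore[return-value]


def validate_terms(terms, tol: float = DEFAULT_TOL_KJMOL) -> ValidationReport:
    """Check both decomposition identities; residuals reported per identity."""
    if tol <= 0:
        raise ChelastabError("tolerance must be positive")
    e_int, e_elec, e_pauli, e_ind, e_disp, e_pol = _six(terms)
    checks = (
        IdentityCheck("int = elec + pauli + ind + disp",
                      e_int - (e_elec + e_pauli + e_ind + e_disp), tol),
        IdentityCheck("pol = ind + disp", e_pol - (e_ind + e_disp), tol),
        IdentityCheck("int = elec + pauli + pol",
                      e_int - (e_elec + e_pauli + e_pol), 2 * tol),
    )
    return ValidationReport(terms.ligand, checks)


def relative_terms(ac: EdaTerms, la: EdaTerms) -> EdaDelta:
    """Componentwise E_Ac - E_La for one ligand.

    Negative deltas mean the term contributes to an interaction more
    favourable for Ac3+ than for La3+.
    """
    if ac.ligand != la.ligand:
        raise ChelastabError(f"ligand mismatch: {ac.ligand!r} vs {la.ligand!r}")
    return EdaDelta(
        ligand=ac.ligand,
        de_int=ac.e_int - la.e_int,
        de_elec=ac.e_elec - la.e_elec,
        de_pauli=ac.e_pauli - la.e_pauli,
        de_ind=ac.e_ind - la.e_ind,
        de_disp=ac.e_disp - la.e_disp,
        de_pol=ac.e_pol - la.e_pol,
    )


def read_eda_table(path: str | Path) -> list[EdaTerms]:
    """Read a delimited EDA table: ligand, metal, E_int..E_pol (kJ/mol)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"ligand", "metal", "E_int", "E_elec", "E_pauli", "E_ind", "E_disp", "E_pol"}
    missing = required - set(df.columns)
    if missing:
        raise ChelastabError(f"{path}: missing columns {sorted(missing)}")
    return [
        EdaTerms(r.ligand, r.metal, r.E_int, r.E_elec, r.E_pauli,
                 r.E_ind, r.E_disp, r.E_pol)
        for r in df.itertuples()
    ]


def terms_to_frame(records: Iterable[EdaTerms | EdaDelta]) -> pd.DataFrame:
    rows = []
    for t in records:
        e_int, e_elec, e_pauli, e_ind, e_disp, e_pol = _six(t)
        row = {"ligand": t.ligand, "E_int": e_int, "E_elec": e_elec,
               "E_pauli": e_pauli, "E_ind": e_ind, "E_disp": e_disp, "E_pol": e_pol}
        if isinstance(t, EdaTerms):
            row["metal"] = t.metal
        rows.append(row)
    return pd.DataFrame(rows)


def _fixture_path() -> Path:
    return Path(str(resources.files("chelastab").joinpath("data/table1_eda_relative.tsv")))


def load_table1_fixture() -> list[EdaDelta]:
    """Load the packaged 17-row relative-EDA table (16 ligands + aqua ion).

    The file checksum is verified, and every record must pass both
    decomposition identities at the default tolerance.
    """
    path = _fixture_path()
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _TABLE1_SHA256:
        raise FixtureIntegrityError(
            f"table1 fixture checksum mismatch: {digest} != {_TABLE1_SHA256}"
        )
    df = pd.read_csv(path, sep="\t", comment="#")
    records = [
        EdaDelta(r.ligand, r.dE_int, r.dE_elec, r.dE_pauli, r.dE_ind, r.dE_disp, r.dE_pol)
        for r in df.itertuples()
    ]
    for rec in records:
        rep = validate_terms(rec)
        if not rep.ok:
            raise FixtureIntegrityError(f"fixture record fails identities:\n{rep}")
    return records
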