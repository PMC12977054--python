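"""Exchange-reaction thermodynamics: from dG298 to relative and absolute log K.

The free energy of the metal-exchange reaction

    [LaL] + Ac3+(aq)  =  [AcL] + La3+(aq)

converts directly into the difference of the two stability constants,

    dlogK(Ac-La) = log K_Ac - log K_La = -dG298 / (R T ln 10),

so an experimental La3+ constant yields a predicted Ac3+ constant:
log K_Ac = log K_La + dlogK.  A negative dG298 (exchange favours the Ac
complex) therefore means the Ac complex is the more stable one.

Units: dG in kJ/mol, T in kelvin, R = 8.31446 J/(mol K) (CODATA); log is
base 10.  Default temperature is the thermochemical standard 298.15 K.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ChelastabError, FixtureIntegrityError

logger = logging.getLogger(__name__)

R_J_MOL_K = 8.31446
T_STANDARD_K = 298.15
CONSISTENCY_TOL = 0.005  # dlogK units: half of the last printed digit

_TABLE2_SHA256 = "130852ee580588e0cf26cd8214b4d66fd78facf4b138c00d93022cdca08b3d9d"


@dataclass(frozen=True)
class ExchangeRecord:
    """Exchange free energy for one ligand, with optional experimental data.

    ``dg298``: kJ/mol for [LaL] + Ac3+(aq) = [AcL] + La3+(aq).
    ``logk_la``: experimental La3+ stability constant, if reported.
    ``dlogk_ref``: an externally supplied dlogK for consistency checking.
    """

    ligand: str
    dg298: float
    logk_la: float | None = None
    medium: str = ""
    reference: str = ""
    dlogk_ref: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.dg298):
            raise ChelastabError(f"{self.ligand}: non-finite dG298")
        if self.logk_la is not None and not 0 <= self.logk_la <= 35:
            raise ChelastabError(
                f"{self.ligand}: log K_La = {self.logk_la} outside plausible range 0-35"
            )


@dataclass(frozen=True)
class StabilityPrediction:
    ligand: str
    dlogk: float
    logk_ac: float | None


def delta_logK(dg298: float, T: float = T_STANDARD_K) -> float:
    """dlogK = -dG298 / (R T ln 10); dG in kJ/mol."""
    if T <= 0:
        raise ChelastabError("temperature must be positive")
    return -dg298 * 1000.0 / (R_J_MOL_K * T * math.log(10.0))


def predict_logK_ac(record: ExchangeRecord, T: float = T_STANDARD_K) -> StabilityPrediction:
    """Predict log K_Ac = log K_La + dlogK; absent if log K_La is unknown."""
    dlk = delta_logK(record.dg298, T)
    if record.logk_la is None:
        logger.info("%s: no experimental log K_La; log K_Ac left absent", record.ligand)
        return StabilityPrediction(record.ligand, dlk, None)
    return StabilityPrediction(record.ligand, dlk, record.logk_la + dlk)


def build_stability_table(
    records: Sequence[ExchangeRecord], T: float = T_STANDARD_K
) -> pd.DataFrame:
    """One prediction row per record, input order preserved.

    When a record carries a reference dlogK, the ``consistent`` column flags
    any row whose recomputed value deviates by more than 0.005 log units.
    Missing optional inputs propagate as missing values, never as zero.
    """
    if not records:
        raise ChelastabError("no exchange records supplied")
    labels = [r.ligand for r in records]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ChelastabError(f"duplicate ligand labels: {dupes}")
    rows = []
    for rec in records:
        pred = predict_logK_ac(rec, T)
        consistent = None
        if rec.dlogk_ref is not None:
            consistent = abs(pred.dlogk - rec.dlogk_ref) <= CONSISTENCY_TOL
        rows.append(
            {
                "ligand": rec.ligand,
                "dG298_kJmol": rec.dg298,
                "dlogK": pred.dlogk,
                "logK_la": rec.logk_la,
                "logK_ac": pred.logk_ac,
                "medium": rec.medium or None,
                "consistent": consistent,
            }
        )
    return pd.DataFrame(rows)


def read_exchange_records(path: str | Path) -> list[ExchangeRecord]:
    """Read a delimited table: ligand, dG298_kJmol, logK_la (blank ok), medium, ref."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"ligand", "dG298_kJmol"} <= set(df.columns):
        raise ChelastabError(f"{path}: need at least columns ligand, dG298_kJmol")
    out = []
    for r in df.itertuples():
        logk = getattr(r, "logK_la", None)
        out.append(
            ExchangeRecord(
                ligand=r.ligand,
                dg298=float(r.dG298_kJmol),
                logk_la=None if logk is None or pd.isna(logk) else float(logk),
                medium=str(getattr(r, "medium", "") or ""),
                reference=str(getattr(r, "ref", "") or ""),
            )
        )
    return out


def _fixture_path() -> Path:
    return Path(str(resources.files("chelastab").joinpath("data/table2_exchange.tsv")))


def load_table2_fixture() -> pd.DataFrame:
    """Packaged 16-ligand exchange table with printed reference columns."""
    path = _fixture_path()
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _TABLE2_SHA256:
        raise FixtureIntegrityError(
            f"table2 fixture checksum mismatch: {digest} != {_TABLE2_SHA256}"
        )
    return pd.read_csv(path, sep="\t", comment="#")


def table2_records() -> list[ExchangeRecord]:
    """The packaged exchange table as ExchangeRecord objects."""
    df = load_table2_fixture()
    return [
        ExchangeRecord(
            ligand=r.ligand,
            dg298=float(r.dG298_kJmol),
            logk_la=None if pd.isna(r.logK_la) else float(r.logK_la),
            medium="" if pd.isna(r.medium) else str(r.medium),
            dlogk_ref=None if pd.isna(r.dlogK_ref) else float(r.dlogK_ref),
        )
        for r in df.itertuples()
    ]
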