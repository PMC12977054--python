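"""Complex geometries, donor perception, and paired-distance analysis.

Reads standard XYZ geometries of metal complexes, identifies the metal's
inner coordination sphere, assigns a chemical class to every O/N donor from
its covalent environment, and pairs equivalent donors between two analogues
of the same ligand (e.g. the La3+ and Ac3+ complexes) to obtain per-donor
bond-length differences  delta_d = d_cmp - d_ref.

Donor classes are perceived heuristically from the bond graph (covalent-radius
distance criterion); the rules are documented on :func:`classify_donors` and
are configurable via module-level defaults.  All coordinates are Angstrom and
are stored exactly as read — no recentering, no reordering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .atomdata import covalent_radius
from .errors import (
    ChelastabError,
    EmptySelectionError,
    MultipleMetalAtomsError,
    NoMetalAtomError,
    StructureMismatchError,
    XYZFormatError,
)

logger = logging.getLogger(__name__)

DEFAULT_METALS = ("La", "Ac")
DEFAULT_CUTOFF_A = 3.1   # coordination cutoff: longest reported inner-sphere
                         # contact (~2.71 A) plus margin, short of second sphere
DEFAULT_BOND_SCALE = 1.3

DONOR_CLASSES = (
    "O_carboxylate",
    "O_amide",
    "O_ether",
    "O_water",
    "O_phenolate",
    "N_pyridine",
    "N_amine",
    "N_amide",
    "other",
)


@dataclass(frozen=True)
class ComplexStructure:
    """A molecular structure with one designated metal center.

    Atom order is preserved from the input file; ``coords`` is (n, 3) in
    Angstrom.
    """

    label: str
    symbols: tuple[str, ...]
    coords: np.ndarray
    metal_index: int

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.symbols), 3):
            raise ChelastabError(
                f"coords shape {coords.shape} inconsistent with "
                f"{len(self.symbols)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ChelastabError("non-finite coordinates")
        if not 0 <= self.metal_index < len(self.symbols):
            raise ChelastabError("metal_index out of range")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def metal_symbol(self) -> str:
        return self.symbols[self.metal_index]

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))


@dataclass(frozen=True)
class DonorContact:
    """One metal-donor contact of the inner coordination sphere."""

    atom_index: int
    element: str
    donor_class: str
    distance: float

    def __post_init__(self):
        if self.distance <= 0:
            raise ChelastabError("donor distance must be positive")
        if self.donor_class not in DONOR_CLASSES:
            raise ChelastabError(f"unknown donor class {self.donor_class!r}")
        if self.donor_class != "other" and not self.donor_class.startswith(
            self.element + "_"
        ):
            raise ChelastabError(
                f"class {self.donor_class} inconsistent with element {self.element}"
            )


@dataclass(frozen=True)
class ContactPair:
    """Equivalent donor matched across two metal analogues of one ligand.

    ``delta = d_cmp - d_ref`` (positive when the comparison metal sits
    farther from the donor).
    """

    ligand: str
    donor_class: str
    atom_index_ref: int
    atom_index_cmp: int
    d_ref: float
    d_cmp: float

    @property
    def delta(self) -> float:
        return self.d_cmp - self.d_ref


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def read_xyz(
    path: str | Path,
    metals: Sequence[str] = DEFAULT_METALS,
    label: str | None = None,
) -> ComplexStructure:
    """Read a standard XYZ file (count line, comment, 'El x y z' lines, A).

    The metal center is the single atom whose element is in ``metals``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file")
    try:
        n_decl = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZFormatError(f"{path}: malformed atom-count line {lines[0]!r}") from None
    body = [ln for ln in lines[2 : 2 + n_decl]]
    if len(body) < n_decl:
        raise XYZFormatError(
            f"{path}: declared {n_decl} atoms but only {len(body)} atom lines"
        )
    symbols: list[str] = []
    coords = np.empty((n_decl, 3), dtype=float)
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZFormatError(f"{path}: atom line {i + 3} too short: {ln!r}")
        symbols.append(parts[0])
        try:
            coords[i] = [float(x) for x in parts[1:4]]
        except ValueError:
            raise XYZFormatError(
                f"{path}: non-numeric coordinate on line {i + 3}: {ln!r}"
            ) from None
    metal_set = set(metals)
    metal_ids = [i for i, s in enumerate(symbols) if s in metal_set]
    if not metal_ids:
        raise NoMetalAtomError(f"{path}: no atom from metal set {sorted(metal_set)}")
    if len(metal_ids) > 1:
        raise MultipleMetalAtomsError(
            f"{path}: {len(metal_ids)} metal atoms at indices {metal_ids}"
        )
    return ComplexStructure(
        label=label if label is not None else path.stem,
        symbols=tuple(symbols),
        coords=coords,
        metal_index=metal_ids[0],
    )


def write_xyz(structure: ComplexStructure, path: str | Path, comment: str = "") -> None:
    """Write a standard XYZ file; coordinates at 6 decimals."""
    path = Path(path)
    out = [str(structure.n_atoms), comment or structure.label]
    for sym, (x, y, z) in zip(structure.symbols, structure.coords):
        out.append(f"{sym} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Bond perception and donor classification
# ---------------------------------------------------------------------------

def bond_graph(structure: ComplexStructure, scale: float = DEFAULT_BOND_SCALE) -> nx.Graph:
    """Distance-criterion bond graph over the non-metal atoms.

    Atoms i, j are bonded iff d(i,j) <= scale * (r_cov(i) + r_cov(j)).
    The metal atom is excluded (its dative contacts are handled by the
    coordination cutoff, not by covalent radii).
    """
    if scale <= 0:
        raise ChelastabError("bond scale must be positive")
    g = nx.Graph()
    idx = [i for i in range(structure.n_atoms) if i != structure.metal_index]
    g.add_nodes_from(idx)
    radii = {i: covalent_radius(structure.symbols[i]) for i in idx}
    for a, i in enumerate(idx):
        for j in idx[a + 1 :]:
            if structure.distance(i, j) <= scale * (radii[i] + radii[j]):
                g.add_edge(i, j)
    return g


def _ring_atoms(graph: nx.Graph, sizes: tuple[int, ...] = (5, 6)) -> set[int]:
    """Atoms belonging to any minimum-cycle-basis ring of the given sizes."""
    members: set[int] = set()
    for cyc in nx.minimum_cycle_basis(graph):
        if len(cyc) in sizes:
            members.update(cyc)
    return members


def _classify_one(
    i: int, structure: ComplexStructure, graph: nx.Graph, rings: set[int]
) -> str:
    """Apply the donor-class rules to atom ``i`` (an O or N).

    Rule order (first match wins):

    O: water (>=2 H neighbours) -> carboxylate (the C neighbour carries exactly
    one other O, terminal) -> amide (on a C that also bonds N) -> phenolate
    (single neighbour, a ring C) -> ether (two C neighbours, no H).

    N: pyridine (exactly two heavy neighbours, both ring members, N in the
    ring) -> amide (bonded to a carbonyl C) -> amine (three sigma-neighbours,
    not in a ring).
    """
    sym = structure.symbols[i]
    nbrs = list(graph.neighbors(i))
    nbr_syms = [structure.symbols[j] for j in nbrs]

    def is_carbonyl_c(c: int) -> bool:
        # C bearing a terminal O (degree-1 oxygen)
        for k in graph.neighbors(c):
            if k != i and structure.symbols[k] == "O" and graph.degree[k] == 1:
                return True
        return False

    if sym == "O":
        if nbr_syms.count("H") >= 2:
            return "O_water"
        c_nbrs = [j for j, s in zip(nbrs, nbr_syms) if s == "C"]
        for c in c_nbrs:
            other_o = [
                k for k in graph.neighbors(c) if k != i and structure.symbols[k] == "O"
            ]
            if len(other_o) == 1 and graph.degree[other_o[0]] == 1:
                return "O_carboxylate"
        for c in c_nbrs:
            if any(structure.symbols[k] == "N" for k in graph.neighbors(c)):
                return "O_amide"
        if len(nbrs) == 1 and nbr_syms[0] == "C" and nbrs[0] in rings:
            return "O_phenolate"
        if len(nbrs) == 2 and nbr_syms == ["C", "C"]:
            return "O_ether"
        return "other"

    if sym == "N":
        heavy = [j for j, s in zip(nbrs, nbr_syms) if s != "H"]
        if len(heavy) == 2 and i in rings and all(j in rings for j in heavy):
            return "N_pyridine"
        if any(structure.symbols[j] == "C" and is_carbonyl_c(j) for j in nbrs):
            return "N_amide"
        if len(nbrs) == 3 and i not in rings:
            return "N_amine"
        return "other"

    return "other"


def classify_donors(
    structure: ComplexStructure,
    cutoff: float = DEFAULT_CUTOFF_A,
    scale: float = DEFAULT_BOND_SCALE,
) -> list[DonorContact]:
    """Find and classify every O/N donor within ``cutoff`` of the metal.

    Returns contacts sorted by atom index.  A donor matching none of the
    rules is kept with class ``"other"`` and a logged warning — never
    silently dropped.
    """
    if cutoff <= 0:
        raise ChelastabError("cutoff must be positive")
    graph = bond_graph(structure, scale=scale)
    rings = _ring_atoms(graph)
    m = structure.metal_index
    contacts: list[DonorContact] = []
    for i in range(structure.n_atoms):
        if i == m or structure.symbols[i] not in ("O", "N"):
            continue
        d = structure.distance(m, i)
        if d > cutoff:
            continue
        cls = _classify_one(i, structure, graph, rings)
        if cls == "other":
            logger.warning(
                "%s: donor %s%d at %.3f A matched no classification rule",
                structure.label, structure.symbols[i], i, d,
            )
        contacts.append(
            DonorContact(atom_index=i, element=structure.symbols[i],
                         donor_class=cls, distance=d)
        )
    return contacts


# ---------------------------------------------------------------------------
# Pairing and statistics
# ---------------------------------------------------------------------------

def pair_contacts(
    ref: ComplexStructure,
    cmp: ComplexStructure,
    mode: str = "by_index",
    cutoff: float = DEFAULT_CUTOFF_A,
    ligand: str | None = None,
) -> list[ContactPair]:
    """Match equivalent donors of two analogues and return distance deltas.

    ``by_index`` (default) assumes the paired optimizations share atom
    ordering and matches donors occurring at the same atom index; a
    different element at any matched index is a hard failure.  ``by_class``
    matches donors of the same class by rank order of distance and warns,
    reporting any unmatched donors.
    """
    if mode not in ("by_index", "by_class"):
        raise ChelastabError(f"unknown pairing mode {mode!r}")
    lig = ligand if ligand is not None else ref.label
    c_ref = classify_donors(ref, cutoff=cutoff)
    c_cmp = classify_donors(cmp, cutoff=cutoff)
    if not c_ref or not c_cmp:
        raise EmptySelectionError("one of the structures has no donor contacts")

    pairs: list[ContactPair] = []
    if mode == "by_index":
        if len(ref.symbols) != len(cmp.symbols):
            raise StructureMismatchError(
                f"{ref.label}/{cmp.label}: atom counts differ "
                f"({ref.n_atoms} vs {cmp.n_atoms})"
            )
        cmp_by_idx = {c.atom_index: c for c in c_cmp}
        for rc in c_ref:
            if ref.symbols[rc.atom_index] != cmp.symbols[rc.atom_index]:
                raise StructureMismatchError(
                    f"element mismatch at index {rc.atom_index}: "
                    f"{ref.symbols[rc.atom_index]} vs {cmp.symbols[rc.atom_index]}"
                )
            cc = cmp_by_idx.get(rc.atom_index)
            if cc is None:
                warnings.warn(
                    f"donor at index {rc.atom_index} of {ref.label} has no "
                    f"counterpart within cutoff in {cmp.label}"
                )
                continue
            pairs.append(
                ContactPair(lig, rc.donor_class, rc.atom_index, cc.atom_index,
                            rc.distance, cc.distance)
            )
    else:
        warnings.warn("by_class pairing is a fallback; donors matched by rank order")
        classes = sorted({c.donor_class for c in c_ref} | {c.donor_class for c in c_cmp})
        for cls in classes:
            a = sorted((c for c in c_ref if c.donor_class == cls), key=lambda c: c.distance)
            b = sorted((c for c in c_cmp if c.donor_class == cls), key=lambda c: c.distance)
            n = min(len(a), len(b))
            if len(a) != len(b):
                warnings.warn(
                    f"class {cls}: {len(a)} ref vs {len(b)} cmp donors; "
                    f"{abs(len(a) - len(b))} left unmatched"
                )
            for rc, cc in zip(a[:n], b[:n]):
                pairs.append(
                    ContactPair(lig, cls, rc.atom_index, cc.atom_index,
                                rc.distance, cc.distance)
                )
    return pairs


def pairs_to_frame(pairs: Iterable[ContactPair]) -> pd.DataFrame:
    """Tabulate contact pairs (ligand, donor_class, distances, delta_A)."""
    return pd.DataFrame(
        [
            {
                "ligand": p.ligand,
                "donor_class": p.donor_class,
                "atom_index": p.atom_index_ref,
                "d_ref_A": p.d_ref,
                "d_cmp_A": p.d_cmp,
                "delta_A": p.delta,
            }
            for p in pairs
        ]
    )


def distance_stats(
    calc: Sequence[tuple[str, str, float]],
    exptl: Sequence[tuple[str, str, float]],
) -> dict[str, dict[str, float]]:
    """Mean absolute deviation and RMSD of calc - exptl bond distances.

    Records are (label, donor_class, distance_A) aligned by position; label
    and donor element must agree row by row.  Statistics are returned per
    donor element (the field's usual M-N vs M-O split) and pooled under
    ``"overall"``.
    """
    if len(calc) != len(exptl):
        raise StructureMismatchError(
            f"record counts differ: {len(calc)} calc vs {len(exptl)} exptl"
        )
    if not calc:
        raise EmptySelectionError("empty join: no matched distance records")
    devs: dict[str, list[float]] = {}
    for (lab_c, cls_c, d_c), (lab_e, cls_e, d_e) in zip(calc, exptl):
        if lab_c != lab_e:
            raise StructureMismatchError(f"label mismatch: {lab_c} vs {lab_e}")
        el_c, el_e = cls_c.split("_")[0], cls_e.split("_")[0]
        if el_c != el_e:
            raise StructureMismatchError(
                f"{lab_c}: donor element mismatch {cls_c} vs {cls_e}"
            )
        devs.setdefault(el_c, []).append(d_c - d_e)
    out: dict[str, dict[str, float]] = {}
    pooled: list[float] = []
    for el, vals in sorted(devs.items()):
        arr = np.asarray(vals)
        pooled.extend(vals)
        out[el] = {
            "mean_abs_dev": float(np.mean(np.abs(arr))),
            "rmsd": float(np.sqrt(np.mean(arr**2))),
            "n": len(vals),
        }
    arr = np.asarray(pooled)
    out["overall"] = {
        "mean_abs_dev": float(np.mean(np.abs(arr))),
        "rmsd": float(np.sqrt(np.mean(arr**2))),
        "n": len(pooled),
    }
    return out
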