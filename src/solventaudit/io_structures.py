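"""Coordinate and reflection I/O.

Reads macromolecular models (PDB / mmCIF) and reflection data (MTZ /
SF-mmCIF) into light internal containers, and counts the entities the
solvent-audit rules operate on: polymer residues, water oxygens and water
hydrogens.  File parsing is delegated to :mod:`gemmi`; the containers here
keep only what the audit needs (element, position, occupancy, isotropic B,
water / amino-acid role) plus per-entry metadata.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Structure",
    "StructureMetadata",
    "ReflectionSet",
    "Method",
    "WATER_RESIDUE_NAMES",
    "parse_coordinates",
    "count_polymer_residues",
    "extract_waters",
    "read_reflections",
    "write_reflections",
    "read_metadata_table",
    "write_waters_csv",
    "structure_to_json",
]

#: Residue names treated as water.  DOD covers deuterated waters from
#: neutron structures; the list is configurable at call sites.
WATER_RESIDUE_NAMES = ("HOH", "WAT", "DOD")


class Method(str, Enum):
    """Experimental method of a deposition."""

    xray = "xray"
    neutron = "neutron"
    other = "other"


@dataclass(frozen=True)
class AtomRecord:
    """One atom site (one altloc conformer = one record)."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_id: int
    position: tuple[float, float, float]  # orthogonal Å
    occupancy: float
    adp: float  # isotropic B, Å²
    element: str
    is_water: bool
    is_polymer_amino_acid: bool
    altloc: str = ""
    icode: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.occupancy):
            raise ValueError(f"non-finite occupancy for atom {self.serial}")
        if not math.isfinite(self.adp):
            raise ValueError(f"non-finite ADP for atom {self.serial}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.serial}")
        if self.is_water and self.is_polymer_amino_acid:
            raise ValueError("atom cannot be both water and polymer amino acid")


@dataclass
class StructureMetadata:
    """Per-entry metadata and validation-report quality metrics.

    Every field may be ``None``: missingness is first-class and is never
    silently replaced by zero.
    """

    entry_id: str = ""
    method: Method | None = None
    resolution: float | None = None
    r_merge: float | None = None
    r_work_depositor: float | None = None
    r_free_depositor: float | None = None
    r_work_dcc: float | None = None
    r_free_dcc: float | None = None
    n_waters: int | None = None
    n_residues: int | None = None
    n_non_h_atoms: int | None = None
    solvent_content: float | None = None  # percent
    wilson_b: float | None = None
    bulk_solvent_b: float | None = None
    bulk_solvent_k: float | None = None
    clashscore: float | None = None
    ramachandran_outliers: float | None = None
    rotamer_outliers: float | None = None
    rsrz_outliers: float | None = None
    rmsz_bonds: float | None = None
    rmsz_angles: float | None = None
    release_year: int | None = None
    is_group_deposition: bool = False
    molecular_weight: float | None = None

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution must be positive when present")
        for name in ("n_waters", "n_residues", "n_non_h_atoms"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Structure:
    """A parsed coordinate model: atoms, unit cell, symmetry, metadata."""

    atoms: list[AtomRecord]
    cell: tuple[float, float, float, float, float, float] = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
    symmetry_ops: list[str] = field(default_factory=lambda: ["x,y,z"])
    metadata: StructureMetadata = field(default_factory=StructureMetadata)

    def __post_init__(self) -> None:
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0:
            raise ValueError("cell lengths must be positive")
        if not all(0.0 < ang < 180.0 for ang in (al, be, ga)):
            raise ValueError("cell angles must be in (0, 180) degrees")

    # -- geometry helpers used by the density module ------------------------

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 fractional->orthogonal matrix (columns are cell vectors)."""
        a, b, c, al, be, ga = self.cell
        al, be, ga = np.radians([al, be, ga])
        cosal, cosbe, cosga = np.cos([al, be, ga])
        singa = np.sin(ga)
        # standard PDB orthogonalization convention
        v = math.sqrt(
            1 - cosal**2 - cosbe**2 - cosga**2 + 2 * cosal * cosbe * cosga
        )
        return np.array(
            [
                [a, b * cosga, c * cosbe],
                [0.0, b * singa, c * (cosal - cosbe * cosga) / singa],
                [0.0, 0.0, c * v / singa],
            ]
        )

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.orth_matrix)))

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def fractional_positions(self) -> np.ndarray:
        return (self.frac_matrix @ self.positions().T).T % 1.0


@dataclass
class ReflectionSet:
    """Miller indices with amplitudes and/or complex structure factors."""

    hkl: np.ndarray  # (n, 3) int
    cell: tuple[float, float, float, float, float, float]
    f_obs: np.ndarray | None = None  # (n,) float amplitudes
    coeffs: np.ndarray | None = None  # (n,) complex
    free_flag: np.ndarray | None = None  # (n,) int
    d_min: float | None = None
    f000: float | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        seen = {tuple(h) for h in self.hkl.tolist()}
        if len(seen) != len(self.hkl):
            raise ValueError("duplicate Miller indices in reflection set")
        if self.f_obs is not None:
            self.f_obs = np.asarray(self.f_obs, dtype=float)
            if np.any(self.f_obs < 0):
                raise ValueError("amplitudes must be non-negative")
            if any((h == 0).all() for h in self.hkl):
                raise ValueError("(0,0,0) must not appear in an f_obs-bearing set")
        if self.coeffs is not None:
            self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.d_min is None:
            self.d_min = float(self.d_spacings().min())

    def d_spacings(self) -> np.ndarray:
        """Resolution d(h) of every reflection, Å."""
        cell = gemmi.UnitCell(*self.cell)
        return np.array([cell.calculate_d(tuple(int(i) for i in h)) for h in self.hkl])

    def __len__(self) -> int:
        return len(self.hkl)


# ---------------------------------------------------------------------------
# coordinate parsing
# ---------------------------------------------------------------------------

_AMINO_CACHE: dict[str, bool] = {}


def _is_amino_acid(residue_name: str) -> bool:
    flag = _AMINO_CACHE.get(residue_name)
    if flag is None:
        info = gemmi.find_tabulated_residue(residue_name)
        flag = bool(info is not None and info.is_amino_acid())
        _AMINO_CACHE[residue_name] = flag
    return flag


def parse_coordinates(
    source: str | Path,
    format: str = "auto",
    water_names: Sequence[str] = WATER_RESIDUE_NAMES,
) -> Structure:
    """Parse PDB or mmCIF coordinates into a :class:`Structure`.

    ``source`` may be a path or the file content itself.  All alternate
    locations are retained as separate records with their stated
    occupancies.  When no CRYST1 / cell is present a unit cell of 1 Å is
    kept and map-dependent operations will fail later with a clear error.
    """
    text, path = _resolve_source(source)
    if format == "auto":
        format = _sniff_coordinate_format(text, path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb_string(text)
        elif format == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown coordinate format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse coordinates ({format}): {exc}") from exc

    waters = set(water_names)
    atoms: list[AtomRecord] = []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                is_wat = res.name in waters
                is_aa = not is_wat and _is_amino_acid(res.name)
                for atom in res:
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            name=atom.name,
                            residue_name=res.name,
                            chain=chain.name,
                            residue_id=res.seqid.num,
                            position=(atom.pos.x, atom.pos.y, atom.pos.z),
                            occupancy=atom.occ,
                            adp=atom.b_iso,
                            element=atom.element.name,
                            is_water=is_wat,
                            is_polymer_amino_acid=is_aa,
                            altloc=atom.altloc if atom.altloc != "\x00" else "",
                            icode=res.seqid.icode.strip(),
                        )
                    )
    if not atoms:
        raise ValueError("no atoms found: empty or unparseable coordinate input")

    cell = st.cell
    if cell.a <= 0 or not cell.is_crystal():
        cell_params = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
    else:
        cell_params = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm or "P 1")
    ops = [op.triplet() for op in sg.operations()] if sg else ["x,y,z"]

    meta = StructureMetadata(
        entry_id=st.name.lower() if st.name else "",
        resolution=st.resolution if st.resolution > 0 else None,
    )
    structure = Structure(atoms=atoms, cell=cell_params, symmetry_ops=ops, metadata=meta)
    meta.n_waters = len(extract_waters(structure)[0])
    meta.n_residues = count_polymer_residues(structure)["total"]
    meta.n_non_h_atoms = sum(1 for a in atoms if a.element not in ("H", "D"))
    return structure


def _resolve_source(source: str | Path) -> tuple[str, Path | None]:
    if isinstance(source, Path):
        return source.read_text(), source
    if source and "\n" not in source and len(source) < 4096:
        p = Path(source)
        if p.is_file():
            return p.read_text(), p
    return source, None


def _sniff_coordinate_format(text: str, path: Path | None) -> str:
    if path is not None:
        suffix = path.suffix.lower()
        if suffix in (".cif", ".mmcif"):
            return "mmcif"
        if suffix in (".pdb", ".ent"):
            return "pdb"
    head = text.lstrip()[:2048]
    if head.startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def count_polymer_residues(structure: Structure) -> dict:
    """Count distinct polymer amino-acid residues per chain and in total.

    A residue is one distinct (chain, residue_id, insertion-code) triple;
    altloc micro-heterogeneity counts once.  Waters and hetero ligands are
    excluded.
    """
    per_chain: dict[str, set] = {}
    for a in structure.atoms:
        if a.is_polymer_amino_acid:
            per_chain.setdefault(a.chain, set()).add((a.residue_id, a.icode))
    counts = {ch: len(s) for ch, s in sorted(per_chain.items())}
    return {"per_chain": counts, "total": sum(counts.values())}


def extract_waters(
    structure: Structure,
) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Return (water O/heavy records, water H/D records).

    Hydrogens are kept separately because the occupancy audit checks them
    against their oxygens (zero-occupancy O with refined B vs full-occupancy
    H with zero B is a reported pathology).
    """
    oxygens = [
        a for a in structure.atoms if a.is_water and a.element not in ("H", "D")
    ]
    hydrogens = [a for a in structure.atoms if a.is_water and a.element in ("H", "D")]
    return oxygens, hydrogens


# ---------------------------------------------------------------------------
# reflection I/O
# ---------------------------------------------------------------------------

_F_OBS_LABELS = ("FP", "F", "FOBS", "F-obs", "F_meas_au", "FOSC")
_PHASE_LABELS = ("PHWT", "PHI", "PHIC", "PHIM")


def read_reflections(
    source: str | Path, format: str = "auto", on_duplicates: str = "error"
) -> ReflectionSet:
    """Read an MTZ or SF-mmCIF reflection file.

    Records which of amplitudes / complex coefficients / free flags are
    present.  ``on_duplicates`` is ``"error"`` (default) or ``"first"``
    (keep the first of each duplicate index).
    """
    path = Path(source)
    if format == "auto":
        if path.suffix.lower() == ".mtz":
            format = "mtz"
        else:
            format = "sf_mmcif"
    if format == "mtz":
        return _read_mtz(path, on_duplicates)
    if format == "sf_mmcif":
        return _read_sf_mmcif(path, on_duplicates)
    raise ValueError(f"unknown reflection format {format!r}")


def _dedup(hkl, arrays, on_duplicates):
    _, first_idx = np.unique(hkl, axis=0, return_index=True)
    if len(first_idx) == len(hkl):
        return hkl, arrays
    if on_duplicates == "error":
        raise ValueError("duplicate Miller indices (pass on_duplicates='first' to keep first)")
    first_idx = np.sort(first_idx)
    return hkl[first_idx], [None if a is None else a[first_idx] for a in arrays]


def _read_mtz(path: Path, on_duplicates: str) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(str(path))
    labels = [c.label for c in mtz.columns]
    arr = mtz.array
    hkl = arr[:, :3].astype(int)

    def col(names):
        for n in names:
            if n in labels:
                return arr[:, labels.index(n)].astype(float)
        return None

    f_obs = col(_F_OBS_LABELS)
    phase = col(_PHASE_LABELS)
    fc_amp = col(("FC", "FWT", "F-model"))
    free = col(("FREE", "FreeR_flag", "R-free-flags"))
    if f_obs is None and fc_amp is None:
        raise ValueError(
            f"no recognizable amplitude column in {path.name}; found {labels}"
        )
    coeffs = None
    if phase is not None and fc_amp is not None:
        coeffs = fc_amp * np.exp(1j * np.radians(phase))
    keep = ~(np.all(hkl == 0, axis=1))
    hkl, (f_obs, coeffs, free) = hkl[keep], [
        None if a is None else a[keep] for a in (f_obs, coeffs, free)
    ]
    hkl, (f_obs, coeffs, free) = _dedup(hkl, [f_obs, coeffs, free], on_duplicates)
    cell = mtz.cell
    return ReflectionSet(
        hkl=hkl,
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        f_obs=f_obs,
        coeffs=coeffs,
        free_flag=None if free is None else free.astype(int),
    )


def _read_sf_mmcif(path: Path, on_duplicates: str) -> ReflectionSet:
    doc = gemmi.cif.read_string(path.read_text())
    block = doc.sole_block()

    def loop(tag):
        vals = block.find_loop(f"_refln.{tag}")
        return list(vals) if vals else None

    h, k, l = loop("index_h"), loop("index_k"), loop("index_l")
    if h is None:
        raise ValueError(f"{path.name}: no _refln.index_h loop")
    hkl = np.array([h, k, l], dtype=int).T
    found = [t for t in block.get_mmcif_category_names()]

    def floats(tag):
        vals = loop(tag)
        if vals is None:
            return None
        return np.array(
            [float(v) if v not in ("?", ".") else np.nan for v in vals], dtype=float
        )

    f_obs = None
    for tag in ("F_meas_au", "F_meas"):
        f_obs = floats(tag)
        if f_obs is not None:
            break
    fc = floats("F_calc_au")
    if fc is None:
        fc = floats("F_calc")
    phase = floats("phase_calc")
    free = loop("status")
    if f_obs is None and fc is None:
        tags = [t for t in block.find_mmcif_category("_refln.").tags]
        raise ValueError(f"{path.name}: no amplitude column; found {tags}")
    coeffs = None
    if fc is not None and phase is not None:
        coeffs = fc * np.exp(1j * np.radians(phase))
    free_arr = None
    if free is not None:
        free_arr = np.array([1 if s == "f" else 0 for s in free], dtype=int)

    cell_tags = ("length_a", "length_b", "length_c", "angle_alpha", "angle_beta", "angle_gamma")
    cell_vals = []
    for t in cell_tags:
        v = block.find_value(f"_cell.{t}")
        cell_vals.append(float(v) if v is not None else (1.0 if len(cell_vals) < 3 else 90.0))
    keep = ~(np.all(hkl == 0, axis=1))
    hkl, (f_obs, coeffs, free_arr) = hkl[keep], [
        None if a is None else a[keep] for a in (f_obs, coeffs, free_arr)
    ]
    hkl, (f_obs, coeffs, free_arr) = _dedup(hkl, [f_obs, coeffs, free_arr], on_duplicates)
    return ReflectionSet(
        hkl=hkl, cell=tuple(cell_vals), f_obs=f_obs, coeffs=coeffs, free_flag=free_arr
    )


def write_reflections(refl: ReflectionSet, path: str | Path, format: str = "auto") -> Path:
    """Write a reflection set as MTZ or SF-mmCIF (by extension for auto)."""
    path = Path(path)
    if format == "auto":
        format = "mtz" if path.suffix.lower() == ".mtz" else "sf_mmcif"
    if format == "mtz":
        mtz = gemmi.Mtz(with_base=True)
        mtz.spacegroup = gemmi.SpaceGroup("P 1")
        mtz.set_cell_for_all(gemmi.UnitCell(*refl.cell))
        mtz.add_dataset("solventaudit")
        cols: list[np.ndarray] = [refl.hkl[:, 0], refl.hkl[:, 1], refl.hkl[:, 2]]
        if refl.f_obs is not None:
            mtz.add_column("FP", "F")
            cols.append(refl.f_obs)
        if refl.coeffs is not None:
            mtz.add_column("FC", "F")
            mtz.add_column("PHIC", "P")
            cols.append(np.abs(refl.coeffs))
            cols.append(np.degrees(np.angle(refl.coeffs)))
        if refl.free_flag is not None:
            mtz.add_column("FREE", "I")
            cols.append(refl.free_flag)
        mtz.set_data(np.column_stack(cols).astype(np.float32))
        mtz.write_to_file(str(path))
        return path

    a, b, c, al, be, ga = refl.cell
    lines = [
        "data_solventaudit",
        f"_cell.length_a {a:.4f}",
        f"_cell.length_b {b:.4f}",
        f"_cell.length_c {c:.4f}",
        f"_cell.angle_alpha {al:.3f}",
        f"_cell.angle_beta {be:.3f}",
        f"_cell.angle_gamma {ga:.3f}",
        "loop_",
        "_refln.index_h",
        "_refln.index_k",
        "_refln.index_l",
    ]
    cols = []
    if refl.f_obs is not None:
        lines.append("_refln.F_meas_au")
        cols.append([f"{v:.6g}" for v in refl.f_obs])
    if refl.coeffs is not None:
        lines.append("_refln.F_calc_au")
        lines.append("_refln.phase_calc")
        cols.append([f"{v:.6g}" for v in np.abs(refl.coeffs)])
        cols.append([f"{v:.4f}" for v in np.degrees(np.angle(refl.coeffs))])
    if refl.free_flag is not None:
        lines.append("_refln.status")
        cols.append(["f" if v else "o" for v in refl.free_flag])
    for i, (h, k, l) in enumerate(refl.hkl):
        row = [str(h), str(k), str(l)] + [col[i] for col in cols]
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# metadata table and serialisation helpers
# ---------------------------------------------------------------------------

_METHOD_ALIASES = {
    "xray": Method.xray,
    "x-ray": Method.xray,
    "x-ray diffraction": Method.xray,
    "neutron": Method.neutron,
    "neutron diffraction": Method.neutron,
}


def read_metadata_table(path: str | Path, sep: str | None = None) -> list[StructureMetadata]:
    """Read a delimited per-entry metadata/quality table.

    One row per entry; column names match :class:`StructureMetadata` field
    names.  Missing cells stay missing (``None``), never zero.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    known = {f.name for f in dataclasses.fields(StructureMetadata)}
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in df.columns:
            if col not in known:
                continue
            val = row[col]
            if pd.isna(val):
                continue
            if col == "method":
                kwargs[col] = _METHOD_ALIASES.get(str(val).strip().lower(), Method.other)
            elif col == "is_group_deposition":
                kwargs[col] = bool(val) if not isinstance(val, str) else val.strip().lower() in ("1", "true", "yes")
            elif col in ("release_year",):
                kwargs[col] = int(val)
            elif col == "entry_id":
                kwargs[col] = str(val)
            else:
                kwargs[col] = float(val)
        records.append(StructureMetadata(**kwargs))
    return records


def write_waters_csv(structure: Structure, path: str | Path) -> Path:
    """Write water oxygen records as CSV for spreadsheet inspection."""
    oxygens, _ = extract_waters(structure)
    df = pd.DataFrame(
        [
            {
                "entry_id": structure.metadata.entry_id,
                "chain": a.chain,
                "resid": a.residue_id,
                "x": a.position[0],
                "y": a.position[1],
                "z": a.position[2],
                "occupancy": a.occupancy,
                "adp": a.adp,
            }
            for a in oxygens
        ]
    )
    df.to_csv(path, index=False)
    return Path(path)


def structure_to_json(structure: Structure, path: str | Path | None = None) -> str:
    """Serialise a structure (atoms + cell + metadata) to normalized JSON."""
    payload = {
        "cell": list(structure.cell),
        "symmetry_ops": structure.symmetry_ops,
        "metadata": {
            k: (v.value if isinstance(v, Method) else v)
            for k, v in dataclasses.asdict(structure.metadata).items()
        },
        "atoms": [dataclasses.asdict(a) for a in structure.atoms],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write the structure in PDB fixed-column format (occ/B to 2 decimals)."""
    lines = [
        "CRYST1{:9.3f}{:9.3f}{:9.3f}{:7.2f}{:7.2f}{:7.2f} P 1".format(*structure.cell)
    ]
    for a in structure.atoms:
        record = "HETATM" if (a.is_water or not a.is_polymer_amino_acid) else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{a.serial:5d} {name:4.4s}{a.altloc or ' ':1s}{a.residue_name:<3.3s} "
            f"{a.chain:1.1s}{a.residue_id:4d}{a.icode or ' ':1s}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.adp:6.2f}          {a.element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
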