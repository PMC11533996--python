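"""Ground-truth synthetic inputs for the audit pipeline.

Everything the pipeline consumes can be generated here with known truth:
toy P1 crystals with protein-like atoms and hydrogen-bonded waters,
simulated observed amplitudes (optionally noisy), truncated models whose
deleted waters become difference-density ground truth, and quality
tables with planted multivariate outliers.  Each generator is a pure
function of its spec and seed.

The crystals make no attempt at real protein geometry (no bonding, no
secondary structure, no bulk solvent); what they guarantee is exactly
what the tests need — minimum atom separations, a polar hydrogen-bond
partner within 2.4–3.2 Å of every water, and known occupancy anomalies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import calc_structure_factors
from .io_structures import (
    AtomRecord,
    Method,
    ReflectionSet,
    Structure,
    StructureMetadata,
)
from .screening import OccupancyClass

__all__ = [
    "ToyCrystalSpec",
    "GroundTruth",
    "make_toy_crystal",
    "simulate_amplitudes",
    "delete_waters",
    "make_quality_table",
]


@dataclass
class ToyCrystalSpec:
    """Specification of a synthetic P1 crystal.

    Defaults describe a sparse 18 Å cubic cell with a dozen four-atom
    pseudo-residues (N, CA, C, O) and a dozen waters, B factors in a
    typical 8–20 Å² room, all placed with a 2.0 Å minimum separation.
    """

    cell: tuple = (18.0, 18.0, 18.0, 90.0, 90.0, 90.0)
    n_protein_atoms: int = 48
    n_waters: int = 12
    b_range: tuple[float, float] = (8.0, 20.0)
    occupancy_spec: tuple = ()  # ((OccupancyClass | str, count), ...)
    min_separation: float = 2.0
    hbond_range: tuple[float, float] = (2.5, 3.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_protein_atoms < 0 or self.n_waters < 0:
            raise ValueError("atom counts must be >= 0")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if sum(c for _, c in self.occupancy_spec) > self.n_waters:
            raise ValueError("occupancy_spec counts exceed n_waters")


@dataclass
class GroundTruth:
    """What a generator planted, for recovery tests."""

    deleted_water_positions: list[tuple[float, float, float]] = field(default_factory=list)
    injected_anomalies: dict[int, OccupancyClass] = field(default_factory=dict)
    planted_outlier_rows: list[str] = field(default_factory=list)


_RESIDUE_ATOMS = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))

_MAX_TRIES = 4000


def _min_image_dist(frac_a: np.ndarray, frac_b: np.ndarray, orth: np.ndarray) -> np.ndarray:
    d = frac_a[None, :] - frac_b
    d -= np.round(d)
    best = np.full(len(frac_b), np.inf)
    for shift in np.ndindex(3, 3, 3):
        cart = (d + (np.array(shift) - 1)) @ orth.T
        best = np.minimum(best, np.linalg.norm(cart, axis=1))
    return best


def _class_occupancy(cls: OccupancyClass, rng: np.random.Generator) -> float:
    if cls is OccupancyClass.zero:
        return 0.0
    if cls is OccupancyClass.near_zero:
        return round(float(rng.uniform(0.01, 0.1)), 2)
    if cls is OccupancyClass.normal:
        return round(float(rng.uniform(0.2, 0.8)), 2)
    if cls is OccupancyClass.near_full:
        return round(float(rng.uniform(0.90, 0.99)), 2)
    if cls is OccupancyClass.over:
        return round(float(rng.uniform(1.1, 2.0)), 2)
    return 1.0


def make_toy_crystal(spec: ToyCrystalSpec) -> tuple[Structure, GroundTruth]:
    """Generate a P1 toy crystal with guaranteed-bondable waters.

    Protein-like atoms are placed by rejection sampling at the spec's
    minimum periodic separation; every water is planted on a sphere of
    hydrogen-bonding radius around a protein N or O atom and kept at
    least 2.4 Å from everything else, so a density-based water search has
    a well-posed target.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    helper = Structure(atoms=[_dummy()], cell=spec.cell)
    orth = helper.orth_matrix
    frac_list: list[np.ndarray] = []

    def try_place(candidate_frac: np.ndarray, min_d: float) -> bool:
        if frac_list:
            d = _min_image_dist(candidate_frac, np.array(frac_list), orth)
            if d.min() < min_d:
                return False
        frac_list.append(candidate_frac)
        return True

    atoms: list[AtomRecord] = []
    serial = 0
    # protein pseudo-residues
    for i in range(spec.n_protein_atoms):
        placed = False
        for _ in range(_MAX_TRIES):
            if try_place(rng.random(3), spec.min_separation):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "cannot pack protein atoms at this separation; use a larger cell"
            )
        name, element = _RESIDUE_ATOMS[i % 4]
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                residue_name="ALA",
                chain="A",
                residue_id=i // 4 + 1,
                position=tuple(orth @ frac_list[-1]),
                occupancy=1.0,
                adp=float(rng.uniform(*spec.b_range)),
                element=element,
                is_water=False,
                is_polymer_amino_acid=True,
            )
        )

    polar_idx = [i for i, a in enumerate(atoms) if a.element in ("N", "O")]
    if spec.n_waters > 0 and not polar_idx:
        raise RuntimeError("no polar protein atoms to anchor waters")

    # water occupancies per anomaly spec, remainder full
    occupancies: list[tuple[float, OccupancyClass | None]] = []
    for cls, count in spec.occupancy_spec:
        cls = OccupancyClass(cls)
        for _ in range(count):
            occupancies.append((_class_occupancy(cls, rng), cls))
    while len(occupancies) < spec.n_waters:
        occupancies.append((1.0, None))
    order = rng.permutation(spec.n_waters)

    truth = GroundTruth()
    frac_inv = np.linalg.inv(orth)
    for j in range(spec.n_waters):
        placed = False
        for _ in range(_MAX_TRIES):
            anchor = atoms[polar_idx[rng.integers(len(polar_idx))]]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            r = rng.uniform(*spec.hbond_range)
            pos = np.asarray(anchor.position) + r * direction
            fr = (frac_inv @ pos) % 1.0
            if try_place(fr, 2.4):
                placed = True
                break
        if not placed:
            raise RuntimeError("cannot place waters; use a larger cell or fewer waters")
        occ, cls = occupancies[order[j]]
        serial += 1
        wid = 101 + j
        if cls is not None:
            truth.injected_anomalies[wid] = cls
        atoms.append(
            AtomRecord(
                serial=serial,
                name="O",
                residue_name="HOH",
                chain="S",
                residue_id=wid,
                position=tuple(orth @ frac_list[-1]),
                occupancy=occ,
                adp=float(rng.uniform(*spec.b_range)),
                element="O",
                is_water=True,
                is_polymer_amino_acid=False,
            )
        )

    n_res = len({(a.chain, a.residue_id) for a in atoms if a.is_polymer_amino_acid})
    meta = StructureMetadata(
        entry_id=f"syn{spec.seed:04d}",
        method=Method.xray,
        n_waters=spec.n_waters,
        n_residues=n_res,
        n_non_h_atoms=len(atoms),
    )
    return Structure(atoms=atoms, cell=spec.cell, metadata=meta), truth


def _dummy() -> AtomRecord:
    return AtomRecord(
        serial=0, name="X", residue_name="UNK", chain="A", residue_id=0,
        position=(0.0, 0.0, 0.0), occupancy=1.0, adp=0.0, element="C",
        is_water=False, is_polymer_amino_acid=False,
    )


def simulate_amplitudes(
    full_model: Structure,
    d_min: float,
    noise_frac: float = 0.0,
    seed: int = 0,
    free_fraction: float = 0.05,
) -> ReflectionSet:
    """Observed amplitudes |Fo| = |Fc(full model)|·(1 + ε), ε ~ N(0, noise_frac).

    The multiplicative factor is clipped at −0.9 so amplitudes stay
    positive; about ``free_fraction`` of reflections get a free flag.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    rng = np.random.default_rng(seed)
    calc = calc_structure_factors(full_model, d_min)
    amp = np.abs(calc.coeffs)
    if noise_frac:
        eps = np.clip(rng.normal(0.0, noise_frac, size=len(amp)), -0.9, None)
        amp = amp * (1.0 + eps)
    free = (rng.random(len(amp)) < free_fraction).astype(int)
    return ReflectionSet(
        hkl=calc.hkl, cell=full_model.cell, f_obs=amp, free_flag=free, d_min=d_min
    )


def delete_waters(
    structure: Structure,
    fraction: float | None = None,
    ids: list[int] | None = None,
    seed: int = 0,
) -> tuple[Structure, GroundTruth]:
    """Remove waters (by fraction or explicit residue ids) recording truth."""
    water_ids = sorted({a.residue_id for a in structure.atoms if a.is_water})
    if ids is None:
        if fraction is None:
            raise ValueError("give either fraction or ids")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        rng = np.random.default_rng(seed)
        n_del = int(round(fraction * len(water_ids)))
        ids = sorted(rng.choice(water_ids, size=n_del, replace=False).tolist())
    selected = set(ids)
    truth = GroundTruth(
        deleted_water_positions=[
            a.position
            for a in structure.atoms
            if a.is_water and a.residue_id in selected and a.element not in ("H", "D")
        ]
    )
    kept = [
        a for a in structure.atoms if not (a.is_water and a.residue_id in selected)
    ]
    meta = StructureMetadata(**{
        **structure.metadata.__dict__,
        "n_waters": sum(1 for a in kept if a.is_water and a.element not in ("H", "D")),
    })
    truncated = Structure(
        atoms=kept, cell=structure.cell,
        symmetry_ops=list(structure.symmetry_ops), metadata=meta,
    )
    return truncated, truth


def make_quality_table(
    n_inliers: int,
    n_outliers: int,
    p: int = 8,
    missing_frac: float = 0.0,
    outlier_shift: float = 10.0,
    seed: int = 0,
):
    """Quality table with a correlated Gaussian inlier cloud and planted outliers.

    Inliers are drawn from a random correlated multivariate normal;
    outliers start from inlier draws and are shifted by ``outlier_shift``
    standard deviations along random directions.  Exactly
    ⌊missing_frac·n·p⌋ cells are masked at random (never a full column).
    Returns (QualityMatrix, GroundTruth).
    """
    from .cohort_stats import QualityMatrix

    if n_outliers >= n_inliers:
        raise ValueError("need fewer outliers than inliers")
    if not 0.0 <= missing_frac < 1.0:
        raise ValueError("missing_frac must be in [0, 1)")
    if p < 2:
        raise ValueError("need at least 2 metrics")
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(p, p))
    cov = a @ a.T
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    chol = np.linalg.cholesky(corr + 1e-9 * np.eye(p))
    n = n_inliers + n_outliers
    x = rng.normal(size=(n, p)) @ chol.T
    outlier_rows = rng.choice(n, size=n_outliers, replace=False)
    for i in outlier_rows:
        direction = rng.normal(size=p)
        direction /= np.linalg.norm(direction)
        x[i] += outlier_shift * direction  # inlier sd is 1 per coordinate
    n_missing = int(np.floor(missing_frac * n * p))
    if n_missing:
        for _ in range(200):
            cells = rng.choice(n * p, size=n_missing, replace=False)
            mask = np.zeros(n * p, dtype=bool)
            mask[cells] = True
            mask = mask.reshape(n, p)
            if not mask.all(axis=0).any():
                break
        else:
            raise RuntimeError("could not mask cells without losing a column")
        x = np.where(mask, np.nan, x)
    row_ids = [f"s{i:04d}" for i in range(n)]
    matrix = QualityMatrix(
        row_ids=row_ids,
        columns=[f"metric_{j}" for j in range(p)],
        values=x,
    )
    truth = GroundTruth(planted_outlier_rows=[row_ids[i] for i in sorted(outlier_rows)])
    return matrix, truth
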