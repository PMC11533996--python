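"""Electron-density verification of solvent models.

The audit's central question — is a modeled water supported by the data,
and does the data demand waters the model lacks? — is answered here by
computing structure factors from a model, synthesizing difference maps
(Fo−Fc, 2Fo−Fc) with calculated phases, scanning them for peaks, and
applying the water-placement rule used throughout the screening: a
positive difference peak of at least 3.5σ with a hydrogen-bond donor or
acceptor within 2.4–3.2 Å.

Maps are plain Fo−Fc / 2Fo−Fc syntheses (no maximum-likelihood m/D
weighting) and no bulk-solvent model is applied; both simplifications are
adequate for the toy P1 crystals the package audits end-to-end, and are
the main cause of R mismatches against refined real entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .io_structures import AtomRecord, ReflectionSet, Structure

__all__ = [
    "MapGrid",
    "Peak",
    "CandidateWater",
    "WaterSupportFlag",
    "SupportThresholds",
    "calc_structure_factors",
    "synthesize_map",
    "sigma_scale",
    "find_peaks",
    "r_factor",
    "place_candidate_waters",
    "find_waters_2fofc",
    "flag_unsupported_waters",
    "write_ccp4_map",
]

#: Effective electron counts for the single-Gaussian form-factor default.
_ELECTRONS = {"H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34, "FE": 26}

#: Width (Å²) of the single-Gaussian form factor.  Chosen so an atom's
#: density blob has a realistic ~0.4 Å standard deviation; peak *shapes*
#: matter for the audit, absolute scattering accuracy does not.
_FORM_B = 12.0


def _electrons(element: str) -> float:
    z = _ELECTRONS.get(element.upper())
    if z is None:
        z = gemmi.Element(element).atomic_number
        if z == 0:
            raise ValueError(f"unknown element {element!r}")
    return float(z)


@dataclass
class MapGrid:
    """Real-space density sampled on a periodic grid over one unit cell.

    ``values[i, j, k]`` is the density at fractional position
    ``(i/nx, j/ny, k/nz)``; the grid is periodic and half-open per axis.
    """

    cell: tuple[float, float, float, float, float, float]
    values: np.ndarray
    orig_mean: float | None = None  # stats before sigma scaling
    orig_sigma: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid needs >= 2 samples per axis")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        return float(self.values.std())

    @property
    def orth_matrix(self) -> np.ndarray:
        return Structure(
            atoms=[_DUMMY_ATOM], cell=self.cell
        ).orth_matrix

    def interpolate(self, frac: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at fractional coordinates (n, 3)."""
        frac = np.atleast_2d(np.asarray(frac, dtype=float)) % 1.0
        dims = np.array(self.dims)
        g = frac * dims
        i0 = np.floor(g).astype(int)
        t = g - i0
        out = np.zeros(len(frac))
        for corner in range(8):
            off = np.array([(corner >> b) & 1 for b in (0, 1, 2)])
            idx = (i0 + off) % dims
            w = np.prod(np.where(off, t, 1.0 - t), axis=1)
            out += w * self.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        return out


_DUMMY_ATOM = AtomRecord(
    serial=0, name="X", residue_name="UNK", chain="A", residue_id=0,
    position=(0.0, 0.0, 0.0), occupancy=1.0, adp=0.0, element="C",
    is_water=False, is_polymer_amino_acid=False,
)


@dataclass(frozen=True)
class Peak:
    """A local extremum of a σ-scaled map."""

    position_frac: tuple[float, float, float]
    position_orth: tuple[float, float, float]
    height_sigma: float

    @property
    def sign(self) -> str:
        return "positive" if self.height_sigma >= 0 else "negative"


@dataclass(frozen=True)
class CandidateWater:
    """A difference peak that qualifies as a putative water site."""

    position: tuple[float, float, float]  # orthogonal Å
    peak_height_sigma: float
    partner_distance: float
    partner_atom: AtomRecord


@dataclass
class SupportThresholds:
    """Thresholds for the deposited-water support audit."""

    negative_sigma: float = -3.0       # Fo−Fc at/below this → negative_density
    positive_support_sigma: float = 1.0  # 2Fo−Fc below this → no_positive_support
    overlap_distance: float = 2.2      # non-water atom closer → protein_overlap
    default_adp: float = 30.00         # rounded refinement-program default
    default_adp_tol: float = 0.005


@dataclass
class WaterSupportFlag:
    water: AtomRecord
    diff_value_sigma: float
    two_fofc_value_sigma: float
    flags: frozenset[str]


# ---------------------------------------------------------------------------
# structure factors
# ---------------------------------------------------------------------------

def _require_cell(structure: Structure) -> None:
    a, b, c = structure.cell[:3]
    if max(a, b, c) <= 1.0:
        raise ValueError("structure has no unit cell; map work needs CRYST1/_cell")


def _expand_p1(structure: Structure) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Fractional positions, occupancies, B's of the P1-expanded model."""
    frac = structure.fractional_positions()
    occ = np.array([a.occupancy for a in structure.atoms])
    b = np.array([a.adp for a in structure.atoms])
    elements = [a.element for a in structure.atoms]
    ops = [gemmi.Op(t) for t in structure.symmetry_ops]
    if all(op == gemmi.Op("x,y,z") for op in ops):
        return frac, occ, b, elements
    fr_list, occ_list, b_list, el_list = [], [], [], []
    for op in ops:
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        fr_list.append((frac @ rot.T + tran) % 1.0)
        occ_list.append(occ)
        b_list.append(b)
        el_list.extend(elements)
    return (
        np.concatenate(fr_list),
        np.concatenate(occ_list),
        np.concatenate(b_list),
        el_list,
    )


def _hemisphere_hkl(structure: Structure, d_min: float) -> tuple[np.ndarray, np.ndarray]:
    """All Miller indices with d >= d_min in one Friedel hemisphere.

    Returns (hkl, s2) where s2 = 1/d² for each reflection.
    """
    recip = structure.frac_matrix  # rows are reciprocal basis vectors
    limits = [int(math.floor(1.0 / (d_min * np.linalg.norm(recip[i])))) for i in range(3)]
    ranges = [np.arange(-m, m + 1) for m in limits]
    h, k, l = np.meshgrid(*ranges, indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    svec = hkl @ recip
    s2 = np.einsum("ij,ij->i", svec, svec)
    in_sphere = (s2 <= 1.0 / d_min**2 + 1e-12) & (s2 > 0)
    hemi = (
        (hkl[:, 2] > 0)
        | ((hkl[:, 2] == 0) & (hkl[:, 1] > 0))
        | ((hkl[:, 2] == 0) & (hkl[:, 1] == 0) & (hkl[:, 0] > 0))
    )
    keep = in_sphere & hemi
    return hkl[keep], s2[keep]


def _form_factor(element: str, s2: np.ndarray, kind: str) -> np.ndarray:
    if kind == "gaussian":
        return _electrons(element) * np.exp(-_FORM_B * s2 / 4.0)
    if kind == "it92":
        coef = gemmi.Element(element).it92
        f = np.full_like(s2, coef.c, dtype=float)
        for a, b in zip(coef.a, coef.b):
            f += a * np.exp(-b * s2 / 4.0)
        return f
    raise ValueError(f"unknown form-factor kind {kind!r}")


def calc_structure_factors(
    structure: Structure, d_min: float, form_factors: str = "gaussian"
) -> ReflectionSet:
    """Direct-summation structure factors of a model to resolution d_min.

    F(h) = Σ_j f_j(s)·occ_j·exp(−B_j s²/4)·exp(2πi h·x_j), s = 1/d(h),
    over the P1-expanded atom list; returns one Friedel hemisphere plus
    F(000) (carried separately on the set).
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    _require_cell(structure)
    frac, occ, b_iso, elements = _expand_p1(structure)
    hkl, s2 = _hemisphere_hkl(structure, d_min)
    f = np.zeros(len(hkl), dtype=complex)
    el_arr = np.array([e.upper() for e in elements])
    for element in np.unique(el_arr):
        mask = el_arr == element
        ff = _form_factor(element, s2, form_factors)  # (n_h,)
        weights = occ[mask] * np.exp(-np.outer(s2, b_iso[mask]) / 4.0)  # (n_h, n_a)
        phases = np.exp(2j * np.pi * (hkl @ frac[mask].T))  # (n_h, n_a)
        f += ff * np.einsum("ha,ha->h", weights, phases)
    f000 = float(np.sum([_electrons(e) * o for e, o in zip(elements, occ)]))
    return ReflectionSet(
        hkl=hkl, cell=structure.cell, coeffs=f, d_min=d_min, f000=f000
    )


# ---------------------------------------------------------------------------
# map synthesis
# ---------------------------------------------------------------------------

def scale_factor(f_obs: np.ndarray, f_calc: np.ndarray) -> float:
    """Least-squares scale k minimising Σ(|Fo| − k|Fc|)²."""
    f_obs = np.abs(np.asarray(f_obs, dtype=float))
    f_calc = np.abs(np.asarray(f_calc))
    denom = np.sum(f_calc**2)
    if denom == 0:
        raise ValueError("all |Fc| are zero; cannot scale")
    return float(np.sum(f_obs * f_calc) / denom)


def synthesize_map(
    refl: ReflectionSet,
    coeff_kind: str = "direct_coeffs",
    grid_spacing: float | None = None,
    include_f000: bool = False,
) -> MapGrid:
    """Inverse Fourier synthesis onto a periodic unit-cell grid.

    ``fo_fc`` uses (k·|Fo|−|Fc|)·exp(iφc), ``two_fo_fc`` uses
    (2k·|Fo|−|Fc|)·exp(iφc) with k the least-squares amplitude scale;
    ``direct_coeffs`` transforms the stored complex coefficients as-is.
    Friedel mates are completed so the map is real.  Default grid spacing
    is d_min/3 (at least 3 samples per resolution element per axis).
    """
    if coeff_kind in ("fo_fc", "two_fo_fc"):
        missing = [n for n, v in (("f_obs", refl.f_obs), ("coeffs", refl.coeffs)) if v is None]
        if missing:
            raise ValueError(f"{coeff_kind} synthesis needs columns: {', '.join(missing)}")
        k = scale_factor(refl.f_obs, refl.coeffs)
        amp = np.abs(refl.coeffs)
        phase = np.exp(1j * np.angle(refl.coeffs))
        if coeff_kind == "fo_fc":
            coeffs = (k * refl.f_obs - amp) * phase
        else:
            coeffs = (2 * k * refl.f_obs - amp) * phase
    elif coeff_kind == "direct_coeffs":
        if refl.coeffs is None:
            raise ValueError("direct_coeffs synthesis needs the coeffs column")
        coeffs = refl.coeffs
    else:
        raise ValueError(f"unknown coeff_kind {coeff_kind!r}")

    d_min = refl.d_min if refl.d_min else float(refl.d_spacings().min())
    spacing = grid_spacing if grid_spacing is not None else d_min / 3.0
    a, b, c = refl.cell[:3]
    hmax = np.abs(refl.hkl).max(axis=0)
    dims = tuple(
        max(int(math.ceil(length / spacing)), 2 * int(m) + 2, 2)
        for length, m in zip((a, b, c), hmax)
    )
    grid = np.zeros(dims, dtype=complex)
    idx = refl.hkl % np.array(dims)
    neg = (-refl.hkl) % np.array(dims)
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = coeffs
    grid[neg[:, 0], neg[:, 1], neg[:, 2]] = np.conj(coeffs)
    if include_f000 and refl.f000 is not None and coeff_kind == "direct_coeffs":
        grid[0, 0, 0] = refl.f000
    cell_obj = Structure(atoms=[_DUMMY_ATOM], cell=refl.cell)
    volume = cell_obj.volume
    # rho(x) = (1/V) Σ_h F(h) exp(−2πi h·x): exactly numpy's forward FFT
    values = np.fft.fftn(grid).real / volume
    return MapGrid(cell=refl.cell, values=values)


def sigma_scale(grid: MapGrid) -> MapGrid:
    """Scale a map to σ units: (v − mean)/σ, recording the original stats."""
    mean, sigma = grid.mean, grid.sigma
    if sigma == 0:
        raise ValueError("constant map: sigma is zero, cannot sigma-scale")
    if grid.orig_sigma is not None and abs(mean) < 1e-9 and abs(sigma - 1) < 1e-9:
        return grid  # already scaled; idempotent
    return MapGrid(
        cell=grid.cell,
        values=(grid.values - mean) / sigma,
        orig_mean=grid.orig_mean if grid.orig_mean is not None else mean,
        orig_sigma=grid.orig_sigma if grid.orig_sigma is not None else sigma,
    )


def _check_usable(grid: MapGrid) -> None:
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("map contains non-finite values")


# ---------------------------------------------------------------------------
# peak search
# ---------------------------------------------------------------------------

_NEIGHBOR_SHIFTS = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def _min_image_distances(
    frac_a: np.ndarray, frac_b: np.ndarray, orth: np.ndarray
) -> np.ndarray:
    """Pairwise periodic distances (n_a, n_b) via 27-image search."""
    d = frac_a[:, None, :] - frac_b[None, :, :]
    d -= np.round(d)
    best = None
    for shift in np.ndindex(3, 3, 3):
        sv = np.array(shift) - 1
        cart = (d + sv) @ orth.T
        dist = np.sqrt(np.einsum("abi,abi->ab", cart, cart))
        best = dist if best is None else np.minimum(best, dist)
    return best


def find_peaks(
    grid: MapGrid,
    threshold_sigma: float,
    sign: str = "positive",
    merge_radius: float = 2.0,
) -> list[Peak]:
    """Strict 26-neighbour local extrema above a σ threshold.

    Positions are refined by per-axis quadratic interpolation; peaks
    closer than ``merge_radius`` (periodic, Å) keep only the highest.
    Sorted by |height| descending.
    """
    if threshold_sigma <= 0:
        raise ValueError("threshold_sigma must be positive")
    _check_usable(grid)
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    if grid.sigma == 0:
        return []  # constant map has no extrema
    v = grid.values if sign == "positive" else -grid.values
    is_max = v > threshold_sigma
    for shift in _NEIGHBOR_SHIFTS:
        is_max &= v > np.roll(v, shift, axis=(0, 1, 2))
        if not is_max.any():
            break
    nodes = np.argwhere(is_max)
    if len(nodes) == 0:
        return []
    dims = np.array(grid.dims)
    peaks: list[tuple[np.ndarray, float]] = []
    for node in nodes:
        pos = node.astype(float)
        h = v[tuple(node)]
        refined = h
        for axis in range(3):
            lo = node.copy(); lo[axis] = (lo[axis] - 1) % dims[axis]
            hi = node.copy(); hi[axis] = (hi[axis] + 1) % dims[axis]
            vm, v0, vp = v[tuple(lo)], h, v[tuple(hi)]
            denom = vm - 2 * v0 + vp
            if denom < 0:
                delta = 0.5 * (vm - vp) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                pos[axis] = node[axis] + delta
                refined = max(refined, v0 - 0.25 * (vm - vp) * delta)
        peaks.append((pos / dims % 1.0, refined))
    peaks.sort(key=lambda p: -p[1])
    orth = grid.orth_matrix
    kept: list[tuple[np.ndarray, float]] = []
    if merge_radius > 0:
        for pos, h in peaks:
            if all(
                _min_image_distances(pos[None], q[None], orth)[0, 0] >= merge_radius
                for q, _ in kept
            ):
                kept.append((pos, h))
    else:
        kept = peaks
    s = 1.0 if sign == "positive" else -1.0
    return [
        Peak(
            position_frac=tuple(pos),
            position_orth=tuple(orth @ pos),
            height_sigma=s * h,
        )
        for pos, h in kept
    ]


# ---------------------------------------------------------------------------
# R factors
# ---------------------------------------------------------------------------

def r_factor(
    f_obs: np.ndarray,
    f_calc: np.ndarray,
    free_flag: np.ndarray | None = None,
) -> dict:
    """Least-squares scale and conventional R between two amplitude sets.

    k = Σ|Fo||Fc| / Σ|Fc|²; R = Σ| |Fo| − k|Fc| | / Σ|Fo|.  When a free
    flag is given (nonzero = free), an R_work/R_free split is reported
    with the same global k.
    """
    f_obs = np.abs(np.asarray(f_obs, dtype=float))
    f_calc = np.abs(np.asarray(f_calc))
    if len(f_obs) == 0 or len(f_obs) != len(f_calc):
        raise ValueError("r_factor needs matching non-empty amplitude arrays")
    k = scale_factor(f_obs, f_calc)

    def _r(mask):
        num = np.sum(np.abs(f_obs[mask] - k * f_calc[mask]))
        den = np.sum(f_obs[mask])
        return float(num / den) if den > 0 else float("nan")

    all_mask = np.ones(len(f_obs), dtype=bool)
    out = {"scale_k": k, "r": _r(all_mask)}
    if free_flag is not None:
        free = np.asarray(free_flag) != 0
        out["r_work"] = _r(~free)
        out["r_free"] = _r(free)
    return out


# ---------------------------------------------------------------------------
# water placement and support audit
# ---------------------------------------------------------------------------

_POLAR_ELEMENTS = ("N", "O")


def place_candidate_waters(
    peaks: Sequence[Peak],
    structure: Structure,
    peak_min_sigma: float = 3.5,
    hbond_range: tuple[float, float] = (2.4, 3.2),
    clash_min: float = 2.2,
) -> list[CandidateWater]:
    """Promote difference peaks to putative waters.

    A peak qualifies if its height is at least ``peak_min_sigma``, at
    least one N or O atom (protein, ligand or existing water) lies within
    ``hbond_range`` under periodic images, and no atom of any kind is
    closer than ``clash_min``.  The nearest qualifying polar atom is
    reported as the hydrogen-bond partner.
    """
    if not peaks:
        return []
    atoms = structure.atoms
    if not atoms:
        return []
    orth = structure.orth_matrix
    frac_atoms = structure.fractional_positions()
    polar = np.array([a.element.upper() in _POLAR_ELEMENTS for a in atoms])
    out: list[CandidateWater] = []
    for peak in peaks:
        if peak.height_sigma < peak_min_sigma:
            continue
        pf = np.asarray(peak.position_frac)[None, :]
        dist = _min_image_distances(pf, frac_atoms, orth)[0]
        if dist.min() < clash_min:
            continue
        ok = polar & (dist >= hbond_range[0]) & (dist <= hbond_range[1])
        if not ok.any():
            continue
        j = int(np.argmin(np.where(ok, dist, np.inf)))
        out.append(
            CandidateWater(
                position=tuple(peak.position_orth),
                peak_height_sigma=peak.height_sigma,
                partner_distance=float(dist[j]),
                partner_atom=atoms[j],
            )
        )
    return out


def find_waters_2fofc(
    grid: MapGrid,
    structure: Structure,
    threshold_sigma: float = 1.4,
    hbond_range: tuple[float, float] = (2.4, 3.2),
    clash_min: float = 2.2,
    merge_radius: float = 2.0,
) -> list[CandidateWater]:
    """Water search in a σ-scaled 2Fo−Fc map at the 1.4σ default level.

    Same acceptance rule as :func:`place_candidate_waters`; "unoccupied"
    means no existing atom within ``clash_min``.
    """
    peaks = find_peaks(grid, threshold_sigma, sign="positive", merge_radius=merge_radius)
    return place_candidate_waters(
        peaks,
        structure,
        peak_min_sigma=threshold_sigma,
        hbond_range=hbond_range,
        clash_min=clash_min,
    )


def flag_unsupported_waters(
    structure: Structure,
    fo_fc: MapGrid,
    two_fo_fc: MapGrid,
    thresholds: SupportThresholds | None = None,
) -> list[WaterSupportFlag]:
    """Audit each deposited water O against the maps and its parameters.

    Flags per water: ``negative_density`` (Fo−Fc ≤ −3σ at the site),
    ``no_positive_support`` (2Fo−Fc below the support level),
    ``protein_overlap`` (a non-water atom within the overlap distance),
    ``default_adp`` (B equal to the 30.00 Å² placement default, i.e. never
    refined) and ``zero_occupancy_with_refined_adp``.
    """
    th = thresholds or SupportThresholds()
    for grid in (fo_fc, two_fo_fc):
        _check_usable(grid)
        if not np.allclose(grid.cell, structure.cell, rtol=1e-4, atol=1e-3):
            raise ValueError("map cell does not match structure cell")
    waters = [a for a in structure.atoms if a.is_water and a.element not in ("H", "D")]
    if not waters:
        return []
    frac_all = structure.fractional_positions()
    water_idx = [i for i, a in enumerate(structure.atoms) if a.is_water and a.element not in ("H", "D")]
    frac_w = frac_all[water_idx]
    non_water_idx = [i for i, a in enumerate(structure.atoms) if not a.is_water]
    orth = structure.orth_matrix
    diff_vals = fo_fc.interpolate(frac_w)
    two_vals = two_fo_fc.interpolate(frac_w)
    if non_water_idx:
        overlap_d = _min_image_distances(frac_w, frac_all[non_water_idx], orth).min(axis=1)
    else:
        overlap_d = np.full(len(waters), np.inf)
    out = []
    for w, dv, tv, od in zip(waters, diff_vals, two_vals, overlap_d):
        flags = set()
        if dv <= th.negative_sigma:
            flags.add("negative_density")
        if tv < th.positive_support_sigma:
            flags.add("no_positive_support")
        if od < th.overlap_distance:
            flags.add("protein_overlap")
        is_default = abs(w.adp - th.default_adp) <= th.default_adp_tol
        if is_default:
            flags.add("default_adp")
        if w.occupancy == 0.0 and not is_default and w.adp > 0:
            flags.add("zero_occupancy_with_refined_adp")
        out.append(
            WaterSupportFlag(
                water=w,
                diff_value_sigma=float(dv),
                two_fofc_value_sigma=float(tv),
                flags=frozenset(flags),
            )
        )
    return out


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def write_ccp4_map(grid: MapGrid, path: str | Path) -> Path:
    """Write the map in CCP4 format for graphics programs."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    ccp4.grid.unit_cell = gemmi.UnitCell(*grid.cell)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P 1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
    return Path(path)


def peaks_to_csv(peaks: Sequence[Peak], path: str | Path) -> Path:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "x": p.position_orth[0],
                "y": p.position_orth[1],
                "z": p.position_orth[2],
                "height_sigma": p.height_sigma,
            }
            for p in peaks
        ]
    )
    df.to_csv(path, index=False)
    return Path(path)


def candidates_to_pdb(
    candidates: Sequence[CandidateWater], cell, path: str | Path
) -> Path:
    """Write candidate waters as HETATM records for visual inspection."""
    lines = ["CRYST1{:9.3f}{:9.3f}{:9.3f}{:7.2f}{:7.2f}{:7.2f} P 1".format(*cell)]
    for i, c in enumerate(candidates, start=1):
        lines.append(
            f"HETATM{i:5d}  O   HOH W{i:4d}    "
            f"{c.position[0]:8.3f}{c.position[1]:8.3f}{c.position[2]:8.3f}"
            f"  1.00{min(c.peak_height_sigma, 99.99):6.2f}           O"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
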