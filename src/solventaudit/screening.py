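"""Working-set filters and per-structure solvent audit rules.

Implements the deposition-screening side of the audit: which entries
enter the cohort (protein crystal structures at 2.5 Å or better, chains
of at least 30 residues, no group depositions), the occupancy anomaly
classes for modeled waters, the R/R_free consistency checks against the
recalculated (DCC) values, and the expected water-per-residue ratio as a
function of resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .density import WaterSupportFlag
from .io_structures import AtomRecord, Method, StructureMetadata

__all__ = [
    "FilterConfig",
    "OccupancyClass",
    "AnomalyReport",
    "RfactorFlags",
    "apply_working_set_filters",
    "classify_occupancy",
    "audit_structure",
    "rfactor_consistency",
    "expected_water_ratio",
    "reference_ratio_curve",
]


@dataclass
class FilterConfig:
    """Cohort-selection rules for the waterless-structure working set."""

    max_resolution: float = 2.5  # Å; "2.5 Å or higher" resolution, inclusive
    min_chain_length: int = 30  # residues in the longest polypeptide chain
    allowed_methods: frozenset = frozenset({Method.xray, Method.neutron})
    exclude_group_depositions: bool = True

    def __post_init__(self) -> None:
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")
        if self.min_chain_length < 1:
            raise ValueError("min_chain_length must be >= 1")


class OccupancyClass(str, Enum):
    """Partition of water occupancy values.

    zero = 0.0; near_zero = (0, 0.1]; normal = (0.1, 0.9);
    near_full = [0.9, 1.0); full = exactly 1.0 (not an anomaly);
    over = (1.0, ∞).  A near-full occupancy like 0.99 is flagged because
    no realistic diffraction experiment distinguishes it from 1.0; the
    upper edge is taken as 1.0 exclusive so that e.g. 0.995 is still
    flagged.
    """

    zero = "zero"
    near_zero = "near_zero"
    normal = "normal"
    near_full = "near_full"
    full = "full"
    over = "over"


#: Classes that indicate a suspicious water model (full occupancy is fine).
ANOMALOUS_CLASSES = (
    OccupancyClass.zero,
    OccupancyClass.near_zero,
    OccupancyClass.near_full,
    OccupancyClass.over,
)


def classify_occupancy(occ: float) -> OccupancyClass:
    """Classify one water occupancy value; negative values are data errors."""
    if not math.isfinite(occ):
        raise ValueError("occupancy must be finite")
    if occ < 0:
        raise ValueError(f"negative occupancy {occ}: data error, report separately")
    if occ == 0.0:
        return OccupancyClass.zero
    if occ <= 0.1:
        return OccupancyClass.near_zero
    if occ < 0.9:
        return OccupancyClass.normal
    if occ < 1.0:
        return OccupancyClass.near_full
    if occ == 1.0:
        return OccupancyClass.full
    return OccupancyClass.over


@dataclass
class RfactorFlags:
    evaluable: bool
    r_gt_rfree_depositor: bool = False
    r_gt_rfree_dcc: bool = False
    dcc_gap_work: bool = False
    dcc_gap_free: bool = False
    gap_work: float | None = None
    gap_free: float | None = None


@dataclass
class AnomalyReport:
    """Per-structure audit result."""

    entry_id: str
    waterless: bool
    n_waters: int
    n_waters_by_class: dict[OccupancyClass, int]
    rfactor_flags: RfactorFlags
    water_residue_ratio: float | None
    expected_ratio: float | None = None
    deficit: float | None = None
    negative_occupancy_waters: int = 0
    default_adp_waters: int = 0
    zero_occ_refined_adp_waters: int = 0
    support_flags: list[WaterSupportFlag] = field(default_factory=list)

    def has_class(self, cls: OccupancyClass) -> bool:
        return self.n_waters_by_class.get(cls, 0) > 0

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "waterless": self.waterless,
            "n_waters": self.n_waters,
            "n_waters_by_class": {k.value: v for k, v in self.n_waters_by_class.items()},
            "r_gt_rfree_depositor": self.rfactor_flags.r_gt_rfree_depositor,
            "r_gt_rfree_dcc": self.rfactor_flags.r_gt_rfree_dcc,
            "dcc_gap_work": self.rfactor_flags.dcc_gap_work,
            "dcc_gap_free": self.rfactor_flags.dcc_gap_free,
            "water_residue_ratio": self.water_residue_ratio,
            "expected_ratio": self.expected_ratio,
            "deficit": self.deficit,
            "negative_occupancy_waters": self.negative_occupancy_waters,
            "default_adp_waters": self.default_adp_waters,
            "zero_occ_refined_adp_waters": self.zero_occ_refined_adp_waters,
        }


# ---------------------------------------------------------------------------
# working-set filters
# ---------------------------------------------------------------------------

def apply_working_set_filters(
    records: Sequence[StructureMetadata],
    cfg: FilterConfig | None = None,
    longest_chain: Sequence[int] | None = None,
) -> tuple[list[StructureMetadata], dict[str, str]]:
    """Select the audit working set; every exclusion names its first failing rule.

    ``longest_chain`` optionally supplies the longest-polypeptide length per
    record; when absent, ``n_residues`` is used as the (single-chain) proxy.
    Returns (retained records, {entry_id: exclusion reason}).
    """
    cfg = cfg or FilterConfig()
    kept: list[StructureMetadata] = []
    excluded: dict[str, str] = {}
    for i, rec in enumerate(records):
        chain_len = (
            longest_chain[i] if longest_chain is not None else rec.n_residues
        )
        reason = None
        if rec.method is None or rec.method not in cfg.allowed_methods:
            reason = "method"
        elif rec.resolution is None:
            reason = "missing_resolution"
        elif rec.resolution > cfg.max_resolution:
            reason = "resolution"
        elif chain_len is None or chain_len < cfg.min_chain_length:
            reason = "chain_length"
        elif cfg.exclude_group_depositions and rec.is_group_deposition:
            reason = "group_deposition"
        if reason is None:
            kept.append(rec)
        else:
            excluded[rec.entry_id] = reason
    return kept, excluded


# ---------------------------------------------------------------------------
# per-structure audit
# ---------------------------------------------------------------------------

def audit_structure(
    metadata: StructureMetadata,
    waters: Sequence[AtomRecord],
    expected_curve=None,
    gap_threshold: float = 0.02,
    default_adp: float = 30.00,
    default_adp_tol: float = 0.005,
) -> AnomalyReport:
    """Build the per-structure anomaly report from metadata and water records.

    ``waters`` are the water oxygen records.  When ``expected_curve`` (a
    resolution -> expected water/residue ratio callable or RatioCurve) is
    given and the metadata has a resolution, the expected ratio and the
    deficit (expected − observed) are filled in.
    """
    counts = {cls: 0 for cls in OccupancyClass}
    negative = 0
    default_b = 0
    zero_occ_refined = 0
    for w in waters:
        if w.occupancy < 0:
            negative += 1
            continue
        counts[classify_occupancy(w.occupancy)] += 1
        is_default = abs(w.adp - default_adp) <= default_adp_tol
        if is_default:
            default_b += 1
        if w.occupancy == 0.0 and not is_default and w.adp > 0:
            zero_occ_refined += 1
    n_waters = len(waters)
    ratio = None
    if metadata.n_residues:
        ratio = n_waters / metadata.n_residues
    expected = None
    deficit = None
    if expected_curve is not None and metadata.resolution is not None:
        expected = expected_water_ratio(metadata.resolution, expected_curve)
        if ratio is not None:
            deficit = expected - ratio
    return AnomalyReport(
        entry_id=metadata.entry_id,
        waterless=n_waters == 0,
        n_waters=n_waters,
        n_waters_by_class=counts,
        rfactor_flags=rfactor_consistency(metadata, gap_threshold),
        water_residue_ratio=ratio,
        expected_ratio=expected,
        deficit=deficit,
        negative_occupancy_waters=negative,
        default_adp_waters=default_b,
        zero_occ_refined_adp_waters=zero_occ_refined,
    )


def rfactor_consistency(
    metadata: StructureMetadata, gap_threshold: float = 0.02
) -> RfactorFlags:
    """Diagnose R/R_free inconsistencies between depositor and DCC values.

    A depositor-to-DCC gap above ``gap_threshold`` suggests the deposited
    model differs from the refined one (e.g. solvent lost on deposition);
    R_work > R_free within one source is an inverted cross-validation
    relationship.  Differences of ~0.01 are expected from program-to-program
    variation, hence the 0.02 default.
    """
    rw_d, rf_d = metadata.r_work_depositor, metadata.r_free_depositor
    rw_c, rf_c = metadata.r_work_dcc, metadata.r_free_dcc
    if all(v is None for v in (rw_d, rf_d, rw_c, rf_c)):
        return RfactorFlags(evaluable=False)
    flags = RfactorFlags(evaluable=True)
    if rw_d is not None and rf_d is not None:
        flags.r_gt_rfree_depositor = rw_d > rf_d
    if rw_c is not None and rf_c is not None:
        flags.r_gt_rfree_dcc = rw_c > rf_c
    if rw_d is not None and rw_c is not None:
        flags.gap_work = rw_c - rw_d
        flags.dcc_gap_work = flags.gap_work > gap_threshold
    if rf_d is not None and rf_c is not None:
        flags.gap_free = rf_c - rf_d
        flags.dcc_gap_free = flags.gap_free > gap_threshold
    return flags


# ---------------------------------------------------------------------------
# expected water/residue ratio vs resolution
# ---------------------------------------------------------------------------

#: Packaged reference for the cohort-average water/residue ratio as a
#: function of resolution.  Anchored at the published cohort means: 1.78
#: for structures at 1.0 Å or better, 0.61 at 2.0 Å and 0.25 at 2.5 Å,
#: with a smooth monotone decay between anchors.
_REFERENCE_TABLE = np.array(
    [
        (0.60, 1.78),
        (1.00, 1.78),
        (1.25, 1.40),
        (1.50, 1.07),
        (1.75, 0.82),
        (2.00, 0.61),
        (2.25, 0.41),
        (2.50, 0.25),
    ]
)


def reference_ratio_curve():
    """Monotone-cubic interpolant of the packaged ratio-vs-resolution table."""
    from scipy.interpolate import PchipInterpolator

    return PchipInterpolator(_REFERENCE_TABLE[:, 0], _REFERENCE_TABLE[:, 1])


def expected_water_ratio(resolution: float, reference=None) -> float:
    """Expected waters-per-residue ratio at a given resolution.

    ``reference`` may be a fitted RatioCurve (from cohort_stats), any
    callable, or None for the packaged reference table.  Outside the
    reference range the nearest-endpoint value is returned.
    """
    if reference is None:
        reference = reference_ratio_curve()
    lo, hi = _fit_range(reference)
    x = min(max(resolution, lo), hi)
    value = reference(x)
    return float(value)


def _fit_range(reference) -> tuple[float, float]:
    rng = getattr(reference, "fit_range", None)
    if rng is not None:
        return rng
    x = getattr(reference, "x", None)
    if x is not None:  # scipy interpolator knots
        return float(np.min(x)), float(np.max(x))
    return (-math.inf, math.inf)
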