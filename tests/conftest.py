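"""Shared fixtures: printed-table water set and reusable toy crystals."""

from __future__ import annotations

import numpy as np
import pytest

from solventaudit import synthetic_data

# The first 20 waters of PDB entry 6ynq as printed in its deposition
# (serial, resid, x, y, z, occupancy, B).  Used as the worked example for
# water parsing and occupancy classification.
TABLE1_WATERS = [
    (5046, 501, 21.069, -3.189, 32.245, 0.85, 48.76),
    (5047, 502, 21.656, -2.374, 25.903, 0.58, 38.42),
    (5048, 503, 12.136, 30.803, -8.812, 0.78, 36.68),
    (5049, 504, 16.659, -5.561, 33.251, 1.00, 47.52),
    (5050, 505, 16.365, 31.436, 0.767, 0.80, 47.21),
    (5051, 506, 15.871, -13.121, 31.723, 1.00, 40.38),
    (5052, 507, 13.213, 23.824, -18.522, 1.00, 55.50),
    (5053, 508, 6.749, -1.420, -4.404, 0.71, 33.78),
    (5054, 509, 3.663, 3.997, -18.333, 0.93, 47.53),
    (5055, 510, 4.326, -6.611, -17.259, 1.00, 49.70),
    (5056, 511, 0.035, -1.289, 12.377, 0.78, 28.89),
    (5057, 512, 19.251, -23.552, 9.203, 0.88, 44.06),
    (5058, 513, 6.327, 10.284, -0.879, 1.00, 25.60),
    (5059, 514, 1.973, 14.147, 0.488, 0.87, 36.33),
    (5060, 515, 10.913, -16.850, 29.957, 0.89, 41.88),
    (5061, 516, 3.010, 5.399, 20.334, 1.00, 29.04),
    (5062, 517, 14.798, -25.987, 26.809, 1.00, 30.70),
    (5063, 518, 15.797, -21.945, 31.403, 0.99, 29.00),
    (5064, 519, 24.445, -5.903, 8.988, 0.86, 38.58),
    (5065, 520, 3.655, 22.359, -0.802, 0.92, 42.03),
]


def waters_pdb_text(rows=TABLE1_WATERS) -> str:
    lines = ["CRYST1   60.000   70.000   80.000  90.00  90.00  90.00 P 1"]
    for serial, resid, x, y, z, occ, b in rows:
        lines.append(
            f"HETATM{serial:5d}  O   HOH A{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           O"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def table1_pdb_text() -> str:
    return waters_pdb_text()


@pytest.fixture(scope="session")
def toy_crystal():
    """A default toy crystal with its ground truth (seed 7)."""
    spec = synthetic_data.ToyCrystalSpec(seed=7)
    return synthetic_data.make_toy_crystal(spec)


@pytest.fixture(scope="session")
def noise_free_deletion():
    """(full, truncated, truth, f_obs) for a 10-water deletion, no noise."""
    spec = synthetic_data.ToyCrystalSpec(seed=11)
    full, _ = synthetic_data.make_toy_crystal(spec)
    refl = synthetic_data.simulate_amplitudes(full, d_min=1.8, noise_frac=0.0, seed=11)
    trunc, truth = synthetic_data.delete_waters(full, fraction=10 / 12, seed=11)
    return full, trunc, truth, refl


def periodic_distance(structure, p, q) -> float:
    """Minimum-image distance between two orthogonal-Å points."""
    frac_inv = np.linalg.inv(structure.orth_matrix)
    d = frac_inv @ np.asarray(p, float) - frac_inv @ np.asarray(q, float)
    d -= np.round(d)
    return float(np.linalg.norm(structure.orth_matrix @ d))
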