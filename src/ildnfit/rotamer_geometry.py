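"""Dihedral geometry, chi1 extraction and three-state rotamer statistics.

chi1 values are partitioned into the canonical side-chain wells

    plus  (p):  chi1 in (0, 120]      -- well centre +60
    minus (m):  chi1 in (-120, 0]     -- well centre -60
    trans (t):  otherwise             -- well centre 180

and a three-state population vector per residue type is compared against a
reference distribution (e.g. helix statistics) with the root-mean-square
deviation over the three states,

    RMSD(a, b) = sqrt( (1/3) * sum_s (a_s - b_s)^2 ).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from ildnfit.torsion_model import wrap_angle

__all__ = [
    "DihedralSeries",
    "RotamerDistribution",
    "dihedral_angle",
    "extract_chi1",
    "classify_rotamer",
    "rotamer_distribution",
    "distribution_rmsd",
    "chi1_atom_quadruple",
    "read_dihedral_series",
    "write_dihedral_series",
    "read_reference_distributions",
    "write_reference_distributions",
    "CHI1_FOURTH_ATOM",
]

ROTAMER_STATES = ("p", "m", "t")

# fourth chi1 atom per residue type; N-CA-CB-<atom>.  Ile follows the CG2
# convention of the published parameter table.
CHI1_FOURTH_ATOM: Dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG2", "VAL": "CG1", "THR": "OG1", "SER": "OG", "CYS": "SG",
}


@dataclass
class DihedralSeries:
    """Per-frame dihedral values (degrees) for one residue and angle label."""

    residue_id: str
    residue_type: str
    angle: str
    values: np.ndarray

    def __post_init__(self):
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if values.size == 0:
            raise ValueError("dihedral series must be non-empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("dihedral series contains non-finite values")
        self.values = np.atleast_1d(wrap_angle(values))
        self.residue_type = self.residue_type.upper()

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RotamerDistribution:
    """Three-state (p, m, t) population vector; fractions sum to 1."""

    p: float
    m: float
    t: float

    def __post_init__(self):
        total = self.p + self.m + self.t
        if min(self.p, self.m, self.t) < 0 or abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"populations must be non-negative and sum to 1, got "
                f"p={self.p} m={self.m} t={self.t}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.m, self.t])

    def __getitem__(self, state: str) -> float:
        return {"p": self.p, "m": self.m, "t": self.t}[state]


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention.

    The angle is measured around the p2-p3 axis; a cis (eclipsed)
    arrangement gives 0 and trans gives 180.  Result lies in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-12:
        raise ValueError("central bond has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate dihedral: three consecutive points are collinear")
    # atan2 formulation is numerically stable near 0 and 180
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def chi1_atom_quadruple(residue_type: str):
    """Atom names (N, CA, CB, X) defining chi1 for a residue type."""
    residue_type = residue_type.upper()
    if residue_type not in CHI1_FOURTH_ATOM:
        raise KeyError(f"residue type {residue_type} has no chi1 dihedral")
    return ("N", "CA", "CB", CHI1_FOURTH_ATOM[residue_type])


def extract_chi1(residue) -> float:
    """chi1 (degrees) of a Bio.PDB residue via its residue-specific quadruple.

    Uses the first model / preferred altloc coordinates that Bio.PDB exposes
    by default.  Raises a KeyError naming the atom if the residue lacks one
    of the four chi1 atoms.
    """
    resname = residue.get_resname().strip().upper()
    quad = chi1_atom_quadruple(resname)
    coords = []
    for atom_name in quad:
        if atom_name not in residue:
            raise KeyError(
                f"residue {resname} {residue.get_id()[1]} is missing atom "
                f"{atom_name} required for chi1"
            )
        coords.append(residue[atom_name].get_coord())
    return dihedral_angle(*coords)


def classify_rotamer(chi1: float) -> str:
    """Map a chi1 angle to its rotamer state 'p', 'm' or 't'."""
    if not np.isfinite(chi1):
        raise ValueError("chi1 must be finite")
    chi1 = wrap_angle(float(chi1))
    if 0.0 < chi1 <= 120.0:
        return "p"
    if -120.0 < chi1 <= 0.0:
        return "m"
    return "t"


def rotamer_distribution(series: DihedralSeries) -> RotamerDistribution:
    """Three-state populations of a chi1 series (state counts / frame count)."""
    values = series.values
    p_mask = (values > 0.0) & (values <= 120.0)
    m_mask = (values > -120.0) & (values <= 0.0)
    t_mask = ~(p_mask | m_mask)
    return RotamerDistribution(
        p=float(np.mean(p_mask)), m=float(np.mean(m_mask)), t=float(np.mean(t_mask))
    )


def distribution_rmsd(a: RotamerDistribution, b: RotamerDistribution) -> float:
    """RMSD between two three-state population vectors."""
    diff = a.as_array() - b.as_array()
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_dihedral_series(series_map: Mapping[str, DihedralSeries], path, sep=",") -> None:
    """Write chi1 time series as columns of a delimited table.

    Column headers are '<residue_id>:<residue_type>'; one row per frame.
    """
    data = {
        f"{s.residue_id}:{s.residue_type}": s.values for s in series_map.values()
    }
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.4f")


def read_dihedral_series(path, angle: str = "chi1") -> Dict[str, DihedralSeries]:
    """Read a delimited chi1 time-series table written by write_dihedral_series."""
    with open(path) as handle:
        first = handle.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    out: Dict[str, DihedralSeries] = {}
    for col in df.columns:
        if ":" in col:
            residue_id, residue_type = col.split(":", 1)
        else:
            residue_id, residue_type = col, col[:3]
        out[col] = DihedralSeries(
            residue_id=residue_id,
            residue_type=residue_type,
            angle=angle,
            values=df[col].to_numpy(dtype=float),
        )
    return out


def write_reference_distributions(dists: Mapping[str, RotamerDistribution], path) -> None:
    """Write a reference rotamer-distribution table (residue_type, p, m, t)."""
    rows = [
        {"residue_type": name, "p": d.p, "m": d.m, "t": d.t}
        for name, d in dists.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_reference_distributions(path) -> Dict[str, RotamerDistribution]:
    """Read a reference rotamer-distribution table (residue_type, p, m, t)."""
    df = pd.read_csv(path, comment="#")
    required = {"residue_type", "p", "m", "t"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: reference table needs columns {sorted(required)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["residue_type"]).upper()] = RotamerDistribution(
            p=float(row["p"]), m=float(row["m"]), t=float(row["t"])
        )
    return out
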