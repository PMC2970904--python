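"""Dihedral scan grids and scan-table I/O.

A scan table pairs side-chain conformations (chi1, optionally chi2, at a
fixed backbone phi/psi) with a reference quantum-mechanical energy ``E_qm``
and the base molecular-mechanics energy ``E_mm_base`` — the force-field
energy with the torsion term under refit already removed.

The canonical grids are the ones used to parameterize ff99SB-ILDN:

* 1D chi1 scans in 15-degree steps crossed with chi2 in {-60, 60, 180}
  (24 x 3 = 72 points, used for Ile and Leu);
* full 2D chi1/chi2 grids in 30-degree steps (12 x 12 = 144 points, Asn),
  halved to 72 points for Asp because its carboxylate makes chi2 two-fold
  symmetric (chi2 and chi2 + 180 are the same physical state).

"Varied between -180 and 180 in s-degree increments" is read as 360/s unique
angles: -180 and +180 are the same conformation and counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ildnfit.torsion_model import wrap_angle

__all__ = [
    "ScanTable",
    "make_chi1_grid",
    "make_chi1_chi2_grid",
    "read_scan_table",
    "write_scan_table",
]

SCAN_COLUMNS = ["chi1", "chi2", "phi", "psi", "E_qm", "E_mm_base"]

# backbone constraint of the dipeptide scans: extended conformation
DEFAULT_PHI = -135.0
DEFAULT_PSI = 135.0


@dataclass
class ScanTable:
    """Ordered collection of scan points with residue/backbone metadata.

    The payload is a DataFrame with columns chi1, chi2, phi, psi, E_qm,
    E_mm_base.  chi2 and the energies may be NaN (pure-chi1 scans, grids not
    yet populated with energies).
    """

    points: pd.DataFrame
    residue: str = ""

    def __post_init__(self):
        df = self.points.copy()
        for col in SCAN_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[SCAN_COLUMNS].reset_index(drop=True)
        df["chi1"] = wrap_angle(df["chi1"].to_numpy(dtype=float))
        chi2 = df["chi2"].to_numpy(dtype=float)
        mask = np.isfinite(chi2)
        chi2[mask] = np.atleast_1d(wrap_angle(chi2[mask]))
        df["chi2"] = chi2
        self.points = df
        self._validate()

    def _validate(self):
        df = self.points
        if len(df) == 0:
            raise ValueError("scan table has no points")
        for col in ("phi", "psi"):
            vals = df[col].dropna().unique()
            if len(vals) > 1:
                raise ValueError(f"backbone angle {col} is not constant across points: {vals}")
        for col in ("E_qm", "E_mm_base"):
            vals = df[col].to_numpy(dtype=float)
            present = ~np.isnan(vals)
            if np.any(~np.isfinite(vals[present])):
                raise ValueError(f"non-finite values in column {col}")
        keys = list(zip(np.round(df["chi1"], 6), np.round(df["chi2"].fillna(0.0), 6)))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chi1, chi2) conformations after angle wrapping")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def phi(self) -> float:
        return float(self.points["phi"].dropna().iloc[0])

    @property
    def psi(self) -> float:
        return float(self.points["psi"].dropna().iloc[0])

    @property
    def has_chi2(self) -> bool:
        return bool(self.points["chi2"].notna().all())

    def has_energies(self) -> bool:
        return bool(self.points[["E_qm", "E_mm_base"]].notna().all().all())

    def with_energies(self, E_qm, E_mm_base) -> "ScanTable":
        df = self.points.copy()
        df["E_qm"] = np.asarray(E_qm, dtype=float)
        df["E_mm_base"] = np.asarray(E_mm_base, dtype=float)
        return ScanTable(df, residue=self.residue)


def _unique_circle(step: float) -> np.ndarray:
    """Unique angles covering the circle in `step`-degree increments."""
    n = 360.0 / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"step {step} deg does not divide 360")
    n = int(round(n))
    return np.atleast_1d(wrap_angle(-180.0 + step * np.arange(n)))


def make_chi1_grid(
    step: float = 15.0,
    chi2_values: Sequence[float] = (-60.0, 60.0, 180.0),
    residue: str = "",
    phi: float = DEFAULT_PHI,
    psi: float = DEFAULT_PSI,
) -> ScanTable:
    """1D chi1 scan grid crossed with a small set of fixed chi2 values.

    With the defaults (15-degree steps, chi2 in {-60, 60, 180}) this yields
    the 72-point Ile/Leu scan layout.
    """
    chi1 = _unique_circle(step)
    rows = [
        {"chi1": c1, "chi2": wrap_angle(c2), "phi": phi, "psi": psi}
        for c2 in chi2_values
        for c1 in chi1
    ]
    return ScanTable(pd.DataFrame(rows), residue=residue)


def make_chi1_chi2_grid(
    step: float = 30.0,
    chi2_symmetric: bool = False,
    residue: str = "",
    phi: float = DEFAULT_PHI,
    psi: float = DEFAULT_PSI,
) -> ScanTable:
    """Full 2D chi1/chi2 grid; optionally halved for a two-fold symmetric chi2.

    When ``chi2_symmetric`` is set, chi2 values are folded into [0, 180)
    under chi2 ~ chi2 + 180 (the Asp carboxylate symmetry), which halves the
    point count: 72 instead of 144 at 30-degree steps.
    """
    chi1 = _unique_circle(step)
    chi2 = _unique_circle(step)
    if chi2_symmetric:
        folded = sorted({c % 180.0 for c in chi2})
        chi2 = np.array(folded)
    rows = [
        {"chi1": c1, "chi2": float(wrap_angle(c2)), "phi": phi, "psi": psi}
        for c2 in chi2
        for c1 in chi1
    ]
    return ScanTable(pd.DataFrame(rows), residue=residue)


def write_scan_table(table: ScanTable, path, sep: str = ",") -> None:
    """Write a scan table as delimited text with a commented metadata header."""
    with open(path, "w") as handle:
        handle.write(f"# residue={table.residue}\n")
        handle.write(f"# phi={table.phi:.4f} psi={table.psi:.4f}\n")
        table.points.to_csv(handle, sep=sep, index=False, float_format="%.8f")


def read_scan_table(path) -> ScanTable:
    """Read a delimited scan table (comma or tab, auto-detected)."""
    residue = ""
    header_lines = 0
    with open(path) as handle:
        first_data = None
        for line in handle:
            if line.startswith("#"):
                header_lines += 1
                if "residue=" in line:
                    residue = line.split("residue=", 1)[1].strip()
            else:
                first_data = line
                break
    if first_data is None:
        raise ValueError(f"{path}: no data rows")
    sep = "\t" if first_data.count("\t") >= first_data.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # surface the offending file in the message
        raise ValueError(f"{path}: malformed scan table: {exc}") from exc
    missing = [c for c in ("chi1", "phi", "psi") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for lineno, row in enumerate(df.itertuples(index=False), start=header_lines + 2):
        for value in row:
            if isinstance(value, float) and np.isinf(value):
                raise ValueError(f"{path}:{lineno}: non-finite value")
    return ScanTable(df, residue=residue)
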