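"""Cosine-series torsion potentials in the Amber convention.

A torsion term is V(theta) = sum_m k_m * [1 + cos(m*theta - theta0)] with the
phase theta0 fixed to 0 degrees in the ff99SB-ILDN parameter set.  Force
constants may be negative; the "1 +" offsets shift the energy by a constant
and never affect forces or fitted populations.

The module also packages the published ff99SB-ILDN replacement parameters for
the chi1 torsions of Ile, Leu, Asp and Asn and the chi2 torsions of Asp and
Asn, together with the dihedral atom quadruple each series applies to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "CosineSeries",
    "TorsionDefinition",
    "RestraintSpec",
    "evaluate_torsion",
    "torsion_amplitude",
    "evaluate_restraint",
    "ildn_parameters",
    "ILDN_RESIDUES",
    "wrap_angle",
    "read_parameter_table",
    "write_parameter_table",
]


def wrap_angle(theta):
    """Wrap an angle in degrees into the interval (-180, 180]."""
    wrapped = np.asarray(theta, dtype=float) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # map -180 (from exactly 180 mod 360 == 180 stays) : 180 stays 180
    wrapped = np.where(wrapped <= -180.0, wrapped + 360.0, wrapped)
    if np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class CosineSeries:
    """Periodic torsion potential: sum_m k_m [1 + cos(m*theta - theta0)].

    Parameters
    ----------
    terms
        Sequence of (multiplicity, force constant) pairs.  Multiplicities are
        distinct positive integers; force constants are in kcal/mol and may
        be negative.
    theta0
        Phase in degrees, applied identically to every term.  The Amber
        convention used throughout this package fixes it at 0.
    """

    terms: Tuple[Tuple[int, float], ...]
    theta0: float = 0.0

    def __init__(self, terms: Iterable[Tuple[int, float]], theta0: float = 0.0):
        terms = tuple((int(m), float(k)) for m, k in terms)
        if not terms:
            raise ValueError("CosineSeries requires at least one term")
        mults = [m for m, _ in terms]
        if any(m < 1 for m in mults):
            raise ValueError(f"multiplicities must be positive integers, got {mults}")
        if len(set(mults)) != len(mults):
            raise ValueError(f"multiplicities must be distinct, got {mults}")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "theta0", float(theta0))

    @classmethod
    def from_constants(cls, force_constants: Sequence[float], theta0: float = 0.0) -> "CosineSeries":
        """Build a series from k_1 ... k_M listed in multiplicity order."""
        return cls([(m, k) for m, k in enumerate(force_constants, start=1)], theta0)

    @property
    def multiplicities(self) -> Tuple[int, ...]:
        return tuple(m for m, _ in self.terms)

    @property
    def force_constants(self) -> Tuple[float, ...]:
        return tuple(k for _, k in self.terms)

    def __call__(self, theta):
        return evaluate_torsion(self, theta)


@dataclass(frozen=True)
class TorsionDefinition:
    """A named dihedral: residue, angle label, and the four atoms defining it."""

    residue: str
    angle: str
    atoms: Tuple[str, str, str, str]

    def __init__(self, residue: str, angle: str, atoms: Sequence[str]):
        atoms = tuple(str(a) for a in atoms)
        if len(atoms) != 4:
            raise ValueError(f"a dihedral is defined by exactly 4 atoms, got {atoms}")
        angle = angle.lower()
        if angle not in ("chi1", "chi2"):
            raise ValueError(f"angle label must be 'chi1' or 'chi2', got {angle!r}")
        object.__setattr__(self, "residue", residue.upper())
        object.__setattr__(self, "angle", angle)
        object.__setattr__(self, "atoms", atoms)

    def __str__(self) -> str:
        return "-".join(self.atoms)


@dataclass(frozen=True)
class RestraintSpec:
    """Single-well periodic restraint k_theta * [1 + cos(theta - theta_ref)].

    The minimum sits at theta_ref - 180 degrees.  With the published settings
    (theta_ref = 122 deg for phi, 133 deg for psi, k_theta = 1 kcal/mol) the
    minima fall at -58 and -47 degrees, i.e. in the alpha-helical basin, so a
    weak restraint of this form keeps a short peptide helical without
    confining the side chain.
    """

    theta_ref: float
    k_theta: float = 1.0

    def __post_init__(self):
        if self.k_theta < 0:
            raise ValueError("restraint force constant must be non-negative")


def evaluate_torsion(series: CosineSeries, theta) -> float:
    """Evaluate V(theta) = sum_m k_m [1 + cos(m*theta - theta0)] in kcal/mol.

    ``theta`` is in degrees; scalars and arrays are both accepted.
    """
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValueError("torsion angle must be finite")
    rad = np.deg2rad(th)
    phase = math.radians(series.theta0)
    energy = np.zeros_like(rad)
    for m, k in series.terms:
        energy = energy + k * (1.0 + np.cos(m * rad - phase))
    if np.ndim(theta) == 0:
        return float(energy)
    return energy


def torsion_amplitude(series: CosineSeries, grid_step: float = 0.05) -> float:
    """Peak-to-peak amplitude max V - min V over a dense angle grid.

    The grid step defaults to 0.05 degrees, comfortably below the 0.1-degree
    resolution at which the published series' amplitudes are quoted.
    """
    if grid_step <= 0 or grid_step > 0.1:
        raise ValueError("grid_step must be in (0, 0.1] degrees")
    grid = np.arange(-180.0, 180.0, grid_step)
    values = evaluate_torsion(series, grid)
    return float(values.max() - values.min())


def evaluate_restraint(spec: RestraintSpec, theta) -> float:
    """Energy of the helical backbone restraint k_theta [1 + cos(theta - theta_ref)]."""
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValueError("restraint angle must be finite")
    energy = spec.k_theta * (1.0 + np.cos(np.deg2rad(th - spec.theta_ref)))
    if np.ndim(theta) == 0:
        return float(energy)
    return energy


# Published ff99SB-ILDN replacement parameters (kcal/mol, theta0 = 0 deg),
# with the dihedral quadruple each correction is applied to.  Asp chi2 is
# applied to both carboxylate oxygens.
_ILDN_TABLE = {
    ("ILE", "chi1"): (
        (0.195, -0.846),
        ("N", "CA", "CB", "CG2"),
    ),
    ("LEU", "chi1"): (
        (0.571, -0.358, 0.135),
        ("C", "CA", "CB", "CG"),
    ),
    ("ASP", "chi1"): (
        (-2.635, -1.190, -0.007, 0.423, 0.232, -0.213),
        ("N", "CA", "CB", "CG"),
    ),
    ("ASP", "chi2"): (
        (0.0, -0.443, 0.0, -0.138, 0.0, -0.013),
        ("CA", "CB", "CG", "OD1"),
    ),
    ("ASN", "chi1"): (
        (0.571, -0.596, 0.118, -0.417, 0.104, -0.101),
        ("C", "CA", "CB", "CG"),
    ),
    ("ASN", "chi2"): (
        (-1.046, -0.181, -0.035, 0.100, 0.130, -0.106),
        ("CA", "CB", "CG", "ND2"),
    ),
}

ILDN_RESIDUES = ("ILE", "LEU", "ASP", "ASN")


def ildn_parameters(residue: str, angle: str = "chi1") -> Tuple[CosineSeries, TorsionDefinition]:
    """Return the published replacement series and dihedral definition.

    Parameters
    ----------
    residue
        Three-letter residue code; one of ILE, LEU, ASP, ASN.
    angle
        'chi1' for all four residues; 'chi2' additionally for ASP and ASN.

    Raises
    ------
    KeyError
        If the residue/angle pair is not part of the modified set.
    """
    key = (residue.upper(), angle.lower())
    if key not in _ILDN_TABLE:
        raise KeyError(
            f"no modified torsion parameters for {key[0]} {key[1]}; "
            f"available: {sorted(_ILDN_TABLE)}"
        )
    constants, atoms = _ILDN_TABLE[key]
    series = CosineSeries.from_constants(constants)
    definition = TorsionDefinition(key[0], key[1], atoms)
    return series, definition


# ---------------------------------------------------------------------------
# plain-text parameter table: one line per term
# residue  angle  atom_quadruple  m  k_m  theta0


def write_parameter_table(entries, path) -> None:
    """Write (TorsionDefinition, CosineSeries) pairs as a plain-text table."""
    lines = ["# residue\tangle\tatoms\tm\tk_m\ttheta0"]
    for definition, series in entries:
        for m, k in series.terms:
            lines.append(
                f"{definition.residue}\t{definition.angle}\t{definition}\t"
                f"{m}\t{k:.3f}\t{series.theta0:.1f}"
            )
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def read_parameter_table(path):
    """Read the plain-text parameter table back into definition/series pairs."""
    groups: dict = {}
    order = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields")
            residue, angle, atoms, m, k, theta0 = parts
            key = (residue, angle, atoms)
            if key not in groups:
                groups[key] = {"terms": [], "theta0": float(theta0)}
                order.append(key)
            groups[key]["terms"].append((int(m), float(k)))
    result = []
    for residue, angle, atoms in order:
        entry = groups[(residue, angle, atoms)]
        definition = TorsionDefinition(residue, angle, atoms.split("-"))
        result.append((definition, CosineSeries(entry["terms"], entry["theta0"])))
    return result
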