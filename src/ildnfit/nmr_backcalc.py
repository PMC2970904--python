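"""Back-calculation of NMR observables from conformational ensembles.

Two observable classes that directly probe side-chain conformation:

* three-bond scalar couplings via the Karplus relation
  J(theta) = A cos^2(theta + delta) + B cos(theta + delta) + C,
  ensemble-averaged by evaluating J per frame and averaging the coupling
  (never the angle);
* residual dipolar couplings (RDCs) via a molecular alignment (Saupe)
  tensor: D = Dmax * u^T S u for a unit bond vector u, with S symmetric
  and traceless (five independent components), fit linearly from >= 5
  measured couplings and then used to predict further bonds as ensemble
  averages.

Karplus coefficients and Dmax scale factors are not part of the fitting
method itself; they live in an editable registry of named presets (YAML)
so that any published coefficient set can be swapped in.  The shipped
defaults are representative literature-style values for the four supported
coupling classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ildnfit.rotamer_geometry import DihedralSeries

__all__ = [
    "KarplusParams",
    "AlignmentTensor",
    "karplus_j",
    "ensemble_j",
    "fit_alignment_tensor",
    "predict_rdc",
    "sum_amide_rdcs",
    "observable_rmsd",
    "default_karplus_registry",
    "load_karplus_registry",
    "save_karplus_registry",
    "COUPLING_CLASSES",
]

COUPLING_CLASSES = ("HA-HB", "N-CG", "C-CG", "C-HB")


@dataclass(frozen=True)
class KarplusParams:
    """Karplus coefficients A, B, C (Hz) with a dihedral phase offset delta.

    ``delta`` (degrees) maps the reported heavy-atom dihedral onto the
    coupling's own dihedral; e.g. an H-beta proton dihedral is chi1 plus a
    roughly tetrahedral +/-120-degree offset when explicit hydrogens are not
    available.
    """

    A: float
    B: float
    C: float
    delta: float = 0.0
    coupling_class: str = "HA-HB"
    source: str = ""

    def __post_init__(self):
        for name, value in (("A", self.A), ("B", self.B), ("C", self.C), ("delta", self.delta)):
            if not math.isfinite(value):
                raise ValueError(f"Karplus coefficient {name} must be finite")
        if self.coupling_class not in COUPLING_CLASSES:
            raise ValueError(
                f"unsupported coupling class {self.coupling_class!r}; "
                f"supported: {COUPLING_CLASSES}"
            )


def karplus_j(theta, params: KarplusParams) -> float:
    """J(theta) = A cos^2(theta + delta) + B cos(theta + delta) + C, in Hz."""
    th = np.deg2rad(np.asarray(theta, dtype=float) + params.delta)
    c = np.cos(th)
    j = params.A * c**2 + params.B * c + params.C
    if np.ndim(theta) == 0:
        return float(j)
    return j


def ensemble_j(series: DihedralSeries, params: KarplusParams) -> float:
    """Ensemble-averaged coupling: mean of karplus_j over frames."""
    return float(np.mean(karplus_j(series.values, params)))


@dataclass(frozen=True)
class AlignmentTensor:
    """Symmetric traceless alignment (Saupe) tensor.

    Stored as the five independent components (Sxx, Syy, Sxy, Sxz, Syz);
    Szz = -(Sxx + Syy).
    """

    Sxx: float
    Syy: float
    Sxy: float
    Sxz: float
    Syz: float

    @property
    def Szz(self) -> float:
        return -(self.Sxx + self.Syy)

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.Sxx, self.Sxy, self.Sxz],
                [self.Sxy, self.Syy, self.Syz],
                [self.Sxz, self.Syz, self.Szz],
            ]
        )

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "AlignmentTensor":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 3):
            raise ValueError("alignment tensor must be 3x3")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("alignment tensor must be symmetric")
        if abs(np.trace(matrix)) > 1e-12:
            raise ValueError("alignment tensor must be traceless")
        return cls(
            Sxx=matrix[0, 0], Syy=matrix[1, 1],
            Sxy=matrix[0, 1], Sxz=matrix[0, 2], Syz=matrix[1, 2],
        )

    def as_vector(self) -> np.ndarray:
        return np.array([self.Sxx, self.Syy, self.Sxy, self.Sxz, self.Syz])


def _normalize_vectors(vectors) -> np.ndarray:
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[1] != 3:
        raise ValueError("bond vectors must be 3-dimensional")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length bond vector")
    return v / norms[:, None]


def _design_rows(unit_vectors: np.ndarray) -> np.ndarray:
    """Row per bond: D/Dmax = u S u expressed in the 5 free components."""
    ux, uy, uz = unit_vectors[:, 0], unit_vectors[:, 1], unit_vectors[:, 2]
    return np.column_stack(
        [ux**2 - uz**2, uy**2 - uz**2, 2 * ux * uy, 2 * ux * uz, 2 * uy * uz]
    )


def fit_alignment_tensor(bond_vectors, rdcs, dmax) -> AlignmentTensor:
    """Least-squares fit of the alignment tensor to measured RDCs.

    Solves D_i = Dmax_i * u_i^T S u_i for the five independent components of
    S via SVD.  ``dmax`` may be a scalar or per-bond array (Hz).  Requires at
    least five bonds with orientations that span the five-dimensional space.
    """
    u = _normalize_vectors(bond_vectors)
    d = np.asarray(rdcs, dtype=float)
    dmax = np.broadcast_to(np.asarray(dmax, dtype=float), d.shape)
    if u.shape[0] != d.size:
        raise ValueError("bond_vectors and rdcs must have equal length")
    if u.shape[0] < 5:
        raise ValueError(f"need >= 5 bond vectors to fit an alignment tensor, got {u.shape[0]}")
    design = _design_rows(u) * dmax[:, None]
    sol, _, rank, _ = np.linalg.lstsq(design, d, rcond=None)
    if rank < 5:
        raise np.linalg.LinAlgError(
            f"bond geometry is rank-deficient (rank {rank} < 5); "
            "orientations do not determine the tensor"
        )
    return AlignmentTensor(*sol)


def predict_rdc(tensor: AlignmentTensor, bond_vector_series, dmax: float) -> float:
    """Ensemble-averaged RDC (Hz): mean over frames of Dmax * u^T S u."""
    u = _normalize_vectors(bond_vector_series)
    per_frame = dmax * (_design_rows(u) @ tensor.as_vector())
    return float(np.mean(per_frame))


def sum_amide_rdcs(tensor: AlignmentTensor, hd1_series, hd2_series, dmax: float) -> float:
    """Sum of the two side-chain amide N-H RDCs (Asn Nd-Hd1 + Nd-Hd2).

    Primary amide experiments often resolve only the sum of the two N-H
    couplings; this predicts that sum from per-frame bond vectors of both
    protons.
    """
    hd1 = np.atleast_2d(np.asarray(hd1_series, dtype=float))
    hd2 = np.atleast_2d(np.asarray(hd2_series, dtype=float))
    if hd1.shape[0] != hd2.shape[0]:
        raise ValueError(
            f"frame-count mismatch between the two amide bonds: "
            f"{hd1.shape[0]} vs {hd2.shape[0]}"
        )
    return predict_rdc(tensor, hd1, dmax) + predict_rdc(tensor, hd2, dmax)


def observable_rmsd(observables: pd.DataFrame, group_by: Optional[str] = None):
    """RMSD between calculated and experimental observables, per group.

    ``observables`` needs columns 'calc' and 'exp' (Hz) and, when
    ``group_by`` is given, the grouping column (e.g. 'residue_type' or
    'coupling_class').  Returns a float for the ungrouped case, otherwise a
    Series of RMSDs indexed by group.
    """
    if len(observables) == 0:
        raise ValueError("no observables to compare")
    for col in ("calc", "exp"):
        if col not in observables.columns:
            raise ValueError(f"observable table must have a {col!r} column")
    sq = (observables["calc"] - observables["exp"]) ** 2
    if group_by is None:
        return float(np.sqrt(sq.mean()))
    if group_by not in observables.columns:
        raise ValueError(f"missing grouping column {group_by!r}")
    return np.sqrt(sq.groupby(observables[group_by]).mean())


# ---------------------------------------------------------------------------
# Karplus / Dmax registry


def default_karplus_registry() -> dict:
    """Editable registry of Karplus presets and Dmax scale factors.

    Coefficients are representative literature-style values for each
    supported coupling class; delta maps chi1 onto the class's own dihedral.
    Dmax magnitudes (Hz) follow conventional gyromagnetic-ratio/bond-length
    choices; every RDC prediction scales linearly in Dmax.
    """
    return {
        "karplus": {
            "default": {
                # 3J(Ha-Hb): H dihedral = chi1 - 120 (Hb2) / chi1 + 120 (Hb3)
                "HA-HB": {"A": 9.5, "B": -1.6, "C": 1.8, "delta": -120.0},
                "N-CG": {"A": 1.29, "B": -0.49, "C": 0.37, "delta": 120.0},
                "C-CG": {"A": 2.31, "B": -0.87, "C": 0.55, "delta": 0.0},
                "C-HB": {"A": 7.2, "B": -2.04, "C": 0.6, "delta": 120.0},
            }
        },
        "dmax": {"N-H": 21700.0, "C-H": 44539.0, "C-C": 15156.0, "N-C": 6125.0},
    }


def load_karplus_registry(path) -> dict:
    with open(path) as handle:
        registry = yaml.safe_load(handle)
    if not isinstance(registry, dict) or "karplus" not in registry:
        raise ValueError(f"{path}: not a Karplus registry (missing 'karplus' section)")
    return registry


def save_karplus_registry(registry: dict, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(registry, handle, sort_keys=True)


def registry_params(registry: dict, coupling_class: str, preset: str = "default") -> KarplusParams:
    """Look up a KarplusParams from a registry preset."""
    try:
        entry = registry["karplus"][preset][coupling_class]
    except KeyError as exc:
        raise KeyError(
            f"no Karplus entry for class {coupling_class!r} in preset {preset!r}"
        ) from exc
    return KarplusParams(
        A=float(entry["A"]), B=float(entry["B"]), C=float(entry["C"]),
        delta=float(entry.get("delta", 0.0)),
        coupling_class=coupling_class, source=preset,
    )
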