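"""Boltzmann-weighted least-squares fitting of replacement torsion terms.

The target is the gap between a reference quantum-mechanical energy surface
and the base force-field energy (the force field with the torsion under
refit removed).  The model

    E_mm_base(i) + sum_angles sum_m k_m [1 + cos(m * theta_i)] + k0  ~  E_qm(i)

is linear in the force constants k_m and the offset k0, so the weighted
least-squares problem

    J = sum_i w_i * (E_mm(i) - E_qm(i))^2,   w_i ~ exp(-beta * E_qm(i))

has a closed-form solution; no iterative optimizer is involved.  The inverse
temperature beta = 1.0 mol/kcal (about 500 K) weights minima strongly while
keeping barrier regions visible; beta = 0 recovers an ordinary unweighted
fit, and beta ~ 1.7 mol/kcal corresponds to room temperature.

Because the Amber convention fixes the phase at 0, the choice of the atom
quadruple that defines chi1 matters: the same correction expressed on
N-CA-CB-CG versus C-CA-CB-CG differs by a rigid offset of the angle.
``select_dihedral_definition`` fits each candidate definition and keeps the
one with the lowest weighted residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from ildnfit.scan_grid import ScanTable
from ildnfit.torsion_model import CosineSeries, TorsionDefinition, evaluate_torsion

__all__ = [
    "FitSpec",
    "FitResult",
    "boltzmann_weights",
    "beta_to_temperature",
    "temperature_to_beta",
    "fit_torsion",
    "select_dihedral_definition",
    "subtract_torsion",
    "GAS_CONSTANT_KCAL",
]

# molar gas constant in kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.987204259e-3


def beta_to_temperature(beta: float) -> float:
    """Temperature in K corresponding to an inverse temperature in mol/kcal."""
    if beta <= 0:
        raise ValueError("beta must be positive to define a temperature")
    return 1.0 / (GAS_CONSTANT_KCAL * beta)


def temperature_to_beta(temperature: float) -> float:
    """Inverse temperature beta = 1/kT in mol/kcal for a temperature in K."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (GAS_CONSTANT_KCAL * temperature)


@dataclass(frozen=True)
class FitSpec:
    """Configuration of a torsion fit.

    Parameters
    ----------
    multiplicities
        Mapping from angle label ('chi1', 'chi2') to the cosine
        multiplicities fitted for that angle, e.g. {'chi1': [1, 2]} for Ile
        or {'chi1': range(1, 7), 'chi2': range(1, 7)} for Asp/Asn.
    beta
        Inverse temperature of the Boltzmann weights in mol/kcal.
        0 gives uniform weights.
    fit_offset
        Whether the constant k0 absorbing the QM/MM energy-zero mismatch is
        a free parameter (default) or fixed at 0.
    """

    multiplicities: Mapping[str, Tuple[int, ...]]
    beta: float = 1.0
    fit_offset: bool = True

    def __init__(self, multiplicities, beta: float = 1.0, fit_offset: bool = True):
        if isinstance(multiplicities, Mapping):
            mults = {k: tuple(int(m) for m in v) for k, v in multiplicities.items()}
        else:  # bare sequence means a chi1-only fit
            mults = {"chi1": tuple(int(m) for m in multiplicities)}
        if not mults:
            raise ValueError("at least one angle must be fitted")
        for angle, ms in mults.items():
            if angle not in ("chi1", "chi2"):
                raise ValueError(f"unknown angle label {angle!r}")
            if not ms or any(m < 1 for m in ms) or len(set(ms)) != len(ms):
                raise ValueError(f"multiplicities for {angle} must be distinct positive ints")
        if beta < 0:
            raise ValueError("beta must be non-negative")
        object.__setattr__(self, "multiplicities", mults)
        object.__setattr__(self, "beta", float(beta))
        object.__setattr__(self, "fit_offset", bool(fit_offset))

    @property
    def angles(self) -> Tuple[str, ...]:
        return tuple(self.multiplicities)

    @property
    def n_parameters(self) -> int:
        return sum(len(v) for v in self.multiplicities.values()) + int(self.fit_offset)


@dataclass
class FitResult:
    """Fitted cosine series per angle plus diagnostics."""

    series: Dict[str, CosineSeries]
    k0: float
    weighted_residual: float
    residuals: np.ndarray
    definition: Optional[TorsionDefinition] = None

    @property
    def chi1(self) -> CosineSeries:
        return self.series["chi1"]

    @property
    def chi2(self) -> CosineSeries:
        return self.series["chi2"]


def boltzmann_weights(E_qm, beta: float) -> np.ndarray:
    """Normalized Boltzmann weights w_i ~ exp(-beta * E_i).

    Energies are shifted so the minimum is 0 before exponentiation; the shift
    cancels in the normalization and protects against overflow.  beta = 0
    yields uniform weights 1/N.
    """
    energies = np.asarray(E_qm, dtype=float)
    if energies.size == 0:
        raise ValueError("cannot weight an empty energy list")
    if not np.all(np.isfinite(energies)):
        raise ValueError("energies must be finite")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    shifted = energies - energies.min()
    weights = np.exp(-beta * shifted)
    return weights / weights.sum()


def _design_matrix(scan: ScanTable, spec: FitSpec):
    """Columns [1 + cos(m*theta)] per fitted angle, plus offset column last."""
    df = scan.points
    columns = []
    labels = []
    for angle, mults in spec.multiplicities.items():
        theta = df[angle].to_numpy(dtype=float)
        if np.any(~np.isfinite(theta)):
            raise ValueError(f"scan table has missing {angle} values but {angle} is fitted")
        rad = np.deg2rad(theta)
        for m in mults:
            columns.append(1.0 + np.cos(m * rad))
            labels.append(f"{angle}:m={m}")
    if spec.fit_offset:
        columns.append(np.ones(len(df)))
        labels.append("k0")
    return np.column_stack(columns), labels


def fit_torsion(scan: ScanTable, spec: FitSpec) -> FitResult:
    """Fit replacement force constants to the QM - base-MM energy gap.

    The scan table must carry E_qm and E_mm_base for every point, with
    E_mm_base excluding the torsion term being replaced (use
    :func:`subtract_torsion` if you have full MM energies).  Returns the
    closed-form weighted least-squares solution.
    """
    if not scan.has_energies():
        raise ValueError("scan table must have E_qm and E_mm_base on every point to fit")
    df = scan.points
    E_qm = df["E_qm"].to_numpy(dtype=float)
    E_base = df["E_mm_base"].to_numpy(dtype=float)
    target = E_qm - E_base

    design, labels = _design_matrix(scan, spec)
    n_params = design.shape[1]
    if len(df) < n_params:
        raise ValueError(
            f"{len(df)} scan points cannot determine {n_params} parameters"
        )

    weights = boltzmann_weights(E_qm, spec.beta)
    sqrt_w = np.sqrt(weights)
    A = design * sqrt_w[:, None]
    b = target * sqrt_w

    # rank-revealing solve; name the degenerate columns on failure
    u, s, vt = np.linalg.svd(A, full_matrices=False)
    tol = s[0] * max(A.shape) * np.finfo(float).eps if s[0] > 0 else 0.0
    rank = int(np.sum(s > tol))
    if rank < n_params:
        null_mask = np.any(np.abs(vt[rank:]) > 1e-8, axis=0)
        degenerate = [lab for lab, bad in zip(labels, null_mask) if bad]
        raise np.linalg.LinAlgError(
            f"design matrix is rank-deficient (rank {rank} < {n_params}); "
            f"degenerate columns: {degenerate}"
        )
    coeffs = vt.T @ ((u.T @ b) / s)

    prediction = design @ coeffs
    residuals = prediction - target  # E_mm - E_qm pointwise
    weighted_residual = float(np.sum(weights * residuals**2))

    series: Dict[str, CosineSeries] = {}
    idx = 0
    for angle, mults in spec.multiplicities.items():
        ks = coeffs[idx : idx + len(mults)]
        series[angle] = CosineSeries(list(zip(mults, ks)))
        idx += len(mults)
    k0 = float(coeffs[idx]) if spec.fit_offset else 0.0
    return FitResult(series=series, k0=k0,
                     weighted_residual=weighted_residual, residuals=residuals)


def select_dihedral_definition(
    candidates: Sequence[Tuple[TorsionDefinition, ScanTable]],
    spec: FitSpec,
) -> FitResult:
    """Fit each candidate dihedral definition; keep the best one.

    Each candidate pairs a :class:`TorsionDefinition` with a scan table whose
    chi1 column holds the dihedral measured on that quadruple (the candidates
    differ by a rigid angular offset set by the local geometry).  The result
    with the lowest weighted residual wins; ties go to the first listed.
    """
    if not candidates:
        raise ValueError("no candidate definitions supplied")
    best: Optional[FitResult] = None
    for definition, scan in candidates:
        result = fit_torsion(scan, spec)
        result.definition = definition
        if best is None or result.weighted_residual < best.weighted_residual:
            best = result
    return best


def subtract_torsion(scan: ScanTable, old_series: Mapping[str, CosineSeries]) -> ScanTable:
    """Remove an existing torsion term from full MM energies.

    For callers holding the complete force-field energy rather than the base
    energy: subtracts V_old(theta) per angle from E_mm_base, yielding the
    base-energy convention :func:`fit_torsion` expects.
    """
    df = scan.points.copy()
    base = df["E_mm_base"].to_numpy(dtype=float)
    for angle, series in old_series.items():
        theta = df[angle].to_numpy(dtype=float)
        base = base - evaluate_torsion(series, theta)
    df["E_mm_base"] = base
    return ScanTable(df, residue=scan.residue)
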