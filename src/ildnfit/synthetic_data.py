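"""Synthetic inputs with known ground truth for every analysis stage.

Three generators, all bit-reproducible under a fixed seed:

* QM-style torsion scans: E_qm = background + generating torsion(s) + noise,
  E_mm_base = background.  The background is a low-order cosine surface with
  an optional chi1/chi2 coupling term, standing in for the nonbonded and
  residual bonded force-field energy that a real fit must separate from the
  torsion signal.  The default noise level of 0.2 kcal/mol mimics the
  sub-kcal/mol residual discrepancies typical of QM-vs-fit comparisons.

* Rotamer-structured chi1 trajectories: mixtures of von Mises components
  centred on the canonical +60/-60/180-degree wells, standing in for the
  chi1 time series of a long helical-peptide simulation.

* RDC datasets: random unit bond vectors with couplings computed from a
  known alignment tensor plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from ildnfit.nmr_backcalc import AlignmentTensor, _design_rows, _normalize_vectors
from ildnfit.rotamer_geometry import DihedralSeries
from ildnfit.scan_grid import ScanTable
from ildnfit.torsion_model import CosineSeries, evaluate_torsion

__all__ = [
    "BackgroundSpec",
    "SyntheticScanSpec",
    "RotamerTrajectorySpec",
    "synth_scan",
    "sample_dihedral_trajectory",
    "synth_rdc_dataset",
    "random_cosine_series",
    "random_alignment_tensor",
]

STATE_CENTERS = {"p": 60.0, "m": -60.0, "t": 180.0}


@dataclass(frozen=True)
class BackgroundSpec:
    """Smooth cosine-surface background standing in for non-torsion energy.

    background(c1, c2) = sum_j a_j cos(j*c1 + p_j) + sum_j b_j cos(j*c2 + q_j)
                         + coupling * cos(c1 - c2)

    Amplitudes in kcal/mol, phases in degrees.  The chi2 terms and coupling
    are ignored for pure-chi1 tables.
    """

    chi1_amplitudes: Tuple[float, ...] = (1.2, 0.4)
    chi1_phases: Tuple[float, ...] = (35.0, -70.0)
    chi2_amplitudes: Tuple[float, ...] = (0.8,)
    chi2_phases: Tuple[float, ...] = (10.0,)
    coupling: float = 0.3

    def __call__(self, chi1, chi2=None) -> np.ndarray:
        c1 = np.deg2rad(np.asarray(chi1, dtype=float))
        energy = np.zeros_like(c1)
        for j, (a, p) in enumerate(zip(self.chi1_amplitudes, self.chi1_phases), start=1):
            energy = energy + a * np.cos(j * c1 + np.deg2rad(p))
        if chi2 is not None:
            c2 = np.deg2rad(np.asarray(chi2, dtype=float))
            if np.all(np.isfinite(c2)):
                for j, (a, p) in enumerate(zip(self.chi2_amplitudes, self.chi2_phases), start=1):
                    energy = energy + a * np.cos(j * c2 + np.deg2rad(p))
                energy = energy + self.coupling * np.cos(c1 - c2)
        return energy

    @classmethod
    def zero(cls) -> "BackgroundSpec":
        return cls(chi1_amplitudes=(), chi1_phases=(), chi2_amplitudes=(),
                   chi2_phases=(), coupling=0.0)

    @classmethod
    def chi2_symmetric(cls) -> "BackgroundSpec":
        """Background even under chi2 -> chi2 + 180 (Asp-like carboxylate)."""
        return cls(chi2_amplitudes=(0.0, 0.6), chi2_phases=(0.0, 20.0), coupling=0.0)


@dataclass(frozen=True)
class SyntheticScanSpec:
    """Ground-truth recipe for a synthetic QM-style scan table."""

    generators: Mapping[str, CosineSeries]
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    noise_sigma: float = 0.2
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for angle in self.generators:
            if angle not in ("chi1", "chi2"):
                raise ValueError(f"unknown generator angle {angle!r}")


def synth_scan(grid: ScanTable, spec: SyntheticScanSpec) -> ScanTable:
    """Populate a scan grid with synthetic QM and base-MM energies.

    E_mm_base is the background surface alone; E_qm adds the generating
    torsion terms, a constant offset and Gaussian noise, so the exact
    QM-minus-base gap is known by construction.
    """
    df = grid.points
    chi1 = df["chi1"].to_numpy(dtype=float)
    chi2 = df["chi2"].to_numpy(dtype=float)
    chi2_arg = chi2 if np.all(np.isfinite(chi2)) else None

    base = spec.background(chi1, chi2_arg)
    signal = np.zeros_like(base)
    for angle, series in spec.generators.items():
        theta = chi1 if angle == "chi1" else chi2
        if np.any(~np.isfinite(theta)):
            raise ValueError(f"grid lacks {angle} values required by the generator")
        signal = signal + evaluate_torsion(series, theta)

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, size=len(df)) if spec.noise_sigma > 0 else 0.0
    return grid.with_energies(
        E_qm=base + signal + spec.offset + noise,
        E_mm_base=base,
    )


@dataclass(frozen=True)
class RotamerTrajectorySpec:
    """Mixture of von Mises rotamer wells for a synthetic chi1 time series."""

    populations: Mapping[str, float]
    concentration: float = 20.0
    n_frames: int = 10_000
    seed: int = 0

    def __post_init__(self):
        pops = dict(self.populations)
        unknown = set(pops) - set(STATE_CENTERS)
        if unknown:
            raise ValueError(f"unknown rotamer states {sorted(unknown)}")
        total = sum(pops.values())
        if abs(total - 1.0) > 1e-9 or min(pops.values(), default=0) < 0:
            raise ValueError("populations must be non-negative and sum to 1")
        if self.concentration <= 0:
            raise ValueError("von Mises concentration must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def sample_dihedral_trajectory(
    spec: RotamerTrajectorySpec,
    residue_id: str = "X1",
    residue_type: str = "LEU",
) -> DihedralSeries:
    """Draw a chi1 series from the von Mises rotamer mixture."""
    rng = np.random.default_rng(spec.seed)
    states = list(STATE_CENTERS)
    probs = np.array([spec.populations.get(s, 0.0) for s in states])
    assignment = rng.choice(len(states), size=spec.n_frames, p=probs / probs.sum())
    centers = np.array([STATE_CENTERS[s] for s in states])
    angles = rng.vonmises(
        np.deg2rad(centers[assignment]), spec.concentration, size=spec.n_frames
    )
    return DihedralSeries(
        residue_id=residue_id,
        residue_type=residue_type,
        angle="chi1",
        values=np.degrees(angles),
    )


def synth_rdc_dataset(
    tensor: AlignmentTensor,
    n_bonds: int,
    noise: float = 0.0,
    seed: int = 0,
    dmax: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Random unit bond vectors and their RDCs under a known tensor.

    Returns (bond_vectors, rdcs); rdcs carry Gaussian noise of the given
    standard deviation (Hz).
    """
    if n_bonds < 5:
        raise ValueError("need at least 5 bonds for a determinable tensor")
    rng = np.random.default_rng(seed)
    vectors = _normalize_vectors(rng.normal(size=(n_bonds, 3)))
    rdcs = dmax * (_design_rows(vectors) @ tensor.as_vector())
    if noise > 0:
        rdcs = rdcs + rng.normal(0.0, noise, size=n_bonds)
    return vectors, rdcs


def random_cosine_series(rng: np.random.Generator, max_terms: int = 4,
                         k_scale: float = 1.5) -> CosineSeries:
    """Random signed cosine series (for round-trip and recovery tests)."""
    n_terms = int(rng.integers(1, max_terms + 1))
    mults = rng.choice(np.arange(1, 7), size=n_terms, replace=False)
    ks = rng.normal(0.0, k_scale, size=n_terms)
    ks[ks == 0.0] = 0.1
    return CosineSeries([(int(m), float(k)) for m, k in zip(mults, ks)])


def random_alignment_tensor(rng: np.random.Generator, scale: float = 1e-3) -> AlignmentTensor:
    """Random symmetric traceless tensor with entries of typical magnitude."""
    raw = rng.normal(0.0, scale, size=5)
    return AlignmentTensor(*raw)
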