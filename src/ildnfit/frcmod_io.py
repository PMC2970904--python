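"""Amber frcmod DIHE records: export of fitted torsions, re-import, round-trip.

Amber's parameter-modification (frcmod) files store each torsion term as

    IT-JT-KT-LT  IDIVF  PK  PHASE  PN

where PK is the barrier height (non-negative), PHASE the phase in degrees
and PN the periodicity; a negative PN marks a continuation line (more terms
follow for the same atom-type quadruple).  A signed force constant k_m maps
onto this convention through

    k (1 + cos(m theta)) = |k| (1 + cos(m theta - 180)) + 2 k        (k < 0)

so negative constants are emitted as PK = |k| with PHASE = 180.  The
additive constant 2k shifts the energy zero only; forces and all relative
energies are unchanged, which is noted in the emitted file header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from ildnfit.torsion_model import CosineSeries

__all__ = [
    "DiheRecord",
    "to_frcmod",
    "parse_frcmod",
    "parse_frcmod_records",
    "records_to_series",
    "format_frcmod",
    "write_frcmod",
    "read_frcmod",
]

logger = logging.getLogger(__name__)

_HEADER_NOTE = (
    "Negative force constants were emitted as PK=|k| with PHASE=180; "
    "this shifts the energy zero only."
)


@dataclass(frozen=True)
class DiheRecord:
    """One DIHE line: atom-type quadruple, divider, barrier, phase, periodicity."""

    atom_types: Tuple[str, str, str, str]
    idivf: int
    pk: float
    phase: float
    pn: int  # negative = continuation line

    def __post_init__(self):
        if len(self.atom_types) != 4:
            raise ValueError("DIHE record requires four atom types")
        if self.idivf < 1:
            raise ValueError("IDIVF must be a positive integer")
        if self.pk < 0:
            raise ValueError("PK (barrier) must be non-negative")
        if abs(self.pn) < 1:
            raise ValueError("|PN| must be >= 1")


def to_frcmod(series: CosineSeries, atom_types: Sequence[str]) -> List[DiheRecord]:
    """Convert a signed cosine series into Amber DIHE records.

    Zero-force-constant terms carry no energy and are dropped (logged).
    All records but the last get a negative PN, per the Amber continuation
    convention for multi-term torsions.
    """
    atom_types = tuple(str(t) for t in atom_types)
    if len(atom_types) != 4:
        raise ValueError("need four atom-type names")
    kept = [(m, k) for m, k in series.terms if k != 0.0]
    dropped = [m for m, k in series.terms if k == 0.0]
    if dropped:
        logger.info("dropping zero-k terms with multiplicities %s", dropped)
    records = []
    for i, (m, k) in enumerate(kept):
        phase = series.theta0 if k > 0 else (series.theta0 + 180.0) % 360.0
        pn = m if i == len(kept) - 1 else -m
        records.append(
            DiheRecord(atom_types=atom_types, idivf=1, pk=abs(k), phase=phase, pn=pn)
        )
    return records


def records_to_series(records: Sequence[DiheRecord]) -> CosineSeries:
    """Reconstruct a signed CosineSeries from DIHE records.

    Phases of 0/180 fold into the sign of k (theta0 = 0); any other phase is
    retained as the series phase, provided it is uniform across terms.
    """
    if not records:
        raise ValueError("no records to convert")
    terms = []
    phases = set()
    for rec in records:
        phase = rec.phase % 360.0
        if phase in (0.0, 180.0):
            terms.append((abs(rec.pn), rec.pk if phase == 0.0 else -rec.pk))
            phases.add(0.0)
        else:
            terms.append((abs(rec.pn), rec.pk))
            phases.add(phase)
    if len(phases) > 1:
        raise ValueError(
            f"records mix phases {sorted(phases)}; cannot express as a single-phase series"
        )
    return CosineSeries(terms, theta0=phases.pop())


def _format_record(rec: DiheRecord) -> str:
    types = "-".join(f"{t:<2s}" for t in rec.atom_types)
    return f"{types} {rec.idivf:4d} {rec.pk:16.10f} {rec.phase:10.3f} {rec.pn:6d}."


def format_frcmod(entries: Sequence[Tuple[Sequence[str], Sequence[DiheRecord]]],
                  title: str = "torsion corrections") -> str:
    """Render a minimal frcmod file with a DIHE section."""
    lines = [title, f"# {_HEADER_NOTE}", "", "DIHE"]
    for _, records in entries:
        for rec in records:
            lines.append(_format_record(rec))
    lines.append("")
    return "\n".join(lines) + "\n"


def parse_frcmod_records(text: str) -> List[Tuple[Tuple[str, ...], List[DiheRecord]]]:
    """Parse the DIHE block into per-quadruple record groups.

    Continuation records (negative PN) are grouped with the following lines
    of the same atom-type quadruple; a dangling continuation at the end of
    the block is an error.
    """
    lines = text.splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.strip() == "DIHE")
    except StopIteration:
        raise ValueError("no DIHE block found") from None
    groups: List[Tuple[Tuple[str, ...], List[DiheRecord]]] = []
    current: List[DiheRecord] = []
    current_types: Tuple[str, ...] = ()
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        stripped = line.strip()
        if not stripped:
            break
        if stripped.startswith("#"):
            continue
        type_field, rest = line[:11], line[11:].split()
        if len(rest) < 4:
            raise ValueError(f"line {lineno}: malformed DIHE record: {line!r}")
        atom_types = tuple(t.strip() for t in type_field.split("-"))
        if len(atom_types) != 4:
            raise ValueError(f"line {lineno}: expected 4 atom types, got {atom_types}")
        try:
            idivf = int(rest[0])
            pk = float(rest[1])
            phase = float(rest[2])
            pn = int(float(rest[3]))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed numeric field: {exc}") from exc
        rec = DiheRecord(atom_types=atom_types, idivf=idivf, pk=pk, phase=phase, pn=pn)
        if current and atom_types != current_types:
            raise ValueError(
                f"line {lineno}: continuation for {current_types} interrupted by {atom_types}"
            )
        current.append(rec)
        current_types = atom_types
        if pn > 0:  # group complete
            groups.append((current_types, current))
            current, current_types = [], ()
    if current:
        raise ValueError("dangling continuation record (negative PN) at end of DIHE block")
    return groups


def parse_frcmod(text: str) -> List[Tuple[Tuple[str, ...], CosineSeries]]:
    """Parse a frcmod DIHE block into (atom types, signed CosineSeries) pairs."""
    return [(types, records_to_series(recs)) for types, recs in parse_frcmod_records(text)]


def write_frcmod(entries, path, title: str = "torsion corrections") -> None:
    with open(path, "w") as handle:
        handle.write(format_frcmod(entries, title=title))


def read_frcmod(path):
    with open(path) as handle:
        return parse_frcmod(handle.read())
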