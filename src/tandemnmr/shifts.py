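"""Chemical-shift tables: parsing, completeness, secondary shifts, CSP mapping.

Shift tables come in as NMR-STAR (the BMRB deposition format, v3
``_Atom_chem_shift`` loop) or as 4-column TSV. All shifts are in ppm and all
residue numbers are author numbering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Random-coil Calpha/Cbeta chemical shifts (ppm), per residue type.
#: Values follow the widely used random-coil compilations for proteins in
#: water near neutral pH; glycine has no Cbeta.
RANDOM_COIL_CA_CB: dict[str, tuple[float, float | None]] = {
    "ALA": (52.5, 19.1),
    "ARG": (56.0, 30.9),
    "ASN": (52.8, 38.9),
    "ASP": (54.2, 41.1),
    "CYS": (58.2, 28.0),
    "GLN": (55.7, 29.4),
    "GLU": (56.6, 29.9),
    "GLY": (45.1, None),
    "HIS": (55.0, 29.0),
    "ILE": (61.1, 38.8),
    "LEU": (55.1, 42.4),
    "LYS": (56.2, 33.1),
    "MET": (55.4, 32.9),
    "PHE": (57.7, 39.6),
    "PRO": (63.3, 31.7),
    "SER": (58.3, 63.8),
    "THR": (61.8, 69.8),
    "TRP": (57.5, 32.5),
    "TYR": (57.9, 38.8),
    "VAL": (62.2, 32.9),
}

#: Default weighting of the 15N shift change in the combined CSP.
DEFAULT_N_WEIGHT = 0.15
#: Default combined-CSP threshold (ppm) for calling a residue "shifted".
DEFAULT_CSP_THRESHOLD = 0.1


@dataclass
class ShiftTable:
    """Assigned chemical shifts, one entry per (residue, atom)."""

    entries: pd.DataFrame  # columns: residue_number, residue_name, atom_name, shift
    sequence: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.entries.reset_index(drop=True)
        dup = df.duplicated(subset=["residue_number", "atom_name"])
        if dup.any():
            bad = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate shift entry for residue {bad.residue_number} atom {bad.atom_name}"
            )
        if not df["shift"].map(math.isfinite).all():
            raise ValueError("shift values must be finite")
        for num, name in zip(df["residue_number"], df["residue_name"]):
            expected = self.sequence.get(int(num))
            if expected is not None and expected != name:
                raise ValueError(
                    f"residue {num} is {name} in the table but {expected} in the sequence"
                )
        self.entries = df
        if not self.sequence:
            self.sequence = {
                int(n): str(r) for n, r in zip(df["residue_number"], df["residue_name"])
            }

    def get(self, residue_number: int, atom_name: str) -> float | None:
        df = self.entries
        hit = df[(df.residue_number == residue_number) & (df.atom_name == atom_name)]
        if hit.empty:
            return None
        return float(hit["shift"].iloc[0])

    def atoms_of(self, residue_number: int) -> set[str]:
        df = self.entries
        return set(df.loc[df.residue_number == residue_number, "atom_name"])

    def residue_numbers(self) -> list[int]:
        return sorted(set(int(n) for n in self.entries["residue_number"]))


@dataclass(frozen=True)
class SecondaryShiftRecord:
    residue_number: int
    delta_ca: float
    delta_cb: float

    @property
    def dca_minus_dcb(self) -> float:
        return self.delta_ca - self.delta_cb


@dataclass(frozen=True)
class CspRecord:
    """Per-residue chemical-shift perturbation between two conditions."""

    residue_number: int
    d_h: float
    d_n: float
    combined: float


# ---------------------------------------------------------------------------
# I/O


def read_shift_table(path: str | Path, sequence: Mapping[int, str] | None = None) -> ShiftTable:
    """Read a shift table from NMR-STAR or 4-column TSV.

    The TSV layout is ``residue_number  residue_name  atom_name  shift_ppm``
    with a header row. NMR-STAR files are scanned for the v3
    ``_Atom_chem_shift`` loop (Seq_ID / Comp_ID / Atom_ID / Val columns).
    """
    path = Path(path)
    text = path.read_text()
    if "_Atom_chem_shift" in text or text.lstrip().startswith("data_"):
        df = _parse_nmrstar_shifts(text, str(path))
    else:
        df = pd.read_csv(path, sep="\t")
        df = df.rename(
            columns={
                df.columns[0]: "residue_number",
                df.columns[1]: "residue_name",
                df.columns[2]: "atom_name",
                df.columns[3]: "shift",
            }
        )[["residue_number", "residue_name", "atom_name", "shift"]]
    df["residue_number"] = df["residue_number"].astype(int)
    df["shift"] = df["shift"].astype(float)
    seq = dict(sequence) if sequence else {}
    return ShiftTable(entries=df, sequence=seq)


def _parse_nmrstar_shifts(text: str, origin: str) -> pd.DataFrame:
    """Extract the assigned-chemical-shift loop from NMR-STAR v3 text."""
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < n and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                cols = {t.split(".", 1)[1]: k for k, t in enumerate(tags)}
                needed = {}
                for want, options in {
                    "residue_number": ("Seq_ID", "Comp_index_ID", "Auth_seq_ID"),
                    "residue_name": ("Comp_ID",),
                    "atom_name": ("Atom_ID",),
                    "shift": ("Val",),
                }.items():
                    for opt in options:
                        if opt in cols:
                            needed[want] = cols[opt]
                            break
                    else:
                        raise ValueError(f"{origin}: _Atom_chem_shift loop lacks a {options[0]} tag")
                rows = []
                while j < n and lines[j].strip() != "stop_":
                    fields = lines[j].split()
                    if fields:
                        if len(fields) < len(tags):
                            raise ValueError(f"{origin}: malformed loop row: {lines[j].strip()!r}")
                        rows.append(
                            {
                                "residue_number": int(fields[needed["residue_number"]]),
                                "residue_name": fields[needed["residue_name"]],
                                "atom_name": fields[needed["atom_name"]],
                                "shift": float(fields[needed["shift"]]),
                            }
                        )
                    j += 1
                return pd.DataFrame(rows)
            i = j
        else:
            i += 1
    raise ValueError(f"{origin}: no _Atom_chem_shift loop found")


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    df = table.entries.rename(columns={"shift": "shift_ppm"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Completeness

#: Atom classes for completeness statistics. Each maps to (expected-atoms
#: rule, assigned rule); chemistry dictates the denominators: prolines have
#: no amide H/N, glycine has no Cbeta/Hbeta and carries two Halpha.
_KNOWN_CLASSES = ("HN_N", "N", "CA", "C", "HA", "CB", "HB")


def completeness(
    table: ShiftTable,
    atom_class: str,
    sequence: Mapping[int, str] | None = None,
    exclude_n_terminal: bool = False,
) -> tuple[int, int, float]:
    """Count assigned vs chemically possible atoms for one class.

    Returns ``(assigned, possible, percent)`` with the percentage rounded to
    one decimal. ``sequence`` defaults to the table's own; pass the full
    construct sequence to count unassigned residues in the denominator.
    ``exclude_n_terminal`` optionally drops the first residue from amide
    classes (its alpha-amino group is not a peptide amide).
    """
    if atom_class not in _KNOWN_CLASSES:
        raise ValueError(f"unknown atom class {atom_class!r}; known: {_KNOWN_CLASSES}")
    seq = dict(sequence) if sequence is not None else dict(table.sequence)
    if not seq:
        raise ValueError("no sequence available for completeness accounting")
    first = min(seq)

    assigned = 0
    possible = 0
    for num in sorted(seq):
        resname = seq[num]
        atoms = table.atoms_of(num)
        if atom_class in ("HN_N", "N"):
            if resname == "PRO":
                continue
            if exclude_n_terminal and num == first:
                continue
            possible += 1
            if atom_class == "HN_N":
                assigned += int("H" in atoms and "N" in atoms)
            else:
                assigned += int("N" in atoms)
        elif atom_class == "CA":
            possible += 1
            assigned += int("CA" in atoms)
        elif atom_class == "C":
            possible += 1
            assigned += int("C" in atoms)
        elif atom_class == "HA":
            if resname == "GLY":
                possible += 2
                assigned += int("HA2" in atoms) + int("HA3" in atoms)
            else:
                possible += 1
                assigned += int("HA" in atoms)
        elif atom_class == "CB":
            if resname == "GLY":
                continue
            possible += 1
            assigned += int("CB" in atoms)
        elif atom_class == "HB":
            if resname == "GLY":
                continue
            possible += 1
            assigned += int(any(a.startswith("HB") for a in atoms))
    percent = round(100.0 * assigned / possible, 1) if possible else 0.0
    return assigned, possible, percent


# ---------------------------------------------------------------------------
# Secondary shifts


def secondary_shifts(
    table: ShiftTable,
    random_coil: Mapping[str, tuple[float, float | None]] | None = None,
) -> list[SecondaryShiftRecord]:
    """Per-residue Calpha/Cbeta secondary shifts relative to random coil.

    The classic empirical rule: the deviation of Calpha and Cbeta shifts from
    their residue-specific random-coil values tracks backbone conformation —
    DeltaCa - DeltaCb is positive in helices and negative in strands.
    Residues missing either carbon are omitted; glycine (no Cbeta) is kept
    with DeltaCb = 0 so its Calpha deviation still contributes.
    """
    rc = dict(random_coil) if random_coil is not None else RANDOM_COIL_CA_CB
    out: list[SecondaryShiftRecord] = []
    for num in table.residue_numbers():
        resname = table.sequence.get(num)
        if resname not in rc:
            continue
        ca_rc, cb_rc = rc[resname]
        ca = table.get(num, "CA")
        if ca is None:
            continue
        if resname == "GLY":
            out.append(SecondaryShiftRecord(num, ca - ca_rc, 0.0))
            continue
        cb = table.get(num, "CB")
        if cb is None or cb_rc is None:
            continue
        out.append(SecondaryShiftRecord(num, ca - ca_rc, cb - cb_rc))
    return out


def classify_secondary_structure(
    records: Sequence[SecondaryShiftRecord],
    helix_cut: float = 0.7,
    strand_cut: float = -0.7,
    min_run: int | tuple[int, int] = (4, 3),
) -> list[tuple[int, int, str]]:
    """Segment the sequence into helix/strand/coil from DeltaCa - DeltaCb runs.

    A residue votes helix when its value exceeds ``helix_cut``, strand when it
    falls below ``strand_cut``, coil otherwise. Votes are consolidated into
    runs of consecutive residue numbers; helix runs shorter than
    ``min_run[0]`` (default 4, one helical turn) and strand runs shorter than
    ``min_run[1]`` (default 3) are demoted to coil. Gaps in assignment break
    runs. Returns ``(start, end, type)`` segments covering every scored
    residue, type in {"helix", "strand", "coil"}.
    """
    if isinstance(min_run, int):
        min_helix = min_strand = min_run
    else:
        min_helix, min_strand = min_run
    recs = sorted(records, key=lambda r: r.residue_number)
    votes: list[tuple[int, str]] = []
    for r in recs:
        v = r.dca_minus_dcb
        label = "helix" if v > helix_cut else "strand" if v < strand_cut else "coil"
        votes.append((r.residue_number, label))

    runs: list[list] = []  # [start, end, label]
    for num, label in votes:
        if runs and label == runs[-1][2] and num == runs[-1][1] + 1:
            runs[-1][1] = num
        else:
            runs.append([num, num, label])
    # demote short structured runs
    for run in runs:
        length = run[1] - run[0] + 1
        if run[2] == "helix" and length < min_helix:
            run[2] = "coil"
        elif run[2] == "strand" and length < min_strand:
            run[2] = "coil"
    # merge adjacent same-label runs (only across contiguous numbering)
    merged: list[list] = []
    for run in runs:
        if merged and merged[-1][2] == run[2] and run[0] == merged[-1][1] + 1:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [(s, e, t) for s, e, t in merged]


def per_residue_labels(segments: Iterable[tuple[int, int, str]]) -> dict[int, str]:
    """Expand classification segments to a residue -> label map."""
    out: dict[int, str] = {}
    for start, end, label in segments:
        for num in range(start, end + 1):
            out[num] = label
    return out


# ---------------------------------------------------------------------------
# Chemical shift perturbation


def csp(
    reference: ShiftTable,
    perturbed: ShiftTable,
    n_weight: float = DEFAULT_N_WEIGHT,
) -> list[CspRecord]:
    """Combined amide chemical-shift perturbation between two conditions.

    combined = sqrt(dH^2 + (w * dN)^2), the standard weighted-Euclidean
    combination with the 15N change scaled by ``n_weight`` (default 0.15) to
    account for the wider 15N shift dispersion. Residues lacking an H or N
    shift in either table are omitted with a warning.
    """
    out: list[CspRecord] = []
    ref_residues = set(reference.residue_numbers())
    per_residues = set(perturbed.residue_numbers())
    for num in sorted(ref_residues | per_residues):
        vals = [reference.get(num, "H"), perturbed.get(num, "H"),
                reference.get(num, "N"), perturbed.get(num, "N")]
        if any(v is None for v in vals):
            logger.warning("residue %d missing amide shifts in one condition; omitted", num)
            continue
        d_h = vals[1] - vals[0]
        d_n = vals[3] - vals[2]
        combined = math.sqrt(d_h**2 + (n_weight * d_n) ** 2)
        out.append(CspRecord(num, d_h, d_n, combined))
    return out


def identify_shifted(records: Iterable[CspRecord], threshold: float = DEFAULT_CSP_THRESHOLD) -> list[int]:
    """Residues whose combined CSP strictly exceeds ``threshold`` (ppm)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return sorted(r.residue_number for r in records if r.combined > threshold)
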