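"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Raw NMR spectra cannot be redistributed or re-measured on demand, so every
reader/analysis stage in this package has a matching generator here that
emits the same tabular or PDB formats plus the ground truth used to make
them. The generators model the observables, not the spin physics: Gaussian,
homoscedastic noise per data type; ideal helical coordinates; two-state
exponentials for exchange; a fast-exchange binding isotherm for titrations.
Each generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .dynamics import IntensityPair, TimedIntensitySeries
from .rdc import AlignmentTensor, RdcDataset, RdcRecord, calc_rdc
from .shifts import RANDOM_COIL_CA_CB, ShiftTable
from .structures import AtomRecord, BondVector, Structure, place_amide_hydrogens

# -- generator constants ----------------------------------------------------

#: Secondary-shift offsets (ppm) added to random-coil CA/CB per state.
SS_OFFSETS: dict[str, tuple[float, float]] = {
    "H": (3.0, -0.5),
    "E": (-1.5, 2.0),
    "C": (0.0, 0.0),
}

#: Exchange rates (1/min) used for the four protection classes. With the
#: canonical 15 min / 24 h / 48 h schedule, reference intensity 1e6 and a
#: 3-sigma detection threshold at noise 1e4, each rate keeps its class with
#: a comfortable margin; neighbouring rates are >= 10x apart.
HDX_CLASS_RATES: dict[str, float] = {
    "unprotected": 1.0,
    "short": 0.02,
    "medium": 2.0e-3,
    "persistent": 1.0e-4,
}

HDX_DEFAULT_TIMEPOINTS: tuple[float, ...] = (15.0, 1440.0, 2880.0)  # minutes
HDX_REFERENCE_INTENSITY = 1.0e6

#: Default alignment tensor magnitude/rhombicity for simulated RDC data.
DEFAULT_DA = 15.0  # Hz
DEFAULT_RHOMBICITY = 0.3
DEFAULT_TENSOR_EULER = (25.0, 40.0, 15.0)  # degrees, z-y-z

# ideal backbone internal coordinates (Angstrom / degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_PHI_HELIX = -57.0
_PSI_HELIX = -47.0

_CSP_SAFE_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "GLN", "GLU", "HIS", "ILE", "LEU",
    "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass
class GroundTruth:
    """Everything the generators decided, for later assertion."""

    tensor_a: AlignmentTensor
    interdomain_axis: np.ndarray  # unit vector
    interdomain_degrees: float
    domains: dict[str, tuple[int, int]]  # label -> (first, last) residue number
    secondary_layout: dict[int, str] = field(default_factory=dict)  # H / E / C
    flexible_residues: set[int] = field(default_factory=set)
    binding_site: set[int] = field(default_factory=set)
    protection_rates: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def domain_of(self, residue_number: int) -> str:
        for label, (lo, hi) in self.domains.items():
            if lo <= residue_number <= hi:
                return label
        raise KeyError(f"residue {residue_number} is outside every domain")

    def rotation(self) -> Rotation:
        return Rotation.from_rotvec(
            np.deg2rad(self.interdomain_degrees) * self.interdomain_axis
        )


# ---------------------------------------------------------------------------
# backbone construction


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta_deg: float,
          tau_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms A, B, C."""
    theta = math.radians(theta_deg)
    tau = math.radians(tau_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(tau),
         r * math.sin(theta) * math.sin(tau)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_helix(n_res: int, start_number: int, chain_id: str) -> list[AtomRecord]:
    """Ideal poly-alanine alpha-helix backbone (N, CA, C, O per residue)."""
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, _PSI_HELIX)
        ca = _nerf(prev["CA"], prev["C"], n, _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        c = _nerf(prev["C"], n, ca, _BOND_CA_C, _ANGLE_N_CA_C, _PHI_HELIX)
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens (trans to the next amide nitrogen)
    for i, named in enumerate(coords):
        named["O"] = _nerf(named["N"], named["CA"], named["C"], _BOND_C_O,
                           _ANGLE_CA_C_O, _PSI_HELIX + 180.0)
    atoms: list[AtomRecord] = []
    for i, named in enumerate(coords):
        num = start_number + i
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_number=num,
                    residue_name="ALA",
                    atom_name=name,
                    element=name[0],
                    position=named[name],
                )
            )
    return atoms


def make_two_domain_structure(
    n_res_a: int,
    n_res_b: int,
    rotation: float = 0.0,
    seed: int = 0,
    start_number: int = 1,
    tensor: AlignmentTensor | None = None,
    separation: float = 25.0,
) -> tuple[Structure, GroundTruth]:
    """Two ideal helical domains, the second rigid-rotated by ``rotation`` deg.

    Domain A spans residues ``start_number .. start_number + n_res_a - 1``,
    domain B follows after a one-residue numbering gap. Domain B is
    translated clear of A and then rotated about its own centroid around the
    ground-truth axis (the y principal axis of the alignment tensor, so the
    tensor z axis seen by domain B tilts by exactly ``rotation`` degrees).
    Amide protons are placed; coordinates are deterministic per seed.
    """
    if n_res_a < 8 or n_res_b < 8:
        raise ValueError("each domain needs >= 8 residues")
    tensor = tensor or AlignmentTensor.from_parameters(
        DEFAULT_DA, DEFAULT_RHOMBICITY, DEFAULT_TENSOR_EULER
    )
    atoms_a = _build_helix(n_res_a, start_number, "A")
    b_start = start_number + n_res_a + 1  # leave a numbering gap between domains
    atoms_b = _build_helix(n_res_b, b_start, "A")

    span_a = max(a.position[0] for a in atoms_a)
    shift = np.array([span_a + separation, 0.0, 0.0])
    atoms_b = [AtomRecord(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                          a.element, a.position + shift) for a in atoms_b]
    axis = tensor.principal_axes[:, 1].copy()
    if rotation != 0.0:
        rot = Rotation.from_rotvec(np.deg2rad(rotation) * axis)
        centroid = np.mean([a.position for a in atoms_b], axis=0)
        atoms_b = [
            AtomRecord(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                       a.element, rot.apply(a.position - centroid) + centroid)
            for a in atoms_b
        ]
    sequence = {a.residue_number: "ALA" for a in atoms_a + atoms_b}
    structure = Structure(atoms=atoms_a + atoms_b, sequence=sequence,
                          gaps={start_number + n_res_a})
    structure = place_amide_hydrogens(structure)

    rng = np.random.default_rng(seed)
    a_range = (start_number, start_number + n_res_a - 1)
    b_range = (b_start, b_start + n_res_b - 1)
    residues = list(range(a_range[0], a_range[1] + 1)) + list(range(b_range[0], b_range[1] + 1))
    flexible = set(residues[:5])  # disordered N-terminal stretch
    candidates = [r for r in residues if r not in flexible and r <= a_range[1]]
    binding = set(rng.choice(candidates, size=min(7, len(candidates)), replace=False).tolist())
    classes = list(HDX_CLASS_RATES)
    protection = {r: HDX_CLASS_RATES[classes[rng.integers(len(classes))]] for r in residues}
    for r in flexible:
        protection[r] = HDX_CLASS_RATES["unprotected"]
    truth = GroundTruth(
        tensor_a=tensor,
        interdomain_axis=axis,
        interdomain_degrees=rotation,
        domains={"A": a_range, "B": b_range},
        secondary_layout=make_secondary_layout(residues, seed),
        flexible_residues=flexible,
        binding_site=binding,
        protection_rates=protection,
        seed=seed,
    )
    return structure, truth


def make_secondary_layout(residues: Sequence[int], seed: int = 0) -> dict[int, str]:
    """Alternating strand/coil/helix segments over the given residues."""
    rng = np.random.default_rng(seed + 101)
    layout: dict[int, str] = {}
    order = ["C", "E", "C", "H"]
    lengths = {"C": (3, 5), "E": (4, 6), "H": (6, 10)}
    i = 0
    k = 0
    residues = sorted(residues)
    while i < len(residues):
        state = order[k % len(order)]
        lo, hi = lengths[state]
        seg = int(rng.integers(lo, hi + 1))
        for num in residues[i : i + seg]:
            layout[num] = state
        i += seg
        k += 1
    return layout


# ---------------------------------------------------------------------------
# RDC simulation


def random_bond_vectors(n: int, seed: int = 0, start_number: int = 1) -> list[BondVector]:
    """Isotropically distributed unit bond vectors, one per residue number."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return [BondVector(start_number + i, v[i]) for i in range(n)]


def rotated_domain_vectors(
    vectors: Iterable[BondVector], truth: GroundTruth
) -> list[BondVector]:
    """Apply the ground-truth interdomain rotation to domain-B bond vectors.

    Turns vectors taken from the reference coordinates into the vectors the
    molecule actually carries in solution when domain B is reoriented.
    """
    rot = truth.rotation()
    out: list[BondVector] = []
    for v in vectors:
        if truth.domain_of(v.residue_number) == "B":
            out.append(BondVector(v.residue_number, rot.apply(v.direction)))
        else:
            out.append(v)
    return out


def simulate_rdcs(
    truth: GroundTruth,
    vectors: Iterable[BondVector],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> RdcDataset:
    """Couplings from the ground-truth tensor plus Gaussian noise.

    One molecule, one alignment tensor: every vector is contracted with
    ``truth.tensor_a``. Pass solution-state vectors (see
    :func:`rotated_domain_vectors`) to emulate an interdomain reorientation
    relative to the reference coordinates used later in fitting. ``sigma`` of
    each record is set to ``noise_sd`` (or 0.5 Hz when noise free, keeping
    sigma positive).
    """
    rng = np.random.default_rng(seed)
    sigma = noise_sd if noise_sd > 0 else 0.5
    records = [
        RdcRecord(
            residue_number=v.residue_number,
            d_exp=calc_rdc(truth.tensor_a, v) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
            sigma=sigma,
            domain=truth.domain_of(v.residue_number),
        )
        for v in vectors
    ]
    return RdcDataset(records, description=f"synthetic RDCs (seed {seed})")


# ---------------------------------------------------------------------------
# chemical shifts


def simulate_shift_table(
    layout: Mapping[int, str],
    noise_sd: float = 0.2,
    seed: int = 0,
    sequence: Mapping[int, str] | None = None,
) -> ShiftTable:
    """CA/CB shifts = random coil + secondary-structure offset + noise."""
    rng = np.random.default_rng(seed)
    if sequence is None:
        names = rng.choice(_CSP_SAFE_RESIDUES, size=len(layout))
        sequence = {num: str(names[i]) for i, num in enumerate(sorted(layout))}
    rows = []
    for num in sorted(layout):
        resname = sequence[num]
        ca_rc, cb_rc = RANDOM_COIL_CA_CB[resname]
        d_ca, d_cb = SS_OFFSETS[layout[num]]
        rows.append((num, resname, "CA", ca_rc + d_ca + rng.normal(0.0, noise_sd)))
        if cb_rc is not None:
            rows.append((num, resname, "CB", cb_rc + d_cb + rng.normal(0.0, noise_sd)))
    df = pd.DataFrame(rows, columns=["residue_number", "residue_name", "atom_name", "shift"])
    return ShiftTable(entries=df, sequence=dict(sequence))


def simulate_titration(
    truth: GroundTruth,
    kd: float,
    ligand_concs: Sequence[float],
    max_csp: float = 0.25,
    seed: int = 0,
    n_weight: float = 0.15,
) -> list[ShiftTable]:
    """Amide H/N shift tables across a fast-exchange ligand titration.

    Binding-site residues move along a straight trajectory whose combined CSP
    at saturation is ``max_csp`` ppm, scaled by the one-site isotherm
    [L] / (Kd + [L]); all other residues are static. Concentrations and Kd
    share any one unit (mM here). Returns one table per concentration, in
    order — pass 0 first to get the apo reference.
    """
    rng = np.random.default_rng(seed)
    residues = sorted(
        set(range(truth.domains["A"][0], truth.domains["A"][1] + 1))
        | set(range(truth.domains["B"][0], truth.domains["B"][1] + 1))
    )
    names = rng.choice(_CSP_SAFE_RESIDUES, size=len(residues))
    sequence = {num: str(names[i]) for i, num in enumerate(residues)}
    base_h = {num: 7.5 + 2.0 * rng.random() for num in residues}
    base_n = {num: 105.0 + 25.0 * rng.random() for num in residues}
    # fixed per-residue partition of the combined CSP into H and N components
    frac_h = {num: 0.4 + 0.5 * rng.random() for num in truth.binding_site}
    sign_h = {num: rng.choice([-1.0, 1.0]) for num in truth.binding_site}
    sign_n = {num: rng.choice([-1.0, 1.0]) for num in truth.binding_site}

    tables: list[ShiftTable] = []
    for conc in ligand_concs:
        saturation = conc / (kd + conc) if conc > 0 else 0.0
        rows = []
        for num in residues:
            d_h = d_n = 0.0
            if num in truth.binding_site:
                combined = max_csp * saturation
                d_h = sign_h[num] * frac_h[num] * combined
                d_n = sign_n[num] * math.sqrt(1.0 - frac_h[num] ** 2) * combined / n_weight
            rows.append((num, sequence[num], "H", base_h[num] + d_h))
            rows.append((num, sequence[num], "N", base_n[num] + d_n))
        df = pd.DataFrame(rows, columns=["residue_number", "residue_name", "atom_name", "shift"])
        tables.append(ShiftTable(entries=df, sequence=dict(sequence)))
    return tables


# ---------------------------------------------------------------------------
# dynamics


def simulate_hetnoe(
    truth: GroundTruth,
    rigid_ratio: float = 0.82,
    flexible_ratio: float = 0.35,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[IntensityPair]:
    """Saturated/reference intensity pairs with class-dependent ratios.

    The reference intensity is fixed at 1e6; the saturated intensity is
    ``ratio * i_ref`` with ``flexible_ratio`` for ground-truth flexible
    residues and ``rigid_ratio`` elsewhere. ``noise_sd`` is recorded on each
    pair for the downstream Monte-Carlo error estimate; the intensities
    themselves are exact, so zero-noise runs recover the flexible set
    exactly.
    """
    i_ref = 1.0e6
    pairs = []
    for label, (lo, hi) in sorted(truth.domains.items()):
        for num in range(lo, hi + 1):
            ratio = flexible_ratio if num in truth.flexible_residues else rigid_ratio
            pairs.append(IntensityPair(num, ratio * i_ref, i_ref, noise_sd))
    return pairs


def simulate_hdx(
    truth: GroundTruth,
    timepoints: Sequence[float] = HDX_DEFAULT_TIMEPOINTS,
    noise_sd: float = 1.0e4,
    seed: int = 0,
    i0: float = HDX_REFERENCE_INTENSITY,
) -> list[TimedIntensitySeries]:
    """Exponentially decaying peak intensities from the ground-truth rates.

    ``noise_sd = 0`` yields exact intensities, but the recorded baseline-noise
    figure (which downstream detection thresholds scale with) stays at the
    default level so classification remains well defined.
    """
    rng = np.random.default_rng(seed)
    recorded_noise = noise_sd if noise_sd > 0 else 1.0e4
    out = []
    for num in sorted(truth.protection_rates):
        rate = truth.protection_rates[num]
        intensities = tuple(
            i0 * math.exp(-rate * t) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            for t in timepoints
        )
        out.append(TimedIntensitySeries(num, tuple(timepoints), intensities, recorded_noise))
    return out


def expected_hdx_class(
    rate: float,
    timepoints: Sequence[float] = HDX_DEFAULT_TIMEPOINTS,
    detect_k: float = 3.0,
    noise_sd: float = 1.0e4,
    i0: float = HDX_REFERENCE_INTENSITY,
) -> str:
    """Closed-form protection class for a noise-free exponential decay."""
    threshold = detect_k * noise_sd
    detected = [i0 * math.exp(-rate * t) > threshold for t in timepoints]
    n_prefix = 0
    for d in detected:
        if not d:
            break
        n_prefix += 1
    if n_prefix == 0:
        return "unprotected"
    if n_prefix == len(detected):
        return "persistent"
    return "short" if n_prefix == 1 else "medium"
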