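"""Residual dipolar couplings: tensor fitting and interdomain orientation.

An RDC measured for an N-H bond under weak alignment reports the bond
orientation relative to the molecular alignment tensor:

    D(theta, phi) = Da * [ (3 cos^2 theta - 1) + (3/2) R sin^2 theta cos 2 phi ]

with (theta, phi) the polar angles of the bond vector in the tensor principal
frame, Da the magnitude (Hz; the dipolar prefactor is folded in) and R the
rhombicity in [0, 2/3]. Equivalently D = v^T S v with S the 3x3 symmetric
traceless Saupe order matrix; both forms are implemented and must agree.

Fitting a single tensor to measured couplings is linear in the five
independent Saupe components (solved by weighted least squares / SVD). To ask
whether two rigid domains share the orientation a reference structure gives
them, a nested pair of models is compared: one tensor for everything (5
parameters) versus a shared magnitude Da and rhombicity R but independent
tensor orientations per domain (8 parameters), with an F-test on the chi^2
drop. The angle between the two fitted principal axes is the interdomain
reorientation suggested by the data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.transform import Rotation

from .dynamics import DEFAULT_NOE_CUTOFF, HetNoeRecord
from .structures import BondVector

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_FLOOR = 0.5  # Hz; floor on per-record uncertainties
_EULER_CONVENTION = "ZYZ"  # intrinsic z-y-z, degrees, throughout I/O


@dataclass(frozen=True)
class RdcRecord:
    residue_number: int
    d_exp: float
    sigma: float
    domain: str

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class RdcDataset:
    records: list[RdcRecord]
    description: str = ""

    def __post_init__(self) -> None:
        nums = [r.residue_number for r in self.records]
        if len(nums) != len(set(nums)):
            raise ValueError("residue numbers in an RDC dataset must be unique")

    def domains(self) -> list[str]:
        return sorted({r.domain for r in self.records})

    def subset(self, domain: str) -> "RdcDataset":
        return RdcDataset(
            [r for r in self.records if r.domain == domain],
            description=f"{self.description} [{domain}]",
        )

    def __len__(self) -> int:
        return len(self.records)


class AlignmentTensor:
    """Symmetric traceless alignment (Saupe) tensor in Hz.

    Canonical form: eigenvalues ordered |Azz| >= |Ayy| >= |Axx|, giving
    Da = Azz / 2 and rhombicity R = (2/3)(Axx - Ayy)/Azz, which the ordering
    makes non-negative. The orientation is the rotation taking principal-frame
    coordinates to the molecular frame, reported as intrinsic z-y-z Euler
    angles in degrees.
    """

    def __init__(self, saupe: np.ndarray):
        S = 0.5 * (np.asarray(saupe, dtype=float) + np.asarray(saupe, dtype=float).T)
        if abs(np.trace(S)) > 1e-9 * max(1.0, float(np.abs(S).max())):
            raise ValueError(f"Saupe matrix must be traceless, trace = {np.trace(S)}")
        S = S - np.eye(3) * (np.trace(S) / 3.0)  # remove numerical residue
        self.saupe = S
        vals, vecs = np.linalg.eigh(S)
        order = np.argsort(np.abs(vals))  # x = smallest |lambda|, z = largest
        vals = vals[order]
        vecs = vecs[:, order]
        if np.linalg.det(vecs) < 0:
            vecs[:, 0] = -vecs[:, 0]
        self._eigvals = vals  # (Axx, Ayy, Azz)
        self._rotation = vecs  # columns: principal axes in molecular frame
        azz = vals[2]
        if azz == 0:
            raise ValueError("degenerate (zero) alignment tensor")
        self.da = float(azz / 2.0)
        r = (2.0 / 3.0) * (vals[0] - vals[1]) / azz
        self.rhombicity = float(min(max(r, 0.0), 2.0 / 3.0))

    @classmethod
    def from_parameters(
        cls, da: float, rhombicity: float, euler: Sequence[float]
    ) -> "AlignmentTensor":
        """Build from (Da, R, z-y-z Euler angles in degrees)."""
        if not (0.0 <= rhombicity <= 2.0 / 3.0):
            raise ValueError("rhombicity must lie in [0, 2/3]")
        axx = -da * (1.0 - 1.5 * rhombicity)
        ayy = -da * (1.0 + 1.5 * rhombicity)
        azz = 2.0 * da
        R = Rotation.from_euler(_EULER_CONVENTION, euler, degrees=True).as_matrix()
        S = R @ np.diag([axx, ayy, azz]) @ R.T
        return cls(S)

    @property
    def euler(self) -> tuple[float, float, float]:
        a, b, g = Rotation.from_matrix(self._rotation).as_euler(_EULER_CONVENTION, degrees=True)
        return float(a), float(b), float(g)

    @property
    def principal_axes(self) -> np.ndarray:
        """3x3 matrix whose columns are the x, y, z principal axes."""
        return self._rotation.copy()

    @property
    def z_axis(self) -> np.ndarray:
        return self._rotation[:, 2].copy()

    def rotated(self, rotation: np.ndarray | Rotation) -> "AlignmentTensor":
        R = rotation.as_matrix() if isinstance(rotation, Rotation) else np.asarray(rotation)
        return AlignmentTensor(R @ self.saupe @ R.T)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        a, b, g = self.euler
        return (
            f"AlignmentTensor(Da={self.da:.3f} Hz, R={self.rhombicity:.3f}, "
            f"euler=({a:.1f}, {b:.1f}, {g:.1f}) deg)"
        )


def calc_rdc(tensor: AlignmentTensor, vector: BondVector) -> float:
    """Back-calculate the coupling for one bond vector: D = v^T S v."""
    v = vector.direction
    return float(v @ tensor.saupe @ v)


def calc_rdc_angular(tensor: AlignmentTensor, vector: BondVector) -> float:
    """Back-calculate via the (Da, R, theta, phi) angular form.

    Provided as an independent route to the same number as :func:`calc_rdc`;
    the two agree to floating-point precision by construction of the
    principal frame.
    """
    u = tensor.principal_axes.T @ vector.direction
    cos_t = np.clip(u[2], -1.0, 1.0)
    sin2 = 1.0 - cos_t**2
    phi = math.atan2(u[1], u[0])
    return float(
        tensor.da * ((3.0 * cos_t**2 - 1.0) + 1.5 * tensor.rhombicity * sin2 * math.cos(2 * phi))
    )


@dataclass
class FitResult:
    """Outcome of an alignment-tensor fit."""

    tensors: dict[str, AlignmentTensor]
    chi2: float
    n_data: int
    n_params: int
    q_per_domain: dict[str, float]
    q_overall: float
    residues_used: list[int]
    d_calc: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        if self.n_params > self.n_data:
            raise ValueError("fit cannot have more parameters than data points")


@dataclass
class TwoDomainFit:
    """Shared-magnitude two-orientation fit plus its nested pooled fit."""

    shared: FitResult
    pooled: FitResult


@dataclass(frozen=True)
class FTestResult:
    f_value: float
    dof: tuple[int, int]
    probability: float

    def __post_init__(self) -> None:
        if self.f_value < 0:
            raise ValueError("F must be non-negative")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")


# ---------------------------------------------------------------------------
# fitting


def _vector_map(vectors: Iterable[BondVector]) -> dict[int, np.ndarray]:
    return {v.residue_number: v.direction for v in vectors}


def _design_row(v: np.ndarray) -> np.ndarray:
    """Row of the linear design for the 5 Saupe components.

    Parameterisation s = (Sxx, Syy, Sxy, Sxz, Syz) with Szz = -Sxx - Syy:
    D = Sxx (x^2 - z^2) + Syy (y^2 - z^2) + 2 Sxy xy + 2 Sxz xz + 2 Syz yz.
    """
    x, y, z = v
    return np.array([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def _saupe_from_components(s: np.ndarray) -> np.ndarray:
    sxx, syy, sxy, sxz, syz = s
    return np.array(
        [[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, -sxx - syy]], dtype=float
    )


def _usable(data: RdcDataset, vmap: Mapping[int, np.ndarray]) -> list[RdcRecord]:
    usable = [r for r in data.records if r.residue_number in vmap]
    missing = len(data.records) - len(usable)
    if missing:
        logger.warning("%d RDC records have no bond vector and are ignored", missing)
    return usable


def _q_factors(records: Sequence[RdcRecord], d_calc: Mapping[int, float]) -> tuple[dict, float]:
    per_domain: dict[str, float] = {}
    for dom in sorted({r.domain for r in records}):
        sub = [r for r in records if r.domain == dom]
        per_domain[dom] = q_factor(
            [r.d_exp for r in sub], [d_calc[r.residue_number] for r in sub]
        )
    overall = q_factor([r.d_exp for r in records], [d_calc[r.residue_number] for r in records])
    return per_domain, overall


def fit_tensor_svd(data: RdcDataset, vectors: Iterable[BondVector]) -> FitResult:
    """Fit one alignment tensor to all records by weighted linear least squares.

    The five independent Saupe components enter the back-calculated coupling
    linearly, so the chi^2-optimal tensor is the solution of a weighted
    least-squares problem (solved via SVD). Records weighted by 1/sigma.
    """
    vmap = _vector_map(vectors)
    usable = _usable(data, vmap)
    if len(usable) < 5:
        raise ValueError(f"need >= 5 RDCs with bond vectors, have {len(usable)}")
    A = np.array([_design_row(vmap[r.residue_number]) for r in usable])
    y = np.array([r.d_exp for r in usable])
    w = np.array([1.0 / r.sigma for r in usable])
    Aw = A * w[:, None]
    yw = y * w
    svals = np.linalg.svd(Aw, compute_uv=False)
    cond = svals[0] / svals[-1] if svals[-1] > 0 else math.inf
    if not math.isfinite(cond) or cond > 1e10:
        raise ValueError(f"rank-deficient RDC design (condition number {cond:.3g}); "
                         "bond vectors are too degenerate to determine a tensor")
    s, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    tensor = AlignmentTensor(_saupe_from_components(s))
    d_calc = {
        r.residue_number: float(A[i] @ s) for i, r in enumerate(usable)
    }
    chi2 = float(np.sum(((y - A @ s) * w) ** 2))
    q_dom, q_all = _q_factors(usable, d_calc)
    tensors = {dom: tensor for dom in sorted({r.domain for r in usable})}
    return FitResult(
        tensors=tensors,
        chi2=chi2,
        n_data=len(usable),
        n_params=5,
        q_per_domain=q_dom,
        q_overall=q_all,
        residues_used=sorted(r.residue_number for r in usable),
        d_calc=d_calc,
    )


def filter_by_noe(
    data: RdcDataset,
    noe: Iterable[HetNoeRecord],
    cutoff: float = DEFAULT_NOE_CUTOFF,
) -> RdcDataset:
    """Drop RDCs of flexible residues (hetNOE ratio below ``cutoff``).

    An RDC measured on a mobile amide averages over internal motion and would
    bias a rigid-body tensor fit, so such residues are excluded. Residues
    without an NOE measurement are retained with a warning.
    """
    ratios = {r.residue_number: r.ratio for r in noe}
    kept: list[RdcRecord] = []
    for rec in data.records:
        ratio = ratios.get(rec.residue_number)
        if ratio is None:
            logger.warning("residue %d has no hetNOE value; RDC retained", rec.residue_number)
            kept.append(rec)
        elif ratio >= cutoff:
            kept.append(rec)
    return RdcDataset(kept, description=f"{data.description} [NOE >= {cutoff}]")


def _shared_fit_residuals(
    angles: np.ndarray,
    dom_of: np.ndarray,
    V: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of the shared-(Da, R) two-orientation model.

    ``angles`` packs two z-y-z Euler triples (radians). For fixed orientations
    the coupling is linear in (a, b) = (Da, Da*R), so those are profiled out
    by an inner weighted least-squares solve (variable projection).
    """
    mats = []
    for d in range(2):
        R = Rotation.from_euler(_EULER_CONVENTION, angles[3 * d : 3 * d + 3]).as_matrix()
        T1 = R @ np.diag([-1.0, -1.0, 2.0]) @ R.T
        T2 = R @ np.diag([1.5, -1.5, 0.0]) @ R.T
        mats.append((T1, T2))
    col1 = np.einsum("ij,jk,ik->i", V, mats[0][0], V)
    col2 = np.einsum("ij,jk,ik->i", V, mats[0][1], V)
    c1b = np.einsum("ij,jk,ik->i", V, mats[1][0], V)
    c2b = np.einsum("ij,jk,ik->i", V, mats[1][1], V)
    is_b = dom_of == 1
    col1 = np.where(is_b, c1b, col1)
    col2 = np.where(is_b, c2b, col2)
    X = np.column_stack([col1, col2]) * w[:, None]
    beta, *_ = np.linalg.lstsq(X, y * w, rcond=None)
    resid = y * w - X @ beta
    return resid, beta


def fit_two_domain_shared(
    data: RdcDataset,
    vectors: Iterable[BondVector],
    n_restarts: int = 4,
    max_nfev: int = 10_000,
) -> TwoDomainFit:
    """Fit a shared-magnitude, two-orientation alignment model.

    Both domains see the same alignment medium, so a single Da and R are
    imposed; the tensor orientation within each domain is free (3 Euler
    angles each, 8 parameters total). The fit minimises the total weighted
    chi^2, starting from the per-domain linear (SVD) solutions, with a few
    deterministic perturbed restarts to guard against local minima. For fixed
    orientations the model is linear in (Da, Da*R), which are profiled out
    analytically, leaving a 6-dimensional angular optimisation.

    Also computes the nested pooled fit (one tensor, 5 parameters, both
    domains together), the reduced model of the orientation F-test.
    """
    vmap = _vector_map(vectors)
    usable = _usable(data, vmap)
    doms = sorted({r.domain for r in usable})
    if len(doms) != 2:
        raise ValueError(f"two-domain fit needs exactly 2 domain labels, got {doms}")
    per_dom_counts = {d: sum(r.domain == d for r in usable) for d in doms}
    if any(c < 5 for c in per_dom_counts.values()):
        raise ValueError(f"each domain needs >= 5 usable RDCs, have {per_dom_counts}")

    sub = RdcDataset(usable, description=data.description)
    pooled = fit_tensor_svd(sub, [BondVector(r.residue_number, vmap[r.residue_number])
                                  for r in usable])
    init_fits = [
        fit_tensor_svd(sub.subset(d), [BondVector(r.residue_number, vmap[r.residue_number])
                                       for r in usable if r.domain == d])
        for d in doms
    ]

    V = np.array([vmap[r.residue_number] for r in usable])
    y = np.array([r.d_exp for r in usable])
    w = np.array([1.0 / r.sigma for r in usable])
    dom_of = np.array([doms.index(r.domain) for r in usable])

    def fun(angles: np.ndarray) -> np.ndarray:
        return _shared_fit_residuals(angles, dom_of, V, y, w)[0]

    base = np.concatenate(
        [np.deg2rad(init_fits[0].tensors[doms[0]].euler),
         np.deg2rad(init_fits[1].tensors[doms[1]].euler)]
    )
    starts = [base]
    rng = np.random.default_rng(0)  # deterministic perturbation pattern
    for _ in range(max(0, n_restarts - 1)):
        starts.append(base + rng.normal(0.0, np.deg2rad(8.0), size=6))

    best = None
    for x0 in starts:
        res = optimize.least_squares(
            fun, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev
        )
        chi2 = float(np.sum(res.fun**2))
        if best is None or chi2 < best[0]:
            best = (chi2, res)
    chi2, res = best
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"two-domain fit failed to converge; best chi^2 {chi2:.4g}")

    _, beta = _shared_fit_residuals(res.x, dom_of, V, y, w)
    tensors: dict[str, AlignmentTensor] = {}
    for d_idx, dom in enumerate(doms):
        R = Rotation.from_euler(_EULER_CONVENTION, res.x[3 * d_idx : 3 * d_idx + 3]).as_matrix()
        T1 = R @ np.diag([-1.0, -1.0, 2.0]) @ R.T
        T2 = R @ np.diag([1.5, -1.5, 0.0]) @ R.T
        tensors[dom] = AlignmentTensor(beta[0] * T1 + beta[1] * T2)
    d_calc = {
        r.residue_number: calc_rdc(
            tensors[r.domain], BondVector(r.residue_number, vmap[r.residue_number])
        )
        for r in usable
    }
    q_dom, q_all = _q_factors(usable, d_calc)
    shared = FitResult(
        tensors=tensors,
        chi2=chi2,
        n_data=len(usable),
        n_params=8,
        q_per_domain=q_dom,
        q_overall=q_all,
        residues_used=sorted(r.residue_number for r in usable),
        d_calc=d_calc,
    )
    return TwoDomainFit(shared=shared, pooled=pooled)


def q_factor(
    d_exp: Sequence[float],
    d_calc: Sequence[float],
    da: float | None = None,
    rhombicity: float | None = None,
    normalization: str = "rms",
) -> float:
    """Quality factor of an RDC fit: rms deviation over rms experimental RDC.

    ``normalization='da'`` instead divides by sqrt(2 Da^2 (4 + 3 R^2) / 5),
    the tensor-magnitude normalisation sometimes used in the literature
    (requires ``da`` and ``rhombicity``).
    """
    if len(d_exp) != len(d_calc) or len(d_exp) == 0:
        raise ValueError("d_exp and d_calc must be equal-length, non-empty")
    e = np.asarray(d_exp, dtype=float)
    c = np.asarray(d_calc, dtype=float)
    rms_dev = math.sqrt(float(np.mean((e - c) ** 2)))
    if normalization == "rms":
        denom = math.sqrt(float(np.mean(e**2)))
        if denom == 0:
            raise ValueError("all experimental RDCs are zero; Q undefined")
    elif normalization == "da":
        if da is None or rhombicity is None:
            raise ValueError("'da' normalization requires da and rhombicity")
        denom = math.sqrt(2.0 * da**2 * (4.0 + 3.0 * rhombicity**2) / 5.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return rms_dev / denom


def f_test(fit_reduced: FitResult, fit_full: FitResult) -> FTestResult:
    """Nested-model F-test on the chi^2 drop between two fits of the same data.

    F = ((chi2_red - chi2_full) / (p_full - p_red)) / (chi2_full / (N - p_full))

    The reported probability is the F-distribution CDF at the observed value
    — the confidence with which the extra parameters are warranted.
    """
    if fit_reduced.n_data != fit_full.n_data or fit_reduced.residues_used != fit_full.residues_used:
        raise ValueError("F-test requires fits of the same data")
    if fit_full.n_params <= fit_reduced.n_params:
        raise ValueError("fits are not nested (full model must have more parameters)")
    dof1 = fit_full.n_params - fit_reduced.n_params
    dof2 = fit_full.n_data - fit_full.n_params
    if dof2 <= 0:
        raise ValueError("full model leaves no residual degrees of freedom")
    num = max(0.0, fit_reduced.chi2 - fit_full.chi2) / dof1
    den = fit_full.chi2 / dof2
    f_value = num / den if den > 0 else 0.0
    probability = float(stats.f.cdf(f_value, dof1, dof2))
    return FTestResult(f_value=f_value, dof=(dof1, dof2), probability=probability)


def interdomain_angle(fit: FitResult) -> float:
    """Angle (degrees) between the two domains' principal tensor axes.

    The principal axis is defined up to sign, so the angle is folded into
    [0, 90] degrees.
    """
    doms = sorted(fit.tensors)
    if len(doms) != 2:
        raise ValueError(f"interdomain angle needs a two-domain fit, got domains {doms}")
    z1 = fit.tensors[doms[0]].z_axis
    z2 = fit.tensors[doms[1]].z_axis
    cosang = abs(float(np.clip(z1 @ z2, -1.0, 1.0)))
    return math.degrees(math.acos(cosang))


# ---------------------------------------------------------------------------
# I/O


def read_rdc_table(path: str | Path, sigma_floor: float = DEFAULT_SIGMA_FLOOR) -> RdcDataset:
    """Read an RDC TSV: residue, d_exp_hz, sigma_hz, domain."""
    df = pd.read_csv(path, sep="\t")
    recs = [
        RdcRecord(
            residue_number=int(row.iloc[0]),
            d_exp=float(row.iloc[1]),
            sigma=max(float(row.iloc[2]), sigma_floor),
            domain=str(row.iloc[3]),
        )
        for _, row in df.iterrows()
    ]
    return RdcDataset(recs, description=str(path))


def write_rdc_table(data: RdcDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "residue_number": [r.residue_number for r in data.records],
            "d_exp_hz": [r.d_exp for r in data.records],
            "sigma_hz": [r.sigma for r in data.records],
            "domain": [r.domain for r in data.records],
        }
    ).to_csv(path, sep="\t", index=False)


def fit_report(fit: FitResult, ftest: FTestResult | None = None) -> dict:
    """JSON-serialisable summary of a fit (Da, R, Euler angles, chi2, Q)."""
    out: dict = {
        "chi2": fit.chi2,
        "n_data": fit.n_data,
        "n_params": fit.n_params,
        "q_overall": fit.q_overall,
        "q_per_domain": fit.q_per_domain,
        "residues_used": fit.residues_used,
        "euler_convention": "intrinsic z-y-z, degrees",
        "tensors": {
            dom: {
                "da_hz": t.da,
                "rhombicity": t.rhombicity,
                "euler_deg": list(t.euler),
            }
            for dom, t in fit.tensors.items()
        },
    }
    if ftest is not None:
        out["f_test"] = {
            "f_value": ftest.f_value,
            "dof": list(ftest.dof),
            "probability": ftest.probability,
        }
    return out
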