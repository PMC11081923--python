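"""Backbone dynamics: heteronuclear NOE ratios and H/D-exchange protection.

The {1H}-15N hetNOE is the ratio of amide peak intensities with and without
proton saturation; ratios below ~0.7 flag sub-nanosecond backbone flexibility.
Uncertainties come from Monte-Carlo resampling with the spectrum baseline
noise as the intensity error. H/D exchange is scored from peak detectability
across a small set of timepoints after transfer into D2O buffer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_N_MC = 500
DEFAULT_NOE_CUTOFF = 0.7
DEFAULT_DETECT_K = 3.0

#: Protection classes ordered from least to most protected.
HDX_CLASSES = ("unprotected", "short", "medium", "persistent")


@dataclass(frozen=True)
class IntensityPair:
    """Saturated/reference peak heights for one residue (arbitrary units)."""

    residue_number: int
    i_sat: float
    i_ref: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class HetNoeRecord:
    residue_number: int
    ratio: float
    ratio_error: float

    def __post_init__(self) -> None:
        if self.ratio_error < 0:
            raise ValueError("ratio_error must be non-negative")


@dataclass(frozen=True)
class TimedIntensitySeries:
    """Peak heights for one residue across exchange timepoints (minutes)."""

    residue_number: int
    times: tuple[float, ...]
    intensities: tuple[float, ...]
    noise_sd: float

    def __post_init__(self) -> None:
        t = self.times
        if len(t) != len(self.intensities):
            raise ValueError("times and intensities differ in length")
        if not t or t[0] <= 0:
            raise ValueError("first timepoint must be > 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing")


def het_noe(
    pairs: Iterable[IntensityPair],
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> list[HetNoeRecord]:
    """hetNOE ratios with Monte-Carlo errors.

    ratio = i_sat / i_ref. The error is the standard deviation of the ratio
    over ``n_mc`` resamples in which independent Gaussian noise of width
    ``noise_sd`` is added to both the saturated and the reference intensity
    (both spectra carry baseline noise). Deterministic for a fixed seed.
    Pairs with a zero reference intensity are skipped with a warning.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[HetNoeRecord] = []
    for p in pairs:
        if p.i_ref == 0:
            logger.warning("residue %d has zero reference intensity; skipped", p.residue_number)
            continue
        ratio = p.i_sat / p.i_ref
        if p.noise_sd == 0:
            err = 0.0
        else:
            sat = p.i_sat + rng.normal(0.0, p.noise_sd, size=n_mc)
            ref = p.i_ref + rng.normal(0.0, p.noise_sd, size=n_mc)
            err = float(np.std(sat / ref, ddof=1)) if n_mc > 1 else 0.0
        out.append(HetNoeRecord(p.residue_number, ratio, err))
    return out


def flag_flexible(records: Iterable[HetNoeRecord], cutoff: float = DEFAULT_NOE_CUTOFF) -> list[int]:
    """Residues whose hetNOE ratio is strictly below ``cutoff``."""
    return sorted(r.residue_number for r in records if r.ratio < cutoff)


def _check_common_grid(series: Sequence[TimedIntensitySeries]) -> tuple[float, ...]:
    grids = {s.times for s in series}
    if len(grids) > 1:
        raise ValueError(f"inconsistent timepoint grids: {sorted(grids)}")
    return next(iter(grids))


def hdx_classify(
    series: Sequence[TimedIntensitySeries],
    detect_k: float = DEFAULT_DETECT_K,
) -> dict[int, str]:
    """Protection class per residue from detectability across timepoints.

    A peak counts as detected at a timepoint when its intensity exceeds
    ``detect_k`` times the noise level. With the canonical three-point
    schedule (15 min, 24 h, 48 h):

    - ``unprotected``: not detected even at the first point;
    - ``short``: detected at the first point only;
    - ``medium``: still detected at the second point but gone by the last;
    - ``persistent``: detected at every point.

    Detection is required to be cumulative from the start — once a peak has
    fallen below threshold it is considered exchanged.
    """
    _check_common_grid(series)
    out: dict[int, str] = {}
    for s in series:
        detected = [i > detect_k * s.noise_sd for i in s.intensities]
        # longest detected prefix
        n_prefix = 0
        for d in detected:
            if not d:
                break
            n_prefix += 1
        if n_prefix == 0:
            cls = "unprotected"
        elif n_prefix == len(detected):
            cls = "persistent"
        elif n_prefix == 1:
            cls = "short"
        else:
            cls = "medium"
        out[s.residue_number] = cls
    return out


def hdx_extent(series: TimedIntensitySeries, reference_intensity: float) -> list[float]:
    """Fractional exchange 1 - I(t)/I_ref at each timepoint, clamped to [0, 1]."""
    if reference_intensity <= 0:
        raise ValueError("reference_intensity must be positive")
    return [min(1.0, max(0.0, 1.0 - i / reference_intensity)) for i in series.intensities]
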