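"""Wavelet sub-band statistics of CSP-projected signals.

Two extractors share the machinery here:

* **CSP-Wavelet** — an L-level discrete wavelet transform (db4) of each
  projected channel; terminal sub-bands are the approximation A_L plus the
  details D_L .. D_1, tiling (0, fs/2] dyadically.
* **CSP-WPD** — a full depth-L wavelet packet tree whose 2^L terminal nodes
  tile (0, fs/2] uniformly.  Nodes are reordered from tree (Paley) order to
  natural frequency order before frequency intervals are assigned.

From each retained sub-band, two statistics per projected channel per
trial: the coefficient energy  e = sum_j |D_ij|^2  and the sample standard
deviation (N-1 divisor)  s = sqrt( sum_j (D_ij - mean)^2 / (N-1) ).

The decomposition depth follows sampling rate: 3 levels at 100 Hz,
4 levels at 250/256 Hz, so the terminal bands around the sensorimotor
8-30 Hz range have comparable width across datasets.  Sub-bands are kept
when their ideal dyadic interval intersects 8-30 Hz (default rule); a
stricter fully-within rule and explicit index lists are also available.
The intersect rule makes the retained interval set identical across
adjacent depths (e.g. L=3 vs 4 at 100 Hz, L=4 vs 5 at 250 Hz), because the
extra level only splits sub-bands that lie entirely outside 8-30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .csp import ProjectedTrials
from .errors import DataError, DecompositionError, PlanningError
from .features import FeatureMatrix

__all__ = [
    "WaveletPlan",
    "plan_wavelet",
    "dwt_subband_coeffs",
    "wpd_subband_coeffs",
    "subband_energy",
    "subband_std",
    "extract_csp_wavelet",
    "extract_csp_wpd",
]

#: band (Hz) that a sub-band must touch to be retained by the default rule
MI_BAND = (8.0, 30.0)


@dataclass
class WaveletPlan:
    """A fixed decomposition recipe: depth, sub-band intervals, retained set.

    ``subband_intervals`` is ordered low to high frequency and tiles
    (0, fs/2]; ``selected`` indexes into it.
    """

    fs: float
    levels: int
    transform: str  # "dwt" | "wpd"
    wavelet: str = "db4"
    boundary_mode: str = "periodization"
    subband_intervals: list[tuple[float, float]] = field(default_factory=list)
    selected: list[int] = field(default_factory=list)
    selection_rule: str = "intersect_8_30"

    @property
    def n_subbands(self) -> int:
        return len(self.subband_intervals)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def selected_intervals(self) -> list[tuple[float, float]]:
        return [self.subband_intervals[i] for i in self.selected]


def _dwt_intervals(fs: float, levels: int) -> list[tuple[float, float]]:
    """A_L then D_L .. D_1, low to high: (0, fs/2^{L+1}), then doubling."""
    edges = [0.0] + [fs / 2 ** (levels + 1 - i) for i in range(levels + 1)]
    return list(zip(edges[:-1], edges[1:]))


def _wpd_intervals(fs: float, levels: int) -> list[tuple[float, float]]:
    width = fs / 2 ** (levels + 1)
    return [(i * width, (i + 1) * width) for i in range(2**levels)]


def plan_wavelet(
    fs: float,
    transform: str = "dwt",
    levels: int | None = None,
    selection_rule: str = "intersect_8_30",
    explicit_selected: list[int] | None = None,
) -> WaveletPlan:
    """Build a decomposition plan for a sampling rate.

    ``levels`` defaults to 3 for fs <= 128 Hz and 4 above (the depths that
    place dyadic band edges usefully around 8-30 Hz for 100 vs 250/256 Hz
    data); pass it explicitly to override.
    """
    if transform not in ("dwt", "wpd"):
        raise PlanningError(f"unknown transform {transform!r}")
    if fs <= 0:
        raise PlanningError(f"sampling rate must be positive, got {fs}")
    if levels is None:
        levels = 3 if fs <= 128 else 4
    if levels < 1:
        raise PlanningError(f"levels must be >= 1, got {levels}")
    narrowest = fs / 2 ** (levels + 1)
    if narrowest < 0.5:
        raise PlanningError(
            f"{levels} levels at fs={fs} Hz give sub-bands of {narrowest:.3g} Hz, "
            "below the 0.5 Hz resolvable floor"
        )
    intervals = (
        _dwt_intervals(fs, levels) if transform == "dwt" else _wpd_intervals(fs, levels)
    )
    lo_sel, hi_sel = MI_BAND
    if selection_rule == "intersect_8_30":
        selected = [i for i, (lo, hi) in enumerate(intervals) if hi > lo_sel and lo < hi_sel]
    elif selection_rule == "within_8_30":
        selected = [i for i, (lo, hi) in enumerate(intervals) if lo >= lo_sel and hi <= hi_sel]
    elif selection_rule == "explicit":
        if not explicit_selected:
            raise PlanningError("explicit selection rule requires explicit_selected")
        if any(i < 0 or i >= len(intervals) for i in explicit_selected):
            raise PlanningError("explicit_selected index out of range")
        selected = sorted(explicit_selected)
    else:
        raise PlanningError(f"unknown selection rule {selection_rule!r}")
    if not selected:
        raise PlanningError(
            f"no sub-band retained at fs={fs}, levels={levels}, rule={selection_rule}"
        )
    return WaveletPlan(
        fs=fs,
        levels=levels,
        transform=transform,
        subband_intervals=intervals,
        selected=selected,
        selection_rule=selection_rule,
    )


def _check_length(signal_1d: np.ndarray, plan: WaveletPlan) -> None:
    n = signal_1d.shape[-1]
    if n < 2**plan.levels:
        raise DecompositionError(
            f"signal of length {n} too short for {plan.levels}-level decomposition"
        )


def dwt_subband_coeffs(signal_1d: np.ndarray, plan: WaveletPlan) -> list[np.ndarray]:
    """Coefficient vectors of the plan's selected DWT sub-bands, low to high."""
    if plan.transform != "dwt":
        raise DataError(f"plan is for {plan.transform!r}, expected 'dwt'")
    x = np.asarray(signal_1d, dtype=float)
    _check_length(x, plan)
    # wavedec returns [cA_L, cD_L, ..., cD_1]: already low-to-high frequency
    coeffs = pywt.wavedec(x, plan.wavelet, mode=plan.boundary_mode, level=plan.levels)
    return [coeffs[i] for i in plan.selected]


def wpd_subband_coeffs(signal_1d: np.ndarray, plan: WaveletPlan) -> list[np.ndarray]:
    """Coefficient vectors of the selected packet nodes in frequency order."""
    if plan.transform != "wpd":
        raise DataError(f"plan is for {plan.transform!r}, expected 'wpd'")
    x = np.asarray(signal_1d, dtype=float)
    _check_length(x, plan)
    wp = pywt.WaveletPacket(
        data=x, wavelet=plan.wavelet, mode=plan.boundary_mode, maxlevel=plan.levels
    )
    nodes = wp.get_level(plan.levels, order="freq")
    return [np.asarray(nodes[i].data, dtype=float) for i in plan.selected]


def subband_energy(coeffs: np.ndarray) -> float:
    """Sum of squared coefficients of one sub-band."""
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise DataError("empty coefficient vector")
    return float(np.sum(c * c))


def subband_std(coeffs: np.ndarray) -> float:
    """Sample standard deviation (N-1 divisor) of one sub-band's coefficients."""
    c = np.asarray(coeffs, dtype=float)
    if c.size < 2:
        raise DataError(f"need >= 2 coefficients for std, got {c.size}")
    return float(np.std(c, ddof=1))


def _extract_wavelet_family(
    proj: ProjectedTrials, plan: WaveletPlan, decomposer
) -> FeatureMatrix:
    n_trials, n_chan, _ = proj.data.shape
    n_bands = plan.n_selected
    intervals = plan.selected_intervals()
    values = np.empty((n_trials, n_chan * n_bands * 2))
    for t in range(n_trials):
        col = 0
        for c in range(n_chan):
            bands = decomposer(proj.data[t, c], plan)
            for coeffs in bands:
                values[t, col] = subband_energy(coeffs)
                values[t, col + 1] = subband_std(coeffs)
                col += 2
    names = []
    for c in range(n_chan):
        for lo, hi in intervals:
            for stat in ("energy", "std"):
                names.append(f"csp{c + 1}|{lo:g}-{hi:g}Hz|{stat}")
    return FeatureMatrix(values=values, feature_names=names, labels=proj.labels)


def extract_csp_wavelet(proj: ProjectedTrials, plan: WaveletPlan) -> FeatureMatrix:
    """(energy, std) of each selected DWT sub-band, per projected channel.

    Layout is channel-major, energy before std within each sub-band:
    ``[e11, s11, ..., eB1, sB1, e12, s12, ...]`` — P = 2m * B * 2.
    """
    if plan.transform != "dwt":
        raise DataError("extract_csp_wavelet requires a DWT plan")
    return _extract_wavelet_family(proj, plan, dwt_subband_coeffs)


def extract_csp_wpd(proj: ProjectedTrials, plan: WaveletPlan) -> FeatureMatrix:
    """Packet-tree analogue of :func:`extract_csp_wavelet`; P = 2m * B' * 2."""
    if plan.transform != "wpd":
        raise DataError("extract_csp_wpd requires a WPD plan")
    return _extract_wavelet_family(proj, plan, wpd_subband_coeffs)
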