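"""Spaceless perikinetic aggregation model (Smoluchowski coagulation).

The size spectrum ``N_k(t)`` (number of aggregates of ``k`` cells) obeys

    dN_k/dt = 1/2 sum_{i+j=k} K_ij N_i N_j - sum_i K_ik N_i N_k

Two kernel scenarios are supported:

* ``constant`` — every pair of clusters merges at the same rate; the
  rate parameter K is defined through the total-count equation
  dN/dt = -K N^2, whose solution is the closed form
  N(t) = N0 / (1 + K N0 t).  In terms of the size-resolved equation
  above this corresponds to kernel entries K_ij = 2K (summing the
  general equation over k gives dN/dt = -1/2 K_ij N^2);
* ``monomer_only`` — only individual cells move, so K_1j = K_j1 = K1 and
  K_ij = 0 for i, j > 1.  The spectrum obeys

      dN_1/dt = -K1 N_1 N
      dN_2/dt = K1 (1/2 N_1^2 - N_1 N_2)
      dN_k/dt = K1 N_1 (N_{k-1} - N_k),  k >= 3

  whose sum telescopes to the total-count equation
  dN/dt = K1 N_1 (N_1/2 - N).

Rates are carried in count-space units (per count per minute); the
conversion to area units (µm²/min, m²/s) multiplies by the area of the
observed field.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

__all__ = [
    "KineticState",
    "KernelSpec",
    "DEFAULT_FIELD_AREA_UM2",
    "constant_kernel_total",
    "coagulation_rhs",
    "integrate_kinetics",
    "fit_kernel",
    "select_kernel",
    "convert_rate_units",
]

#: area of the observed experimental field: 1280 x 0.658 µm by 1080 x 0.658 µm
DEFAULT_FIELD_AREA_UM2 = (1280 * 0.658) * (1080 * 0.658)

_KINDS = ("constant", "monomer_only")


@dataclass
class KineticState:
    """Size spectrum at one instant; ``spectrum[k-1]`` holds N_k."""

    spectrum: np.ndarray
    time: float = 0.0

    @property
    def total(self) -> float:
        """Total number of aggregates N = sum_k N_k (singletons included)."""
        return float(self.spectrum.sum())

    @property
    def mass(self) -> float:
        """Total number of cells sum_k k N_k (conserved by coagulation)."""
        k = np.arange(1, len(self.spectrum) + 1)
        return float(np.dot(k, self.spectrum))


@dataclass(frozen=True)
class KernelSpec:
    """Aggregation kernel: ``kind`` in {constant, monomer_only} and the
    rate K (constant kernel) or K1 (monomer-only), count-space per min."""

    kind: str
    rate: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


def constant_kernel_total(t, n0: float, rate: float):
    """Closed-form total count under the constant kernel:
    N(t) = N0 / (1 + K N0 t)."""
    t = np.asarray(t, dtype=float)
    return n0 / (1.0 + rate * n0 * t)


def coagulation_rhs(spectrum: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Time derivative of the (truncated) size spectrum.

    Gain into sizes beyond the truncation ``kmax = len(spectrum)`` is
    dropped; the corresponding loss terms are kept, so truncated mass can
    be monitored as N0 - sum k N_k.
    """
    nk = np.asarray(spectrum, dtype=float)
    kmax = len(nk)
    if kmax < 2:
        raise ValueError("spectrum must resolve at least sizes 1 and 2")
    K = kernel.rate
    out = np.empty_like(nk)
    if kernel.kind == "constant":
        # kernel entries are 2K so that the total obeys dN/dt = -K N^2
        K2 = 2.0 * K
        total = nk.sum()
        # gain: 1/2 * sum_{i+j=k} N_i N_j  == 1/2 (N*N)_conv
        conv = np.convolve(nk, nk)[: kmax]  # index k-2 holds sum_{i+j=k}
        gain = np.zeros(kmax)
        gain[1:] = 0.5 * conv[: kmax - 1]
        out[:] = K2 * (gain - nk * total)
    else:  # monomer_only
        n1 = nk[0]
        total = nk.sum()
        out[0] = -K * n1 * total
        out[1] = K * (0.5 * n1 * n1 - n1 * nk[1])
        if kmax > 2:
            out[2:] = K * n1 * (nk[1:-1] - nk[2:])
    return out


def integrate_kinetics(
    n0: float,
    kernel: KernelSpec,
    t_grid,
    kmax: int = 256,
    rtol: float = 1e-8,
    initial_spectrum=None,
    max_truncated_mass: float = 0.01,
):
    """Integrate the coagulation system on ``t_grid`` from a monodisperse
    start (all cells individual) unless an initial spectrum is given.

    Returns ``(totals, spectra)``: the total aggregate count at each grid
    time and the (n_times, kmax) spectrum array.  If more than
    ``max_truncated_mass`` of the mass leaks past ``kmax`` the truncation
    is doubled and the integration repeated.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    while True:
        if initial_spectrum is not None:
            y0 = np.zeros(kmax)
            y0[: len(initial_spectrum)] = initial_spectrum
            mass0 = np.dot(np.arange(1, kmax + 1), y0)
        else:
            y0 = np.zeros(kmax)
            y0[0] = n0
            mass0 = n0
        sol = solve_ivp(
            lambda t, y: coagulation_rhs(y, kernel),
            (t_grid[0], t_grid[-1]),
            y0,
            t_eval=t_grid,
            method="LSODA",
            rtol=rtol,
            atol=1e-12 * max(n0, 1.0),
        )
        if not sol.success:
            raise RuntimeError(f"kinetics integration failed: {sol.message}")
        spectra = sol.y.T
        k = np.arange(1, kmax + 1)
        mass = spectra @ k
        lost = 1.0 - mass.min() / mass0
        if lost <= max_truncated_mass:
            return spectra.sum(axis=1), spectra
        kmax *= 2


def fit_kernel(times, counts, kind: str, n0: float | None = None, kmax: int = 256, sd=None):
    """Least-squares fit of the single kernel rate to a (time, count)
    series.

    The constant kernel uses the closed form; the monomer-only kernel is
    integrated numerically.  With ``sd`` (per-point replicate standard
    deviations) the objective is inverse-variance weighted.  Returns
    ``(rate, sse)`` with the rate in count-space per unit of ``times``.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if sd is not None:
        sd = np.asarray(sd, dtype=float)
        if np.any(sd <= 0):
            raise ValueError("sd must be positive")
        w = 1.0 / sd**2
    else:
        w = np.ones_like(counts)
    if len(times) < 3:
        raise ValueError("need at least 3 points to fit")
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    if kind not in _KINDS:
        raise ValueError(f"unknown kernel kind {kind!r}")
    if n0 is None:
        n0 = counts[0]
    if np.ptp(counts) == 0.0:
        warnings.warn("constant count series: returning rate 0", stacklevel=2)
        return 0.0, float(np.sum((counts - counts[0]) ** 2))

    def predict(rate):
        if kind == "constant":
            return constant_kernel_total(times, n0, rate)
        totals, _ = integrate_kinetics(n0, KernelSpec(kind, rate), times, kmax=kmax)
        return totals

    def sse(log_rate):
        return float(np.sum(w * (predict(np.exp(log_rate)) - counts) ** 2))

    # bracket on a log-spaced grid, then refine
    # scale guess: constant-kernel rate for which the count halves mid-series
    k_scale = max((n0 / counts[-1] - 1.0) / (n0 * times[-1] + 1e-30), 1e-12 / (n0 * (times[-1] + 1.0)))
    grid = np.log(k_scale) + np.log(10.0) * np.linspace(-3, 3, 25)
    vals = [sse(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    rate = float(np.exp(res.x))
    return rate, float(res.fun)


def select_kernel(times, counts, n0: float | None = None):
    """Fit both kernel scenarios and return the better one.

    Returns ``(best_kind, {kind: (rate, sse)})``; ties go to the constant
    kernel (the analytically solvable scenario).
    """
    fits = {kind: fit_kernel(times, counts, kind, n0=n0) for kind in _KINDS}
    best = "constant" if fits["constant"][1] <= fits["monomer_only"][1] else "monomer_only"
    return best, fits


_UM2_PER_MIN_TO_M2_PER_S = 1e-12 / 60.0


def convert_rate_units(rate: float, field_area_um2: float = DEFAULT_FIELD_AREA_UM2, target: str = "um2/min"):
    """Convert a count-space rate (per count per minute) to area units.

    A count-space kernel entry K corresponds to K x field_area in area
    units, because concentrations in the observed field are counts per
    field area.  Targets: ``um2/min`` or ``m2/s``.
    """
    if field_area_um2 <= 0:
        raise ValueError("field_area_um2 must be positive")
    in_um2_min = rate * field_area_um2
    if target == "um2/min":
        return in_um2_min
    if target == "m2/s":
        return in_um2_min * _UM2_PER_MIN_TO_M2_PER_S
    raise ValueError(f"unknown unit token {target!r}")


def area_rate_um2min_to_m2s(rate_um2_min: float) -> float:
    """1 µm²/min = 1e-12/60 m²/s."""
    return rate_um2_min * _UM2_PER_MIN_TO_M2_PER_S


def area_rate_m2s_to_um2min(rate_m2_s: float) -> float:
    return rate_m2_s / _UM2_PER_MIN_TO_M2_PER_S
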