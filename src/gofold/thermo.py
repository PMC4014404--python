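"""Thermodynamic analysis: heat capacity, transition temperature, WHAM.

The folding transition temperature T_f is located at the maximum of the
heat capacity, computed from energy fluctuations at each replica
temperature, ``Cv(T) = (<E^2> - <E>^2) / T^2`` in k_B units.  Free-energy
surfaces over arbitrary reaction coordinates (E, Rg, RMSD, Q) combine the
multi-temperature histograms through the weighted histogram analysis
method: the dimensionless free energies f_k of the sampled temperatures are
iterated to self-consistency on the energy histograms, after which every
sample receives a weight appropriate to any target temperature and can be
binned along any coordinate recorded with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "heat_capacity",
    "find_Tf",
    "WhamInput",
    "WhamResult",
    "wham",
    "wham_free_energy",
    "basin_population",
]


def heat_capacity(
    energy_samples: Sequence[np.ndarray], temperatures: Sequence[float]
) -> np.ndarray:
    """Fluctuation heat capacity Cv(T) = var(E)/T^2 per temperature (k_B)."""
    temps = np.asarray(temperatures, float)
    if len(energy_samples) != len(temps):
        raise ValueError("one energy sample array per temperature required")
    cv = np.empty(len(temps))
    for k, (e, t) in enumerate(zip(energy_samples, temps)):
        e = np.asarray(e, float)
        if len(e) < 2:
            raise ValueError(f"need >= 2 samples at T={t} to estimate Cv")
        cv[k] = e.var() / t**2
    return cv


def find_Tf(
    temperatures: Sequence[float], cv: Sequence[float]
) -> tuple[float, bool]:
    """Transition temperature at the Cv maximum.

    Returns ``(T_f, at_edge)``; the argmax is refined by a parabola through
    the three bracketing points, and ``at_edge`` warns when the maximum sits
    on the boundary of the sampled grid (the true peak may lie outside).
    """
    t = np.asarray(temperatures, float)
    c = np.asarray(cv, float)
    if len(t) != len(c) or len(t) < 1:
        raise ValueError("temperature and Cv grids must match and be non-empty")
    k = int(np.argmax(c))
    if k == 0 or k == len(t) - 1:
        return float(t[k]), True
    x0, x1, x2 = t[k - 1], t[k], t[k + 1]
    y0, y1, y2 = c[k - 1], c[k], c[k + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate (flat or upward) parabola: keep the grid argmax
        return float(x1), False
    tf = -b / (2 * a)
    if not x0 <= tf <= x2:  # refinement left the bracket: keep grid argmax
        return float(x1), False
    return float(tf), False


@dataclass
class WhamInput:
    """Per-temperature samples: energies plus any coordinates to reweight.

    ``coordinates`` maps a coordinate name (e.g. "rmsd", "rg", "q") to a
    list of per-temperature arrays congruent with ``energies``.
    """

    temperatures: np.ndarray
    energies: list[np.ndarray]
    coordinates: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, float)
        if len(self.energies) != len(self.temperatures):
            raise ValueError("need one energy array per temperature")
        for name, arrs in self.coordinates.items():
            if len(arrs) != len(self.temperatures) or any(
                len(a) != len(e) for a, e in zip(arrs, self.energies)
            ):
                raise ValueError(
                    f"coordinate {name!r} not congruent with energies"
                )

    def pooled(self, name: str | None = None) -> np.ndarray:
        arrs = self.energies if name is None else self.coordinates[name]
        return np.concatenate([np.asarray(a, float) for a in arrs])


@dataclass
class WhamResult:
    """Self-consistent WHAM solution over a temperature ladder."""

    input: WhamInput
    f_k: np.ndarray  # dimensionless free energy per sampled temperature
    n_iter: int
    residual: float

    def log_weights(self, target_T: float) -> np.ndarray:
        """Log sample weights at *target_T* (unnormalized), pooled order."""
        E = self.input.pooled()
        temps = self.input.temperatures
        n_k = np.array([len(e) for e in self.input.energies], float)
        # denominator: sum_k N_k exp(f_k - E/T_k)
        log_den = logsumexp(
            np.log(n_k)[None, :] + self.f_k[None, :] - E[:, None] / temps[None, :],
            axis=1,
        )
        return -E / target_T - log_den

    def weights(self, target_T: float) -> np.ndarray:
        lw = self.log_weights(target_T)
        w = np.exp(lw - logsumexp(lw))
        return w

    def free_energy(
        self,
        target_T: float,
        coords: Sequence[str],
        bins: int | Sequence[int] = 40,
    ) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
        """F over a 1-D or 2-D coordinate grid at *target_T*, in k_B*T.

        Coordinates are named columns of the input ("E" selects the energy
        itself).  Returns ``(bin_edges, F, probability)``; F is shifted so
        its minimum is zero, with +inf in empty bins.
        """
        coords = list(coords)
        if not 1 <= len(coords) <= 2:
            raise ValueError("free_energy supports 1 or 2 coordinates")
        cols = [
            self.input.pooled(None if c == "E" else c) for c in coords
        ]
        if isinstance(bins, int):
            bins = [bins] * len(coords)
        w = self.weights(target_T)
        hist, edges = np.histogramdd(
            np.column_stack(cols), bins=bins, weights=w
        )
        p = hist / hist.sum()
        with np.errstate(divide="ignore"):
            F = -np.log(p)
        F -= F.min()
        return list(edges), F, p


def wham(
    input: WhamInput,
    n_bins: int = 40,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> WhamResult:
    """Iterate the WHAM equations on binned energy histograms.

    Convergence requires overlapping energy histograms between neighbouring
    temperatures; a diagnostic overlap matrix is included in the error when
    the iteration fails to converge.
    """
    temps = input.temperatures
    K = len(temps)
    E_all = input.pooled()
    edges = np.linspace(E_all.min(), E_all.max() + 1e-12, n_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    H = np.zeros(n_bins)
    h_k = np.zeros((K, n_bins))
    for k, e in enumerate(input.energies):
        h_k[k], _ = np.histogram(e, bins=edges)
    H = h_k.sum(axis=0)
    n_k = np.array([len(e) for e in input.energies], float)
    occupied = H > 0
    f = np.zeros(K)
    log_nk = np.log(n_k)
    logH = np.where(occupied, np.log(np.maximum(H, 1)), -np.inf)
    beta_E = mid[None, :] / temps[:, None]  # (K, B)
    residual = np.inf
    for it in range(1, max_iter + 1):
        # log Omega_b = log H_b - logsumexp_k [log N_k + f_k - E_b/T_k]
        log_omega = logH - logsumexp(
            log_nk[:, None] + f[:, None] - beta_E, axis=0
        )
        f_new = -logsumexp(log_omega[None, :] - beta_E, axis=1)
        f_new -= f_new[0]
        residual = float(np.abs(f_new - f).max())
        f = f_new
        if residual < tol:
            return WhamResult(input, f, it, residual)
    overlap = _overlap_matrix(h_k)
    raise RuntimeError(
        f"WHAM failed to converge ({max_iter} iterations, residual "
        f"{residual:.2e}); histogram overlap matrix:\n{overlap}"
    )


def _overlap_matrix(h_k: np.ndarray) -> np.ndarray:
    """Fraction of shared occupied energy bins between temperature pairs."""
    occ = h_k > 0
    K = len(occ)
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            union = (occ[a] | occ[b]).sum()
            out[a, b] = (occ[a] & occ[b]).sum() / union if union else 0.0
    return out


def wham_free_energy(
    input: WhamInput,
    target_T: float,
    coords: Sequence[str],
    bins: int | Sequence[int] = 40,
    n_energy_bins: int = 40,
):
    """Convenience wrapper: solve WHAM, then bin F over *coords*."""
    return wham(input, n_bins=n_energy_bins).free_energy(
        target_T, coords, bins
    )


def basin_population(
    weights: np.ndarray,
    coordinates: Mapping[str, np.ndarray],
    basins: Mapping[str, Mapping[str, tuple[float, float]]],
) -> dict[str, float]:
    """Weighted population fraction of rectangular basins.

    Each basin is a mapping ``coordinate -> (lo, hi)``; a sample belongs to
    a basin when every listed coordinate lies in its closed interval.
    Basins must be disjoint over the sampled points.
    """
    w = np.asarray(weights, float)
    masks = {}
    for name, box in basins.items():
        m = np.ones(len(w), dtype=bool)
        for cname, (lo, hi) in box.items():
            x = np.asarray(coordinates[cname], float)
            if len(x) != len(w):
                raise ValueError(f"coordinate {cname!r} length mismatch")
            m &= (x >= lo) & (x <= hi)
        masks[name] = m
    names = list(masks)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if (masks[names[a]] & masks[names[b]]).any():
                raise ValueError(
                    f"basins {names[a]!r} and {names[b]!r} overlap"
                )
    total = w.sum()
    return {name: float(w[m].sum() / total) for name, m in masks.items()}
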