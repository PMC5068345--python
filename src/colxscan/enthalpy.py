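"""Energy time-series analysis: equilibration, ΔH of formation, block SEM.

The enthalpy of cross-link formation is estimated as the difference between
the mean total energy of the singly cross-linked system and that of the
mass-balanced reference system (native molecule plus an unbound open-chain
glucose minus three waters), averaged over the post-equilibration analysis
window. MD total energies are strongly autocorrelated, so the standard error
is estimated by block averaging: the window is cut into contiguous blocks
whose means are treated as independent samples. A per-frame (naive) SEM is
available for comparison but understates the error under autocorrelation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EnergyTrace",
    "AnalysisWindow",
    "EnthalpyEstimate",
    "load_energy_table",
    "save_energy_table",
    "equilibration_window",
    "delta_enthalpy",
    "classify_sites",
    "mean_pair_distance",
]

PS_PER_NS = 1000.0


@dataclass
class EnergyTrace:
    """A (time, total energy) series from one simulation.

    Times are ps, energies kcal/mol.
    """

    times: np.ndarray
    energies: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.energies.shape:
            raise ValueError("times and energies must be 1-D and the same length")
        if len(self.times) == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.energies)):
            raise ValueError("energies contain NaN/inf")

    @property
    def span_ns(self) -> float:
        return (self.times[-1] - self.times[0]) / PS_PER_NS

    def window_values(self, w: "AnalysisWindow") -> np.ndarray:
        lo, hi = w.start * PS_PER_NS, w.end * PS_PER_NS
        if self.times[0] > lo + 1e-9 or self.times[-1] < hi - 1e-9:
            raise ValueError(
                f"trace {self.label!r} ({self.times[0]}..{self.times[-1]} ps) "
                f"does not cover window [{w.start}, {w.end}] ns"
            )
        mask = (self.times >= lo) & (self.times <= hi)
        return self.energies[mask]


@dataclass
class AnalysisWindow:
    """Analysis interval in ns."""

    start: float
    end: float
    policy: str = "fixed_last"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")


@dataclass
class EnthalpyEstimate:
    delta_h: float  # kcal/mol
    sem: float  # kcal/mol
    n_blocks: int

    @property
    def favourable(self) -> bool:
        """Strictly exothermic formation (ΔH < 0)."""
        return self.delta_h < 0


def load_energy_table(path) -> EnergyTrace:
    """Load a 2-column TSV (time, total energy) with one header line.

    Times are taken as ps unless the first column header mentions ``ns``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, got {df.shape[1]}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty data section")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if "ns" in df.columns[0].lower().split("_"):
        times = times * PS_PER_NS
    energies = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(pd.isna(df.iloc[:, 1])):
        raise ValueError(f"{path}: NaN energies")
    return EnergyTrace(times, energies, label=path.stem)


def save_energy_table(trace: EnergyTrace, path) -> None:
    pd.DataFrame(
        {"time_ps": trace.times, "total_energy_kcal_mol": trace.energies}
    ).to_csv(path, sep="\t", index=False)


def equilibration_window(
    trace: EnergyTrace,
    policy: str = "fixed_last",
    last_ns: float = 25.0,
    tolerance: float | None = None,
    min_tail_ns: float = 10.0,
) -> AnalysisWindow:
    """Choose the analysis window of a production trace.

    ``fixed_last`` keeps the final ``last_ns`` of the trace (the default of
    25 ns reflects convergence of density and potential energy at 35 ns of a
    60 ns run). ``auto`` is a heuristic: scanning from the start, it returns
    the earliest time from which the reverse cumulative mean stays within
    ``tolerance`` of the mean of the final ``min_tail_ns`` (default tolerance
    0.1 x the SD of the last half of the trace). The heuristic is a
    convenience for synthetic traces, not a convergence proof.
    """
    end = trace.times[-1] / PS_PER_NS
    if policy == "fixed_last":
        start = end - last_ns
        if start < trace.times[0] / PS_PER_NS - 1e-9:
            raise ValueError(
                f"trace spans {trace.span_ns:.3f} ns, shorter than the "
                f"fixed_last window of {last_ns} ns"
            )
        return AnalysisWindow(max(start, 0.0), end, "fixed_last")
    if policy != "auto":
        raise ValueError(f"unknown policy {policy!r}")

    t, e = trace.times, trace.energies
    n = len(e)
    if tolerance is None:
        tolerance = 0.1 * float(np.std(e[n // 2 :]))
    # reverse cumulative means m_k = mean(e[k:])
    rev_mean = np.cumsum(e[::-1])[::-1] / np.arange(n, 0, -1)
    tail_start = np.searchsorted(t, t[-1] - min_tail_ns * PS_PER_NS)
    if tail_start >= n:
        raise ValueError("trace shorter than min_tail_ns")
    ref = rev_mean[tail_start]
    within = np.abs(rev_mean[: tail_start + 1] - ref) < tolerance
    # earliest k such that every later candidate also satisfies the band
    ok_from = np.logical_and.accumulate(within[::-1])[::-1]
    k = int(np.argmax(ok_from)) if ok_from.any() else tail_start
    return AnalysisWindow(t[k] / PS_PER_NS, end, "auto")


def _blocked_sem(values: np.ndarray, n_blocks: int) -> float:
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(values) < n_blocks:
        raise ValueError("fewer samples than blocks")
    usable = len(values) - len(values) % n_blocks
    means = values[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_blocks))


def delta_enthalpy(
    xlink: EnergyTrace,
    ref: EnergyTrace,
    w: AnalysisWindow,
    n_blocks: int = 5,
    sem_method: str = "blocked",
) -> EnthalpyEstimate:
    """ΔH = mean(xlink) - mean(ref) over the window, with its SEM.

    ``blocked`` (default) block-averages the difference series when the two
    traces share the same sampling grid, otherwise blocks each trace and
    combines the SEMs in quadrature. ``per_frame`` uses the naive SEM of
    independent frames.
    """
    x = xlink.window_values(w)
    r = ref.window_values(w)
    dh = float(x.mean() - r.mean())
    if sem_method == "per_frame":
        sem = math.sqrt(x.var(ddof=1) / len(x) + r.var(ddof=1) / len(r))
    elif sem_method == "blocked":
        if len(x) == len(r):
            sem = _blocked_sem(x - r, n_blocks)
        else:
            sem = math.hypot(_blocked_sem(x, n_blocks), _blocked_sem(r, n_blocks))
    else:
        raise ValueError(f"unknown sem_method {sem_method!r}")
    return EnthalpyEstimate(delta_h=dh, sem=sem, n_blocks=n_blocks)


def classify_sites(table) -> list[str]:
    """Return the IDs of energetically favourable sites (ΔH < 0).

    ``table`` is a mapping or pandas Series of site ID -> ΔH (kcal/mol);
    entries with missing ΔH (None/NaN) are ignored. Order is preserved.
    """
    items = table.items() if hasattr(table, "items") else table
    out = []
    for site, dh in items:
        if dh is None or (isinstance(dh, float) and math.isnan(dh)):
            continue
        if dh < 0:
            out.append(site)
    return out


def mean_pair_distance(frames, a, b) -> float:
    """Mean Euclidean distance between two atoms over trajectory frames.

    ``a`` and ``b`` are ``(chain_label, helical_num, atom_name)`` selectors
    into each :class:`~colxscan.structure_io.Structure` frame.
    """
    if not frames:
        raise ValueError("no frames")
    dists = []
    for i, s in enumerate(frames):
        try:
            pa = s.find_residue(a[0], a[1]).atom(a[2]).position
            pb = s.find_residue(b[0], b[1]).atom(b[2]).position
        except KeyError as exc:
            raise ValueError(f"frame {i}: {exc.args[0]}") from None
        dists.append(float(np.linalg.norm(pa - pb)))
    return float(np.mean(dists))
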