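"""Synthetic collagen structures and MD-like energy traces.

The generator stands in for the atomistic model and its MD engine in tests:

* :func:`build_triple_helix` winds three Gly-X-Y chains as an idealized
  left-handed helix about a straight common axis (no supercoil writhe), one
  residue of inter-chain stagger, and places backbone atoms plus the lysine
  and arginine side-chain atoms the distance criteria need, on extended
  rotamers pointing radially outward.
* :func:`plant_site` moves one side chain so a chosen criterion atom pair
  sits at an exact target distance — a controllable oracle for the scanner.
* :func:`gen_energy_trace` emulates a production-run total-energy series:
  a linear equilibration drift decaying to zero at the equilibration time,
  then stationary AR(1) noise about a configurable mean. Defaults emulate a
  60 ns run converging at 35 ns with a ~9 ps integrated autocorrelation time
  and fluctuations sized so the 25 ns-window block SEM of an energy
  difference lands near 0.7 kcal/mol.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

from .enthalpy import EnergyTrace, PS_PER_NS
from .structure_io import (
    NUMBERING_OFFSETS,
    AtomRecord,
    Residue,
    ResidueRef,
    Structure,
    chain_kind,
)

__all__ = [
    "HelixParams",
    "PlantSpec",
    "TraceParams",
    "build_triple_helix",
    "plant_site",
    "gen_energy_trace",
]

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "O": "HYP", "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR",
    "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: Side-chain heavy atoms placed on extended rotamers, as (name, element,
#: radial step Å, tangential offset Å). Only the criterion-relevant residues
#: get side chains beyond Cβ.
_SIDECHAINS = {
    "LYS": [
        ("CB", "C", 1.53, 0.0),
        ("CG", "C", 1.27, 0.45),
        ("CD", "C", 1.27, -0.45),
        ("CE", "C", 1.27, 0.45),
        ("NZ", "N", 1.30, -0.45),
    ],
    "ARG": [
        ("CB", "C", 1.53, 0.0),
        ("CG", "C", 1.27, 0.45),
        ("CD", "C", 1.27, -0.45),
        ("NE", "N", 1.30, 0.45),
        ("CZ", "C", 1.33, -0.45),
        ("NH1", "N", 1.08, 0.72),
        ("NH2", "N", 1.08, -0.72),
    ],
}

_CRITERION_PAIRS = {
    "NZ-NH": ("NZ", "NH1"),
    "CE-NE": ("CE", "NE"),
    "CD-CD": ("CD", "CD"),
}


@dataclass
class HelixParams:
    """Idealized triple-helix geometry.

    Defaults: 2.86 Å axial rise per residue, 3.33 residues per (left-handed)
    turn per chain, 2.8 Å chain-axis radius, one residue of stagger between
    consecutive chains.
    """

    rise_per_residue: float = 2.86
    residues_per_turn: float = 3.33
    helix_radius: float = 2.8
    stagger: float = 1.0

    def __post_init__(self):
        for name in ("rise_per_residue", "residues_per_turn", "helix_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class PlantSpec:
    """Where to plant a cross-chain Lys/Arg pair and which distance to fix."""

    lys_chain: str
    lys_helical: int
    arg_chain: str
    arg_helical: int
    target_pair: str = "NZ-NH"
    target_distance: float = 4.8

    def __post_init__(self):
        if self.lys_chain == self.arg_chain:
            raise ValueError("planted pairs must span two different chains")
        if self.target_distance <= 0:
            raise ValueError("target_distance must be positive")
        if self.target_pair not in _CRITERION_PAIRS:
            raise ValueError(f"unknown criterion pair {self.target_pair!r}")


@dataclass
class TraceParams:
    """Parameters of a synthetic total-energy trace.

    ``noise_sd`` is the AR(1) innovation SD; the stationary SD is
    ``noise_sd / sqrt(1 - ar1_phi**2)``. ``drift_amplitude`` is the initial
    offset of the linear equilibration drift, which reaches zero at
    ``equil_time`` and stays zero after.
    """

    total_time: float = 60.0  # ns
    dt: float = 1.0  # ps per sample
    equil_time: float = 35.0  # ns
    mean_energy: float = -120_000.0  # kcal/mol
    drift_amplitude: float = 400.0  # kcal/mol
    ar1_phi: float = 0.8
    noise_sd: float = 16.0  # kcal/mol
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.equil_time < self.total_time:
            raise ValueError("require 0 <= equil_time < total_time")
        if not abs(self.ar1_phi) < 1:
            raise ValueError("|ar1_phi| must be < 1")
        if self.dt <= 0 or self.noise_sd < 0:
            raise ValueError("dt must be positive and noise_sd non-negative")


def _local_frame(theta: float):
    e_r = np.array([np.cos(theta), np.sin(theta), 0.0])
    e_t = np.array([-np.sin(theta), np.cos(theta), 0.0])
    e_z = np.array([0.0, 0.0, 1.0])
    return e_r, e_t, e_z


def _build_residue(label: str, helical: int, resname: str, theta: float, z: float,
                   radius: float) -> Residue:
    e_r, e_t, e_z = _local_frame(theta)
    ca = radius * e_r + z * e_z
    atoms = [
        AtomRecord("N", "N", ca - 1.2 * e_t - 0.45 * e_z),
        AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", ca + 1.2 * e_t + 0.45 * e_z),
        AtomRecord("O", "O", ca + 1.2 * e_t + 1.65 * e_z),
    ]
    r = radius
    for name, elem, step, tang in _SIDECHAINS.get(resname, []):
        r += step
        atoms.append(AtomRecord(name, elem, r * e_r + tang * e_t + z * e_z))
    uniprot = NUMBERING_OFFSETS[chain_kind(label)] + helical
    return Residue(ResidueRef(label, resname, uniprot, helical), atoms)


def build_triple_helix(sequences, params: HelixParams | None = None) -> Structure:
    """Wind three Gly-X-Y chains (one-letter codes, O = Hyp) about one axis.

    Chain i is rotated by 120° and shifted axially by ``i * stagger * rise``.
    A warning (not an error) is raised if glycine is not at every third
    position. Construction is fully deterministic.
    """
    params = params or HelixParams()
    if len(sequences) != 3:
        raise ValueError(f"need exactly 3 chain sequences, got {len(sequences)}")
    for seq in sequences:
        if len(seq) < 3:
            raise ValueError("each chain sequence must have length >= 3")
        if any(c != "G" for c in seq[::3]):
            warnings.warn("sequence does not have Gly at every third position")

    s = Structure()
    dtheta = -2 * np.pi / params.residues_per_turn
    for i, (label, seq) in enumerate(zip(("α1a", "α1b", "α2"), sequences)):
        chain = []
        for j, one in enumerate(seq.upper()):
            try:
                resname = _THREE[one]
            except KeyError:
                raise ValueError(f"unknown residue code {one!r}") from None
            theta = j * dtheta + i * 2 * np.pi / 3
            z = (j + i * params.stagger) * params.rise_per_residue
            chain.append(
                _build_residue(label, j + 1, resname, theta, z, params.helix_radius)
            )
        s.chains[label] = chain
    return s


def _ensure_sidechain(s: Structure, chain: str, helical: int, resname: str) -> Residue:
    """Mutate the residue to ``resname``, rebuilding its side chain in place."""
    res = s.find_residue(chain, helical)
    if res.ref.residue_name != resname:
        ca = res.atom("CA").position
        # radial direction recovered from the Cα position (axis = z)
        e_r = np.array([ca[0], ca[1], 0.0])
        radius = np.linalg.norm(e_r)
        e_r = e_r / radius
        e_t = np.array([-e_r[1], e_r[0], 0.0])
        res.ref.residue_name = resname
        res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
        r = radius
        for name, elem, step, tang in _SIDECHAINS[resname]:
            r += step
            res.atoms.append(
                AtomRecord(name, elem, r * e_r + tang * e_t + ca[2] * np.array([0, 0, 1.0]))
            )
    return res


def _rotate_about_axis(points, origin, axis, angle):
    axis = axis / np.linalg.norm(axis)
    k = axis
    p = points - origin
    cos, sin = np.cos(angle), np.sin(angle)
    rot = p * cos + np.cross(k, p) * sin + np.outer(p @ k, k) * (1 - cos)
    return rot + origin


def plant_site(s: Structure, spec: PlantSpec) -> Structure:
    """Place a cross-chain Lys/Arg pair at an exact criterion distance.

    The two residues are mutated to LYS/ARG if needed. The lysine side chain
    is first rigid-rotated about the Cα–Cβ axis towards the target; if the
    target distance is unreachable by rotation, the side-chain atoms beyond
    Cβ are rigidly translated along the inter-atom line until the criterion
    distance matches to well within 0.01 Å. All other residues are untouched.
    """
    lys = _ensure_sidechain(s, spec.lys_chain, spec.lys_helical, "LYS")
    arg = _ensure_sidechain(s, spec.arg_chain, spec.arg_helical, "ARG")
    lys_name, arg_name = _CRITERION_PAIRS[spec.target_pair]

    movable = [a for a in lys.atoms if a.name not in ("N", "CA", "C", "O", "CB")]
    ca = lys.atom("CA").position
    cb = lys.atom("CB").position
    target_atom = lys.atom(lys_name)
    partner = arg.atom(arg_name).position

    def crit_dist() -> float:
        d = np.linalg.norm(target_atom.position - partner)
        if spec.target_pair == "NZ-NH":
            d = min(d, np.linalg.norm(target_atom.position - arg.atom("NH2").position))
        return float(d)

    def dist_at(angle: float) -> float:
        pts = np.array([a.position for a in movable])
        rot = _rotate_about_axis(pts, cb, cb - ca, angle)
        return float(np.linalg.norm(rot[movable.index(target_atom)] - partner))

    # rotation pass: find an angle bracketing the target, if one exists
    angles = np.linspace(0, 2 * np.pi, 73)
    vals = np.array([dist_at(a) for a in angles]) - spec.target_distance
    best = None
    for i in range(len(angles) - 1):
        if vals[i] == 0 or vals[i] * vals[i + 1] < 0:
            best = brentq(
                lambda a: dist_at(a) - spec.target_distance, angles[i], angles[i + 1]
            )
            break
    if best is not None:
        pts = np.array([a.position for a in movable])
        rot = _rotate_about_axis(pts, cb, cb - ca, best)
        for a, p in zip(movable, rot):
            a.position = p
    # translation pass: exact placement of the criterion pair (also fixes the
    # min(NH1, NH2) semantics of the Nζ–Nη criterion after rotation)
    for _ in range(50):
        d = crit_dist()
        if abs(d - spec.target_distance) < 1e-6:
            break
        near = partner
        if spec.target_pair == "NZ-NH":
            d1 = np.linalg.norm(target_atom.position - partner)
            d2 = np.linalg.norm(target_atom.position - arg.atom("NH2").position)
            near = partner if d1 <= d2 else arg.atom("NH2").position
        u = target_atom.position - near
        u = u / np.linalg.norm(u)
        shift = (spec.target_distance - np.linalg.norm(target_atom.position - near)) * u
        for a in movable:
            a.position = a.position + shift
    return s


def gen_energy_trace(p: TraceParams | None = None, label: str = "") -> EnergyTrace:
    """Generate a synthetic total-energy trace (see module docstring)."""
    p = p or TraceParams()
    rng = np.random.default_rng(p.seed)
    times = np.arange(p.dt, p.total_time * PS_PER_NS + p.dt / 2, p.dt)
    n = len(times)
    stat_sd = p.noise_sd / np.sqrt(1 - p.ar1_phi**2) if p.noise_sd > 0 else 0.0
    if p.noise_sd > 0:
        eps = rng.normal(0.0, p.noise_sd, n)
        x0 = rng.normal(0.0, stat_sd)
        noise = lfilter([1.0], [1.0, -p.ar1_phi], eps, zi=[p.ar1_phi * x0])[0]
    else:
        noise = np.zeros(n)
    t_ns = times / PS_PER_NS
    if p.equil_time > 0:
        drift = p.drift_amplitude * np.clip(1.0 - t_ns / p.equil_time, 0.0, None)
    else:
        drift = np.zeros(n)
    return EnergyTrace(times, p.mean_energy + drift + noise, label=label)
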