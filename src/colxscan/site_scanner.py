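"""Distance-criterion search for cross-chain lysine–arginine AGE sites.

A Lys/Arg pair on *different* chains of the triple helix is a candidate
cross-linking site if at least one of three atom-pair distances falls within
the cut-off (default 5 Å, double the shortest N–N separation inside the
DOGDIC imidazolium):

1. lysine Nζ to the nearer of arginine Nη1/Nη2,
2. lysine Cε to arginine Nε,
3. lysine Cδ to arginine Cδ.

Hydroxylysine is not a donor; only LYS and ARG residues are scanned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Residue, ResidueRef, Structure

__all__ = ["ScanConfig", "CandidateSite", "pair_distances", "scan", "ion_proximity"]

#: (label, lysine atom, arginine atoms) for the three criteria, in order.
CRITERIA = (
    ("NZ-NH", "NZ", ("NH1", "NH2")),
    ("CE-NE", "CE", ("NE",)),
    ("CD-CD", "CD", ("CD",)),
)

_LYS_ATOMS = ("NZ", "CE", "CD")
_ARG_ATOMS = ("NH1", "NH2", "NE", "CD")


@dataclass
class ScanConfig:
    cutoff: float = 5.0  # Å, criterion cut-off
    elec_cutoff: float = 8.0  # Å, electrostatic cut-off for ion proximity
    use_min_image: bool = False

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class CandidateSite:
    """A cross-chain Lys–Arg pair with its three criterion distances (Å)."""

    lys: ResidueRef
    arg: ResidueRef
    distances: tuple[float, float, float]
    met: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.lys.chain_label == self.arg.chain_label:
            raise ValueError("candidate sites must span two different chains")

    @property
    def min_distance(self) -> float:
        return min(self.distances)

    @property
    def position(self) -> int:
        """Representative helical position: the smaller of the pair."""
        pair = [
            p for p in (self.lys.helical_num, self.arg.helical_num) if p is not None
        ]
        if not pair:
            raise ValueError("site residues carry no helical numbering")
        return min(pair)


def _dist(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    d = a - b
    if box is not None:
        d = d - box * np.round(d / box)
    return float(np.linalg.norm(d))


def pair_distances(
    lys: Residue, arg: Residue, box: np.ndarray | None = None
) -> tuple[float, float, float]:
    """The three criterion distances for one Lys/Arg pair.

    The Nζ–Nη criterion takes the minimum over NH1/NH2 (the permissive
    reading of the unbranched η designation). ``box`` enables minimum-image
    distances.
    """
    out = []
    for _label, lys_name, arg_names in CRITERIA:
        la = lys.atom(lys_name).position
        out.append(min(_dist(la, arg.atom(n).position, box) for n in arg_names))
    return tuple(out)


def scan(s: Structure, cfg: ScanConfig | None = None) -> list[CandidateSite]:
    """All cross-chain Lys–Arg pairs meeting at least one criterion.

    Sites are reported once each, ordered by ascending representative helical
    position (then by chain-pair label for determinism). Residues missing any
    criterion atom raise; structures with no Lys or no Arg yield an empty
    list.
    """
    cfg = cfg or ScanConfig()
    box = s.box if (cfg.use_min_image and s.box is not None) else None
    chains = s.collagen_chains()

    lys_res = [
        r for chain in chains.values() for r in chain if r.ref.residue_name == "LYS"
    ]
    arg_res = [
        r for chain in chains.values() for r in chain if r.ref.residue_name == "ARG"
    ]
    if not lys_res or not arg_res:
        return []

    # vectorised pre-filter on all criterion-atom pairs, then exact distances
    lys_xyz = np.array([[r.atom(n).position for n in _LYS_ATOMS] for r in lys_res])
    arg_xyz = np.array([[r.atom(n).position for n in _ARG_ATOMS] for r in arg_res])
    diff = lys_xyz[:, None, :, None, :] - arg_xyz[None, :, None, :, :]
    if box is not None:
        diff = diff - box * np.round(diff / box)
    dmin = np.sqrt((diff**2).sum(-1)).reshape(len(lys_res), len(arg_res), -1).min(-1)

    sites = []
    for i, lys in enumerate(lys_res):
        for j, arg in enumerate(arg_res):
            if lys.ref.chain_label == arg.ref.chain_label:
                continue
            if dmin[i, j] > cfg.cutoff:
                continue
            dists = pair_distances(lys, arg, box)
            met = tuple(
                lab for (lab, *_), d in zip(CRITERIA, dists) if d <= cfg.cutoff
            )
            if met:
                sites.append(CandidateSite(lys.ref, arg.ref, dists, met))
    sites.sort(key=lambda c: (c.position, c.lys.chain_label, c.arg.chain_label))
    return sites


def ion_proximity(
    s: Structure,
    site: CandidateSite,
    ion_name: str = "CL",
    cfg: ScanConfig | None = None,
) -> tuple[float, bool]:
    """Minimum distance from any ion to any atom of the site's residues.

    Returns ``(min_distance, outside_cutoff)`` where ``outside_cutoff`` is
    True when the nearest ion lies beyond the electrostatic cut-off (no ions
    at all gives ``(inf, True)``).
    """
    cfg = cfg or ScanConfig()
    box = s.box if (cfg.use_min_image and s.box is not None) else None
    ions = [
        a.position
        for res, a in s.atoms()
        if a.name.upper() == ion_name.upper()
        and res.ref.chain_label not in ("α1a", "α1b", "α2")
    ]
    site_atoms = []
    for ref in (site.lys, site.arg):
        res = next(
            r
            for r in s.chains[ref.chain_label]
            if r.ref.uniprot_num == ref.uniprot_num
        )
        site_atoms.extend(a.position for a in res.atoms)
    if not ions:
        return math.inf, True
    dmin = min(_dist(i, a, box) for i in ions for a in site_atoms)
    return dmin, dmin > cfg.elec_cutoff
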