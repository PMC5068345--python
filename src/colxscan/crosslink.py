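"""AGE cross-link templates, geometric feasibility, and system bookkeeping.

Both lysine–arginine AGEs handled here form from d-glucose via the Schiff
base and carry an imidazolium core whose two bridging N–N separations are
the geometric fingerprint: 2.5/3.5 Å for DOGDIC, 2.6/3.8 Å for glucosepane.
DOGDIC carries three hydroxyls on its aliphatic chain, glucosepane two.

The cross-link is represented at bookkeeping/geometry level only: inserting
one replaces the Lys/Arg side chains beyond Cβ with idealized template
atoms, and the ledger keeps the cross-linked system mass-balanced against
the reference system (native molecule + one open-chain glucose − three
waters). No force-field terms are attached.
"""

from __future__ import annotations

import copy
import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .site_scanner import CandidateSite
from .structure_io import AtomRecord, Structure

__all__ = [
    "CrosslinkTemplate",
    "SystemLedger",
    "build_template",
    "feasible",
    "apply_crosslink",
    "GLUCOSE_FORMULA",
    "WATER_FORMULA",
    "TEMPLATE_FORMULA",
    "SIDECHAIN_REMOVED_FORMULA",
]

#: Molecular formulas used in the mass balance. The protein-side hydrogen
#: adjustment on conjugation is a fixed constant per kind: the side chains
#: beyond Cβ (C6H18N4 combined at pH 7) are replaced by the template
#: (C12H24N4O3 = side-chain heavy atoms + glucose − 3 waters), i.e. a net
#: +6 H on the protein, balanced exactly by the condensation stoichiometry.
GLUCOSE_FORMULA = Counter({"C": 6, "H": 12, "O": 6})
WATER_FORMULA = Counter({"H": 2, "O": 1})
TEMPLATE_FORMULA = Counter({"C": 12, "H": 24, "N": 4, "O": 3})
SIDECHAIN_REMOVED_FORMULA = Counter({"C": 6, "H": 18, "N": 4})

_KINDS = {
    # kind: (nn_short, nn_long, n_hydroxyls, residue name in emitted PDB)
    "DOGDIC": (2.5, 3.5, 3, "DOG"),
    "glucosepane": (2.6, 3.8, 2, "GCP"),
}

#: Atoms stripped from the conjugated residues (everything beyond Cβ).
_REMOVED = {
    "LYS": ("CG", "CD", "CE", "NZ"),
    "ARG": ("CG", "CD", "NE", "CZ", "NH1", "NH2"),
}


@dataclass
class CrosslinkTemplate:
    kind: str
    nn_short: float
    nn_long: float
    n_hydroxyls: int
    atoms: list[AtomRecord]
    released_waters: int = 3
    formula: Counter = field(default_factory=lambda: Counter(TEMPLATE_FORMULA))

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def nn_distances(self) -> tuple[float, float]:
        n1 = self.atom("N1").position
        return (
            float(np.linalg.norm(self.atom("N2").position - n1)),
            float(np.linalg.norm(self.atom("N3").position - n1)),
        )


def build_template(kind: str) -> CrosslinkTemplate:
    """Idealized 3-D template for one cross-link kind.

    N1 is the lysine-derived nitrogen; N2/N3 the two arginine-derived
    bridging nitrogens, placed so the N1–N2 / N1–N3 separations realize the
    kind's fingerprint distances exactly. The aliphatic chain and hydroxyls
    extend away from the core; coordinates are deterministic.
    """
    try:
        nn_short, nn_long, n_oh, _ = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown cross-link kind {kind!r}") from None

    ring_nn = 2.25  # Å, separation of the two arginine N within the core
    x3 = (nn_long**2 + nn_short**2 - ring_nn**2) / (2 * nn_short)
    y3 = float(np.sqrt(nn_long**2 - x3**2))

    atoms = [
        AtomRecord("N1", "N", (0.0, 0.0, 0.0)),
        AtomRecord("N2", "N", (nn_short, 0.0, 0.0)),
        AtomRecord("N3", "N", (x3, y3, 0.0)),
        # amidine carbon between the bridging nitrogens, lifted off-plane
        AtomRecord("C1", "C", ((nn_short + x3) / 2, y3 / 2, 0.45)),
        # ring carbons closing the lysine-side ring
        AtomRecord("C2", "C", (-0.7, 1.2, 0.0)),
        AtomRecord("C3", "C", (0.5, 2.0, 0.0)),
        # arginine Nε-derived nitrogen
        AtomRecord("N4", "N", (x3 + 1.1, y3 + 0.9, 0.0)),
        # aliphatic linker back to the lysine chain
        AtomRecord("C4", "C", (-1.4, -0.6, 0.0)),
        AtomRecord("C5", "C", (-2.6, 0.2, 0.4)),
        AtomRecord("C6", "C", (-3.9, -0.5, 0.1)),
    ]
    # hydroxylated chain: one carbon per hydroxyl, then plain carbons so the
    # heavy-atom count is identical for both kinds
    for i in range(3):
        atoms.append(AtomRecord(f"C{7 + i}", "C", (-5.1 - 1.3 * i, 0.2, 0.5 * (i % 2))))
    for i in range(n_oh):
        atoms.append(AtomRecord(f"O{i + 1}", "O", (-5.1 - 1.3 * i, 1.2, 1.2)))
    for i in range(3 - n_oh):
        # non-hydroxyl oxygen (ring/carbonyl) keeps the formula fixed
        atoms.append(AtomRecord(f"O{n_oh + 1 + i}", "O", (1.9 + 1.1 * i, 2.9, 0.6)))
    atoms.append(AtomRecord("C10", "C", (-6.3 - 1.3, -0.8, 0.2)))
    atoms.append(AtomRecord("C11", "C", (-6.3 - 2.6, 0.0, 0.6)))
    atoms.append(AtomRecord("C12", "C", (-6.3 - 3.9, -0.6, 0.3)))

    counts = Counter(a.element for a in atoms)
    heavy_expect = Counter({k: v for k, v in TEMPLATE_FORMULA.items() if k != "H"})
    assert counts == heavy_expect, f"template heavy atoms {counts} != {heavy_expect}"
    return CrosslinkTemplate(kind, nn_short, nn_long, n_oh, atoms)


def feasible(
    site: CandidateSite, t: CrosslinkTemplate, max_span: float | None = None
) -> bool:
    """Geometric pre-filter: the residues must be close enough to bridge.

    The default ``max_span`` is twice the template's shortest N–N separation
    (the doubling rule behind the 5 Å scan cut-off).
    """
    if max_span is None:
        max_span = 2 * t.nn_short
    return site.min_distance <= max_span


def _lincomb(*terms: tuple[int, Counter]) -> Counter:
    """Integer linear combination of element counters, without the clamping
    Counter arithmetic applies to non-positive intermediate counts."""
    out: dict[str, int] = {}
    for coef, counter in terms:
        for elem, n in counter.items():
            out[elem] = out.get(elem, 0) + coef * n
    if any(v < 0 for v in out.values()):
        raise ValueError(f"negative element count in ledger: {out}")
    return Counter({k: v for k, v in out.items() if v})


@dataclass
class SystemLedger:
    """Element bookkeeping for the cross-linked and reference systems.

    Each system resolves to species -> total element Counter. The invariant
    is exact element balance between the two systems: every cross-link adds
    a glucose-minus-three-waters moiety to the protein, and the reference
    system holds the glucose and gives up the three waters instead.
    """

    protein_base: Counter  # native protein element counts (heavy atoms)
    n_waters: int
    kinds: tuple[str, ...] = ()

    @property
    def n_links(self) -> int:
        return len(self.kinds)

    @property
    def crosslinked(self) -> dict[str, Counter]:
        k = self.n_links
        protein = _lincomb(
            (1, self.protein_base),
            (-k, SIDECHAIN_REMOVED_FORMULA),
            (k, TEMPLATE_FORMULA),
        )
        return {
            "protein": protein,
            "water": Counter({k: v * self.n_waters for k, v in WATER_FORMULA.items()}),
        }

    @property
    def reference(self) -> dict[str, Counter]:
        k = self.n_links
        nw = self.n_waters - 3 * k
        return {
            "protein": Counter(self.protein_base),
            "glucose": Counter({e: v * k for e, v in GLUCOSE_FORMULA.items()}),
            "water": Counter({e: v * nw for e, v in WATER_FORMULA.items()}),
        }

    def totals(self, side: str) -> Counter:
        out: Counter = Counter()
        for c in getattr(self, side).values():
            out.update(c)
        return out

    def balanced(self) -> bool:
        return self.totals("crosslinked") == self.totals("reference")

    def compose(self, other: "SystemLedger") -> "SystemLedger":
        """Ledger of successive cross-links on the same molecule/solvent."""
        if +self.protein_base != +other.protein_base or self.n_waters != other.n_waters:
            raise ValueError("can only compose ledgers of the same system")
        return SystemLedger(
            Counter(self.protein_base), self.n_waters, self.kinds + other.kinds
        )

    def to_json(self, path=None) -> str:
        payload = {
            side: {sp: dict(+cnt) for sp, cnt in getattr(self, side).items()}
            for side in ("crosslinked", "reference")
        }
        payload["n_links"] = self.n_links
        payload["kinds"] = list(self.kinds)
        payload["balanced"] = self.balanced()
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def apply_crosslink(
    s: Structure,
    site: CandidateSite,
    t: CrosslinkTemplate,
    n_waters: int = 11_980,
) -> tuple[Structure, SystemLedger]:
    """Insert one cross-link at a feasible site; return structure + ledger.

    The Lys/Arg side chains beyond Cβ are removed; the template is rigidly
    placed with N1 at the old Nζ position, oriented towards the old Nη. The
    lysine residue is renamed DOG/GCP to mark the cross-link. The returned
    ledger is exactly element-balanced against the reference system.
    """
    if not feasible(site, t):
        raise ValueError(
            f"site {site.lys.chain_label}:{site.lys.uniprot_num} / "
            f"{site.arg.chain_label}:{site.arg.uniprot_num} is infeasible for "
            f"{t.kind} (min distance {site.min_distance:.2f} Å)"
        )
    native_heavy = Counter(a.element for _res, a in s.atoms())

    out = copy.deepcopy(s)
    lys = out.find_residue(site.lys.chain_label, site.lys.helical_num)
    arg = out.find_residue(site.arg.chain_label, site.arg.helical_num)
    nz = lys.atom("NZ").position.copy()
    nh = arg.atom("NH1").position.copy()
    lys.atoms = [a for a in lys.atoms if a.name not in _REMOVED["LYS"]]
    arg.atoms = [a for a in arg.atoms if a.name not in _REMOVED["ARG"]]
    lys.ref.residue_name = _KINDS[t.kind][3]

    # rigid placement: N1 -> old Nζ, template x-axis -> Nζ→Nη direction
    direction = nh - nz
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        rot = Rotation.identity()
    else:
        rot, _ = Rotation.align_vectors([direction / norm], [[1.0, 0.0, 0.0]])
    for a in t.atoms:
        lys.atoms.append(AtomRecord(a.name, a.element, rot.apply(a.position) + nz))

    # heavy-atom consistency of the realized structure
    new_heavy = Counter(a.element for _res, a in out.atoms())
    expect = _lincomb(
        (1, native_heavy),
        (-1, Counter({k: v for k, v in SIDECHAIN_REMOVED_FORMULA.items() if k != "H"})),
        (1, Counter({k: v for k, v in TEMPLATE_FORMULA.items() if k != "H"})),
    )
    assert +new_heavy == expect, "cross-linked structure heavy atoms off-balance"

    ledger = SystemLedger(native_heavy, n_waters, (t.kind,))
    return out, ledger
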