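"""PDB structure I/O, dual residue numbering, and system composition.

Type I collagen is a heterotrimer of two α1 chains and one α2 chain. Residues
carry two numbering frames: the full-sequence (UniProt) position and the
triple-helical position counted from the start of the helical domain. The two
frames differ by a constant per chain kind; the constants used here were
derived by exhaustive consistency over every published dual-numbered site pair
(a single offset per chain kind fits all of them).

PDB reading and writing are delegated to Bio.PDB; this module only adds the
collagen-specific bookkeeping (chain labels, numbering frames, composition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import molecular_weight

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "Residue",
    "Structure",
    "SystemComposition",
    "read_pdb",
    "write_pdb",
    "map_numbering",
    "compute_composition",
    "read_sequences",
    "CHAIN_LABELS",
    "NUMBERING_OFFSETS",
    "HELICAL_DOMAIN_LENGTH",
    "WATER_MASS",
]

#: PDB chain id -> collagen chain label (two α1 chains and one α2 chain).
CHAIN_LABELS = {"A": "α1a", "B": "α1b", "C": "α2"}
_LABEL_TO_ID = {v: k for k, v in CHAIN_LABELS.items()}

#: uniprot_num - helical_num, one constant per chain kind (brute-force derived).
NUMBERING_OFFSETS = {"α1": 167, "α2": 96}

#: Length of the triple-helical domain in residues, both chain kinds.
HELICAL_DOMAIN_LENGTH = 1014

#: Average molecular mass of water, g/mol.
WATER_MASS = 18.0153

#: Mass added by hydroxylation of Pro -> Hyp or Lys -> Hyl (one oxygen).
_HYDROXYL_MASS = 15.9994


def chain_kind(chain_label: str) -> str:
    """α1a/α1b -> α1, α2 -> α2; other labels are non-collagen."""
    if chain_label in ("α1a", "α1b"):
        return "α1"
    if chain_label == "α2":
        return "α2"
    raise ValueError(f"not a collagen chain label: {chain_label!r}")


@dataclass
class AtomRecord:
    """A single atom with its PDB v3 name, element symbol and position (Å)."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class ResidueRef:
    """Identity of a residue in both numbering frames.

    ``helical_num`` is None for residues outside the triple-helical domain
    (telopeptides, ions, solvent).
    """

    chain_label: str
    residue_name: str
    uniprot_num: int
    helical_num: int | None = None

    def __post_init__(self):
        if self.uniprot_num < 1:
            raise ValueError("uniprot_num must be >= 1")
        if self.helical_num is not None:
            off = NUMBERING_OFFSETS[chain_kind(self.chain_label)]
            if self.uniprot_num - self.helical_num != off:
                raise ValueError(
                    f"inconsistent dual numbering for {self.chain_label} "
                    f"{self.residue_name}: uniprot {self.uniprot_num}, "
                    f"helical {self.helical_num} (offset must be {off})"
                )


@dataclass
class Residue:
    ref: ResidueRef
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"atom {name} missing in {self.ref.chain_label} "
            f"{self.ref.residue_name} {self.ref.uniprot_num}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """Chains of residues; optionally an orthorhombic box (3 cell lengths, Å)."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    box: np.ndarray | None = None

    def __post_init__(self):
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    def collagen_chains(self) -> dict[str, list[Residue]]:
        return {k: v for k, v in self.chains.items() if k in _LABEL_TO_ID}

    def residues(self):
        for label, chain in self.chains.items():
            yield from chain

    def atoms(self):
        for res in self.residues():
            for a in res.atoms:
                yield res, a

    def find_residue(self, chain_label: str, helical_num: int) -> Residue:
        for res in self.chains[chain_label]:
            if res.ref.helical_num == helical_num:
                return res
        raise KeyError(f"no residue at helical position {helical_num} in {chain_label}")


@dataclass
class SystemComposition:
    """Mass/charge/solvation bookkeeping for a simulated system."""

    protein_mass: float  # g/mol
    net_charge: int  # elementary charges
    n_waters: int
    n_chloride: int

    @property
    def water_ratio(self) -> float:
        """g water per g protein."""
        return self.n_waters * WATER_MASS / self.protein_mass


def map_numbering(kind: str, n: int, direction: str) -> int:
    """Convert a residue number between UniProt and triple-helical frames.

    ``kind`` is ``"α1"`` or ``"α2"``; ``direction`` is ``"uniprot->helical"``
    or ``"helical->uniprot"``. Raises ValueError outside the helical domain.
    """
    off = NUMBERING_OFFSETS[kind]
    if direction == "uniprot->helical":
        h = n - off
    elif direction == "helical->uniprot":
        h = n
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if not 1 <= h <= HELICAL_DOMAIN_LENGTH:
        raise ValueError(
            f"residue {n} ({direction}) falls outside the {kind} helical domain"
        )
    return h if direction == "uniprot->helical" else n + off


def _validate_pdb_text(path: Path) -> np.ndarray | None:
    """Pre-scan for malformed ATOM/HETATM records and duplicate atoms.

    Returns the box lengths if a CRYST1 record is present. Raises ValueError
    naming the offending line number.
    """
    box = None
    seen: set[tuple] = set()
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                n_atoms += 1
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"{path}: malformed {rec} record at line {lineno}")
                try:
                    [float(line[i : i + 8]) for i in (30, 38, 46)]
                except ValueError:
                    raise ValueError(
                        f"{path}: unparseable coordinates at line {lineno}"
                    ) from None
                key = (line[21], line[22:27], line[12:16], line[16])
                if key in seen:
                    raise ValueError(
                        f"{path}: duplicate atom {line[12:16].strip()} in residue "
                        f"{line[17:20].strip()} {line[22:26].strip()} at line {lineno}"
                    )
                seen.add(key)
            elif rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                except ValueError:
                    raise ValueError(f"{path}: malformed CRYST1 at line {lineno}") from None
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return box


def read_pdb(path, numbering: str = "helical") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    ``numbering`` declares the frame the file's residue numbers are in
    (``"helical"`` or ``"uniprot"``); the complementary frame is derived via
    :func:`map_numbering` where the position lies inside the helical domain.
    Chain ids A/B/C map to α1a/α1b/α2; other chain ids are kept as-is and
    treated as non-collagen (ions, solvent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    box = _validate_pdb_text(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio = PDBParser(QUIET=True).get_structure("s", str(path))

    out = Structure(box=box)
    model = next(bio.get_models())
    for bchain in model:
        label = CHAIN_LABELS.get(bchain.id, bchain.id)
        residues: list[Residue] = []
        for bres in bchain:
            n = bres.id[1]
            name = bres.get_resname().strip()
            if label in _LABEL_TO_ID:
                kind = chain_kind(label)
                if numbering == "helical":
                    ref = ResidueRef(label, name, NUMBERING_OFFSETS[kind] + n, n)
                else:
                    try:
                        h = map_numbering(kind, n, "uniprot->helical")
                    except ValueError:
                        h = None
                    ref = ResidueRef(label, name, n, h)
            else:
                ref = ResidueRef(label, name, n, None)
            atoms = [
                AtomRecord(a.get_name(), (a.element or "").strip() or a.get_name()[0], a.coord)
                for a in bres
            ]
            residues.append(Residue(ref, atoms))
        out.chains[label] = residues
    return out


def write_pdb(s: Structure, path, numbering: str = "helical") -> None:
    """Write a :class:`Structure` as PDB v3 via Bio.PDB.

    Residue numbers are emitted in the requested frame (helical where
    available, otherwise the UniProt number is written unchanged).
    """
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    serial = 1
    for label, chain in s.chains.items():
        builder.init_chain(_LABEL_TO_ID.get(label, label[:1] or "X"))
        builder.init_seg("    ")
        for res in chain:
            if numbering == "helical" and res.ref.helical_num is not None:
                num = res.ref.helical_num
            else:
                num = res.ref.uniprot_num
            hetflag = " " if label in _LABEL_TO_ID else "H"
            builder.init_residue(res.ref.residue_name, hetflag, num, " ")
            for atom in res.atoms:
                builder.init_atom(
                    atom.name,
                    np.asarray(atom.position, dtype=np.float32),
                    0.0,
                    1.0,
                    " ",
                    atom.name.center(4)[:4],
                    serial,
                    atom.element,
                )
                serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    path = Path(path)
    with open(path, "w") as fh:
        if s.box is not None:
            fh.write(
                "CRYST1"
                + "".join(f"{x:9.3f}" for x in s.box)
                + f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        io.save(fh)


_POSITIVE = set("KR")  # Hyl is a modified K and retains its +1
_NEGATIVE = set("DE")
_PTM_CODES = {"HYP": "P", "HYL": "K"}


def compute_composition(
    sequences: dict[str, str],
    n_waters: int,
    ptms: dict[str, dict[int, str]] | None = None,
) -> SystemComposition:
    """Formal pH-7 composition of a multi-chain protein system.

    ``sequences`` maps chain label to one-letter sequence. ``ptms`` maps chain
    label to {position (1-based): "HYP"|"HYL"}; each hydroxylation adds one
    oxygen to the mass and leaves the formal charge unchanged. Charges: Lys,
    Hyl and Arg +1; Asp and Glu -1; His neutral; chain termini zwitterionic
    and cancelling. Each chain contributes one water of mass for its termini
    (peptide-bonded residue masses otherwise).
    """
    ptms = ptms or {}
    mass = 0.0
    charge = 0
    for label, seq in sequences.items():
        seq = seq.upper()
        bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ValueError(f"chain {label}: unknown residue code(s) {sorted(bad)}")
        for pos, code in ptms.get(label, {}).items():
            if code not in _PTM_CODES:
                raise ValueError(f"chain {label}: unknown PTM code {code!r}")
            if not 1 <= pos <= len(seq) or seq[pos - 1] != _PTM_CODES[code]:
                raise ValueError(
                    f"chain {label}: PTM {code} at position {pos} does not sit on "
                    f"a {_PTM_CODES[code]} residue"
                )
        mass += molecular_weight(seq, seq_type="protein")
        mass += _HYDROXYL_MASS * len(ptms.get(label, {}))
        charge += sum(seq.count(c) for c in _POSITIVE)
        charge -= sum(seq.count(c) for c in _NEGATIVE)
    return SystemComposition(
        protein_mass=mass,
        net_charge=charge,
        n_waters=n_waters,
        n_chloride=charge if charge > 0 else 0,
    )


def read_sequences(fasta_path, ptm_table_path=None):
    """Read chain sequences from FASTA plus an optional PTM side-car table.

    The side-car is whitespace-delimited text with columns
    ``chain position ptm_code`` (``HYP``/``HYL``), ``#`` comments allowed.
    Returns ``(sequences, ptms)`` suitable for :func:`compute_composition`.
    """
    from Bio import SeqIO

    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not sequences:
        raise ValueError(f"{fasta_path}: no FASTA records")
    ptms: dict[str, dict[int, str]] = {}
    if ptm_table_path is not None:
        with open(ptm_table_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chain, pos, code = line.split()
                ptms.setdefault(chain, {})[int(pos)] = code.upper()
    return sequences, ptms
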