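"""Axial D-band mapping: gap/overlap classification of helical positions.

Collagen fibrils show a 67 nm axial periodicity (the D-band) arising from
staggered molecular packing; each period splits into a gap region (0.54 D)
and a higher-density overlap region (0.46 D). With a 2.86 Å axial rise a
D-period corresponds to 234 residues, the standard fibrillar value.

Which residue sits at a region boundary (the registration) is not fixed by
the molecular sequence alone; it is exposed here as an integer offset and a
calibrated value is shipped (derived by :func:`calibrate_registration` from
the favourable-site region labels; see the package methods note). The frame
is anchored at a gap start: positions whose axial fraction is below the gap
fraction are gap, the remainder overlap. With 234 residues per period this
makes the integer overlap window 107 residues wide, which is the only
anchoring under which a single favourable site can fall in the overlap
region.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DBandConfig",
    "axial_fraction",
    "classify_region",
    "calibrate_registration",
    "CALIBRATED_REGISTRATION_OFFSET",
]

#: Registration offset calibrated against the favourable-site labels
#: (one site in overlap, five in gap); unique minimiser, mismatch 0.
#: A derived value, not an experimentally reported one.
CALIBRATED_REGISTRATION_OFFSET = 179


@dataclass
class DBandConfig:
    d_length: float = 67.0  # nm
    residues_per_d: int = 234
    overlap_fraction: float = 0.46
    gap_fraction: float = 0.54
    registration_offset: int = 0  # residues

    def __post_init__(self):
        if self.residues_per_d <= 0:
            raise ValueError("residues_per_d must be positive")
        if abs(self.overlap_fraction + self.gap_fraction - 1.0) > 1e-9:
            raise ValueError("overlap_fraction + gap_fraction must equal 1")


def axial_fraction(helical_pos: int, cfg: DBandConfig | None = None) -> float:
    """Fractional position within the D-period, in [0, 1)."""
    cfg = cfg or DBandConfig()
    if helical_pos < 1:
        raise ValueError("helical_pos must be >= 1")
    return (
        (helical_pos - 1 + cfg.registration_offset) % cfg.residues_per_d
    ) / cfg.residues_per_d


def classify_region(helical_pos: int, cfg: DBandConfig | None = None) -> str:
    """``"gap"`` or ``"overlap"`` for a helical position.

    The frame is anchored at a gap start: fraction < gap_fraction -> gap.
    """
    cfg = cfg or DBandConfig()
    return "gap" if axial_fraction(helical_pos, cfg) < cfg.gap_fraction else "overlap"


def calibrate_registration(
    labelled_sites, cfg: DBandConfig | None = None
) -> tuple[set[int], int]:
    """Brute-force the registration offset against labelled positions.

    ``labelled_sites`` is an iterable of ``(helical_pos, "gap"|"overlap")``.
    Every integer offset 0..residues_per_d-1 is tried; returns the set of all
    offsets achieving the minimal label-mismatch count, and that count.
    """
    cfg = cfg or DBandConfig()
    labelled = list(labelled_sites)
    if not labelled:
        raise ValueError("need at least one labelled site")
    for _pos, label in labelled:
        if label not in ("gap", "overlap"):
            raise ValueError(f"unknown region label {label!r}")
    best: set[int] = set()
    best_mismatch = len(labelled) + 1
    for off in range(cfg.residues_per_d):
        trial = DBandConfig(
            d_length=cfg.d_length,
            residues_per_d=cfg.residues_per_d,
            overlap_fraction=cfg.overlap_fraction,
            gap_fraction=cfg.gap_fraction,
            registration_offset=off,
        )
        mism = sum(
            1 for pos, label in labelled if classify_region(pos, trial) != label
        )
        if mism < best_mismatch:
            best_mismatch = mism
            best = {off}
        elif mism == best_mismatch:
            best.add(off)
    return best, best_mismatch
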