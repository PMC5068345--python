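"""Interaction-domain annotation, cross-AGE comparison, per-site reports.

Ships two packaged fixtures: the 24-site candidate table with DOGDIC and
glucosepane formation enthalpies (dual residue numbering per site), and the
qualitative map of extracellular-matrix biomolecule binding locations that
overlap the favourable DOGDIC sites. The domain map is site -> name lists,
not sequence intervals: the underlying interaction-domain coordinates are
not reproduced here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .dband import CALIBRATED_REGISTRATION_OFFSET, DBandConfig, classify_region
from .enthalpy import classify_sites
from .structure_io import NUMBERING_OFFSETS, chain_kind

__all__ = [
    "DomainTrack",
    "ComparisonReport",
    "load_table1",
    "load_table2",
    "annotate",
    "compare_age",
    "summarize",
    "VOCABULARY",
]

VOCABULARY = frozenset(
    {
        "Heat Shock Protein 47",
        "Interleukin-2",
        "α2β1 integrin",
        "Matrix Metalloproteinase 1",
        "Dermatan Sulfate",
        "Keratan Sulfate PG",
        "Phosphophoryn",
        "heparin",
        "Amyloid Precursor Protein",
    }
)

#: Entries the packaged candidate table must leave blank in the glucosepane
#: column (recorded at load time, not assumed elsewhere).
EXPECTED_MISSING_GLUCOSEPANE = frozenset({"D1", "D23"})


def _data_path(name: str) -> Path:
    return Path(resources.files("colxscan").joinpath("data", name))


def _normalize_site(site_id) -> str:
    s = str(site_id)
    return s if s.startswith("D") else f"D{s}"


@dataclass
class DomainTrack:
    """Site ID -> overlapping biomolecule binding locations."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for site, names in self.entries.items():
            unknown = set(names) - VOCABULARY
            if unknown:
                raise ValueError(f"site {site}: names outside vocabulary: {unknown}")


@dataclass
class ComparisonReport:
    set_a: list[str]
    set_b: list[str]
    intersection: list[str]
    per_site: dict[str, tuple[float | None, float | None]]

    @property
    def set_a_size(self) -> int:
        return len(self.set_a)

    @property
    def set_b_size(self) -> int:
        return len(self.set_b)


def load_table1(path=None) -> pd.DataFrame:
    """Load and validate the packaged 24-site candidate/enthalpy table.

    Validation: 24 unique sites; ΔH column for DOGDIC fully populated; the
    exact set of blank glucosepane entries recorded and checked; dual
    numbering consistent with the chain-kind offsets on every row.
    """
    path = Path(path) if path is not None else _data_path("table1.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    if len(df) != 24 or df["site"].nunique() != 24:
        raise ValueError(f"{path}: expected 24 unique sites, got {len(df)}")
    if df["dogdic_dh"].isna().any():
        raise ValueError(f"{path}: DOGDIC enthalpy column must be fully populated")
    missing = set(df.loc[df["glucosepane_dh"].isna(), "site"])
    if missing != set(EXPECTED_MISSING_GLUCOSEPANE):
        raise ValueError(
            f"{path}: glucosepane entries missing for {sorted(missing)}, "
            f"expected {sorted(EXPECTED_MISSING_GLUCOSEPANE)}"
        )
    for _, row in df.iterrows():
        for role in ("lys", "arg"):
            kind = chain_kind(row[f"{role}_chain"])
            if row[f"{role}_uniprot"] - row[f"{role}_helical"] != NUMBERING_OFFSETS[kind]:
                raise ValueError(
                    f"{path}: inconsistent dual numbering at site {row['site']}"
                )
        if row["lys_chain"] == row["arg_chain"]:
            raise ValueError(f"{path}: same-chain pair at site {row['site']}")
    return df


def load_table2(path=None) -> DomainTrack:
    """Load the packaged domain map (site -> ';'-joined biomolecule names)."""
    path = Path(path) if path is not None else _data_path("table2.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    return DomainTrack(
        {row["site"]: row["biomolecules"].split(";") for _, row in df.iterrows()}
    )


def annotate(site_id, track: DomainTrack) -> list[str]:
    """Biomolecule binding locations overlapping a site (empty if unknown)."""
    return list(track.entries.get(_normalize_site(site_id), []))


def compare_age(dh_a, dh_b) -> ComparisonReport:
    """Compare favourable-site sets of two AGE kinds over shared site IDs.

    ``dh_a``/``dh_b`` map site ID -> ΔH (kcal/mol); missing entries (None or
    NaN) are excluded from the corresponding favourable set.
    """
    fav_a = classify_sites(dh_a)
    fav_b = classify_sites(dh_b)
    inter = [s for s in fav_a if s in set(fav_b)]
    sites = list(dict.fromkeys(list(dict(dh_a)) + list(dict(dh_b))))
    per_site = {s: (dict(dh_a).get(s), dict(dh_b).get(s)) for s in sites}
    return ComparisonReport(fav_a, fav_b, inter, per_site)


def summarize(
    candidates: pd.DataFrame,
    enthalpies: dict[str, float],
    dband_cfg: DBandConfig | None = None,
    track: DomainTrack | None = None,
    sems: dict[str, float] | None = None,
    tsv_path=None,
    json_path=None,
) -> pd.DataFrame:
    """Assemble the per-site report table.

    ``candidates`` must carry the table-1 style columns (site, dual numbering
    for both residues, optionally criterion distances d1..d3). ``enthalpies``
    maps site ID -> ΔH; IDs must match exactly (orphans on either side are an
    error). Each row gains the ΔH, favourability, D-band region at the site's
    representative position, and the domain list. Output is deterministic.
    """
    if dband_cfg is None:
        dband_cfg = DBandConfig(registration_offset=CALIBRATED_REGISTRATION_OFFSET)
    track = track or DomainTrack()
    sems = sems or {}
    cand_ids = list(candidates["site"])
    orphans = sorted(set(cand_ids) ^ set(enthalpies))
    if orphans:
        raise ValueError(f"site ID mismatch between candidates and enthalpies: {orphans}")
    fav = set(classify_sites(enthalpies))
    rows = []
    for _, row in candidates.iterrows():
        site = row["site"]
        pos = int(min(row["lys_helical"], row["arg_helical"]))
        out = {c: row[c] for c in candidates.columns}
        out.update(
            delta_h=enthalpies[site],
            sem=sems.get(site),
            favourable=site in fav,
            region=classify_region(pos, dband_cfg),
            domains=";".join(annotate(site, track)),
        )
        rows.append(out)
    report = pd.DataFrame(rows)
    if tsv_path is not None:
        report.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report.to_dict(orient="records"), fh, indent=2, sort_keys=True)
    return report
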