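import math

import numpy as np
import pytest

from colxscan import site_scanner as ss
from colxscan import synthetic_collagen as sc
from colxscan.site_scanner import CandidateSite, ScanConfig, ion_proximity, scan
from colxscan.structure_io import AtomRecord, Residue, ResidueRef, Structure
from conftest import brute_force_sites


def lys_at(nz, ce=(9.0, 9.0, 9.0), cd=(9.5, 9.5, 9.5), chain="α1a", helical=1):
    ref = ResidueRef(chain, "LYS", 167 + helical, helical)
    return Residue(ref, [
        AtomRecord("NZ", "N", nz),
        AtomRecord("CE", "C", ce),
        AtomRecord("CD", "C", cd),
    ])


def arg_at(nh1, nh2, ne=(8.0, 8.0, 8.0), cd=(8.5, 8.5, 8.5), chain="α1b", helical=2):
    ref = ResidueRef(chain, "ARG", 167 + helical, helical)
    return Residue(ref, [
        AtomRecord("NH1", "N", nh1),
        AtomRecord("NH2", "N", nh2),
        AtomRecord("NE", "N", ne),
        AtomRecord("CD", "C", cd),
    ])


class TestPairDistances:
    def test_coincident_atoms(self):
        d = ss.pair_distances(lys_at((0, 0, 0)), arg_at((0, 0, 0), (5, 5, 5)))
        assert d[0] == 0.0

    def test_three_four_five_min_semantics(self):
        # NH1 at 5 Å (3-4-5 triangle), NH2 at 6 Å: criterion 1 takes the min
        d = ss.pair_distances(lys_at((0, 0, 0)), arg_at((3, 4, 0), (0, 0, 6)))
        assert d[0] == pytest.approx(5.0)

    def test_planted_distance_reported(self, gpo_helix):
        s = sc.plant_site(gpo_helix, sc.PlantSpec("α1a", 8, "α2", 11, "CE-NE", 4.2))
        lys = s.find_residue("α1a", 8)
        arg = s.find_residue("α2", 11)
        assert ss.pair_distances(lys, arg)[1] == pytest.approx(4.2, abs=0.01)

    def test_missing_atom_names_residue(self):
        broken = lys_at((0, 0, 0))
        broken.atoms = [a for a in broken.atoms if a.name != "CE"]
        with pytest.raises(KeyError, match="CE.*LYS"):
            ss.pair_distances(broken, arg_at((3, 4, 0), (0, 0, 6)))


class TestScan:
    def test_planted_cross_chain_site_found(self, gpo_helix):
        s = sc.plant_site(gpo_helix, sc.PlantSpec("α1a", 8, "α1b", 14, "NZ-NH", 4.8))
        sites = scan(s)
        assert len(sites) == 1
        assert sites[0].lys.chain_label == "α1a"
        assert sites[0].met  # at least one criterion

    def test_beyond_cutoff_not_reported(self, gpo_helix):
        s = sc.plant_site(gpo_helix, sc.PlantSpec("α1a", 8, "α1b", 14, "NZ-NH", 5.2))
        sites = [c for c in scan(s) if min(c.distances) > 5.0]
        assert sites == []

    def test_no_lys_or_arg_empty(self, gpo_helix):
        assert scan(gpo_helix) == []

    def test_same_chain_pair_excluded(self):
        with pytest.raises(ValueError, match="different chains"):
            CandidateSite(
                ResidueRef("α1a", "LYS", 168, 1),
                ResidueRef("α1a", "ARG", 170, 3),
                (3.0, 4.0, 5.0),
            )

    def test_oracle_equivalence_random_structures(self, random_structure_factory):
        rng = np.random.default_rng(42)
        for _ in range(20):
            s = random_structure_factory(rng)
            for cutoff in (4.0, 5.0, 6.0):
                got = {
                    (
                        (c.lys.chain_label, c.lys.helical_num),
                        (c.arg.chain_label, c.arg.helical_num),
                    )
                    for c in scan(s, ScanConfig(cutoff=cutoff))
                }
                assert got == brute_force_sites(s, cutoff)

    def test_monotone_in_cutoff(self, random_structure_factory):
        rng = np.random.default_rng(7)
        s = random_structure_factory(rng)
        keys = lambda sites: {
            (c.lys.chain_label, c.lys.helical_num, c.arg.chain_label, c.arg.helical_num)
            for c in sites
        }
        small = keys(scan(s, ScanConfig(cutoff=4.0)))
        large = keys(scan(s, ScanConfig(cutoff=6.0)))
        assert small <= large

    def test_chain_relabel_invariance(self, gpo_helix):
        s = sc.plant_site(gpo_helix, sc.PlantSpec("α1a", 8, "α1b", 14, "NZ-NH", 4.8))
        swapped = Structure(chains={
            "α1a": s.chains["α1b"], "α1b": s.chains["α1a"], "α2": s.chains["α2"],
        })
        for label, chain in swapped.chains.items():
            for r in chain:
                r.ref.chain_label = label
        orig = {(c.lys.helical_num, c.arg.helical_num) for c in scan(s)}
        after = {(c.lys.helical_num, c.arg.helical_num) for c in scan(swapped)}
        assert orig == after

    def test_hydroxylysine_not_a_donor(self, gpo_helix):
        s = sc.plant_site(gpo_helix, sc.PlantSpec("α1a", 8, "α1b", 14, "NZ-NH", 4.0))
        s.find_residue("α1a", 8).ref.residue_name = "HYL"
        assert scan(s) == []

    def test_report_order_deterministic(self, random_structure_factory):
        rng = np.random.default_rng(3)
        s = random_structure_factory(rng)
        sites = scan(s, ScanConfig(cutoff=6.5))
        positions = [c.position for c in sites]
        assert positions == sorted(positions)


class TestIonProximity:
    def _with_ions(self, gpo_helix, distances):
        s = sc.plant_site(gpo_helix, sc.PlantSpec("α1a", 8, "α1b", 14, "NZ-NH", 4.8))
        site = scan(s)[0]
        nz = s.find_residue("α1a", 8).atom("NZ").position
        # place each ion along +x from the Nζ atom, then verify the reported
        # minimum is against the *nearest site atom*, which may not be Nζ
        ions = [
            Residue(
                ResidueRef("I", "CL", i + 1, None),
                [AtomRecord("CL", "Cl", nz + np.array([d + 20.0, 0, 0]))],
            )
            for i, d in enumerate(distances)
        ]
        s.chains["I"] = ions
        return s, site

    def test_no_ions_infinite(self, gpo_helix):
        s = sc.plant_site(gpo_helix, sc.PlantSpec("α1a", 8, "α1b", 14, "NZ-NH", 4.8))
        site = scan(s)[0]
        d, outside = ion_proximity(s, site)
        assert math.isinf(d) and outside

    def test_single_far_ion(self, gpo_helix):
        s, site = self._with_ions(gpo_helix, [0.0])
        d, outside = ion_proximity(s, site)
        assert d > 8.0 and outside

    def test_near_ion_inside_cutoff(self, gpo_helix):
        s = sc.plant_site(gpo_helix, sc.PlantSpec("α1a", 8, "α1b", 14, "NZ-NH", 4.8))
        site = scan(s)[0]
        nz = s.find_residue("α1a", 8).atom("NZ").position
        s.chains["I"] = [Residue(
            ResidueRef("I", "CL", 1, None),
            [AtomRecord("CL", "Cl", nz + np.array([5.0, 0, 0]))],
        )]
        d, outside = ion_proximity(s, site)
        assert d <= 5.0 and not outside

    def test_min_over_ions(self, gpo_helix):
        s = sc.plant_site(gpo_helix, sc.PlantSpec("α1a", 8, "α1b", 14, "NZ-NH", 4.8))
        site = scan(s)[0]
        nz = s.find_residue("α1a", 8).atom("NZ").position
        far = nz + np.array([0.0, 50.0, 0.0])
        nearer = nz + np.array([0.0, 40.0, 0.0])
        s.chains["I"] = [
            Residue(ResidueRef("I", "CL", 1, None), [AtomRecord("CL", "Cl", far)]),
            Residue(ResidueRef("I", "CL", 2, None), [AtomRecord("CL", "Cl", nearer)]),
        ]
        d, outside = ion_proximity(s, site)
        d_expected = min(
            np.linalg.norm(nearer - a.position)
            for ref in (site.lys, site.arg)
            for a in s.find_residue(ref.chain_label, ref.helical_num).atoms
        )
        assert d == pytest.approx(d_expected) and outside
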