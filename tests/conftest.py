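import numpy as np
import pytest
from hypothesis import settings

from colxscan import annotate_report as ar
from colxscan import site_scanner as ss
from colxscan import synthetic_collagen as sc

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return ar.load_table1()


@pytest.fixture(scope="session")
def table2():
    return ar.load_table2()


@pytest.fixture
def gpo_helix():
    return sc.build_triple_helix(["GPO" * 12] * 3)


def brute_force_sites(s, cutoff):
    """Independent all-pairs scanner oracle: plain python triple loop.

    Returns a set of ((lys_chain, lys_helical), (arg_chain, arg_helical))
    keys for every cross-chain Lys/Arg pair with any criterion distance
    within the cut-off.
    """

    def dist(a, b):
        return sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5

    found = set()
    residues = [r for chain in s.collagen_chains().values() for r in chain]
    for lys in residues:
        if lys.ref.residue_name != "LYS":
            continue
        for arg in residues:
            if arg.ref.residue_name != "ARG":
                continue
            if lys.ref.chain_label == arg.ref.chain_label:
                continue
            nz = lys.atom("NZ").position
            d1 = min(
                dist(nz, arg.atom("NH1").position),
                dist(nz, arg.atom("NH2").position),
            )
            d2 = dist(lys.atom("CE").position, arg.atom("NE").position)
            d3 = dist(lys.atom("CD").position, arg.atom("CD").position)
            if min(d1, d2, d3) <= cutoff:
                found.add(
                    (
                        (lys.ref.chain_label, lys.ref.helical_num),
                        (arg.ref.chain_label, arg.ref.helical_num),
                    )
                )
    return found


def make_random_planted_structure(rng):
    """A small triple helix with several Lys/Arg pairs planted at random
    criterion distances straddling the 5 Å cut-off."""
    n_res = 3 * int(rng.integers(8, 14))
    seqs = []
    for _ in range(3):
        seq = []
        for j in range(n_res):
            seq.append("G" if j % 3 == 0 else rng.choice(list("POASKR")))
        seqs.append("".join(seq))
    s = sc.build_triple_helix(seqs)
    chains = ["α1a", "α1b", "α2"]
    for _ in range(int(rng.integers(1, 4))):
        ci, cj = rng.choice(3, size=2, replace=False)
        # keep Gly positions Gly: plant only on non-Gly slots
        pos = [int(p) for p in rng.integers(1, n_res + 1, size=2)]
        pos = [p + 1 if (p - 1) % 3 == 0 else p for p in pos]
        pair = str(rng.choice(["NZ-NH", "CE-NE", "CD-CD"]))
        d = float(rng.uniform(3.0, 7.0))
        try:
            sc.plant_site(
                s,
                sc.PlantSpec(chains[ci], pos[0], chains[cj], pos[1], pair, d),
            )
        except KeyError:
            continue
    return s


@pytest.fixture
def random_structure_factory():
    return make_random_planted_structure
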