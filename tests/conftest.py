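import random

import pytest

from struct3dmap.fixtures import ChainSpec, FixtureSpec, demo_fixture_tree, make_structure_fixture

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def demo_tree(tmp_path_factory):
    """The canonical end-to-end scenario: 12-residue query, 10-residue
    chain A template, chain B opposite positions 3-4 at 4.5 A, five designed
    variants."""
    outdir = tmp_path_factory.mktemp("demo_tree")
    return demo_fixture_tree(outdir, seed=7)


@pytest.fixture()
def two_strand_fixture(tmp_path):
    """Two parallel 6-residue strands 4.5 A apart, written as .pdb + .cif."""
    spec = FixtureSpec(
        structure_id="pair1",
        seed=3,
        cutoff=5.0,
        chains=[
            ChainSpec(chain_id="A", length=6),
            ChainSpec(chain_id="B", length=6, y_offset=4.5),
        ],
    )
    return make_structure_fixture(spec, tmp_path)


def random_fixture_spec(structure_id: str, rng: random.Random) -> FixtureSpec:
    """A small random two-or-three-entity structure for oracle comparisons."""
    chains = [
        ChainSpec(chain_id="A", length=rng.randint(3, 7)),
        ChainSpec(
            chain_id="B",
            length=rng.randint(2, 6),
            y_offset=rng.choice([2.5, 3.5, 4.2, 4.9, 6.0, 7.5]),
            x_shift=rng.randint(0, 2),
        ),
    ]
    if rng.random() < 0.5:
        chains.append(
            ChainSpec(
                chain_id="C", kind="ligand", component="HEM",
                start_resnum=201,
                y_offset=rng.choice([-3.0, -4.5, -6.5]),
                x_shift=rng.randint(0, 3),
            )
        )
    if rng.random() < 0.3:
        chains.append(
            ChainSpec(
                chain_id="D", kind="nucleic", length=rng.randint(2, 4),
                y_offset=rng.choice([3.0, 5.5, 8.0]), z_offset=1.0,
            )
        )
    return FixtureSpec(structure_id=structure_id, seed=rng.randint(0, 10_000),
                       chains=chains)
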