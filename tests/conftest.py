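"""Shared fixtures: the fixture tree and a small noise-free simulation whose
emitted files back most round-trip tests."""

from __future__ import annotations

import pathlib

import pytest

import intronevo as ie
from intronevo import simulate as sim


@pytest.fixture(scope="session")
def default_tree() -> ie.SpeciesTree:
    return sim.make_default_tree()


@pytest.fixture(scope="session")
def noise_free_config() -> ie.SimConfig:
    return ie.SimConfig(n_genes=40, substitution_rate=0.0, utr_fraction=0.05,
                        seed=101)


@pytest.fixture(scope="session")
def truth(default_tree, noise_free_config) -> sim.TruthTable:
    return sim.simulate_intron_evolution(default_tree, noise_free_config)


@pytest.fixture(scope="session")
def sim_dir(truth, tmp_path_factory) -> pathlib.Path:
    out = tmp_path_factory.mktemp("sim")
    sim.emit_all(truth, out, junction_species=["Scer", "Skud", "Suva", "Ncas"])
    return out


@pytest.fixture(scope="session")
def alignments(sim_dir):
    import intronevo.io as eio

    return [eio.read_alignment(fa, fa.with_suffix(".gff3"))
            for fa in sorted((sim_dir / "alignments").glob("*.fa"))]


@pytest.fixture(scope="session")
def pillar(sim_dir):
    import intronevo.io as eio

    return eio.read_pillar(sim_dir / "pillar.tsv")


@pytest.fixture(scope="session")
def state_matrix(alignments, pillar):
    return ie.build_state_matrix(alignments, pillar)
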