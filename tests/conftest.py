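from __future__ import annotations

import textwrap

import pytest

from plastmark.simulate import (
    SimulationConfig,
    RegionSpec,
    assemble_synthetic_plastomes,
    iris_like_config,
)

GENBANK_TEMPLATE = """\
LOCUS       {name}                {length} bp    DNA     circular PLN 01-JAN-2024
DEFINITION  synthetic test record.
ACCESSION   {name}
FEATURES             Location/Qualifiers
     source          1..{length}
{features}ORIGIN
{origin}//
"""


def make_genbank(name: str, sequence: str, features: list[str]) -> str:
    """Render a minimal GenBank flat file for a toy sequence."""
    feature_block = ""
    for loc, gene in features:
        feature_block += f"     gene            {loc}\n"
        feature_block += f'                     /gene="{gene}"\n'
    origin = ""
    for i in range(0, len(sequence), 60):
        chunk = sequence[i : i + 60].lower()
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        origin += f"{i + 1:>9} {grouped}\n"
    return GENBANK_TEMPLATE.format(
        name=name, length=len(sequence), features=feature_block, origin=origin
    )


@pytest.fixture
def toy_genbank(tmp_path):
    seq = "ACGT" * 15  # 60 bp
    text = make_genbank(
        "TEST01",
        seq,
        [("10..30", "gA"), ("complement(join(35..40,50..55))", "gB")],
    )
    path = tmp_path / "toy.gb"
    path.write_text(text)
    return path


def tiny_plastome_config(seed: int = 0, n_taxa: int = 4) -> SimulationConfig:
    """Small quadripartite template for fast structural tests."""
    regions = [
        RegionSpec("ga", "gene", 1500, 0.8, "LSC"),
        RegionSpec("ga-gb", "IGS", 400, 1.6, "LSC"),
        RegionSpec("gb", "gene", 1200, 0.8, "LSC"),
        RegionSpec("ra", "gene", 1300, 0.35, "IR"),
        RegionSpec("sa", "gene", 900, 1.3, "SSC"),
        RegionSpec("sa-sb", "IGS", 300, 2.2, "SSC"),
        RegionSpec("sb", "gene", 600, 1.3, "SSC"),
    ]
    return SimulationConfig(n_taxa=n_taxa, regions=regions, seed=seed)


@pytest.fixture(scope="session")
def small_dataset():
    """An 8-taxon run of the default preset, shared across tests."""
    return assemble_synthetic_plastomes(iris_like_config(seed=11, n_taxa=8))
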