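"""Shared fixtures and hypothesis configuration for the suite."""

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from netquery import GeneSet, SymbolTable, build_index, load_symbol_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def symbol_table() -> SymbolTable:
    """The packaged ~50-row synthetic HGNC-style table."""
    return load_symbol_table(DATA_DIR / "synthetic_symbols.tsv")


@pytest.fixture()
def three_network_index():
    """The closed-form collection: D1={A,B}, D2={B,C}, D3={C,D}."""
    return build_index(
        [
            GeneSet("D1", "D1", frozenset("AB"), "gmt"),
            GeneSet("D2", "D2", frozenset("BC"), "gmt"),
            GeneSet("D3", "D3", frozenset("CD"), "gmt"),
        ]
    )


def approved_only(genes) -> SymbolTable:
    """A table where every given gene is approved and nothing else."""
    return SymbolTable(approved={g.upper() for g in genes})


@pytest.fixture()
def approved_only_table():
    return approved_only
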