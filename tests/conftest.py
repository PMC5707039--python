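from __future__ import annotations

import random

import pytest

from segaloh import default_panel, default_snps
from segaloh.panel import GeneRegion, Interval, PanelDefinition
from segaloh.simulate import reference_base

try:
    from importlib.resources import files
except ImportError:  # pragma: no cover
    files = None

from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def snps(panel):
    return default_snps(panel)


@pytest.fixture(scope="session")
def cohort_fixture_path():
    return str(files("segaloh").joinpath("data/sega_cohort_results.tsv"))


@pytest.fixture(scope="session")
def loh_test_panel():
    """Single-gene panel sized for 50 informative SNPs plus a mutation site."""
    return PanelDefinition(
        genes={
            "TSC2": GeneRegion(
                "TSC2",
                Interval("chr16", 2110000, 2110300),
                [Interval("chr16", 2110000, 2110300)],
            )
        }
    )


def make_random_line_tokens(rng: random.Random, max_symbols: int = 50):
    """Random pileup read tokens plus their expected oriented counts.

    Expected counts come from the construction itself (each token's meaning
    is known when it is generated), independent of any parsing code.
    """
    n = rng.randint(1, max_symbols)
    fwd: dict[str, int] = {}
    rev: dict[str, int] = {}
    chunks: list[str] = []
    bases = "ACGT"
    for _ in range(n):
        if rng.random() < 0.15:
            chunks.append("^" + chr(rng.randint(33, 126)))
        forward = rng.random() < 0.5
        r = rng.random()
        if r < 0.45:
            sym, key = (".", "ref") if forward else (",", "ref")
        elif r < 0.75:
            b = rng.choice(bases + "N")
            sym, key = (b, b) if forward else (b.lower(), b)
            if key == "N":
                key = "N"
        elif r < 0.85:
            sym, key = ("*", "*") if forward else ("#", "*")
        else:
            sign = rng.choice("+-")
            seq = "".join(rng.choice(bases) for _ in range(rng.randint(1, 4)))
            anchor = "." if forward else ","
            written = seq if forward else seq.lower()
            sym = anchor + sign + str(len(seq)) + written
            key = sign + seq
        chunks.append(sym)
        target = fwd if forward else rev
        target[key] = target.get(key, 0) + 1
        if rng.random() < 0.1:
            chunks.append("$")
    return "".join(chunks), fwd, rev, n
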