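from __future__ import annotations

import numpy as np
import pytest

from varfunnel import fixtures
from varfunnel.core import CallSet, FunctionalClass, Variant
from varfunnel.simulate import SimulationParams, simulate_cohort


def build_callset(entries, samples):
    """Build a CallSet from (chrom, pos, ref, alt, gene, fclass, dosages)
    tuples; dosages align with ``samples`` and may contain None."""
    variants = [
        Variant(chrom, pos, ref, alt, gene=gene, functional_class=fclass)
        for chrom, pos, ref, alt, gene, fclass, _ in entries
    ]
    matrix = np.array(
        [[-1 if d is None else d for d in dosages] for *_, dosages in entries],
        dtype=np.int8,
    ).reshape(len(entries), len(samples))
    return CallSet(variants, samples, matrix)


def simple_variant(pos=1, fclass=FunctionalClass.MISSENSE, gene=None, chrom="chr1"):
    return Variant(chrom, pos, "A", "G", gene=gene, functional_class=fclass)


@pytest.fixture(scope="session")
def studbook():
    return fixtures.load_studbook()


@pytest.fixture(scope="session")
def missense_panel():
    return fixtures.load_missense_panel()


@pytest.fixture(scope="session")
def iqcb1_cohort():
    return fixtures.load_iqcb1_cohort()


@pytest.fixture(scope="session")
def default_bundle():
    return simulate_cohort(SimulationParams(seed=11))
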