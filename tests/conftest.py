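"""Shared fixtures: tiny hand-built matrices and one mid-size simulated pulse."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popstrata import (
    GenotypeMatrix,
    make_component_set,
    make_samples,
    simulate_admixed,
    uniform_map,
    variant_table,
)
from popstrata.io_qc import MISSING


def build_gm(
    calls,
    populations=None,
    chromosomes=None,
    cm=None,
    positions=None,
    alleles=None,
    ids=None,
) -> GenotypeMatrix:
    """Construct a GenotypeMatrix from a call array with minimal metadata."""
    calls = np.asarray(calls, dtype=np.int16)
    n, v = calls.shape
    populations = populations or ["pop"] * n
    samples = make_samples(ids or [f"s{i}" for i in range(n)], populations)
    chromosomes = chromosomes or ["1"] * v
    cm = cm if cm is not None else np.arange(v, dtype=float)
    positions = positions if positions is not None else (np.asarray(cm) * 1e6).astype(int)
    alleles = alleles or [("A", "G")] * v
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(v)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "genetic_pos_cM": cm,
            "allele_a": [a for a, _ in alleles],
            "allele_b": [b for _, b in alleles],
        }
    )
    return GenotypeMatrix(samples, variants, calls)


@pytest.fixture(scope="session")
def pulse_sim():
    """A single-pulse 50/50 admixture (G=20) with its sources, 20k variants."""
    gmap = uniform_map(22, 100.0)
    variants = variant_table(20_000, gmap)
    comps = make_component_set({"src1": 0.1, "src2": 0.1}, 20_000, seed=101)
    gm, panel = simulate_admixed(
        comps, [0.5, 0.5], 20, gmap, 100, seed=202, variants=variants, population="admixed"
    )
    return {"gmap": gmap, "variants": variants, "components": comps, "gm": gm, "panel": panel}
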