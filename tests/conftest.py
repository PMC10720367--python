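import numpy as np
import pandas as pd
import pytest

from namqtl import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_map():
    """Two-chromosome toy map with 10 cM spacing."""
    rows = []
    for chrom, length in (("1A", 100.0), ("2B", 60.0)):
        for i, p in enumerate(np.arange(0.0, length + 1, 10.0)):
            rows.append((chrom, f"m_{chrom}_{i}", p, int(p * 1e5) + 1))
    return simdata.GeneticMap(pd.DataFrame(
        rows, columns=["chromosome", "marker_id", "position_cM", "position_bp"]))


@pytest.fixture(scope="session")
def biparental():
    """300 F5 RILs from a single cross, fully polymorphic, no noise."""
    gmap = simdata.GeneticMap(pd.DataFrame({
        "chromosome": ["1A"] * 11,
        "marker_id": [f"m{i}" for i in range(11)],
        "position_cM": np.arange(0.0, 101.0, 10.0),
    }))
    rng = np.random.default_rng(7)
    parents = simdata.make_parents(gmap, rng, donor_ids=("D1",),
                                   donor_poly_rate=1.0)
    sim = simdata.simulate_nam(parents, gmap, simdata.SimConfig(
        n_rils_per_cross=(300,), missing_rate=0.0,
        genotyping_error_rate=0.0, seed=11))
    prog = sim.true_genotypes.subset_lines(~sim.pedigree["is_parent"].to_numpy())
    return gmap, parents, prog


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down default study shared by slower tests."""
    return simdata.simulate_study(seed=42, n_markers=420)
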