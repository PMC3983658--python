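import numpy as np
import pandas as pd
import pytest

import repliphase as rp


@pytest.fixture(scope="session")
def default_dataset():
    """One fully simulated dataset at the default study conditions."""
    params = rp.SimulationParams(seed=7)
    genes, oris, profile, expr, async_expr, truth = rp.simulate_dataset(params)
    return dict(params=params, genes=genes, oris=oris, profile=profile,
                expr=expr, async_expr=async_expr, truth=truth)


@pytest.fixture()
def small_params():
    return rp.SimulationParams(seed=3, n_chrom=2, chrom_length=400_000,
                               n_genes=160, n_oris=20)


def make_genes(rows):
    """rows: (gene_id, chrom, start, end, strand)"""
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand"])


def make_oris(rows):
    """rows: (ori_id, chrom, start, end, status)"""
    return pd.DataFrame(rows, columns=["ori_id", "chrom", "start", "end",
                                       "status"])


def make_profile(positions, trep, chrom="chrI", s_start=0.0, s_end=60.0):
    return rp.TrepProfile(chroms={chrom: (np.asarray(positions, dtype=float),
                                          np.asarray(trep, dtype=float))},
                          s_start=s_start, s_end=s_end)


@pytest.fixture()
def tiny_expr():
    """4 genes x 4 timepoints with one NA."""
    values = pd.DataFrame(
        [[-1.0, 0.0, 2.0, 1.0],
         [0.5, 0.5, 0.5, 0.5],
         [np.nan, 1.0, -1.0, 0.0],
         [0.0, 2.0, 0.0, 2.0]],
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
        columns=[0.0, 10.0, 20.0, 30.0])
    return rp.ExpressionTimecourse(values=values, phases=["G1", "S", "G2", "M"])
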