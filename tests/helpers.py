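"""Shared test-construction helpers."""

import numpy as np
import pandas as pd

from alfasnp.io import CountsTable


def make_counts(ref, var, qual=None, genotypes=None):
    """CountsTable from literal per-site read-count arrays."""
    ref = np.atleast_2d(np.asarray(ref))
    var = np.atleast_2d(np.asarray(var))
    qual = np.full(ref.shape, 30.0) if qual is None else np.atleast_2d(np.asarray(qual, float))
    n, g = ref.shape
    sites = pd.DataFrame(
        {
            "contig": ["c1"] * n,
            "pos0": np.arange(n) * 100,
            "ref_allele": ["A"] * n,
            "var_allele": ["G"] * n,
            "variant_class": ["SNP"] * n,
        }
    )
    return CountsTable(
        sites=sites,
        genotypes=genotypes or [f"g{j}" for j in range(g)],
        ref_reads=ref.astype(np.int64),
        var_reads=var.astype(np.int64),
        mean_var_qual=qual,
    )
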