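import numpy as np
import pandas as pd
import pytest

from atacage import synthetic


def random_interval_set(rng, n_max=8, span=10_000, chroms=("chr1", "chr2")):
    """Random small interval set on a <=10 kb coordinate span."""
    n = rng.integers(1, n_max + 1)
    starts = rng.integers(0, span - 10, n)
    lengths = rng.integers(1, span // 4, n)
    return pd.DataFrame({
        "chrom": rng.choice(chroms, n),
        "start": starts,
        "end": np.minimum(starts + lengths, span),
    })


def coverage_depth(sets, span=10_000, chroms=("chr1", "chr2")):
    """Brute-force per-base depth counter (each set counts once per base)."""
    depth = {c: np.zeros(span, dtype=int) for c in chroms}
    for s in sets:
        seen = {c: np.zeros(span, dtype=bool) for c in chroms}
        for row in s.itertuples():
            seen[row.chrom][row.start:row.end] = True
        for c in chroms:
            depth[c] += seen[c]
    return depth


def depth_to_intervals(depth, thresh):
    """Maximal runs with depth >= thresh, as a sorted interval DataFrame."""
    rows = []
    for c in sorted(depth):
        mask = depth[c] >= thresh
        d = np.diff(mask.astype(int), prepend=0, append=0)
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            rows.append((c, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared by statistics tests (read-only)."""
    return synthetic.generate_cohort(
        synthetic.GeneratorConfig(n_samples=80, n_ocrs=600, n_genes=200, n_cpgs=400, seed=7)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full default-scale cohort (study conditions); generated once."""
    return synthetic.generate_cohort(synthetic.GeneratorConfig(seed=42))
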