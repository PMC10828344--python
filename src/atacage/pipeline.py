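"""End-to-end driver: simulate -> consensus -> count -> qc -> agecorr -> clock CV.

One function runs the whole pipeline at a configurable desk scale from a
single seed and returns every intermediate table, so reproducibility can be
checked byte-for-byte (``digest`` hashes the serialized outputs).
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from . import agecorr, clock, intervals, quantify, synthetic


def run_end_to_end(
    seed: int = 0,
    fragment_cfg: synthetic.FragmentConfig | None = None,
    min_samples: int | None = None,
    contamination: float = 0.1,
    n_groups: int = 5,
    lambda_grid=(0.01, 0.1, 1.0),
    alpha_grid=(0.5,),
    n_samples: int = 60,
    n_ocrs: int = 300,
    n_genes: int = 120,
) -> dict:
    """Small-scale full pipeline; every stage is the library implementation.

    The fragment-level stages (consensus, counting, FRIP/QC) run on the
    fragment generator's output; the statistical stages (age correlations,
    clock CV) run on a matching cohort-level simulation.
    """
    fcfg = fragment_cfg or synthetic.FragmentConfig(seed=seed)
    sim = synthetic.generate_fragments(fcfg)
    if min_samples is None:
        min_samples = max(2, int(0.6 * fcfg.n_samples))
    consensus = intervals.build_consensus(list(sim["peaks"].values()), min_samples)
    counts = quantify.count_cut_sites(sim["fragments"], consensus)
    lengths = (consensus["end"] - consensus["start"]).to_numpy()
    normalized, log_norm = quantify.normalize(counts, lengths)
    qc = pd.DataFrame({
        "sample_id": list(sim["fragments"]),
        "n_alignments": [2 * len(f) for f in sim["fragments"].values()],
        "frip": [quantify.compute_frip(f, consensus) for f in sim["fragments"].values()],
    })
    qc = quantify.qc_filter(qc, depth_min=int(0.5 * 2 * fcfg.n_fragments), frip_min=0.05)
    outliers = quantify.remove_outliers(log_norm, contamination=contamination, seed=seed)

    cohort = synthetic.generate_cohort(synthetic.GeneratorConfig(
        n_samples=n_samples, n_ocrs=n_ocrs, n_genes=n_genes, n_cpgs=200, seed=seed,
    ))
    corr = agecorr.age_correlations(cohort["log_normalized"], cohort["samples"]["age"])
    X = cohort["log_normalized"].T
    ages = pd.Series(cohort["samples"]["age"].to_numpy(), index=X.index)
    folds = clock.assign_groups(ages, k=n_groups, seed=seed)
    report = clock.nested_cv(X, ages, folds, lambda_grid=lambda_grid, alpha_grid=alpha_grid)
    return {
        "consensus": consensus,
        "counts": counts,
        "normalized": normalized,
        "qc": qc,
        "outliers": outliers,
        "age_correlations": corr,
        "cv_predictions": report["predictions"],
        "cv_fold_metrics": report["fold_metrics"],
    }


def digest(results: dict) -> str:
    """SHA-256 over the serialized pipeline outputs (byte-level determinism)."""
    h = hashlib.sha256()
    for key in sorted(results):
        obj = results[key]
        h.update(key.encode())
        if isinstance(obj, pd.DataFrame):
            h.update(obj.to_csv(float_format="%.10g").encode())
        elif isinstance(obj, pd.Series):
            h.update(obj.to_csv(float_format="%.10g").encode())
        else:
            h.update(repr(obj).encode())
    return h.hexdigest()
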