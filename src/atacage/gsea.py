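"""Preranked gene-set enrichment and the OCR→gene ranking procedure.

The ranked list is built from OCR–gene links: per gene, the single OCR whose
accessibility best tracks that gene's expression (|Spearman| across the
samples shared by the ATAC and RNA matrices) is retained, and the gene is
scored by the Spearman correlation of that OCR's accessibility with age.
Enrichment uses the weighted Kolmogorov–Smirnov running sum with a
gene-label permutation null; NES divides ES by the mean |null ES| of
matching sign.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .agecorr import _spearman_vs_vector

logger = logging.getLogger(__name__)


def build_ranked_list_from_atac(
    ocr_gene_links: pd.DataFrame,
    atac_matrix: pd.DataFrame,
    rna_matrix: pd.DataFrame,
    ages: pd.Series,
    mode: str = "best_pair",
    ocr_annotations: pd.Series | None = None,
) -> pd.Series:
    """1:1 OCR→gene ranking: genes scored by their kept OCR's age Spearman.

    mode="best_pair": among a gene's linked OCRs, keep the one maximising
    |Spearman(accessibility, expression)| over the common samples.
    mode="promoter_only": keep only promoter-class pairs (needs
    ``ocr_annotations``); a gene with several promoter OCRs falls back to
    the best-correlated of those.

    Returns a descending pd.Series score indexed by gene.
    """
    common = [s for s in atac_matrix.columns if s in set(rna_matrix.columns)]
    if not common:
        raise ValueError("no common samples between ATAC and RNA matrices")
    ages = pd.Series(ages)
    age_common = ages.reindex(common).to_numpy(dtype=float)

    links = ocr_gene_links.dropna(subset=["gene"])
    links = links[links["gene"].isin(rna_matrix.index)]  # expressed genes only
    links = links[links["ocr_id"].isin(atac_matrix.index)]
    if mode == "promoter_only":
        if ocr_annotations is None:
            raise ValueError("promoter_only mode needs ocr_annotations")
        ann = ocr_annotations.reindex(links["ocr_id"]).to_numpy()
        links = links[(ann == "promoter") | (ann == "promoter_and_enhancer")]
    elif mode != "best_pair":
        raise ValueError(f"unknown mode {mode!r}")
    if len(links) == 0:
        return pd.Series(dtype=float)

    A = atac_matrix.loc[links["ocr_id"], common].to_numpy(dtype=float)
    E = rna_matrix.loc[links["gene"], common].to_numpy(dtype=float)
    # per-pair |Spearman(accessibility, expression)| over common samples
    from scipy import stats

    ra = np.apply_along_axis(stats.rankdata, 1, A)
    re = np.apply_along_axis(stats.rankdata, 1, E)
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    re_c = re - re.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra_c**2).sum(axis=1) * (re_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_r = (ra_c * re_c).sum(axis=1) / denom
    pair_r = np.nan_to_num(pair_r)

    df = links.copy()
    df["abs_pair_r"] = np.abs(pair_r)
    best = (
        df.sort_values(["gene", "abs_pair_r", "ocr_id"], ascending=[True, False, True])
        .groupby("gene", sort=True)
        .head(1)
    )
    age_r, _ = _spearman_vs_vector(
        atac_matrix.loc[best["ocr_id"], common].to_numpy(dtype=float), age_common
    )
    scores = pd.Series(age_r, index=best["gene"].to_numpy(), name="score")
    return scores.sort_values(ascending=False)


def _es_from_positions(
    pos: np.ndarray, w: np.ndarray, n_total: int
) -> np.ndarray:
    """Batch ES from sorted hit positions.

    pos: (B, k) 0-based positions of hits in the ranked list (ascending per
    row); w: (B, k) corresponding nonnegative hit weights; returns (B,) ES,
    the running-sum value of maximal absolute size.
    """
    B, k = pos.shape
    wsum = w.sum(axis=1, keepdims=True)
    wsum = np.where(wsum == 0, 1.0, wsum)  # all-zero weights: hits count 0
    cum_hit = np.cumsum(w, axis=1) / wsum
    miss_step = 1.0 / max(n_total - k, 1)
    m = np.arange(k)[None, :]
    misses_before = (pos - m) * miss_step  # misses preceding hit m
    valley = np.concatenate([np.zeros((B, 1)), cum_hit[:, :-1]], axis=1) - misses_before
    peak = cum_hit - misses_before
    cand = np.concatenate([valley, peak], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


def enrichment_score(
    ranked: pd.Series, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum.

    Hits step up by |score|^p / Σ_hits |score|^p, misses step down by
    1/(N - N_hits); ES is the signed extremum (maximal |value|) of the
    running sum. Scores must be sorted descending with unique gene labels.
    """
    genes = ranked.index.to_numpy()
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list has duplicate genes")
    scores = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    n, nh = len(genes), int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no genes in the ranked list")
    w = np.abs(scores) ** weight_p
    wh = np.where(hit, w, 0.0)
    whsum = wh.sum() or 1.0
    if nh == n:
        running = np.cumsum(wh / whsum)
        return float(running[np.argmax(np.abs(running))]), running
    running = np.cumsum(np.where(hit, wh / whsum, -1.0 / (n - nh)))
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: dict[str, list],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a GMT-style dict with a gene-label permutation null.

    Per term: ES from the running sum; null ES from ``n_perm`` random
    same-size gene sets; NES = ES / mean(|null ES| of the same sign);
    nominal p = fraction of same-sign null ES at least as extreme; q = BH
    over reported terms. Terms with no overlap are skipped with a log line.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    n = len(genes)
    w_all = np.abs(scores) ** weight_p

    null_cache: dict[int, np.ndarray] = {}

    def null_es(k: int) -> np.ndarray:
        if k not in null_cache:
            pos = np.sort(
                np.array([rng.choice(n, size=k, replace=False) for _ in range(n_perm)]),
                axis=1,
            )
            null_cache[k] = _es_from_positions(pos, w_all[pos], n)
        return null_cache[k]

    rows = []
    for term, members in gene_sets.items():
        hit_pos = np.flatnonzero(np.isin(genes, list(members)))
        k = len(hit_pos)
        if k == 0:
            logger.info("term %s skipped: no overlap with ranked list", term)
            continue
        es = float(_es_from_positions(hit_pos[None, :], w_all[hit_pos][None, :], n)[0])
        null = null_es(k)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        if es == 0:
            p = 1.0
        else:
            n_same = max(len(same), 1)
            p = (np.sum(np.abs(same) >= abs(es)) + 1) / (n_same + 1)
        lead = _leading_edge(genes, scores, hit_pos, es, w_all, n)
        rows.append(
            {
                "term_id": term,
                "term_size": k,
                "ES": es,
                "NES": nes,
                "p_value": float(p),
                "leading_edge": lead,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def _leading_edge(genes, scores, hit_pos, es, w_all, n) -> list:
    """Hits at or before (after, for negative ES) the running-sum extremum."""
    running = _running_sum(hit_pos, w_all, n)
    ext = int(np.argmax(np.abs(running)))
    if es >= 0:
        return [genes[i] for i in hit_pos if i <= ext]
    return [genes[i] for i in hit_pos if i >= ext]


def _running_sum(hit_pos: np.ndarray, w_all: np.ndarray, n: int) -> np.ndarray:
    hit = np.zeros(n, dtype=bool)
    hit[hit_pos] = True
    wh = np.where(hit, w_all, 0.0)
    whsum = wh.sum() or 1.0
    nh = len(hit_pos)
    if nh == n:
        return np.cumsum(wh / whsum)
    return np.cumsum(np.where(hit, wh / whsum, -1.0 / (n - nh)))


def read_gmt(path) -> dict[str, list]:
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_ranked_list(ranked: pd.Series, path) -> None:
    ranked.rename("score").rename_axis("gene").to_csv(path, sep="\t")
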