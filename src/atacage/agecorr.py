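"""Genome-wide age-association statistics and cross-modality integration.

Per-feature Spearman correlation with age, Benjamini-Hochberg FDR, and a
three-way classification (opening/up, closing/down, stable at a q-value
threshold); Fisher's exact enrichment of annotation classes among age-
associated features; one-sided two-sample Kolmogorov-Smirnov shift tests;
and the "correlation of correlations" integration of accessibility,
expression and methylation age effects over linked feature pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Q_THRESHOLD_DEFAULT = 0.01


def _spearman_vs_vector(matrix: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman r against y with average-rank ties and t-approx p."""
    n = matrix.shape[1]
    ry = stats.rankdata(y)
    rm = np.apply_along_axis(stats.rankdata, 1, matrix)
    rm_c = rm - rm.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rm_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rm_c @ ry_c) / denom
    constant = ~np.isfinite(r)
    r = np.where(constant, 0.0, np.clip(r, -1.0, 1.0))
    # two-sided p from the t approximation, exact-1 guarded
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(constant, 1.0, np.clip(p, 0.0, 1.0))
    return r, p


def age_correlations(
    matrix: pd.DataFrame,
    ages: np.ndarray | pd.Series,
    q_threshold: float = Q_THRESHOLD_DEFAULT,
    modality: str = "atac",
) -> pd.DataFrame:
    """Feature x sample matrix -> per-feature Spearman-with-age table.

    Columns: feature_id, modality, spearman_r, p_value, q_value (BH over
    all rows), class in {opening, closing, stable}, constant flag.
    Constant features get r=0, p=1, class=stable.
    """
    ages = np.asarray(ages, dtype=float)
    if matrix.shape[1] != len(ages):
        raise ValueError("ages length must match sample columns")
    if len(ages) < 3:
        raise ValueError("need >= 3 samples")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    r, p = _spearman_vs_vector(matrix.to_numpy(dtype=float), ages)
    q = multipletests(p, method="fdr_bh")[1]
    cls = np.where(
        (q < q_threshold) & (r > 0),
        "opening",
        np.where((q < q_threshold) & (r < 0), "closing", "stable"),
    )
    constant = matrix.to_numpy().std(axis=1) == 0
    return pd.DataFrame(
        {
            "feature_id": matrix.index.to_numpy(),
            "modality": modality,
            "spearman_r": r,
            "p_value": p,
            "q_value": q,
            "class": cls,
            "constant": constant,
        }
    )


def annotation_enrichment(
    table: pd.DataFrame,
    ocrs: pd.DataFrame,
    direction: str,
    annotation: str = "enhancer",
) -> dict:
    """Fisher's exact enrichment of an annotation among direction-class OCRs.

    2x2 table: rows = (in direction class, background = all other OCRs),
    columns = (carries the annotation, does not). The annotation predicate
    counts ``promoter_and_enhancer`` as both promoter and enhancer.
    Two-sided test.
    """
    if direction not in ("opening", "closing"):
        raise ValueError("direction must be opening or closing")
    ann = ocrs.set_index("ocr_id")["annotation"]
    tab = table.set_index("feature_id")
    has_ann = ann.isin([annotation, "promoter_and_enhancer"]) if annotation in (
        "promoter",
        "enhancer",
    ) else (ann == annotation)
    in_class = tab["class"].reindex(ann.index) == direction
    if int(in_class.sum()) == 0:
        raise ValueError(f"no OCRs in class {direction!r}")
    a = int((in_class & has_ann).sum())
    b = int((in_class & ~has_ann).sum())
    c = int((~in_class & has_ann).sum())
    d = int((~in_class & ~has_ann).sum())
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "annotation_class": annotation,
        "direction": direction,
        "table": [[a, b], [c, d]],
        "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
        "log_odds": float(np.log(odds)) if 0 < odds < np.inf else (np.inf if odds == np.inf else -np.inf),
        "p_value": float(p),
    }


def ks_shift(
    target_values: np.ndarray, background_values: np.ndarray, direction: str
) -> dict:
    """One-sided two-sample KS shift test.

    direction="greater": alternative is that target values are
    stochastically greater than background, D = max_x (F_bg - F_target);
    direction="less": D = max_x (F_target - F_bg). Asymptotic
    p = exp(-2 * n_eff * D^2) with n_eff = n1*n2/(n1+n2).
    """
    t = np.sort(np.asarray(target_values, dtype=float))
    b = np.sort(np.asarray(background_values, dtype=float))
    if len(t) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values in each sample")
    grid = np.concatenate([t, b])
    ft = np.searchsorted(t, grid, side="right") / len(t)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    if direction == "greater":
        d = float(np.max(fb - ft))
    elif direction == "less":
        d = float(np.max(ft - fb))
    else:
        raise ValueError("direction must be greater or less")
    d = max(d, 0.0)
    n_eff = len(t) * len(b) / (len(t) + len(b))
    p = float(np.exp(-2 * n_eff * d**2))
    return {"D": d, "p_value": min(p, 1.0), "direction": direction, "n_target": len(t), "n_background": len(b)}


def link_cpgs_to_ocrs(cpgs: pd.DataFrame, ocrs: pd.DataFrame) -> pd.DataFrame:
    """Assign each 1-bp CpG position to the OCR containing it.

    ``cpgs`` needs cpg_id, chrom, pos columns. Positions at an OCR's end
    coordinate are outside it (half-open). Returns (cpg_id, ocr_id) rows for
    assigned CpGs only.
    """
    rows = []
    for chrom, grp in cpgs.groupby("chrom"):
        oc = ocrs[ocrs["chrom"] == chrom].sort_values("start")
        if len(oc) == 0:
            continue
        ss, ee = oc["start"].to_numpy(), oc["end"].to_numpy()
        ids = oc["ocr_id"].to_numpy()
        p = grp["pos"].to_numpy()
        j = np.searchsorted(ss, p, side="right") - 1
        inside = (j >= 0) & (p < ee[np.maximum(j, 0)])
        for cpg_id, ok, jj in zip(grp["cpg_id"], inside, j):
            if ok:
                rows.append((cpg_id, ids[jj]))
    return pd.DataFrame(rows, columns=["cpg_id", "ocr_id"])


def correlation_of_correlations(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    links: pd.DataFrame,
    region_class: str | None = None,
    ocr_annotations: pd.Series | None = None,
) -> dict:
    """Pearson r between two per-feature age-correlation vectors over links.

    ``links`` has columns feature_a, feature_b (ids into the two tables);
    each link is one observation (a feature linked n times contributes n
    points). Optionally restrict to links whose feature_a annotation equals
    ``region_class`` (``promoter``/``enhancer`` also match the dual class).
    """
    lk = links.copy()
    if region_class is not None:
        if ocr_annotations is None:
            raise ValueError("region_class filtering needs ocr_annotations")
        ann = ocr_annotations.reindex(lk["feature_a"]).to_numpy()
        if region_class in ("promoter", "enhancer"):
            keep = (ann == region_class) | (ann == "promoter_and_enhancer")
        else:
            keep = ann == region_class
        lk = lk[keep]
    ra = table_a.set_index("feature_id")["spearman_r"].reindex(lk["feature_a"]).to_numpy()
    rb = table_b.set_index("feature_id")["spearman_r"].reindex(lk["feature_b"]).to_numpy()
    ok = np.isfinite(ra) & np.isfinite(rb)
    ra, rb = ra[ok], rb[ok]
    if len(ra) < 3:
        raise ValueError(f"need >= 3 linked pairs with finite r, got {len(ra)}")
    r, p = stats.pearsonr(ra, rb)
    return {"pearson_r": float(r), "p_value": float(p), "n_links": int(len(ra)), "region_class": region_class}
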