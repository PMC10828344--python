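"""Cut-site counting over OCRs, normalization, FRIP and sample QC.

Accessibility is quantified by Tn5 cut sites rather than whole fragments:
each fragment contributes two 1-bp insertion sites, its start and its last
covered base (end - 1). Counts are normalized to densities (per kbp of OCR)
per million reads-in-peaks, so per-sample totals are comparable regardless
of depth. QC combines absolute thresholds (alignments, FRIP) with a robust
multivariate outlier step: an elliptic envelope fitted on the first two
principal components of the log-normalized matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import INTERVAL_COLS, merge_union

logger = logging.getLogger(__name__)

DEPTH_MIN_DEFAULT = 11_000_000  # good-quality alignments
FRIP_MIN_DEFAULT = 0.18


def cut_sites(fragments: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return (chrom codes as object array, positions) of both cut sites.

    A fragment [start, end) yields sites at start and end - 1.
    """
    chroms = np.concatenate([fragments["chrom"].to_numpy()] * 2)
    pos = np.concatenate(
        [fragments["start"].to_numpy(), fragments["end"].to_numpy() - 1]
    )
    return chroms, pos


def _site_ocr_index(chroms, pos, ocrs: pd.DataFrame) -> np.ndarray:
    """Per cut site, the positional index of the containing OCR or -1.

    OCRs are assumed disjoint (a consensus set); sites on chromosomes absent
    from the OCR set are counted as unassigned and logged.
    """
    out = np.full(len(pos), -1, dtype=np.int64)
    known = set(ocrs["chrom"].unique())
    n_unknown_chrom = 0
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        if chrom not in known:
            n_unknown_chrom += int(mask.sum())
            continue
        grp = ocrs[ocrs["chrom"] == chrom].sort_values("start")
        idx = grp.index.to_numpy()
        ss, ee = grp["start"].to_numpy(), grp["end"].to_numpy()
        p = pos[mask]
        j = np.searchsorted(ss, p, side="right") - 1
        inside = (j >= 0) & (p < ee[np.maximum(j, 0)])
        res = np.where(inside, idx[np.maximum(j, 0)], -1)
        out[np.flatnonzero(mask)] = res
    if n_unknown_chrom:
        logger.info("skipped %d cut sites on chromosomes absent from OCR set", n_unknown_chrom)
    return out


def count_cut_sites(
    fragments_by_sample: dict[str, pd.DataFrame], ocrs: pd.DataFrame
) -> pd.DataFrame:
    """OCR x sample matrix of Tn5 cut-site counts.

    A cut site increments an OCR's count iff its 1-bp position lies within
    the OCR; a fragment can contribute 0, 1 or 2 counts.
    """
    ocrs = ocrs.reset_index(drop=True)
    mat = np.zeros((len(ocrs), len(fragments_by_sample)), dtype=np.int64)
    for sj, (sample, frags) in enumerate(fragments_by_sample.items()):
        chroms, pos = cut_sites(frags)
        hit = _site_ocr_index(chroms, pos, ocrs)
        hit = hit[hit >= 0]
        np.add.at(mat[:, sj], hit, 1)
    return pd.DataFrame(mat, index=ocrs["ocr_id"].to_numpy(), columns=list(fragments_by_sample))


def normalize(
    counts: pd.DataFrame, ocr_lengths_bp: np.ndarray | pd.Series, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Density / reads-in-peaks normalization and its log transform.

    density_ij = count_ij / (length_i / 1000)
    normalized_ij = density_ij / (reads_in_peaks_j / 1e6)
    log_normalized = ln(normalized + pseudocount)
    """
    lengths = np.asarray(ocr_lengths_bp, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("OCR lengths must be positive")
    rip = counts.sum(axis=0).to_numpy(dtype=float)
    zero = np.flatnonzero(rip == 0)
    if len(zero):
        raise ValueError(f"all-zero count column(s): {list(counts.columns[zero])}")
    density = counts.to_numpy(dtype=float) / (lengths[:, None] / 1000.0)
    normalized = density / (rip[None, :] / 1e6)
    norm_df = pd.DataFrame(normalized, index=counts.index, columns=counts.columns)
    log_df = pd.DataFrame(
        np.log(normalized + pseudocount), index=counts.index, columns=counts.columns
    )
    return norm_df, log_df


def compute_frip(fragments: pd.DataFrame, ocrs: pd.DataFrame) -> float:
    """Fraction of Tn5 cut sites falling within the (merged) OCR set."""
    if len(fragments) == 0:
        raise ValueError("zero fragments")
    merged = merge_union([ocrs[INTERVAL_COLS]])
    merged = merged.copy()
    merged["ocr_id"] = ""
    chroms, pos = cut_sites(fragments)
    hit = _site_ocr_index(chroms, pos, merged)
    return float((hit >= 0).mean())


def qc_filter(
    sample_qcs: pd.DataFrame,
    depth_min: int = DEPTH_MIN_DEFAULT,
    frip_min: float = FRIP_MIN_DEFAULT,
) -> pd.DataFrame:
    """Low-quality flags: fail iff alignments < depth_min OR frip < frip_min.

    Boundary values pass (failure is phrased strictly below threshold).
    Input needs columns sample_id, n_alignments, frip.
    """
    out = sample_qcs.copy()
    out["pass_depth"] = out["n_alignments"] >= depth_min
    out["pass_frip"] = out["frip"] >= frip_min
    out["pass_qc"] = out["pass_depth"] & out["pass_frip"]
    return out


def remove_outliers(
    log_normalized: pd.DataFrame,
    contamination: float = 0.10,
    seed: int = 0,
) -> pd.Series:
    """Robust outlier flags from an elliptic envelope on the first two PCs.

    Samples (columns) are projected onto the top two principal components of
    the feature-centered log-normalized matrix, then a minimum-covariance-
    determinant ellipse flags roughly ``contamination`` of them. A
    degenerate (zero-variance) projection flags nothing.
    """
    X = log_normalized.to_numpy(dtype=float).T  # samples x features
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need >= 10 samples for robust outlier detection, got {n}")
    if not (0 < contamination < 0.5):
        if contamination == 0:
            return pd.Series(False, index=log_normalized.columns, name="is_outlier")
        raise ValueError("contamination must lie in (0, 0.5)")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        return pd.Series(False, index=log_normalized.columns, name="is_outlier")
    from sklearn.decomposition import PCA
    from sklearn.covariance import EllipticEnvelope

    pcs = PCA(n_components=2, random_state=seed).fit_transform(Xc)
    if np.allclose(pcs.std(axis=0), 0):
        return pd.Series(False, index=log_normalized.columns, name="is_outlier")
    env = EllipticEnvelope(contamination=contamination, random_state=seed)
    flags = env.fit_predict(pcs) == -1
    return pd.Series(flags, index=log_normalized.columns, name="is_outlier")


def read_fragments_bed(path, tn5_shift: bool = False) -> pd.DataFrame:
    """Per-sample fragment BED3 (optionally gzipped).

    ``tn5_shift=True`` applies the (+4, -5) transposase offset to raw
    (unshifted) fragment coordinates; by default fragments are assumed
    already shift-corrected by their producer.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})[INTERVAL_COLS]
    if tn5_shift:
        df["start"] = df["start"] + 4
        df["end"] = df["end"] - 5
        df = df[df["end"] > df["start"]].reset_index(drop=True)
    return df
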