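"""Genomic-interval engine: consensus OCR peakset construction and annotation.

All coordinates are 0-based half-open (BED convention). Interval sets are
pandas DataFrames with at least ``chrom`` (str), ``start`` (int), ``end``
(int) columns; OCR sets additionally carry ``ocr_id``, ``annotation``
(one of ``promoter``, ``enhancer``, ``promoter_and_enhancer``,
``unannotated``) and ``linked_gene``.

The consensus procedure mirrors the standard bulk ATAC-seq recipe: union of
per-sample peak calls, restriction to union peaks containing a region called
in at least ``min_samples`` samples, and removal of peaks touching a
blacklist. Promoters are OCRs within a fixed window of a transcription start
site; enhancers are OCRs overlapping a curated enhancer region; the two
classes may co-occur ("promoter_and_enhancer").
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]

ANNOTATION_CLASSES = (
    "promoter",
    "enhancer",
    "promoter_and_enhancer",
    "unannotated",
)


class MalformedIntervalError(ValueError):
    """An interval with end <= start or start < 0."""


def _as_frame(intervals: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(intervals)
    missing = [c for c in INTERVAL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"interval set lacks columns {missing}")
    return df


def validate_intervals(intervals: pd.DataFrame, label: str = "interval set") -> pd.DataFrame:
    """Check half-open sanity (start >= 0, end > start); raise naming offenders."""
    df = _as_frame(intervals)
    bad = df[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        ids = [f"{r.chrom}:{r.start}-{r.end}" for r in bad.head(5).itertuples()]
        raise MalformedIntervalError(f"{label}: malformed intervals (end<=start or start<0): {ids}")
    return df


def sort_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    return (
        _as_frame(intervals)
        .sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )


def _merge_sorted_chrom(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sweep-line merge of sorted-by-start intervals on one chromosome.

    Book-ended intervals (next.start == current.end) are merged.
    """
    if len(starts) == 0:
        return starts, ends
    # run-max of ends; a new block starts where start > max(end of previous)
    run_end = np.maximum.accumulate(ends)
    new_block = np.empty(len(starts), dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > run_end[:-1]
    out_starts = starts[new_block]
    out_ends = np.maximum.reduceat(ends, np.flatnonzero(new_block))
    return out_starts, out_ends


def merge_union(peak_sets: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Minimal disjoint interval set covering the union of all input sets.

    Overlapping or book-ended intervals are merged. Raises
    :class:`MalformedIntervalError` on any end <= start.
    """
    frames = [validate_intervals(s, f"peak set {i}") for i, s in enumerate(peak_sets)]
    if not frames:
        return pd.DataFrame(columns=INTERVAL_COLS)
    allpeaks = sort_intervals(pd.concat([f[INTERVAL_COLS] for f in frames], ignore_index=True))
    out = []
    for chrom, grp in allpeaks.groupby("chrom", sort=True):
        s, e = _merge_sorted_chrom(grp["start"].to_numpy(), grp["end"].to_numpy())
        out.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if not out:
        return pd.DataFrame(columns=INTERVAL_COLS)
    return pd.concat(out, ignore_index=True)


def reliably_called_regions(
    peak_sets: list[pd.DataFrame], min_samples: int
) -> pd.DataFrame:
    """Maximal sub-regions where at least ``min_samples`` peak sets overlap.

    Multi-way intersection by sweep-line depth counting; each input set is
    self-merged first so it contributes depth at most 1 per base.
    """
    n = len(peak_sets)
    if min_samples < 1 or min_samples > n:
        raise ValueError(f"min_samples={min_samples} outside [1, {n}]")
    merged_sets = [merge_union([s]) for s in peak_sets]
    events: dict[str, list[np.ndarray]] = {}
    for ms in merged_sets:
        for chrom, grp in ms.groupby("chrom"):
            events.setdefault(chrom, []).append(
                np.stack([grp["start"].to_numpy(), grp["end"].to_numpy()])
            )
    out = []
    for chrom in sorted(events):
        se = np.concatenate(events[chrom], axis=1)
        pos = np.concatenate([se[0], se[1]])
        delta = np.concatenate([np.ones(se.shape[1], int), -np.ones(se.shape[1], int)])
        order = np.argsort(pos, kind="mergesort")
        pos, delta = pos[order], delta[order]
        # collapse equal positions, then depth between consecutive breakpoints
        upos, idx = np.unique(pos, return_inverse=True)
        net = np.zeros(len(upos), int)
        np.add.at(net, idx, delta)
        depth = np.cumsum(net)[:-1]  # depth on [upos[i], upos[i+1])
        keep = depth >= min_samples
        if not keep.any():
            continue
        s, e = _merge_sorted_chrom(upos[:-1][keep], upos[1:][keep])
        out.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if not out:
        return pd.DataFrame(columns=INTERVAL_COLS)
    return pd.concat(out, ignore_index=True)


def _overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: >=1 bp intersection with any subject interval."""
    hits = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return hits
    subj = merge_union([subject])
    for chrom, sgrp in subj.groupby("chrom"):
        qmask = (query["chrom"] == chrom).to_numpy()
        if not qmask.any():
            continue
        qs = query.loc[qmask, "start"].to_numpy()
        qe = query.loc[qmask, "end"].to_numpy()
        ss = sgrp["start"].to_numpy()
        se = sgrp["end"].to_numpy()
        # disjoint sorted subject: query overlaps iff the first subject with
        # end > qs has start < qe
        j = np.searchsorted(se, qs, side="right")
        ok = (j < len(ss)) & (np.where(j < len(ss), ss[np.minimum(j, len(ss) - 1)], 0) < qe)
        hits[np.flatnonzero(qmask)] = ok
    return hits


def build_consensus(
    peak_sets: list[pd.DataFrame],
    min_samples: int,
    blacklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Consensus OCR set from per-sample peak calls.

    Union peaks are kept iff they overlap (>=1 bp) a region called in at
    least ``min_samples`` samples; peaks overlapping the blacklist by >=1 bp
    are then removed. OCR ids are ``chrom:start-end``.
    """
    union = merge_union(peak_sets)
    reliable = reliably_called_regions(peak_sets, min_samples)
    keep = _overlaps_any(union, reliable)
    ocrs = union[keep].reset_index(drop=True)
    if blacklist is not None and len(blacklist):
        banned = _overlaps_any(ocrs, validate_intervals(blacklist, "blacklist"))
        ocrs = ocrs[~banned].reset_index(drop=True)
    if len(ocrs) == 0:
        import warnings

        warnings.warn("consensus peak set is empty", stacklevel=2)
    ocrs = ocrs.copy()
    ocrs["ocr_id"] = [f"{c}:{s}-{e}" for c, s, e in zip(ocrs["chrom"], ocrs["start"], ocrs["end"])]
    return ocrs


def annotate(
    ocrs: pd.DataFrame,
    genes: pd.DataFrame,
    enhancers: pd.DataFrame | None,
    promoter_window_bp: int = 1000,
) -> pd.DataFrame:
    """Assign each OCR one of four mutually exclusive annotation classes.

    promoter: the OCR intersects ``[tss - w, tss + w]`` (closed on both
    ends) for some TSS; enhancer: >=1 bp overlap with an enhancer region;
    both criteria -> ``promoter_and_enhancer``; neither -> ``unannotated``.

    ``genes`` needs columns gene, chrom, tss (0-based position), strand.
    """
    if promoter_window_bp <= 0:
        raise ValueError("promoter_window_bp must be > 0")
    ocrs = ocrs.reset_index(drop=True)
    # promoter windows as half-open intervals [tss-w, tss+w+1)
    win = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(genes["tss"].to_numpy() - promoter_window_bp, 0),
            "end": genes["tss"].to_numpy() + promoter_window_bp + 1,
        }
    )
    is_prom = _overlaps_any(ocrs, win)
    if enhancers is not None and len(enhancers):
        is_enh = _overlaps_any(ocrs, enhancers[INTERVAL_COLS])
    else:
        is_enh = np.zeros(len(ocrs), dtype=bool)
    cls = np.where(
        is_prom & is_enh,
        "promoter_and_enhancer",
        np.where(is_prom, "promoter", np.where(is_enh, "enhancer", "unannotated")),
    )
    out = ocrs.copy()
    out["annotation"] = cls
    out["length_bp"] = out["end"] - out["start"]
    return out


def link_genes(
    ocrs: pd.DataFrame,
    genes: pd.DataFrame,
    links: pd.DataFrame | None = None,
    mode: Literal["nearest", "link_table"] = "nearest",
) -> pd.DataFrame:
    """Map OCRs to genes.

    nearest: exactly one gene per OCR, minimising |OCR midpoint - TSS|
    (ties broken by lexicographically smallest gene symbol; TSS on another
    chromosome never matches). link_table: 0..n genes per OCR via >=1 bp
    overlap with linked enhancer records (columns chrom,start,end,gene).

    Returns a long DataFrame (ocr_id, gene).
    """
    if genes is None or len(genes) == 0:
        raise ValueError("empty gene annotation")
    if mode == "nearest":
        rows = []
        for chrom, grp in ocrs.groupby("chrom"):
            g = genes[genes["chrom"] == chrom]
            if len(g) == 0:
                continue
            g = g.sort_values(["tss", "gene"], kind="mergesort")
            tss = g["tss"].to_numpy()
            mid = ((grp["start"] + grp["end"]) // 2).to_numpy()
            # candidates: insertion neighbours; resolve tie by symbol
            j = np.searchsorted(tss, mid)
            for ocr_id, m, jj in zip(grp["ocr_id"], mid, j):
                cand = [k for k in (jj - 1, jj) if 0 <= k < len(tss)]
                dists = [abs(int(tss[k]) - int(m)) for k in cand]
                dmin = min(dists)
                # among ALL tss at distance dmin pick smallest symbol
                best = sorted(
                    g["gene"].to_numpy()[np.abs(tss - m) == dmin]
                )[0]
                rows.append((ocr_id, best))
        return pd.DataFrame(rows, columns=["ocr_id", "gene"])
    elif mode == "link_table":
        if links is None or len(links) == 0:
            return pd.DataFrame(columns=["ocr_id", "gene"])
        rows = []
        for gene, lg in links.groupby("gene"):
            hit = _overlaps_any(ocrs, lg[INTERVAL_COLS])
            for ocr_id in ocrs.loc[hit, "ocr_id"]:
                rows.append((ocr_id, gene))
        return (
            pd.DataFrame(rows, columns=["ocr_id", "gene"])
            .drop_duplicates()
            .sort_values(["ocr_id", "gene"])
            .reset_index(drop=True)
        )
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Readers / writers (tab-separated, headerless BED family)

def read_bed(path) -> pd.DataFrame:
    """BED3+ (tab-separated, no header); extra columns ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})[INTERVAL_COLS]
    return validate_intervals(df, str(path))


def read_narrowpeak(path) -> pd.DataFrame:
    """MACS2 narrowPeak; the summit column is intentionally ignored."""
    return read_bed(path)


def read_tss_table(path) -> pd.DataFrame:
    """TSV with header: gene, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "chrom", "tss", "strand"}
    if not need.issubset(df.columns):
        raise ValueError(f"TSS table must have columns {sorted(need)}")
    return df


def read_enhancer_links(path) -> pd.DataFrame:
    """TSV with header: chrom, start, end, gene, tissue."""
    df = pd.read_csv(path, sep="\t")
    validate_intervals(df, str(path))
    return df


def write_ocr_bed(ocrs: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "ocr_id"]
    if "annotation" in ocrs.columns:
        cols.append("annotation")
    ocrs[cols].to_csv(path, sep="\t", header=False, index=False)
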