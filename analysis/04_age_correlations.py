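#!/usr/bin/env python
"""Genome-wide age associations and the multi-omic integration analysis.

Computes per-feature Spearman correlations with age (FDR < 0.01 classes)
for accessibility, expression and methylation; Fisher enrichment of
annotation classes among opening/closing OCRs; the KS shift of expression
age-correlations for genes behind opening/closing promoters; and the
cross-modality correlation-of-correlations matrix.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from atacage import agecorr, synthetic


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--fdr", type=float, default=0.01)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.generate_cohort(synthetic.GeneratorConfig(seed=args.seed))
    ages = cohort["samples"]["age"]
    acc = agecorr.age_correlations(cohort["log_normalized"], ages, q_threshold=args.fdr)
    rna = agecorr.age_correlations(cohort["expression"], ages, args.fdr, modality="rna")
    meth = agecorr.age_correlations(cohort["methylation"], ages, args.fdr, modality="methylation")

    n_open = int((acc["class"] == "opening").sum())
    n_close = int((acc["class"] == "closing").sum())
    print(f"accessibility: {n_open} opening, {n_close} closing of {len(acc)} OCRs "
          f"(FDR < {args.fdr})")
    print(f"expression: {(rna['class']=='opening').sum()} up, "
          f"{(rna['class']=='closing').sum()} down of {len(rna)} genes")

    enrich = []
    for direction in ("opening", "closing"):
        for annotation in ("promoter", "enhancer"):
            e = agecorr.annotation_enrichment(acc, cohort["ocrs"], direction, annotation)
            e.pop("table")
            enrich.append(e)
            print(f"  {annotation} in {direction}: OR={e['odds_ratio']:.2f} p={e['p_value']:.3g}")

    # expression shifts for genes behind opening/closing promoters
    tocr = cohort["truth"]["ocr"]
    prom = tocr[tocr["annotation"].isin(["promoter", "promoter_and_enhancer"])].dropna(
        subset=["linked_gene"])
    acc_cls = acc.set_index("feature_id")["class"]
    rna_r = rna.set_index("feature_id")["spearman_r"]
    ks_results = {}
    for direction, side in (("opening", "greater"), ("closing", "less")):
        genes = prom.loc[acc_cls.reindex(prom["ocr_id"]).to_numpy() == direction, "linked_gene"]
        target = rna_r.reindex(genes.unique()).dropna()
        background = rna_r.drop(index=target.index, errors="ignore")
        ks = agecorr.ks_shift(target.to_numpy(), background.to_numpy(), side)
        ks_results[direction] = ks
        print(f"  genes behind {direction} promoters: KS D={ks['D']:.2f} p={ks['p_value']:.2g}")

    links = tocr.dropna(subset=["linked_gene"]).rename(
        columns={"ocr_id": "feature_a", "linked_gene": "feature_b"})[["feature_a", "feature_b"]]
    ann = cohort["ocrs"].set_index("ocr_id")["annotation"]
    cross = {}
    for cls in ("promoter", "enhancer"):
        cross[f"acc_expr_{cls}"] = agecorr.correlation_of_correlations(acc, rna, links, cls, ann)
    cl = cohort["truth"]["cpg"][cohort["truth"]["cpg"]["host_ocr"] != ""].copy()
    mlinks = cl.rename(columns={"cpg_id": "feature_a", "host_ocr": "feature_b"})[
        ["feature_a", "feature_b"]]
    host_ann = ann.reindex(mlinks["feature_b"]).to_numpy()
    for cls in ("promoter", "enhancer"):
        keep = (host_ann == cls) | (host_ann == "promoter_and_enhancer")
        cross[f"meth_acc_{cls}"] = agecorr.correlation_of_correlations(meth, acc, mlinks[keep])
    hostg = tocr.set_index("ocr_id")["linked_gene"]
    cl["feature_b"] = hostg.reindex(cl["host_ocr"]).to_numpy()
    me = cl.dropna(subset=["feature_b"]).rename(columns={"cpg_id": "feature_a"})
    cross["meth_expr"] = agecorr.correlation_of_correlations(meth, rna, me[["feature_a", "feature_b"]])
    for k, v in cross.items():
        print(f"  age-corr coupling {k}: r={v['pearson_r']:.3f} (n={v['n_links']})")

    acc.round(5).to_csv(out / "age_correlations_atac.tsv", sep="\t", index=False)
    summary = {
        "n_opening": n_open, "n_closing": n_close, "fdr": args.fdr,
        "enrichment": enrich,
        "ks_shifts": {k: {kk: vv for kk, vv in v.items()} for k, v in ks_results.items()},
        "cross_modality": {k: {"pearson_r": v["pearson_r"], "n_links": v["n_links"]}
                           for k, v in cross.items()},
    }
    (out / "age_correlation_summary.json").write_text(json.dumps(summary, indent=1, default=float))
    print(f"wrote {out/'age_correlations_atac.tsv'} and {out/'age_correlation_summary.json'}")


if __name__ == "__main__":
    main()
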