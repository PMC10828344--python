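#!/usr/bin/env python
"""Generate the synthetic PBMC aging cohort that drives all later steps.

Writes the sample table (ages, sex, condition, flow-cytometry-style cell
fractions) and small summaries of the planted ground truth to results/.
The full matrices are regenerated deterministically by each downstream
script from the same seed, so nothing bulky needs to be stored.
"""

import argparse
import json
from pathlib import Path

from atacage import synthetic


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.GeneratorConfig(seed=args.seed)
    cohort = synthetic.generate_cohort(cfg)

    cohort["samples"].round(4).to_csv(out / "samples.tsv", sep="\t", index=False)
    truth_counts = cohort["truth"]["gene"].groupby(["class", "tier"]).size()
    ann_counts = cohort["ocrs"]["annotation"].value_counts()
    summary = {
        "config": synthetic.config_to_dict(cfg),
        "n_samples": int(cfg.n_samples),
        "age_min": float(cohort["samples"]["age"].min()),
        "age_max": float(cohort["samples"]["age"].max()),
        "ocr_annotation_counts": {k: int(v) for k, v in ann_counts.items()},
        "planted_gene_classes": {f"{c}/{t}": int(n) for (c, t), n in truth_counts.items()},
    }
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"cohort: {cfg.n_samples} samples, ages "
          f"{summary['age_min']:.0f}-{summary['age_max']:.0f}, {cfg.n_ocrs} OCRs "
          f"({dict(ann_counts)})")
    print(f"planted aging genes: {summary['planted_gene_classes']}")
    print(f"wrote {out/'samples.tsv'} and {out/'cohort_summary.json'}")


if __name__ == "__main__":
    main()
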