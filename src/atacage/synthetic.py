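"""Synthetic PBMC aging-cohort generator with recoverable ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale:

* donor ages uniform over a wide range, with sex and an optional condition
  label;
* flow-cytometry-style cell fractions from a logistic-normal model whose
  NK and CD8 T slopes reproduce the mild composition-age correlations seen
  in blood (NK up, CD8 T down);
* a consensus-style OCR universe laid out on synthetic chromosomes with
  promoter / enhancer / dual / unannotated classes and OCR-gene links;
* cell-intrinsic aging effects planted at a minority of genes in two
  effect-size tiers, propagated coherently to the gene's promoter and
  (attenuated) enhancer OCRs, so accessibility-expression age-effect
  coupling is stronger at promoters than enhancers;
* CpG methylation slopes anti-coupled to the host OCR's accessibility
  effect (more strongly at enhancers), and only indirectly - hence weakly -
  coupled to expression;
* negative-binomial cut-site counts with per-sample library sizes, plus
  composition-driven nuisance variance that is linear in the measured cell
  fractions (and therefore removable by composition correction);
* an optional condition subgroup shifted along the planted aging axis by a
  configurable number of years.

Every planted quantity is returned in truth tables keyed by feature id.
All randomness flows from one seed through named substreams, so layers are
independently reproducible and identical configs give identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import quantify

LEAF_POPULATIONS = ("monocytes", "granulocytes", "B", "NK", "CD4T", "CD8T")
ALL_POPULATIONS = ("monocytes", "granulocytes", "lymphocytes", "T", "CD4T", "CD8T", "B", "NK")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort (defaults ARE the conditions)."""

    n_samples: int = 150
    n_ocrs: int = 5000
    n_genes: int = 1500
    n_cpgs: int = 3000
    age_range: tuple = (20.0, 74.0)
    # annotation mix (exclusive classes): promoter-only, enhancer-only, dual, unannotated
    class_fractions: tuple = (0.191, 0.532, 0.050, 0.227)
    # logistic-normal composition model
    baseline_fractions: tuple = (0.20, 0.03, 0.12, 0.10, 0.35, 0.20)  # LEAF_POPULATIONS order
    comp_age_slopes: tuple = (0.0, 0.0, 0.0, 0.0070, 0.0, -0.0059)  # per-year latent slopes
    comp_noise_sd: float = 0.35  # logistic-normal latent sd
    # planted cell-intrinsic aging effects (gene level)
    frac_opening: float = 0.033
    frac_closing: float = 0.047
    tier_strong: float = 0.50   # target Spearman-with-age magnitude
    tier_weak: float = 0.25
    background_effect_sd: float = 0.18  # continuous background aging rates
    # cross-modality coupling (age-effect correlations)
    rho_promoter: float = 0.32
    rho_enhancer: float = 0.25
    rho_meth_acc_enhancer: float = -0.20
    rho_meth_acc_promoter: float = -0.045
    # noise model
    count_dispersion: float = 0.05
    library_log_sd: float = 0.30
    intrinsic_noise_sd: float = 0.30   # per-OCR log-scale residual sd
    comp_weight_sd: float = 1.5        # composition loading sd (on fraction deviations)
    comp_sensitive_frac: float = 0.4   # OCRs carrying composition loadings
    expr_noise_sd: float = 0.40
    meth_noise_sd: float = 0.50
    sex_effect_sd: float = 0.20
    sex_sensitive_frac: float = 0.10
    frac_female: float = 0.26
    # condition subgroup
    condition_fraction: float = 0.0
    condition_effect_years: float = 5.0
    # CpG placement
    frac_cpg_in_ocr: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_opening <= 1 and 0 <= self.frac_closing <= 1):
            raise ValueError("planted fractions must lie in [0,1]")
        if self.frac_opening + self.frac_closing > 1:
            raise ValueError("frac_opening + frac_closing must be <= 1")
        if abs(sum(self.baseline_fractions) - 1.0) > 1e-9:
            raise ValueError("baseline cell fractions must sum to 1")
        for t in (self.tier_strong, self.tier_weak):
            if not 0 <= t < 1:
                raise ValueError("effect tiers are target |Spearman r| and must lie in [0,1)")
        for r in (self.rho_promoter, self.rho_enhancer,
                  self.rho_meth_acc_enhancer, self.rho_meth_acc_promoter):
            if not -1 < r < 1:
                raise ValueError("coupling rho outside (-1, 1)")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent, reproducible per data layer."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Layout

def _build_universe(cfg: GeneratorConfig, rng: np.random.Generator):
    """OCR coordinates, classes, gene links, TSS table, enhancer records."""
    M = cfg.n_ocrs
    n_po, n_eo, n_du, _ = (int(round(f * M)) for f in cfg.class_fractions)
    n_un = M - n_po - n_eo - n_du
    n_prom_genes = n_po + n_du
    if n_prom_genes > cfg.n_genes:
        raise ValueError("class fractions need more promoter genes than n_genes")

    genes = [f"G{g:05d}" for g in range(cfg.n_genes)]
    chroms = np.array([f"chr{g % 5 + 1}" for g in range(cfg.n_genes)])
    tss = 5000 + (np.arange(cfg.n_genes) // 5) * 30000
    tss_table = pd.DataFrame({"gene": genes, "chrom": chroms, "tss": tss,
                              "strand": np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-")})

    rows = []  # chrom, start, end, class, gene
    prom_gene_idx = rng.permutation(cfg.n_genes)[:n_prom_genes]
    dual_set = set(prom_gene_idx[:n_du])
    for g in prom_gene_idx:
        cls = "promoter_and_enhancer" if g in dual_set else "promoter"
        rows.append((chroms[g], tss[g] - 400, tss[g] + 400, cls, genes[g]))
    # enhancer-only OCRs dealt round-robin over all genes, <=4 slots each
    eg = [g for k in range(4) for g in range(cfg.n_genes)][:n_eo]
    slot_count: dict[int, int] = {}
    for g in eg:
        k = slot_count.get(g, 0)
        slot_count[g] = k + 1
        start = tss[g] + 4000 + k * 1200
        rows.append((chroms[g], start, start + 400, "enhancer", genes[g]))
    for u in range(n_un):
        g = u % cfg.n_genes
        start = tss[g] + 16000 + (u // cfg.n_genes) * 900
        rows.append((chroms[g], start, start + 400, "unannotated", None))

    ocrs = pd.DataFrame(rows, columns=["chrom", "start", "end", "annotation", "linked_gene"])
    ocrs = ocrs.sort_values(["chrom", "start"]).reset_index(drop=True)
    ocrs["ocr_id"] = [f"{c}:{s}-{e}" for c, s, e in zip(ocrs["chrom"], ocrs["start"], ocrs["end"])]
    ocrs["length_bp"] = ocrs["end"] - ocrs["start"]
    enh_mask = ocrs["annotation"].isin(["enhancer", "promoter_and_enhancer"])
    enhancer_records = ocrs.loc[enh_mask, ["chrom", "start", "end", "linked_gene"]].rename(
        columns={"linked_gene": "gene"}
    )
    enhancer_records["tissue"] = "blood"
    return ocrs, tss_table, enhancer_records.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohort

def _sample_table(cfg: GeneratorConfig, seed: int) -> pd.DataFrame:
    rng_age = _rng(seed, "ages")
    rng_sex = _rng(seed, "sex")
    rng_comp = _rng(seed, "composition")
    rng_cond = _rng(seed, "condition")
    n = cfg.n_samples
    ages = rng_age.uniform(*cfg.age_range, size=n)
    sex = np.where(rng_sex.random(n) < cfg.frac_female, "F", "M")
    cond = np.where(rng_cond.random(n) < cfg.condition_fraction, "positive", "negative")

    base = np.log(np.asarray(cfg.baseline_fractions))
    slopes = np.asarray(cfg.comp_age_slopes)
    eta = base[None, :] + slopes[None, :] * (ages[:, None] - ages.mean()) \
        + rng_comp.normal(0, cfg.comp_noise_sd, size=(n, len(base)))
    f = np.exp(eta)
    f = f / f.sum(axis=1, keepdims=True)
    leaf = pd.DataFrame(f, columns=list(LEAF_POPULATIONS))
    tbl = pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n)],
        "age": ages, "sex": sex, "condition": cond,
    })
    tbl["T"] = leaf["CD4T"] + leaf["CD8T"]
    tbl["lymphocytes"] = tbl["T"] + leaf["B"] + leaf["NK"]
    for c in LEAF_POPULATIONS:
        tbl[c] = leaf[c]
    return tbl


def _gene_effects(cfg: GeneratorConfig, seed: int, n_genes: int):
    """Per-gene aging rate t_g (Spearman-r scale) and tier/class labels."""
    rng = _rng(seed, "gene_effects")
    cls = np.array(["stable"] * n_genes, dtype=object)
    n_op = int(round(cfg.frac_opening * n_genes))
    n_cl = int(round(cfg.frac_closing * n_genes))
    planted = rng.permutation(n_genes)[: n_op + n_cl]
    cls[planted[:n_op]] = "opening"
    cls[planted[n_op:]] = "closing"
    tier = np.array(["none"] * n_genes, dtype=object)
    mag = np.zeros(n_genes)
    for idxs in (planted[:n_op], planted[n_op:]):
        half = len(idxs) // 2
        shuffled = rng.permutation(idxs)
        tier[shuffled[:half]] = "strong"
        tier[shuffled[half:]] = "weak"
        mag[shuffled[:half]] = cfg.tier_strong
        mag[shuffled[half:]] = cfg.tier_weak
    sign = np.where(cls == "opening", 1.0, np.where(cls == "closing", -1.0, 0.0))
    t = sign * mag + rng.normal(0, cfg.background_effect_sd, n_genes)
    return t, cls, tier


def generate_cohort(cfg: GeneratorConfig):
    """Full synthetic cohort.

    Returns dict with: ocrs (annotated OCR table), counts, normalized,
    log_normalized (OCR x sample), expression (gene x sample), methylation
    (CpG x sample betas), cpg_table (coordinates), samples (SampleTable),
    tss, enhancer_links, and truth (per-OCR / per-gene / per-CpG tables).
    """
    seed = cfg.seed
    ocrs, tss_table, enh_records = _build_universe(cfg, _rng(seed, "universe"))
    samples = _sample_table(cfg, seed)
    n, M, G = cfg.n_samples, len(ocrs), cfg.n_genes

    ages = samples["age"].to_numpy()
    z_age = (ages - ages.mean()) / ages.std()
    age_sd = ages.std()

    t_gene, cls_gene, tier_gene = _gene_effects(cfg, seed, G)
    gene_pos = {g: i for i, g in enumerate(tss_table["gene"])}

    # per-OCR target aging rate (Spearman-r scale)
    rng_ocr = _rng(seed, "ocr_effects")
    sigma_t = np.sqrt(
        (cfg.frac_opening + cfg.frac_closing) * (cfg.tier_strong**2 + cfg.tier_weak**2) / 2
        + cfg.background_effect_sd**2
    )
    sigma_t = max(sigma_t, 1e-12)  # null configs: all effects identically zero
    q_enh = cfg.rho_enhancer / cfg.rho_promoter  # enhancer degradation of the gene axis
    r_ocr = np.zeros(M)
    for i, (ann, gname) in enumerate(zip(ocrs["annotation"], ocrs["linked_gene"])):
        if gname is None or (isinstance(gname, float) and np.isnan(gname)):
            r_ocr[i] = rng_ocr.normal(0, sigma_t)
        elif ann in ("promoter", "promoter_and_enhancer"):
            r_ocr[i] = t_gene[gene_pos[gname]]
        else:  # enhancer
            r_ocr[i] = q_enh * t_gene[gene_pos[gname]] + np.sqrt(max(1 - q_enh**2, 0.0)) \
                * sigma_t * rng_ocr.standard_normal()
    r_ocr = np.clip(r_ocr, -0.95, 0.95)

    # expression age effects: coupled to the gene axis at rho_promoter
    rng_expr = _rng(seed, "expression")
    rho_p = cfg.rho_promoter
    r_gene = rho_p * t_gene / sigma_t * sigma_t + np.sqrt(1 - rho_p**2) * sigma_t \
        * rng_expr.standard_normal(G)
    r_gene = np.clip(r_gene, -0.95, 0.95)

    # --- accessibility latent, counts ------------------------------------
    rng_acc = _rng(seed, "accessibility")
    leafF = samples[list(LEAF_POPULATIONS)].to_numpy()
    dF = leafF - leafF.mean(axis=0, keepdims=True)  # n x 6
    comp_w = np.zeros((M, len(LEAF_POPULATIONS)))
    comp_sensitive = rng_acc.random(M) < cfg.comp_sensitive_frac
    which_pop = rng_acc.integers(0, len(LEAF_POPULATIONS), M)
    comp_w[np.arange(M), which_pop] = rng_acc.normal(0, cfg.comp_weight_sd, M)
    comp_w[~comp_sensitive] = 0.0

    sex_w = np.zeros(M)
    sex_sensitive = rng_acc.random(M) < cfg.sex_sensitive_frac
    sex_w[sex_sensitive] = rng_acc.normal(0, cfg.sex_effect_sd, int(sex_sensitive.sum()))
    is_f = (samples["sex"] == "F").to_numpy().astype(float)

    comp_var = (comp_w**2 @ dF.var(axis=0))
    noise_sd = np.sqrt(cfg.intrinsic_noise_sd**2 + comp_var
                       + cfg.count_dispersion + 0.005)  # approx NB log-noise
    beta = noise_sd * r_ocr / np.sqrt(1 - r_ocr**2)

    cond_ind = (samples["condition"] == "positive").to_numpy().astype(float)
    age_axis = z_age[None, :] + (cfg.condition_effect_years / age_sd) * cond_ind[None, :]

    L = (beta[:, None] * age_axis
         + comp_w @ dF.T
         + sex_w[:, None] * is_f[None, :]
         + rng_acc.normal(0, cfg.intrinsic_noise_sd, size=(M, n)))
    logbase = rng_acc.uniform(np.log(50), np.log(500), M)
    lib = np.exp(rng_acc.normal(0, cfg.library_log_sd, n))
    mean = np.exp(logbase[:, None] + L) * lib[None, :]
    shape = 1.0 / cfg.count_dispersion
    lam = rng_acc.gamma(shape, mean / shape)
    counts = rng_acc.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=ocrs["ocr_id"].to_numpy(),
                             columns=samples["sample_id"].to_numpy())
    normalized, log_normalized = quantify.normalize(counts_df, ocrs["length_bp"].to_numpy())

    # --- expression -------------------------------------------------------
    beta_e = cfg.expr_noise_sd * r_gene / np.sqrt(1 - r_gene**2)
    E = (rng_expr.normal(5.0, 1.5, G)[:, None]
         + beta_e[:, None] * z_age[None, :]
         + rng_expr.normal(0, cfg.expr_noise_sd, size=(G, n)))
    expression = pd.DataFrame(E, index=tss_table["gene"].to_numpy(),
                              columns=samples["sample_id"].to_numpy())

    # --- methylation ------------------------------------------------------
    rng_meth = _rng(seed, "methylation")
    n_in = int(round(cfg.frac_cpg_in_ocr * cfg.n_cpgs))
    host_idx = rng_meth.integers(0, M, n_in)
    in_pos = (ocrs["start"].to_numpy()[host_idx]
              + rng_meth.integers(0, 400, n_in))
    out_g = rng_meth.integers(0, G, cfg.n_cpgs - n_in)
    out_pos = (tss_table["tss"].to_numpy()[out_g] + 22000
               + rng_meth.integers(0, 3000, cfg.n_cpgs - n_in))
    cpg_table = pd.DataFrame({
        "cpg_id": [f"cg{i:06d}" for i in range(cfg.n_cpgs)],
        "chrom": np.concatenate([ocrs["chrom"].to_numpy()[host_idx],
                                 tss_table["chrom"].to_numpy()[out_g]]),
        "pos": np.concatenate([in_pos, out_pos]),
        "host_ocr": np.concatenate([ocrs["ocr_id"].to_numpy()[host_idx],
                                    np.full(cfg.n_cpgs - n_in, "", dtype=object)]),
    })
    host_ann = np.concatenate([ocrs["annotation"].to_numpy()[host_idx],
                               np.full(cfg.n_cpgs - n_in, "none", dtype=object)])
    rho_m = np.where(np.isin(host_ann, ["enhancer"]), cfg.rho_meth_acc_enhancer,
                     np.where(np.isin(host_ann, ["promoter", "promoter_and_enhancer"]),
                              cfg.rho_meth_acc_promoter, 0.0))
    host_r = np.concatenate([r_ocr[host_idx], np.zeros(cfg.n_cpgs - n_in)])
    sigma_r = max(float(np.std(r_ocr)), 1e-9)
    r_cpg = rho_m * host_r / sigma_r * sigma_r + np.sqrt(1 - rho_m**2) * sigma_r \
        * rng_meth.standard_normal(cfg.n_cpgs)
    r_cpg = np.clip(r_cpg, -0.95, 0.95)
    beta_m = cfg.meth_noise_sd * r_cpg / np.sqrt(1 - r_cpg**2)
    lat = (rng_meth.normal(0, 1.2, cfg.n_cpgs)[:, None]
           + beta_m[:, None] * z_age[None, :]
           + rng_meth.normal(0, cfg.meth_noise_sd, size=(cfg.n_cpgs, n)))
    methylation = pd.DataFrame(1 / (1 + np.exp(-lat)),
                               index=cpg_table["cpg_id"].to_numpy(),
                               columns=samples["sample_id"].to_numpy())

    truth_ocr = ocrs[["ocr_id", "annotation", "linked_gene", "length_bp"]].copy()
    truth_ocr["true_r"] = r_ocr
    truth_ocr["gene_class"] = [
        cls_gene[gene_pos[g]] if isinstance(g, str) else "none" for g in ocrs["linked_gene"]
    ]
    truth_ocr["gene_tier"] = [
        tier_gene[gene_pos[g]] if isinstance(g, str) else "none" for g in ocrs["linked_gene"]
    ]
    truth_gene = pd.DataFrame({"gene": tss_table["gene"], "true_r": r_gene,
                               "class": cls_gene, "tier": tier_gene})
    truth_cpg = cpg_table[["cpg_id", "host_ocr"]].copy()
    truth_cpg["true_r"] = r_cpg

    return {
        "config": cfg,
        "ocrs": ocrs,
        "counts": counts_df,
        "normalized": normalized,
        "log_normalized": log_normalized,
        "expression": expression,
        "methylation": methylation,
        "cpg_table": cpg_table,
        "samples": samples,
        "tss": tss_table,
        "enhancer_links": enh_records,
        "truth": {"ocr": truth_ocr, "gene": truth_gene, "cpg": truth_cpg},
    }


# ---------------------------------------------------------------------------
# Fragment-level small-scale generator

@dataclass
class FragmentConfig:
    """Small-scale fragment/peak generator feeding the interval pipeline."""

    n_samples: int = 20
    n_ocrs: int = 40
    chrom: str = "chrS"
    chrom_length: int = 200_000
    ocr_width: int = 400
    n_fragments: int = 4000
    frip_target: float = 0.5
    peak_dropout: float = 0.1
    boundary_jitter: int = 30
    depth_scale: int = 1  # multiplies n_fragments to emulate deep samples
    seed: int = 0


def generate_fragments(cfg: FragmentConfig):
    """Per-sample fragment BED frames + per-sample peak calls + true OCRs.

    Fragments land inside a true OCR with probability ``frip_target`` and
    strictly outside all OCRs otherwise, so the realized cut-site FRIP is
    binomial around the target. Per-sample peak calls are the true OCRs
    with Bernoulli dropout and uniformly jittered boundaries.
    """
    rng = _rng(cfg.seed, "fragments")
    spacing = cfg.chrom_length // cfg.n_ocrs
    if spacing < cfg.ocr_width + 600:
        raise ValueError("chrom too short for requested OCR count/width")
    starts = np.arange(cfg.n_ocrs) * spacing + 100
    ocrs = pd.DataFrame({"chrom": cfg.chrom, "start": starts, "end": starts + cfg.ocr_width})
    ocrs["ocr_id"] = [f"{cfg.chrom}:{s}-{e}" for s, e in zip(ocrs["start"], ocrs["end"])]

    frag_len_lo, frag_len_hi = 60, min(250, cfg.ocr_width - 10)
    fragments = {}
    peaks = {}
    nf = cfg.n_fragments * cfg.depth_scale
    for si in range(cfg.n_samples):
        sid = f"S{si:03d}"
        in_peak = rng.random(nf) < cfg.frip_target
        lens = rng.integers(frag_len_lo, frag_len_hi + 1, nf)
        fstart = np.empty(nf, dtype=np.int64)
        # inside: both cut sites within one OCR
        k = int(in_peak.sum())
        which = rng.integers(0, cfg.n_ocrs, k)
        offs = rng.random(k) * (cfg.ocr_width - lens[in_peak])
        fstart[in_peak] = starts[which] + offs.astype(np.int64)
        # outside: in the gap after each OCR, away from any OCR
        m = nf - k
        gap_ocr = rng.integers(0, cfg.n_ocrs, m)
        gap_lo = starts[gap_ocr] + cfg.ocr_width + 50
        gap_span = spacing - cfg.ocr_width - 500 - lens[~in_peak]
        fstart[~in_peak] = gap_lo + (rng.random(m) * np.maximum(gap_span, 1)).astype(np.int64)
        fragments[sid] = pd.DataFrame(
            {"chrom": cfg.chrom, "start": fstart, "end": fstart + lens}
        ).sort_values("start").reset_index(drop=True)

        keep = rng.random(cfg.n_ocrs) >= cfg.peak_dropout
        j1 = rng.integers(-cfg.boundary_jitter, cfg.boundary_jitter + 1, cfg.n_ocrs)
        j2 = rng.integers(-cfg.boundary_jitter, cfg.boundary_jitter + 1, cfg.n_ocrs)
        pk = pd.DataFrame({
            "chrom": cfg.chrom,
            "start": np.maximum(starts + j1, 0),
            "end": starts + cfg.ocr_width + j2,
        })[keep]
        peaks[sid] = pk[pk["end"] > pk["start"]].reset_index(drop=True)
    return {"fragments": fragments, "peaks": peaks, "true_ocrs": ocrs, "config": cfg}


def config_to_dict(cfg) -> dict:
    return asdict(cfg)
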