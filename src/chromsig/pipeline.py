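"""End-to-end orchestration: binarize -> joint HMM -> signatures ->
expression integration -> male/female comparisons -> permutation statistics.

Every stage reads and writes the plain-text formats of the other modules;
each output table carries a header comment naming the producing stage and
the run's config hash, and a run log records the seed, config and stage
timings.  Any stage failure aborts the run with the stage name and leaves a
FAILED marker next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from chromsig import io_tracks, hmm, signatures as sigmod, expression as exprmod
from chromsig import comparative, stats as statsmod

log = logging.getLogger("chromsig")


@dataclass
class RunConfig:
    layout: str
    genes: str
    chip_dir: str                   # chip_{sex}_{mark}_rep{r}.bed + control_{sex}.bed
    counts: str
    gene_lengths: str
    de_table: str
    out_dir: str
    te_table: str | None = None
    age_table: str | None = None
    marks: list[str] = field(default_factory=lambda: [
        "H3K4me3", "H3K9ac", "H3K27ac", "H3K36me3", "H3K79me2", "H4K20me3"])
    sexes: list[str] = field(default_factory=lambda: ["female", "male"])
    n_replicates: int = 2
    bin_size: int = 200
    p_threshold: float = 1e-4
    replicate_rule: str = "OR"
    K: int = 12
    k_min: int | None = None        # set k_min/k_max to select K instead
    k_max: int | None = None
    max_iter: int = 200
    tol: float = 1e-4
    decode_method: str = "posterior"
    state_group_map: str | None = None   # TSV path; default 12-state map
    class_table: str | None = None
    tpm_threshold: float = 1.0
    log2fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    n_perm: int = 100_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapped(ctx, *a, **kw):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(ctx, *a, **kw)
            except Exception as e:
                marker = os.path.join(ctx["cfg"].out_dir, "FAILED")
                with open(marker, "w") as fh:
                    fh.write(f"stage {name} failed: {e}\n")
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


def _write(ctx, df: pd.DataFrame, name: str, stage: str) -> None:
    path = os.path.join(ctx["cfg"].out_dir, name)
    io_tracks.write_tsv(df, path, comment=f"stage={stage} config={ctx['hash']}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@_stage("binarize")
def stage_binarize(ctx):
    cfg = ctx["cfg"]
    layout = ctx["layout"]
    matrices = {}
    for sex in cfg.sexes:
        control_path = os.path.join(cfg.chip_dir, f"control_{sex}.bed")
        control_iv = pd.read_csv(control_path, sep="\t", header=None,
                                 names=["chromosome", "start", "end"])
        control = io_tracks.bin_signal(control_iv, layout, cfg.bin_size)
        columns = {}
        for mark in cfg.marks:
            reps = []
            for r in range(1, cfg.n_replicates + 1):
                path = os.path.join(cfg.chip_dir, f"chip_{sex}_{mark}_rep{r}.bed")
                iv = pd.read_csv(path, sep="\t", header=None,
                                 names=["chromosome", "start", "end"])
                track = io_tracks.bin_signal(iv, layout, cfg.bin_size,
                                             mark=mark, sample=f"{sex}_rep{r}")
                reps.append(io_tracks.binarize(track, control,
                                               p_threshold=cfg.p_threshold))
            columns[mark] = io_tracks.combine_replicates(reps, cfg.replicate_rule)
        matrices[sex] = io_tracks.assemble_binary_matrix(
            columns, bin_size=cfg.bin_size, sample=sex, mark_order=cfg.marks)
    ctx["binary"] = matrices


@_stage("fit")
def stage_fit(ctx):
    cfg = ctx["cfg"]
    obs = [ctx["binary"][sex] for sex in cfg.sexes]
    if cfg.k_min is not None and cfg.k_max is not None:
        chosen, curve = hmm.select_state_count(
            obs, k_max=cfg.k_max, k_min=cfg.k_min, seed=cfg.seed,
            max_iter=cfg.max_iter, tol=cfg.tol)
        _write(ctx, curve, "state_count_selection.tsv", "fit")
        K = chosen
    else:
        K = cfg.K
    model = hmm.fit_hmm(obs, K=K, seed=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol)
    model.save(os.path.join(cfg.out_dir, "model"))
    ctx["model"] = model


@_stage("decode")
def stage_decode(ctx):
    cfg = ctx["cfg"]
    ctx["segmentations"] = {}
    for sex in cfg.sexes:
        seg = hmm.decode(ctx["model"], ctx["binary"][sex], method=cfg.decode_method)
        io_tracks.write_segmentation(
            seg, os.path.join(cfg.out_dir, f"segmentation_{sex}.bed"))
        ctx["segmentations"][sex] = seg


@_stage("signatures")
def stage_signatures(ctx):
    cfg = ctx["cfg"]
    if cfg.state_group_map:
        gmap = sigmod.StateGroupMap.load(cfg.state_group_map)
    else:
        gmap = sigmod.infer_state_groups(ctx["model"])
        gmap.save(os.path.join(cfg.out_dir, "state_groups.tsv"))
    class_table = sigmod.load_class_table(cfg.class_table) if cfg.class_table else None
    ctx["group_map"] = gmap
    ctx["signatures"] = {}
    for sex in cfg.sexes:
        ssets = sigmod.intersect_states_with_genes(
            ctx["segmentations"][sex], ctx["genes"])
        table = sigmod.assign_signatures(ssets, gmap, class_table=class_table,
                                         sample=sex)
        table.save(os.path.join(cfg.out_dir, f"signatures_{sex}.tsv"))
        ctx["signatures"][sex] = table
        props = sigmod.signature_proportions(table)
        _write(ctx, props, f"signature_proportions_{sex}.tsv", "signatures")


@_stage("expression")
def stage_expression(ctx):
    cfg = ctx["cfg"]
    counts = pd.read_csv(cfg.counts, sep="\t", comment="#").set_index("gene_id")
    lengths = pd.read_csv(cfg.gene_lengths, sep="\t", comment="#") \
        .set_index("gene_id")["length"]
    meta = pd.DataFrame(index=counts.columns)
    meta["sex"] = ["female" if c.startswith("female") else "male"
                   for c in counts.columns]
    table = exprmod.compute_tpm(counts, lengths, metadata=meta)
    cats = exprmod.expression_categories(table)
    de = pd.read_csv(cfg.de_table, sep="\t", comment="#").set_index("gene_id")
    bias = exprmod.call_sex_bias(de, table,
                                 log2fc_threshold=cfg.log2fc_threshold,
                                 fdr_threshold=cfg.fdr_threshold,
                                 min_tpm=cfg.tpm_threshold)
    ctx["expression"] = table
    ctx["categories"] = cats
    ctx["bias"] = bias
    _write(ctx, cats.reset_index(names="gene_id"), "expression_categories.tsv",
           "expression")
    _write(ctx, bias.table.reset_index(names="gene_id"), "sex_bias.tsv",
           "expression")
    # expression by signature per sex (transcript-abundance table)
    rows = []
    for sex in cfg.sexes:
        sig = ctx["signatures"][sex].table.set_index("gene_id")["signature"]
        expr = np.log2(table.mean_tpm(sex) + 1.0)
        for s, grp in expr.groupby(sig):
            rows.append((sex, s, len(grp), float(grp.mean()), float(grp.median())))
    _write(ctx, pd.DataFrame(rows, columns=[
        "sex", "signature", "n_genes", "mean_log2_tpm1", "median_log2_tpm1"]),
        "expression_by_signature.tsv", "expression")
    # rank-sum comparison of activation- vs repression-class genes per sex
    from scipy.stats import mannwhitneyu
    wil = []
    for sex in cfg.sexes:
        tab = ctx["signatures"][sex].table.set_index("gene_id")
        expr = np.log2(table.mean_tpm(sex) + 1.0)
        act = expr[tab.index[tab["signature_class"] == "ACTIVATION"]]
        rep = expr[tab.index[tab["signature_class"] == "REPRESSION"]]
        if len(act) >= 2 and len(rep) >= 2:
            stat, p = mannwhitneyu(act, rep, alternative="two-sided")
            wil.append((sex, "ACTIVATION_vs_REPRESSION", len(act), len(rep),
                        float(act.median()), float(rep.median()), float(p)))
    _write(ctx, pd.DataFrame(wil, columns=[
        "sex", "comparison", "n_a", "n_b", "median_a", "median_b", "p_value"]),
        "wilcoxon_by_class.tsv", "expression")


@_stage("compare")
def stage_compare(ctx):
    cfg = ctx["cfg"]
    female, male = ctx["signatures"]["female"], ctx["signatures"]["male"]
    trans = comparative.signature_transitions(female, male)
    _write(ctx, trans.edge_list(), "transitions_all.tsv", "compare")
    biased = [g for g in ctx["bias"].table.index
              if ctx["bias"].table.loc[g, "bias"] != "UNBIASED"
              and g in set(female.table["gene_id"])]
    summary = [("all", trans.total, trans.fraction_changed)]
    if biased:
        tb = comparative.signature_transitions(female, male, subset=biased,
                                               subset_label="sex_biased")
        _write(ctx, tb.edge_list(), "transitions_sex_biased.tsv", "compare")
        summary.append(("sex_biased", tb.total, tb.fraction_changed))
    _write(ctx, pd.DataFrame(summary, columns=["subset", "n_genes",
                                               "fraction_changed"]),
           "transition_summary.tsv", "compare")
    # per-mark coverage by region from the binary calls
    enriched = {}
    bs = cfg.bin_size
    for sex in cfg.sexes:
        bm = ctx["binary"][sex]
        for mi, mark in enumerate(bm.marks):
            rows = []
            for chrom, X in bm.data.items():
                for b in np.flatnonzero(X[:, mi]):
                    rows.append((chrom, int(b) * bs, (int(b) + 1) * bs))
            enriched[(mark, sex)] = pd.DataFrame(
                rows, columns=["chromosome", "start", "end"])
    cov = comparative.coverage_by_region(enriched, ctx["layout"])
    _write(ctx, cov, "coverage_by_region.tsv", "compare")
    # region x signature tables
    rows = []
    gene_region = {g.gene_id: g.region_class for g in ctx["genes"]}
    for sex in cfg.sexes:
        tab = ctx["signatures"][sex].table
        for region, sub in tab.groupby(tab["gene_id"].map(gene_region)):
            vc = sub["signature"].value_counts()
            for s in sigmod.SIGNATURE_IDS:
                rows.append((sex, region, s, int(vc.get(s, 0))))
    _write(ctx, pd.DataFrame(rows, columns=["sex", "region", "signature", "count"]),
           "signatures_by_region.tsv", "compare")


@_stage("stats")
def stage_stats(ctx):
    cfg = ctx["cfg"]
    genes = ctx["genes"]
    covariates = pd.DataFrame({
        "te_overlap": {g.gene_id: g.te_overlap for g in genes},
        "expression": np.log2(ctx["expression"].mean_tpm() + 1.0),
    })
    autosomal = [g.gene_id for g in genes if g.region_class == "AUTOSOME"]
    par = [g.gene_id for g in genes if g.region_class == "PAR"]
    results = []
    for sex in cfg.sexes:
        sig = ctx["signatures"][sex]
        for matching in ("NONE", "TE_PREVALENCE"):
            try:
                r = statsmod.matched_permutation_test(
                    par, autosomal, sig, n_perm=cfg.n_perm, matching=matching,
                    covariates=covariates, seed=cfg.seed)
            except ValueError as e:
                log.warning("PAR-vs-autosome test (%s, %s) skipped: %s",
                            sex, matching, e)
                continue
            results.append((sex, "PAR_vs_autosome", matching,
                            r.observed_statistic, r.p_value, r.n_perm))
        young = [g.gene_id for g in genes
                 if g.age_class == "YOUNG" and g.region_class != "AUTOSOME"]
        conserved = [g.gene_id for g in genes
                     if g.age_class == "CONSERVED" and g.region_class == "AUTOSOME"]
        if young and len(conserved) > len(young):
            try:
                r = statsmod.matched_permutation_test(
                    young, conserved, sig, n_perm=cfg.n_perm,
                    matching="EXPRESSION_WINDOW", covariates=covariates,
                    seed=cfg.seed)
                results.append((sex, "young_vs_conserved", "EXPRESSION_WINDOW",
                                r.observed_statistic, r.p_value, r.n_perm))
            except ValueError as e:
                log.warning("young-gene test skipped: %s", e)
    _write(ctx, pd.DataFrame(results, columns=[
        "sex", "contrast", "matching", "observed_chi2", "p_value", "n_perm"]),
        "permutation_tests.tsv", "stats")
    # signature x location model per sex (autosome vs PAR genes)
    for sex in cfg.sexes:
        sig = ctx["signatures"][sex].table.set_index("gene_id")["signature"]
        region = pd.Series({g.gene_id: g.region_class for g in genes})
        keep = region.isin(["AUTOSOME", "PAR"])
        expr = np.log2(ctx["expression"].mean_tpm(sex) + 1.0)
        ref = "S1" if "S1" in set(sig[keep]) else sig[keep].mode().iloc[0]
        try:
            fit = statsmod.signature_expression_model(
                expr[keep], sig[keep], region[keep], reference_signature=ref)
            _write(ctx, fit.coefficients, f"expression_model_{sex}.tsv", "stats")
        except ValueError as e:
            log.warning("expression model (%s) skipped: %s", sex, e)


STAGE_ORDER = ["binarize", "fit", "decode", "signatures", "expression",
               "compare", "stats"]


def run_pipeline(cfg: RunConfig, upto: str = "stats") -> str:
    """Run the stages in order up to ``upto`` (default: all); returns the
    output directory."""
    if upto not in STAGE_ORDER:
        raise ValueError(f"unknown stage {upto!r}; one of {STAGE_ORDER}")
    os.makedirs(cfg.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.out_dir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        import chromsig
        ctx = {"cfg": cfg, "hash": cfg.config_hash()}
        log.info("chromsig %s seed=%d config=%s", chromsig.__version__,
                 cfg.seed, ctx["hash"])
        with open(os.path.join(cfg.out_dir, "run_config.yaml"), "w") as fh:
            yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
        ctx["layout"] = io_tracks.load_genome_layout(cfg.layout)
        te = io_tracks.read_tsv(cfg.te_table) if cfg.te_table else None
        age = io_tracks.read_tsv(cfg.age_table) if cfg.age_table else None
        ctx["genes"] = io_tracks.load_gene_models(cfg.genes, ctx["layout"],
                                                  te_table=te, age_table=age)
        stage_fns = {"binarize": stage_binarize, "fit": stage_fit,
                     "decode": stage_decode, "signatures": stage_signatures,
                     "expression": stage_expression, "compare": stage_compare,
                     "stats": stage_stats}
        for name in STAGE_ORDER[:STAGE_ORDER.index(upto) + 1]:
            stage_fns[name](ctx)
        failed = os.path.join(cfg.out_dir, "FAILED")
        if os.path.exists(failed):
            os.remove(failed)
        log.info("pipeline complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return cfg.out_dir


def config_for_synthetic(data_dir: str, out_dir: str, **overrides) -> RunConfig:
    """RunConfig wired to the file layout of generate_dataset."""
    cfg = RunConfig(
        layout=os.path.join(data_dir, "layout.yaml"),
        genes=os.path.join(data_dir, "genes.gff3"),
        chip_dir=data_dir,
        counts=os.path.join(data_dir, "counts.tsv"),
        gene_lengths=os.path.join(data_dir, "gene_lengths.tsv"),
        de_table=os.path.join(data_dir, "de_table.tsv"),
        te_table=os.path.join(data_dir, "te_overlap.tsv"),
        age_table=os.path.join(data_dir, "gene_age.tsv"),
        out_dir=out_dir,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
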