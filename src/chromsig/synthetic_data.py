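"""Ground-truthed miniature datasets with the structure the analysis assumes.

The generator emulates the study design end to end: a small genome (four
autosomes plus one sex chromosome carrying a shared PAR and per-sex SDRs),
bin-aligned gene models with TE-overlap and gene-age labels, per-sex
chromatin states painted over gene bodies from planted chromatin-signature
assignments (null state elsewhere), ChIP read intervals for six histone
marks x two sexes x two replicates drawn by Poisson sampling with per-bin
rate proportional to the true state's emission probability, flat control
tracks, replicate count tables whose expression couples to the planted
signature class, and a differential-expression table written directly from
the planted sex-bias labels.  Everything is deterministic given the seed,
and per-gene truth is re-derived through the signatures module from the
true segmentation, so truth and emitted files cannot disagree.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chromsig.io_tracks import (
    GenomeLayout, GeneModel, genes_to_frame, write_genome_layout, write_tsv,
)
from chromsig.hmm import Segmentation, match_states, _emission_correlation
from chromsig.signatures import (
    StateGroupMap, assign_signatures, intersect_states_with_genes,
    default_id_table, NON_NULL_GROUPS,
)

MARKS = ["H3K4me3", "H3K9ac", "H3K27ac", "H3K36me3", "H3K79me2", "H4K20me3"]

# 12 true states: E1-E3 permissive-1 (TSS marks), E4-E5 permissive-2
# (H3K36me3), E6-E8 mixed, E9-E11 silent (H3K79me2/H4K20me3), E12 null.
_HI, _MID, _LO = 0.85, 0.50, 0.03
TRUE_EMISSION = np.array([
    [_HI, _HI, _LO, _LO, _LO, _LO],   # E1
    [_HI, _LO, _HI, _LO, _LO, _LO],   # E2
    [_HI, _HI, _HI, _MID, _LO, _LO],  # E3
    [_LO, _LO, _LO, _HI, _LO, _LO],   # E4
    [_MID, _LO, _LO, _HI, _LO, _LO],  # E5
    [_HI, _HI, _LO, _LO, _HI, _LO],   # E6
    [_HI, _LO, _LO, _MID, _LO, _HI],  # E7
    [_LO, _HI, _HI, _LO, _HI, _HI],   # E8
    [_LO, _LO, _LO, _LO, _HI, _LO],   # E9
    [_LO, _LO, _LO, _LO, _LO, _HI],   # E10
    [_LO, _LO, _LO, _MID, _HI, _HI],  # E11
    [_LO, _LO, _LO, _LO, _LO, _LO],   # E12
])

_GROUP_STATES = {
    "PERMISSIVE1": [0, 1, 2],
    "PERMISSIVE2": [3, 4],
    "MIXED": [5, 6, 7],
    "SILENT": [8, 9, 10],
}
_NULL_STATE = 11

# Per-class menus of group subsets (bitmask: P1=1, P2=2, MIX=4, SIL=8) and
# their sampling weights; S3 ({P1,P2}) dominates activation as in real data.
_CLASS_SUBSETS = {
    "ACTIVATION": ([frozenset({"PERMISSIVE1"}), frozenset({"PERMISSIVE2"}),
                    frozenset({"PERMISSIVE1", "PERMISSIVE2"})], [0.25, 0.15, 0.60]),
    "MIXED": ([frozenset({"PERMISSIVE1", "MIXED"}),
               frozenset({"PERMISSIVE1", "PERMISSIVE2", "MIXED"}),
               frozenset({"PERMISSIVE2", "SILENT"}),
               frozenset({"PERMISSIVE1", "PERMISSIVE2", "MIXED", "SILENT"})],
              [0.30, 0.35, 0.20, 0.15]),
    "REPRESSION": ([frozenset({"SILENT"}), frozenset({"MIXED"}),
                    frozenset({"MIXED", "SILENT"})], [0.60, 0.15, 0.25]),
    "NULL": ([frozenset()], [1.0]),
}

_CLASS_ORDER = ["ACTIVATION", "MIXED", "REPRESSION", "NULL"]


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the miniature dataset."""

    seed: int = 0
    n_autosomes: int = 4
    autosome_length: int = 400_000
    sex_chromosome_length: int = 400_000
    par_end: int = 320_000           # PAR [0, par_end)
    sdr_female: tuple = (320_000, 360_000)
    sdr_male: tuple = (360_000, 400_000)
    bin_size: int = 200
    gene_lengths: tuple = (800, 1000, 1200)       # bin-aligned, >= 4 bins
    gene_gaps: tuple = (200, 400)
    # per-region planted signature-class proportions (ACT, MIX, REP, NULL);
    # the PAR carries a planted excess of repression-class (silent) signatures
    class_probs: dict = field(default_factory=lambda: {
        "AUTOSOME": (0.55, 0.20, 0.15, 0.10),
        "PAR": (0.30, 0.20, 0.40, 0.10),
        "SDR_FEMALE": (0.25, 0.25, 0.35, 0.15),
        "SDR_MALE": (0.25, 0.25, 0.35, 0.15),
    })
    te_fraction: dict = field(default_factory=lambda: {
        "AUTOSOME": 0.15, "PAR": 0.45, "SDR_FEMALE": 0.60, "SDR_MALE": 0.60})
    young_fraction: dict = field(default_factory=lambda: {
        "AUTOSOME": 0.05, "PAR": 0.30, "SDR_FEMALE": 0.40, "SDR_MALE": 0.40})
    sex_biased_fraction: float = 0.05
    bias_log2fc: tuple = (1.5, 3.0)            # planted |log2 FC| range
    biased_signature_switch_prob: float = 0.60  # biased gene changes signature
    unbiased_signature_switch_prob: float = 0.05
    chip_depth: float = 15.0     # mean reads/bin = emission x depth
    control_rate: float = 1.0    # flat control mean reads/bin
    n_replicates: int = 2
    read_length: int = 50
    rna_depth_factor: float = 2.0   # counts = Poisson(TPM x kb x factor x noise)
    replicate_noise_sd: float = 0.10
    # log2(TPM+1) means per planted class
    expression_mu: dict = field(default_factory=lambda: {
        "ACTIVATION": 6.0, "MIXED": 3.5, "REPRESSION": 1.5, "NULL": 0.5})
    expression_sd: float = 0.8

    def validate(self) -> None:
        if self.sdr_female[1] > self.sex_chromosome_length or \
                self.sdr_male[1] > self.sex_chromosome_length:
            raise ValueError("SDR extends beyond the sex chromosome")
        for probs in self.class_probs.values():
            if not np.isclose(sum(probs), 1.0):
                raise ValueError("class proportions must sum to 1")


@dataclass
class TruthBundle:
    layout: GenomeLayout
    genes: list[GeneModel]
    true_states: dict[str, dict[str, np.ndarray]]   # sex -> chrom -> per-bin state idx
    true_signatures: dict[str, object]              # sex -> GeneSignatureTable
    gene_truth: pd.DataFrame    # planted class/subset/bias per gene and sex
    emission: np.ndarray
    marks: list[str]
    manifest: pd.DataFrame | None = None

    def true_segmentation(self, sex: str, bin_size: int = 200) -> Segmentation:
        rows = []
        for chrom, states in self.true_states[sex].items():
            change = np.flatnonzero(np.diff(states)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(states)]])
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s) * bin_size, int(e) * bin_size,
                             f"E{states[s] + 1}"))
        tiles = pd.DataFrame(rows, columns=["chromosome", "start", "end", "state"])
        return Segmentation(tiles=tiles, bin_size=bin_size, sample=sex)


# ---------------------------------------------------------------------------
# Construction helpers
# ---------------------------------------------------------------------------

def _build_layout(cfg: SyntheticConfig) -> GenomeLayout:
    chroms = {f"chr{i + 1}": cfg.autosome_length for i in range(cfg.n_autosomes)}
    chroms["chrUV"] = cfg.sex_chromosome_length
    regions = pd.DataFrame(
        [("chrUV", 0, cfg.par_end, "PAR"),
         ("chrUV", *cfg.sdr_female, "SDR_FEMALE"),
         ("chrUV", *cfg.sdr_male, "SDR_MALE")],
        columns=["chromosome", "start", "end", "region_class"])
    return GenomeLayout(chromosomes=chroms, regions=regions)


def _place_genes(cfg: SyntheticConfig, layout: GenomeLayout,
                 rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    i = 0
    for chrom, length in layout.chromosomes.items():
        cursor = int(rng.choice(cfg.gene_gaps))
        while True:
            glen = int(rng.choice(cfg.gene_lengths))
            if cursor + glen > length:
                break
            i += 1
            mid = cursor + glen // 2
            region = layout.region_class_at(chrom, mid)
            genes.append(GeneModel(
                gene_id=f"g{i:05d}", chromosome=chrom, start=cursor,
                end=cursor + glen, strand="+" if rng.random() < 0.5 else "-",
                region_class=region,
                te_overlap=bool(rng.random() < cfg.te_fraction[region]),
                age_class="YOUNG" if rng.random() < cfg.young_fraction[region]
                          else "CONSERVED",
            ))
            cursor += glen + int(rng.choice(cfg.gene_gaps))
    return genes


def _sample_subset(cls: str, rng: np.random.Generator) -> frozenset:
    subsets, weights = _CLASS_SUBSETS[cls]
    return subsets[rng.choice(len(subsets), p=weights)]


def _plant_gene_truth(cfg: SyntheticConfig, genes: list[GeneModel],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Planted per-gene class/subset per sex plus sex-bias labels."""
    rows = []
    for g in genes:
        probs = cfg.class_probs[g.region_class]
        cls_f = _CLASS_ORDER[rng.choice(4, p=np.asarray(probs))]
        sub_f = _sample_subset(cls_f, rng)
        biased = rng.random() < cfg.sex_biased_fraction
        direction = ""
        cls_m, sub_m = cls_f, sub_f
        if biased:
            direction = "MALE_BIASED" if rng.random() < 0.5 else "FEMALE_BIASED"
            if rng.random() < cfg.biased_signature_switch_prob:
                up_cls = "ACTIVATION"
                down_cls = "REPRESSION" if rng.random() < 0.7 else "MIXED"
                if direction == "MALE_BIASED":
                    cls_m, cls_f = up_cls, down_cls
                else:
                    cls_f, cls_m = up_cls, down_cls
                sub_f = _sample_subset(cls_f, rng)
                sub_m = _sample_subset(cls_m, rng)
        elif rng.random() < cfg.unbiased_signature_switch_prob:
            cls_m = _CLASS_ORDER[rng.choice(4, p=np.asarray(probs))]
            sub_m = _sample_subset(cls_m, rng)
        rows.append((g.gene_id, g.region_class, g.te_overlap, g.age_class,
                     cls_f, ",".join(sorted(sub_f)), cls_m, ",".join(sorted(sub_m)),
                     direction or "UNBIASED"))
    return pd.DataFrame(rows, columns=[
        "gene_id", "region_class", "te_overlap", "age_class",
        "class_female", "groups_female", "class_male", "groups_male", "bias"])


def _paint_states(cfg: SyntheticConfig, layout: GenomeLayout,
                  genes: list[GeneModel], truth: pd.DataFrame, sex: str,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-bin true state per chromosome: null everywhere, each gene's bins
    partitioned among the states of its planted group subset."""
    nb = layout.n_bins(cfg.bin_size)
    states = {c: np.full(n, _NULL_STATE, dtype=np.int64) for c, n in nb.items()}
    col = f"groups_{sex}"
    planted = truth.set_index("gene_id")[col]
    for g in genes:
        groups = [x for x in planted[g.gene_id].split(",") if x]
        if not groups:
            continue  # null signature: gene bins stay E12
        b0 = g.start // cfg.bin_size
        b1 = g.end // cfg.bin_size  # bin-aligned genes: end is exclusive bin
        n_bins = b1 - b0
        # contiguous block per group, each at least one bin
        cuts = np.linspace(0, n_bins, len(groups) + 1).round().astype(int)
        for gi, grp in enumerate(groups):
            st = int(rng.choice(_GROUP_STATES[grp]))
            states[g.chromosome][b0 + cuts[gi]: b0 + cuts[gi + 1]] = st
    return states


def _derive_signatures(cfg, layout, genes, states, sex):
    rows = []
    tiles_seg = TruthBundle(
        layout=layout, genes=genes, true_states={sex: states},
        true_signatures={}, gene_truth=pd.DataFrame(), emission=TRUE_EMISSION,
        marks=MARKS).true_segmentation(sex, cfg.bin_size)
    gmap = StateGroupMap.default_12_state()
    ssets = intersect_states_with_genes(tiles_seg, genes)
    return assign_signatures(ssets, gmap, sample=sex)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _plant_expression(cfg: SyntheticConfig, truth: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Planted mean TPM per gene per sex, coupled to the planted class and
    adjusted to honour the planted sex-bias direction and effect size."""
    base_noise = rng.normal(0.0, cfg.expression_sd, size=len(truth))
    rows = []
    for i, r in enumerate(truth.itertuples()):
        mu_f = cfg.expression_mu[r.class_female] + base_noise[i]
        mu_m = cfg.expression_mu[r.class_male] + base_noise[i]
        tpm_f = max(2.0 ** mu_f - 1.0, 0.0)
        tpm_m = max(2.0 ** mu_m - 1.0, 0.0)
        if r.bias != "UNBIASED":
            delta = rng.uniform(*cfg.bias_log2fc)
            hi = max(tpm_f, tpm_m, 2.0)
            lo = hi / 2.0 ** delta
            if r.bias == "MALE_BIASED":
                tpm_m, tpm_f = hi, lo
            else:
                tpm_f, tpm_m = hi, lo
        rows.append((r.gene_id, tpm_f, tpm_m))
    return pd.DataFrame(rows, columns=["gene_id", "tpm_female", "tpm_male"])


def _counts_from_tpm(cfg: SyntheticConfig, genes: list[GeneModel],
                     expr: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    lengths = pd.Series({g.gene_id: g.end - g.start for g in genes})
    out = pd.DataFrame(index=expr["gene_id"])
    for sex in ("female", "male"):
        mean_tpm = expr.set_index("gene_id")[f"tpm_{sex}"]
        for rep in range(1, cfg.n_replicates + 1):
            noise = rng.lognormal(0.0, cfg.replicate_noise_sd, size=len(mean_tpm))
            lam = mean_tpm.to_numpy() * (lengths[mean_tpm.index].to_numpy() / 1000.0) \
                * cfg.rna_depth_factor * noise
            out[f"{sex}_rep{rep}"] = rng.poisson(lam)
    out.index.name = "gene_id"
    return out


def _de_table(cfg: SyntheticConfig, expr: pd.DataFrame, truth: pd.DataFrame,
              rng: np.random.Generator) -> pd.DataFrame:
    e = expr.set_index("gene_id")
    log2fc = np.log2((e["tpm_male"] + 0.1) / (e["tpm_female"] + 0.1))
    bias = truth.set_index("gene_id")["bias"].reindex(e.index)
    padj = np.where(bias != "UNBIASED",
                    10.0 ** rng.uniform(-8, -3, size=len(e)),
                    rng.uniform(0.2, 1.0, size=len(e)))
    return pd.DataFrame({"gene_id": e.index, "log2fc": log2fc.to_numpy(),
                         "fdr": padj})


# ---------------------------------------------------------------------------
# ChIP read intervals
# ---------------------------------------------------------------------------

def _write_reads(path, layout: GenomeLayout, rates: dict[str, np.ndarray],
                 bin_size: int, read_length: int, rng: np.random.Generator) -> int:
    """Poisson reads per bin at the given per-bin rate; read starts uniform
    within the bin.  Returns the number of reads written."""
    n = 0
    with open(path, "w") as fh:
        for chrom, rate in rates.items():
            counts = rng.poisson(rate)
            length = layout.chromosomes[chrom]
            for b in np.flatnonzero(counts):
                lo = b * bin_size
                hi = min(lo + bin_size, length)
                starts = np.sort(rng.integers(lo, hi, size=counts[b]))
                for s in starts:
                    fh.write(f"{chrom}\t{s}\t{min(s + read_length, length)}\n")
                n += int(counts[b])
    return n


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig | None = None,
                     out_dir: str | None = None) -> TruthBundle:
    """Generate the full miniature dataset; write files when ``out_dir`` given."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = _build_layout(cfg)
    genes = _place_genes(cfg, layout, rng)
    truth = _plant_gene_truth(cfg, genes, rng)
    states = {sex: _paint_states(cfg, layout, genes, truth, sex, rng)
              for sex in ("female", "male")}
    bundle = TruthBundle(
        layout=layout, genes=genes, true_states=states,
        true_signatures={}, gene_truth=truth, emission=TRUE_EMISSION.copy(),
        marks=list(MARKS))
    for sex in ("female", "male"):
        bundle.true_signatures[sex] = _derive_signatures(cfg, layout, genes,
                                                         states[sex], sex)
    expr = _plant_expression(cfg, truth, rng)
    counts = _counts_from_tpm(cfg, genes, expr, rng)
    de = _de_table(cfg, expr, truth, rng)
    bundle.gene_truth = truth.merge(expr, on="gene_id")

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest = []

        def _reg(name, kind):
            manifest.append((name, kind))
            return os.path.join(out_dir, name)

        write_genome_layout(layout, _reg("layout.yaml", "layout"))
        with open(_reg("genes.gff3", "genes"), "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(f"{g.chromosome}\tchromsig_sim\tgene\t{g.start + 1}\t{g.end}"
                         f"\t.\t{g.strand}\t.\tID={g.gene_id}\n")
        write_tsv(pd.DataFrame(
            [(g.gene_id, g.te_overlap) for g in genes],
            columns=["gene_id", "te_overlap"]), _reg("te_overlap.tsv", "te"))
        write_tsv(pd.DataFrame(
            [(g.gene_id, g.age_class) for g in genes],
            columns=["gene_id", "age_class"]), _reg("gene_age.tsv", "age"))
        for sex in ("female", "male"):
            emission = TRUE_EMISSION
            st = states[sex]
            for mi, mark in enumerate(MARKS):
                for rep in range(1, cfg.n_replicates + 1):
                    rates = {c: emission[st[c], mi] * cfg.chip_depth for c in st}
                    _write_reads(
                        _reg(f"chip_{sex}_{mark}_rep{rep}.bed", "chip"),
                        layout, rates, cfg.bin_size, cfg.read_length, rng)
            ctl_rates = {c: np.full(len(v), cfg.control_rate) for c, v in st.items()}
            _write_reads(_reg(f"control_{sex}.bed", "control"),
                         layout, ctl_rates, cfg.bin_size, cfg.read_length, rng)
        counts.reset_index().to_csv(
            _reg("counts.tsv", "counts"), sep="\t", index=False)
        write_tsv(pd.DataFrame(
            [(g.gene_id, g.end - g.start) for g in genes],
            columns=["gene_id", "length"]), _reg("gene_lengths.tsv", "lengths"))
        write_tsv(de, _reg("de_table.tsv", "de"),
                  comment="log2fc orientation: male over female")
        write_tsv(bundle.gene_truth, _reg("truth_genes.tsv", "truth"))
        for sex in ("female", "male"):
            from chromsig.io_tracks import write_segmentation
            write_segmentation(bundle.true_segmentation(sex, cfg.bin_size),
                               _reg(f"truth_states_{sex}.bed", "truth"))
            bundle.true_signatures[sex].save(
                _reg(f"truth_signatures_{sex}.tsv", "truth"))
        bundle.manifest = pd.DataFrame(manifest, columns=["file", "kind"])
        write_tsv(bundle.manifest, os.path.join(out_dir, "manifest.tsv"))
    return bundle


# ---------------------------------------------------------------------------
# Scoring against truth
# ---------------------------------------------------------------------------

def evaluate_against_truth(
    truth: TruthBundle,
    fitted_emission: np.ndarray | None = None,
    decoded_states: dict[str, dict[str, np.ndarray]] | None = None,
    predicted_signatures: dict[str, object] | None = None,
    predicted_bias: pd.Series | None = None,
) -> pd.DataFrame:
    """Score pipeline outputs against planted truth; all metrics in [0, 1].

    Decoded states are matched to true states by maximal emission
    correlation before computing bin-level accuracy.
    """
    rows = []
    if decoded_states is not None:
        if fitted_emission is None:
            raise ValueError("state accuracy needs the fitted emission matrix")
        mapping = match_states(truth.emission, fitted_emission)
        inverse = np.full(fitted_emission.shape[0], -1)
        inverse[mapping] = np.arange(len(mapping))
        for sex, per_chrom in decoded_states.items():
            correct = total = 0
            for chrom, dec in per_chrom.items():
                t = truth.true_states[sex][chrom]
                correct += int((inverse[dec] == t).sum())
                total += len(t)
            rows.append((f"state_accuracy_{sex}", correct / total))
    if predicted_signatures is not None:
        for sex, pred in predicted_signatures.items():
            t = truth.true_signatures[sex].table.set_index("gene_id")["signature"]
            p = pred.table.set_index("gene_id")["signature"].reindex(t.index)
            rows.append((f"signature_agreement_{sex}", float((p == t).mean())))
    if predicted_bias is not None:
        t = truth.gene_truth.set_index("gene_id")["bias"]
        p = predicted_bias.reindex(t.index)
        rows.append(("bias_agreement", float((p == t).mean())))
    if not rows:
        raise ValueError("nothing to evaluate: no predictions supplied")
    return pd.DataFrame(rows, columns=["metric", "score"])


def signature_showcase():
    """A constructed segmentation + gene set realizing every group subset.

    One chromosome; 16 genes, one per subset of the four non-null groups
    (including the empty set, whose gene overlaps only the null state), so
    signature assignment must produce all 16 distinct signatures.
    Returns (layout, genes, segmentation, group_map).
    """
    bin_size = 200
    gmap = StateGroupMap.default_12_state()
    rep_state = {"PERMISSIVE1": "E1", "PERMISSIVE2": "E4",
                 "MIXED": "E6", "SILENT": "E9"}
    tiles = []
    genes = []
    cursor = 0
    for mask in range(16):
        subset = [g for i, g in enumerate(NON_NULL_GROUPS) if mask & (1 << i)]
        start = cursor
        if not subset:
            tiles.append(("chrT", cursor, cursor + bin_size, "E12"))
            cursor += bin_size
        else:
            for grp in subset:
                tiles.append(("chrT", cursor, cursor + bin_size, rep_state[grp]))
                cursor += bin_size
        genes.append(GeneModel(gene_id=f"sub{mask:02d}", chromosome="chrT",
                               start=start, end=cursor))
        tiles.append(("chrT", cursor, cursor + bin_size, "E12"))  # spacer
        cursor += bin_size
    layout = GenomeLayout(chromosomes={"chrT": cursor})
    seg = Segmentation(
        tiles=pd.DataFrame(tiles, columns=["chromosome", "start", "end", "state"]),
        bin_size=bin_size)
    return layout, genes, seg, gmap
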