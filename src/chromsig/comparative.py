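"""Male/female comparisons: signature transitions, sex-specific mark domains,
and per-region histone-PTM coverage.

Regions are each autosome as a whole plus the PAR and SDR portions of the
sex chromosome, analyzed separately; coverage is the merged genomic
footprint of a mark clipped to the region, divided by the region length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromsig.signatures import SIGNATURE_IDS, GeneSignatureTable


# ---------------------------------------------------------------------------
# Interval utilities (0-based half-open)
# ---------------------------------------------------------------------------

def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or contained intervals per chromosome; abutting
    intervals (end == next start) stay separate under the half-open rule
    but merging them changes no coverage, so they are merged too."""
    out = []
    for chrom, sub in df.groupby("chromosome"):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chromosome", "start", "end"])


def _overlaps_any(chrom: str, start: int, end: int, merged: pd.DataFrame) -> bool:
    sub = merged[merged["chromosome"] == chrom]
    if sub.empty:
        return False
    s = sub["start"].to_numpy()
    e = sub["end"].to_numpy()
    return bool(np.any((s < end) & (start < e)))


# ---------------------------------------------------------------------------
# Signature transitions between sexes
# ---------------------------------------------------------------------------

@dataclass
class TransitionTable:
    counts: pd.DataFrame      # 16x16: rows female signature, cols male signature
    subset_label: str = "all"

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def fraction_changed(self) -> float:
        n = self.total
        diag = float(np.trace(self.counts.to_numpy()))
        return 1.0 - diag / n if n else 0.0

    def edge_list(self) -> pd.DataFrame:
        """Long-format (female_signature, male_signature, count) edges with
        nonzero counts, for external chord-style plotting."""
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["female_signature", "male_signature", "count"]
        return long[long["count"] > 0].reset_index(drop=True)


def signature_transitions(
    female: GeneSignatureTable,
    male: GeneSignatureTable,
    subset=None,
    subset_label: str = "all",
) -> TransitionTable:
    """Cross-tabulate each gene's signature in females against males."""
    f = female.table.set_index("gene_id")["signature"]
    m = male.table.set_index("gene_id")["signature"]
    genes = list(subset) if subset is not None else list(f.index)
    missing = [g for g in genes if g not in f.index or g not in m.index]
    if missing:
        raise ValueError(f"genes missing from a signature table: {missing[:10]}")
    ct = pd.crosstab(f.loc[genes], m.loc[genes])
    ct = ct.reindex(index=SIGNATURE_IDS, columns=SIGNATURE_IDS, fill_value=0)
    ct.index.name = "female_signature"
    ct.columns.name = "male_signature"
    return TransitionTable(counts=ct, subset_label=subset_label)


# ---------------------------------------------------------------------------
# Sex-specific mark domains
# ---------------------------------------------------------------------------

def _ensure_merged(domains: pd.DataFrame, label: str) -> pd.DataFrame:
    merged = merge_intervals(domains)
    if len(merged) != len(domains):
        warnings.warn(f"{label} domains were unmerged/overlapping; auto-merged")
    return merged


def sex_specific_domains(
    domains_a: pd.DataFrame,
    domains_b: pd.DataFrame,
    genes,
) -> dict:
    """Domains of one sex absent from the other, and the genes carrying them.

    A domain of sex a is sex-specific iff it overlaps no domain of sex b by
    >= 1 bp; a gene carries one iff its body overlaps a sex-specific domain
    by >= 1 bp.  Returns per-sex specific domains, gene lists and fractions.
    """
    a = _ensure_merged(domains_a, "sex-a")
    b = _ensure_merged(domains_b, "sex-b")
    mask_a = np.array([not _overlaps_any(r.chromosome, r.start, r.end, b)
                       for r in a.itertuples()], dtype=bool)
    mask_b = np.array([not _overlaps_any(r.chromosome, r.start, r.end, a)
                       for r in b.itertuples()], dtype=bool)
    spec_a = a[mask_a].reset_index(drop=True)
    spec_b = b[mask_b].reset_index(drop=True)
    genes = list(genes)
    genes_a = [g.gene_id for g in genes
               if _overlaps_any(g.chromosome, g.start, g.end, spec_a)]
    genes_b = [g.gene_id for g in genes
               if _overlaps_any(g.chromosome, g.start, g.end, spec_b)]
    n = len(genes)
    return {
        "specific_domains_a": spec_a,
        "specific_domains_b": spec_b,
        "genes_a": genes_a,
        "genes_b": genes_b,
        "fraction_a": len(genes_a) / n if n else 0.0,
        "fraction_b": len(genes_b) / n if n else 0.0,
    }


# ---------------------------------------------------------------------------
# Coverage per region
# ---------------------------------------------------------------------------

def coverage_by_region(
    enriched: dict[tuple[str, str], pd.DataFrame],
    layout,
) -> pd.DataFrame:
    """Fraction of each analysis region covered by each mark in each sex.

    ``enriched`` maps (mark, sex) to an interval DataFrame (chromosome,
    start, end).  Regions are each autosome plus PAR and SDR separately;
    intervals are merged before clipping so coverage is always <= 1.
    """
    spans = layout.region_spans()
    if (spans["end"] - spans["start"] <= 0).any():
        raise ValueError("zero-length analysis region in layout")
    rows = []
    for (mark, sex), intervals in enriched.items():
        merged = merge_intervals(intervals)
        for r in spans.itertuples():
            sub = merged[merged["chromosome"] == r.chromosome]
            s = np.maximum(sub["start"].to_numpy(), r.start)
            e = np.minimum(sub["end"].to_numpy(), r.end)
            covered = int(np.maximum(e - s, 0).sum())
            rows.append((mark, sex, r.region, r.region_class,
                         covered / (r.end - r.start)))
    return pd.DataFrame(rows, columns=["mark", "sex", "region", "region_class",
                                       "coverage"])


def state_group_domains(seg, group_map, group: str = "SILENT") -> pd.DataFrame:
    """Merged genomic footprint of all tiles whose state belongs to a group —
    the default operational notion of a mark 'domain' when no external peak
    calls are supplied."""
    states = {s for s, g in group_map.groups.items() if g == group}
    tiles = seg.tiles[seg.tiles["state"].isin(states)][["chromosome", "start", "end"]]
    return merge_intervals(tiles)
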