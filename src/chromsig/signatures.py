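"""Gene-level chromatin signatures from a state segmentation.

Emission states fall into five groups — two permissive (activation-
associated) groups, a mixed group, a silent group and a null group.  Each
gene collects the set of emission states whose tiles overlap its body; the
non-null groups present define one of 16 signatures: the 15 non-empty
subsets of {PERMISSIVE1, PERMISSIVE2, MIXED, SILENT} map to S1-S15 via a
bitmask (PERMISSIVE1=bit0, PERMISSIVE2=bit1, MIXED=bit2, SILENT=bit3) and
the empty set — a gene overlapping nothing but null-group states — is the
null signature S16.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("PERMISSIVE1", "PERMISSIVE2", "MIXED", "SILENT", "NULL")
NON_NULL_GROUPS = ("PERMISSIVE1", "PERMISSIVE2", "MIXED", "SILENT")
SIGNATURE_IDS = tuple(f"S{i}" for i in range(1, 17))

_GROUP_BIT = {g: 1 << i for i, g in enumerate(NON_NULL_GROUPS)}


@dataclass
class StateGroupMap:
    """Map from emission state label (``E<k>``) to one of the five groups."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.groups.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown groups: {bad}")
        if "NULL" not in self.groups.values():
            raise ValueError("state-group map must contain at least one NULL state")

    def group_of(self, state: str) -> str:
        try:
            return self.groups[state]
        except KeyError:
            raise KeyError(f"state {state!r} missing from state-group map") from None

    @classmethod
    def default_12_state(cls) -> "StateGroupMap":
        """E1-E3 permissive 1 (TSS activation marks), E4-E5 permissive 2
        (H3K36me3), E6-E8 mixed, E9-E11 silent, E12 null."""
        groups = {}
        for k in range(1, 13):
            if k <= 3:
                g = "PERMISSIVE1"
            elif k <= 5:
                g = "PERMISSIVE2"
            elif k <= 8:
                g = "MIXED"
            elif k <= 11:
                g = "SILENT"
            else:
                g = "NULL"
            groups[f"E{k}"] = g
        return cls(groups)

    def save(self, path) -> None:
        pd.DataFrame(sorted(self.groups.items()), columns=["state", "group"]) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "StateGroupMap":
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
        return cls(dict(zip(df["state"], df["group"])))


DEFAULT_MARK_ROLES = {
    "H3K4me3": "TSS", "H3K9ac": "TSS", "H3K27ac": "TSS",
    "H3K36me3": "BROAD", "H3K79me2": "REPRESSIVE", "H4K20me3": "REPRESSIVE",
}


def infer_state_groups(
    model,
    mark_roles: dict[str, str] | None = None,
    threshold: float = 0.5,
) -> StateGroupMap:
    """Classify each fitted state into the five groups from its emissions.

    Fitted state indices carry no meaning, so the group of a state is read
    off its emission profile the way one reads the emission heat map: marks
    emitting above ``threshold`` count as present.  States with any
    repressive mark alongside an activation mark are MIXED; repressive-only
    states are SILENT; activation-only states are PERMISSIVE1 when dominated
    by TSS marks (two or more, or a TSS mark without the broad mark) and
    PERMISSIVE2 when the broad gene-body mark (H3K36me3) dominates; states
    emitting nothing are NULL.
    """
    roles = mark_roles or DEFAULT_MARK_ROLES
    groups: dict[str, str] = {}
    for k, state in enumerate(model.state_names):
        hi = {m for m, e in zip(model.marks, model.emission[k]) if e > threshold}
        tss = sum(1 for m in hi if roles.get(m) == "TSS")
        broad = any(roles.get(m) == "BROAD" for m in hi)
        rep = any(roles.get(m) == "REPRESSIVE" for m in hi)
        if rep and (tss or broad):
            g = "MIXED"
        elif rep:
            g = "SILENT"
        elif tss >= 2 or (tss == 1 and not broad):
            g = "PERMISSIVE1"
        elif broad:
            g = "PERMISSIVE2"
        else:
            g = "NULL"
        groups[state] = g
    if "NULL" not in groups.values():
        # guarantee the invariant: the least-emitting state is the null
        weakest = min(range(model.n_states), key=lambda k: model.emission[k].sum())
        groups[model.state_names[weakest]] = "NULL"
    return StateGroupMap(groups)


def default_id_table() -> dict[frozenset, str]:
    """Canonical bitmask order: subset mask k in 1..15 -> S_k; empty -> S16."""
    table: dict[frozenset, str] = {frozenset(): "S16"}
    for mask in range(1, 16):
        subset = frozenset(g for g in NON_NULL_GROUPS if mask & _GROUP_BIT[g])
        table[subset] = f"S{mask}"
    return table


def default_class_rule(group_set: frozenset) -> str:
    """Signature class: activation when only permissive groups are present,
    repression when no permissive group is, mixed otherwise, null for the
    empty set.  The class table is configurable downstream."""
    if not group_set:
        return "NULL"
    permissive = bool(group_set & {"PERMISSIVE1", "PERMISSIVE2"})
    repressive = bool(group_set & {"MIXED", "SILENT"})
    if permissive and repressive:
        return "MIXED"
    return "ACTIVATION" if permissive else "REPRESSION"


def load_class_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    return dict(zip(df["signature"], df["signature_class"]))


@dataclass
class GeneSignatureTable:
    """Per-gene state sets, group sets, signature IDs and class labels."""

    table: pd.DataFrame  # gene_id, states, groups, signature, signature_class
    sample: str = ""

    def signature_of(self, gene_id: str) -> str:
        return self.table.set_index("gene_id").loc[gene_id, "signature"]

    def counts(self, subset=None) -> pd.Series:
        df = self.table
        if subset is not None:
            df = df[df["gene_id"].isin(set(subset))]
        return df["signature"].value_counts().reindex(SIGNATURE_IDS, fill_value=0)

    def save(self, path) -> None:
        out = self.table.copy()
        out["sex"] = self.sample
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# State-gene intersection
# ---------------------------------------------------------------------------

def intersect_states_with_genes(seg, genes, min_overlap: int = 1) -> dict[str, set]:
    """States overlapping each gene body by at least ``min_overlap`` bp.

    The segmentation's tiles are sorted and partition each chromosome, so the
    overlapping tile range per gene is found by binary search.  Strand is
    ignored; intervals are half-open, so an abutting tile (overlap 0) never
    counts.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom = {}
    for chrom, sub in seg.tiles.groupby("chromosome"):
        sub = sub.sort_values("start")
        by_chrom[chrom] = (
            sub["start"].to_numpy(), sub["end"].to_numpy(), sub["state"].to_numpy())
    out: dict[str, set] = {}
    for g in genes:
        if g.chromosome not in by_chrom:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chromosome!r} "
                             "absent from segmentation")
        starts, ends, states = by_chrom[g.chromosome]
        lo = int(np.searchsorted(ends, g.start, side="right"))
        hi = int(np.searchsorted(starts, g.end, side="left"))
        hits = set()
        for i in range(lo, hi):
            ov = min(ends[i], g.end) - max(starts[i], g.start)
            if ov >= min_overlap:
                hits.add(states[i])
        out[g.gene_id] = hits
    return out


def assign_signatures(
    state_sets: dict[str, set],
    group_map: StateGroupMap,
    id_table: dict[frozenset, str] | None = None,
    class_table: dict[str, str] | None = None,
    sample: str = "",
) -> GeneSignatureTable:
    """Assign each gene its chromatin signature.

    The gene's group set is the set of groups of its overlapping states with
    NULL removed; genes whose states are all null-group (or that overlap no
    state at all) get the null signature.
    """
    if id_table is None:
        id_table = default_id_table()
    rows = []
    for gene_id, states in state_sets.items():
        groups = frozenset(group_map.group_of(s) for s in states) - {"NULL"}
        sig = id_table[groups]
        cls = class_table[sig] if class_table is not None else default_class_rule(groups)
        rows.append((
            gene_id,
            ",".join(sorted(states, key=lambda s: int(s[1:]))),
            ",".join(sorted(groups)),
            sig,
            cls,
        ))
    table = pd.DataFrame(
        rows, columns=["gene_id", "states", "groups", "signature", "signature_class"])
    return GeneSignatureTable(table=table, sample=sample)


def signature_proportions(sig_table: GeneSignatureTable, gene_subset=None) -> pd.DataFrame:
    """Fraction of a gene subset carrying each of the 16 signatures."""
    if gene_subset is not None:
        gene_subset = list(gene_subset)
        if not gene_subset:
            raise ValueError("empty gene subset")
        known = set(sig_table.table["gene_id"])
        missing = set(gene_subset) - known
        if missing:
            raise ValueError(f"genes absent from signature table: {sorted(missing)[:5]}")
    counts = sig_table.counts(gene_subset)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty gene subset")
    out = counts.rename("count").to_frame()
    out["fraction"] = counts / total
    return out.reset_index(names="signature")
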