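"""State-gene intersection, signature assignment, proportions, group inference."""

import numpy as np
import pandas as pd
import pytest

from chromsig.hmm import BernoulliHMM, Segmentation
from chromsig.io_tracks import GeneModel
from chromsig.signatures import (
    NON_NULL_GROUPS, StateGroupMap, assign_signatures, default_class_rule,
    default_id_table, infer_state_groups, intersect_states_with_genes,
    signature_proportions,
)
from chromsig.synthetic_data import MARKS, TRUE_EMISSION, signature_showcase


def seg_from(tiles):
    return Segmentation(tiles=pd.DataFrame(
        tiles, columns=["chromosome", "start", "end", "state"]), bin_size=200)


def gene(gid, start, end, chrom="chr1"):
    return GeneModel(gene_id=gid, chromosome=chrom, start=start, end=end)


GMAP = StateGroupMap.default_12_state()


class TestIntersection:
    def test_gene_inside_single_tile(self):
        seg = seg_from([("chr1", 0, 600, "E3")])
        out = intersect_states_with_genes(seg, [gene("g", 100, 300)])
        assert out["g"] == {"E3"}

    def test_gene_spanning_three_tiles(self):
        seg = seg_from([("chr1", 0, 200, "E3"), ("chr1", 200, 400, "E12"),
                        ("chr1", 400, 600, "E9")])
        out = intersect_states_with_genes(seg, [gene("g", 100, 500)])
        assert out["g"] == {"E3", "E12", "E9"}

    def test_abutting_tile_excluded_half_open(self):
        seg = seg_from([("chr1", 0, 200, "E1"), ("chr1", 200, 400, "E9")])
        out = intersect_states_with_genes(seg, [gene("g", 0, 200)])
        assert out["g"] == {"E1"}

    def test_min_overlap_filter(self):
        seg = seg_from([("chr1", 0, 200, "E1"), ("chr1", 200, 400, "E9")])
        out = intersect_states_with_genes(seg, [gene("g", 150, 250)],
                                          min_overlap=60)
        assert out["g"] == set()

    def test_gene_on_missing_chromosome_rejected(self):
        seg = seg_from([("chr1", 0, 200, "E1")])
        with pytest.raises(ValueError, match="chr2"):
            intersect_states_with_genes(seg, [gene("g", 0, 100, chrom="chr2")])


class TestAssignment:
    def test_null_only_gene_gets_s16(self):
        t = assign_signatures({"g": {"E12"}}, GMAP)
        row = t.table.iloc[0]
        assert (row["signature"], row["signature_class"]) == ("S16", "NULL")

    def test_both_permissive_groups_give_s3(self):
        t = assign_signatures({"g": {"E1", "E4"}}, GMAP)
        assert t.table.iloc[0]["signature"] == "S3"

    def test_null_dropped_when_other_states_present(self):
        t = assign_signatures({"g": {"E9", "E12"}}, GMAP)
        row = t.table.iloc[0]
        assert row["groups"] == "SILENT"
        assert row["signature"] == "S8"

    def test_unmapped_state_rejected_by_name(self):
        with pytest.raises(KeyError, match="E99"):
            assign_signatures({"g": {"E99"}}, GMAP)

    def test_id_table_is_a_bijection_over_16_subsets(self):
        table = default_id_table()
        assert len(table) == 16
        assert sorted(table.values()) == sorted(f"S{i}" for i in range(1, 17))

    def test_class_rule_split_sizes(self):
        table = default_id_table()
        classes = pd.Series({sig: default_class_rule(sub)
                             for sub, sig in table.items()})
        assert classes.value_counts().to_dict() == {
            "MIXED": 9, "ACTIVATION": 3, "REPRESSION": 3, "NULL": 1}

    def test_showcase_realizes_all_16_signatures(self):
        layout, genes, seg, gmap = signature_showcase()
        out = intersect_states_with_genes(seg, genes)
        t = assign_signatures(out, gmap)
        assert t.table["signature"].nunique() == 16


def brute_force_signatures(seg, genes, gmap, min_overlap=1):
    """Oracle: test every gene-tile pair directly, then reapply the rules."""
    table = default_id_table()
    out = {}
    for g in genes:
        states = set()
        for r in seg.tiles.itertuples():
            if r.chromosome != g.chromosome:
                continue
            ov = min(r.end, g.end) - max(r.start, g.start)
            if ov >= min_overlap:
                states.add(r.state)
        groups = frozenset(gmap.group_of(s) for s in states) - {"NULL"}
        out[g.gene_id] = table[groups]
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed)
        n_bins = 200
        states = rng.integers(0, 12, size=n_bins)
        tiles = [("c", i * 200, (i + 1) * 200, f"E{states[i] + 1}")
                 for i in range(n_bins)]
        seg = seg_from(tiles)
        genes = []
        for i in range(rng.integers(20, 200)):
            start = int(rng.integers(0, n_bins * 200 - 300))
            end = start + int(rng.integers(100, 3000))
            genes.append(gene(f"g{i}", start, min(end, n_bins * 200), chrom="c"))
        fast = assign_signatures(intersect_states_with_genes(seg, genes), GMAP)
        slow = brute_force_signatures(seg, genes, GMAP)
        got = dict(zip(fast.table["gene_id"], fast.table["signature"]))
        assert got == slow

    def test_invariant_to_tile_fragmentation(self):
        seg = seg_from([("c", 0, 1000, "E3"), ("c", 1000, 2000, "E9")])
        frag = seg_from([("c", 0, 200, "E3"), ("c", 200, 1000, "E3"),
                         ("c", 1000, 1400, "E9"), ("c", 1400, 2000, "E9")])
        genes = [gene("a", 100, 1200, chrom="c"), gene("b", 1500, 1900, chrom="c")]
        t1 = assign_signatures(intersect_states_with_genes(seg, genes), GMAP)
        t2 = assign_signatures(intersect_states_with_genes(frag, genes), GMAP)
        pd.testing.assert_frame_equal(t1.table, t2.table)


class TestProportions:
    def test_uniform_subset(self):
        t = assign_signatures({f"g{i}": {"E1", "E4"} for i in range(4)}, GMAP)
        props = signature_proportions(t)
        assert props.set_index("signature").loc["S3", "fraction"] == 1.0

    def test_mixed_counting(self):
        sets = {"a": {"E1", "E4"}, "b": {"E1", "E4"}, "c": {"E12"},
                "d": {"E1", "E4", "E6"}}
        props = signature_proportions(assign_signatures(sets, GMAP)) \
            .set_index("signature")["fraction"]
        assert props["S3"] == 0.5 and props["S16"] == 0.25 and props["S7"] == 0.25

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        sets = {f"g{i}": {f"E{rng.integers(1, 13)}"} for i in range(100)}
        props = signature_proportions(assign_signatures(sets, GMAP))
        assert props["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_subsets_recombine_by_weighted_average(self):
        rng = np.random.default_rng(2)
        sets = {f"g{i}": {f"E{rng.integers(1, 13)}"} for i in range(60)}
        t = assign_signatures(sets, GMAP)
        ids = list(sets)
        a, b = ids[:20], ids[20:]
        pa = signature_proportions(t, a).set_index("signature")["fraction"]
        pb = signature_proportions(t, b).set_index("signature")["fraction"]
        pall = signature_proportions(t).set_index("signature")["fraction"]
        recombined = (len(a) * pa + len(b) * pb) / 60
        assert np.allclose(recombined, pall)

    def test_empty_subset_rejected(self):
        t = assign_signatures({"g": {"E1"}}, GMAP)
        with pytest.raises(ValueError):
            signature_proportions(t, [])


class TestGroupInference:
    def test_true_emission_profiles_classified_as_designed(self):
        model = BernoulliHMM(
            emission=np.clip(TRUE_EMISSION, 1e-6, 1 - 1e-6),
            transition=np.full((12, 12), 1 / 12), initial=np.full(12, 1 / 12),
            marks=MARKS)
        gmap = infer_state_groups(model)
        expected = StateGroupMap.default_12_state()
        assert gmap.groups == expected.groups

    def test_permuting_states_permutes_groups(self):
        rng = np.random.default_rng(3)
        perm = rng.permutation(12)
        model = BernoulliHMM(
            emission=np.clip(TRUE_EMISSION[perm], 1e-6, 1 - 1e-6),
            transition=np.full((12, 12), 1 / 12), initial=np.full(12, 1 / 12),
            marks=MARKS)
        gmap = infer_state_groups(model)
        expected = StateGroupMap.default_12_state()
        for k in range(12):
            assert gmap.groups[f"E{k + 1}"] == expected.groups[f"E{perm[k] + 1}"]

    def test_map_round_trip_preserves_null(self, tmp_path):
        gmap = StateGroupMap.default_12_state()
        gmap.save(tmp_path / "map.tsv")
        back = StateGroupMap.load(tmp_path / "map.tsv")
        assert back.groups == gmap.groups
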