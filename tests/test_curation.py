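"""Curation chain: filters, replicate averaging, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietlink import simulate
from dietlink.curation import (
    CurationError,
    MotuMeta,
    ReplicateCountTable,
    SampleCompositionTable,
    aggregate_taxonomy,
    basic_motu_filter,
    collapse_replicates,
    density_intersection,
    replicate_outlier_filter,
    rra_identity_filter,
)


def _meta(frame: dict, ids: list[str]) -> MotuMeta:
    return MotuMeta(pd.DataFrame(frame, index=pd.Index(ids, name="motu_id")))


class TestBasicMotuFilter:
    @pytest.mark.parametrize(
        "length,total,kept",
        [
            (10, 11, True),    # both at the inclusive boundary survive
            (9, 11, False),    # one base too short
            (10, 10, False),   # exactly 10 reads is excluded
            (8, 5, False),
        ],
    )
    def test_boundaries(self, length, total, kept):
        counts = pd.DataFrame({"r1": [total]},
                              index=pd.Index(["m1"], name="motu_id"))
        table = ReplicateCountTable(counts=counts,
                                    replicate_to_sample={"r1": "s1"})
        meta = _meta({"seq_length": [length], "total_reads": [total],
                      "best_identity": [1.0], "family": ["f"],
                      "functional_group": ["g"]}, ["m1"])
        out, removed = basic_motu_filter(table, meta)
        assert (len(out.motu_ids) == 1) is kept
        assert (removed == ["m1"]) is not kept

    def test_empty_table(self):
        counts = pd.DataFrame({"r1": []},
                              index=pd.Index([], name="motu_id"), dtype=int)
        table = ReplicateCountTable(counts=counts,
                                    replicate_to_sample={"r1": "s1"})
        meta = _meta({"seq_length": [], "total_reads": [],
                      "best_identity": [], "family": [],
                      "functional_group": []}, [])
        out, removed = basic_motu_filter(table, meta)
        assert out.motu_ids == [] and removed == []

    def test_motu_missing_from_meta_is_an_error(self, tiny_replicates):
        meta = _meta({"seq_length": [40], "total_reads": [102],
                      "best_identity": [1.0], "family": ["f"],
                      "functional_group": ["g"]}, ["m1"])
        with pytest.raises(CurationError, match="m2"):
            basic_motu_filter(tiny_replicates, meta)

    def test_surviving_counts_unchanged(self, tiny_replicates, tiny_meta):
        out, removed = basic_motu_filter(tiny_replicates, tiny_meta)
        assert removed == []
        pd.testing.assert_frame_equal(out.counts, tiny_replicates.counts)


class TestReplicateOutlierFilter:
    def test_identical_replicates_nothing_removed(self):
        col = [60, 30, 10]
        counts = pd.DataFrame(
            {f"{s}_r{j}": col if s == "A" else [10, 20, 70]
             for s in "AB" for j in (1, 2, 3)},
            index=pd.Index(["m1", "m2", "m3"], name="motu_id"),
        )
        mapping = {c: c.split("_")[0] for c in counts.columns}
        res = replicate_outlier_filter(
            ReplicateCountTable(counts=counts, replicate_to_sample=mapping)
        )
        assert res.iterations == 1
        assert res.removed_replicates == [] and res.removed_samples == []

    def test_orthogonal_replicate_removed_matches_hand_computation(self):
        # two samples, three replicates each; B_r3 sits on an axis
        # orthogonal to every other profile
        counts = pd.DataFrame(
            {
                "A_r1": [100, 0, 0, 0], "A_r2": [98, 2, 0, 0],
                "A_r3": [99, 1, 0, 0],
                "B_r1": [0, 50, 50, 0], "B_r2": [0, 48, 52, 0],
                "B_r3": [0, 0, 0, 100],
            },
            index=pd.Index(["m1", "m2", "m3", "m4"], name="motu_id"),
        )
        mapping = {c: c.split("_")[0] for c in counts.columns}
        table = ReplicateCountTable(counts=counts,
                                    replicate_to_sample=mapping)

        # independent brute-force oracle for iteration 1
        props = counts / counts.sum(axis=0)
        means = {s: props[[c for c in counts.columns
                           if c.startswith(s)]].mean(axis=1) for s in "AB"}
        dw = {c: float(np.linalg.norm(props[c] - means[c[0]]))
              for c in counts.columns}
        db = [float(np.linalg.norm(means["A"] - means["B"]))]
        thr = density_intersection(np.array(list(dw.values())),
                                   np.array(db))
        # single between-sample distance -> midpoint-of-means fallback
        assert thr == pytest.approx(
            0.5 * (np.mean(list(dw.values())) + db[0])
        )
        assert [c for c, v in dw.items() if v > thr] == ["B_r3"]

        res = replicate_outlier_filter(table)
        assert [r for r, _, _ in res.removed_replicates] == ["B_r3"]
        assert res.removed_samples == []
        assert res.removed_replicates[0][1] == 1  # removed in iteration 1

    def test_planted_outlier_recovery(self):
        """Sensitivity and false-removal against the ground-truth labels."""
        sens, fps = [], []
        for seed in range(5):
            cfg = simulate.default_config(seed=seed)
            table, meta, _mb, _host, reg = simulate.generate_study(cfg)
            table, _ = basic_motu_filter(table, meta)
            res = replicate_outlier_filter(table)
            removed = set(table.replicate_ids) - set(res.kept.replicate_ids)
            out = reg.outlier_replicates
            good = set(table.replicate_ids) - out
            sens.append(len(removed & out) / len(out))
            fps.append(len(removed & good) / len(good))
        assert np.mean(sens) >= 0.9
        assert np.mean(fps) <= 0.05

    def test_idempotent_after_convergence(self, default_study):
        table, meta, *_ = default_study
        table, _ = basic_motu_filter(table, meta)
        res1 = replicate_outlier_filter(table)
        res2 = replicate_outlier_filter(res1.kept)
        assert res2.removed_replicates == []
        assert res2.removed_samples == []
        assert set(res2.kept.replicate_ids) == set(res1.kept.replicate_ids)

    def test_termination_bound(self, default_study):
        table, meta, *_ = default_study
        table, _ = basic_motu_filter(table, meta)
        res = replicate_outlier_filter(table)
        assert 1 <= res.iterations <= len(table.replicate_ids)
        assert len(res.thresholds) == res.iterations

    def test_fewer_than_two_samples_is_an_error(self):
        counts = pd.DataFrame(
            {"A_r1": [10, 20], "A_r2": [12, 18]},
            index=pd.Index(["m1", "m2"], name="motu_id"),
        )
        with pytest.raises(CurationError):
            replicate_outlier_filter(ReplicateCountTable(
                counts=counts,
                replicate_to_sample={"A_r1": "A", "A_r2": "A"},
            ))


class TestCollapseReplicates:
    def test_mean_of_proportions(self, tiny_replicates):
        comp = collapse_replicates(tiny_replicates)
        # sample A: mean of [0.3, 0.7] and [0.5, 0.5] -> [0.4, 0.6]
        assert comp.rra.loc["A", "m1"] == pytest.approx(0.4)
        assert comp.rra.loc["A", "m2"] == pytest.approx(0.6)

    def test_single_replicate_passthrough(self):
        counts = pd.DataFrame(
            {"A_r1": [30, 70], "B_r1": [10, 90]},
            index=pd.Index(["m1", "m2"], name="motu_id"),
        )
        comp = collapse_replicates(ReplicateCountTable(
            counts=counts,
            replicate_to_sample={"A_r1": "A", "B_r1": "B"},
        ))
        assert comp.rra.loc["A"].tolist() == pytest.approx([0.3, 0.7])

    def test_equal_weight_under_depth_rescaling(self, tiny_replicates):
        before = collapse_replicates(tiny_replicates)
        boosted = tiny_replicates.counts.copy()
        boosted["A_r2"] *= 10  # same composition, 10x the reads
        after = collapse_replicates(ReplicateCountTable(
            counts=boosted,
            replicate_to_sample=dict(tiny_replicates.replicate_to_sample),
        ))
        pd.testing.assert_frame_equal(before.rra, after.rra)

    def test_zero_read_replicate_is_an_error(self):
        counts = pd.DataFrame(
            {"A_r1": [5, 5], "A_r2": [0, 0], "B_r1": [2, 8]},
            index=pd.Index(["m1", "m2"], name="motu_id"),
        )
        with pytest.raises(CurationError, match="A_r2"):
            collapse_replicates(ReplicateCountTable(
                counts=counts,
                replicate_to_sample={"A_r1": "A", "A_r2": "A", "B_r1": "B"},
            ))


class TestRraIdentityFilter:
    def _table(self, rra: dict, ids: list[str]) -> SampleCompositionTable:
        return SampleCompositionTable(
            rra=pd.DataFrame(rra, index=pd.Index(ids, name="sample_id"))
        )

    def test_sub_one_percent_everywhere_removed(self):
        table = self._table(
            {"m1": [0.996, 0.992], "m2": [0.004, 0.008]}, ["s1", "s2"]
        )
        meta = _meta({"seq_length": [40, 40], "total_reads": [500, 500],
                      "best_identity": [1.0, 1.0], "family": ["f", "f"],
                      "functional_group": ["g", "g"]}, ["m1", "m2"])
        out, removed = rra_identity_filter(table, meta)
        assert removed == ["m2"]
        assert out.rra["m1"].tolist() == pytest.approx([1.0, 1.0])
        assert out.log["discarded_mass"].tolist() == pytest.approx(
            [0.004, 0.008]
        )

    def test_low_identity_removed_despite_abundance(self):
        table = self._table({"m1": [0.5], "m2": [0.5]}, ["s1"])
        meta = _meta({"seq_length": [40, 40], "total_reads": [500, 500],
                      "best_identity": [0.939, 1.0], "family": ["f", "f"],
                      "functional_group": ["g", "g"]}, ["m1", "m2"])
        out, removed = rra_identity_filter(table, meta)
        assert removed == ["m1"]

    def test_boundary_identity_kept(self):
        table = self._table({"m1": [0.5], "m2": [0.5]}, ["s1"])
        meta = _meta({"seq_length": [40, 40], "total_reads": [500, 500],
                      "best_identity": [0.94, 1.0], "family": ["f", "f"],
                      "functional_group": ["g", "g"]}, ["m1", "m2"])
        _out, removed = rra_identity_filter(table, meta)
        assert removed == []

    def test_all_passing_is_a_noop(self, tiny_replicates, tiny_meta):
        comp = collapse_replicates(tiny_replicates)
        out, removed = rra_identity_filter(comp, tiny_meta)
        assert removed == []
        pd.testing.assert_frame_equal(out.rra, comp.rra)


class TestAggregateTaxonomy:
    def test_family_sums(self, tiny_replicates, tiny_meta):
        comp = collapse_replicates(tiny_replicates)
        fam = aggregate_taxonomy(comp, tiny_meta, "family")
        assert fam.rra.loc["A", "Salicaceae"] == pytest.approx(1.0)
        # B: m1+m2 proportions (0.1+0.1 and 0.12+0.08) average to 0.2
        assert fam.rra.loc["B", "Salicaceae"] == pytest.approx(0.2)
        assert fam.rra.loc["B", "Poaceae"] == pytest.approx(0.8)
        assert list(fam.rra.columns) == sorted(fam.rra.columns)

    def test_identity_when_every_motu_its_own_family(self, tiny_replicates):
        meta = _meta({"seq_length": [40] * 3, "total_reads": [100] * 3,
                      "best_identity": [1.0] * 3,
                      "family": ["f1", "f2", "f3"],
                      "functional_group": ["g"] * 3}, ["m1", "m2", "m3"])
        comp = collapse_replicates(tiny_replicates)
        agg = aggregate_taxonomy(comp, meta, "family")
        expected = comp.rra.rename(columns={"m1": "f1", "m2": "f2",
                                            "m3": "f3"})
        pd.testing.assert_frame_equal(agg.rra, expected[sorted(expected)],
                                      check_names=False)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_row_sums_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n_motus, n_samples = 12, 5
        rra = rng.dirichlet(np.ones(n_motus), size=n_samples)
        fams = rng.choice(["fa", "fb", "fc", "fd"], size=n_motus)
        ids = [f"m{i}" for i in range(n_motus)]
        table = SampleCompositionTable(rra=pd.DataFrame(
            rra, index=pd.Index([f"s{i}" for i in range(n_samples)],
                                name="sample_id"), columns=ids))
        meta = _meta({"seq_length": [40] * n_motus,
                      "total_reads": [100] * n_motus,
                      "best_identity": [1.0] * n_motus,
                      "family": fams,
                      "functional_group": ["g"] * n_motus}, ids)
        agg = aggregate_taxonomy(table, meta, "family")
        np.testing.assert_allclose(agg.rra.sum(axis=1), 1.0, atol=1e-12)
        # conservation against direct summation
        for f in np.unique(fams):
            direct = table.rra.loc[:, fams == f].sum(axis=1)
            np.testing.assert_allclose(agg.rra[f], direct, atol=1e-12)

    def test_missing_label_is_an_error(self, tiny_replicates):
        meta_frame = pd.DataFrame(
            {"seq_length": [40] * 3, "total_reads": [100] * 3,
             "best_identity": [1.0] * 3,
             "family": ["f1", "f2", "f3"],
             "functional_group": ["g"] * 3},
            index=pd.Index(["m1", "m2", "m3"], name="motu_id"))
        meta = MotuMeta(meta_frame)
        meta.table.loc["m2", "family"] = ""
        comp = collapse_replicates(tiny_replicates)
        with pytest.raises(CurationError, match="m2"):
            aggregate_taxonomy(comp, meta, "family")


def test_artefact_free_study_loses_nothing():
    """With no planted defects the whole chain is a pass-through."""
    for seed in (0, 1, 2):
        cfg = simulate.default_config(
            seed=seed, outlier_replicate_rate=0.0, artefact_motu_count=0
        )
        table, meta, _mb, _host, reg = simulate.generate_study(cfg)
        assert reg.outlier_replicates == set()
        t1, removed_basic = basic_motu_filter(table, meta)
        res = replicate_outlier_filter(t1)
        comp = collapse_replicates(res.kept)
        comp, removed_rra = rra_identity_filter(comp, meta)
        assert removed_basic == []
        assert res.removed_replicates == [] and res.removed_samples == []
        assert removed_rra == []
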