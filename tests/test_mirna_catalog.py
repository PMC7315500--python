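import numpy as np
import pandas as pd
import pytest

from mirisonet.core_io import ExpressionMatrix, GenomicInterval, MirnaRecord
from mirisonet.de import bh_adjust
from mirisonet.mirna_catalog import (
    annotate_te_overlap,
    base_composition,
    collapse_identical_matures,
    de_mirna,
    filter_and_collapse,
    inherit_te_flags,
    tissue_presence,
    tpm_quantify,
)


def _matrix(values, samples, design, unit="count", features=None):
    features = features or [f"f{i}" for i in range(len(values))]
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), unit, design
    )


class TestFilterAndCollapse:
    def test_length_bounds_inclusive_18_to_29(self):
        reads = ["A" * 17, "C" * 18, "G" * 29, "U" * 30]
        tab = filter_and_collapse(reads)
        assert set(tab["sequence"]) == {"C" * 18, "G" * 29}

    def test_identical_reads_collapse_with_summed_counts(self):
        tab = filter_and_collapse(["ACGUACGUACGUACGUACGUA"] * 3)
        assert len(tab) == 1
        assert tab.iloc[0]["count"] == 3

    def test_sorted_by_count_then_sequence(self):
        a, b, c = "A" * 21, "C" * 21, "G" * 21
        tab = filter_and_collapse([b, b, c, a, a])
        assert list(tab["sequence"]) == [a, b, c]

    def test_n_reads_dropped_and_empty_ok(self):
        assert len(filter_and_collapse(["ACGUN" + "A" * 16])) == 0
        assert len(filter_and_collapse([])) == 0


class TestTeAnnotation:
    def test_one_bp_overlap_flags(self):
        flags = annotate_te_overlap(
            {"p": GenomicInterval("chr1", 100, 180)},
            [GenomicInterval("chr1", 150, 300)],
        )
        assert flags == {"p": True}

    def test_half_open_abutment_is_no_overlap(self):
        flags = annotate_te_overlap(
            {"p": GenomicInterval("chr1", 100, 180)},
            [GenomicInterval("chr1", 180, 300)],
        )
        assert flags == {"p": False}

    def test_unknown_chromosome_treated_as_no_overlap(self):
        flags = annotate_te_overlap(
            {"p": GenomicInterval("chr9", 100, 180)},
            [GenomicInterval("chr1", 100, 180)],
        )
        assert flags == {"p": False}

    def test_mature_inherits_from_any_flagged_precursor(self):
        flags = inherit_te_flags(
            {"m1": ["p1", "p2"], "m2": ["p3"]}, {"p1": False, "p2": True, "p3": False}
        )
        assert flags == {"m1": True, "m2": False}


class TestTpm:
    def test_two_feature_example(self):
        m = _matrix([[5.0], [15.0]], ["s1"], {"s1": "leaf"})
        tpm = tpm_quantify(m)
        assert tpm.values.iloc[0, 0] == pytest.approx(250000)
        assert tpm.values.iloc[1, 0] == pytest.approx(750000)

    def test_single_feature_gets_full_million(self):
        m = _matrix([[42.0]], ["s1"], {"s1": "leaf"})
        assert tpm_quantify(m).values.iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_one_million_on_random_matrices(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 500, size=(30, 4)).astype(float) + 1
        m = _matrix(vals, ["a", "b", "c", "d"], {s: "t" for s in "abcd"})
        sums = tpm_quantify(m).values.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_zero_column_rejected_naming_sample(self):
        m = _matrix([[0.0, 1.0]], ["bad", "ok"], {"bad": "t", "ok": "t"})
        with pytest.raises(ValueError, match="bad"):
            tpm_quantify(m)


class TestTissuePresence:
    def _abund(self):
        design = {"l1": "leaf", "l2": "leaf", "a1": "anther"}
        vals = pd.DataFrame(
            {
                "l1": [5.0, 0.0, 0.0],
                "l2": [0.0, 0.0, 0.0],
                "a1": [2.0, 1.0, 0.0],
            },
            index=["everywhere", "anther_only", "silent"],
        )
        return ExpressionMatrix(vals, "TPM", design)

    def test_common_unique_and_absent(self):
        s = tissue_presence(self._abund())
        assert s.common_all == 1  # 'everywhere'
        assert s.unique_per_tissue["anther"] == 1
        assert not s.presence.loc["silent"].any()
        assert s.per_tissue["leaf"] == 1

    def test_any_replicate_above_threshold_counts(self):
        s = tissue_presence(self._abund(), threshold=0.0)
        assert s.presence.at["everywhere", "leaf"]  # only l1 is nonzero


class TestDeMirna:
    def _counts(self, rng, fold=1.0, n=3, base=100.0):
        design = {}
        cols = {}
        for i in range(n):
            design[f"a{i}"] = "A"
            cols[f"a{i}"] = rng.poisson(base * fold, 40)
        for i in range(n):
            design[f"b{i}"] = "B"
            cols[f"b{i}"] = rng.poisson(base, 40)
        vals = pd.DataFrame(cols, index=[f"m{j}" for j in range(40)]).astype(float)
        return ExpressionMatrix(vals, "count", design)

    def test_identical_groups_yield_no_calls(self):
        m = self._counts(np.random.default_rng(0), fold=1.0)
        tab = de_mirna(m, ("A", "B"))
        assert not tab["de"].any()

    def test_planted_eightfold_change_called_with_sign(self):
        rng = np.random.default_rng(1)
        design = {"a0": "A", "a1": "A", "a2": "A", "b0": "B", "b1": "B", "b2": "B"}
        base = rng.poisson(200.0, size=(30, 6)).astype(float)
        vals = pd.DataFrame(base, index=[f"m{j}" for j in range(30)],
                            columns=list(design))
        vals.iloc[0, :3] *= 8  # up in A
        m = ExpressionMatrix(vals, "count", design)
        tab = de_mirna(m, ("A", "B"))
        assert bool(tab.iloc[0]["de"])
        assert tab.iloc[0]["direction"] == "up"
        assert tab.iloc[1:]["de"].sum() == 0

    def test_group_swap_negates_log2fc_and_preserves_calls(self):
        rng = np.random.default_rng(2)
        m = self._counts(rng, fold=4.0)
        ab = de_mirna(m, ("A", "B"))
        ba = de_mirna(m, ("B", "A"))
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert (ab["de"] == ba["de"]).all()

    def test_missing_contrast_group_rejected(self):
        m = self._counts(np.random.default_rng(0))
        with pytest.raises(ValueError, match="petal"):
            de_mirna(m, ("A", "petal"))


class TestBh:
    def test_hand_worked_step_up(self):
        # p = [.01,.02,.03,.04], m=4: adjusted all equal 0.04
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


class TestBaseComposition:
    def test_uniform_first_bases(self):
        seqs = ["A" + "C" * 20, "C" + "C" * 20, "G" + "C" * 20, "U" + "C" * 20]
        tab = base_composition(seqs)
        assert np.allclose(tab.loc[21], 0.25)

    def test_all_u_class(self):
        tab = base_composition(["U" * 21, "UA" * 10 + "U"])
        assert tab.at[21, "U"] == 1.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        seqs = [
            "".join(rng.choice(list("ACGU"), rng.integers(18, 25)))
            for _ in range(60)
        ]
        tab = base_composition(seqs)
        assert np.allclose(tab.sum(axis=1), 1.0)

    def test_identical_matures_collapse(self):
        recs = [
            MirnaRecord("m1", "ACGUACGUACGUACGUACGUA", False),
            MirnaRecord("m2", "ACGUACGUACGUACGUACGUA", True),
            MirnaRecord("m3", "UUUUACGUACGUACGUACGUA", False),
        ]
        collapsed = collapse_identical_matures(recs)
        assert len(collapsed) == 2
        assert any(r.is_te_related for r in collapsed)
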