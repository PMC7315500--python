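import numpy as np
import pandas as pd
import pytest

from mirisonet.core_io import ExpressionMatrix
from mirisonet.divergence import (
    category_proportions,
    category_shift,
    enrichment_from_counts,
    find_giddm,
    homolog_category,
    targeted_vs_untargeted,
)
from mirisonet.network import ModuleAssignment


def _assignment(mapping):
    return ModuleAssignment(labels=pd.Series(mapping, dtype=object))


class TestGiddm:
    def test_two_modules_is_giddm(self):
        asn = _assignment({"g1.1": "blue", "g1.2": "brown"})
        rep = find_giddm(asn, {"g1.1": "g1", "g1.2": "g1"})
        assert rep.giddm_genes == {"g1"}

    def test_grey_isoforms_ignored(self):
        asn = _assignment({"g1.1": "blue", "g1.2": "blue", "g1.3": "grey"})
        rep = find_giddm(asn, {f"g1.{i}": "g1" for i in (1, 2, 3)})
        assert rep.giddm_genes == set()
        assert rep.n_genes_multi_isoform_assigned == 1

    def test_single_assigned_isoform_not_counted(self):
        asn = _assignment({"g1.1": "blue", "g1.2": "grey"})
        rep = find_giddm(asn, {"g1.1": "g1", "g1.2": "g1"})
        assert rep.n_genes_multi_isoform_assigned == 0

    def test_missing_gene_mapping_rejected(self):
        asn = _assignment({"x.1": "blue"})
        with pytest.raises(KeyError, match="x.1"):
            find_giddm(asn, {})

    def test_targeted_giddm_flagging(self):
        asn = _assignment({"g1.1": "blue", "g1.2": "brown", "g2.1": "blue", "g2.2": "brown"})
        gm = {"g1.1": "g1", "g1.2": "g1", "g2.1": "g2", "g2.2": "g2"}
        sites = pd.DataFrame({"isoform_id": ["g1.1"]})
        rep = find_giddm(asn, gm, sites)
        assert rep.giddm_genes == {"g1", "g2"}
        assert rep.targeted_giddm_genes == {"g1"}

    def test_planted_split_module_genes_recovered(self, default_dataset):
        truth = default_dataset.truth_modules
        asn = ModuleAssignment(
            labels=truth.replace("flat", "grey").astype(object)
        )
        rep = find_giddm(asn, default_dataset.gene_map)
        planted = {
            g
            for g, sub in truth.groupby(
                pd.Series(default_dataset.gene_map)[truth.index]
            )
            if len(set(sub) - {"flat"}) >= 2 and (sub != "flat").sum() >= 2
        }
        assert rep.giddm_genes == planted
        assert len(planted) > 0


class TestHubEnrichment:
    def test_equal_proportions_not_significant(self):
        res = enrichment_from_counts(40, 400, 10, 100)
        assert res.pvalue > 0.5

    def test_strong_hub_bias_significant(self):
        res = enrichment_from_counts(
            n_targeted_module=184, module_size=2260, n_targeted_hubs=51, hub_size=150
        )
        assert round(100 * res.proportion_background, 2) == 8.14
        assert round(100 * res.proportion_study, 1) == 34.0
        assert res.pvalue < 0.01

    def test_chi2_agrees_with_fisher_oracle(self):
        from scipy.stats import fisher_exact

        # hubs 50/200 targeted vs non-hubs 60/200: all cells >= 20
        res = enrichment_from_counts(110, 400, 50, 200)
        _, p_f = fisher_exact([[50, 150], [60, 140]])
        assert res.pvalue == pytest.approx(p_f, rel=0.10)


class TestTargetedVsUntargeted:
    def _fpkm(self, rows, features):
        design = {"s1": "leaf", "s2": "leaf"}
        vals = pd.DataFrame(rows, index=features, columns=list(design))
        return ExpressionMatrix(vals.astype(float), "FPKM", design)

    def test_identical_values_give_unit_pvalue(self):
        features = [f"g{i}.{j}" for i in range(6) for j in (1, 2)]
        gm = {f: f.split(".")[0] for f in features}
        fpkm = self._fpkm(np.full((12, 2), 7.0), features)
        sites = pd.DataFrame({"isoform_id": [f for f in features if f.endswith(".1")]})
        res = targeted_vs_untargeted(fpkm, gm, sites, "leaf")
        assert res.median_difference == 0.0
        assert res.pvalue == 1.0

    def test_planted_higher_targeted_expression_detected(self):
        rng = np.random.default_rng(0)
        features, rows = [], []
        for i in range(12):
            features += [f"g{i}.1", f"g{i}.2"]
            base = rng.uniform(5, 10)
            rows.append([base * 4] * 2)  # targeted isoform 4x higher
            rows.append([base] * 2)
        gm = {f: f.split(".")[0] for f in features}
        fpkm = self._fpkm(np.array(rows), features)
        sites = pd.DataFrame({"isoform_id": [f for f in features if f.endswith(".1")]})
        res = targeted_vs_untargeted(fpkm, gm, sites, "leaf")
        assert res.median_difference > 0
        assert res.pvalue < 0.05

    def test_genes_without_both_classes_excluded(self):
        features = ["g1.1", "g1.2", "g2.1", "g2.2"]
        gm = {f: f.split(".")[0] for f in features}
        fpkm = self._fpkm(np.arange(8, dtype=float).reshape(4, 2), features)
        # g2 fully targeted -> contributes nothing
        sites = pd.DataFrame({"isoform_id": ["g1.1", "g2.1", "g2.2"]})
        res = targeted_vs_untargeted(fpkm, gm, sites, "leaf")
        assert res.n_genes == 1
        assert res.low_power


class TestHomologCategories:
    def test_same_species_isoform_is_category_ii(self):
        gm = {"g.1": "g", "g.2": "g"}
        hits = {"g.1": ("X", "X.1"), "g.2": ("X", "X.1")}
        assert homolog_category(gm, hits)["g"].category == "II"

    def test_different_isoforms_same_gene_is_iii(self):
        gm = {"g.1": "g", "g.2": "g"}
        hits = {"g.1": ("X", "X.1"), "g.2": ("X", "X.2")}
        assert homolog_category(gm, hits)["g"].category == "III"

    def test_different_genes_is_i_with_precedence(self):
        gm = {"g.1": "g", "g.2": "g", "g.3": "g"}
        hits = {"g.1": ("X", "X.1"), "g.2": ("X", "X.2"), "g.3": ("Y", "Y.1")}
        assert homolog_category(gm, hits)["g"].category == "I"

    def test_precedence_is_order_invariant(self):
        gm = {"g.1": "g", "g.2": "g", "g.3": "g"}
        hits = {"g.1": ("X", "X.1"), "g.2": ("X", "X.2"), "g.3": ("Y", "Y.1")}
        for order in (["g.1", "g.2", "g.3"], ["g.3", "g.1", "g.2"]):
            shuffled = {k: hits[k] for k in order}
            assert homolog_category(gm, shuffled)["g"].category == "I"

    def test_single_hit_genes_excluded(self):
        gm = {"g.1": "g", "g.2": "g"}
        hits = {"g.1": ("X", "X.1")}
        assert homolog_category(gm, hits) == {}

    def test_malformed_hit_rejected(self):
        gm = {"g.1": "g", "g.2": "g"}
        hits = {"g.1": ("X", "X.1", "extra"), "g.2": ("X", "X.1")}
        with pytest.raises(ValueError, match="single"):
            homolog_category(gm, hits)

    def test_planted_categories_recovered_exactly(self, default_dataset):
        gm = default_dataset.gene_map
        for species, table in default_dataset.truth_homologs.items():
            best = {
                r.isoform_id: (r.sp_gene, r.sp_isoform)
                for r in table.itertuples(index=False)
            }
            cats = homolog_category(gm, best)
            truth = default_dataset.truth_categories[species]
            got = {g: c.category for g, c in cats.items()}
            assert got == truth

    def test_category_shift_arithmetic(self):
        gm = {f"g{i}.{j}": f"g{i}" for i in range(4) for j in (1, 2)}
        hits = {}
        for i, cat in enumerate(["I", "I", "II", "III"]):
            if cat == "I":
                hits[f"g{i}.1"] = (f"X{i}", f"X{i}.1")
                hits[f"g{i}.2"] = (f"Y{i}", f"Y{i}.1")
            elif cat == "II":
                hits[f"g{i}.1"] = hits[f"g{i}.2"] = (f"X{i}", f"X{i}.1")
            else:
                hits[f"g{i}.1"] = (f"X{i}", f"X{i}.1")
                hits[f"g{i}.2"] = (f"X{i}", f"X{i}.2")
        cats = homolog_category(gm, hits)
        props = category_proportions(cats)
        assert props["I"] == 0.5
        shift = category_shift(cats, {"g0", "g1"})
        assert shift.at["I", "subset"] == 1.0
        assert shift.at["I", "difference"] == pytest.approx(0.5)
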