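"""Two-step normalization, distribution classes, LCA rule, EC resolution."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcaprof.distribution import (
    AverageMatrix,
    build_presence,
    clade_average,
    classify,
    ec_presence,
    genus_average,
    infer_lca,
)
from lcaprof.hits import FilterConfig, ProfileDef
from lcaprof.taxonomy import GenomeRecord, Taxonomy

from conftest import build_taxonomy, make_hit, nested_mean_oracle


def _presence(tax, data):
    """data: genome -> {profile: 0/1}; missing cells are 0."""
    profiles = sorted({p for row in data.values() for p in row})
    m = pd.DataFrame(
        0, index=pd.Index(tax.genome_ids, name="genome_id"),
        columns=pd.Index(profiles, name="profile_id"), dtype=np.int8,
    )
    for g, row in data.items():
        for p, v in row.items():
            m.at[g, p] = v
    return m


class TestBuildPresence:
    def test_binarization_and_zero_rows(self, small_taxonomy, small_catalogue):
        hits = [
            make_hit(genome="bg1_s1", profile="P1"),
            make_hit(genome="bg1_s1", profile="P1", query="q2"),
            make_hit(genome="bg1_s1", profile="P1", query="q3"),
        ]
        m = build_presence(hits, small_taxonomy, small_catalogue)
        assert m.at["bg1_s1", "P1"] == 1
        assert set(m.index) == set(small_taxonomy.genome_ids)
        assert (m.loc["eg1_s1"] == 0).all()  # genome with no hits present

    def test_unknown_genome_raises(self, small_taxonomy, small_catalogue):
        with pytest.raises(KeyError, match="ghost"):
            build_presence(
                [make_hit(genome="ghost")], small_taxonomy, small_catalogue
            )


class TestAveraging:
    def test_genus_mean(self, small_taxonomy):
        m = _presence(
            small_taxonomy,
            {"bg1_s1": {"P1": 1}, "bg1_s2": {"P1": 0}, "bg1_s3": {"P1": 1}},
        )
        g = genus_average(m, small_taxonomy)
        assert g.values.at["bg1", "P1"] == pytest.approx(2 / 3)
        assert g.values.at["bg2", "P1"] == 0.0

    def test_single_genome_genus_identity(self, small_taxonomy):
        m = _presence(small_taxonomy, {"eg1_s1": {"P1": 1}})
        g = genus_average(m, small_taxonomy)
        assert g.values.at["eg1", "P1"] == 1.0

    def test_clade_mean_weights_genera_not_genomes(self):
        # clade with genera of 9 and 1 genomes, values 1.0 and 0.0 -> 0.5
        tax = build_taxonomy({"Bacteria": {"c1": {"gBig": 9, "gSmall": 1}}})
        data = {f"gBig_s{i}": {"P1": 1} for i in range(1, 10)}
        data["gSmall_s1"] = {"P1": 0}
        m = _presence(tax, data)
        c = clade_average(genus_average(m, tax), tax)
        assert c.values.at["c1", "P1"] == pytest.approx(0.5)
        # pooled genome mean would be 0.9 — explicitly not what we compute
        assert m["P1"].mean() == pytest.approx(0.9)

    def test_single_genus_clade_identity(self, small_taxonomy):
        m = _presence(small_taxonomy, {"ag1_s1": {"P1": 1}, "ag1_s2": {"P1": 0}})
        g = genus_average(m, small_taxonomy)
        c = clade_average(g, small_taxonomy)
        assert c.values.at["ac1", "P1"] == g.values.at["ag1", "P1"]

    def test_values_bounded_and_consistent(self, small_taxonomy):
        rng = np.random.default_rng(0)
        m = _presence(small_taxonomy, {})
        m["P1"] = rng.integers(0, 2, len(m))
        g = genus_average(m, small_taxonomy)
        c = clade_average(g, small_taxonomy)
        for a in (g, c):
            assert ((a.values >= 0) & (a.values <= 1)).all().all()
        for clade, genera in small_taxonomy.clade_genera.items():
            expected = g.values.loc[genera, "P1"].mean()
            assert abs(c.values.at[clade, "P1"] - expected) < 1e-12

    def test_exact_mode_matches_oracle(self, small_taxonomy):
        rng = np.random.default_rng(1)
        m = _presence(small_taxonomy, {})
        m["P1"] = rng.integers(0, 2, len(m))
        c = clade_average(
            genus_average(m, small_taxonomy, exact=True),
            small_taxonomy,
            exact=True,
        )
        oracle = nested_mean_oracle(m, small_taxonomy)
        for clade in c.values.index:
            assert c.values.at[clade, "P1"] == oracle[(clade, "P1")]

    def test_level_mismatch_rejected(self, small_taxonomy):
        m = _presence(small_taxonomy, {"bg1_s1": {"P1": 1}})
        g = genus_average(m, small_taxonomy)
        with pytest.raises(ValueError, match="genus-level"):
            clade_average(AverageMatrix(values=g.values, level="clade"),
                          small_taxonomy)


@st.composite
def random_instances(draw):
    """Random nested taxonomy (<=3 domains x <=4 clades x <=4 genera x <=5
    genomes) with random binary presence for one enzyme."""
    domains = draw(st.sampled_from([1, 2, 3]))
    shape: dict = {}
    records = []
    presence = {}
    names = ["Bacteria", "Archaea", "Eukarya"][:domains]
    for d, domain in enumerate(names):
        for c in range(draw(st.integers(1, 4))):
            clade = f"d{d}c{c}"
            for g in range(draw(st.integers(1, 4))):
                genus = f"{clade}g{g}"
                for s in range(draw(st.integers(1, 5))):
                    gid = f"{genus}s{s}"
                    records.append(
                        GenomeRecord(gid, domain, clade, genus, 2000)
                    )
                    presence[gid] = draw(st.integers(0, 1))
    return Taxonomy(records), presence


class TestTwoStepOracle:
    @given(inst=random_instances())
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force_nested_means(self, inst):
        tax, presence = inst
        m = pd.DataFrame(
            {"E": [presence[g] for g in tax.genome_ids]},
            index=pd.Index(tax.genome_ids, name="genome_id"),
        )
        c = clade_average(genus_average(m, tax, exact=True), tax, exact=True)
        oracle = nested_mean_oracle(m, tax)
        for clade in c.values.index:
            assert c.values.at[clade, "E"] == oracle[(clade, "E")]
        # float mode agrees to additive 1e-12
        cf = clade_average(genus_average(m, tax), tax)
        for clade in c.values.index:
            assert abs(cf.values.at[clade, "E"] - float(oracle[(clade, "E")])) < 1e-12

    @given(inst=random_instances())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_degenerate_nesting_equals_raw_fraction(self, inst):
        tax, presence = inst
        # collapse: one genome per genus, one genus per clade
        records = [
            GenomeRecord(r.genome_id, r.domain, f"cl_{r.genome_id}",
                         f"ge_{r.genome_id}", 2000)
            for r in tax
        ]
        flat = Taxonomy(records)
        m = pd.DataFrame(
            {"E": [presence[g] for g in flat.genome_ids]},
            index=pd.Index(flat.genome_ids, name="genome_id"),
        )
        summary = classify(
            clade_average(genus_average(m, flat), flat), flat, FilterConfig()
        )
        for domain in flat.domains():
            genomes = [r.genome_id for r in flat if r.domain == domain]
            raw = sum(presence[g] for g in genomes) / len(genomes)
            assert summary.fraction("E", domain) == pytest.approx(raw)

    @given(inst=random_instances(), flip=st.integers(0, 10 ** 6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_flipping_presence_on_is_monotone(self, inst, flip):
        tax, presence = inst
        zeros = [g for g, v in sorted(presence.items()) if v == 0]
        if not zeros:
            return
        flipped = dict(presence)
        flipped[zeros[flip % len(zeros)]] = 1

        def run(pres):
            m = pd.DataFrame(
                {"E": [pres[g] for g in tax.genome_ids]},
                index=pd.Index(tax.genome_ids, name="genome_id"),
            )
            c = clade_average(genus_average(m, tax), tax)
            s = classify(c, tax, FilterConfig())
            return c, s

        c0, s0 = run(presence)
        c1, s1 = run(flipped)
        assert (c1.values["E"] >= c0.values["E"] - 1e-12).all()
        for domain in tax.domains():
            assert s1.fraction("E", domain) >= s0.fraction("E", domain)


class TestClassify:
    def _tax_with_clades(self, n_clades):
        return build_taxonomy(
            {"Bacteria": {f"c{i}": {f"g{i}": 1} for i in range(n_clades)}}
        )

    @pytest.mark.parametrize(
        "n_present,expected",
        [(6, "widely"), (5, "partially"), (0, "absent"), (1, "sparsely")],
    )
    def test_wide_rule_strict_majority_of_clades(self, n_present, expected):
        tax = self._tax_with_clades(10)
        data = {f"g{i}_s1": {"P1": 1 if i < n_present else 0} for i in range(10)}
        m = _presence(tax, data)
        summary = classify(
            clade_average(genus_average(m, tax), tax), tax, FilterConfig()
        )
        assert summary.fraction("P1", "Bacteria") == pytest.approx(n_present / 10)
        assert summary.dist_class("P1", "Bacteria") == expected

    def test_presence_cutoff_configurable(self):
        tax = build_taxonomy({"Bacteria": {"c0": {"g0": 4}}})
        data = {f"g0_s{i}": {"P1": 1 if i == 1 else 0} for i in range(1, 5)}
        m = _presence(tax, data)
        c = clade_average(genus_average(m, tax), tax)
        lo = classify(c, tax, FilterConfig(presence_cutoff=0.0))
        hi = classify(c, tax, FilterConfig(presence_cutoff=0.3))
        assert lo.dist_class("P1", "Bacteria") == "widely"  # 1/1 clades
        assert hi.dist_class("P1", "Bacteria") == "absent"  # 0.25 <= 0.3


class TestInferLCA:
    def _summary(self, classes):
        rows = [
            {"enzyme": "E", "domain": d, "n_clades_present": 0, "n_clades": 1,
             "clade_fraction": 1.0 if cl == "widely" else 0.0, "dist_class": cl}
            for d, cl in classes.items()
        ]
        from lcaprof.distribution import DistributionSummary

        return DistributionSummary(table=pd.DataFrame(rows))

    def test_widely_in_all_three_domains_is_lca(self):
        s = self._summary(
            {"Bacteria": "widely", "Archaea": "widely", "Eukarya": "widely"}
        )
        assert infer_lca(s)["E"]

    @pytest.mark.parametrize("eukarya_class", ["partially", "sparsely", "absent"])
    def test_any_non_wide_domain_blocks_lca(self, eukarya_class):
        s = self._summary(
            {"Bacteria": "widely", "Archaea": "widely", "Eukarya": eukarya_class}
        )
        assert not infer_lca(s)["E"]

    def test_missing_domain_raises(self):
        s = self._summary({"Bacteria": "widely", "Archaea": "widely"})
        with pytest.raises(ValueError, match="Eukarya"):
            infer_lca(s)


class TestEcPresence:
    def test_subunit_and_rule(self, small_taxonomy, small_catalogue):
        m = _presence(
            small_taxonomy,
            {
                "bg1_s1": {"SU1a": 1, "SU1b": 0},
                "bg1_s2": {"SU1a": 1, "SU1b": 1},
            },
        )
        for p in small_catalogue:
            if p not in m.columns:
                m[p] = 0
        ec = ec_presence(m, small_catalogue)
        assert ec.at["bg1_s1", "6.3.5.3"] == 0  # one subunit missing
        assert ec.at["bg1_s2", "6.3.5.3"] == 1

    def test_analog_or_rule(self, small_taxonomy, small_catalogue):
        m = _presence(
            small_taxonomy,
            {
                "bg1_s1": {"AN1a": 1, "AN1b": 0},
                "bg1_s2": {"AN1a": 0, "AN1b": 0},
            },
        )
        for p in small_catalogue:
            if p not in m.columns:
                m[p] = 0
        ec = ec_presence(m, small_catalogue)
        assert ec.at["bg1_s1", "2.1.2.2"] == 1  # any analog suffices
        assert ec.at["bg1_s2", "2.1.2.2"] == 0

    def test_singles_catalogue_is_column_identity(self, small_taxonomy):
        cat = {
            "1.1.1.1": ProfileDef("1.1.1.1", "1.1.1.1", "single", "", "", 100),
            "2.2.2.2": ProfileDef("2.2.2.2", "2.2.2.2", "single", "", "", 100),
        }
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.integers(0, 2, (len(small_taxonomy), 2)).astype(np.int8),
            index=pd.Index(small_taxonomy.genome_ids, name="genome_id"),
            columns=["1.1.1.1", "2.2.2.2"],
        )
        ec = ec_presence(m, cat)
        assert (ec[m.columns] == m).all().all()

    def test_analogous_ecs_remain_distinct_columns(self, small_taxonomy):
        # 5.4.2.2 / 5.4.2.7 are different ECs for the same reaction; EC
        # resolution never merges them — step-level OR lives in pathways
        cat = {
            "PGM": ProfileDef("PGM", "5.4.2.2", "single", "", "sfA", 100),
            "PPM": ProfileDef("PPM", "5.4.2.7", "single", "", "sfB", 100),
        }
        m = _presence(small_taxonomy, {"bg1_s1": {"PGM": 1, "PPM": 0}})
        ec = ec_presence(m, cat)
        assert ec.at["bg1_s1", "5.4.2.2"] == 1
        assert ec.at["bg1_s1", "5.4.2.7"] == 0
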