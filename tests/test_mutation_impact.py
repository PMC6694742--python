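from itertools import chain, combinations

import numpy as np
import pytest
import scipy.stats

from calpsite import synthetic_data as sd
from calpsite.mutation_impact import (
    CATEGORIES,
    ImpactCall,
    affected_bonds,
    apply_missense,
    bootstrap_site_enrichment,
    categorize_site_sets,
    classify_impact,
    cohort_summary,
)
from calpsite.sequence_io import CleavageSite, MissenseVariant, Protein, extract_window


def powerset(universe):
    return [
        set(c)
        for c in chain.from_iterable(
            combinations(universe, r) for r in range(len(universe) + 1)
        )
    ]


class TestApplyMissense:
    def test_substitution(self):
        out = apply_missense(Protein("P", "MKL"), MissenseVariant("P", 2, "K", "R"))
        assert out.sequence == "MRL"

    def test_involution(self):
        prot = Protein("P", "MKL")
        fwd = apply_missense(prot, MissenseVariant("P", 2, "K", "R"))
        back = apply_missense(fwd, MissenseVariant("P", 2, "R", "K"))
        assert back.sequence == prot.sequence

    def test_last_residue(self):
        out = apply_missense(Protein("P", "MKL"), MissenseVariant("P", 3, "L", "W"))
        assert out.sequence == "MKW"

    def test_ref_mismatch(self):
        with pytest.raises(ValueError):
            apply_missense(Protein("P", "MKL"), MissenseVariant("P", 2, "L", "R"))


class TestAffectedBonds:
    def test_interior_position(self):
        assert affected_bonds(20, protein_length=100, flank=15) == set(range(5, 35))

    def test_n_terminal_truncation(self):
        assert affected_bonds(1, protein_length=100, flank=15) == set(range(1, 16))

    def test_c_terminal_truncation(self):
        assert affected_bonds(100, protein_length=100, flank=15) == set(range(85, 100))

    @pytest.mark.parametrize("pos", [1, 7, 30, 55, 60])
    def test_every_returned_bonds_window_contains_position(self, pos):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        prot = Protein("P", seq)
        for bond in affected_bonds(pos, 60, flank=15):
            win = extract_window(prot, bond, flank=15)
            offset = pos - (bond - 15 + 1)  # 0-based index of pos inside window
            assert 0 <= offset < 30
            assert win[offset] == seq[pos - 1]


class TestCategorization:
    def test_defining_cases(self):
        assert categorize_site_sets(set(), {12}) == "gain"
        assert categorize_site_sets({12, 14}, set()) == "loss"
        assert categorize_site_sets({12}, {13}) == "change"
        assert categorize_site_sets(set(), set()) == "no_change"
        assert categorize_site_sets({12}, {12}) == "no_change"
        assert categorize_site_sets({12}, {12, 13}) == "gain"

    def test_exhaustive_truth_table_is_a_partition(self):
        """Every (before, after) pair over a 3-bond universe gets exactly one category."""
        counts = dict.fromkeys(CATEGORIES, 0)
        for before in powerset({1, 2, 3}):
            for after in powerset({1, 2, 3}):
                cat = categorize_site_sets(before, after)
                assert cat in CATEGORIES
                counts[cat] += 1
                # independent re-derivation of the rules
                if before == after:
                    assert cat == "no_change"
                elif before < after:
                    assert cat == "gain"
                elif before and not after:
                    assert cat == "loss"
                else:
                    assert cat == "change"
        assert sum(counts.values()) == 64
        assert all(v > 0 for v in counts.values())


class TestClassifyImpact:
    def test_call_is_consistent_with_site_sets(self, tiny_model, synth_corpus):
        proteins, _, variants = synth_corpus
        by_id = {p.id: p for p in proteins}
        for v in variants[:10]:
            call = classify_impact(tiny_model, by_id[v.protein_id], v, threshold=0.5)
            assert call.category == categorize_site_sets(
                set(call.sites_before), set(call.sites_after)
            )
            allowed = affected_bonds(v.position, len(by_id[v.protein_id]), tiny_model.flank)
            assert set(call.sites_before) <= allowed
            assert set(call.sites_after) <= allowed

    def test_extreme_thresholds_force_no_change(self, tiny_model, synth_corpus):
        """With an unreachable threshold no bond is ever a site, before or after."""
        proteins, _, variants = synth_corpus
        by_id = {p.id: p for p in proteins}
        v = variants[0]
        call = classify_impact(tiny_model, by_id[v.protein_id], v, threshold=1.1)
        assert call.category == "no_change"
        assert not call.sites_before and not call.sites_after


class TestCohortSummary:
    def _call(self, pid, pos, cat, before=frozenset(), after=frozenset()):
        v = MissenseVariant(pid, pos, "A", "C")
        return ImpactCall(v, cat, frozenset(before), frozenset(after), 0.5)

    def test_protein_counted_once_per_category(self):
        calls = [
            self._call("P1", 1, "gain", after={5}),
            self._call("P1", 2, "gain", after={6}),
            self._call("P1", 3, "loss", before={5}),
        ]
        tab = cohort_summary(calls).set_index("category")
        assert tab.loc["gain", "n_proteins"] == 1
        assert tab.loc["loss", "n_proteins"] == 1
        assert tab.loc["gain", "n_variants"] == 2

    def test_empty_calls_all_zero(self):
        tab = cohort_summary([])
        assert (tab[["n_variants", "n_sites_affected", "n_proteins"]] == 0).all().all()

    def test_category_counts_sum_to_variant_count(self):
        calls = [
            self._call("P1", 1, "gain", after={5}),
            self._call("P2", 1, "no_change"),
            self._call("P3", 2, "change", before={4}, after={5}),
        ]
        assert cohort_summary(calls)["n_variants"].sum() == len(calls)


class TestBootstrapEnrichment:
    def test_enriched_variants_give_small_p(self, synth_corpus):
        proteins, sites, _ = synth_corpus
        near = sd.generate_variants(proteins, sites, n_near=120, n_far=0, seed=1)
        res = bootstrap_site_enrichment(
            near, sites, proteins, n_iterations=1000, seed=2
        )
        assert res.observed == 1.0
        assert res.p_value <= 0.01

    def test_p_never_below_estimator_floor(self, synth_corpus):
        proteins, sites, _ = synth_corpus
        near = sd.generate_variants(proteins, sites, n_near=50, n_far=0, seed=3)
        res = bootstrap_site_enrichment(
            near, sites, proteins, n_iterations=500, seed=4
        )
        assert res.p_value >= 1 / 501

    def test_uniform_variants_calibrate_to_ratio_one(self, synth_corpus):
        proteins, sites, _ = synth_corpus
        rng = np.random.default_rng(5)
        variants = []
        for _ in range(400):
            prot = proteins[rng.integers(len(proteins))]
            pos = int(rng.integers(1, len(prot) + 1))
            ref = prot.sequence[pos - 1]
            alt = "A" if ref != "A" else "C"
            variants.append(MissenseVariant(prot.id, pos, ref, alt))
        res = bootstrap_site_enrichment(
            variants, sites, proteins, n_iterations=2000, seed=6
        )
        assert abs(res.ratio - 1.0) < 0.1

    def test_null_p_values_approximately_uniform(self, synth_corpus):
        """p-values under the null are uniform (KS distance < 0.1 at 200 replicates)."""
        proteins, sites, _ = synth_corpus
        rng = np.random.default_rng(7)
        # enough variants per replicate that the discrete statistic's tie atoms
        # (which make the +1-corrected p conservative) are small
        pvals = []
        for rep in range(200):
            variants = []
            for _ in range(100):
                prot = proteins[rng.integers(len(proteins))]
                pos = int(rng.integers(1, len(prot) + 1))
                ref = prot.sequence[pos - 1]
                alt = "A" if ref != "A" else "C"
                variants.append(MissenseVariant(prot.id, pos, ref, alt))
            res = bootstrap_site_enrichment(
                variants, sites, proteins, n_iterations=500, seed=rep
            )
            pvals.append(res.p_value)
        ks = scipy.stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1

    def test_too_few_iterations_rejected(self, synth_corpus):
        proteins, sites, variants = synth_corpus
        with pytest.raises(ValueError):
            bootstrap_site_enrichment(variants, sites, proteins, n_iterations=10)
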