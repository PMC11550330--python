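"""LGT classification: clade / composition / short-cluster criteria and
donor inference."""

import itertools

import numpy as np
import pytest

from symbio.lgt import (
    UNASSIGNED,
    LgtParams,
    classify_short_cluster,
    classify_tree,
    infer_donor,
)
from symbio.trees import Orthogroup, read_gene_tree_string

from conftest import make_taxonomy, oracle_classify, random_annotated_tree


def classify_host(newick, classes, **kw):
    tree = read_gene_tree_string(newick)
    tax = make_taxonomy(classes)
    params = LgtParams(**kw)
    (call,) = [c for c in classify_tree(tree, tax, params) if c.gene_id == "host"]
    return call


class TestCladeCriterion:
    def test_supported_host_prok_clade(self):
        call = classify_host(
            "((host,p1)90,(e1,e2)80,e3);",
            {
                "host": ("host_query", ""),
                "p1": ("prokaryote", "Proteobacteria"),
                "e1": ("eukaryote", "Amoebozoa"),
                "e2": ("eukaryote", "Amoebozoa"),
                "e3": ("eukaryote", "Amoebozoa"),
            },
        )
        assert call.is_lgt and call.criterion == "clade"
        assert call.clade_leaves == {"host", "p1"}
        assert call.support == 90
        assert call.donor == "Proteobacteria"

    def test_no_prokaryote_anywhere_is_negative(self):
        call = classify_host(
            "((host,e1)99,(e2,e3)99);",
            {
                "host": ("host_query", ""),
                "e1": ("eukaryote", "Amoebozoa"),
                "e2": ("eukaryote", "Amoebozoa"),
                "e3": ("eukaryote", "Opisthokonta"),
            },
        )
        assert not call.is_lgt and call.criterion == "none"

    def test_one_stray_eukaryote_allowed(self):
        call = classify_host(
            "((host,p1,e1)85,(e2,e3)50,e4);",
            {
                "host": ("host_query", ""),
                "p1": ("prokaryote", "Firmicutes"),
                "e1": ("eukaryote", "Amoebozoa"),
                "e2": ("eukaryote", "Amoebozoa"),
                "e3": ("eukaryote", "Amoebozoa"),
                "e4": ("eukaryote", "Amoebozoa"),
            },
        )
        assert call.is_lgt and call.criterion == "clade"
        assert call.clade_leaves == {"host", "p1", "e1"}

    def test_two_stray_eukaryotes_block_the_clade(self):
        call = classify_host(
            "((host,p1,e1,e2)85,(e3,e4)50,e5);",
            {
                "host": ("host_query", ""),
                "p1": ("prokaryote", "Firmicutes"),
                **{f"e{i}": ("eukaryote", "Amoebozoa") for i in range(1, 6)},
            },
        )
        assert not call.is_lgt

    def test_support_below_threshold_blocks(self):
        # complements of the euk clades hold >= 2 stray eukaryotes, so only
        # the 69-support host+prok clade could fire — and it is below 70
        call = classify_host(
            "((host,p1)69,(e1,e2)99,(e3,e4)99);",
            {
                "host": ("host_query", ""),
                "p1": ("prokaryote", "Proteobacteria"),
                "e1": ("eukaryote", "Amoebozoa"),
                "e2": ("eukaryote", "Amoebozoa"),
                "e3": ("eukaryote", "Amoebozoa"),
                "e4": ("eukaryote", "Amoebozoa"),
            },
        )
        assert not call.is_lgt

    def test_smallest_qualifying_clade_recorded(self):
        # both {host,p1} and {host,p1,p2} qualify; the smaller wins
        call = classify_host(
            "(((host,p1)95,p2)90,(e1,e2)50,e3);",
            {
                "host": ("host_query", ""),
                "p1": ("prokaryote", "Proteobacteria"),
                "p2": ("prokaryote", "Firmicutes"),
                "e1": ("eukaryote", "Amoebozoa"),
                "e2": ("eukaryote", "Amoebozoa"),
                "e3": ("eukaryote", "Amoebozoa"),
            },
        )
        assert call.clade_leaves == {"host", "p1"}

    def test_no_host_leaf_raises(self):
        tree = read_gene_tree_string("((a,b)90,c);")
        tax = make_taxonomy({x: ("prokaryote", "Firmicutes") for x in "abc"})
        with pytest.raises(ValueError, match="host"):
            classify_tree(tree, tax)


class TestCompositionCriterion:
    def test_boundary_19_of_20_fires(self):
        # host + 19 prokaryotes, all supports 50: 19/20 = 0.95 >= 0.95
        leaves = [f"p{i:02d}" for i in range(19)]
        inner = leaves[0]
        for p in leaves[1:]:
            inner = f"({inner},{p})50"
        newick = f"({inner},host);"
        classes = {"host": ("host_query", "")}
        classes.update({p: ("prokaryote", "Proteobacteria") for p in leaves})
        call = classify_host(newick, classes)
        assert call.is_lgt and call.criterion == "composition"

    def test_below_fraction_is_negative(self):
        call = classify_host(
            "((p1,p2)50,host,e1);",
            {
                "host": ("host_query", ""),
                "p1": ("prokaryote", "Firmicutes"),
                "p2": ("prokaryote", "Firmicutes"),
                "e1": ("eukaryote", "Amoebozoa"),
            },
        )
        assert not call.is_lgt

    def test_invariant_to_topology_at_fixed_composition(self, rng):
        """Criterion ii depends only on the leaf composition."""
        leaves = [f"p{i:02d}" for i in range(19)] + ["host"]
        classes = {"host": ("host_query", "")}
        classes.update(
            {l: ("prokaryote", "Proteobacteria") for l in leaves if l != "host"}
        )
        results = set()
        for _ in range(10):
            order = [leaves[i] for i in rng.permutation(len(leaves))]
            inner = order[0]
            for l in order[1:-1]:
                inner = f"({inner},{l})50"
            newick = f"({inner},{order[-1]});"
            call = classify_host(newick, classes)
            results.add((call.is_lgt, call.criterion))
        assert results == {(True, "composition")}


class TestShortCluster:
    tax = make_taxonomy(
        {
            "host1": ("host_query", ""),
            "host2": ("host_query", ""),
            "b1": ("prokaryote", "Proteobacteria"),
            "b2": ("prokaryote", "Proteobacteria"),
            "e1": ("eukaryote", "Amoebozoa"),
            "v1": ("virus", "Naldaviricetes"),
        }
    )

    def _og(self, members):
        return Orthogroup("OG1", list(members), {m: "BMAN" for m in members})

    def test_all_prokaryotic_cluster_is_lgt(self):
        (call,) = classify_short_cluster(self._og(["host1", "b1", "b2"]), self.tax, 60)
        assert call.is_lgt and call.criterion == "short_cluster"
        assert call.donor == "Proteobacteria"

    def test_mixed_cluster_is_not(self):
        (call,) = classify_short_cluster(self._og(["host1", "b1", "e1"]), self.tax, 60)
        assert not call.is_lgt

    def test_viral_cluster_donor(self):
        calls = classify_short_cluster(self._og(["host1", "host2", "v1"]), self.tax, 40)
        assert len(calls) == 2
        assert all(c.is_lgt and c.donor == "Naldaviricetes" for c in calls)

    def test_host_only_cluster_warns_and_is_negative(self):
        with pytest.warns(UserWarning, match="only host"):
            calls = classify_short_cluster(self._og(["host1", "host2"]), self.tax, 40)
        assert all(not c.is_lgt for c in calls)

    def test_long_alignment_rejected(self):
        with pytest.raises(ValueError, match="classify_tree"):
            classify_short_cluster(self._og(["host1", "b1"]), self.tax, 80)


class TestDonorInference:
    tax = make_taxonomy(
        {
            "host": ("host_query", ""),
            "g1": ("prokaryote", "Proteobacteria"),
            "g2": ("prokaryote", "Proteobacteria"),
            "f1": ("prokaryote", "Firmicutes"),
            "b1": ("prokaryote", "Bacteroidota"),
        }
    )

    def test_majority_share(self):
        assert (
            infer_donor({"host", "g1", "g2", "f1"}, self.tax) == "Proteobacteria"
        )

    def test_exact_tie_unassigned(self):
        assert infer_donor({"host", "f1", "b1"}, self.tax) == UNASSIGNED

    def test_single_non_host(self):
        assert infer_donor({"host", "b1"}, self.tax) == "Bacteroidota"

    def test_empty_clade_raises(self):
        with pytest.raises(ValueError):
            infer_donor(set(), self.tax)

    def test_unassigned_exactly_on_ties_exhaustive(self):
        """With the strict default majority, unassigned <=> no group holds
        a strict plurality share above 1/2 — exhaustively for all clade
        compositions over three phyla with up to 6 non-host leaves."""
        phyla = ("Proteobacteria", "Firmicutes", "Bacteroidota")
        pool = {"host": ("host_query", "")}
        for i, ph in enumerate(phyla):
            for j in range(6):
                pool[f"{ph[:2].lower()}{j}"] = ("prokaryote", ph)
        tax = make_taxonomy(pool)
        for total in range(1, 7):
            for counts in itertools.product(range(total + 1), repeat=3):
                if sum(counts) != total:
                    continue
                clade = {"host"}
                for ph, c in zip(phyla, counts):
                    clade |= {f"{ph[:2].lower()}{j}" for j in range(c)}
                donor = infer_donor(clade, tax)
                top = max(counts)
                if top / total > 0.5:
                    expected = phyla[counts.index(top)]
                    assert donor == expected
                else:
                    assert donor == UNASSIGNED


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_trees(self, rng):
        """Classifier output equals a literal bipartition-enumeration oracle
        (independent parser) on random annotated trees."""
        for _ in range(100):
            newick, classes = random_annotated_tree(rng)
            call = classify_host(newick, classes)
            is_lgt, criterion, clade, support = oracle_classify(newick, classes)
            assert call.is_lgt == is_lgt
            assert call.criterion == criterion
            if criterion == "clade":
                assert call.clade_leaves == clade
                assert call.support == support


class TestMonotonicity:
    def test_raising_threshold_never_creates_calls(self, rng):
        trees = []
        for _ in range(30):
            newick, classes = random_annotated_tree(rng)
            trees.append((newick, classes))
        prev_count = None
        for thr in (50, 60, 70, 80, 90, 95):
            count = 0
            positives = set()
            for i, (newick, classes) in enumerate(trees):
                call = classify_host(newick, classes, support_threshold=thr)
                if call.is_lgt:
                    count += 1
                    positives.add(i)
            if prev_count is not None:
                assert count <= prev_count
                assert positives <= prev_positives
            prev_count, prev_positives = count, positives


class TestParams:
    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            LgtParams(support_threshold=101)
        with pytest.raises(ValueError):
            LgtParams(composition_fraction=0.0)
        with pytest.raises(ValueError):
            LgtParams(composition_gate="sometimes")

    def test_host_excluded_denominator_flag(self):
        # 19 prok + host: default 19/20 fires; excluding host, 19/19 fires too,
        # but 18 prok + 1 euk + host: 18/20 fails, 18/19 still fails, while
        # 19 prok + 1 euk + host: 19/21 fails default, 19/20 = 0.95 fires
        leaves = [f"p{i:02d}" for i in range(19)] + ["e1"]
        inner = leaves[0]
        for l in leaves[1:]:
            inner = f"({inner},{l})50"
        newick = f"({inner},host);"
        classes = {"host": ("host_query", ""), "e1": ("eukaryote", "Amoebozoa")}
        classes.update(
            {l: ("prokaryote", "Proteobacteria") for l in leaves if l != "e1"}
        )
        assert not classify_host(newick, classes).is_lgt
        call = classify_host(newick, classes, include_host_in_denominator=False)
        assert call.is_lgt and call.criterion == "composition"
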