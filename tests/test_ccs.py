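import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from ccsconv import (
    OrthologAlignment,
    SpeciesDesign,
    aggregate,
    classify_site,
    generate_study,
    scan_gene,
    symmetric_chi2,
)

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_classify(column, design, threshold):
    """Independent literal transcription of the conservative-convergence
    rule, used as the oracle for classify_site."""
    O = column[design.outgroup]
    if O not in AMINO:
        return ("none", None)

    def all_equal_o(taxa):
        return all(column[t] == O and column[t] in AMINO for t in taxa)

    cons_fg = all_equal_o(design.background_taxa)   # controls match O
    cons_bg = all_equal_o(design.foreground_taxa)
    if cons_fg and cons_bg:
        return ("none", None)

    def called(clusters):
        hits = []
        for d in AMINO:
            if d == O:
                continue
            if all(
                sum(column[t] == d for t in cl) >= threshold for cl in clusters
            ):
                hits.append(d)
        return hits[0] if len(hits) == 1 else None

    if cons_fg:
        return ("foreground", called(design.foreground_clusters))
    if cons_bg:
        return ("background", called(design.background_clusters))
    return ("none", None)


@pytest.fixture
def design17(topo17):
    return topo17[1]


def make_column(design, outgroup, fg1, fg2, bg1, bg2):
    col = {design.outgroup: outgroup}
    for taxa, states in zip(
        (*design.foreground_clusters, *design.background_clusters),
        (fg1, fg2, bg1, bg2),
    ):
        col.update(dict(zip(taxa, states)))
    return col


class TestClassifySite:
    def test_full_parallel_substitution_pattern(self, design17):
        # ancestral D in outgroup and all controls, derived E in all eight
        # foreground taxa: the canonical convergent call
        col = make_column(design17, "D", "EEEE", "EEEE", "DDDD", "DDDD")
        call = classify_site(col, design17, column_index=401)
        assert call.is_convergent and call.direction == "foreground"
        assert call.ancestral_state == "D" and call.derived_state == "E"
        assert call.substitution_label == "D401E"
        assert len(call.supporting_taxa) == 8

    def test_invariant_column_not_convergent(self, design17):
        col = make_column(design17, "K", "KKKK", "KKKK", "KKKK", "KKKK")
        call = classify_site(col, design17)
        assert not call.is_convergent
        assert call.direction == "none"

    def test_three_of_four_per_cluster(self, design17):
        # I -> V in 3 of 4 taxa of each foreground cluster (fourth taxon
        # carries I or an unrelated residue): still a call with 6 supporters
        col = make_column(design17, "I", "VVVI", "VVVL", "IIII", "IIII")
        call = classify_site(col, design17, column_index=515)
        assert call.is_convergent and call.derived_state == "V"
        assert call.substitution_label == "I515V"
        assert len(call.supporting_taxa) == 6

    def test_two_of_four_insufficient(self, design17):
        col = make_column(design17, "I", "VVII", "VVII", "IIII", "IIII")
        assert not classify_site(col, design17).is_convergent

    def test_background_direction_is_symmetric(self, design17):
        col = make_column(design17, "D", "DDDD", "DDDD", "EEEE", "EEEE")
        call = classify_site(col, design17)
        assert call.is_convergent and call.direction == "background"
        swapped = classify_site(col, design17.swapped())
        assert swapped.direction == "foreground"

    def test_gapped_outgroup_skipped(self, design17):
        col = make_column(design17, "-", "EEEE", "EEEE", "DDDD", "DDDD")
        call = classify_site(col, design17)
        assert call.direction == "none" and not call.is_convergent

    def test_gap_in_control_breaks_conservativeness(self, design17):
        col = make_column(design17, "D", "EEEE", "EEEE", "DDD-", "DDDD")
        assert not classify_site(col, design17).is_convergent

    def test_gap_does_not_support_derived(self, design17):
        col = make_column(design17, "D", "EE--", "EEEE", "DDDD", "DDDD")
        assert not classify_site(col, design17).is_convergent

    def test_missing_design_taxon_raises(self, design17):
        col = make_column(design17, "D", "EEEE", "EEEE", "DDDD", "DDDD")
        del col[design17.outgroup]
        with pytest.raises(KeyError):
            classify_site(col, design17)

    def test_total_support_mode(self, design17):
        # 4+2 split: rejected per-cluster, accepted in total mode (>= 6 of 8)
        col = make_column(design17, "D", "EEEE", "EEDD", "DDDD", "DDDD")
        assert not classify_site(col, design17).is_convergent
        call = classify_site(col, design17, support_mode="total")
        assert call.is_convergent and call.derived_state == "E"

    def test_ambiguous_two_residues_rejected(self, reduced_design):
        # with 2+2 clusters and threshold 2, both E and W meet the rule
        col = {
            "out": "D", "p1a": "E", "p1b": "W", "p2a": "E", "p2b": "W",
            "a1a": "D", "a1b": "D", "a2a": "D", "a2b": "D",
        }
        call = classify_site(col, reduced_design, min_shared_per_cluster=2)
        assert not call.is_convergent

    def test_matches_brute_force_on_random_columns(self, design17, rng):
        states = list(AMINO[:6]) + ["-", "X"]
        for _ in range(300):
            col = {t: rng.choice(states) for t in design17.all_taxa}
            expected = brute_force_classify(col, design17, 3)
            call = classify_site(col, design17)
            got = (
                call.direction,
                call.derived_state if call.is_convergent else None,
            )
            assert got == expected


class TestScanGene:
    def test_planted_sites_recovered_exactly(self):
        study = generate_study(
            n_genes=4, gene_length=100, planted_fg=6, planted_bg=2, seed=3
        )
        for gene in study.genes:
            calls = scan_gene(gene, study.design)
            called = {(c.column, c.direction) for c in calls}
            planted = {(col, d) for col, d, _ in study.truth[gene.gene_id]}
            assert planted <= called

    def test_identical_columns_no_calls(self, design17):
        seqs = {t: "MKVDEW" * 10 for t in design17.all_taxa}
        aln = OrthologAlignment("g", design17.all_taxa, seqs)
        assert scan_gene(aln, design17) == []

    def test_multi_site_gene(self, design17):
        # two convergent columns in one gene: the multi-site phenomenon
        base = {t: "MKV" for t in design17.all_taxa}
        col1 = make_column(design17, "D", "EEEE", "EEEE", "DDDD", "DDDD")
        col2 = make_column(design17, "K", "RRRR", "RRRR", "KKKK", "KKKK")
        seqs = {
            t: base[t] + col1[t] + "W" + col2[t] for t in design17.all_taxa
        }
        aln = OrthologAlignment("g", design17.all_taxa, seqs)
        calls = scan_gene(aln, design17)
        assert [(c.column, c.substitution_label) for c in calls] == [
            (4, "D4E"), (6, "K6R")
        ]
        report = aggregate({"g": calls})
        assert report.multi_site_genes == 1

    def test_scan_agrees_with_per_column_classifier(self, design17, rng):
        states = list("ADEK") + ["-"]
        seqs = {
            t: "".join(rng.choice(states, size=80)) for t in design17.all_taxa
        }
        aln = OrthologAlignment("g", design17.all_taxa, seqs)
        scanned = {
            c.column: (c.direction, c.derived_state)
            for c in scan_gene(aln, design17)
        }
        for col in range(1, 81):
            call = classify_site(aln.column(col), design17, column_index=col)
            if call.is_convergent:
                assert scanned[col] == (call.direction, call.derived_state)
            else:
                assert col not in scanned

    def test_threshold_monotonicity(self, design17, rng):
        states = list("ADE")
        seqs = {
            t: "".join(rng.choice(states, size=200)) for t in design17.all_taxa
        }
        aln = OrthologAlignment("g", design17.all_taxa, seqs)
        n_calls = [
            len(scan_gene(aln, design17, min_shared_per_cluster=t))
            for t in (2, 3, 4)
        ]
        assert n_calls == sorted(n_calls, reverse=True)

    def test_label_swap_symmetry(self, rng):
        study = generate_study(
            n_genes=3, gene_length=150, planted_fg=4, planted_bg=1, seed=9
        )
        for gene in study.genes:
            fwd = scan_gene(gene, study.design)
            rev = scan_gene(gene, study.design.swapped())
            count = lambda calls, d: sum(c.direction == d for c in calls)
            assert count(fwd, "foreground") == count(rev, "background")
            assert count(fwd, "background") == count(rev, "foreground")

    def test_drop_gapped_columns(self, design17):
        col = make_column(design17, "D", "EEEE", "EEEE", "DDDD", "DDDD")
        seqs = {}
        for t in design17.all_taxa:
            gap = "-" if t == design17.all_taxa[3] else "M"
            seqs[t] = gap + col[t]
        aln = OrthologAlignment("g", design17.all_taxa, seqs)
        with_gaps = scan_gene(aln, design17, drop_gapped_columns=False)
        trimmed = scan_gene(aln, design17, drop_gapped_columns=True)
        assert [c.column for c in with_gaps] == [2]
        assert [c.column for c in trimmed] == [2]  # original coordinates kept


class TestAggregate:
    def test_totals_arithmetic(self, design17):
        def call(gene, col, direction):
            column = make_column(
                design17, "D",
                *(("EEEE", "EEEE", "DDDD", "DDDD") if direction == "foreground"
                  else ("DDDD", "DDDD", "EEEE", "EEEE")),
            )
            return classify_site(column, design17, column_index=col, gene_id=gene)

        gene_calls = {
            "g1": [call("g1", 1, "foreground"), call("g1", 2, "foreground")],
            "g2": [call("g2", 1, "foreground"), call("g2", 2, "background")],
            "g3": [],
        }
        report = aggregate(gene_calls)
        assert (report.foreground_count, report.background_count) == (3, 1)
        assert report.genes_with_foreground == 2
        assert report.multi_site_genes == 1
        assert report.chi2_stat == pytest.approx(1.0)
        assert report.p_value == pytest.approx(chi2_dist.sf(1.0, 1))

    def test_empty_input(self):
        report = aggregate({})
        assert report.foreground_count == report.background_count == 0
        assert report.chi2_stat is None and report.p_value is None

    def test_totals_equal_per_gene_sums(self, rng):
        study = generate_study(
            n_genes=6, gene_length=120, planted_fg=8, planted_bg=5, seed=21
        )
        gene_calls = {g.gene_id: scan_gene(g, study.design) for g in study.genes}
        report = aggregate(gene_calls)
        assert report.foreground_count == sum(
            len(v["foreground"]) for v in report.per_gene.values()
        )
        assert report.background_count == sum(
            len(v["background"]) for v in report.per_gene.values()
        )


class TestSymmetricChi2:
    def test_equal_counts_no_signal(self):
        stat, p = symmetric_chi2(10, 10)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_three_one(self):
        stat, p = symmetric_chi2(3, 1)
        assert stat == pytest.approx(1.0)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_paper_scale_counts_significant(self):
        _, p = symmetric_chi2(125, 36)
        assert p < 0.05

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            symmetric_chi2(0, 0)

    @given(f=st.integers(0, 500), b=st.integers(0, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_textbook_formula(self, f, b):
        if f + b == 0:
            return
        stat, p = symmetric_chi2(f, b)
        assert stat == pytest.approx((f - b) ** 2 / (f + b))
        assert p == pytest.approx(float(chi2_dist.sf(stat, 1)))
        # order of arguments never matters
        assert symmetric_chi2(b, f) == (stat, p)
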