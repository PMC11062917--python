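"""Domain merging, TSS annotation, CRE assignment, and enrichment statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from garfinder.enrichment import (
    annotate_tss,
    assign_cres,
    domain_size_diagnostic,
    gene_gar_enrichment,
    merge_contact_domains,
    overlap_test,
)
from garfinder.gff import GeneModel, Transcript
from garfinder.intervals import GenomicInterval, IntervalSet


def iv(start, end, id="", chrom="chr1"):
    return GenomicInterval(chrom, start, end, id)


def hypergeom_oracle(N, K, n, k):
    """Exact combinatorial tail P(X >= k) via integer arithmetic."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / total


class TestMergeContactDomains:
    def test_nested_collapse_to_outer(self):
        out = merge_contact_domains(IntervalSet([iv(0, 100), iv(10, 90)]))
        assert [(d.start, d.end) for d in out] == [(0, 100)]

    def test_identical_collapse_to_one(self):
        out = merge_contact_domains(
            [IntervalSet([iv(0, 100)]), IntervalSet([iv(0, 100)])]
        )
        assert len(out) == 1

    def test_partial_overlap_both_retained(self):
        out = merge_contact_domains(IntervalSet([iv(0, 100), iv(50, 150)]))
        assert [(d.start, d.end) for d in out] == [(0, 100), (50, 150)]

    def test_disjoint_retained_unchanged(self):
        out = merge_contact_domains(IntervalSet([iv(0, 100), iv(200, 300)]))
        assert [(d.start, d.end) for d in out] == [(0, 100), (200, 300)]

    @given(
        st.lists(
            st.tuples(st.integers(0, 400), st.integers(1, 120)), max_size=40
        )
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_containment_free_and_idempotent(self, raw):
        pool = IntervalSet([iv(s, s + l) for s, l in raw])
        merged = merge_contact_domains(pool)
        ds = list(merged)
        for i, a in enumerate(ds):
            for b in ds[i + 1 :]:
                assert not (a.contains(b) or b.contains(a))
        assert merge_contact_domains(merged) == merged
        # every input domain is contained in some output domain
        for d in pool:
            assert any(o.contains(d) for o in ds)


def make_gene(gene_id, exon_spans, strand, chrom="chr1"):
    exons = [GenomicInterval(chrom, s, e, strand=strand) for s, e in exon_spans]
    return GeneModel(gene_id, [Transcript(f"{gene_id}.t1", strand, exons)])


class TestAnnotateTss:
    GENOME = {"chr1": "C" * 5000 + "ATG" + "C" * 4000}

    def test_plus_strand_atg_start_1kb_upstream(self):
        g = make_gene("g", [(5000, 5200), (6000, 6100)], "+")
        (t,) = annotate_tss([g], self.GENOME)
        assert (t.tss_position, t.rule_used) == (4000, "atg_1kb")

    def test_plus_strand_utr_start_1bp_upstream(self):
        g = make_gene("g", [(4000, 4200)], "+")  # genome has C here
        (t,) = annotate_tss([g], self.GENOME)
        assert (t.tss_position, t.rule_used) == (3999, "utr_1bp")

    def test_minus_strand_atg_mirrored(self):
        # first exon in transcript orientation = rightmost; its last 3 bases
        # must read ATG after reverse complement -> genomic "CAT"
        genome = {"chr1": "G" * 5197 + "CAT" + "G" * 3000}
        g = make_gene("g", [(4000, 4100), (5000, 5200)], "-")
        (t,) = annotate_tss([g], genome)
        assert (t.tss_position, t.rule_used) == (6200, "atg_1kb")

    def test_minus_strand_utr_1bp(self):
        genome = {"chr1": "G" * 9000}
        g = make_gene("g", [(5000, 5200)], "-")
        (t,) = annotate_tss([g], genome)
        assert (t.tss_position, t.rule_used) == (5201, "utr_1bp")

    def test_short_first_exon_falls_back_with_warning(self):
        g = make_gene("g", [(5000, 5002)], "+")
        with pytest.warns(UserWarning, match="shorter than 3"):
            (t,) = annotate_tss([g], self.GENOME)
        assert t.rule_used == "utr_1bp"

    def test_tss_clipped_at_chromosome_start(self):
        g = make_gene("g", [(500, 700)], "+")
        genome = {"chr1": "ATG" + "C" * 1000}
        genome = {"chr1": "C" * 500 + "ATG" + "C" * 500}
        (t,) = annotate_tss([g], genome)
        assert t.tss_position == 0  # 500 - 1000 clipped

    def test_longest_transcript_is_representative(self):
        tx_short = Transcript("g.t1", "+", [GenomicInterval("chr1", 4000, 4100)])
        tx_long = Transcript(
            "g.t2", "+",
            [GenomicInterval("chr1", 5000, 5200), GenomicInterval("chr1", 8000, 8100)],
        )
        g = GeneModel("g", [tx_short, tx_long])
        (t,) = annotate_tss([g], self.GENOME)
        assert t.tss_position == 4000  # from t2 whose first exon starts ATG


class TestAssignCres:
    def test_nearest_tss_within_domain(self):
        from garfinder.enrichment import TssAnnotation

        domains = IntervalSet([iv(0, 100_000)])
        tss = [
            TssAnnotation("geneA", "chr1", 40_000, "+", "utr_1bp"),
            TssAnnotation("geneB", "chr1", 58_000, "+", "utr_1bp"),
        ]
        cres = IntervalSet([iv(49_900, 50_100, "cre1")])
        out = assign_cres(cres, tss, domains, mode="domain")
        assert out.loc[0, "gene_id"] == "geneB"  # 8 kb < 10 kb

    def test_cre_outside_domains_unassigned_in_domain_mode(self):
        from garfinder.enrichment import TssAnnotation

        domains = IntervalSet([iv(0, 10_000)])
        tss = [TssAnnotation("g", "chr1", 5_000, "+", "utr_1bp")]
        cres = IntervalSet([iv(20_000, 20_300, "far")])
        out = assign_cres(cres, tss, domains, mode="domain")
        assert out.loc[0, "gene_id"] == ""
        # distance mode has no such restriction
        out2 = assign_cres(cres, tss, None, mode="distance")
        assert out2.loc[0, "gene_id"] == "g"

    def test_domain_without_tss_leaves_cre_unassigned(self):
        from garfinder.enrichment import TssAnnotation

        domains = IntervalSet([iv(0, 10_000), iv(20_000, 30_000)])
        tss = [TssAnnotation("g", "chr1", 5_000, "+", "utr_1bp")]
        cres = IntervalSet([iv(25_000, 25_300, "lonely")])
        out = assign_cres(cres, tss, domains, mode="domain")
        assert out.loc[0, "gene_id"] == ""

    def test_assignment_pairs_share_a_domain(self):
        from garfinder.enrichment import TssAnnotation

        rng = np.random.default_rng(3)
        domains = merge_contact_domains(
            IntervalSet([iv(i * 10_000, i * 10_000 + 9_000) for i in range(10)])
        )
        tss = [
            TssAnnotation(f"g{i}", "chr1", int(p), "+", "utr_1bp")
            for i, p in enumerate(rng.integers(0, 95_000, 12))
        ]
        cres = IntervalSet(
            [iv(int(s), int(s) + 200, f"c{i}") for i, s in enumerate(rng.integers(0, 95_000, 30))]
        )
        out = assign_cres(cres, tss, domains, mode="domain")
        tss_by_gene = {t.gene_id: t for t in tss}
        for _, row in out[out["gene_id"] != ""].iterrows():
            mid = (row["start"] + row["end"]) / 2
            t = tss_by_gene[row["gene_id"]]
            shared = [
                d for d in domains
                if d.start <= mid < d.end and d.start <= t.tss_position < d.end
            ]
            assert shared


class TestGeneGarEnrichment:
    def _assignments(self, spec):
        """spec: gene -> (n, k); builds an assignment table with GAR ids."""
        rows, gars = [], set()
        i = 0
        for gene, (n, k) in spec.items():
            for j in range(n):
                eid = f"e{i}"
                i += 1
                rows.append((eid, "chr1", 0, 100, gene, 1.0, 1))
                if j < k:
                    gars.add(eid)
        df = pd.DataFrame(
            rows, columns=["element_id", "chrom", "start", "end", "gene_id", "distance", "n_candidates"]
        )
        return df, gars

    def test_hypergeometric_matches_exact_oracle(self):
        df, gars = self._assignments({"gA": (5, 3), "gB": (95, 7)})
        res = {r.gene_id: r for r in gene_gar_enrichment(df, gars, "hypergeometric")}
        assert res["gA"].p_value == pytest.approx(
            hypergeom_oracle(100, 10, 5, 3), abs=1e-12
        )
        assert res["gB"].p_value == pytest.approx(
            hypergeom_oracle(100, 10, 95, 7), abs=1e-12
        )

    def test_k_zero_gives_p_one(self):
        df, gars = self._assignments({"gA": (5, 0), "gB": (10, 4)})
        res = {r.gene_id: r for r in gene_gar_enrichment(df, gars, "hypergeometric")}
        assert res["gA"].p_value == pytest.approx(1.0, abs=1e-12)

    def test_single_gene_draws_everything_p_one(self):
        df, gars = self._assignments({"gA": (8, 3)})
        res = gene_gar_enrichment(df, gars, "hypergeometric")
        assert res[0].p_value == pytest.approx(1.0, abs=1e-12)

    def test_binomial_matches_scipy_free_oracle(self):
        # independent oracle: explicit Bernoulli sum
        df, gars = self._assignments({"gA": (6, 4), "gB": (94, 6)})
        res = {r.gene_id: r for r in gene_gar_enrichment(df, gars, "binomial")}
        q = 10 / 100
        expected = sum(
            math.comb(6, i) * q**i * (1 - q) ** (6 - i) for i in range(4, 7)
        )
        assert res["gA"].p_value == pytest.approx(expected, abs=1e-12)

    def test_p_monotone_nonincreasing_in_k(self):
        ps = []
        for k in range(0, 6):
            df, gars = self._assignments({"gA": (5, k), "pad": (95, 10 - k)})
            res = {r.gene_id: r for r in gene_gar_enrichment(df, gars, "hypergeometric")}
            ps.append(res["gA"].p_value)
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_hypergeom_close_to_binom_when_n_much_less_than_N(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            N = int(rng.integers(2000, 8000))
            K = int(rng.integers(50, N // 10))
            n = int(rng.integers(1, max(2, N // 200)))  # n/N < 0.01 regime
            k = int(rng.integers(0, min(n, 4) + 1))
            ph = hypergeom_oracle(N, K, n, k)
            q = K / N
            pb = sum(
                math.comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(k, n + 1)
            )
            assert ph == pytest.approx(pb, rel=0.1)

    def test_no_gars_warns(self):
        df, _ = self._assignments({"gA": (5, 0), "gB": (5, 0)})
        with pytest.warns(UserWarning, match="no GARs"):
            res = gene_gar_enrichment(df, set(), "hypergeometric")
        assert all(r.p_value == 1.0 for r in res)


class TestOverlapTest:
    def test_certain_overlap_p_one(self):
        u = {f"g{i}" for i in range(10)}
        p, n, _ = overlap_test(u, u, u)
        assert n == 10 and p == pytest.approx(1.0, abs=1e-12)

    def test_zero_overlap_p_one(self):
        u = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(50, 60)}
        p, n, _ = overlap_test(a, b, u)
        assert n == 0 and p == pytest.approx(1.0, abs=1e-12)

    def test_matches_exact_oracle(self):
        u = {f"g{i}" for i in range(1000)}
        a = {f"g{i}" for i in range(420)}
        b = {f"g{i}" for i in range(400, 480)}  # overlap 20
        p, n, _ = overlap_test(a, b, u)
        assert n == 20
        assert p == pytest.approx(hypergeom_oracle(1000, 420, 80, 20), abs=1e-12)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="empty universe"):
            overlap_test(set(), set(), set())

    def test_nonsubset_raises(self):
        with pytest.raises(ValueError, match="subsets"):
            overlap_test({"x"}, set(), {"y"})


class TestDomainSizeDiagnostic:
    def _assignments_for(self, domains, counts, rng):
        rows = []
        i = 0
        for d, c in zip(domains, counts):
            for _ in range(c):
                s = int(rng.integers(d.start, d.end - 10))
                rows.append((f"e{i}", d.chrom, s, s + 10, "g", 1.0, 1))
                i += 1
        return pd.DataFrame(
            rows, columns=["element_id", "chrom", "start", "end", "gene_id", "distance", "n_candidates"]
        )

    def test_proportional_counts_r2_one(self, rng):
        domains = IntervalSet([iv(i * 1000, i * 1000 + 100 * (i + 1)) for i in range(6)])
        counts = [len(d) // 100 for d in domains]
        asn = self._assignments_for(list(domains), counts, rng)
        table, r2 = domain_size_diagnostic(domains, asn)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert (table["n_cres"] == counts).all()

    def test_constant_counts_r2_zero(self, rng):
        domains = IntervalSet([iv(i * 1000, i * 1000 + 100 * (i + 1)) for i in range(6)])
        asn = self._assignments_for(list(domains), [3] * 6, rng)
        _, r2 = domain_size_diagnostic(domains, asn)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_permuted_counts_r2_small(self):
        rng = np.random.default_rng(42)
        sizes = rng.integers(100, 5000, 200)
        domains = IntervalSet(
            [iv(int(i * 10_000), int(i * 10_000 + s)) for i, s in enumerate(sizes)]
        )
        counts = rng.permutation(np.clip(sizes // 500, 0, 10)).tolist()
        asn = self._assignments_for(list(domains), counts, rng)
        _, r2 = domain_size_diagnostic(domains, asn)
        assert r2 < 0.1

    def test_fewer_than_three_domains_undefined(self, rng):
        domains = IntervalSet([iv(0, 1000), iv(2000, 2500)])
        asn = self._assignments_for(list(domains), [2, 1], rng)
        _, r2 = domain_size_diagnostic(domains, asn)
        assert r2 is None
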