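"""Trimming/filtering rules on constructed toy alignments, incl. boundaries."""

import math

import pytest

from garfinder.msa import OrthologueAlignment
from garfinder.msa_filter import (
    FilterRejection,
    RetentionRule,
    check_retention,
    drop_gappy_sequences,
    filter_alignment,
    remove_gappy_columns,
    trim_gappy_ends,
    trim_to_reference,
)


def aln(rows: dict[str, str], ref="ref", eid="e1") -> OrthologueAlignment:
    return OrthologueAlignment(eid, rows, ref)


def sliding_window_oracle(rows, window, species_frac, max_gaps):
    """Brute-force scan: first qualifying offset from each end."""
    seqs = list(rows.values())
    n, L = len(seqs), len(seqs[0])
    need = math.ceil(species_frac * n)

    def qualifies(off):
        good = sum(
            1
            for s in seqs
            if sum(c in "-N" for c in s[off : off + window]) <= max_gaps
        )
        return good >= need

    offsets = [o for o in range(L - window + 1) if qualifies(o)]
    if not offsets:
        return None
    return offsets[0], offsets[-1] + window


class TestTrimToReference:
    def test_flanking_gaps_removed(self):
        m = aln({"ref": "--ACGT--", "x": "TTACGTTT"})
        out = trim_to_reference(m)
        assert out.rows == {"ref": "ACGT", "x": "ACGT"}

    def test_no_flanking_gaps_is_identity(self):
        m = aln({"ref": "ACGT", "x": "AC-T"})
        assert trim_to_reference(m).rows == m.rows

    def test_all_gap_reference_rejected(self):
        with pytest.raises(FilterRejection, match="empty_reference"):
            trim_to_reference(aln({"ref": "--------", "x": "ACGTACGT"}))

    def test_internal_reference_gaps_survive(self):
        m = aln({"ref": "-A--T-", "x": "CAGGTC"})
        assert trim_to_reference(m).rows["ref"] == "A--T"


class TestTrimGappyEnds:
    def test_gapless_alignment_unchanged(self):
        rows = {f"s{i}": "ACGT" * 15 for i in range(4)}
        rows["ref"] = "ACGT" * 15
        m = aln(rows)
        assert trim_gappy_ends(m).rows == m.rows

    def test_left_trim_matches_window_oracle(self):
        # 2 of 4 rows have 10 leading gaps: offset 0 has only 2/4 = 50% rows
        # with <= 5 window gaps (< 75%); trimming must advance
        clean = "ACGT" * 15
        rows = {
            "ref": clean,
            "s1": clean,
            "s2": "-" * 10 + clean[10:],
            "s3": "-" * 10 + clean[10:],
        }
        m = aln(rows)
        oracle = sliding_window_oracle(rows, 20, 0.75, 5)
        out = trim_gappy_ends(m)
        assert oracle is not None
        left, right = oracle
        assert out.length == right - left
        assert out.rows["ref"] == clean[left:right]

    @pytest.mark.parametrize("n_lead_gaps", [6, 12, 19, 25])
    def test_both_ends_match_oracle(self, n_lead_gaps):
        clean = "ACGTACGTAC" * 8
        gappy = "-" * n_lead_gaps + clean[n_lead_gaps:-n_lead_gaps] + "N" * n_lead_gaps
        rows = {"ref": clean, "s1": clean, "s2": gappy, "s3": gappy, "s4": gappy}
        m = aln(rows)
        left, right = sliding_window_oracle(rows, 20, 0.75, 5)
        out = trim_gappy_ends(m)
        assert (out.rows["ref"], out.length) == (clean[left:right], right - left)

    def test_all_gaps_rejected(self):
        rows = {"ref": "-" * 40, "x": "-" * 40}
        with pytest.raises(FilterRejection, match="all_gappy"):
            trim_gappy_ends(aln(rows))

    def test_short_alignment_warns_and_passes_through(self):
        m = aln({"ref": "ACGTACGT", "x": "ACGTACGT"})
        with pytest.warns(UserWarning, match="shorter than window"):
            assert trim_gappy_ends(m).rows == m.rows

    def test_idempotent(self):
        clean = "ACGT" * 20
        rows = {"ref": clean, "s1": clean, "s2": "-" * 15 + clean[15:], "s3": clean}
        once = trim_gappy_ends(aln(rows))
        assert trim_gappy_ends(once).rows == once.rows


class TestRemoveGappyColumns:
    def test_gapless_identity_both_modes(self):
        m = aln({"ref": "ACGTAC", "x": "ACGTAC", "y": "ACGTAC"})
        assert remove_gappy_columns(m, "fixed").rows == m.rows
        assert remove_gappy_columns(m, "gappyout").rows == m.rows

    def test_fixed_threshold_strictly_greater(self):
        # col 0: 3/4 gaps (0.75) removed at threshold 0.5; col 1: 2/4 kept
        m = aln({"ref": "AA", "a": "-A", "b": "--", "c": "-C"})
        out = remove_gappy_columns(m, "fixed", fixed_threshold=0.5)
        assert out.rows == {"ref": "A", "a": "A", "b": "-", "c": "C"}

    def test_gappyout_bimodal_removes_gappy_half(self):
        # 10 rows; half the columns gapless, half with 9/10 gaps
        n = 10
        rows = {}
        for i in range(n):
            clean = "ACGTACGTAC"
            gappy = "".join("A" if i == 0 else "-" for _ in range(10))
            rows[f"s{i}" if i else "ref"] = clean + gappy
        m = aln(rows)
        out = remove_gappy_columns(m, "gappyout")
        assert out.length == 10
        assert out.rows["ref"] == "ACGTACGTAC"

    def test_all_columns_removed_rejects(self):
        m = aln({"ref": "A-", "a": "--", "b": "--", "c": "--"})
        with pytest.raises(FilterRejection, match="no_columns"):
            remove_gappy_columns(m, "fixed", fixed_threshold=0.1)

    def test_fixed_mode_idempotent(self):
        m = aln({"ref": "ACGTA", "a": "A--TA", "b": "AC--A", "c": "-C-TA"})
        once = remove_gappy_columns(m, "fixed", fixed_threshold=0.5)
        again = remove_gappy_columns(once, "fixed", fixed_threshold=0.5)
        assert again.rows == once.rows


class TestDropGappySequences:
    def _base(self, row: str) -> OrthologueAlignment:
        L = len(row)
        return aln({"ref": "A" * L, "keepme": "C" * L, "probe": row})

    def test_26_gaps_in_100_removed(self):
        row = "-" * 13 + "A" * 74 + "-" * 13  # 26 gaps, max run 13 > 10
        row_scattered = ("A-" * 26) + "A" * 48  # 26 gaps, runs of 1
        out = drop_gappy_sequences(self._base(row_scattered))
        assert "probe" not in out.rows

    def test_run_of_11_in_100_removed_by_run_rule(self):
        row = "-" * 11 + "A" * 89  # 11 gaps total: 11% > 10% run rule only
        out = drop_gappy_sequences(self._base(row))
        assert "probe" not in out.rows

    def test_boundary_25_gaps_run_10_kept(self):
        # exactly 25% gaps and max run exactly 10: both strict rules pass
        row = "-" * 10 + ("A" * 5 + "-") * 15 + "A" * 0
        row = row[:100].ljust(100, "A")
        assert len(row) == 100
        assert row.count("-") == 25
        out = drop_gappy_sequences(self._base(row))
        assert "probe" in out.rows

    def test_n_counts_as_gap(self):
        row = "N" * 26 + "A" * 74
        out = drop_gappy_sequences(self._base(row))
        assert "probe" not in out.rows

    def test_failing_reference_rejects_element(self):
        m = aln({"ref": "-" * 30 + "A" * 70, "x": "A" * 100})
        with pytest.raises(FilterRejection, match="reference_gappy"):
            drop_gappy_sequences(m)


class TestCheckRetention:
    RULE = RetentionRule(
        min_species=5,
        required_pairs=(("g1", "s1"), ("g2", "s2")),
        outgroup_groups={"A": ("oA1", "oA2"), "B": ("oB1",)},
    )

    def _aln(self, species):
        rows = {sp: "ACGT" for sp in species}
        return OrthologueAlignment("e", rows, species[0])

    def test_four_species_too_few(self):
        ok, reason = check_retention(self._aln(["g1", "s1", "oA1", "oB1"]), self.RULE)
        assert (ok, reason) == (False, "too_few_species")

    def test_glider_without_sister_fails(self):
        ok, reason = check_retention(
            self._aln(["g1", "s2", "x1", "oA1", "oB1", "x2"]), self.RULE
        )
        assert (ok, reason) == (False, "no_glider_sister_pair")

    def test_missing_outgroup_group_fails(self):
        ok, reason = check_retention(
            self._aln(["g1", "s1", "x1", "oA1", "x2"]), self.RULE
        )
        assert (ok, reason) == (False, "missing_outgroup:B")

    def test_minimal_valid_composition_passes(self):
        ok, reason = check_retention(
            self._aln(["g2", "s2", "oA2", "oB1", "x1"]), self.RULE
        )
        assert ok

    def test_full_species_set_passes(self):
        species = ["g1", "s1", "g2", "s2", "oA1", "oA2", "oB1"] + [f"x{i}" for i in range(10)]
        assert check_retention(self._aln(species), self.RULE)[0]


class TestFullFilter:
    RULE = RetentionRule(min_species=3, required_pairs=(("g1", "s1"),),
                         outgroup_groups={"A": ("o1",)})

    def test_stage_order_and_shrinking(self):
        clean = "ACGT" * 20
        rows = {
            "ref": "--" + clean + "--",
            "g1": "GG" + clean + "TT",
            "s1": "GG" + clean + "TT",
            "o1": "GG" + clean + "TT",
        }
        m = OrthologueAlignment("e", rows, "ref")
        out = filter_alignment(m, self.RULE)
        assert out.length <= m.length
        assert set(out.rows) <= set(rows)
        # degapped survivors are substrings of their original ungapped rows
        for sp in out.rows:
            assert out.degapped(sp).replace("N", "") in rows[sp].replace("-", "").replace("N", "")

    def test_retention_failure_raises(self):
        clean = "ACGT" * 20
        rows = {"ref": clean, "g1": clean}
        with pytest.raises(FilterRejection, match="too_few_species"):
            filter_alignment(OrthologueAlignment("e", rows, "ref"), self.RULE)
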