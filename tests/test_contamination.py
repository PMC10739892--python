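"""Marker family selection and the marker-based contamination
estimator, including parameter recovery on planted mixtures."""

import numpy as np
import pytest

from ferretforge.annotate import BestAnnotation
from ferretforge.contamination import (
    contam_report_frame,
    estimate_contamination,
    marker_sequences,
    select_marker_pfams,
)
from ferretforge.formats import AlignmentHit
from ferretforge.synth import FixtureSpec, make_entries, make_marker_hits
from ferretforge.taxonomy import OTHER_BIN, UNKNOWN_BIN


def ann(aa_id, entry, pfam, name):
    return BestAnnotation(aa_id, entry, pfam, name)


class TestSelectMarkers:
    def test_strict_prevalence_inequality(self):
        """Present in 10/10 entries qualifies; 9/10 = 0.90 is not > 0.90
        and does not."""
        best = []
        for e in range(1, 11):
            best.append(ann(f"e{e}a", e, "PF00010", "Ribosomal_S7"))
            if e < 10:
                best.append(ann(f"e{e}b", e, "PF00011", "Ribosomal_L2"))
            best.append(ann(f"e{e}c", e, "PF00020", "Pkinase"))
        assert select_marker_pfams(best) == {"PF00010"}

    def test_non_ribosomal_name_excluded_at_full_prevalence(self):
        best = [ann(f"e{e}", e, "PF00020", "Pkinase") for e in range(5)]
        assert select_marker_pfams(best) == set()

    def test_single_entry_prevalence_is_all_or_nothing(self):
        best = [
            ann("a", 1, "PF00010", "Ribosomal_S7"),
            ann("b", 1, "PF00020", "Pkinase"),
        ]
        assert select_marker_pfams(best) == {"PF00010"}

    def test_empty_patterns_rejected(self):
        with pytest.raises(ValueError):
            select_marker_pfams([ann("a", 1, "PF00010", "Ribosomal_S7")], ())


class TestMarkerSequences:
    def test_only_marker_annotated_ids(self):
        best = [ann(f"m{i}", 1, "PF00010", "Ribosomal_S7") for i in range(3)]
        best += [ann(f"o{i}", 1, "PF00020", "Pkinase") for i in range(7)]
        assert marker_sequences(best, {"PF00010"}) == {"m0", "m1", "m2"}

    def test_no_markers_is_empty(self):
        assert marker_sequences([ann("a", 1, "PF00020", "Pk")], {"PF00010"}) == set()

    def test_best_annotation_decides_membership(self):
        # the sequence's best annotation is non-marker, so it is out even
        # though a weaker marker hit existed upstream of the reduction
        best = [ann("s1", 1, "PF00020", "Pkinase")]
        assert marker_sequences(best, {"PF00010"}) == set()


class TestEstimate:
    def _best(self, n, entry=1):
        return [ann(f"m{i}", entry, "PF00010", "Ribosomal_S7") for i in range(n)]

    def test_hand_counted_mixture(self, tree, bins):
        """7 own-bin, 2 other-bin, 1 unplaced marker: 100*2/9 = 22.2%."""
        best = self._best(10)
        own, foreign = 1000, 1100  # species under lineage bins 0 and 1
        hits = {}
        for i in range(7):
            hits[f"m{i}"] = [AlignmentHit(f"m{i}", own, 100.0, 1e-30)]
        for i in range(7, 9):
            hits[f"m{i}"] = [AlignmentHit(f"m{i}", foreign, 100.0, 1e-30)]
        report = estimate_contamination(
            1, own, best, {"PF00010"}, hits, tree, bins
        )
        assert report.n_seqs == 10 and report.n_pfams == 1
        assert report.bin_counts[UNKNOWN_BIN] == 1
        assert report.contam_pct == pytest.approx(100 * 2 / 9)

    def test_all_in_expected_bin_is_zero(self, tree, bins):
        best = self._best(5)
        hits = {
            f"m{i}": [AlignmentHit(f"m{i}", 1001, 90.0, 1e-30)] for i in range(5)
        }
        report = estimate_contamination(1, 1001, best, {"PF00010"}, hits, tree, bins)
        assert report.contam_pct == 0.0

    def test_no_placeable_marker_gives_absent_estimate(self, tree, bins):
        report = estimate_contamination(
            1, 1000, self._best(3), {"PF00010"}, {}, tree, bins
        )
        assert report.contam_pct is None
        assert report.bin_counts[UNKNOWN_BIN] == 3

    def test_unknown_policy_count_penalizes_unplaced(self, tree, bins):
        best = self._best(4)
        hits = {f"m{i}": [AlignmentHit(f"m{i}", 1000, 90.0, 1e-30)] for i in range(2)}
        report = estimate_contamination(
            1, 1000, best, {"PF00010"}, hits, tree, bins, unknown_policy="count"
        )
        assert report.contam_pct == pytest.approx(50.0)

    def test_expected_bin_other_warns(self, tree, bins):
        # the root lies in no bin subtree
        report = estimate_contamination(
            1, tree.root, self._best(1), {"PF00010"}, {}, tree, bins
        )
        assert report.tax_group == OTHER_BIN and report.warnings

    def test_duplicated_hit_rows_leave_estimate_invariant(self, tree, bins, toy_hits=None):
        spec = FixtureSpec(seed=9, contamination_rho=0.4)
        marker_ids = [f"m{i}" for i in range(30)]
        hits, _ = make_marker_hits(
            spec, tree, bins, 1000, marker_ids, rng=np.random.default_rng(4)
        )
        best = self._best(30)
        grouped = {}
        for h in hits:
            grouped.setdefault(h.query_id, []).append(h)
        doubled = {q: hs + hs for q, hs in grouped.items()}
        r1 = estimate_contamination(1, 1000, best, {"PF00010"}, grouped, tree, bins)
        r2 = estimate_contamination(1, 1000, best, {"PF00010"}, doubled, tree, bins)
        assert r1.contam_pct == r2.contam_pct
        assert r1.bin_counts == r2.bin_counts

    def test_report_columns_follow_bin_order(self, tree, bins):
        report = estimate_contamination(
            1, 1000, self._best(1), {"PF00010"}, {}, tree, bins
        )
        assert tuple(report.bin_counts) == bins.column_names
        frame = contam_report_frame([report], bins)
        assert tuple(frame.columns[7:]) == bins.column_names

    def test_counts_sum_to_n_seqs(self, tree, bins):
        spec = FixtureSpec(seed=2, contamination_rho=0.5)
        marker_ids = [f"m{i}" for i in range(20)]
        hits, _ = make_marker_hits(
            spec, tree, bins, 1100, marker_ids, rng=np.random.default_rng(1)
        )
        grouped = {}
        for h in hits:
            grouped.setdefault(h.query_id, []).append(h)
        report = estimate_contamination(
            1, 1100, self._best(20), {"PF00010"}, grouped, tree, bins
        )
        assert sum(report.bin_counts.values()) == report.n_seqs == 20


class TestParameterRecovery:
    def test_planted_mixture_recovered_within_binomial_noise(self, tree, bins):
        """With 200 markers at rho = 0.3 the estimate sits within the
        3-sigma binomial band of 30%."""
        spec = FixtureSpec(seed=13, contamination_rho=0.3)
        n = 200
        marker_ids = [f"m{i}" for i in range(n)]
        hits, truth = make_marker_hits(
            spec, tree, bins, 1000, marker_ids, rng=np.random.default_rng(77)
        )
        grouped = {}
        for h in hits:
            grouped.setdefault(h.query_id, []).append(h)
        best = [
            BestAnnotation(m, 1, "PF00010", "Ribosomal_S7") for m in marker_ids
        ]
        report = estimate_contamination(
            1, 1000, best, {"PF00010"}, grouped, tree, bins
        )
        band = 3 * np.sqrt(0.3 * 0.7 / n) * 100
        assert abs(report.contam_pct - 30.0) <= band
        # the estimator reproduces the planted Bernoulli draws exactly
        assert report.contam_pct == pytest.approx(
            100 * sum(truth.values()) / n
        )

    def test_error_shrinks_with_marker_count(self, tree, bins):
        """Mean |estimate - 100 rho| over seeds decreases as the marker
        count grows."""
        rho = 0.3
        spec = FixtureSpec(seed=21, contamination_rho=rho)
        mean_err = {}
        for n in (50, 200, 800):
            errs = []
            for seed in range(20):
                marker_ids = [f"m{i}" for i in range(n)]
                hits, _ = make_marker_hits(
                    spec, tree, bins, 1000, marker_ids,
                    rng=np.random.default_rng(1000 + seed),
                )
                grouped = {}
                for h in hits:
                    grouped.setdefault(h.query_id, []).append(h)
                best = [
                    BestAnnotation(m, 1, "PF00010", "Ribosomal_S7")
                    for m in marker_ids
                ]
                report = estimate_contamination(
                    1, 1000, best, {"PF00010"}, grouped, tree, bins
                )
                errs.append(abs(report.contam_pct - 100 * rho))
            mean_err[n] = np.mean(errs)
        assert mean_err[50] > mean_err[200] > mean_err[800]


def test_markers_from_generated_corpus_are_the_planted_families(tree):
    """Marker selection on the synthetic corpus recovers exactly the
    generator's ribosomal families."""
    spec = FixtureSpec(seed=3)
    corpus = make_entries(spec, tree)
    best = []
    for entry_id, seq_truth in corpus.truth.items():
        for seq_id, (pfam_id, above) in seq_truth.items():
            if above:
                name = next(
                    f.name for f in corpus.families if f.pfam_id == pfam_id
                )
                best.append(BestAnnotation(seq_id, entry_id, pfam_id, name))
    assert select_marker_pfams(best) == corpus.marker_family_ids
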