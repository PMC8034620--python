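"""Integration-event annotation: merging, classification, exclusions."""

import pandas as pd
import pytest

from spacerseq.annotate import (
    GAP_SENTINEL,
    PlasmidFeatureDb,
    annotate_colonies,
    annotate_event,
    merge_colony_reads,
    summarize_events,
)
from spacerseq.models import ColonyReadPair
from spacerseq.simulate import (
    design_prespacer,
    simulate_integration_colonies,
)

REASON_TO_CLASS = {
    "low_quality": "low_quality_trace",
    "non_repeat_edge": "ectopic_site",
    "nonconsecutive_flank": "nonconsecutive_flank",
    "end_mutation_indel": "prespacer_end_indel",
}


def predicted_class(event) -> str:
    if not event.excluded:
        return "full_site_repeat_edge"
    return REASON_TO_CLASS[event.exclusion_reason]


@pytest.fixture(scope="module")
def db(parent_model_3sp, cassette):
    return PlasmidFeatureDb(model=parent_model_3sp, cassette=cassette)


def simulate(model, substrate, probs, n, seed, **kw):
    return simulate_integration_colonies(model, substrate, probs, n,
                                         seed=seed, **kw)


class TestMerge:
    def test_error_free_pair_is_anchored(self, parent_model_3sp, substrate,
                                         db):
        pairs, _ = simulate(parent_model_3sp, substrate,
                            {"full_site_repeat_edge": 1.0}, 5, seed=1)
        for p in pairs:
            comp = merge_colony_reads(p, db)
            assert comp.interpretable
            assert not comp.low_quality
            assert len(comp.sequence) == (len(p.fwd_read) + len(p.rev_read)
                                          + len(GAP_SENTINEL))

    def test_scrambled_reverse_read_uninterpretable(self, parent_model_3sp,
                                                    substrate, db):
        pairs, _ = simulate(parent_model_3sp, substrate,
                            {"full_site_repeat_edge": 1.0}, 1, seed=2)
        p = pairs[0]
        bad = ColonyReadPair(p.colony_id, p.fwd_read, p.rev_read[::-1],
                             p.fwd_quality, p.rev_quality)
        comp = merge_colony_reads(bad, db)
        assert not comp.rev_anchor_found
        ev = annotate_event(comp, db, substrate)
        assert ev.excluded and ev.exclusion_reason == "low_quality"


class TestAnnotate:
    def test_full_site_kept_with_exact_length(self, parent_model_3sp,
                                              substrate, db):
        pairs, truth = simulate(parent_model_3sp, substrate,
                                {"full_site_repeat_edge": 1.0}, 50, seed=3)
        events = annotate_colonies(pairs, db, substrate)
        for e, row in zip(events, truth.itertuples()):
            assert not e.excluded
            assert e.site_class == "repeat_edge"
            assert e.spacer_length == row.spacer_length == substrate.total_span
            assert e.orientation == row.orientation
            assert e.repeat_index_from_leader == row.repeat_index
            assert e.leader_proximal == row.leader_proximal

    def test_trimmed_substrate_length_recovered(self, parent_model_3sp, db):
        sub = design_prespacer(40, 6, 6, with_bbsi=True, seed=9)
        pairs, _ = simulate(parent_model_3sp, sub,
                            {"full_site_repeat_edge": 1.0}, 40, seed=4,
                            trimmed_length=30)
        events = annotate_colonies(pairs, db, sub)
        assert all(not e.excluded and e.spacer_length == 30 for e in events)

    def test_ectopic_excluded_as_non_repeat_edge(self, parent_model_3sp,
                                                 substrate, db):
        pairs, _ = simulate(parent_model_3sp, substrate,
                            {"ectopic_site": 1.0}, 20, seed=5)
        events = annotate_colonies(pairs, db, substrate)
        assert all(e.excluded and e.exclusion_reason == "non_repeat_edge"
                   for e in events)

    def test_end_indel_excluded(self, parent_model_3sp, substrate, db):
        pairs, _ = simulate(parent_model_3sp, substrate,
                            {"prespacer_end_indel": 1.0}, 30, seed=6)
        events = annotate_colonies(pairs, db, substrate)
        assert all(e.excluded and e.exclusion_reason == "end_mutation_indel"
                   for e in events)

    def test_nonconsecutive_flank_excluded(self, parent_model_3sp, substrate,
                                           db):
        pairs, _ = simulate(parent_model_3sp, substrate,
                            {"nonconsecutive_flank": 1.0}, 30, seed=7)
        events = annotate_colonies(pairs, db, substrate)
        assert all(e.excluded and e.exclusion_reason == "nonconsecutive_flank"
                   for e in events)

    def test_low_quality_outranks_other_defects(self, parent_model_3sp,
                                                substrate, db):
        # an ectopic colony whose traces are also degraded: the primary
        # reason must be low_quality, per the fixed priority order
        pairs, _ = simulate(parent_model_3sp, substrate,
                            {"ectopic_site": 1.0}, 3, seed=8)
        for p in pairs:
            bad = ColonyReadPair(p.colony_id, p.fwd_read, p.rev_read,
                                 (8,) * len(p.fwd_quality),
                                 (8,) * len(p.rev_quality))
            ev = annotate_event(merge_colony_reads(bad, db), db, substrate)
            assert ev.exclusion_reason == "low_quality"

    def test_orientation_balance_within_binomial_bound(self, parent_model_3sp,
                                                       substrate, db):
        pairs, truth = simulate(parent_model_3sp, substrate,
                                {"full_site_repeat_edge": 1.0}, 1000, seed=9)
        n_fwd = (truth["orientation"] == "forward").sum()
        se = (1000 * 0.25) ** 0.5
        assert abs(n_fwd - 500) < 3 * se
        events = annotate_colonies(pairs, db, substrate)
        assert sum(e.orientation == "forward" for e in events) == n_fwd

    def test_exclusion_tally_matches_truth(self, parent_model_3sp, substrate,
                                           db):
        probs = dict.fromkeys(REASON_TO_CLASS.values(), 0.2)
        probs["full_site_repeat_edge"] = 0.2
        pairs, truth = simulate(parent_model_3sp, substrate, probs, 200,
                                seed=10)
        events = annotate_colonies(pairs, db, substrate)
        summary = summarize_events(events)
        truth_counts = truth["event_class"].value_counts()
        for reason, cls in REASON_TO_CLASS.items():
            assert summary["exclusions"][reason] == truth_counts.get(cls, 0)
        assert summary["n_kept"] == truth_counts.get("full_site_repeat_edge", 0)


class TestSummarize:
    def test_single_length_histogram(self, parent_model_3sp, substrate, db):
        pairs, _ = simulate(parent_model_3sp, substrate,
                            {"full_site_repeat_edge": 1.0}, 25, seed=11)
        events = annotate_colonies(pairs, db, substrate)
        s = summarize_events(events)
        assert s["spacer_length_histogram"] == {substrate.total_span: 25}

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            summarize_events([])


def test_feature_db_tiles_parent_plasmid(parent_model_3sp, cassette):
    db = PlasmidFeatureDb(model=parent_model_3sp, cassette=cassette)
    feats = db.features()
    assert list(feats["label"])[:3] == ["upstream_flank", "leader", "repeat_1"]
    assert (feats["start"].iloc[1:].values == feats["end"].iloc[:-1].values).all()
    assert feats["end"].iloc[-1] == len(parent_model_3sp.locus_sequence())
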