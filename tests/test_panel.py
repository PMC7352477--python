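import numpy as np
import pandas as pd
import pytest

from tepswarm.evaluation import auc_mann_whitney
from tepswarm.panel import (
    BiomarkerPanel,
    ParticleParams,
    build_panel,
    classify,
    label_correlation,
    loocv,
    restrict_panel,
    tep_score,
)
from tepswarm.preprocessing import NormalizedMatrix

from conftest import make_cohort, prepare, series_ids


def norm_with_labels(values, labels01):
    cols = pd.Index([f"s{i}" for i in range(values.shape[1])])
    idx = pd.Index([f"t{i}" for i in range(values.shape[0])])
    norm = NormalizedMatrix(
        pd.DataFrame(values, index=idx, columns=cols), pd.Series(1e6, index=cols)
    )
    labels = pd.Series(np.where(labels01, "sarcoma", "control"), index=cols)
    return norm, labels


class TestLabelCorrelation:
    def test_transcript_equal_to_label_has_r_one(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        norm, labels = norm_with_labels(np.vstack([y, 1.0 - y]), y)
        r = label_correlation(norm, labels)
        assert r["t0"] == pytest.approx(1.0)
        assert r["t1"] == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self, rng):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = rng.normal(size=(1, 6))
        norm, labels = norm_with_labels(x, y)
        expected = np.corrcoef(x[0], y)[0, 1]
        assert label_correlation(norm, labels)["t0"] == pytest.approx(expected, abs=1e-12)

    def test_single_class_is_an_error(self):
        norm, labels = norm_with_labels(np.ones((1, 4)), np.ones(4))
        with pytest.raises(ValueError, match="both classes"):
            label_correlation(norm, labels)


@pytest.fixture(scope="module")
def training(planted_cohort):
    norm, ann, labels = prepare(planted_cohort)
    tr = series_ids(ann, "training")
    return norm.subset_samples(tr), labels.loc[tr]


class TestBuildPanel:
    def test_planted_transcripts_dominate_panel(self):
        cohort = make_cohort(n_transcripts=1000, n_de=100, effect_log2fc=2.0, seed=19)
        norm, _, labels = prepare(cohort)
        params = ParticleParams(-0.1, 0.05, 0.5, 200)
        panel = build_panel(norm, labels, params, seed=0)
        planted = set(cohort.truth.index)
        frac = sum(t in planted for t in panel.transcripts) / len(panel.transcripts)
        assert frac >= 0.8

    def test_panel_size_capped_by_n_ranked(self, training):
        norm, labels = training
        panel = build_panel(norm, labels, ParticleParams(-0.1, 0.5, 0.5, 5), seed=0)
        assert 0 < len(panel.transcripts) <= 5

    def test_fdr_one_disables_fdr_filter(self, training):
        norm, labels = training
        wide = build_panel(norm, labels, ParticleParams(-0.1, 1.0, 0.5, 10**6), seed=0)
        # every transcript passing the correlation filter is in the panel
        from tepswarm.panel import label_correlation as lc
        from tepswarm.preprocessing import libsize_correlation_filter

        kept = libsize_correlation_filter(norm, lo=-0.1, hi=1.0)
        r = lc(norm.subset_transcripts(kept), labels)
        assert len(wide.transcripts) == int((r.abs() >= 0.5).sum())

    def test_impossible_filters_give_degenerate_panel(self, training):
        norm, labels = training
        panel = build_panel(norm, labels, ParticleParams(-0.1, 1e-5 , 1.0, 200), seed=0)
        assert panel.degenerate
        scores = tep_score(panel, norm)
        assert (scores == 0.5).all()

    def test_deterministic_and_json_round_trip(self, training):
        norm, labels = training
        params = ParticleParams(-0.1, 0.05, 0.5, 100)
        a = build_panel(norm, labels, params, seed=1)
        b = build_panel(norm, labels, params, seed=1)
        assert a.to_json() == b.to_json()
        back = BiomarkerPanel.from_json(a.to_json())
        assert back.to_json() == a.to_json()
        assert np.allclose(tep_score(back, norm), tep_score(a, norm))

    def test_bounds_violation_rejected(self, training):
        norm, labels = training
        from tepswarm.io import ParamBounds

        with pytest.raises(ValueError, match="outside bounds"):
            build_panel(norm, labels, ParticleParams(-0.5, 0.05, 0.5, 100),
                        bounds=ParamBounds(), seed=0)


class TestTepScore:
    def test_training_samples_on_correct_side_when_separable(self, training):
        norm, labels = training
        panel = build_panel(norm, labels, ParticleParams(-0.1, 0.05, 0.5, 100), seed=0)
        scores = tep_score(panel, norm)
        calls = classify(scores)
        assert (calls == labels).mean() >= 0.95

    def test_duplicate_columns_score_identically(self, training):
        norm, labels = training
        panel = build_panel(norm, labels, ParticleParams(-0.1, 0.05, 0.5, 100), seed=0)
        s = norm.samples[0]
        scores = tep_score(panel, norm)
        again = tep_score(panel, norm.subset_samples([s]))
        assert scores[s] == pytest.approx(again.iloc[0])

    def test_scores_are_probabilities(self, training):
        norm, labels = training
        panel = build_panel(norm, labels, ParticleParams(-0.1, 0.05, 0.5, 100), seed=0)
        scores = tep_score(panel, norm)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_missing_panel_transcript_is_an_error(self, training):
        norm, labels = training
        panel = build_panel(norm, labels, ParticleParams(-0.1, 0.05, 0.5, 10), seed=0)
        reduced = norm.subset_transcripts(
            [t for t in norm.transcripts if t != panel.transcripts[0]]
        )
        with pytest.raises(ValueError, match="lack panel transcript"):
            tep_score(panel, reduced)

    def test_unlocked_panel_rejected_for_heldout_scoring(self, training):
        norm, labels = training
        panel = build_panel(norm, labels, ParticleParams(-0.1, 0.05, 0.5, 10), seed=0)
        with pytest.raises(RuntimeError, match="locked"):
            tep_score(panel, norm, require_locked=True)
        locked = panel.lock()
        tep_score(locked, norm, require_locked=True)  # no error

    def test_locked_panel_hash_unchanged_by_scoring(self, training):
        norm, labels = training
        panel = build_panel(norm, labels, ParticleParams(-0.1, 0.05, 0.5, 50), seed=0).lock()
        h0 = panel.content_hash()
        for _ in range(3):
            tep_score(panel, norm, require_locked=True)
        assert panel.content_hash() == h0


class TestClassify:
    def test_tie_at_cutoff_goes_to_sarcoma(self):
        scores = pd.Series([0.49, 0.50, 0.51], index=list("abc"))
        assert list(classify(scores, 0.5)) == ["control", "sarcoma", "sarcoma"]

    def test_tiny_cutoff_calls_everything_sarcoma(self):
        scores = pd.Series([0.01, 0.99], index=list("ab"))
        assert (classify(scores, 1e-9) == "sarcoma").all()

    def test_raising_cutoff_never_flips_control_to_sarcoma(self, rng):
        scores = pd.Series(rng.random(50))
        lower = classify(scores, 0.3)
        higher = classify(scores, 0.7)
        flipped = (lower == "control") & (higher == "sarcoma")
        assert not flipped.any()


class TestLoocv:
    def test_one_score_per_sample_and_deterministic(self, training):
        norm, labels = training
        params = ParticleParams(-0.1, 0.05, 0.5, 50)
        a = loocv(norm, labels, params, seed=0)
        b = loocv(norm, labels, params, seed=0)
        assert len(a) == norm.values.shape[1]
        assert a.equals(b)

    def test_null_cohort_loocv_auc_near_chance(self):
        aucs = []
        for seed in range(10):
            cohort = make_cohort(n_transcripts=300, n_de=0, seed=100 + seed)
            norm, ann, labels = prepare(cohort, min_total=0, min_samples=0)
            tr = series_ids(ann, "training")
            scores = loocv(
                norm.subset_samples(tr), labels.loc[tr],
                ParticleParams(-0.1, 0.5, 0.5, 50), seed=seed,
            )
            aucs.append(auc_mann_whitney(scores, labels.loc[tr]))
        assert 0.3 <= float(np.mean(aucs)) <= 0.7


class TestRestrictPanel:
    def test_full_universe_is_identity(self, training):
        norm, labels = training
        params = ParticleParams(-0.1, 0.05, 0.5, 100)
        panel = build_panel(norm, labels, params, seed=0)
        again = restrict_panel(panel, norm.transcripts, norm, labels)
        assert again.to_json() == panel.to_json()

    def test_single_allowed_transcript(self, planted_cohort, training):
        norm, labels = training
        params = ParticleParams(-0.1, 0.5, 0.5, 100)
        allowed = [planted_cohort.truth.index[0]]
        panel = restrict_panel(
            build_panel(norm, labels, params, seed=0), allowed, norm, labels
        )
        assert len(panel.transcripts) <= 1

    def test_empty_allowed_set_rejected(self, training):
        norm, labels = training
        panel = build_panel(norm, labels, ParticleParams(-0.1, 0.5, 0.5, 10), seed=0)
        with pytest.raises(ValueError, match="nonempty"):
            restrict_panel(panel, [], norm, labels)

    def test_non_signature_universe_does_not_beat_original(self, planted_cohort):
        norm, ann, labels = prepare(planted_cohort)
        tr, ev, va = (series_ids(ann, s) for s in ("training", "evaluation", "validation"))
        params = ParticleParams(-0.1, 0.05, 0.5, 100)
        orig = build_panel(norm.subset_samples(tr), labels.loc[tr], params, seed=0)
        decoys = norm.transcripts.difference(planted_cohort.truth.index)
        restricted = restrict_panel(orig, decoys, norm.subset_samples(tr), labels.loc[tr])
        auc = lambda p: auc_mann_whitney(
            tep_score(p, norm.subset_samples(va)), labels.loc[va]
        )
        assert auc(restricted) <= auc(orig) + 1e-9
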