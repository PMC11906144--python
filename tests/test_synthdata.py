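import numpy as np
import pytest
from lightgbm import LGBMClassifier
from rdkit import Chem
from sklearn.metrics import adjusted_rand_score

from odorcascade import (
    SynthConfig,
    build_odor_graph,
    cluster_undersample,
    generate_study,
    greedy_modularity_partition,
    join_features,
)
from odorcascade.metrics import classification_metrics, confusion_from_predictions
from odorcascade.pipeline import _mol_features
from odorcascade.protfeats import featurize_receptors
from odorcascade.synthdata import match_communities


class TestStudyShape:
    def test_full_cross_and_positive_rate(self, default_study):
        cfg = default_study.config
        assert len(default_study.binding_samples) == 63 * 61 == 3843
        n_pos = sum(s.label for s in default_study.binding_samples)
        assert abs(n_pos / 3843 - cfg.positive_rate) <= 0.2 * cfg.positive_rate

    def test_molecules_parse_and_are_unique(self, default_study):
        canon = set()
        for m in default_study.molecules:
            mol = Chem.MolFromSmiles(m.smiles)
            assert mol is not None
            canon.add(Chem.MolToSmiles(mol))
        assert len(canon) == 63

    def test_receptor_lengths_in_configured_range(self, default_study):
        lo, hi = default_study.config.receptor_length
        assert all(lo <= len(r.sequence) <= hi for r in default_study.receptors)

    def test_binder_strengths_in_configured_range(self, default_study):
        lo, hi = default_study.config.ec50_range
        pos = [s.log_ec50 for s in default_study.binding_samples if s.label == 1]
        assert min(pos) >= lo and max(pos) <= hi

    def test_ground_truth_is_consistent(self, default_study):
        k = default_study.config.n_communities
        assert set(default_study.receptor_groups.values()) <= set(range(1, k + 1))
        for mid, comms in default_study.true_assignments.items():
            assert comms <= set(range(1, k + 1))
            if mid in default_study.majority_community:
                assert default_study.majority_community[mid] in comms

    def test_homolog_extension_beyond_curated_list(self):
        study = generate_study(SynthConfig(seed=3, n_molecules=160))
        canon = {
            Chem.MolToSmiles(Chem.MolFromSmiles(m.smiles))
            for m in study.molecules
        }
        assert len(canon) == 160


class TestDeterminism:
    def test_same_seed_is_byte_identical(self, default_study):
        again = generate_study(SynthConfig(seed=0))
        assert [r.sequence for r in again.receptors] == [
            r.sequence for r in default_study.receptors
        ]
        assert [(s.molecule_id, s.receptor_id, s.log_ec50)
                for s in again.binding_samples] == [
            (s.molecule_id, s.receptor_id, s.log_ec50)
            for s in default_study.binding_samples
        ]
        assert [m.odor_labels for m in again.molecules] == [
            m.odor_labels for m in default_study.molecules
        ]

    def test_different_seeds_differ(self, default_study):
        other = generate_study(SynthConfig(seed=1))
        assert [s.log_ec50 for s in other.binding_samples] != [
            s.log_ec50 for s in default_study.binding_samples
        ]


class TestPlantedSignal:
    def _half_grid_f(self, study, noise_label):
        # the cascade's default featurization: Morgan bits + trigram counts
        mol_b = _mol_features(study.molecules, "morgan")
        prot_b = featurize_receptors(study.receptors, "3AAF")
        pairs = [(s.molecule_id, s.receptor_id) for s in study.binding_samples]
        x = join_features(mol_b, prot_b, pairs).values
        y = np.array([s.label for s in study.binding_samples])
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        tr, te = idx[: len(y) // 2], idx[len(y) // 2:]
        res_tr = cluster_undersample(x[tr], y[tr], seed=0)
        clf = LGBMClassifier(random_state=0, n_jobs=1, verbose=-1)
        clf.fit(x[tr][res_tr.kept_indices], y[tr][res_tr.kept_indices])
        # evaluate on a *random* balanced subsample of the held-out half:
        # all positives plus an equal number of uniformly drawn negatives
        pos = te[y[te] == 1]
        neg = rng.permutation(te[y[te] == 0])[: len(pos)]
        ev = np.concatenate([pos, neg])
        return classification_metrics(
            confusion_from_predictions(y[ev], clf.predict(x[ev]))
        )

    def test_signal_present_at_default_noise(self, default_study):
        """A binding classifier on half the grid beats the balanced baseline."""
        m = self._half_grid_f(default_study, noise_label=False)
        assert m["f_measure"] >= 0.7
        assert m["accuracy"] > 0.6  # majority baseline on balanced data is 0.5

    def test_signal_destroyed_by_noise(self):
        """Saturating noise collapses performance to chance (leakage guard)."""
        study = generate_study(
            SynthConfig(seed=0, noise_sd=1e3, label_noise_rate=0.5)
        )
        m = self._half_grid_f(study, noise_label=True)
        assert abs(m["accuracy"] - 0.5) <= 0.1


class TestCommunityRecovery:
    def test_partition_recovered_at_default_noise(self):
        """Greedy modularity on the label graph matches the planted partition."""
        aris = []
        for seed in [0, 1, 2]:
            study = generate_study(SynthConfig(seed=seed))
            labeled = [m for m in study.molecules if m.odor_labels]
            part = greedy_modularity_partition(build_odor_graph(labeled))
            common = [l for l in part.community_of if l in study.true_partition]
            aris.append(
                adjusted_rand_score(
                    [study.true_partition[l] for l in common],
                    [part.community_of[l] for l in common],
                )
            )
        assert np.mean(aris) >= 0.8

    def test_match_communities_maps_by_overlap(self):
        learned = {"a": 1, "b": 1, "c": 2, "d": 2, "e": 2}
        reference = {"a": 7, "b": 7, "c": 9, "d": 9, "e": 7}
        assert match_communities(learned, reference) == {1: 7, 2: 9}


class TestFeasibilityGuard:
    def test_degenerate_config_raises_after_retries(self):
        # four molecules cannot realize a 23-label vocabulary
        cfg = SynthConfig(seed=0, n_molecules=4, max_retries=2)
        with pytest.raises(RuntimeError, match="no feasible study"):
            generate_study(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(positive_rate=0.0)
        with pytest.raises(ValueError):
            SynthConfig(n_communities=30, n_odor_labels=20)
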