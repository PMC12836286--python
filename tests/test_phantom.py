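"""Synthetic cohort generator: determinism, structure, generative signal."""

import hashlib
import math

import numpy as np
import pytest

from noderad.core import ValidationError
from noderad.evaluate import roc_auc
from noderad.phantom import (
    PhantomConfig,
    generate_cohort,
    malignancy_probability,
    sample_cohort_metadata,
)


def _cohort_hash(cases):
    h = hashlib.sha256()
    for case in cases:
        h.update(case.volume.values.tobytes())
        h.update(case.tumor_mask.mask.tobytes())
        for node in case.nodes:
            h.update(node.mask.tobytes())
            h.update(node.label.encode())
    return h.hexdigest()


class TestConfig:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            sample_cohort_metadata(PhantomConfig(n_patients=0))

    def test_unnormalised_site_probs_rejected(self):
        with pytest.raises(ValidationError):
            sample_cohort_metadata(
                PhantomConfig(site_probs=(0.5, 0.5, 0.5, 0.0, 0.0))
            )

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValidationError):
            sample_cohort_metadata(PhantomConfig(noise_sd_benign=0.0))


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = PhantomConfig(n_patients=3, seed=42)
        assert _cohort_hash(generate_cohort(cfg)) == _cohort_hash(
            generate_cohort(cfg)
        )

    def test_different_seed_differs(self):
        a = generate_cohort(PhantomConfig(n_patients=2, seed=1))
        b = generate_cohort(PhantomConfig(n_patients=2, seed=2))
        assert _cohort_hash(a) != _cohort_hash(b)


class TestStructure:
    def test_rois_pairwise_disjoint_and_in_frame(self, tiny_case):
        for meta, case in tiny_case:
            total = case.tumor_mask.mask.astype(int)
            for node in case.nodes:
                total = total + node.mask.astype(int)
            assert total.max() <= 1, "overlapping ROIs"
            assert case.tumor_mask.mask.any()
            for node in case.nodes:
                assert node.mask.any()

    def test_every_patient_has_at_least_one_node(self):
        metas = sample_cohort_metadata(PhantomConfig(n_patients=50, seed=9))
        assert all(len(m.nodes) >= 1 for m in metas)

    def test_malignant_nodes_render_larger_and_noisier(self):
        metas = sample_cohort_metadata(PhantomConfig(n_patients=300, seed=17))
        nodes = [n for m in metas for n in m.nodes]
        mal = [n for n in nodes if n.label == "malignant"]
        ben = [n for n in nodes if n.label == "benign"]
        assert np.mean([np.prod(n.semi_axes) for n in mal]) > np.mean(
            [np.prod(n.semi_axes) for n in ben]
        )
        assert np.mean([n.render_noise_sd for n in mal]) > np.mean(
            [n.render_noise_sd for n in ben]
        )


class TestGenerativeModel:
    def test_site_frequencies_match_multinomial(self):
        probs = (0.34, 0.32, 0.03, 0.28, 0.03)
        n = 2000
        metas = sample_cohort_metadata(
            PhantomConfig(n_patients=n, site_probs=probs, seed=4)
        )
        from noderad.core import TUMOR_TYPES

        counts = {t: 0 for t in TUMOR_TYPES}
        for m in metas:
            counts[m.tumor_type] += 1
        for p, t in zip(probs, TUMOR_TYPES):
            sd = math.sqrt(n * p * (1 - p))
            assert abs(counts[t] - n * p) < 3 * sd, t

    def test_logistic_probability_contract(self):
        cfg = PhantomConfig(
            malignancy_logit_weights=(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        )
        p = malignancy_probability(cfg, 30.0, True, "II", "tonsil", 300.0, 8.0)
        # zero weights leave only the fixed level/site profile terms
        cfg0 = PhantomConfig(
            malignancy_logit_weights=(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        )
        assert 0 < p < 1
        p_oro = malignancy_probability(cfg0, 0.0, False, "III", "oropharynx", 0.0, 8.0)
        assert p_oro == pytest.approx(0.5)  # zero logit -> 0.5

    def test_probability_decreasing_in_distance(self):
        cfg = PhantomConfig()
        ps = [
            malignancy_probability(cfg, d, True, "II", "tonsil", 300.0, 8.0)
            for d in (0, 20, 40, 80, 1e4)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-4

    def test_prevalence_near_configured_target(self):
        """Default weights reproduce the ~0.194 malignant fraction within
        the binomial 99% interval."""
        metas = sample_cohort_metadata(PhantomConfig(n_patients=192, seed=0))
        labels = [n.label == "malignant" for m in metas for n in m.nodes]
        target = 270 / 1389
        half_width = 2.576 * math.sqrt(target * (1 - target) / len(labels))
        assert abs(np.mean(labels) - target) < half_width

    def test_spatial_features_alone_carry_signal(self):
        """Logistic regression on the 5 spatial attributes beats chance by
        > 3 null SEs on a ~2000-node metadata cohort."""
        from sklearn.linear_model import LogisticRegression

        from noderad.spatial import (
            NODE_LEVEL_CODES,
            TUMOR_LATERALITY_CODES,
            TUMOR_TYPE_CODES,
        )

        metas = sample_cohort_metadata(PhantomConfig(n_patients=280, seed=6))
        rows, labels = [], []
        for m in metas:
            for nd in m.nodes:
                rows.append(
                    [
                        TUMOR_TYPE_CODES[m.tumor_type],
                        NODE_LEVEL_CODES[nd.parent_level],
                        0 if nd.laterality == "left" else 1,
                        TUMOR_LATERALITY_CODES[m.tumor_laterality],
                        nd.distance_mm,
                    ]
                )
                labels.append(1 if nd.label == "malignant" else 0)
        X = np.asarray(rows)
        y = np.asarray(labels)
        auc = roc_auc(y, LogisticRegression(max_iter=2000).fit(X, y).predict_proba(X)[:, 1])
        m_pos, m_neg = y.sum(), len(y) - y.sum()
        se_null = math.sqrt((m_pos + m_neg + 1) / (12 * m_pos * m_neg))
        assert auc > 0.5 + 3 * se_null
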