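"""Contracts of the synthetic H&E scene generator and manifests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from dcfcnn.exceptions import ConfigError, InvalidCategoryError
from dcfcnn.synthetic import (
    CATEGORIES,
    SynthConfig,
    build_manifest,
    generate_scene,
    load_manifest,
    merge_labels,
    scene_rng,
    write_dataset,
)

SMALL = dict(image_height=64, image_width=64)


def test_generation_is_deterministic_under_fixed_seed():
    cfg = SynthConfig(separability=1.0, seed=7, **SMALL)
    a = generate_scene("no_cancer", cfg, scene_rng(7, "s"))
    b = generate_scene("no_cancer", cfg, scene_rng(7, "s"))
    assert np.array_equal(a, b)
    assert a.dtype == np.uint8 and a.shape == (64, 64, 3)


def test_invalid_category_rejected():
    cfg = SynthConfig(**SMALL)
    with pytest.raises(InvalidCategoryError):
        generate_scene("tumour", cfg, scene_rng(0, "s"))
    with pytest.raises(InvalidCategoryError):
        merge_labels("tumour")


def test_full_vs_no_cancer_green_gap_exceeds_three_sigma():
    """Mean green intensity separates the extreme categories by >3 sigma."""
    cfg = SynthConfig(separability=1.0, seed=1, **SMALL)

    def greens(cat):
        return np.array([
            generate_scene(cat, cfg, scene_rng(1, f"{cat}{i}")).mean(axis=(0, 1))[1]
            for i in range(50)
        ])

    g_full, g_no = greens("full_cancer"), greens("no_cancer")
    gap = abs(g_full.mean() - g_no.mean())
    assert gap > 3 * max(g_full.std(), g_no.std())


def test_zero_separability_equalises_class_means():
    """At separability 0 all categories draw identical blob parameters."""
    cfg = SynthConfig(separability=0.0, seed=2, **SMALL)
    means = {}
    for cat in CATEGORIES:
        vals = [generate_scene(cat, cfg, scene_rng(2, f"{cat}{i}")).mean()
                for i in range(25)]
        means[cat] = (np.mean(vals), np.std(vals) / np.sqrt(len(vals)))
    mus = [m for m, _ in means.values()]
    ses = [s for _, s in means.values()]
    assert max(mus) - min(mus) < 4 * max(ses) + 1.0


def test_intensity_threshold_auc_tracks_separability():
    """One-feature classifier: AUC >= 0.95 at s=1, ~0.5 at s=0 (100/class)."""
    for s, lo, hi in [(1.0, 0.95, 1.0), (0.0, 0.4, 0.6)]:
        cfg = SynthConfig(separability=s, seed=3, **SMALL)
        ben = [generate_scene("no_cancer", cfg, scene_rng(3, f"b{i}")).mean(axis=(0, 1))[1]
               for i in range(100)]
        mal = [generate_scene("partial_cancer", cfg, scene_rng(3, f"p{i}")).mean(axis=(0, 1))[1]
               for i in range(90)]
        mal += [generate_scene("full_cancer", cfg, scene_rng(3, f"f{i}")).mean(axis=(0, 1))[1]
                for i in range(10)]
        auc = roc_auc_score([0] * 100 + [1] * 100, -np.array(ben + mal))
        assert lo <= auc <= hi, f"separability={s}: AUC={auc}"


def test_merge_rule():
    assert merge_labels("no_cancer") == "benign"
    assert merge_labels("partial_cancer") == "malignant"
    assert merge_labels("full_cancer") == "malignant"


def test_published_composition_yields_880_scenes_738_malignant():
    m = build_manifest(SynthConfig())
    assert len(m) == 880
    counts = m.label_counts()
    assert counts["malignant"] == 738
    assert counts["benign"] == 142


def test_empty_manifest():
    m = build_manifest(SynthConfig(n_no_cancer=0, n_partial=0, n_full=0, **SMALL))
    assert len(m) == 0
    assert all(v == 0 for v in m.counts.values())


def test_small_manifest_label_tally():
    # 2 partial + 1 full -> 3 malignant; 3 no_cancer -> 3 benign
    m = build_manifest(SynthConfig(n_no_cancer=3, n_partial=2, n_full=1, **SMALL))
    assert len(m) == 6
    assert m.label_counts() == {"benign": 3, "malignant": 3}


@given(n_none=st.integers(0, 40), n_part=st.integers(0, 40), n_full=st.integers(0, 40))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_label_counts_follow_merge_rule(n_none, n_part, n_full):
    m = build_manifest(SynthConfig(n_no_cancer=n_none, n_partial=n_part,
                                   n_full=n_full, **SMALL))
    counts = m.label_counts()
    assert counts["malignant"] == n_part + n_full
    assert counts["benign"] == n_none
    assert sum(m.counts.values()) == len(m)


def test_patients_never_straddle_categories_and_scene_ids_unique():
    m = build_manifest(SynthConfig())
    by_patient = {}
    for s in m.samples:
        assert s.patient_id
        by_patient.setdefault(s.patient_id, set()).add(s.category)
    assert all(len(cats) == 1 for cats in by_patient.values())
    # matches the published patient composition
    pats = {c: {s.patient_id for s in m.samples if s.category == c} for c in CATEGORIES}
    assert len(pats["partial_cancer"]) == 125
    assert len(pats["full_cancer"]) == 14
    assert len(pats["no_cancer"]) == 35


def test_separability_out_of_range_rejected():
    with pytest.raises(ConfigError):
        SynthConfig(separability=1.5)
    with pytest.raises(ConfigError):
        SynthConfig(n_partial=-1)


def test_regeneration_reproduces_identical_files(tmp_path):
    cfg = SynthConfig(n_no_cancer=2, n_partial=1, n_full=1, seed=9, **SMALL)
    m1 = write_dataset(cfg, tmp_path / "a")
    m2 = write_dataset(cfg, tmp_path / "b")
    assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
           (tmp_path / "b" / "manifest.csv").read_bytes()
    for s1, s2 in zip(m1.samples, m2.samples):
        assert (tmp_path / "a" / s1.path).read_bytes() == \
               (tmp_path / "b" / s2.path).read_bytes()


def test_manifest_roundtrip(tmp_path):
    cfg = SynthConfig(n_no_cancer=2, n_partial=2, n_full=1, seed=4, **SMALL)
    written = write_dataset(cfg, tmp_path)
    loaded = load_manifest(tmp_path / "manifest.csv")
    assert [s.scene_id for s in loaded.samples] == [s.scene_id for s in written.samples]
    assert [s.label for s in loaded.samples] == [s.label for s in written.samples]
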