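import numpy as np
import pandas as pd
import pytest

from isomirev.isomir import AlignPolicy, align_read, classify_read
from isomirev.preprocess import process_fastq
from isomirev.qpcr import expression_matrix, normalize_delta_ct, pooled_reference
from isomirev.simulate import (
    FIXTURE_HAIRPINS,
    ISOFORM_CATEGORIES,
    SimConfig,
    isoform_key,
    isoform_sequence,
    make_toy_reference,
    simulate_cohort,
    simulate_count_matrix,
    simulate_qpcr,
    validation_config,
)


class TestToyReference:
    def test_fixtures_present_and_deterministic(self):
        ref = make_toy_reference(seed=1, n_mirnas=10)
        for _, mirna_id, canonical, _, _ in FIXTURE_HAIRPINS:
            assert ref.canonical_sequence(mirna_id) == canonical
        again = make_toy_reference(seed=1, n_mirnas=10)
        assert again.hairpins == ref.hairpins

    def test_decoys_have_3prime_flank_for_elongation(self):
        ref = make_toy_reference(seed=2, n_mirnas=20)
        for ann in ref.matures:
            hp = ref.hairpins[ann.hairpin_id]
            assert len(hp) - ann.end >= 4

    def test_different_seeds_same_fixtures_different_decoys(self):
        r1 = make_toy_reference(seed=1, n_mirnas=8)
        r2 = make_toy_reference(seed=2, n_mirnas=8)
        for hid, _, _, _, _ in FIXTURE_HAIRPINS:
            assert r1.hairpins[hid] == r2.hairpins[hid]
        decoys1 = {h: s for h, s in r1.hairpins.items() if h.startswith("toy")}
        decoys2 = {h: s for h, s in r2.hairpins.items() if h.startswith("toy")}
        assert decoys1 != decoys2

    def test_every_isoform_category_constructible_and_classified(self):
        """Generated isoform sequences classify back to their truth keys."""
        ref = make_toy_reference(seed=3, n_mirnas=12)
        policy = AlignPolicy()
        for ann in ref.matures:
            for cat in ISOFORM_CATEGORIES:
                seq = isoform_sequence(ref, ann.mirna_id, cat)
                hit = align_read(seq, ref, policy)
                assert hit is not None, (ann.mirna_id, cat)
                call = classify_read(seq, hit, ref, policy)
                assert call.isoform_key == isoform_key(ref, ann.mirna_id, cat)


class TestSimulateCohort:
    def test_fastq_file_count_and_determinism(self, tmp_path):
        cfg = SimConfig(n_control=2, n_cancer=3, n_mirnas=5, reads_per_sample=500, seed=7)
        ref = make_toy_reference(seed=7, n_mirnas=5)
        c1 = simulate_cohort(cfg, ref, out_dir=tmp_path / "a")
        c2 = simulate_cohort(cfg, ref, out_dir=tmp_path / "b")
        assert len(c1.fastq_paths) == 5
        for sid in c1.sample_ids:
            assert c1.fastq_paths[sid].read_bytes() == c2.fastq_paths[sid].read_bytes()
        pd.testing.assert_frame_equal(c1.truth, c2.truth)
        pd.testing.assert_frame_equal(c1.clinical, c2.clinical)

    def test_planted_fold_exact_in_truth(self):
        cfg = SimConfig(seed=4)
        ref = make_toy_reference(seed=4, n_mirnas=cfg.n_mirnas)
        cohort = simulate_cohort(cfg, ref, emit_fastq=False)
        tr = cohort.truth
        for mirna, cat, fold in cfg.planted_effects:
            sub = tr[(tr.mirna_id == mirna) & (tr.category == cat)]
            ctrl = sub[sub.group == "control"]["true_rpm"].mean()
            canc = sub[sub.group == "cancer"]["true_rpm"].mean()
            # RPM ratio is the planted fold times a common compositional factor
            assert canc / ctrl == pytest.approx(fold, rel=0.12)

    def test_unknown_planted_category_rejected(self):
        ref = make_toy_reference(seed=1, n_mirnas=3)
        cfg = SimConfig(
            n_mirnas=3, planted_effects=(("miR-21-5p", "NTA-G", 2.0),), seed=1
        )
        with pytest.raises(ValueError, match="unknown isoform category"):
            simulate_cohort(cfg, ref, emit_fastq=False)

    def test_nta_matching_template_rejected(self):
        # a hairpin continuing with U makes a "non-templated" U impossible:
        # the same read would be templated elongation
        from isomirev.refdb import MatureAnnotation, ReferenceSet

        ref = ReferenceSet(
            hairpins={"hp": "AAAA" + "UAGCUUAUCAGACUGAUGUUGA" + "UGGG"},
            matures=[MatureAnnotation("miR-x", "hp", 4, 26, "5p")],
        )
        with pytest.raises(ValueError, match="not constructible"):
            isoform_sequence(ref, "miR-x", "NTA-U")

    def test_elongation_needs_flank(self):
        from isomirev.refdb import MatureAnnotation, ReferenceSet

        ref = ReferenceSet(
            hairpins={"hp": "AAAA" + "UAGCUUAUCAGACUGAUGUUGA"},
            matures=[MatureAnnotation("miR-x", "hp", 4, 26, "5p")],
        )
        with pytest.raises(ValueError, match="not constructible"):
            isoform_sequence(ref, "miR-x", "elong1")

    def test_emitted_proportions_converge_to_sampled(self, tmp_path):
        """At 1e5 Poisson reads the realized isoform split of each panel
        miRNA is within 0.02 of the generator's proportions."""
        cfg = SimConfig(
            n_control=1,
            n_cancer=1,
            n_mirnas=3,
            reads_per_sample=100_000,
            dispersion=0.0,
            planted_effects=(),
            seed=11,
        )
        ref = make_toy_reference(seed=11, n_mirnas=3)
        cohort = simulate_cohort(cfg, ref, out_dir=tmp_path)
        urs = process_fastq(cohort.fastq_paths["ctrl-01"])
        from isomirev.isomir import call_sample

        cs = call_sample(urs, ref, AlignPolicy())
        counts = {}
        for call in cs.calls:
            counts.setdefault(call.mirna_id, {})[call.isoform_key] = call.count
        for mirna_id, per_iso in counts.items():
            total = sum(per_iso.values())
            for cat in ISOFORM_CATEGORIES:
                key = isoform_key(ref, mirna_id, cat)
                observed = per_iso.get(key, 0) / total
                expected = cohort.proportions.loc[mirna_id, cat]
                assert observed == pytest.approx(expected, abs=0.02)


class TestSimulateQpcr:
    def test_noise_free_ct_affine_in_log2_rpm(self):
        cfg = SimConfig(ct_noise_sd=0.0, seed=2)
        ref = make_toy_reference(seed=2, n_mirnas=cfg.n_mirnas)
        cohort = simulate_cohort(cfg, ref, emit_fastq=False)
        ct, _ = simulate_qpcr(cohort, ct_noise_sd=0.0)
        tr = cohort.truth.set_index(["sample_id", "mirna_id", "category"])
        sub = ct[ct.assay_id == "miR-21-5p"]
        for row in sub.itertuples(index=False):
            rpm = tr.loc[(row.sample_id, "miR-21-5p", "mature"), "true_rpm"]
            assert row.ct == pytest.approx(38.0 - np.log2(rpm + 1.0), abs=1e-9)

    def test_doubling_rpm_lowers_ct_by_one_cycle(self):
        # construction identity of the Ct model at high abundance
        rpm = 5000.0
        ct_lo = 38.0 - np.log2(rpm + 1)
        ct_hi = 38.0 - np.log2(2 * rpm + 1)
        assert ct_lo - ct_hi == pytest.approx(1.0, abs=1e-3)

    def test_equal_psa_groups_give_chance_auc(self):
        from isomirev.diagnostics import PSA_COLUMN, loocv_probabilities, roc_curve

        from .oracles import mann_whitney_auc

        cfg = validation_config(seed=5, psa_lognormal=(2.0, 2.0, 0.9))
        ref = make_toy_reference(seed=5, n_mirnas=cfg.n_mirnas)
        cohort = simulate_cohort(cfg, ref, emit_fastq=False)
        _, clinical = simulate_qpcr(cohort)
        # with identical PSA distributions the raw PSA ranking is at chance
        auc = mann_whitney_auc(
            np.log(clinical["psa"].values), clinical["label"].values
        )
        assert 0.35 <= auc <= 0.65

    def test_delta_ct_pipeline_recovers_truth_exactly_without_noise(self):
        cfg = SimConfig(ct_noise_sd=0.0, seed=6)
        ref = make_toy_reference(seed=6, n_mirnas=cfg.n_mirnas)
        cohort = simulate_cohort(cfg, ref, emit_fastq=False)
        ct, clinical = simulate_qpcr(cohort, ct_noise_sd=0.0)
        controls = clinical.loc[clinical.label == 0, "sample_id"]
        expr = normalize_delta_ct(ct, pooled_reference(ct, controls))
        mat = expression_matrix(expr)
        tr = cohort.truth.set_index(["sample_id", "mirna_id", "category"])
        # ln_expr should equal ln(rpm+1) centred on the control mean
        for assay, (mirna, cat) in {
            "miR-21-5p": ("miR-21-5p", "mature"),
            "UUCCCUUUGUCAUCCUAUGCCUG": ("miR-204-5p", "elong1"),
        }.items():
            lnr = np.array(
                [np.log(tr.loc[(s, mirna, cat), "true_rpm"] + 1.0) for s in mat.index]
            )
            centred = lnr - np.mean(
                [np.log(tr.loc[(s, mirna, cat), "true_rpm"] + 1.0) for s in controls]
            )
            assert np.allclose(mat[assay].values, centred, atol=1e-9)


class TestSimulateCountMatrix:
    def test_shapes_and_groups(self):
        cm, groups, truth = simulate_count_matrix(
            n_features=100, n_control=4, n_cancer=9, seed=1
        )
        assert cm.data.shape == (100, 13)
        assert (groups == "control").sum() == 4
        assert truth.shape[0] == 100

    def test_planted_features_marked_and_folded(self):
        cm, groups, truth = simulate_count_matrix(
            n_features=500, n_planted=20, planted_fold=0.25, seed=2
        )
        assert truth["planted"].sum() == 20
        assert (truth.loc[truth.planted, "fold"] == 0.25).all()
        assert (truth.loc[truth.planted, "variant_class"] == "trimming").all()

    def test_deterministic(self):
        a, _, _ = simulate_count_matrix(n_features=50, seed=9)
        b, _, _ = simulate_count_matrix(n_features=50, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)
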