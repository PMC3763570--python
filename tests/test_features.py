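"""Descriptor computation: oracles, invariants and the vectorizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pspcp import (
    RESIDUE_ORDER,
    FeatureConfig,
    ProteinRecord,
    PspcpVectorizer,
    StandardizedProfile,
    composition,
    descriptor_vector,
    extract_features,
    feature_names,
    one_hot_profile,
    pseudofactors,
    pspcp,
    write_ascii_pssm,
)
from pspcp.features import (
    FeatureError,
    check_descriptor,
    read_feature_tsv,
    write_feature_tsv,
)
from pspcp.profiles import PSSMMatrix
from _oracles import naive_ampseaac, naive_descriptor, random_profile


class TestPspcp:
    def test_one_hot_profile_collapses_to_residue_property(self, props):
        seq = "ACDEFGHIKL"
        d = pspcp(one_hot_profile(ProteinRecord("p", seq)), props)
        for i, aa in enumerate(seq):
            j = RESIDUE_ORDER.index(aa)
            assert np.allclose(d[i], props.h[:, j], atol=1e-12)

    def test_uniform_row_gives_zero(self, props):
        prof = one_hot_profile(ProteinRecord("p", "XX"))
        d = pspcp(prof, props)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_matches_naive_double_loop(self, props):
        rng = np.random.default_rng(1)
        prof = random_profile(rng, 15)
        d = pspcp(prof, props)
        naive = np.array(
            [
                [
                    sum(prof.A[i, j] * props.h[r, j] for j in range(20))
                    for r in range(props.R)
                ]
                for i in range(15)
            ]
        )
        assert np.allclose(d, naive, atol=1e-12)


class TestComposition:
    def test_sums_to_one(self, props):
        rng = np.random.default_rng(2)
        f = composition(random_profile(rng, 25))
        assert f.sum() == pytest.approx(1.0, abs=1e-10)

    def test_homopolymer_one_hot(self):
        f = composition(one_hot_profile(ProteinRecord("p", "AAAA")))
        assert f[0] == 1.0 and f[1:].sum() == 0.0

    def test_matches_naive_column_means(self):
        rng = np.random.default_rng(3)
        prof = random_profile(rng, 12)
        naive = [sum(prof.A[i, j] for i in range(12)) / 12 for j in range(20)]
        assert np.allclose(composition(prof), naive, atol=1e-12)


class TestPseudofactors:
    def test_constant_column_gives_square(self):
        d = np.full((10, 2), 0.0)
        d[:, 0] = 1.5
        d[:, 1] = -0.5
        u = pseudofactors(d, 4)
        assert np.allclose(u[:, 0], 1.5**2, atol=1e-12)
        assert np.allclose(u[:, 1], 0.25, atol=1e-12)

    def test_hand_expanded_length_4(self):
        d = np.array([[1.0], [2.0], [-1.0], [0.5]])
        u = pseudofactors(d, 3)
        assert u[0, 0] == pytest.approx((1 * 2 + 2 * -1 + -1 * 0.5) / 3)
        assert u[1, 0] == pytest.approx((1 * -1 + 2 * 0.5) / 2)
        assert u[2, 0] == pytest.approx(1 * 0.5 / 1)

    def test_lambda_equal_length_rejected(self):
        with pytest.raises(FeatureError, match="length 4"):
            pseudofactors(np.ones((4, 1)), 4, identifier="shorty")


class TestDescriptorVector:
    def test_sums_to_one(self, props, default_config):
        rng = np.random.default_rng(4)
        vec = descriptor_vector(random_profile(rng, 30), props, default_config)
        assert vec.q.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("lam,expected", [(11, 119), (9, 101)])
    def test_dimension_20_plus_lambda_R(self, props, lam, expected):
        cfg = FeatureConfig(w=0.15, lam=lam,
                            property_accessions=props.source_accessions)
        assert cfg.n_features == expected
        rng = np.random.default_rng(5)
        vec = descriptor_vector(random_profile(rng, 40), props, cfg)
        assert vec.q.shape == (expected,)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_oracle_equivalence_random_instances(self, props, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(12, 41))
        R = int(rng.integers(1, 10))
        lam = int(rng.integers(1, L))
        w = float(rng.uniform(0.05, 0.95))
        h = props.h[:R]
        prof = random_profile(rng, L)
        cfg = FeatureConfig(w=w, lam=lam,
                            property_accessions=props.source_accessions[:R])
        from pspcp.properties import NormalizedPropertyTable

        table = NormalizedPropertyTable(h, props.source_accessions[:R])
        # the shared denominator can legitimately go non-positive for signed
        # pseudofactors; that case must be the declared error, not a vector
        try:
            q = descriptor_vector(prof, table, cfg).q
        except FeatureError:
            d = prof.A @ h.T
            u = [
                (d[:-k] * d[k:]).mean(axis=0) for k in range(1, lam + 1)
            ]
            assert 1.0 + w * np.sum(u) <= 0
            return
        assert q.shape == (20 + lam * R,)
        assert np.allclose(q, naive_descriptor(prof.A, h, w, lam), atol=1e-10)

    def test_one_hot_pipeline_degrades_to_ampseaac(self, props):
        rng = np.random.default_rng(6)
        for _ in range(10):
            L = int(rng.integers(15, 40))
            seq = "".join(rng.choice(list(RESIDUE_ORDER), L))
            lam = int(rng.integers(1, 10))
            w = float(rng.uniform(0.05, 0.95))
            cfg = FeatureConfig(w=w, lam=lam,
                                property_accessions=props.source_accessions)
            try:
                q = descriptor_vector(
                    one_hot_profile(ProteinRecord("p", seq)), props, cfg
                ).q
            except FeatureError:
                # non-positive shared denominator: verify independently
                idx = [RESIDUE_ORDER.index(aa) for aa in seq]
                total_u = sum(
                    sum(props.h[r][idx[i]] * props.h[r][idx[i + k]]
                        for i in range(L - k)) / (L - k)
                    for r in range(props.R)
                    for k in range(1, lam + 1)
                )
                assert 1.0 + w * total_u <= 0
                continue
            assert np.allclose(q, naive_ampseaac(seq, props.h, w, lam), atol=1e-10)

    def test_pseudo_block_is_property_major(self, props):
        # entry 20 + (r-1)*lam + k must hold w*u[k, r]/Z
        rng = np.random.default_rng(7)
        prof = random_profile(rng, 20)
        cfg = FeatureConfig(w=0.3, lam=4,
                            property_accessions=props.source_accessions)
        q = descriptor_vector(prof, props, cfg).q
        d = pspcp(prof, props)
        u = pseudofactors(d, 4)
        Z = composition(prof).sum() + 0.3 * u.sum()
        for r in range(props.R):
            for k in range(1, 5):
                n = 20 + r * 4 + (k - 1)
                assert q[n] == pytest.approx(0.3 * u[k - 1, r] / Z, abs=1e-12)

    def test_increasing_w_shifts_mass_to_pseudo_block(self, props):
        rng = np.random.default_rng(8)
        prof = random_profile(rng, 30)
        ratios = []
        for w in (0.1, 0.3, 0.6, 0.9):
            cfg = FeatureConfig(w=w, lam=5,
                                property_accessions=props.source_accessions)
            q = descriptor_vector(prof, props, cfg).q
            ratios.append(abs(q[20:]).sum() / abs(q[:20]).sum())
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_diagnostics_mode(self, props, default_config):
        rng = np.random.default_rng(9)
        q = descriptor_vector(random_profile(rng, 30), props, default_config).q
        check_descriptor(q, default_config)  # length + sum only
        if np.any(q < 0):
            with pytest.raises(FeatureError, match="negative"):
                check_descriptor(q, default_config, require_nonnegative=True)


class TestExtractFeatures:
    def test_origin_flags_and_row_order(self, tmp_path, props):
        rng = np.random.default_rng(10)
        records = [
            ProteinRecord(f"p{i}", "".join(rng.choice(list(RESIDUE_ORDER), 20)))
            for i in range(3)
        ]
        for rec in records[:2]:
            E = rng.integers(-5, 6, size=(rec.length, 20))
            write_ascii_pssm(
                PSSMMatrix(rec.identifier, E, rec.sequence),
                tmp_path / f"{rec.identifier}.pssm",
            )
        cfg = FeatureConfig(w=0.15, lam=5,
                            property_accessions=props.source_accessions)
        res = extract_features(records, tmp_path, props, cfg)
        assert res.identifiers == ["p0", "p1", "p2"]
        assert res.origins == ["pssm", "pssm", "one_hot"]

    def test_empty_record_list_rejected(self, props):
        with pytest.raises(FeatureError, match="no records"):
            extract_features([], None, props)

    def test_identical_records_give_identical_rows(self, props):
        rec = ProteinRecord("a", "ACDEFGHIKLMNPQ")
        rec2 = ProteinRecord("b", "ACDEFGHIKLMNPQ")
        cfg = FeatureConfig(w=0.15, lam=3,
                            property_accessions=props.source_accessions)
        res = extract_features([rec, rec2], None, props, cfg)
        assert np.array_equal(res.X[0], res.X[1])

    def test_short_sequence_skipped_and_reported(self, props):
        cfg = FeatureConfig(w=0.15, lam=10,
                            property_accessions=props.source_accessions)
        res = extract_features(
            [ProteinRecord("ok", "A" * 30), ProteinRecord("short", "ACD")],
            None, props, cfg,
        )
        assert res.identifiers == ["ok"]
        assert res.errors and res.errors[0][0] == "short"
        with pytest.raises(FeatureError, match="short"):
            extract_features(
                [ProteinRecord("short", "ACD")], None, props, cfg, strict=True
            )

    def test_feature_tsv_round_trip(self, tmp_path, props):
        rec = ProteinRecord("a", "ACDEFGHIKLMNPQRSTVWY")
        cfg = FeatureConfig(w=0.15, lam=4,
                            property_accessions=props.source_accessions)
        res = extract_features([rec], None, props, cfg)
        path = tmp_path / "f.tsv"
        write_feature_tsv(res, path)
        X, ids, names = read_feature_tsv(path)
        assert ids == ["a"]
        assert names == feature_names(cfg)
        assert names[0] == "f_A" and names[20] == "u_BULH740101_k1"
        assert np.allclose(X, res.X, rtol=0, atol=0)  # 17 sig digits: exact


class TestVectorizer:
    def test_sklearn_contract(self, easy_dataset):
        from sklearn.pipeline import make_pipeline
        from pspcp import LocationSVC

        vec = PspcpVectorizer(w=0.15, lam=11)
        pipe = make_pipeline(vec, LocationSVC(gamma=8, C=8))
        pipe.fit(easy_dataset.profiles, easy_dataset.labels)
        assert vec.n_features_out_ == 119
        preds = pipe.predict(easy_dataset.profiles)
        assert len(preds) == len(easy_dataset)
        assert vec.get_feature_names_out()[0] == "f_A"

    def test_records_degrade_to_one_hot(self, props):
        vec = PspcpVectorizer(w=0.15, lam=2).fit()
        recs = [ProteinRecord("a", "ACDEFGH")]
        X = vec.transform(recs)
        q = descriptor_vector(
            one_hot_profile(recs[0]), props,
            FeatureConfig(w=0.15, lam=2,
                          property_accessions=props.source_accessions),
        ).q
        assert np.allclose(X[0], q, atol=1e-12)


class TestFeatureConfig:
    @pytest.mark.parametrize("w", [0.0, 1.0, -0.1, 1.5])
    def test_w_outside_open_unit_interval_rejected(self, w):
        with pytest.raises(FeatureError):
            FeatureConfig(w=w, lam=3)

    def test_lambda_must_be_positive_integer(self):
        with pytest.raises(FeatureError):
            FeatureConfig(w=0.5, lam=0)
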