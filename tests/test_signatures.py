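"""Catalog construction and signature refitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihrdkit.contexts import CONTEXTS_96, CONTEXT_INDEX, context_key
from ihrdkit.signatures import (
    CSIG3_MIN_ATTRIBUTED,
    SignatureExposure,
    SignatureMatrix,
    SignatureRefitter,
    TrinucleotideCatalog,
    build_catalog,
    call_csig3,
    fit_signatures,
    synthetic_signature_matrix,
)

from _oracles import constrained_ls_weights, grid_two_signature_weights


class TestContexts:
    def test_canonical_ordering(self):
        assert len(CONTEXTS_96) == 96 == len(set(CONTEXTS_96))
        assert CONTEXTS_96[0] == "A[C>A]A"
        assert CONTEXTS_96[16] == "A[C>G]A"
        assert CONTEXTS_96[-1] == "T[T>G]T"
        # within a block: 5' base varies slowest, 3' base fastest
        assert CONTEXTS_96[1] == "A[C>A]C"
        assert CONTEXTS_96[4] == "C[C>A]A"

    @pytest.mark.parametrize("ref,alt,tri,expected", [
        ("C", "T", "ACA", "A[C>T]A"),
        ("G", "A", "TGT", "A[C>T]A"),   # purine strand flips
        ("A", "C", "AAA", "T[T>G]T"),
        ("T", "G", "TTT", "T[T>G]T"),
    ])
    def test_pyrimidine_strand_normalisation(self, ref, alt, tri, expected):
        assert context_key(ref, alt, tri) == expected

    def test_strand_symmetry_everywhere(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(50):
            key = CONTEXTS_96[rng.integers(96)]
            five, ref, alt, three = key[0], key[2], key[4], key[6]
            flipped = context_key(
                comp[ref], comp[alt], comp[three] + comp[ref] + comp[five]
            )
            assert flipped == key


class TestBuildCatalog:
    def test_empty_input_gives_zero_catalog(self):
        report = build_catalog("t", [])
        assert report.catalog.n_snvs == 0
        assert report.catalog.counts.sum() == 0

    def test_single_snv_and_reverse_complement(self):
        report = build_catalog("t", [
            ("1", 100, "C", "T", "ACA"),
            ("1", 200, "G", "A", "TGT"),
        ])
        assert report.catalog.n_snvs == 2
        assert report.catalog.counts[CONTEXT_INDEX["A[C>T]A"]] == 2

    def test_invalid_records_reported_not_dropped_silently(self):
        report = build_catalog("t", [
            ("1", 1, "C", "T", "ACA"),
            ("1", 2, "CT", "C", "ACA"),   # indel
            ("1", 3, "C", "T", "ANA"),    # unknown base
            ("1", 4, "C", "T", "AGA"),    # middle base mismatch
        ])
        assert report.catalog.n_snvs == 1
        assert report.n_rejected == 3
        reasons = " ".join(r for _, r in report.rejected)
        assert "substitution" in reasons and "unknown" in reasons

    def test_missing_context_without_source_is_hard_error(self):
        with pytest.raises(ValueError, match="context_source"):
            build_catalog("t", [("1", 1, "C", "T")])

    def test_context_source_resolves_contexts(self):
        report = build_catalog(
            "t", [("1", 5, "C", "T")], context_source=lambda c, p: "GCG"
        )
        assert report.catalog.counts[CONTEXT_INDEX["G[C>T]G"]] == 1


class TestFitSignatures:
    def test_pure_signature_recovered_exactly(self, small_sigs):
        for name in small_sigs.signature_ids:
            catalog = TrinucleotideCatalog(
                "t", np.round(small_sigs.column(name) * 9600)
            )
            exposure = fit_signatures(catalog, small_sigs)
            assert exposure.weight(name) == pytest.approx(1.0, abs=1e-6)
            assert exposure.weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_pure_signature_recovery_full_reference(self):
        sigs = synthetic_signature_matrix()
        for name in ("CSig1", "CSig3", "CSig17"):
            catalog = TrinucleotideCatalog("t", sigs.column(name) * 50_000)
            assert fit_signatures(catalog, sigs).weight(name) == pytest.approx(
                1.0, abs=1e-6
            )

    def test_two_signature_mixture_matches_grid_oracle(self, small_sigs):
        two = SignatureMatrix(
            ("CSigA", "CSig1"), small_sigs.profiles[:, :2]
        )
        target = 0.6 * two.column("CSigA") + 0.4 * two.column("CSig1")
        catalog = TrinucleotideCatalog("t", np.round(target * 10_000))
        exposure = fit_signatures(catalog, two, weight_cutoff=0.0)
        oracle = grid_two_signature_weights(catalog.normalized(), two.profiles)
        assert exposure.weights == pytest.approx([0.6, 0.4], abs=1e-3)
        assert exposure.weights == pytest.approx(oracle, abs=2e-4)

    def test_matches_constrained_ls_oracle_on_random_catalogs(self, small_sigs, rng):
        for _ in range(20):
            counts = rng.multinomial(
                300, rng.dirichlet(np.full(96, 0.5))
            )
            catalog = TrinucleotideCatalog("t", counts)
            ours = fit_signatures(catalog, small_sigs, weight_cutoff=0.0).weights
            oracle = constrained_ls_weights(catalog.normalized(), small_sigs.profiles)
            assert np.max(np.abs(ours - oracle)) < 1e-4

    def test_cutoff_zeroes_small_weights_and_renormalises(self, small_sigs):
        three = SignatureMatrix(("CSigA", "CSig1", "CSig3"),
                                small_sigs.profiles[:, :3])
        mix = (0.57 * three.column("CSigA") + 0.40 * three.column("CSig1")
               + 0.03 * three.column("CSig3"))
        catalog = TrinucleotideCatalog("t", np.round(mix * 100_000))
        # oracle: constrained LS weights with the cutoff applied by hand
        raw = constrained_ls_weights(catalog.normalized(), three.profiles)
        kept = np.where(raw >= 0.06, raw, 0.0)
        expected = kept * raw.sum() / kept.sum()
        exposure = fit_signatures(catalog, three, weight_cutoff=0.06)
        assert exposure.weight("CSig3") == 0.0
        assert exposure.weights == pytest.approx(expected, abs=1e-4)
        # renormalisation preserves the pre-cutoff total exactly
        pre = fit_signatures(catalog, three, weight_cutoff=0.0)
        assert exposure.weights.sum() == pytest.approx(pre.weights.sum(), abs=1e-12)

    def test_mixture_recovery_under_multinomial_noise(self, small_sigs):
        rng = np.random.default_rng(42)
        truth = np.array([0.35, 0.30, 0.25, 0.10])
        target = small_sigs.profiles @ truth
        maes = []
        for _ in range(200):
            catalog = TrinucleotideCatalog("t", rng.multinomial(500, target))
            exposure = fit_signatures(catalog, small_sigs)
            maes.append(np.abs(exposure.weights - truth).mean())
        assert np.mean(maes) < 0.05

    def test_context_scaling_flag(self, small_sigs):
        catalog = TrinucleotideCatalog(
            "t", np.round(small_sigs.column("CSig1") * 2000)
        )
        unscaled = fit_signatures(catalog, small_sigs)
        identity = fit_signatures(catalog, small_sigs,
                                  context_scaling=np.ones(96))
        assert identity.weights == pytest.approx(unscaled.weights, abs=1e-9)
        assert identity.n_snvs == catalog.n_snvs
        with pytest.raises(ValueError, match="positive 96-vector"):
            fit_signatures(catalog, small_sigs, context_scaling=np.zeros(96))

    def test_empty_catalog_rejected(self, small_sigs):
        with pytest.raises(ValueError, match="empty"):
            fit_signatures(TrinucleotideCatalog("t", np.zeros(96)), small_sigs)


def _exposure(w3: float, n: int) -> SignatureExposure:
    return SignatureExposure(
        sample_id="t",
        signature_ids=("CSig3", "CSig1"),
        weights=np.array([w3, min(1 - w3, 0.5)]),
        n_snvs=n,
        reliable=n > 50,
        csig3_positive=False,
        csig8_positive=False,
    )


class TestCSig3Call:
    @pytest.mark.parametrize("w,n,expected", [
        (0.25, 1000, True),    # 250 attributed
        (0.25, 100, False),    # only 25 attributed
        (0.20, 10_000, False),  # weight must strictly exceed 0.20
        (0.21, 30, False),     # unreliable catalog
    ])
    def test_rule(self, w, n, expected):
        assert call_csig3(_exposure(w, n)) is expected

    def test_missing_signature_is_hard_error(self):
        exp = SignatureExposure("t", ("CSig1",), np.array([0.5]), 100,
                                True, False, False)
        with pytest.raises(KeyError):
            call_csig3(exp)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        w=st.floats(0.0, 1.0),
        n1=st.integers(0, 3000),
        n2=st.integers(0, 3000),
    )
    def test_monotone_in_n_snvs_at_fixed_weight(self, w, n1, n2):
        lo, hi = sorted((n1, n2))
        if call_csig3(_exposure(w, lo)):
            assert call_csig3(_exposure(w, hi))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        w1=st.floats(0.0, 1.0),
        w2=st.floats(0.0, 1.0),
        n=st.integers(0, 3000),
    )
    def test_monotone_in_weight_at_fixed_n(self, w1, w2, n):
        lo, hi = sorted((w1, w2))
        if call_csig3(_exposure(lo, n)):
            assert call_csig3(_exposure(hi, n))


class TestSignatureRefitter:
    def test_transformer_matches_function_api(self, small_sigs, rng):
        X = np.vstack([
            rng.multinomial(400, small_sigs.mixture_profile(
                {"CSigA": 0.5, "CSig3": 0.5}))
            for _ in range(5)
        ])
        refitter = SignatureRefitter(small_sigs).fit()
        W = refitter.transform(X)
        for i in range(5):
            exposure = fit_signatures(
                TrinucleotideCatalog(f"s{i}", X[i]), small_sigs
            )
            assert W[i] == pytest.approx(exposure.weights, abs=1e-9)

    def test_validates_matrix_and_bins(self, small_sigs):
        with pytest.raises(ValueError, match="96"):
            SignatureRefitter(small_sigs).fit().transform(np.ones((2, 50)))
        with pytest.raises(ValueError, match="sum to 1"):
            SignatureMatrix(("a",), np.full((96, 1), 0.5))
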