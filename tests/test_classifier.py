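"""Dual-axis dichotomy and feature-matrix classifiers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixstrat import (
    CohortConfig,
    DiagnosisLabel,
    FeatureMatrix,
    FeatureVector,
    Thresholds,
    ad_axis_positive,
    classify_cohort,
    classify_dichotomy,
    classify_feature_matrix,
    feature_vector,
    generate_cohort,
    vascular_axis_positive,
    well_separated_group_params,
)
from mixstrat.classify import FEATURE_NAMES, TIE_PRECEDENCE
from mixstrat.exceptions import MissingDataError
from mixstrat.labels import UNCLASSIFIED

L = DiagnosisLabel
TH = Thresholds()


def record(**overrides):
    """A fully-normal control-like record; override fields per test."""
    base = dict(
        ptau=50.0,
        ab_ratio=0.10,
        md_z=0.0,
        t_memory=52.0,
        t_executive=51.0,
        albumin_index=5.0,
        hyperreflexia=False,
        imbalance=False,
        wmh_present=False,
        infarct=False,
    )
    base.update(overrides)
    return base


class TestAxes:
    def test_ptau_elevation_positive(self):
        # the mixed-dementia group's typical Ptau is far above the cut
        assert ad_axis_positive(record(ptau=118.86), TH)

    def test_normal_analytes_negative(self):
        assert not ad_axis_positive(record(ptau=50, ab_ratio=0.10), TH)

    def test_rule_both_requires_both(self):
        th = Thresholds(ad_axis_rule="both")
        assert not ad_axis_positive(record(ptau=120, ab_ratio=0.10), th)
        assert ad_axis_positive(record(ptau=120, ab_ratio=0.05), th)

    def test_single_analyte_rules(self):
        assert ad_axis_positive(record(ptau=120), Thresholds(ad_axis_rule="ptau_only"))
        assert not ad_axis_positive(
            record(ptau=120, ab_ratio=0.10), Thresholds(ad_axis_rule="amyloid_only")
        )

    @pytest.mark.parametrize("md_z, expected", [(2.94, True), (0.74, False), (2.0, True)])
    def test_vascular_axis(self, md_z, expected):
        # 2.94 is the typical SIVD z, 0.74 the typical AD z; 2.0 is the boundary
        assert vascular_axis_positive(record(md_z=md_z), TH) is expected

    def test_missing_analyte_errors(self):
        with pytest.raises(MissingDataError):
            ad_axis_positive(record(ptau=float("nan")), TH)
        with pytest.raises(MissingDataError):
            vascular_axis_positive(record(md_z=None), TH)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        ptau=st.floats(1, 300),
        bump=st.floats(0, 200),
        md_z=st.floats(-3, 8),
        dz=st.floats(0, 5),
    )
    def test_monotonicity(self, ptau, bump, md_z, dz):
        """Raising Ptau or md_z never turns a positive axis negative."""
        if ad_axis_positive(record(ptau=ptau), TH):
            assert ad_axis_positive(record(ptau=ptau + bump), TH)
        if vascular_axis_positive(record(md_z=md_z), TH):
            assert vascular_axis_positive(record(md_z=md_z + dz), TH)


class TestDichotomy:
    def test_quadrants_enumerated(self):
        """All four axis combinations map to the four quadrant labels."""
        high_ptau, low_ptau = 120.0, 40.0
        high_md, low_md = 3.0, 0.0
        expected = {
            (True, True): L.MX,
            (True, False): L.AD,
            (False, True): L.SIVD,
            (False, False): L.LA,
        }
        for (ad_pos, vasc_pos), label in expected.items():
            r = record(
                ptau=high_ptau if ad_pos else low_ptau,
                md_z=high_md if vasc_pos else low_md,
            )
            assert ad_axis_positive(r, TH) is ad_pos
            assert vascular_axis_positive(r, TH) is vasc_pos
            assert classify_dichotomy(r, TH) is label
            # MX if and only if both axes positive (non-MI records)
            assert (classify_dichotomy(r, TH) is L.MX) == (ad_pos and vasc_pos)

    def test_infarct_overrides_everything(self):
        for ptau, md_z in itertools.product([40.0, 120.0], [0.0, 3.0]):
            assert classify_dichotomy(record(ptau=ptau, md_z=md_z, infarct=True), TH) is L.MI

    def test_partition_totality(self):
        """Every classifiable record receives exactly one of the five labels."""
        rng = np.random.default_rng(0)
        for _ in range(500):
            r = record(
                ptau=float(rng.uniform(1, 250)),
                ab_ratio=float(rng.uniform(0.01, 0.2)),
                md_z=float(rng.normal(1.5, 2)),
                infarct=bool(rng.random() < 0.1),
            )
            assert classify_dichotomy(r, TH) in {L.MI, L.MX, L.AD, L.SIVD, L.LA}


class TestFeatureVector:
    def test_ad_archetype_binarization(self):
        """Low memory + normal DTI + extreme Ptau flags memory deficit, not DTI."""
        fv = feature_vector(record(t_memory=25, md_z=0.3, ptau=200), TH)
        assert fv.memory_deficit and not fv.md_dti_high and fv.ptau_positive

    def test_all_normal_control(self):
        fv = feature_vector(record(), TH)
        assert not any(fv.as_tuple())

    def test_boundary_values_positive_at_cut(self):
        fv = feature_vector(
            record(
                t_memory=TH.t_memory_low,
                t_executive=TH.t_executive_low,
                ptau=TH.ptau_high,
                ab_ratio=TH.ab_ratio_low,
                md_z=TH.md_z_high,
                albumin_index=TH.albumin_index_high,
            ),
            TH,
        )
        assert fv.memory_deficit and fv.executive_deficit
        assert fv.ptau_positive and fv.amyloid_positive
        assert fv.md_dti_high and fv.albumin_index_high

    def test_missing_field_errors(self):
        with pytest.raises(MissingDataError):
            feature_vector(record(albumin_index=None), TH)


def hamming_oracle(fv: FeatureVector, fm: FeatureMatrix):
    """Independent exhaustive Hamming-distance minimizer over the columns."""
    observed = fv.as_tuple()
    distances = {
        label: sum(o != e for o, e in zip(observed, signs)) for label, signs in fm.signs.items()
    }
    best = min(distances.values())
    winners = {label for label, d in distances.items() if d == best}
    for label in TIE_PRECEDENCE:
        if label in winners:
            return label
    return winners.pop()


class TestFeatureMatrix:
    @pytest.mark.parametrize("label", [L.SIVD, L.AD, L.MX, L.LA])
    def test_archetypes_score_nine(self, label):
        fm = FeatureMatrix()
        fv = FeatureVector(*fm.signs[label])
        winner, scores = classify_feature_matrix(fv, fm)
        assert winner is label and scores[label] == 9

    def test_tie_goes_to_precedence(self):
        fm = FeatureMatrix()
        # flip features until two columns are equidistant, then check order
        fv = FeatureVector(True, True, False, True, True, True, True, True, True)
        winner, scores = classify_feature_matrix(fv, fm)
        best = max(scores.values())
        tied = [l for l in scores if scores[l] == best]
        assert winner == next(l for l in TIE_PRECEDENCE if l in tied)
        assert len(scores) == 4

    def test_matches_hamming_oracle_exhaustively(self):
        """Agreement-maximizer equals the brute-force Hamming minimizer.

        All 2^9 = 512 feature vectors exist; checking 10,000 random draws
        (with replacement) therefore covers the space many times over.
        """
        fm = FeatureMatrix()
        rng = np.random.default_rng(7)
        draws = rng.integers(0, 2, size=(10_000, 9)).astype(bool)
        for row in draws:
            fv = FeatureVector(*map(bool, row))
            assert classify_feature_matrix(fv, fm)[0] is hamming_oracle(fv, fm)

    def test_both_classifiers_agree_on_archetypes(self):
        """Records built exactly at the sign-matrix archetypes get the same
        label from the dichotomy and the feature matcher (MX/AD/SIVD/LA)."""
        fm = FeatureMatrix()
        value_for = {
            "hyperreflexia": lambda s: s,
            "imbalance": lambda s: s,
            "executive_deficit": lambda s: 30.0 if s else 55.0,
            "memory_deficit": lambda s: 30.0 if s else 55.0,
            "wmh_flair": lambda s: s,
            "md_dti_high": lambda s: 3.5 if s else 0.0,
            "amyloid_positive": lambda s: 0.04 if s else 0.12,
            "ptau_positive": lambda s: 150.0 if s else 40.0,
            "albumin_index_high": lambda s: 9.0 if s else 5.0,
        }
        field_for = {
            "executive_deficit": "t_executive",
            "memory_deficit": "t_memory",
            "wmh_flair": "wmh_present",
            "md_dti_high": "md_z",
            "amyloid_positive": "ab_ratio",
            "ptau_positive": "ptau",
        }
        for label, signs in fm.signs.items():
            overrides = {}
            for name, sign in zip(FEATURE_NAMES, signs):
                overrides[field_for.get(name, name)] = value_for[name](sign)
            r = record(**overrides)
            assert classify_feature_matrix(feature_vector(r, TH), fm)[0] is label
            assert classify_dichotomy(r, TH) is label


class TestClassifyCohort:
    def test_controls_and_la_never_mx_or_ad(self, study_sized_cohort):
        """With well-separated CSF defaults, Control and LA rows stay off the
        Alzheimer quadrants under the dichotomy."""
        labeled = classify_cohort(study_sized_cohort, TH, method="dichotomy")
        benign = labeled[labeled["biological_label"].isin(["CONTROL", "LA"])]
        # Control/LA Ptau and amyloid-ratio distributions sit mostly below the
        # cuts; a small tail can cross, so require a dominant majority
        assert (benign["biological_label_predicted"].isin(["LA", "SIVD"])).mean() > 0.60

    def test_empty_table(self, study_sized_cohort):
        labeled = classify_cohort(study_sized_cohort.iloc[0:0])
        assert labeled.empty and "biological_label_predicted" in labeled.columns

    def test_missing_column_unclassified(self, study_sized_cohort):
        broken = study_sized_cohort.drop(columns=["md_z"]).head(10)
        labeled = classify_cohort(broken, TH, method="dichotomy")
        assert (labeled["biological_label_predicted"] == UNCLASSIFIED).all()
        assert labeled["unclassified_reason"].str.contains("md_z").all()

    def test_missing_value_unclassified(self, study_sized_cohort):
        table = study_sized_cohort.head(10).copy()
        table.loc[table.index[0], "ptau"] = float("nan")
        labeled = classify_cohort(table, TH)
        assert labeled["biological_label_predicted"].iloc[0] == UNCLASSIFIED
        assert (labeled["biological_label_predicted"].iloc[1:] != UNCLASSIFIED).all()

    def test_feature_method_adds_scores(self, study_sized_cohort):
        labeled = classify_cohort(study_sized_cohort.head(5), TH, method="feature_matrix")
        for label in ("SIVD", "AD", "MX", "LA"):
            assert f"score_{label}" in labeled.columns
            assert labeled[f"score_{label}"].between(0, 9).all()

    def test_recovery_on_well_separated_cohort(self):
        """At default thresholds the dichotomy recovers >=90% of biological
        labels in a low-noise cohort of the four sign-matrix groups."""
        sizes = {L.SIVD: 100, L.AD: 100, L.MX: 100, L.LA: 100}
        identity = {label: {label: 1.0} for label in L}
        table = generate_cohort(
            CohortConfig(group_sizes=sizes, seed=17, confusion=identity),
            well_separated_group_params(),
        )
        labeled = classify_cohort(table, TH, method="dichotomy")
        accuracy = (labeled["biological_label_predicted"] == labeled["biological_label"]).mean()
        assert accuracy >= 0.90
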