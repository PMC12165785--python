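"""Evidence-code assignment and both code-combination systems."""

import itertools

import pytest

from crisprselect.acmg import (
    CLASSES,
    EvidenceCode,
    VariantAnnotation,
    apply_asserted_splicing_codes,
    assemble_codes,
    classify_variant,
    combine_points,
    combine_qualitative,
    computational_code,
    points_for,
    population_code,
    read_annotation_table,
    write_annotation_table,
)


def ann(**kwargs):
    return VariantAnnotation(variant_id=kwargs.pop("variant_id", "c.1A>G"), **kwargs)


class TestPopulationCode:
    @pytest.mark.parametrize(
        "fields,code_id,strength",
        [
            ({"faf_max": 0.002}, "BA1", "very_strong"),
            ({"faf_max": 0.0005}, "BS1", "strong"),
            ({"faf_max": 0.00005}, "BS1", "supporting"),
            ({"maf_max": 0.00001}, "PM2", "indeterminate"),
            ({}, "PM2", "supporting"),
        ],
    )
    def test_frequency_bands(self, fields, code_id, strength):
        code = population_code(ann(**fields))
        assert (code.code_id, code.strength) == (code_id, strength)

    def test_ba1_is_stand_alone(self):
        assert population_code(ann(faf_max=0.01)).direction == "stand_alone_benign"

    def test_absent_in_controls_scores_plus_one(self):
        assert population_code(ann()).points == 1


class TestComputationalCode:
    @pytest.mark.parametrize(
        "bayesdel,spliceai,expected",
        [
            (0.35, 0.05, "PP3"),  # BayesDel alone suffices
            (0.10, 0.50, "PP3"),  # SpliceAI alone suffices
            (0.10, 0.05, "BP4"),  # both in the benign band
            (0.10, 0.15, None),  # gap zone
            (0.25, 0.05, None),  # BayesDel between the bands
        ],
    )
    def test_bands(self, bayesdel, spliceai, expected):
        code = computational_code(ann(bayesdel_noaf=bayesdel, spliceai_delta=spliceai))
        assert (code.code_id if code else None) == expected

    def test_missing_scores_yield_none(self):
        assert computational_code(ann(bayesdel_noaf=0.5)) is None

    def test_pp3_suppressed_under_pvs1(self):
        a = ann(bayesdel_noaf=0.1, spliceai_delta=0.9)
        assert computational_code(a).code_id == "PP3"
        assert computational_code(a, pvs1_asserted=True) is None


class TestAssertedSplicingCodes:
    def test_pvs1_suppresses_ps1_with_warning(self):
        a = ann(asserted_codes=(("PVS1_RNA", "strong"), ("PS1_splicing", "moderate")))
        with pytest.warns(UserWarning, match="PS1_splicing dropped"):
            codes = apply_asserted_splicing_codes(a)
        assert [c.code_id for c in codes] == ["PVS1_RNA"]

    def test_ps1_passes_through(self):
        codes = apply_asserted_splicing_codes(ann(asserted_codes=(("PS1_splicing", "moderate"),)))
        assert [(c.code_id, c.strength) for c in codes] == [("PS1_splicing", "moderate")]

    def test_no_assertions(self):
        assert apply_asserted_splicing_codes(ann()) == []

    def test_pvs1_also_suppresses_pp3_in_assembly(self):
        a = ann(
            bayesdel_noaf=0.1,
            spliceai_delta=0.9,
            asserted_codes=(("PVS1_RNA", "strong"),),
        )
        codes = assemble_codes(None, a)
        ids = [c.code_id for c in codes]
        assert "PVS1_RNA" in ids and "PP3" not in ids


class TestPoints:
    @pytest.mark.parametrize(
        "code,direction,strength,expected",
        [
            ("PS3", "pathogenic", "moderate", 2),
            ("BP4", "benign", "supporting", -1),
            ("PS3", "pathogenic", "indeterminate", 0),
            ("PVS1_RNA", "pathogenic", "very_strong", 8),
            ("BS3", "benign", "strong", -4),
        ],
    )
    def test_point_table(self, code, direction, strength, expected):
        assert points_for(code, direction, strength) == expected

    def test_unknown_strength_rejected(self):
        with pytest.raises(ValueError):
            points_for("PS3", "pathogenic", "huge")


def bundle(*specs):
    return [EvidenceCode(cid, d, s) for cid, d, s in specs]


class TestCombinePoints:
    def test_likely_pathogenic_sum(self):
        codes = bundle(
            ("PVS1_RNA", "pathogenic", "strong"),
            ("PS3", "pathogenic", "moderate"),
            ("PM2", "pathogenic", "supporting"),
        )
        assert combine_points(codes) == (7, "likely_pathogenic")

    def test_uncertain_sum(self):
        codes = bundle(
            ("PS3", "pathogenic", "moderate"),
            ("BP4", "benign", "supporting"),
            ("PM2", "pathogenic", "indeterminate"),
        )
        assert combine_points(codes) == (1, "uncertain")

    def test_likely_benign_sum(self):
        codes = bundle(("BS3", "benign", "moderate"), ("BP4", "benign", "supporting"))
        assert combine_points(codes) == (-3, "likely_benign")

    def test_ba1_short_circuits(self):
        codes = bundle(
            ("BA1", "stand_alone_benign", "very_strong"),
            ("PS3", "pathogenic", "strong"),
            ("PVS1_RNA", "pathogenic", "very_strong"),
        )
        _, cls = combine_points(codes)
        assert cls == "benign"

    @pytest.mark.parametrize(
        "total,expected",
        [(-7, "benign"), (-6, "likely_benign"), (-2, "likely_benign"), (-1, "uncertain"),
         (5, "uncertain"), (6, "likely_pathogenic"), (9, "likely_pathogenic"), (10, "pathogenic")],
    )
    def test_point_scale_boundaries(self, total, expected):
        # Build a bundle summing to the target via very-strong and supporting codes.
        codes = []
        rest = total
        while rest >= 1:
            codes.append(EvidenceCode("PM2", "pathogenic", "supporting"))
            rest -= 1
        while rest <= -1:
            codes.append(EvidenceCode("BP4", "benign", "supporting"))
            rest += 1
        got_total, cls = combine_points(codes)
        assert got_total == total
        assert cls == expected


class TestCombineQualitative:
    def test_strong_plus_moderate_plus_supporting(self):
        codes = bundle(
            ("PVS1_RNA", "pathogenic", "strong"),
            ("PS3", "pathogenic", "moderate"),
            ("PM2", "pathogenic", "supporting"),
        )
        assert combine_qualitative(codes) == "likely_pathogenic"

    def test_bs3_moderate_counts_as_two_supporting(self):
        codes = bundle(("BS3", "benign", "moderate"), ("BP4", "benign", "supporting"))
        assert combine_qualitative(codes) == "likely_benign"

    def test_moderate_plus_supporting_insufficient(self):
        codes = bundle(("PS3", "pathogenic", "moderate"), ("PM2", "pathogenic", "supporting"))
        assert combine_qualitative(codes) == "uncertain"

    def test_indeterminate_codes_ignored(self):
        codes = bundle(("PS3", "pathogenic", "indeterminate"), ("PM2", "pathogenic", "indeterminate"))
        assert combine_qualitative(codes) == "uncertain"

    def test_two_strong_benign(self):
        codes = bundle(("BS3", "benign", "strong"), ("BS1", "benign", "strong"))
        assert combine_qualitative(codes) == "benign"


# Worked classification bundles mirroring the study's exemplar variants.
class TestClassifyVariant:
    def test_splice_loss_bundle_is_likely_pathogenic_in_both_systems(self):
        functional = EvidenceCode("PS3", "pathogenic", "moderate")
        a = ann(
            bayesdel_noaf=0.10,
            spliceai_delta=0.95,
            asserted_codes=(("PVS1_RNA", "strong"),),
        )
        res = classify_variant(functional, a)
        assert res.point_total == 7
        assert res.point_class == "likely_pathogenic"
        assert res.qualitative_class == "likely_pathogenic"
        assert res.final_class == "likely_pathogenic"
        assert not res.discordant

    def test_discordant_insilico_bundle_stays_uncertain(self):
        # Deleterious in the assay but benign-band in-silico scores: PS3
        # moderate + BP4 + PM2 indeterminate cannot move off uncertain.
        functional = EvidenceCode("PS3", "pathogenic", "moderate")
        a = ann(maf_max=1e-5, bayesdel_noaf=0.10, spliceai_delta=0.05)
        res = classify_variant(functional, a)
        assert res.point_total == 1
        assert res.final_class == "uncertain"

    def test_neutral_bundle_is_likely_benign(self):
        functional = EvidenceCode("BS3", "benign", "moderate")
        a = ann(faf_max=5e-5, bayesdel_noaf=0.05, spliceai_delta=0.02)
        res = classify_variant(functional, a)
        assert res.point_total == -4
        assert res.final_class == "likely_benign"

    def test_ba1_dominates_any_bundle(self):
        functional = EvidenceCode("PS3", "pathogenic", "moderate")
        res = classify_variant(functional, ann(faf_max=0.002))
        assert res.final_class == "benign"


FUNCTIONAL_OPTIONS = [None] + [
    EvidenceCode("PS3", "pathogenic", s) for s in ("indeterminate", "supporting", "moderate", "strong")
] + [EvidenceCode("BS3", "benign", s) for s in ("supporting", "moderate", "strong")]
POPULATION_OPTIONS = [
    EvidenceCode("BA1", "stand_alone_benign", "very_strong"),
    EvidenceCode("BS1", "benign", "strong"),
    EvidenceCode("BS1", "benign", "supporting"),
    EvidenceCode("PM2", "pathogenic", "indeterminate"),
    EvidenceCode("PM2", "pathogenic", "supporting"),
    None,
]
COMPUTATIONAL_OPTIONS = [
    None,
    EvidenceCode("PP3", "pathogenic", "supporting"),
    EvidenceCode("BP4", "benign", "supporting"),
]
SPLICING_OPTIONS = [
    (),
    (EvidenceCode("PS1_splicing", "pathogenic", "moderate"),),
    (EvidenceCode("PVS1_RNA", "pathogenic", "strong"),),
    (EvidenceCode("PVS1_RNA", "pathogenic", "very_strong"),),
]


def test_point_and_qualitative_systems_never_flatly_contradict():
    """Exhaustive scan over all implementable code bundles: no bundle is
    fully pathogenic in one system and fully benign in the other, and any
    bundle on which the systems land on opposite sides at the "likely"
    level (possible for extreme discordant evidence, e.g. a very-strong
    RNA-assay code alongside two benign-supporting codes) is resolved to
    uncertain by the concordance requirement."""
    path_side = {"pathogenic", "likely_pathogenic"}
    benign_side = {"benign", "likely_benign"}
    n_checked = 0
    for func, pop, comp, splice in itertools.product(
        FUNCTIONAL_OPTIONS, POPULATION_OPTIONS, COMPUTATIONAL_OPTIONS, SPLICING_OPTIONS
    ):
        codes = [c for c in (func, pop, comp, *splice) if c is not None]
        _, point_class = combine_points(codes)
        qual_class = combine_qualitative(codes)
        assert not (point_class == "pathogenic" and qual_class == "benign"), codes
        assert not (point_class == "benign" and qual_class == "pathogenic"), codes
        crossed = (point_class in path_side and qual_class in benign_side) or (
            point_class in benign_side and qual_class in path_side
        )
        if crossed:
            # Disagreeing systems never produce a reportable call.
            assert point_class != qual_class
        n_checked += 1
    assert n_checked == len(FUNCTIONAL_OPTIONS) * 6 * 3 * 4


def test_adding_benign_supporting_decrements_points_and_never_helps_pathogenic():
    rank = {cls: i for i, cls in enumerate(CLASSES)}
    for func, pop in itertools.product(FUNCTIONAL_OPTIONS, POPULATION_OPTIONS):
        codes = [c for c in (func, pop) if c is not None]
        total, cls = combine_points(codes)
        total2, cls2 = combine_points(codes + [EvidenceCode("BP4", "benign", "supporting")])
        assert total2 == total - 1
        assert rank[cls2] <= rank[cls]


def test_annotation_table_round_trip(tmp_path):
    annotations = [
        ann(variant_id="c.5A>G", faf_max=0.0005, bayesdel_noaf=0.1, spliceai_delta=0.05),
        ann(
            variant_id="c.67G>C",
            role="query",
            maf_max=1e-5,
            asserted_codes=(("PVS1_RNA", "strong"),),
        ),
        ann(variant_id="c.9T>A", role="control_pathogenic", prior_classification="pathogenic"),
    ]
    path = tmp_path / "annotations.tsv"
    write_annotation_table(annotations, path)
    assert read_annotation_table(path) == annotations
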