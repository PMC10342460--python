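import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bariscore.association import AssociationResult
from bariscore.errors import EmptyRiskScoreError, InvalidArgumentError, UnknownSNPError
from bariscore.genotypes import GenotypeMatrix
from bariscore.manifest import SNPManifest, SNPVariant
from bariscore.panel import reference_risk_definition
from bariscore.risk_score import (
    RiskScoreDefinition,
    RiskScoreEntry,
    build_rs_definition,
    categorize_scores,
    score_patients,
)

ALT_RISK = {0: 0, 1: 1, 2: 2}
REF_RISK = {0: 2, 1: 1, 2: 0}


def result(rsid, phenotype, significant=True, qc=True, points=ALT_RISK, allele="G"):
    r = AssociationResult(rsid=rsid, gene="X", phenotype=phenotype,
                          significant=significant, qc_pass=qc)
    if significant and qc:
        r.risk_allele = allele
        r.risk_points = points
    return r


def matrix(dosages: dict[str, list[int]]):
    rsids = list(dosages)
    manifest = SNPManifest([SNPVariant("G", r, "A", "G", 0.3) for r in rsids])
    arr = np.array([dosages[r] for r in rsids]).T
    ids = [f"p{i}" for i in range(arr.shape[0])]
    return GenotypeMatrix(patient_ids=ids, manifest=manifest, dosage=arr)


class TestBuildDefinition:
    def test_collects_significant_qc_passing_entries(self):
        results = [
            result("rs1", "twl_6y"),
            result("rs2", "twl_6y", points=REF_RISK, allele="A"),
            result("rs3", "twl_6y", significant=False),
            result("rs4", "twl_6y", qc=False),
            result("rs5", "wr_mwl"),
        ]
        rs_def = build_rs_definition(results, "twl_6y")
        assert rs_def.rsids == ["rs1", "rs2"]
        assert rs_def.max_score == 4

    def test_no_significant_snps_refused(self):
        with pytest.raises(EmptyRiskScoreError):
            build_rs_definition([result("rs1", "twl_6y", significant=False)], "twl_6y")

    def test_reference_definitions_max_scores(self):
        assert reference_risk_definition("twl_6y").max_score == 12
        assert len(reference_risk_definition("twl_6y").entries) == 6
        assert reference_risk_definition("twl_nadir").max_score == 6
        assert len(reference_risk_definition("twl_nadir").entries) == 3
        # three regain SNPs under the 2-points-per-SNP rule
        assert reference_risk_definition("wr_mwl").max_score == 6

    def test_points_validation(self):
        with pytest.raises(InvalidArgumentError):
            RiskScoreEntry(rsid="rs1", risk_allele="G", points={0: 0, 1: 1})
        with pytest.raises(InvalidArgumentError):
            RiskScoreEntry(rsid="rs1", risk_allele="G", points={0: 0, 1: 1, 2: 3})


class TestScoring:
    def test_risk_homozygote_everywhere_hits_max(self):
        rs_def = reference_risk_definition("twl_6y")
        manifest = SNPManifest.default()
        dosage = np.zeros((1, 48), dtype=np.int8)
        for entry in rs_def.entries:
            j = manifest.rsids.index(entry.rsid)
            dosage[0, j] = max(entry.points, key=entry.points.get)
        g = GenotypeMatrix(patient_ids=["p0"], manifest=manifest, dosage=dosage)
        assert score_patients(g, rs_def).loc["p0", "score"] == 12

    def test_no_risk_alleles_scores_zero(self):
        g = matrix({"rs1": [0, 0], "rs2": [0, 0]})
        rs_def = RiskScoreDefinition(
            "x",
            [RiskScoreEntry("rs1", "G", ALT_RISK), RiskScoreEntry("rs2", "G", ALT_RISK)],
        )
        assert (score_patients(g, rs_def)["score"] == 0).all()

    def test_single_heterozygote_scores_one(self):
        g = matrix({"rs1": [1], "rs2": [0]})
        rs_def = RiskScoreDefinition(
            "x",
            [RiskScoreEntry("rs1", "G", ALT_RISK), RiskScoreEntry("rs2", "G", ALT_RISK)],
        )
        assert score_patients(g, rs_def).loc["p0", "score"] == 1

    def test_reference_risk_allele_orientation(self):
        # when the reference allele is the risk allele, ref-hom scores 2
        g = matrix({"rs1": [0, 1, 2]})
        rs_def = RiskScoreDefinition("x", [RiskScoreEntry("rs1", "A", REF_RISK)])
        assert list(score_patients(g, rs_def)["score"]) == [2, 1, 0]

    def test_missing_contributes_zero_and_is_counted(self):
        g = matrix({"rs1": [-1, 2]})
        rs_def = RiskScoreDefinition("x", [RiskScoreEntry("rs1", "G", ALT_RISK)])
        scores = score_patients(g, rs_def)
        assert scores.loc["p0", "score"] == 0 and scores.loc["p0", "n_missing"] == 1
        assert scores.loc["p1", "score"] == 2

    def test_exclude_policy_masks_score(self):
        g = matrix({"rs1": [-1, 2]})
        rs_def = RiskScoreDefinition("x", [RiskScoreEntry("rs1", "G", ALT_RISK)])
        scores = score_patients(g, rs_def, missing_policy="exclude")
        assert pd.isna(scores.loc["p0", "score"])

    def test_unknown_rsid_raises(self):
        g = matrix({"rs1": [0]})
        rs_def = RiskScoreDefinition("x", [RiskScoreEntry("rs9", "G", ALT_RISK)])
        with pytest.raises(UnknownSNPError):
            score_patients(g, rs_def)

    @given(
        dosages=st.lists(
            st.tuples(*(st.sampled_from([0, 1, 2]) for _ in range(4))),
            min_size=1, max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_additivity_and_bounds(self, dosages):
        arr = {f"rs{j}": [d[j] for d in dosages] for j in range(4)}
        g = matrix(arr)
        entries = [RiskScoreEntry(f"rs{j}", "G", ALT_RISK) for j in range(4)]
        whole = RiskScoreDefinition("x", entries)
        part_a = RiskScoreDefinition("x", entries[:2])
        part_b = RiskScoreDefinition("x", entries[2:])
        s_all = score_patients(g, whole)["score"]
        s_a = score_patients(g, part_a)["score"]
        s_b = score_patients(g, part_b)["score"]
        assert (s_all == s_a + s_b).all()  # additive over disjoint entry sets
        assert (s_all >= 0).all() and (s_all <= whole.max_score).all()

    def test_entry_order_invariance(self):
        g = matrix({"rs1": [1, 2], "rs2": [2, 0]})
        e1 = RiskScoreEntry("rs1", "G", ALT_RISK)
        e2 = RiskScoreEntry("rs2", "G", ALT_RISK)
        a = score_patients(g, RiskScoreDefinition("x", [e1, e2]))["score"]
        b = score_patients(g, RiskScoreDefinition("x", [e2, e1]))["score"]
        assert (a == b).all()


class TestCategorization:
    def test_linear_interpolation_percentile_example(self):
        cats = categorize_scores([4, 4, 5, 5, 6, 6, 7, 8])
        assert cats.cutoff == pytest.approx(6.25)
        high = set(np.array([4, 4, 5, 5, 6, 6, 7, 8])[cats.categories == "high"])
        assert high == {7, 8}
        assert cats.realized_threshold == 7

    def test_all_equal_scores_warns_and_all_low(self):
        with pytest.warns(UserWarning):
            cats = categorize_scores([3, 3, 3])
        assert (cats.categories == "low").all()
        assert cats.realized_threshold is None

    def test_high_class_never_contains_cutoff(self):
        scores = np.random.default_rng(0).integers(0, 13, 200)
        cats = categorize_scores(scores)
        assert (scores[cats.categories == "high"] > cats.cutoff).all()
        assert (scores[cats.categories == "low"] <= cats.cutoff).all()

    def test_permutation_invariance_of_cutoff(self):
        scores = [0, 2, 5, 7, 9, 9, 11, 3, 4]
        a = categorize_scores(scores)
        b = categorize_scores(scores[::-1])
        assert a.cutoff == b.cutoff and a.realized_threshold == b.realized_threshold

    def test_p75_between_6_and_7_realizes_threshold_7(self):
        # distribution whose P75 lies in [6, 7): high class begins at 7 points
        scores = [2, 3, 4, 4, 5, 5, 6, 6, 6, 7, 8, 9]
        cats = categorize_scores(scores)
        assert 6 <= cats.cutoff < 7
        assert cats.realized_threshold == 7

    def test_json_round_trip(self, tmp_path):
        rs_def = reference_risk_definition("wr_mwl")
        path = tmp_path / "def.json"
        rs_def.to_json(path)
        back = RiskScoreDefinition.from_json(path)
        assert back.phenotype == rs_def.phenotype
        assert back.max_score == rs_def.max_score
        assert [e.rsid for e in back.entries] == [e.rsid for e in rs_def.entries]
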