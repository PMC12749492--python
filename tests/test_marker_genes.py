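import numpy as np
import pandas as pd
import pytest

from forelandeco import marker_genes as mg
from forelandeco import synthetic_data as sd


def make_hit(query="r1", family="sqr", identity=60.0, length=50,
             qcov=90.0, scov=10.0, bitscore=100.0) -> dict:
    return {"query_id": query, "family": family, "pct_identity": identity,
            "alignment_length_aa": length, "mismatches": 0,
            "gap_openings": 0, "q_start": 1, "q_end": 33, "s_start": 1,
            "s_end": 33, "evalue": 1e-10, "bitscore": bitscore,
            "query_cov_pct": qcov, "subject_cov_pct": scov}


@pytest.fixture
def manifest() -> pd.DataFrame:
    return mg.default_manifest()


class TestReadFiltering:
    @pytest.mark.parametrize("family,identity,kept", [
        ("rho", 42.0, True),     # rho threshold is relaxed to 40%
        ("sqr", 42.0, False),    # generic families need 50%
        ("sqr", 55.0, True),
        ("psaA", 75.0, False),   # psaA is tightened to 80%
        ("psaA", 85.0, True),
        ("hbsT", 74.0, False),   # hbsT 75%
        ("coxL", 61.0, True),    # coxL 60%
    ])
    def test_family_identity_thresholds(self, manifest, family, identity,
                                        kept):
        hits = pd.DataFrame([make_hit(family=family, identity=identity)])
        out = mg.filter_read_hits(hits, manifest)
        assert (len(out) == 1) is kept

    def test_query_coverage_floor(self, manifest):
        hits = pd.DataFrame([make_hit(identity=90.0, qcov=79.0)])
        assert mg.filter_read_hits(hits, manifest).empty

    def test_best_hit_per_read_by_bitscore(self, manifest):
        hits = pd.DataFrame([
            make_hit(query="r1", family="sqr", bitscore=80.0),
            make_hit(query="r1", family="coxL", identity=90.0,
                     bitscore=120.0),
        ])
        out = mg.filter_read_hits(hits, manifest)
        assert out["family"].tolist() == ["coxL"]

    def test_unknown_family_lists_offender(self, manifest):
        hits = pd.DataFrame([make_hit(family="madeUp")])
        with pytest.raises(KeyError, match="madeUp"):
            mg.filter_read_hits(hits, manifest)

    def test_filtering_idempotent(self, manifest):
        hits = pd.DataFrame([make_hit(query=f"r{i}",
                                      identity=40.0 + i * 5.0)
                             for i in range(10)])
        once = mg.filter_read_hits(hits, manifest)
        twice = mg.filter_read_hits(once, manifest)
        pd.testing.assert_frame_equal(once, twice)


class TestMagFiltering:
    def test_short_alignment_with_subject_coverage(self, manifest):
        hits = pd.DataFrame([make_hit(length=35, qcov=20.0, scov=85.0,
                                      identity=70.0)])
        assert len(mg.filter_mag_hits(hits, manifest)) == 1

    def test_cyc2_relaxed_threshold(self, manifest):
        hits = pd.DataFrame([make_hit(family="cyc2", identity=36.0,
                                      length=50, qcov=20.0, scov=20.0)])
        assert len(mg.filter_mag_hits(hits, manifest)) == 1

    def test_all_disjuncts_fail(self, manifest):
        hits = pd.DataFrame([make_hit(length=30, qcov=50.0, scov=50.0,
                                      identity=99.0)])
        assert mg.filter_mag_hits(hits, manifest).empty

    @pytest.mark.parametrize("family,identity,kept", [
        ("atpA", 62.0, True), ("atpA", 58.0, False),
        ("rdhA", 46.0, True), ("rho", 31.0, True), ("rho", 29.0, False),
    ])
    def test_mag_identity_overrides(self, manifest, family, identity, kept):
        hits = pd.DataFrame([make_hit(family=family, identity=identity,
                                      length=50)])
        assert (len(mg.filter_mag_hits(hits, manifest)) == 1) is kept


class TestRpkm:
    def test_worked_value(self):
        # 30 hits over a 500 aa (1.5 kb) reference in 2 million reads
        assert mg.rpkm(30, 500.0, 2_000_000) == pytest.approx(10.0)

    def test_zero_hits(self):
        assert mg.rpkm(0, 500.0, 1_000_000) == 0.0

    def test_depth_proportionality(self):
        assert mg.rpkm(30, 500.0, 4_000_000) == \
            pytest.approx(mg.rpkm(30, 500.0, 2_000_000) / 2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            mg.rpkm(1, 0.0, 1000)


class TestCopiesPerOrganism:
    def _profile(self, fam_rpkm: float, ribo_rpkm: float) -> pd.DataFrame:
        return pd.DataFrame({
            "filtered_hit_count": [1, 1],
            "rpkm": [fam_rpkm, ribo_rpkm],
            "is_single_copy_ribosomal": [False, True],
        }, index=["fam", "ribo"])

    def test_equal_to_ribosomal_mean_is_one_copy(self):
        out = mg.copies_per_organism(self._profile(40.0, 40.0))
        assert out.loc["fam", "copies_per_organism"] == pytest.approx(1.0)
        assert out.loc["fam", "percent_of_cells"] == pytest.approx(100.0)

    def test_quarter_copy(self):
        out = mg.copies_per_organism(self._profile(10.0, 40.0))
        assert out.loc["fam", "copies_per_organism"] == pytest.approx(0.25)

    def test_multicopy_uncapped_and_flagged(self):
        out = mg.copies_per_organism(self._profile(120.0, 40.0))
        assert out.loc["fam", "percent_of_cells"] == pytest.approx(300.0)
        assert bool(out.loc["fam", "multicopy_flag"])

    def test_zero_ribosomal_rejected(self):
        with pytest.raises(ValueError, match="ribosomal"):
            mg.copies_per_organism(self._profile(10.0, 0.0))


class TestSyntheticProfiles:
    """Generator-truth checks: planted carrier fractions are recovered."""

    def _community(self, seed=1):
        design = sd.swiss_design(seed=seed)
        truths = sd.default_truths()
        return sd.generate_community(design, truths, 100_000)

    def test_saturated_and_absent_families(self, manifest):
        matrix, registry = self._community()
        # plant hhyL in every taxon and mmoX in none
        for info in registry["taxa"].values():
            info["marker_genes"] = sorted(
                (set(info["marker_genes"]) | {"hhyL"}) - {"mmoX"})
        hits = sd.generate_marker_hits(matrix, registry, manifest,
                                       reads_total=1_000_000, seed=5)
        filtered = mg.filter_read_hits(hits, manifest)
        profile = mg.copies_per_organism(
            mg.gene_profile(filtered, manifest, 1_000_000))
        assert profile.loc["hhyL", "copies_per_organism"] == \
            pytest.approx(1.0, rel=0.1)
        assert profile.loc["mmoX", "copies_per_organism"] == 0.0

    def test_planted_failures_removed_exactly(self, manifest):
        matrix, registry = self._community()
        hits = sd.generate_marker_hits(matrix, registry, manifest,
                                       reads_total=200_000,
                                       fail_fraction=0.2, seed=6)
        filtered = mg.filter_read_hits(hits, manifest)
        thr = manifest["min_identity_pct"]
        # every removed row violates its family threshold; every retained
        # row satisfies it
        removed = hits.loc[~hits["query_id"].isin(filtered["query_id"])]
        assert (removed["pct_identity"].to_numpy()
                < thr.reindex(removed["family"]).to_numpy()).all()
        assert (filtered["pct_identity"].to_numpy()
                >= thr.reindex(filtered["family"]).to_numpy()).all()

    def test_depth_invariance_of_copies(self, manifest):
        matrix, registry = self._community()
        hits = sd.generate_marker_hits(matrix, registry, manifest,
                                       reads_total=500_000, seed=7)
        filtered = mg.filter_read_hits(hits, manifest)
        p1 = mg.copies_per_organism(
            mg.gene_profile(filtered, manifest, 500_000))
        p2 = mg.copies_per_organism(
            mg.gene_profile(filtered, manifest, 5_000_000))
        pd.testing.assert_series_equal(p1["copies_per_organism"],
                                       p2["copies_per_organism"])


class TestMagSummary:
    def test_completeness_correction(self):
        ann = mg.MagAnnotation("m1", 50.0, 2.0,
                               frozenset({"a", "b", "c", "d", "e", "f"}))
        assert ann.signature_gene_count_corrected == pytest.approx(12.0)
        full = mg.MagAnnotation("m2", 100.0, 0.0, frozenset({"a"}))
        assert full.signature_gene_count_corrected == \
            full.signature_gene_count_raw

    def test_class_means_ordered_by_planted_content(self):
        rng = np.random.default_rng(0)
        anns, rows = [], []
        fams = [f"f{i}" for i in range(12)]
        for i in range(20):
            generalist = i < 10
            n_genes = 10 if generalist else 5
            anns.append(mg.MagAnnotation(
                f"mag{i}", float(rng.uniform(60, 100)), 1.0,
                frozenset(fams[:n_genes])))
            rows.append({"mag_id": f"mag{i}",
                         "habitat_class":
                             "generalist" if generalist else "specialist"})
        spec_table = pd.DataFrame(rows).set_index("mag_id")
        summary = mg.mag_signature_summary(anns, spec_table)
        assert summary.loc["generalist", "corrected"] > \
            summary.loc["specialist", "corrected"]

    def test_unmatched_ids_warn(self):
        anns = [mg.MagAnnotation("mag1", 90.0, 1.0, frozenset({"a"}))]
        spec_table = pd.DataFrame({"habitat_class": ["generalist"]},
                                  index=["other"])
        with pytest.warns(UserWarning, match="unmatched"):
            mg.mag_signature_summary(anns, spec_table)
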