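"""Variant calling thresholds, diagnostic classification, linkage assignment."""

import numpy as np
import pandas as pd
import pytest

from homeosort import snp
from homeosort._seq import encode
from homeosort.seqmap import Hit, KmerIndex
from homeosort.simulate import SimConfig, simulate_experiment, split_transcript_id
from homeosort.snp import MappedRead


def mk_pileup(ref, reads):
    """reads: list of (start, bases str) placed on a single gene 'g'."""
    arr = np.zeros((4, len(ref)), dtype=np.int32)
    for start, bases in reads:
        for i, b in enumerate(bases):
            arr["ACGT".index(b), start + i] += 1
    return {"g": arr}, {"g": encode(ref)}


class TestPileup:
    def test_empty(self):
        assert snp.pileup([], {"g": encode("ACGT" * 10)}) == {}

    def test_single_read_counted_once(self):
        ref = encode("ACGTACGTACGT")
        mr = MappedRead(0, ref[2:10].copy(), Hit("g", 2, "+", 0))
        piles = snp.pileup([mr], {"g": ref})
        assert piles["g"].sum() == 8
        cov = piles["g"].sum(axis=0)
        assert list(np.flatnonzero(cov)) == list(range(2, 10))

    def test_out_of_bounds_rejected(self):
        ref = encode("ACGTACGT")
        mr = MappedRead(0, ref[:6].copy(), Hit("g", 4, "+", 0))
        with pytest.raises(ValueError, match="bounds"):
            snp.pileup([mr], {"g": ref})

    def test_totals_match_interval_overlap_oracle(self, rng):
        ref = rng.integers(0, 4, 200).astype(np.uint8)
        mapped = []
        starts = rng.integers(0, 150, 50)
        for i, s in enumerate(starts):
            mapped.append(MappedRead(i, ref[s : s + 50].copy(), Hit("g", int(s), "+", 0)))
        piles = snp.pileup(mapped, {"g": ref})
        cov = piles["g"].sum(axis=0)
        oracle = np.zeros(200, int)
        for s in starts:
            oracle[s : s + 50] += 1
        assert np.array_equal(cov, oracle)


class TestCalling:
    def test_parent_below_coverage_no_call(self):
        piles, ref = mk_pileup("AAAA", [(0, "CCCC")] * 4)
        assert len(snp.call_parent_variants(piles, ref, min_cov=5)) == 0

    def test_parent_fixed_alt_called(self):
        piles, ref = mk_pileup("AAAA", [(0, "CAAA")] * 10)
        calls = snp.call_parent_variants(piles, ref)
        assert len(calls) == 1
        assert calls.iloc[0][["position", "ref", "alt", "alt_count"]].tolist() == [0, "A", "C", 10]

    def test_parent_tie_no_call(self):
        piles, ref = mk_pileup("AAAA", [(0, "C")] * 5 + [(0, "G")] * 5)
        assert len(snp.call_parent_variants(piles, ref)) == 0

    def test_allo_minor_fraction_thresholds(self):
        piles, ref = mk_pileup("A" * 100, [(0, "C")] * 2 + [(0, "A")] * 98)
        assert len(snp.call_allo_variants(piles, ref, min_alt_reads=3)) == 0
        piles, ref = mk_pileup("A" * 100, [(0, "C")] * 30 + [(0, "A")] * 70)
        calls = snp.call_allo_variants(piles, ref)
        assert len(calls) == 1 and calls.iloc[0]["alt"] == "C"


def classify_sets(p1, p2, allo):
    def df(keys):
        return pd.DataFrame(
            [(g, p, "A", a, 10, 10) for g, p, a in keys],
            columns=["gene_id", "position", "ref", "alt", "ref_count", "alt_count"],
        )

    return snp.classify_snps(df(p1), df(p2), df(allo))


class TestClassification:
    def test_examples(self):
        v = ("g", 5, "C")
        assert classify_sets([v], [v], [v])["cls"].iloc[0] == "ancestral"
        assert classify_sets([], [v], [v])["cls"].iloc[0] == "p2_shared"
        assert classify_sets([v], [], [])["cls"].iloc[0] == "p1_unique"
        assert classify_sets([v], [v], [])["cls"].iloc[0] == "parent_shared_residual"
        assert classify_sets([], [], [v])["cls"].iloc[0] == "allo_unclassified"
        assert len(classify_sets([], [], [])) == 0

    def test_multiallelic_excluded(self):
        out = classify_sets([("g", 5, "C")], [("g", 5, "G")], [])
        assert (out["cls"] == "multiallelic").all()

    def test_partition_property(self, rng):
        keys = [(f"g{rng.integers(3)}", int(p), "ACGT"[rng.integers(4)]) for p in rng.integers(0, 50, 40)]
        keys = list(set(keys))
        member = rng.random((len(keys), 3)) < 0.5
        p1 = [k for k, m in zip(keys, member) if m[0]]
        p2 = [k for k, m in zip(keys, member) if m[1]]
        allo = [k for k, m in zip(keys, member) if m[2]]
        out = classify_sets(p1, p2, allo)
        got = set(zip(out["gene_id"], out["position"], out["alt"]))
        expected = {k for k, m in zip(keys, member) if m.any()}
        assert got == expected
        assert not out.duplicated(subset=["gene_id", "position", "alt"]).any()

    def test_swap_symmetry(self, rng):
        keys = [("g", int(p), "C") for p in range(20)]
        member = rng.random((20, 3)) < 0.6
        p1 = [k for k, m in zip(keys, member) if m[0]]
        p2 = [k for k, m in zip(keys, member) if m[1]]
        allo = [k for k, m in zip(keys, member) if m[2]]
        a = classify_sets(p1, p2, allo).set_index("position")["cls"]
        b = classify_sets(p2, p1, allo).set_index("position")["cls"]
        swap = {
            "p1_unique": "p2_unique",
            "p2_unique": "p1_unique",
            "p1_shared": "p2_shared",
            "p2_shared": "p1_shared",
        }
        assert (b == a.map(lambda c: swap.get(c, c))).all()

    def test_class_counts_hand_tally(self):
        df = pd.DataFrame(
            {
                "gene_id": ["g"] * 6,
                "position": range(6),
                "ref": "A",
                "alt": "C",
                "cls": ["ancestral", "p1_shared", "p2_shared", "allo_p1", "allo_p2", "allo_unclassified"],
            }
        )
        cc = snp.class_counts(df)
        assert cc["ancestral"] == 1 and cc["p1_shared"] == 1
        assert cc["allo_unique"] == 3 == cc["allo_p1"] + cc["allo_p2"] + cc["allo_unclassified"]

    def test_class_counts_empty(self):
        cc = snp.class_counts(pd.DataFrame(columns=["gene_id", "position", "ref", "alt", "cls"]))
        assert (cc[list(snp.CLASSES)] == 0).all()


def _ld_fixture(n_linking, conflict=0):
    """One gene, one p1_shared diagnostic site (pos 10, alt C), one
    unclassified allo SNP (pos 30, alt G)."""
    ref = encode("A" * 60)
    classified = pd.DataFrame(
        {
            "gene_id": ["g", "g"],
            "position": [10, 30],
            "ref": ["A", "A"],
            "alt": ["C", "G"],
            "cls": ["p1_shared", "allo_unclassified"],
        }
    )
    reads = []
    for i in range(n_linking):
        bases = ref[0:50].copy()
        bases[30] = 2  # G: the unclassified alt
        bases[10] = 1 if i >= conflict else 0  # C (p1 allele) or ref A (p2 evidence)
        reads.append(MappedRead(i, bases, Hit("g", 0, "+", 0)))
    return reads, classified


class TestLdAssignment:
    def test_five_consistent_links_assign_p1(self):
        reads, classified = _ld_fixture(5)
        out = snp.assign_allo_unique_by_ld(reads, classified)
        assert out.loc[out["position"] == 30, "cls"].iloc[0] == "allo_p1"

    def test_two_links_below_minimum(self):
        reads, classified = _ld_fixture(2)
        out = snp.assign_allo_unique_by_ld(reads, classified)
        assert out.loc[out["position"] == 30, "cls"].iloc[0] == "allo_unclassified"

    def test_conflicting_links_not_assigned(self):
        reads, classified = _ld_fixture(6, conflict=3)  # 3 votes each way
        out = snp.assign_allo_unique_by_ld(reads, classified)
        assert out.loc[out["position"] == 30, "cls"].iloc[0] == "allo_unclassified"

    def test_reference_allele_at_p1_site_votes_p2(self):
        reads, classified = _ld_fixture(5, conflict=5)  # all carry ref at the p1 site
        out = snp.assign_allo_unique_by_ld(reads, classified)
        assert out.loc[out["position"] == 30, "cls"].iloc[0] == "allo_p2"


class TestMarkerAncestry:
    def _sites(self):
        return pd.DataFrame(
            {
                "marker": ["m"] * 3,
                "gene_id": ["g"] * 3,
                "position": [0, 1, 2],
                "p1_base": ["C", "C", "C"],
                "p2_base": ["G", "G", "G"],
            }
        )

    def test_sole_p1(self):
        piles, _ = mk_pileup("AAA", [(0, "CCC")] * 4)
        out = snp.marker_ancestry(piles, self._sites())
        assert out.iloc[0]["verdict"] == "sole-P1"

    def test_mixed(self):
        piles, _ = mk_pileup("AAA", [(0, "CCC")] * 3 + [(0, "GGG")] * 3)
        assert snp.marker_ancestry(piles, self._sites()).iloc[0]["verdict"] == "mixed"

    def test_insufficient(self):
        piles, _ = mk_pileup("AAA", [(0, "CCC")] * 1)
        assert snp.marker_ancestry(piles, self._sites()).iloc[0]["verdict"] == "insufficient"


class TestVcfRoundTrip:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "position": [0, 9, 4],
                "ref": ["A", "C", "G"],
                "alt": ["G", "T", "A"],
                "cls": ["ancestral", "p2_shared", "allo_p1"],
            }
        )
        path = tmp_path / "x.vcf"
        snp.write_vcf(df, {"g1": 20, "g2": 20}, path)
        back = snp.read_vcf(path)
        pd.testing.assert_frame_equal(
            back.sort_values(["gene_id", "position"]).reset_index(drop=True),
            df.sort_values(["gene_id", "position"]).reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# simulation-truth oracles

@pytest.fixture(scope="module")
def deep_discovery():
    """Small deep-coverage experiment with discovery stage artifacts."""
    from homeosort.pipeline import Thresholds, discover_snps

    cfg = SimConfig(
        n_genes=30,
        library_sizes=(8_000, 8_000, 20_000),
        n_replicates=1,
        error_rate=0.001,
        n_deletion_clusters=1,
        deletion_cluster_size=2,
        seed=13,
    )
    sim = simulate_experiment(cfg)
    th = Thresholds()
    classified, mapped_allo = discover_snps(sim, th)
    return sim, classified, mapped_allo


def _allo_truth_variants(sim):
    """Truth variants present in the allopolyploid genomes (per subgenome)."""
    deleted = {
        (r["gene_id"], r["subgenome"]) for _, r in sim.truth.deletions.iterrows()
    }
    v = sim.truth.variants
    side = v["lineage"].map(
        {
            "ancestral": "both",
            "p1_branch": "P1",
            "p2_branch": "P2",
            "allo_p1_branch": "P1",
            "allo_p2_branch": "P2",
        }
    )
    keep = []
    for (_, row), s in zip(v.iterrows(), side):
        sides = ("P1", "P2") if s == "both" else (s,)
        if any((row["gene_id"], sd) not in deleted for sd in sides):
            keep.append(True)
        else:
            keep.append(False)
    return v[np.array(keep)]


class TestSimulationTruth:
    def test_allo_call_recall_precision(self, deep_discovery):
        """Deep-coverage allopolyploid calling recovers truth variants."""
        sim, classified, _ = deep_discovery
        expr = sim.truth.expression.set_index("gene_id")
        tot = expr[["expr_allo_p1", "expr_allo_p2"]].sum().sum()
        n_frags = sim.config.library_sizes[2]
        # genes where each expressed homeolog expects >=30x site coverage
        deep = []
        for g, row in expr.iterrows():
            shares = [row["expr_allo_p1"], row["expr_allo_p2"]]
            covs = [
                s / tot * n_frags * 2 * sim.config.read_length / sim.genes.length(g)
                for s in shares
                if s > 0
            ]
            if covs and min(covs) >= 30:
                deep.append(g)
        truth = _allo_truth_variants(sim)
        truth = truth[truth["gene_id"].isin(deep)]
        truth_keys = set(zip(truth["gene_id"], truth["position"], truth["alt"]))
        called = classified[
            classified["cls"].isin(
                ("ancestral", "p1_shared", "p2_shared", "allo_p1", "allo_p2", "allo_unclassified")
            )
            & classified["gene_id"].isin(deep)
        ]
        called_keys = set(zip(called["gene_id"], called["position"], called["alt"]))
        recall = len(truth_keys & called_keys) / len(truth_keys)
        precision = len(truth_keys & called_keys) / len(called_keys)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_diagnostic_classes_match_lineage_truth(self, deep_discovery):
        """Shared/ancestral class labels agree with the simulated branches."""
        sim, classified, _ = deep_discovery
        truth = sim.truth.variants.set_index(["gene_id", "position", "alt"])["lineage"]
        expected_of = {"ancestral": {"ancestral"}, "p1_shared": {"p1_branch"}, "p2_shared": {"p2_branch"}}
        checked = wrong = 0
        for _, r in classified.iterrows():
            if r["cls"] not in expected_of:
                continue
            lin = truth.get((r["gene_id"], r["position"], r["alt"]))
            if lin is None:
                wrong += 1
            elif lin not in expected_of[r["cls"]]:
                wrong += 1
            checked += 1
        assert checked > 100
        assert wrong / checked < 0.01

    def test_ld_assignment_correct_and_sensitive(self, deep_discovery):
        """Allo-branch variants get the right subgenome; none the wrong one."""
        sim, classified, _ = deep_discovery
        truth = sim.truth.variants.set_index(["gene_id", "position", "alt"])["lineage"]
        assigned = classified[classified["cls"].isin(("allo_p1", "allo_p2"))]
        for _, r in assigned.iterrows():
            lin = truth.get((r["gene_id"], r["position"], r["alt"]))
            if lin is None:
                continue  # detection artifact, checked elsewhere
            want = "P1" if lin in ("allo_p1_branch", "p1_branch") else "P2"
            got = "P1" if r["cls"] == "allo_p1" else "P2"
            assert got == want, f"misassigned {r['gene_id']}:{r['position']}"
        # sensitivity: detected allo-branch variants mostly get assigned
        allo_truth = sim.truth.variants[
            sim.truth.variants["lineage"].isin(("allo_p1_branch", "allo_p2_branch"))
        ]
        det = classified.set_index(["gene_id", "position", "alt"])["cls"]
        statuses = [
            det.get((r["gene_id"], r["position"], r["alt"]))
            for _, r in allo_truth.iterrows()
        ]
        detected = [s for s in statuses if s in ("allo_p1", "allo_p2", "allo_unclassified")]
        if len(detected) >= 10:
            frac = sum(s != "allo_unclassified" for s in detected) / len(detected)
            assert frac >= 0.9
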