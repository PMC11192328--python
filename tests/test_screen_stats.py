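"""Phenotype computation, gene scoring and hit calling."""

import numpy as np
import pandas as pd
import pytest

from invascreen import (
    CountMatrix,
    HitCall,
    LibraryTable,
    average_replicates,
    call_hits,
    compute_phenotypes,
    gene_scores,
    pseudo_gene_scores,
    volcano_table,
)
from invascreen.screen_stats import GENE_SCORE_COLUMNS, ScreenError


def _cm(library, t0, end, replicate=1):
    return CountMatrix(
        pd.DataFrame(
            {f"T0_r{replicate}": t0, f"endpoint_r{replicate}": end},
            index=pd.Index(library.sgrna_ids, name="sgrna_id"),
        )
    )


class TestComputePhenotypes:
    def test_identical_columns_give_zero_phenotypes(self, toy_library):
        t0 = np.arange(100, 100 + len(toy_library))
        cm = _cm(toy_library, t0, t0)
        phen = compute_phenotypes(cm, toy_library)
        assert np.allclose(phen.table["phenotype_mean"], 0.0)

    def test_depth_invariance(self, toy_library):
        rng = np.random.default_rng(5)
        t0 = rng.integers(200, 2000, len(toy_library))
        end = rng.integers(200, 2000, len(toy_library))
        base = compute_phenotypes(_cm(toy_library, t0, end), toy_library)
        scaled = compute_phenotypes(_cm(toy_library, t0, end * 7), toy_library)
        # note: rescaling changes the pseudocount's weight only negligibly
        # at these counts; exact invariance holds for the rpm ratio itself
        assert np.allclose(
            base.table["phenotype_mean"], scaled.table["phenotype_mean"], atol=5e-3
        )

    def test_uniform_doubling_of_endpoint_gives_zero(self, toy_library):
        t0 = np.full(len(toy_library), 1000)
        phen = compute_phenotypes(_cm(toy_library, t0, 2 * t0), toy_library)
        assert np.allclose(phen.table["phenotype_mean"], 0.0, atol=1e-12)

    def test_known_rpm_ratio(self):
        # 4 NTCs at rpm ratio 1 and 2 targeting sgRNAs at rpm ratio 4:
        # phenotype of the targeting sgRNAs is log2(4) = 2 after NTC centering
        lib = LibraryTable(
            pd.DataFrame(
                {
                    "sgrna_id": ["g_sg1", "g_sg2", "n1", "n2", "n3", "n4"],
                    "gene_id": ["GENE", "GENE", "NTC", "NTC", "NTC", "NTC"],
                    "protospacer": ["ACGT", "CGTA", "GTAC", "TACG", "AAAA", "CCCC"],
                }
            )
        )
        t0 = np.array([100, 100, 100, 100, 100, 100])
        end = np.array([400, 400, 100, 100, 100, 100])
        # pseudocount tiny so the arithmetic is exact up to rpm renormalisation
        phen = compute_phenotypes(_cm(lib, t0, end), lib, pseudocount=1e-9)
        vals = phen.table["phenotype_mean"]
        assert vals.loc["g_sg1"] == pytest.approx(2.0, abs=1e-6)
        assert vals.loc["n1"] == pytest.approx(0.0, abs=1e-6)

    def test_ntc_median_zero_every_replicate(self, toy_counts, toy_library):
        for r in (1, 2):
            phen = compute_phenotypes(toy_counts, toy_library, replicate=r)
            ntc = phen.table.loc[phen.table["is_ntc"], f"phenotype_rep{r}"]
            assert abs(np.median(ntc)) < 1e-9

    def test_zero_sum_sample_rejected(self, toy_library):
        t0 = np.zeros(len(toy_library), dtype=int)
        end = np.ones(len(toy_library), dtype=int)
        with pytest.raises(ScreenError, match="zero total"):
            compute_phenotypes(_cm(toy_library, t0, end), toy_library)

    def test_nonpositive_pseudocount_rejected(self, toy_counts, toy_library):
        with pytest.raises(ScreenError, match="pseudocount"):
            compute_phenotypes(toy_counts, toy_library, pseudocount=0.0, replicate=1)


class TestAverageReplicates:
    def _phen(self, toy_counts, toy_library, r):
        return compute_phenotypes(toy_counts, toy_library, replicate=r)

    def test_mean_of_identical_tables(self, toy_counts, toy_library):
        p1 = self._phen(toy_counts, toy_library, 1)
        p2 = compute_phenotypes(
            CountMatrix(
                toy_counts.counts[["T0_r1", "endpoint_r1"]].rename(
                    columns={"T0_r1": "T0_r2", "endpoint_r1": "endpoint_r2"}
                )
            ),
            toy_library,
        )
        avg = average_replicates([p1, p2])
        assert np.allclose(avg.table["phenotype_mean"], p1.table["phenotype_mean"])

    def test_arithmetic_mean(self, toy_counts, toy_library):
        p1 = self._phen(toy_counts, toy_library, 1)
        p2 = self._phen(toy_counts, toy_library, 2)
        avg = average_replicates([p1, p2])
        expected = (p1.table["phenotype_rep1"] + p2.table["phenotype_rep2"]) / 2
        assert np.allclose(avg.table["phenotype_mean"], expected)

    def test_mismatched_sets_rejected(self, toy_counts, toy_library):
        p1 = self._phen(toy_counts, toy_library, 1)
        p2 = self._phen(toy_counts, toy_library, 2)
        object.__setattr__(p2, "table", p2.table.iloc[:-1])
        with pytest.raises(ScreenError, match="mismatched"):
            average_replicates([p1, p2])


def _phenotype_table(values, ntc_values):
    """Assemble a PhenotypeTable directly from phenotype values."""
    from invascreen.screen_stats import PhenotypeTable

    rows = {}
    for gene, vals in values.items():
        for j, v in enumerate(vals):
            rows[f"{gene}_sg{j+1:02d}"] = (False, v)
    for j, v in enumerate(ntc_values):
        rows[f"NTC_sg{j+1:03d}"] = (True, v)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["is_ntc", "phenotype_rep1"])
    df.index.name = "sgrna_id"
    df["phenotype_mean"] = df["phenotype_rep1"]
    return PhenotypeTable(table=df, replicates=(1,))


def _library_for(values, n_ntc):
    rng = np.random.default_rng(11)
    seen, rows = set(), []
    def spacer():
        while True:
            s = "".join(rng.choice(list("ACGT"), 20))
            if s not in seen:
                seen.add(s)
                return s
    for gene, vals in values.items():
        for j in range(len(vals)):
            rows.append((f"{gene}_sg{j+1:02d}", gene, spacer()))
    for j in range(n_ntc):
        rows.append((f"NTC_sg{j+1:03d}", "NTC", spacer()))
    return LibraryTable(pd.DataFrame(rows, columns=["sgrna_id", "gene_id", "protospacer"]))


class TestGeneScores:
    def test_null_gene_scores_near_zero(self):
        # a gene whose phenotypes are a subsample of the NTC values should
        # look null: across draws the typical p is large and scores small
        rng = np.random.default_rng(8)
        ntc = rng.standard_normal(247)
        ps, scores_abs = [], []
        for _ in range(20):
            sub = rng.choice(ntc, 10, replace=False)
            values = {"GENE1": sub}
            phen = _phenotype_table(values, ntc)
            lib = _library_for(values, 247)
            scores = gene_scores(phen, lib)
            ps.append(scores.loc["GENE1", "mw_p"])
            scores_abs.append(abs(scores.loc["GENE1", "screen_score"]))
        assert np.median(ps) > 0.2
        assert np.median(scores_abs) < 1.0

    def test_top3_rule(self):
        values = {"GENE1": [2.0, 2.0, 2.0, 0, 0, 0, 0, 0, 0, 0]}
        phen = _phenotype_table(values, np.zeros(20))
        lib = _library_for(values, 20)
        scores = gene_scores(phen, lib)
        assert scores.loc["GENE1", "avg_top3_phenotype"] == pytest.approx(2.0)
        assert scores.loc["GENE1", "screen_score"] > 0

    def test_screen_score_sign_and_zero_identities(self):
        rng = np.random.default_rng(9)
        values = {"UP": rng.normal(1.0, 0.05, 10), "DOWN": rng.normal(-1.0, 0.05, 10)}
        phen = _phenotype_table(values, rng.normal(0, 0.05, 50))
        scores = gene_scores(phen, _library_for(values, 50))
        assert scores.loc["UP", "screen_score"] > 0
        assert scores.loc["DOWN", "screen_score"] < 0
        # |avg_top3| never exceeds the gene's largest |phenotype|
        for gene, vals in values.items():
            assert abs(scores.loc[gene, "avg_top3_phenotype"]) <= np.abs(vals).max() + 1e-12

    def test_planted_gene_attains_max_score(self):
        rng = np.random.default_rng(10)
        values = {f"G{i:03d}": rng.normal(0, 0.1, 10) for i in range(30)}
        values["PLANTED"] = rng.normal(1.0, 0.1, 10)
        phen = _phenotype_table(values, rng.normal(0, 0.1, 247))
        scores = gene_scores(phen, _library_for(values, 247))
        assert scores["screen_score"].idxmax() == "PLANTED"

    def test_too_few_ntcs_rejected(self):
        values = {"GENE1": [0.0] * 10}
        phen = _phenotype_table(values, np.zeros(5))
        with pytest.raises(ScreenError, match="NTC"):
            gene_scores(phen, _library_for(values, 5))


class TestPseudoGenes:
    def _null_phen(self, n_ntc=100, sd=0.0):
        rng = np.random.default_rng(12)
        values = {"GENE1": rng.normal(0, max(sd, 1e-12), 10)}
        return _phenotype_table(values, rng.normal(0, sd, n_ntc) if sd else np.zeros(n_ntc))

    def test_all_zero_phenotypes_give_zero_scores(self):
        phen = self._null_phen(sd=0.0)
        pseudo = pseudo_gene_scores(phen, n_pseudo=20, seed=1)
        assert (pseudo["screen_score"] == 0).all()
        assert (pseudo["is_pseudo"]).all()

    def test_seed_reproducibility(self):
        phen = self._null_phen(sd=0.3)
        a = pseudo_gene_scores(phen, n_pseudo=25, seed=9)
        b = pseudo_gene_scores(phen, n_pseudo=25, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_n_pseudo(self):
        with pytest.raises(ScreenError):
            pseudo_gene_scores(self._null_phen(), n_pseudo=0, seed=1)


def _score_frame(rows):
    df = pd.DataFrame(
        rows, columns=["gene_id", "avg_top3_phenotype", "mw_p"]
    ).set_index("gene_id")
    df["n_sgrnas"] = 10
    df["screen_score"] = df["avg_top3_phenotype"] * -np.log10(df["mw_p"])
    df["hit"] = False
    df["is_pseudo"] = False
    return df[GENE_SCORE_COLUMNS]


class TestCallHits:
    def test_threshold_rule(self):
        scores = _score_frame(
            [("a", 0.8, 0.001), ("b", 0.8, 0.001), ("c", -0.8, 0.001),
             ("d", 0.9, 0.2), ("e", -0.9, 0.2), ("f", 0.1, 0.001)]
        )
        flagged, summary = call_hits(scores, pseudo=None,
                                     call=HitCall(0.05, 0.415))
        assert summary["n_hits"] == 3
        assert summary["n_hits_positive"] == 2
        assert summary["n_hits_negative"] == 1
        assert flagged.loc[["a", "b", "c"], "hit"].all()
        assert summary["empirical_fdr"] is None

    def test_fdr_unavailable_when_nothing_passes(self):
        scores = _score_frame([("a", 0.1, 0.9)])
        pseudo = _score_frame([("p1", 0.0, 1.0)])
        _, summary = call_hits(scores, pseudo)
        assert summary["n_hits"] == 0
        assert summary["empirical_fdr"] is None

    def test_fdr_ratio(self):
        scores = _score_frame([("a", 0.8, 0.001), ("b", 0.9, 0.01)])
        pseudo = _score_frame([(f"p{i}", 0.5, 0.5) for i in range(9)] + [("p9", 0.8, 0.01)])
        _, summary = call_hits(scores, pseudo)
        # 1/10 pseudo pass vs 2/2 real pass
        assert summary["empirical_fdr"] == pytest.approx(0.1)


class TestVolcano:
    def test_rows_and_nonnegative_neglog10(self):
        scores = _score_frame([("a", 0.8, 0.001), ("b", -0.2, 0.7)])
        pseudo = _score_frame([("p1", 0.0, 1.0)])
        tab = volcano_table(scores, pseudo)
        assert len(tab) == 3
        assert (tab["neg_log10_p"] >= 0).all()
        assert tab.loc["a", "screen_score"] == scores.loc["a", "screen_score"]
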