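"""Hypergeometric TF enrichment, PWM scanning, ternary network expansion."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from netkit.dataio import GeneSetCollection, PFM
from netkit.transtf import (
    hypergeom_upper,
    pfm_targets,
    tf_enrich,
    ternary_network,
)


def exact_tail(k, K, n, N) -> Fraction:
    """Exact upper-tail probability as a rational number."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i),
                          math.comb(N, n))
    return total


class TestHypergeomUpper:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper(0, 5, 5, 10) == 1.0

    def test_worked_half_case(self):
        assert hypergeom_upper(3, 5, 5, 10) == pytest.approx(0.5, rel=1e-12)

    def test_worked_single_term_case(self):
        assert hypergeom_upper(5, 5, 5, 10) == pytest.approx(1 / 252,
                                                             rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper(0, 11, 5, 10)

    def test_monotone_nonincreasing_in_k(self):
        ps = [hypergeom_upper(k, 20, 30, 100) for k in range(0, 21)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_matches_literal_draw_enumeration(self):
        # every possible draw of n items from a universe with K marked ones
        for N, K, n in [(6, 3, 2), (7, 4, 3), (8, 3, 4), (9, 5, 4)]:
            marked = set(range(K))
            for k in range(0, min(n, K) + 1):
                count = sum(1 for draw in
                            itertools.combinations(range(N), n)
                            if len(marked & set(draw)) >= k)
                expected = count / math.comb(N, n)
                assert hypergeom_upper(k, K, n, N) == pytest.approx(
                    expected, rel=1e-12)


class TestPfmTargets:
    def _toy_pfm(self, consensus="ACGTAC"):
        counts = np.ones((4, len(consensus)))
        for j, b in enumerate(consensus):
            counts["ACGT".index(b), j] = 17.0
        return PFM(motif_id="M1", tf_name="TFX", counts=counts)

    def test_window_score_is_sum_of_log_odds(self):
        from netkit.transtf import _best_window_score, _pwm_log_odds

        counts = np.array([[8.0, 0, 0, 0], [0, 8, 0, 0],
                           [0, 0, 8, 0], [0, 0, 0, 8]])
        pfm = PFM(motif_id="M", tf_name="T", counts=counts)
        pwm = _pwm_log_odds(pfm, pseudocount=0.25)
        # hand-computed: p = (8+.25)/9 for the consensus base, else .25/9
        hi = np.log2((8.25 / 9) / 0.25)
        assert _best_window_score("ACGT", pwm) == pytest.approx(4 * hi)

    def test_consensus_promoter_is_target(self, rng, small_bundle):
        pfm = self._toy_pfm()
        promoters = {f"g{i}": "".join(rng.choice(list("ACGT"), size=300))
                     for i in range(50)}
        promoters["hit"] = "ACGTAC" * 50  # repeated consensus: maximal score
        targets = pfm_targets([pfm], promoters, rng_seed=3)
        assert "hit" in targets.members("TFX")

    def test_null_promoters_hit_near_quantile_rate(self, rng):
        # random counts give a near-continuous score distribution, so the
        # 0.99-quantile threshold is not an atom shared by many promoters
        counts = rng.integers(1, 20, size=(4, 8)).astype(float)
        pfm = PFM(motif_id="M2", tf_name="TFX", counts=counts)
        promoters = {f"g{i}": "".join(rng.choice(list("ACGT"), size=300))
                     for i in range(200)}
        targets = pfm_targets([pfm], promoters, score_quantile=0.99,
                              rng_seed=3)
        n_hit = len(targets.members("TFX")) if "TFX" in targets.names() else 0
        assert n_hit <= 12  # ~1% expected of 200, allow sampling slack

    def test_short_promoter_skipped(self):
        pfm = self._toy_pfm("ACGTACGTAC")
        targets = pfm_targets([pfm], {"short": "ACG",
                                      "ok": "ACGTACGTAC" * 10}, rng_seed=0)
        assert "short" not in (targets.members("TFX")
                               if "TFX" in targets.names() else set())


class TestTfEnrich:
    UNIVERSE = {f"g{i}" for i in range(100)}

    def test_exact_target_match_retained_with_minimal_p(self):
        targets = GeneSetCollection({
            "TF1": ("d", tuple(f"g{i}" for i in range(10))),
            "TF2": ("d", tuple(f"g{i}" for i in range(50, 70))),
        })
        coexpr = {"lncA": {f"g{i}" for i in range(10)}}
        out = tf_enrich(coexpr, targets, self.UNIVERSE)
        assert list(out["tf_name"]) == ["TF1"]
        assert out.loc[0, "k"] == 10
        assert out.loc[0, "overlap_genes"].split(",") == \
            sorted(f"g{i}" for i in range(10))

    def test_disjoint_sets_retain_nothing(self):
        targets = GeneSetCollection({"TF1": ("d", ("g1", "g2", "g3"))})
        out = tf_enrich({"lncA": {"g50", "g51"}}, targets, self.UNIVERSE)
        assert out.empty

    def test_random_sets_stay_at_null_expectation(self, rng):
        universe = {f"g{i}" for i in range(2000)}
        targets = GeneSetCollection({
            f"TF{t}": ("d", tuple(rng.choice(sorted(universe), size=40,
                                             replace=False)))
            for t in range(50)})
        coexpr = {f"lnc{i}": set(rng.choice(sorted(universe), size=30,
                                            replace=False))
                  for i in range(100)}
        out = tf_enrich(coexpr, targets, universe)
        assert len(out) / 5000 <= 0.01  # at most the raw p<0.01 rate

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            tf_enrich({}, GeneSetCollection({"T": ("d", ("g",))}), set())


class TestTernaryNetwork:
    def _enrichment(self, genes):
        return pd.DataFrame([{
            "lnc_id": "lncA", "tf_name": "TF1", "k": len(genes),
            "K": 10, "n": 5, "N": 100, "p_value": 1e-5, "fdr": 1e-4,
            "overlap_genes": ",".join(genes)}])

    def test_single_enrichment_expansion(self):
        edges, counts = ternary_network(self._enrichment(["g1", "g2", "g3"]))
        assert counts == {"n_lnc": 1, "n_tf": 1, "n_gene": 3,
                          "n_nodes": 5, "n_edges": 4}

    def test_empty_enrichment_gives_empty_network(self):
        empty = self._enrichment(["g1"]).iloc[:0]
        edges, counts = ternary_network(empty)
        assert edges.empty and counts["n_nodes"] == 0

    def test_counts_match_recount_from_edge_table(self, small_bundle):
        # moderately sized synthetic enrichment table
        rows = []
        for i in range(5):
            genes = [f"g{j}" for j in range(i, i + 4)]
            rows.append({"lnc_id": f"lnc{i % 3}", "tf_name": f"TF{i % 2}",
                         "k": 4, "K": 10, "n": 6, "N": 100,
                         "p_value": 1e-4, "fdr": 1e-3,
                         "overlap_genes": ",".join(genes)})
        edges, counts = ternary_network(pd.DataFrame(rows))
        assert counts["n_edges"] == len(edges)
        nodes = set(edges["source"]) | set(edges["target"])
        assert counts["n_nodes"] == len(nodes)
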