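"""Normalization, z-scoring, significance testing and hit calling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import stdtr

from osteoscreen.model import Role, WellMeasurement
from osteoscreen.stats import test_vs_nt as pooled_ttest
from osteoscreen.stats import (
    GeneResult,
    HitCategory,
    HitThresholds,
    NormalizationError,
    aggregate_genes,
    call_hits,
    classify_table,
    load_candidate_table,
    normalize_to_nt,
    zscore_log2,
)


def _well(plate, well, role, gene, cells, alp):
    return WellMeasurement(plate, well, gene, role, cells, alp, None, 15)


class TestNormalizeToNT:
    def _plate(self, sample_alp):
        return [
            _well("p1", "A1", Role.NON_TARGETING, "", 1000, 1.5),
            _well("p1", "A2", Role.NON_TARGETING, "", 1000, 2.5),
            _well("p1", "B1", Role.LIBRARY, "Hgf", 800, sample_alp),
        ]

    def test_well_equal_to_nt_mean_is_100(self):
        normed = normalize_to_nt(self._plate(2.0))
        gene = next(w for w in normed if w.gene_symbol == "Hgf")
        assert gene.pct_alp == pytest.approx(100.0)

    def test_suppressor_boundary_160(self):
        gene = next(
            w for w in normalize_to_nt(self._plate(3.2)) if w.gene_symbol == "Hgf"
        )
        assert gene.pct_alp == pytest.approx(160.0)

    def test_activator_boundary_40(self):
        gene = next(
            w for w in normalize_to_nt(self._plate(0.8)) if w.gene_symbol == "Hgf"
        )
        assert gene.pct_alp == pytest.approx(40.0)

    def test_nt_mean_pct_is_exactly_100(self):
        normed = normalize_to_nt(self._plate(1.0))
        nt_pct = [w.pct_alp for w in normed if w.role == Role.NON_TARGETING]
        assert np.mean(nt_pct) == pytest.approx(100.0, abs=1e-12)
        nt_cells = [w.pct_cell_number for w in normed if w.role == Role.NON_TARGETING]
        assert np.mean(nt_cells) == pytest.approx(100.0, abs=1e-12)

    def test_no_nt_wells_fatal(self):
        with pytest.raises(NormalizationError):
            normalize_to_nt([_well("p1", "B1", Role.LIBRARY, "Hgf", 800, 1.0)])

    def test_zero_alp_gets_flagged_pseudocount(self):
        wells = self._plate(0.0)
        normed = normalize_to_nt(wells)
        gene = next(w for w in normed if w.gene_symbol == "Hgf")
        assert gene.zero_alp_imputed
        assert gene.log2_alp == pytest.approx(math.log2(0.5 * 1.5))


class TestZScore:
    def _normed(self, log2_values, roles=None):
        wells = [
            _well("p1", f"A{i + 1}", Role.NON_TARGETING, "", 1000, 2.0 ** v)
            for i, v in enumerate(log2_values)
        ]
        if roles:
            for w, r in zip(wells, roles):
                w.role = r
                w.gene_symbol = "G" if r == Role.LIBRARY else ""
        return normalize_to_nt(wells)

    def test_hand_computed_example(self):
        normed, z_nt = zscore_log2(self._normed([0.0, 1.0, 2.0]))
        assert [w.z_alp for w in normed] == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_variance_names_plate(self):
        with pytest.raises(NormalizationError, match="p1"):
            zscore_log2(self._normed([1.0, 1.0, 1.0]))

    def test_location_invariance(self):
        a, _ = zscore_log2(self._normed([0.0, 1.0, 3.0]))
        b, _ = zscore_log2(self._normed([5.0, 6.0, 8.0]))
        assert [w.z_alp for w in a] == pytest.approx([w.z_alp for w in b])

    def test_mean_zero_sd_one(self):
        normed, _ = zscore_log2(self._normed([0.2, 0.9, 1.7, 2.4, 3.3]))
        zs = np.array([w.z_alp for w in normed])
        assert abs(zs.mean()) < 1e-9
        assert abs(zs.std(ddof=1) - 1.0) < 1e-9


class TestTTest:
    def test_identical_groups_p_one(self):
        assert pooled_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_matches_textbook_pooled_formula(self):
        x, y = [0.9, 1.0, 1.1], [-0.1, 0.0, 0.1]
        p = pooled_ttest(x, y)
        # independent closed-form oracle
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
        t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        p_oracle = 2 * stdtr(nx + ny - 2, -abs(t))
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_symmetry_under_group_swap(self):
        x, y = [0.3, 0.5, 0.9], [0.1, 0.2, 0.15]
        assert pooled_ttest(x, y) == pytest.approx(pooled_ttest(y, x))


def _result(gene, pct_cells, pct_alp, z, p):
    return GeneResult(gene, pct_cells, pct_alp, z, p, 3)


class TestCallHits:
    def test_suppressor_archetype(self):
        calls = call_hits([_result("H2-Ob", 95.0, 231.79, 2.4, 0.03)], z_nt=0.4)
        assert calls[0].category == HitCategory.SUPPRESSOR
        assert all(
            [calls[0].passed_viability, calls[0].passed_alp_threshold,
             calls[0].passed_p, calls[0].passed_z]
        )

    def test_activator_archetype(self):
        calls = call_hits([_result("Hgfac", 90.0, 12.52, -2.5, 0.0005)], z_nt=0.4)
        assert calls[0].category == HitCategory.ACTIVATOR

    def test_viability_exclusion_overrides_alp(self):
        calls = call_hits([_result("Kif11", 25.0, 300.0, 3.0, 0.001)], z_nt=0.0)
        assert calls[0].category == HitCategory.EXCLUDED_VIABILITY
        assert not calls[0].passed_viability

    def test_unchanged_alp_not_hit(self):
        calls = call_hits([_result("G", 100.0, 100.0, 0.0, 0.9)], z_nt=0.0)
        assert calls[0].category == HitCategory.NOT_HIT

    def test_missing_p_value_cannot_be_hit(self):
        calls = call_hits([GeneResult("G", 100.0, 250.0, 2.0, None, 1)], z_nt=0.0)
        assert calls[0].category == HitCategory.NOT_HIT and not calls[0].passed_p

    def test_z_criterion_centered_on_nt(self):
        # z = 1.2 passes against z_nt = 0 but not against z_nt = 0.5
        r = [_result("G", 100.0, 200.0, 1.2, 0.01)]
        assert call_hits(r, z_nt=0.0)[0].category == HitCategory.SUPPRESSOR
        assert call_hits(r, z_nt=0.5)[0].category == HitCategory.NOT_HIT

    @given(
        st.floats(0, 400, allow_nan=False),
        st.floats(0, 400, allow_nan=False),
        st.floats(-4, 4),
        st.floats(0.0001, 1.0),
    )
    def test_categories_exclusive_and_exhaustive(self, pct_cells, pct_alp, z, p):
        calls = call_hits([_result("G", pct_cells, pct_alp, z, p)], z_nt=0.2)
        assert calls[0].category in set(HitCategory)
        if calls[0].category in (HitCategory.SUPPRESSOR, HitCategory.ACTIVATOR):
            assert calls[0].passed_viability and calls[0].passed_alp_threshold
            assert calls[0].passed_p and calls[0].passed_z

    @given(st.lists(st.floats(0, 400, allow_nan=False), min_size=2, max_size=8))
    def test_increasing_alp_never_flips_suppressor_to_activator(self, pcts):
        pcts = sorted(pcts)
        cats = [
            call_hits([_result("G", 100.0, pct, 3.0 if pct >= 100 else -3.0, 0.001)], z_nt=0.0)[0].category
            for pct in pcts
        ]
        seen_suppressor = False
        for c in cats:
            if c == HitCategory.SUPPRESSOR:
                seen_suppressor = True
            assert not (seen_suppressor and c == HitCategory.ACTIVATOR)


class TestClassifyTable:
    def test_candidate_table_counts(self):
        table, counts = classify_table(load_candidate_table())
        assert counts["suppressor"] == 5
        assert counts["activator"] == 60
        assert counts["not_hit"] == 0

    def test_empty_table_all_zero(self):
        import pandas as pd

        _, counts = classify_table(
            pd.DataFrame(columns=["gene_symbol", "pct_alp", "p_bound"])
        )
        assert all(v == 0 for v in counts.values())


def test_gene_aggregation_p_values_on_log2_scale():
    """Replicate t-test distinguishes a planted 2x gene from a null gene."""
    wells = []
    rng = np.random.default_rng(0)
    for rep in range(1, 4):
        plate = f"p-r{rep}"
        for i in range(4):
            wells.append(_well(plate, f"A{i + 1}", Role.NON_TARGETING, "", 1000, 2.0 * rng.lognormal(0, 0.1)))
        wells.append(_well(plate, "B1", Role.LIBRARY, "Up", 1000, 4.0 * rng.lognormal(0, 0.1)))
        wells.append(_well(plate, "B2", Role.LIBRARY, "Null", 1000, 2.0 * rng.lognormal(0, 0.1)))
    normed = normalize_to_nt(wells)
    normed, z_nt = zscore_log2(normed)
    results = {r.gene_symbol: r for r in aggregate_genes(normed)}
    assert results["Up"].p_value < 0.05
    assert results["Null"].p_value > 0.05
    assert results["Up"].mean_pct_alp == pytest.approx(200.0, rel=0.2)
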