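"""Target classification: strict thresholds, evidence routes, network sums."""

import math

import pytest

from bindxpress.classify import (
    ClassificationThresholds, build_network, classify_activated,
    classify_repressed, resolve_conflicts, select_unchanged,
)
from bindxpress.io_formats import DiffExprRecord, MicroarrayRecord

THR = ClassificationThresholds()


def de(gene, log_fc, p, pct_wt=50.0, pct_mut=50.0, tissue="SG"):
    return DiffExprRecord(
        gene_id=gene, tissue=tissue, log_fc=log_fc, p_value=p,
        pct_wt=pct_wt, pct_mut=pct_mut,
    )


class TestActivatedRoutes:
    def test_scrna_route(self):
        got = classify_activated([de("a", -0.20, 0.01)], set(), [], THR)
        assert got == {"a": frozenset({"scrna"})}

    def test_boundary_logfc_excluded(self):
        # strict inequality: logFC == -0.15 is not activated
        assert classify_activated([de("a", -0.15, 0.01)], set(), [], THR) == {}

    def test_insitu_route_ignores_expression(self):
        got = classify_activated([de("a", +0.05, 0.9)], {"a"}, [], THR)
        assert got == {"a": frozenset({"insitu"})}

    def test_microarray_route_requires_pct_and_direction(self):
        ma = [MicroarrayRecord("a", -1.5, 0.01)]
        # fails the >10% wild-type expression filter
        assert classify_activated(
            [de("a", -0.05, 0.5, pct_wt=5)], set(), ma, THR
        ) == {}
        # fails the logFC < 0 direction requirement
        assert classify_activated(
            [de("a", +0.02, 0.5, pct_wt=50)], set(), ma, THR
        ) == {}
        # passes both
        got = classify_activated(
            [de("a", -0.05, 0.5, pct_wt=50)], set(), ma, THR
        )
        assert got == {"a": frozenset({"microarray"})}

    def test_microarray_gene_absent_from_de_fails_closed(self):
        ma = [MicroarrayRecord("ghost", -2.0, 0.001)]
        assert classify_activated([de("a", -0.5, 0.01)], set(), ma, THR) \
            == {"a": frozenset({"scrna"})}

    def test_multiple_routes_all_recorded(self):
        ma = [MicroarrayRecord("a", -1.5, 0.01)]
        got = classify_activated([de("a", -0.3, 0.01)], {"a"}, ma, THR)
        assert got["a"] == frozenset({"scrna", "insitu", "microarray"})

    def test_matches_truth_table_oracle(self, rng):
        genes = [f"g{i}" for i in range(200)]
        table = [
            de(
                g,
                float(rng.normal(0, 0.3)),
                float(rng.uniform(1e-4, 1.0)),
                pct_wt=float(rng.uniform(0, 100)),
            )
            for g in genes
        ]
        insitu = set(rng.choice(genes, size=20, replace=False))
        ma = [
            MicroarrayRecord(
                g, float(rng.uniform(-3, 3)) or 0.5,
                float(rng.uniform(1e-4, 1.0)),
            )
            for g in rng.choice(genes, size=80, replace=False)
        ]
        got = classify_activated(table, insitu, ma, THR)
        de_by = {r.gene_id: r for r in table}
        ma_by = {m.gene_id: m for m in ma}
        for g in genes:
            r = de_by[g]
            scrna = r.log_fc < -0.15 and r.p_value < 0.05
            m = ma_by.get(g)
            micro = (
                m is not None and m.fold_change < -1.25 and m.p_value < 0.05
                and r.pct_wt > 10 and r.log_fc < 0
            )
            expect = scrna or (g in insitu) or micro
            assert (g in got) == expect, g
            if g in got:
                assert ("scrna" in got[g]) == scrna
                assert ("insitu" in got[g]) == (g in insitu)
                assert ("microarray" in got[g]) == micro


class TestRepressedAndBoundaries:
    def test_repressed_basic(self):
        assert classify_repressed([de("a", 0.20, 0.01)], THR) == {"a"}
        assert classify_repressed([de("a", 0.20, 0.10)], THR) == set()

    @pytest.mark.parametrize(
        "lfc,expected",
        [(-0.151, True), (-0.150, False), (-0.149, False)],
    )
    def test_activation_logfc_boundary_sweep(self, lfc, expected):
        got = classify_activated([de("a", lfc, 0.01)], set(), [], THR)
        assert ("a" in got) is expected

    @pytest.mark.parametrize(
        "lfc,expected",
        [(0.151, True), (0.150, False), (0.149, False)],
    )
    def test_repression_logfc_boundary_sweep(self, lfc, expected):
        assert (classify_repressed([de("a", lfc, 0.01)], THR) == {"a"}) \
            is expected

    @pytest.mark.parametrize(
        "p,expected", [(0.049, True), (0.050, False), (0.051, False)]
    )
    def test_p_value_boundary_sweep(self, p, expected):
        got = classify_activated([de("a", -0.5, p)], set(), [], THR)
        assert ("a" in got) is expected

    @pytest.mark.parametrize(
        "fc,expected", [(-1.251, True), (-1.250, False), (-1.249, False)]
    )
    def test_microarray_fc_boundary_sweep(self, fc, expected):
        ma = [MicroarrayRecord("a", fc, 0.01)]
        got = classify_activated(
            [de("a", -0.05, 0.5, pct_wt=50)], set(), ma, THR
        )
        assert ("a" in got) is expected

    @pytest.mark.parametrize(
        "pct,expected", [(10.1, True), (10.0, False), (9.9, False)]
    )
    def test_pct_wt_boundary_sweep(self, pct, expected):
        ma = [MicroarrayRecord("a", -2.0, 0.01)]
        got = classify_activated(
            [de("a", -0.05, 0.5, pct_wt=pct)], set(), ma, THR
        )
        assert ("a" in got) is expected


class TestConflictsAndUnchanged:
    def test_conflicting_gene_excluded_from_both(self):
        # in the in-situ list yet significantly up by scRNA
        table = [de("a", +0.20, 0.01)]
        act = classify_activated(table, {"a"}, [], THR)
        rep = classify_repressed(table, THR)
        act, rep, conflicts = resolve_conflicts(act, rep)
        assert conflicts == {"a"} and not act and not rep

    def test_unchanged_smallest_abs_logfc(self):
        table = [de("a", 0.01, 0.5), de("b", -0.02, 0.5), de("c", 0.5, 0.5)]
        thr = ClassificationThresholds(unchanged_n=2)
        assert select_unchanged(table, thr) == {"a", "b"}

    def test_unchanged_tie_break_prefers_larger_p(self):
        table = [de("a", 0.1, 0.2), de("b", -0.1, 0.9), de("c", 0.1, 0.5)]
        thr = ClassificationThresholds(unchanged_n=1)
        assert select_unchanged(table, thr) == {"b"}

    def test_unchanged_matches_full_sort_oracle(self, rng):
        table = [
            de(f"g{i}", float(rng.normal(0, 0.5)),
               float(rng.uniform(1e-3, 1.0)))
            for i in range(400)
        ]
        got = select_unchanged(table, ClassificationThresholds())
        oracle = sorted(
            table, key=lambda r: (abs(r.log_fc), -r.p_value, r.gene_id)
        )[:150]
        assert got == {r.gene_id for r in oracle}

    def test_short_table_returns_all_with_warning(self, caplog):
        table = [de("a", 0.1, 0.5)]
        with caplog.at_level("WARNING"):
            got = select_unchanged(table, ClassificationThresholds())
        assert got == {"a"} and "1 genes" in caplog.text

    def test_order_permutation_invariance(self, rng):
        table = [
            de(f"g{i}", float(rng.normal(0, 0.3)),
               float(rng.uniform(1e-4, 1.0)))
            for i in range(100)
        ]
        shuffled = list(table)
        rng.shuffle(shuffled)
        assert classify_activated(table, set(), [], THR) == \
            classify_activated(shuffled, set(), [], THR)
        assert select_unchanged(table, THR) == select_unchanged(shuffled, THR)


class TestNetwork:
    def test_set_arithmetic_fractions(self):
        net = build_network(
            {"A", "B", "C", "D"}, {"A", "E"}, {"B"}, spcg={"A", "Z"}
        )
        assert net.fraction_bound_regulated == 0.5
        assert net.fraction_activated_bound == 0.5
        assert net.fraction_repressed_bound == 1.0
        assert net.bound_activated == {"A"}
        assert net.spcg_bound_count == 1
        assert net.spcg_bound_down_count == 1

    def test_disjoint_sets_give_zero_fractions(self):
        net = build_network({"A"}, {"B"}, {"C"})
        assert net.fraction_bound_regulated == 0

    def test_empty_bound_gives_nan_sentinel_not_zero(self):
        net = build_network(set(), {"A"}, set())
        assert math.isnan(net.fraction_bound_regulated)
        assert math.isnan(net.fraction_repressed_bound)
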