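import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tradefd import (
    FilterSpec,
    TradeRecord,
    WOERule,
    WOETable,
    build_matrix,
    convert_to_woe,
    default_woe_table,
    exclude_sparse,
    filter_records,
    parse_ledger,
    to_woe,
)


def rec(**kw):
    base = dict(
        year=2010, taxon="Boa constrictor", term="live", quantity=1.0,
        exporter="MG", importer="US", source="W", purpose="T",
    )
    base.update(kw)
    return TradeRecord(**base)


class TestParse:
    CSV = (
        "Year,App.,Taxon,Term,Unit,Quantity,Exporter,Importer,Origin,Source,Purpose\n"
        "2005,II,Boa constrictor,live,,10,MG,US,,W,T\n"
        "2006,II,Varanus niloticus,skins,,250,TZ,FR,,W,T\n"
        "2007,II,Python regius,live,,3,GH,JP,,C,T\n"
    )

    def test_identity_parse(self):
        parsed = parse_ledger(io.StringIO(self.CSV))
        assert len(parsed.records) == 3 and parsed.n_rejected == 0
        r = parsed.records[0]
        assert (r.year, r.taxon, r.quantity, r.exporter) == (2005, "Boa constrictor", 10.0, "MG")
        assert r.unit == "" and r.origin == ""

    def test_bad_quantity_rejected_with_line_number(self):
        csv = self.CSV + "2008,II,Python regius,live,,abc,GH,JP,,W,T\n"
        parsed = parse_ledger(io.StringIO(csv))
        assert len(parsed.records) == 3
        assert parsed.n_rejected == 1
        line, reason = parsed.rejected[0]
        assert line == 4 and "quantity" in reason

    def test_missing_mapped_column_is_hard_error(self):
        with pytest.raises(ValueError, match="missing mapped columns"):
            parse_ledger(io.StringIO("Year,Taxon\n2001,X\n"))

    def test_custom_schema_matches_hand_built_records(self):
        csv = (
            "yr,species,what,unit,qty,from,to,origin,src,why\n"
            "2005,Boa constrictor,live,,10,MG,US,,W,T\n"
        )
        schema = {
            "year": "yr", "taxon": "species", "term": "what", "quantity": "qty",
            "exporter": "from", "importer": "to", "origin": "origin",
            "source": "src", "purpose": "why", "unit": "unit", "appendix": "yr",
        }
        parsed = parse_ledger(io.StringIO(csv), schema=schema)
        expected = TradeRecord(
            year=2005, taxon="Boa constrictor", term="live", quantity=10.0,
            exporter="MG", importer="US", source="W", purpose="T", appendix="2005",
        )
        assert parsed.records == [expected]


class TestFilter:
    @pytest.mark.parametrize(
        "record,kept",
        [
            (rec(source="I"), False),  # seized specimens are neither wild nor captive
            (rec(source="W", purpose="T", year=2010), True),
            (rec(source="X"), True),
            (rec(source="R"), True),
            (rec(source="C"), False),  # captive under a wild-source spec
            (rec(purpose="S"), False),  # non-commercial purpose
            (rec(purpose="P"), True),
            (rec(year=1999), False),
            (rec(year=2021), False),
            (rec(origin="MG", exporter="US"), False),  # re-export
            (rec(origin="US", exporter="US"), True),  # origin equals exporter
        ],
    )
    def test_wild_commercial_filter(self, record, kept):
        out = filter_records([record], FilterSpec(source_class="wild"))
        assert (len(out) == 1) is kept

    def test_captive_class(self):
        out = filter_records(
            [rec(source="C"), rec(source="W")], FilterSpec(source_class="captive")
        )
        assert [r.source for r in out] == ["C"]

    def test_reexports_kept_when_disabled(self):
        r = rec(origin="MG", exporter="US")
        assert filter_records([r], FilterSpec(drop_reexports=False)) == [r]

    def test_delisted_species_removed_in_later_years(self):
        records = [rec(year=y) for y in (2005, 2006, 2007)]
        out = filter_records(records, FilterSpec(), delisting_year={"Boa constrictor": 2006})
        assert [r.year for r in out] == [2005, 2006]

    def test_idempotence(self):
        records = [rec(source=s, purpose=p, year=y)
                   for s in "WXRCDFI" for p in "TPSZ" for y in (1999, 2010)]
        spec = FilterSpec()
        once = filter_records(records, spec)
        assert filter_records(once, spec) == once


class TestWOE:
    def test_count_identity(self):
        assert to_woe(rec(term="live", quantity=10), default_woe_table()) == 10.0

    def test_mass_based_arithmetic(self):
        r = rec(term="meat", unit="kg", quantity=12)
        assert to_woe(r, default_woe_table(), body_mass_g=3000.0) == pytest.approx(4.0)

    def test_mass_in_grams(self):
        r = rec(term="meat", unit="g", quantity=6000)
        assert to_woe(r, default_woe_table(), body_mass_g=3000.0) == pytest.approx(2.0)

    def test_drop_term_logs(self):
        log = []
        assert to_woe(rec(term="derivatives", quantity=99), default_woe_table(), log=log) == 0.0
        assert len(log) == 1 and "drop" in log[0].reason

    def test_mass_term_without_body_mass_dropped_and_logged(self):
        log = []
        r = rec(term="meat", unit="kg", quantity=5)
        assert to_woe(r, default_woe_table(), body_mass_g=None, log=log) == 0.0
        assert len(log) == 1 and "body mass" in log[0].reason

    def test_unknown_term_policies(self):
        r = rec(term="gall bladders")
        log = []
        assert to_woe(r, default_woe_table(), log=log) == 0.0 and len(log) == 1
        strict = default_woe_table()
        strict.unknown_policy = "error"
        with pytest.raises(KeyError):
            to_woe(r, strict)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(q=st.floats(0, 1e6, allow_nan=False), c=st.floats(0.01, 100))
    def test_homogeneous_in_quantity(self, q, c):
        table = WOETable({("skins", ""): WOERule("count_factor", factor=2.0)})
        w1 = to_woe(rec(term="skins", quantity=q), table)
        wc = to_woe(rec(term="skins", quantity=c * q), table)
        assert wc == pytest.approx(c * w1, rel=1e-12, abs=1e-9)


class TestMatrix:
    POOL = ["sp_a", "sp_b", "sp_c", "sp_d", "sp_e"]

    def test_additivity_same_cell(self):
        pairs = [(rec(taxon="sp_a", exporter="MG"), 3.0), (rec(taxon="sp_a", exporter="MG"), 4.0)]
        m = build_matrix(pairs, "exporter", pool=self.POOL)
        assert m.data.loc[("MG",), "sp_a"] == 7.0

    def test_nontraded_pool_species_are_zero_columns(self):
        pairs = [(rec(taxon="sp_a"), 1.0), (rec(taxon="sp_b"), 2.0)]
        m = build_matrix(pairs, "exporter", pool=self.POOL)
        zero_cols = [c for c in m.pool if (m.data[c] == 0).all()]
        assert sorted(zero_cols) == ["sp_c", "sp_d", "sp_e"]

    def test_species_missing_from_pool_is_hard_error(self):
        with pytest.raises(ValueError, match="sp_z"):
            build_matrix([(rec(taxon="sp_z"), 1.0)], "exporter", pool=self.POOL)

    def test_market_stratum_from_term(self):
        pairs = [(rec(taxon="sp_a", term="live"), 1.0), (rec(taxon="sp_a", term="skins"), 2.0)]
        m = build_matrix(pairs, "exporter", pool=self.POOL, strata=("market",))
        assert m.data.loc[("MG", "live"), "sp_a"] == 1.0
        assert m.data.loc[("MG", "dead"), "sp_a"] == 2.0

    def test_data_deficient_excluded_from_threat_strata(self):
        iucn = {"sp_a": "CR", "sp_b": "LC", "sp_c": "DD"}
        pairs = [(rec(taxon=s), 1.0) for s in ("sp_a", "sp_b", "sp_c")]
        m = build_matrix(pairs, "exporter", pool=self.POOL, strata=("threat",), iucn=iucn)
        levels = m.data.index.get_level_values("threat")
        assert set(levels) == {"threatened", "non_threatened"}
        assert m.total_woe == 2.0  # the DD record contributes nowhere

    def test_continental_grouping_requires_mapping(self):
        with pytest.raises(KeyError):
            build_matrix([(rec(taxon="sp_a"), 1.0)], "exporter_continent", pool=self.POOL)


class TestPipelineProperties:
    def _woe_pairs(self, synthetic_run):
        pool, led, cfg = synthetic_run
        buf = io.StringIO()
        led.ledger.to_csv(buf, index=False)
        buf.seek(0)
        parsed = parse_ledger(buf)
        recs = filter_records(parsed.records, FilterSpec())
        pairs, _ = convert_to_woe(recs, default_woe_table())
        return pool, pairs

    def test_conservation_matrix_equals_ledger_total(self, synthetic_run):
        pool, pairs = self._woe_pairs(synthetic_run)
        total = sum(w for _, w in pairs)
        for grouping in ("exporter", "importer", "route"):
            m = build_matrix(pairs, grouping, pool=list(pool.truth.index))
            assert m.total_woe == pytest.approx(total, rel=1e-9)

    def test_route_rows_refine_exporter_rows(self, synthetic_run):
        pool, pairs = self._woe_pairs(synthetic_run)
        species = list(pool.truth.index)
        by_route = build_matrix(pairs, "route", pool=species)
        by_exp = build_matrix(pairs, "exporter", pool=species)
        summed = by_route.data.groupby(level="exporter").sum()
        flat = by_exp.data.set_axis(by_exp.data.index.get_level_values("exporter"))
        pd.testing.assert_frame_equal(summed, flat, check_like=True)


class TestExcludeSparse:
    def _matrix(self):
        pairs = []
        # exporter A trades 3 species (dropped), B trades 4 (kept)
        for i, sp in enumerate(["sp_a", "sp_b", "sp_c"]):
            pairs.append((rec(taxon=sp, exporter="A"), float(i + 1)))
        for i, sp in enumerate(["sp_a", "sp_b", "sp_c", "sp_d"]):
            pairs.append((rec(taxon=sp, exporter="B"), 10.0))
        return build_matrix(pairs, "exporter", pool=TestMatrix.POOL)

    def test_boundary(self):
        kept, report = exclude_sparse(self._matrix(), min_species=4)
        assert list(kept.data.index) == [("B",)]
        assert list(report.dropped.index) == [("A",)]
        assert report.dropped.loc[("A",), "n_species"] == 3

    def test_share_matches_hand_computation(self):
        # dropped WOE = 1+2+3 = 6; total = 6 + 40
        _, report = exclude_sparse(self._matrix(), min_species=4)
        assert report.dropped_share == pytest.approx(6.0 / 46.0, rel=1e-12)

    def test_min_species_one_keeps_everything(self):
        m = self._matrix()
        kept, report = exclude_sparse(m, min_species=1)
        assert len(kept.data) == len(m.data) and report.dropped.empty
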