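import logging

import pytest

from betalains.catalog import (
    BETACYANIN_FRAMEWORK_IONS,
    BetalainClass,
    Catalog,
    catalog_stats,
    condense_betaxanthin,
    derivative_ops_from_name,
    enumerate_derivatives,
    load_catalog,
    relative_rt,
    validate_catalog,
)
from betalains.chem import compose_add, compose_subtract, parse_formula, protonated_mz


class TestLoadCatalog:
    def test_bundled_has_86_records(self, catalog):
        assert len(catalog) == 86

    def test_betanin_row(self, catalog):
        betanin = catalog.by_name("Betanin")
        assert betanin.rt == 3.43
        assert betanin.theoretical_mz == 551.1508
        assert betanin.observed_mz == 551.1483
        assert betanin.betalain_class.name == "betanin-type"
        assert not betanin.is_derivative

    def test_empty_file_with_header(self, tmp_path, catalog_tsv_header):
        path = tmp_path / "empty.tsv"
        path.write_text(catalog_tsv_header, encoding="utf-8")
        assert len(load_catalog(path)) == 0

    def test_schema_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("name\tmz\nBetanin\t551.15\n", encoding="utf-8")
        with pytest.raises(ValueError, match="missing columns"):
            load_catalog(path)

    def test_inconsistent_mz_warns_but_loads(
        self, tmp_path, catalog_tsv_header, caplog
    ):
        row = (
            "1\t1\tBogus\tbetacyanin\tbetanin-type\tC24H26N2O13\t3.43\t1\t"
            "550.0000\t\t\t389.09\t0\t\n"
        )
        path = tmp_path / "off.tsv"
        path.write_text(catalog_tsv_header + row, encoding="utf-8")
        with caplog.at_level(logging.WARNING, logger="betalains.catalog"):
            cat = load_catalog(path)
        assert len(cat) == 1
        assert any("differs from" in rec.message for rec in caplog.records)

    def test_duplicate_name_rt_rejected(self, tiny_catalog_tsv):
        cat = load_catalog(tiny_catalog_tsv)
        with pytest.raises(ValueError, match="duplicate"):
            Catalog(list(cat) + [cat[0]])

    def test_tentative_flags(self, catalog):
        assert not catalog.by_name("Betanin").tentative
        assert catalog.by_name("Unknown-1").tentative


class TestCatalogStats:
    def test_totals(self, catalog):
        stats = catalog_stats(catalog)
        assert stats["total"] == 86
        assert stats["by_parent"]["betaxanthin"] == 19
        assert stats["abstract_partition"] == {
            "betacyanin": 31,
            "betacyanin-derivative": 36,
            "betaxanthin": 19,
        }

    def test_class_counts_partition_total(self, catalog):
        stats = catalog_stats(catalog)
        assert sum(stats["by_class"].values()) == stats["total"]
        assert sum(stats["by_category"].values()) == stats["total"]

    def test_empty_catalog(self):
        stats = catalog_stats(Catalog([]))
        assert stats["total"] == 0
        assert stats["by_category"] == {}
        assert stats["mz_range"] == (None, None)


class TestValidateCatalog:
    def test_all_mz_consistent(self, catalog):
        v = validate_catalog(catalog)
        assert v.mz_pass.all()
        assert len(v) == 86

    def test_ppm_column_reproduced(self, catalog):
        assert validate_catalog(catalog).ppm_pass.all()

    def test_relative_rt_reproduced(self, catalog):
        assert validate_catalog(catalog).relative_rt_pass.all()

    def test_fault_injection_flags_only_corrupt_record(
        self, tmp_path, catalog_tsv_header, tiny_catalog_tsv
    ):
        text = tiny_catalog_tsv.read_text(encoding="utf-8")
        # corrupt the second record's formula (drop one oxygen)
        corrupted = text.replace(
            "Isobetanin\tbetacyanin\tbetanin-type\tC24H26N2O13",
            "Isobetanin\tbetacyanin\tbetanin-type\tC24H26N2O12",
        )
        path = tmp_path / "corrupt.tsv"
        path.write_text(corrupted, encoding="utf-8")
        v = validate_catalog(load_catalog(path))
        assert list(v.mz_pass) == [True, False]


class TestEnumerateDerivatives:
    def test_monodecarboxy_betanin(self, catalog):
        betanin = catalog.by_name("Betanin")
        (deriv,) = enumerate_derivatives(betanin, [["decarboxy"]])
        assert deriv.formula == parse_formula("C23H26N2O11")
        assert deriv.theoretical_mz == pytest.approx(507.1609, abs=5e-5)
        assert deriv.is_derivative

    def test_neo_betanin(self, catalog):
        (deriv,) = enumerate_derivatives(
            catalog.by_name("Betanin"), [["dehydro-14,15"]]
        )
        assert deriv.formula == parse_formula("C24H24N2O13")
        assert deriv.theoretical_mz == pytest.approx(549.1351, abs=5e-5)

    def test_bidecarboxy_xan(self, catalog):
        (deriv,) = enumerate_derivatives(
            catalog.by_name("Betanin"), [["decarboxy", "decarboxy", "dehydro-2,3"]]
        )
        assert deriv.formula == parse_formula("C22H24N2O9")
        assert deriv.theoretical_mz == pytest.approx(461.1555, abs=1e-4)

    def test_empty_ops_is_identity(self, catalog):
        betanin = catalog.by_name("Betanin")
        assert enumerate_derivatives(betanin, [[]]) == [betanin]

    def test_derivative_base_rejected(self, catalog):
        deriv = catalog.by_name("17-decarboxy-betanin")
        with pytest.raises(ValueError, match="itself a derivative"):
            enumerate_derivatives(deriv, [["decarboxy"]])

    def test_over_modification_rejected(self, catalog):
        with pytest.raises(ValueError):
            enumerate_derivatives(
                catalog.by_name("Betanin"), [["decarboxy"] * 4]
            )

    def test_mass_shifts_independent_of_base(self, catalog):
        # -43.9898 Da per decarboxylation, -2.0157 Da per dehydrogenation,
        # for every intact betacyanin in the catalog
        bases = [r for r in catalog if r.category == "betacyanin"]
        assert bases
        for base in bases:
            dec, neo = enumerate_derivatives(
                base, [["decarboxy"], ["dehydro-14,15"]]
            )
            base_mz = protonated_mz(base.formula, decimals=None)
            assert base_mz - protonated_mz(dec.formula, decimals=None) == pytest.approx(
                43.9898, abs=1e-4
            )
            assert base_mz - protonated_mz(neo.formula, decimals=None) == pytest.approx(
                2.0157, abs=1e-4
            )


CONJUGATE_PAIRS = [
    ("Prebetanin", "SO3"),
    ("Phyllocactin", "C3H2O3"),
    ("Hylocerenin", "C6H8O4"),
    ("Lampranthin-I", "C9H6O2"),
    ("Lampranthin II", "C10H8O3"),
    ("Melocactin", "C6H10O5"),
    ("Apiocactin", "C5H8O4"),
]


class TestConjugateArithmetic:
    @pytest.mark.parametrize("name, residue", CONJUGATE_PAIRS)
    def test_betanin_plus_residue(self, catalog, name, residue):
        betanin = catalog.by_name("Betanin")
        total = compose_add(betanin.formula, parse_formula(residue))
        record = catalog.by_name(name)
        assert total == record.formula
        assert protonated_mz(total, decimals=None) == pytest.approx(
            record.theoretical_mz, abs=2e-4
        )

    def test_amaranthin_framework_ion(self, catalog):
        total = compose_add(
            catalog.by_name("Betanin").formula, parse_formula("C6H8O6")
        )
        assert protonated_mz(total, decimals=None) == pytest.approx(
            BETACYANIN_FRAMEWORK_IONS["amaranthin-type"], abs=2e-4
        )


class TestCondenseBetaxanthin:
    @pytest.mark.parametrize(
        "amine, expected_formula, expected_mz",
        [
            ("C5H10N2O3", "C14H17N3O7", 340.1139),  # glutamine
            ("C2H5NO2", "C11H12N2O6", 269.0768),    # glycine
            ("C11H12N2O2", "C20H19N3O6", 398.1347),  # tryptophan
        ],
    )
    def test_condensation(self, amine, expected_formula, expected_mz):
        record = condense_betaxanthin(parse_formula(amine), "test-bx")
        assert record.formula == parse_formula(expected_formula)
        assert record.theoretical_mz == pytest.approx(expected_mz, abs=1e-4)
        assert record.parent == "betaxanthin"

    def test_condensation_matches_direct_arithmetic(self, catalog):
        # independent oracle: betalamic acid + tryptophan - water, composed
        # by hand, against the catalog's printed tryptophan-bx row
        expected = compose_subtract(
            compose_add(parse_formula("C9H9NO5"), parse_formula("C11H12N2O2")),
            parse_formula("H2O"),
        )
        row = catalog.by_name("Tryptophan-bx")
        assert expected == row.formula
        assert protonated_mz(expected) == pytest.approx(row.theoretical_mz, abs=1e-4)

    def test_nitrogen_required(self):
        with pytest.raises(ValueError, match="nitrogen"):
            condense_betaxanthin(parse_formula("C6H12O6"), "not-an-amine")


class TestRelativeRt:
    @pytest.mark.parametrize(
        "rt, ref, expected",
        [(6.59, 3.43, 1.92), (3.43, 3.43, 1.00), (5.83, 3.43, 1.70)],
    )
    def test_examples(self, rt, ref, expected):
        assert relative_rt(rt, ref) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_rt(5.0, 0.0)


class TestDerivativeOpsFromName:
    @pytest.mark.parametrize(
        "name, ops",
        [
            ("17-decarboxy-betanin", ("decarboxy",)),
            ("Neobetanin", ("dehydro-14,15",)),
            ("2-decarboxy-xanbetanin", ("decarboxy", "dehydro-2,3")),
            (
                "2,17-bidecarboxy-xanneobetanin",
                ("decarboxy", "decarboxy", "dehydro-2,3", "dehydro-14,15"),
            ),
            (
                "2,15,17-tridecarboxy-neobetanin",
                ("decarboxy", "decarboxy", "decarboxy", "dehydro-14,15"),
            ),
            ("2-descarboxy-phyllocactin", ("decarboxy",)),
            ("Betanin", ()),
            ("Tryptophan-bx", ()),
        ],
    )
    def test_grammar(self, name, ops):
        assert derivative_ops_from_name(name) == ops

    def test_ops_formula_consistency(self, catalog):
        # every named derivative's formula equals base-reconstruction:
        # formula + k*CO2 + j*H2 must belong to some intact catalog record
        co2, h2 = parse_formula("CO2"), parse_formula("H2")
        intact_formulas = {
            r.formula for r in catalog if r.category in ("betacyanin", "betalamic-acid")
        }
        named = [
            r for r in catalog if r.is_derivative and r.derivative_ops
        ]
        assert len(named) == 34  # all but the two unnamed unknown derivatives
        for r in named:
            base = r.formula
            for op in r.derivative_ops:
                base = compose_add(base, co2 if op == "decarboxy" else h2)
            assert base in intact_formulas, r.name


class TestNeutralLossTable:
    def test_masses_consistent_with_formulas(self, loss_table):
        # NeutralLossTable itself validates at 1e-4 Da on construction
        assert len(loss_table) == 11

    def test_named_lookup(self, loss_table):
        assert loss_table.get("glucosyl").mass == pytest.approx(162.0528, abs=1e-4)
        with pytest.raises(KeyError):
            loss_table.get("nonexistent")


def test_betalain_class_taxonomy():
    cls = BetalainClass.from_name("betanin-type")
    assert cls.parent == "betacyanin"
    assert cls.framework_ion == 551.1508
    assert BetalainClass.from_name("hydrophobic").parent == "betaxanthin"
    assert BetalainClass.from_name("unknown-type").framework_ion is None
    with pytest.raises(ValueError):
        BetalainClass.from_name("no-such-class")
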