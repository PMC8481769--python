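"""Litter chemistry loading, treatment enumeration, mixtures and ratios."""

import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primesplit.chemistry import (
    TRAITS,
    LitterChemistry,
    chemistry_ratio,
    chemistry_to_frame,
    enumerate_treatments,
    expected_mixture_chemistry,
    load_chemistry_table,
    load_chemistry_table_long,
    mass_weighted_d13c,
    mixture_code,
    round_half_away,
    split_mixture_code,
)
from primesplit.errors import ValidationError


class TestLoadChemistry:
    def test_fixture_values(self, chemistry):
        assert chemistry["Cm"].N == pytest.approx(36.84)
        assert chemistry["Cm"].se("N") == pytest.approx(0.14)
        assert chemistry["Ah"].d13C == pytest.approx(-28.59)
        assert chemistry["Ps"].Ct == pytest.approx(88.98)
        assert set(chemistry) == {"Ah", "Cm", "Ps", "AhCm", "AhPs", "CmPs", "AhCmPs"}

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("litter_code," + ",".join(TRAITS) + "\n")
        with pytest.raises(ValidationError, match="empty"):
            load_chemistry_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("litter_code,N\nAh,17.74\n")
        with pytest.raises(ValidationError, match="missing trait columns"):
            load_chemistry_table(p)

    def test_duplicate_code_rejected(self, tmp_path):
        header = "litter_code," + ",".join(TRAITS)
        row = "Ah," + ",".join(["1"] * 8 + ["-28"])
        p = tmp_path / "dup.csv"
        p.write_text(header + "\n" + row + "\n" + row + "\n")
        with pytest.raises(ValidationError, match="duplicate"):
            load_chemistry_table(p)

    def test_unknown_mixture_species_rejected(self, tmp_path):
        header = "litter_code," + ",".join(TRAITS)
        row = "AhXy," + ",".join(["1"] * 8 + ["-28"])
        p = tmp_path / "orphan.csv"
        p.write_text(header + "\n" + row + "\n")
        with pytest.raises(ValidationError):
            load_chemistry_table(p)

    def test_plus_minus_text_dialect(self, tmp_path):
        header = "litter_code," + ",".join(TRAITS)
        vals = ["17.74 ± 0.15"] + ["1"] * 7 + ["-28.59 ± 0.02"]
        p = tmp_path / "pm.csv"
        p.write_text(header + "\nAh," + ",".join(f'"{v}"' for v in vals) + "\n")
        rec = load_chemistry_table(p)["Ah"]
        assert rec.N == pytest.approx(17.74)
        assert rec.se("N") == pytest.approx(0.15)
        assert rec.se("d13C") == pytest.approx(0.02)

    def test_long_form_roundtrip(self, tmp_path, chemistry):
        wide = chemistry_to_frame(chemistry)
        long = wide.melt(
            id_vars="litter_code",
            value_vars=list(TRAITS),
            var_name="trait",
            value_name="value",
        )
        ses = wide.melt(
            id_vars="litter_code",
            value_vars=[f"{t}_se" for t in TRAITS],
            value_name="se",
        )
        long["se"] = ses["se"].values
        p = tmp_path / "long.csv"
        long.to_csv(p, index=False)
        again = load_chemistry_table_long(p)
        assert again["Cm"].N == pytest.approx(chemistry["Cm"].N)
        assert again["Ps"].se("Ct") == pytest.approx(chemistry["Ps"].se("Ct"))

    def test_record_invariants_enforced(self):
        good = {t: 1.0 for t in TRAITS} | {"d13C": -28.0}
        with pytest.raises(ValidationError, match="negative"):
            LitterChemistry("Ah", good | {"N": -1.0}, {})
        with pytest.raises(ValidationError, match="d13C"):
            LitterChemistry("Ah", good | {"d13C": 5.0}, {})
        with pytest.raises(ValidationError, match="C > 1000"):
            LitterChemistry("Ah", good | {"C": 1200.0}, {})


class TestEnumerateTreatments:
    def test_paper_design_seven_treatments(self):
        design = enumerate_treatments(("Ah", "Cm", "Ps"), 3)
        assert design.treatments == (
            "Ah", "Cm", "Ps", "AhCm", "AhPs", "CmPs", "AhCmPs",
        )
        assert design.groups[-1] == "CK"

    def test_single_species(self):
        assert enumerate_treatments(("Ah",), 1).treatments == ("Ah",)

    def test_pairs_only(self):
        design = enumerate_treatments(("Ah", "Cm", "Ps"), 2)
        assert len(design.treatments) == 6

    def test_empty_species_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_treatments((), 1)

    @given(k=st.integers(min_value=1, max_value=6))
    @settings(deadline=None)
    def test_full_order_counts_all_subsets(self, k):
        species = tuple(f"S{i}" for i in range(k))
        design = enumerate_treatments(species, k)
        assert len(design.treatments) == 2**k - 1
        assert len(set(design.treatments)) == len(design.treatments)


class TestExpectedMixture:
    def test_pair_mean(self, chemistry):
        rec = expected_mixture_chemistry(chemistry, "AhCm")
        assert rec.N == pytest.approx(27.29)
        assert rec.expected

    def test_triple_mean(self, chemistry):
        rec = expected_mixture_chemistry(chemistry, "AhCmPs")
        assert rec.Ce == pytest.approx((138.33 + 137.06 + 177.15) / 3)
        assert rec.Ce == pytest.approx(150.85, abs=0.005)

    def test_singleton_identity(self, chemistry):
        rec = expected_mixture_chemistry(chemistry, "Ah")
        for t in TRAITS:
            assert rec.values[t] == pytest.approx(chemistry["Ah"].values[t])
            assert rec.se(t) == pytest.approx(chemistry["Ah"].se(t))
        assert rec.expected

    def test_missing_constituent(self, chemistry):
        singles = {k: v for k, v in chemistry.items() if k != "Cm"}
        with pytest.raises(ValidationError, match="missing"):
            expected_mixture_chemistry(singles, "AhCm")

    def test_se_combination(self, chemistry):
        rec = expected_mixture_chemistry(chemistry, "AhCm")
        expect = math.sqrt(0.15**2 + 0.14**2) / 2
        assert rec.se("N") == pytest.approx(expect)

    def test_permutation_invariance_via_canonical_code(self, chemistry):
        # constituents reach the mean symmetrically; codes canonicalize
        assert mixture_code(["Ps", "Ah"]) == "AhPs"
        assert split_mixture_code("AhCmPs") == ("Ah", "Cm", "Ps")

    def test_mass_weighted_d13c_between_extremes(self, chemistry):
        d = mass_weighted_d13c(chemistry, "AhPs")
        assert min(-28.59, -28.05) <= d <= max(-28.59, -28.05)


class TestChemistryRatio:
    @pytest.mark.parametrize(
        "trait,num,den,expected",
        [("Ct", "Cm", "Ah", 47), ("Ct", "Cm", "Ps", 10), ("Ss", "Cm", "Ps", 59)],
    )
    def test_printed_ratios(self, chemistry, trait, num, den, expected):
        assert chemistry_ratio(chemistry, trait, num, den, True) == expected

    def test_self_ratio(self, chemistry):
        assert chemistry_ratio(chemistry, "N", "Ah", "Ah", True) == 100

    def test_ss_ah_ps_unrounded(self, chemistry):
        # 48.15/71.12 = 67.70%: rounds to 68, one off the printed 67
        assert chemistry_ratio(chemistry, "Ss", "Ah", "Ps") == pytest.approx(
            67.70, abs=0.005
        )

    def test_reciprocal_product(self, chemistry):
        fwd = chemistry_ratio(chemistry, "Ct", "Cm", "Ah")
        rev = chemistry_ratio(chemistry, "Ct", "Ah", "Cm")
        assert fwd * rev == pytest.approx(1e4)

    def test_zero_denominator(self, chemistry):
        zero = {t: 1.0 for t in TRAITS} | {"d13C": -28.0, "Ct": 0.0}
        table = dict(chemistry)
        table["Zz"] = LitterChemistry("Ah", zero, {})
        with pytest.raises(ValidationError, match="zero"):
            chemistry_ratio(table, "Ct", "Ah", "Zz")

    @pytest.mark.parametrize("x,expected", [(0.5, 1), (1.5, 2), (-0.5, -1), (2.4, 2)])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected
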