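"""Litter chemistry tables and the incubation treatment design.

A litter (single species or an equal-proportion mixture) is described by
eight chemical traits — nitrogen (N), carbon (C), lignin (L), cellulose
(Ce), soluble sugar (Ss), methanol-soluble phenol (phM), water-soluble
phenol (phW) and condensed tannin (Ct), all mg g^-1 dry litter — plus its
δ13C signature (‰ vs VPDB), each with a standard error.

The packaged fixture carries the measured chemistry of three species
(Artemisia halodendron ``Ah``, Caragana microphylla ``Cm``, Populus
simonii ``Ps``) and their four equal-proportion mixtures.  Measured
mixture chemistry is authoritative downstream; the equal-proportion
expectation computed here is a diagnostic only.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

#: Canonical species order; mixture codes concatenate species in this order.
SPECIES_ORDER = ("Ah", "Cm", "Ps")

TRAITS = ("N", "C", "L", "Ce", "Ss", "phM", "phW", "Ct", "d13C")
#: Traits measured as concentrations (mg g^-1); d13C is handled separately.
CONCENTRATION_TRAITS = TRAITS[:-1]


@dataclass(frozen=True)
class LitterChemistry:
    """Chemical traits and δ13C of one litter, with standard errors.

    ``values`` and ``ses`` map trait name -> value / SE.  ``expected`` marks
    records built from the equal-proportion mixing expectation rather than
    measured directly.
    """

    litter_code: str
    values: Mapping[str, float]
    ses: Mapping[str, float]
    expected: bool = False

    def __post_init__(self) -> None:
        missing = [t for t in TRAITS if t not in self.values]
        if missing:
            raise ValidationError(
                f"litter {self.litter_code!r}: missing traits {missing}"
            )
        for trait in TRAITS:
            v = float(self.values[trait])
            se = float(self.ses.get(trait, 0.0))
            if not math.isfinite(v) or not math.isfinite(se):
                raise ValidationError(
                    f"litter {self.litter_code!r}, trait {trait}: non-finite value"
                )
            if se < 0:
                raise ValidationError(
                    f"litter {self.litter_code!r}, trait {trait}: SE < 0"
                )
            if trait == "d13C":
                if not -40.0 < v < 0.0:
                    raise ValidationError(
                        f"litter {self.litter_code!r}: d13C {v}‰ outside (-40, 0)"
                    )
            else:
                if v < 0:
                    raise ValidationError(
                        f"litter {self.litter_code!r}, trait {trait}: negative concentration"
                    )
        if float(self.values["C"]) > 1000.0:
            raise ValidationError(
                f"litter {self.litter_code!r}: C > 1000 mg g^-1 dry litter"
            )

    def __getattr__(self, name: str) -> float:
        if name in TRAITS:
            return float(self.values[name])
        raise AttributeError(name)

    def se(self, trait: str) -> float:
        return float(self.ses.get(trait, 0.0))

    @property
    def constituents(self) -> tuple[str, ...]:
        return split_mixture_code(self.litter_code)


@dataclass(frozen=True)
class TreatmentDesign:
    """The litter-addition design: which subsets of species go into jars."""

    species_codes: tuple[str, ...]
    treatments: tuple[str, ...]
    replicates_per_treatment: int = 5
    litter_mass: float = 2.0  # g dry litter per jar
    soil_mass: float = 200.0  # g dry soil per jar
    includes_control: bool = True

    def __post_init__(self) -> None:
        if self.replicates_per_treatment <= 0:
            raise ValidationError("replicates_per_treatment must be > 0")
        if self.litter_mass <= 0 or self.soil_mass <= 0:
            raise ValidationError("litter_mass and soil_mass must be > 0")

    @property
    def groups(self) -> tuple[str, ...]:
        """Treatment codes plus the no-litter control label."""
        if self.includes_control:
            return self.treatments + ("CK",)
        return self.treatments


def split_mixture_code(code: str, species: Sequence[str] = SPECIES_ORDER) -> tuple[str, ...]:
    """Split a concatenated mixture code (``AhCmPs``) into species codes.

    Codes are matched greedily against the known species list; an
    unrecognised fragment raises :class:`ValidationError`.
    """
    parts: list[str] = []
    rest = code
    while rest:
        for sp in sorted(species, key=len, reverse=True):
            if rest.startswith(sp):
                parts.append(sp)
                rest = rest[len(sp):]
                break
        else:
            raise ValidationError(f"unknown species fragment in litter code {code!r}")
    return tuple(parts)


def mixture_code(species_subset: Sequence[str]) -> str:
    """Canonical mixture code: species concatenated in Ah < Cm < Ps order."""
    order = {sp: i for i, sp in enumerate(SPECIES_ORDER)}
    unknown = [s for s in species_subset if s not in order]
    if unknown:
        # allow unknown species but keep a deterministic lexicographic order
        return "".join(sorted(set(species_subset)))
    return "".join(sorted(set(species_subset), key=order.__getitem__))


_PM_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*(?:±|\+/-)\s*(\d+(?:\.\d+)?)\s*$")


def _parse_value_se(cell) -> tuple[float, float]:
    """Accept a bare number or a 'value ± se' text cell."""
    if isinstance(cell, str):
        m = _PM_RE.match(cell)
        if m:
            return float(m.group(1)), float(m.group(2))
        try:
            return float(cell), 0.0
        except ValueError as exc:
            raise ValidationError(f"cell {cell!r} is not numeric or 'v ± s'") from exc
    return float(cell), 0.0


def load_chemistry_table(path=None) -> dict[str, LitterChemistry]:
    """Load a wide-form litter chemistry CSV (one row per litter code).

    Columns: ``litter_code`` plus, for each trait, either ``<trait>`` and
    ``<trait>_se`` (two-column dialect) or a single ``<trait>`` column whose
    cells may read ``value ± se``.  With ``path=None`` the packaged fixture
    of measured single-species and mixture chemistry is loaded.

    Every mixture code's constituent species must be present as singles.
    """
    if path is None:
        with resources.files("primesplit.data").joinpath("litter_chemistry.csv").open() as fh:
            df = pd.read_csv(fh, dtype={"litter_code": str})
    else:
        df = pd.read_csv(path, dtype={"litter_code": str})
    if df.empty:
        raise ValidationError("chemistry table is empty")
    if "litter_code" not in df.columns:
        raise ValidationError("chemistry table: missing column 'litter_code'")
    missing = [t for t in TRAITS if t not in df.columns]
    if missing:
        raise ValidationError(f"chemistry table: missing trait columns {missing}")
    dupes = df["litter_code"][df["litter_code"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"chemistry table: duplicate litter codes {dupes}")

    records: dict[str, LitterChemistry] = {}
    for i, row in df.iterrows():
        code = row["litter_code"]
        values: dict[str, float] = {}
        ses: dict[str, float] = {}
        for trait in TRAITS:
            try:
                v, s = _parse_value_se(row[trait])
            except ValidationError as exc:
                raise ValidationError(f"row {i} ({code}), column {trait}: {exc}") from exc
            se_col = f"{trait}_se"
            if se_col in df.columns and not pd.isna(row[se_col]):
                s = float(row[se_col])
            values[trait], ses[trait] = v, s
        records[code] = LitterChemistry(code, values, ses)

    for code, rec in records.items():
        for sp in rec.constituents:
            if sp not in records:
                raise ValidationError(
                    f"mixture {code!r}: constituent species {sp!r} has no single-species row"
                )
    return records


def load_chemistry_table_long(path) -> dict[str, LitterChemistry]:
    """Load the long-form dialect: columns litter_code, trait, value, se."""
    df = pd.read_csv(path, dtype={"litter_code": str, "trait": str})
    required = {"litter_code", "trait", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"long-form chemistry table: need columns {sorted(required)}"
        )
    if df.empty:
        raise ValidationError("chemistry table is empty")
    dup = df.duplicated(subset=["litter_code", "trait"])
    if dup.any():
        raise ValidationError(
            f"long-form chemistry table: duplicate (litter_code, trait) rows at index {df.index[dup].tolist()}"
        )
    records: dict[str, LitterChemistry] = {}
    for code, grp in df.groupby("litter_code", sort=False):
        values = dict(zip(grp["trait"], grp["value"].astype(float)))
        if "se" in grp.columns:
            ses = dict(zip(grp["trait"], grp["se"].fillna(0.0).astype(float)))
        else:
            ses = {t: 0.0 for t in values}
        records[str(code)] = LitterChemistry(str(code), values, ses)
    for code, rec in records.items():
        for sp in rec.constituents:
            if sp not in records:
                raise ValidationError(
                    f"mixture {code!r}: constituent species {sp!r} has no single-species row"
                )
    return records


def chemistry_to_frame(records: Mapping[str, LitterChemistry]) -> pd.DataFrame:
    """Wide DataFrame view (one row per litter, trait and trait_se columns)."""
    rows = []
    for code, rec in records.items():
        row: dict[str, object] = {"litter_code": code}
        for t in TRAITS:
            row[t] = rec.values[t]
            row[f"{t}_se"] = rec.se(t)
        rows.append(row)
    return pd.DataFrame(rows)


def enumerate_treatments(
    species_codes: Sequence[str],
    max_order: int | None = None,
    *,
    replicates_per_treatment: int = 5,
    litter_mass: float = 2.0,
    soil_mass: float = 200.0,
    includes_control: bool = True,
) -> TreatmentDesign:
    """All non-empty species subsets of size <= max_order, as treatment codes.

    Singles come first, then each higher order, lexicographic (canonical
    species order) within an order.  Three species at full order give the
    seven-treatment design (Ah, Cm, Ps, AhCm, AhPs, CmPs, AhCmPs).
    """
    species = tuple(dict.fromkeys(species_codes))
    if not species:
        raise ValidationError("species_codes must be non-empty")
    if max_order is None:
        max_order = len(species)
    if not 1 <= max_order <= len(species):
        raise ValidationError(
            f"max_order must be in [1, {len(species)}], got {max_order}"
        )
    order = {sp: i for i, sp in enumerate(SPECIES_ORDER)}
    species = tuple(sorted(species, key=lambda s: order.get(s, len(order))))
    treatments = tuple(
        mixture_code(combo)
        for size in range(1, max_order + 1)
        for combo in itertools.combinations(species, size)
    )
    return TreatmentDesign(
        species_codes=species,
        treatments=treatments,
        replicates_per_treatment=replicates_per_treatment,
        litter_mass=litter_mass,
        soil_mass=soil_mass,
        includes_control=includes_control,
    )


def expected_mixture_chemistry(
    singles: Mapping[str, LitterChemistry], mix_code: str
) -> LitterChemistry:
    """Equal-proportion expectation for a mixture's chemistry.

    Each trait is the arithmetic mean over constituents (equal mass
    shares); SEs combine as sqrt(sum SE^2)/k.  The result is flagged
    ``expected`` and must never replace measured mixture values in the
    isotope partitioning.
    """
    parts = split_mixture_code(mix_code)
    missing = [sp for sp in parts if sp not in singles]
    if missing:
        raise ValidationError(f"mixture {mix_code!r}: missing constituents {missing}")
    k = len(parts)
    values = {
        t: sum(float(singles[sp].values[t]) for sp in parts) / k for t in TRAITS
    }
    ses = {
        t: math.sqrt(sum(singles[sp].se(t) ** 2 for sp in parts)) / k for t in TRAITS
    }
    return LitterChemistry(mixture_code(parts), values, ses, expected=True)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def chemistry_ratio(
    table: Mapping[str, LitterChemistry],
    trait: str,
    numerator_code: str,
    denominator_code: str,
    as_percent_rounded: bool = False,
) -> float | int:
    """Percent ratio of one litter's trait to another's: 100·num/den.

    With ``as_percent_rounded`` the result is rounded half-away-from-zero
    to an integer percent, the convention used for printed trait ratios.
    """
    if trait not in TRAITS:
        raise ValidationError(f"unknown trait {trait!r}")
    for code in (numerator_code, denominator_code):
        if code not in table:
            raise ValidationError(f"litter code {code!r} not in chemistry table")
    den = float(table[denominator_code].values[trait])
    if den == 0:
        raise ValidationError(
            f"denominator trait {trait} of {denominator_code!r} is zero"
        )
    ratio = 100.0 * float(table[numerator_code].values[trait]) / den
    if as_percent_rounded:
        return round_half_away(ratio)
    return ratio


def mass_weighted_d13c(singles: Mapping[str, LitterChemistry], mix_code: str) -> float:
    """Diagnostic C-mass-weighted δ13C of an equal-proportion mixture.

    Weighted by constituent C concentration; the measured mixture δ13C
    from the chemistry table remains the partitioning end-member.
    """
    parts = split_mixture_code(mix_code)
    missing = [sp for sp in parts if sp not in singles]
    if missing:
        raise ValidationError(f"mixture {mix_code!r}: missing constituents {missing}")
    c_mass = [float(singles[sp].values["C"]) for sp in parts]
    d13 = [float(singles[sp].values["d13C"]) for sp in parts]
    return sum(c * d for c, d in zip(c_mass, d13)) / sum(c_mass)
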