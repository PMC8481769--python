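"""File-format contracts: jar tables, abundance tables, input validation.

All tables are plain CSV with header rows.  Missing values are empty
cells, never sentinel numbers.  Schemas:

* ``jars.csv`` — one row per jar: jar_id, treatment_code, replicate,
  soil_mass, litter_mass, litter_C_added, SOC_initial, TOC_final,
  d13C_final, d13C_native, d13C_litter.
* ``chemistry.csv`` — wide form (litter_code + trait / trait_se columns)
  or long form (litter_code, trait, value, se).
* ``abundance.csv`` — long form: sample_id, taxon_id, level, count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import pandas as pd

from .chemistry import LitterChemistry, load_chemistry_table, load_chemistry_table_long
from .errors import ValidationError
from .partitioning import CONTROL_CODE, JarObservation

JAR_COLUMNS = (
    "jar_id",
    "treatment_code",
    "replicate",
    "soil_mass",
    "litter_mass",
    "litter_C_added",
    "SOC_initial",
    "TOC_final",
    "d13C_final",
    "d13C_native",
    "d13C_litter",
)


def load_jars(path) -> list[JarObservation]:
    """Read jars.csv into validated observations."""
    df = pd.read_csv(path, dtype={"jar_id": str, "treatment_code": str})
    missing = [c for c in JAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"jars table: missing columns {missing}")
    dupes = df["jar_id"][df["jar_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"jars table: duplicate jar ids {dupes}")
    obs = []
    for i, row in df.iterrows():
        try:
            obs.append(
                JarObservation(
                    jar_id=row["jar_id"],
                    treatment_code=row["treatment_code"],
                    replicate=int(row["replicate"]),
                    soil_mass=float(row["soil_mass"]),
                    litter_mass=float(row["litter_mass"]),
                    litter_C_added=float(row["litter_C_added"]),
                    SOC_initial=float(row["SOC_initial"]),
                    TOC_final=float(row["TOC_final"]),
                    d13C_final=float(row["d13C_final"]),
                    d13C_native=float(row["d13C_native"]),
                    d13C_litter=float(row["d13C_litter"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"jars table row {i}: {exc}") from exc
    return obs


def load_chemistry(path) -> dict[str, LitterChemistry]:
    """Read chemistry.csv, auto-detecting the wide vs long dialect."""
    head = pd.read_csv(path, nrows=0)
    if {"trait", "value"}.issubset(head.columns):
        return load_chemistry_table_long(path)
    return load_chemistry_table(path)


def load_abundance(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "taxon_id": str, "level": str})
    required = {"sample_id", "taxon_id", "level", "count"}
    if not required.issubset(df.columns):
        raise ValidationError(f"abundance table: need columns {sorted(required)}")
    return df


@dataclass
class ValidationReport:
    """Schema / join / unit-sanity findings, split into errors and warnings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    jars_path=None, chemistry_path=None, abundance_path=None
) -> ValidationReport:
    """Check schemas, join keys and unit sanity across the input files.

    Unit sanity: δ values inside (−40, 0) ‰ (a value outside is a
    warning, not an error); carbon pools positive; litter treatments must
    join to a chemistry row; a control group must exist for priming.
    """
    report = ValidationReport()
    jars: list[JarObservation] = []
    chem: dict[str, LitterChemistry] = {}

    if chemistry_path is not None:
        try:
            chem = load_chemistry(chemistry_path)
        except (ValidationError, OSError, pd.errors.ParserError) as exc:
            report.errors.append(f"chemistry: {exc}")
    if jars_path is not None:
        try:
            jars = load_jars(jars_path)
        except (ValidationError, OSError, pd.errors.ParserError) as exc:
            report.errors.append(f"jars: {exc}")

    for o in jars:
        for name in ("d13C_final", "d13C_native"):
            v = getattr(o, name)
            if not -40.0 < v < 0.0:
                report.warnings.append(
                    f"jar {o.jar_id}: {name} = {v}‰ outside the plausible (−40, 0) range"
                )
        if not o.is_control and not -40.0 < o.d13C_litter < 0.0:
            report.warnings.append(
                f"jar {o.jar_id}: d13C_litter = {o.d13C_litter}‰ outside (−40, 0)"
            )
        if o.SOC_initial <= 0:
            report.errors.append(f"jar {o.jar_id}: SOC_initial must be positive")
        if chem and not o.is_control and o.treatment_code not in chem:
            report.errors.append(
                f"jar {o.jar_id}: treatment {o.treatment_code!r} has no chemistry row"
            )
    if jars and not any(o.is_control for o in jars):
        report.warnings.append(
            f"no {CONTROL_CODE} jars present; priming contrasts will be unavailable"
        )

    if abundance_path is not None:
        try:
            ab = load_abundance(abundance_path)
            if jars:
                jar_ids = {o.jar_id for o in jars}
                orphans = sorted(set(ab["sample_id"]) - jar_ids)
                if orphans:
                    report.warnings.append(
                        f"abundance samples with no matching jar: {orphans[:5]}"
                    )
        except (ValidationError, OSError, pd.errors.ParserError) as exc:
            report.errors.append(f"abundance: {exc}")
    return report


def fixture_checksum() -> str:
    """SHA-256 of the packaged litter chemistry fixture (for --version)."""
    import hashlib
    from importlib import resources

    data = (
        resources.files("primesplit.data")
        .joinpath("litter_chemistry.csv")
        .read_bytes()
    )
    return hashlib.sha256(data).hexdigest()[:12]
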