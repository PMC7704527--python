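"""Published QSAR equations and drug-likeness screening rules.

Holds the four published anti-proliferative (MCF-7) pIC50 equations at full
printed precision, the Lipinski rule-of-five filter, and the six-axis
bioavailability-radar range check.  Property values (MW, TPSA, logP, ...)
are consumed from tables produced by external property calculators; nothing
here derives properties from structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data import _read_csv
from .errors import ParseError
from .regression import LinearModel

__all__ = [
    "PUBLISHED_MODELS",
    "published_model",
    "PropertyProfile",
    "RuleOfFiveResult",
    "RadarResult",
    "lipinski_violations",
    "radar_check",
    "screen_table",
    "read_property_table",
    "ScreeningSummary",
    "RO5_THRESHOLDS",
    "RADAR_RANGES",
]

#: The four published equations, coefficients kept at full printed precision.
PUBLISHED_MODELS: dict[int, LinearModel] = {
    1: LinearModel(
        name="model_1",
        descriptor_names=("MATS4e", "GATS5e", "SpMax4_Bhs", "RDF150u"),
        coefficients=(4.888518176, -2.570261057, -1.514002889, 0.086137333),
        intercept=13.256220911,
    ),
    2: LinearModel(
        name="model_2",
        descriptor_names=("ALogp2", "MATS4e", "GATS5e", "RDF150u"),
        coefficients=(-0.018183153, 4.669978294, -1.245497827, 0.065416696),
        intercept=6.326485838,
    ),
    3: LinearModel(
        name="model_3",
        descriptor_names=("ALogp2", "MATS4e", "GATS4e", "RDF150u"),
        coefficients=(-0.021417358, 2.673511925, -1.523695399, 0.061648777),
        intercept=6.593640317,
    ),
    4: LinearModel(
        name="model_4",
        descriptor_names=("MATS4e", "GATS5e", "RDF150u", "P1m"),
        coefficients=(4.242442241, -1.572590496, 0.065174802, -0.392069439),
        intercept=6.739118905,
    ),
}


def published_model(model_id: int) -> LinearModel:
    """Return published equation 1-4 by number."""
    try:
        return PUBLISHED_MODELS[int(model_id)]
    except (KeyError, ValueError, TypeError):
        raise KeyError(
            f"unknown published model {model_id!r}; choose from 1-4"
        ) from None


@dataclass
class PropertyProfile:
    """Physicochemical properties of one compound, as reported by a
    property calculator (units: MW g/mol, TPSA Angstrom^2)."""

    compound_id: str
    mw: float | None = None
    n_aromatic_heavy: int | None = None
    n_rotatable: int | None = None
    hba: int | None = None
    hbd: int | None = None
    mr: float | None = None
    tpsa: float | None = None
    logp: float | None = None
    xlogp3: float | None = None
    esol_logs: float | None = None
    fraction_csp3: float | None = None
    annotations: dict = field(default_factory=dict)  # BBB / PAINS / Brenk etc.


#: Rule-of-five limits; a property strictly above its limit is a violation.
RO5_THRESHOLDS = {"mw": 500.0, "logp": 5.0, "hbd": 5, "hba": 10}

#: Bioavailability-radar ideal ranges (SwissADME conventions).
RADAR_RANGES = {
    "lipophilicity": (-0.7, 5.0),  # XLOGP3
    "size": (150.0, 500.0),  # MW, g/mol
    "polarity": (20.0, 130.0),  # TPSA, A^2
    "solubility": (-6.0, None),  # ESOL log S >= -6
    "saturation": (0.25, None),  # fraction Csp3 >= 0.25
    "flexibility": (None, 9),  # rotatable bonds, strictly < 9
}


@dataclass
class RuleOfFiveResult:
    """Lipinski verdict: a compound passes with at most one violation."""

    compound_id: str
    violations: list[str]

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    @property
    def passes(self) -> bool:
        return self.n_violations <= 1


@dataclass
class RadarResult:
    """Per-axis in-range verdicts; ``None`` marks an axis not evaluated
    because its property was not supplied."""

    compound_id: str
    axes: dict[str, bool | None]

    @property
    def all_in_range(self) -> bool:
        return all(v is True for v in self.axes.values() if v is not None)

    @property
    def not_evaluated(self) -> list[str]:
        return [k for k, v in self.axes.items() if v is None]


def lipinski_violations(
    profile: PropertyProfile, thresholds: dict | None = None
) -> RuleOfFiveResult:
    """Count rule-of-five violations: MW > 500, logP > 5, HBD > 5, HBA > 10.

    All four properties must be present; comparisons are strict, and a
    compound is deemed orally acceptable with at most one violation.
    """
    th = dict(RO5_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    values = {
        "mw": profile.mw,
        "logp": profile.logp if profile.logp is not None else profile.xlogp3,
        "hbd": profile.hbd,
        "hba": profile.hba,
    }
    missing = [k for k, v in values.items() if v is None]
    if missing:
        raise ParseError(
            f"compound {profile.compound_id!r}: missing propert"
            f"{'ies' if len(missing) > 1 else 'y'} {missing} for rule-of-five"
        )
    labels = {
        "mw": f"MW>{th['mw']:g}",
        "logp": f"logP>{th['logp']:g}",
        "hbd": f"HBD>{th['hbd']:g}",
        "hba": f"HBA>{th['hba']:g}",
    }
    violations = [labels[k] for k in ("mw", "logp", "hbd", "hba") if values[k] > th[k]]
    return RuleOfFiveResult(compound_id=profile.compound_id, violations=violations)


def radar_check(
    profile: PropertyProfile, ranges: dict | None = None
) -> RadarResult:
    """Six-axis bioavailability-radar check with configurable ranges.

    Bounds are inclusive except flexibility, which requires strictly fewer
    than 9 rotatable bonds.  Axes whose property is absent are reported as
    not evaluated rather than failing.
    """
    rr = dict(RADAR_RANGES)
    if ranges:
        rr.update(ranges)
    axis_values = {
        "lipophilicity": profile.xlogp3,
        "size": profile.mw,
        "polarity": profile.tpsa,
        "solubility": profile.esol_logs,
        "saturation": profile.fraction_csp3,
        "flexibility": profile.n_rotatable,
    }
    axes: dict[str, bool | None] = {}
    for axis, value in axis_values.items():
        if value is None:
            axes[axis] = None
            continue
        lo, hi = rr[axis]
        ok = True
        if lo is not None:
            ok = ok and value >= lo
        if hi is not None:
            # flexibility is an open upper bound; the others are closed
            ok = ok and (value < hi if axis == "flexibility" else value <= hi)
        axes[axis] = ok
    return RadarResult(compound_id=profile.compound_id, axes=axes)


@dataclass
class ScreeningSummary:
    """Per-compound screening verdicts plus whole-table counts."""

    ro5: list[RuleOfFiveResult]
    radar: list[RadarResult]

    @property
    def n_passing_ro5(self) -> int:
        return sum(r.passes for r in self.ro5)

    @property
    def n_failing_ro5(self) -> int:
        return sum(not r.passes for r in self.ro5)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ro5, radar in zip(self.ro5, self.radar):
            row = {
                "compound_id": ro5.compound_id,
                "ro5_violations": ";".join(ro5.violations),
                "ro5_n_violations": ro5.n_violations,
                "ro5_passes": ro5.passes,
            }
            for axis, verdict in radar.axes.items():
                row[f"radar_{axis}"] = (
                    "not evaluated" if verdict is None else bool(verdict)
                )
            rows.append(row)
        return pd.DataFrame(rows)


def screen_table(
    profiles: list[PropertyProfile],
    ro5_thresholds: dict | None = None,
    radar_ranges: dict | None = None,
) -> ScreeningSummary:
    """Screen a table of compounds through rule-of-five and radar checks."""
    if not profiles:
        raise ValueError("no property profiles to screen")
    return ScreeningSummary(
        ro5=[lipinski_violations(p, ro5_thresholds) for p in profiles],
        radar=[radar_check(p, radar_ranges) for p in profiles],
    )


_PROPERTY_COLUMNS = {
    "mw": "mw",
    "nah": "n_aromatic_heavy",
    "n_aromatic_heavy": "n_aromatic_heavy",
    "nrb": "n_rotatable",
    "n_rotatable": "n_rotatable",
    "hba": "hba",
    "hbd": "hbd",
    "mr": "mr",
    "tpsa": "tpsa",
    "ilogp": "logp",
    "alogp": "logp",
    "logp": "logp",
    "xlogp3": "xlogp3",
    "esol": "esol_logs",
    "logs": "esol_logs",
    "esol_logs": "esol_logs",
    "fsp3": "fraction_csp3",
    "fraction_csp3": "fraction_csp3",
}

_INT_FIELDS = {"n_aromatic_heavy", "n_rotatable", "hba", "hbd"}


def read_property_table(source) -> list[PropertyProfile]:
    """Read a physicochemical property CSV into :class:`PropertyProfile`\\ s.

    Column headers follow the usual property-calculator abbreviations (MW,
    nAH, nRB, HBA, HBD, MR, TPSA, iLOGP, XLOGP3, ...), case-insensitive.
    Unrecognised columns (BBB, PAINS, Brenk, ...) are carried through as
    annotations.
    """
    df = _read_csv(source)
    cols = {c.lower().strip().replace("/", "").replace(".", ""): c for c in df.columns}
    id_col = next(
        (cols[k] for k in ("compound_id", "sno", "name", "id") if k in cols),
        df.columns[0],
    )
    profiles = []
    for row_idx, row in df.iterrows():
        kwargs = {}
        annotations = {}
        for key, col in cols.items():
            if col == id_col:
                continue
            val = row[col]
            if key in _PROPERTY_COLUMNS:
                fieldname = _PROPERTY_COLUMNS[key]
                if pd.isna(val):
                    kwargs[fieldname] = None
                else:
                    try:
                        num = float(val)
                    except (TypeError, ValueError):
                        raise ParseError(
                            f"row {row_idx}, column {col!r}: unparsable "
                            f"numeric {val!r}",
                            row=row_idx,
                            column=col,
                        ) from None
                    kwargs[fieldname] = (
                        int(num) if fieldname in _INT_FIELDS else num
                    )
            else:
                annotations[col] = val
        profiles.append(
            PropertyProfile(
                compound_id=str(row[id_col]).strip(),
                annotations=annotations,
                **kwargs,
            )
        )
    return profiles
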