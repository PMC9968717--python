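"""Population parameters of the benazeprilat-RAAS model.

The model ships with a machine-readable defaults file holding the full
population parameter table: typical values (fixed effects), the SD of the
inter-individual random effect on each parameter, the link function used to
realize individual parameters, and the proportional residual-error SDs.
Keys in the defaults file follow the programming-language variable names of
the published table (``Frxn_0abs_pop``, ``Shcc_pop``, ...) so every number
can be audited 1:1; this module maps them onto the field names used by the
dynamical core.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path

__all__ = [
    "FixedEffects",
    "IIVSpec",
    "ModelConstants",
    "ConfigurationError",
    "load_defaults",
    "default_parameter_path",
    "parameter_file_checksum",
    "TABLE_KEY_TO_FIELD",
]


class ConfigurationError(ValueError):
    """Raised when a parameter set or configuration is invalid."""


#: defaults-file key -> FixedEffects field name (1:1 audit trail)
TABLE_KEY_TO_FIELD = {
    "Frxn_0abs_pop": "F0abs",
    "F_bio_pop": "Fbio",
    "Frxn_ACE_fr_pop": "FACEfr",
    "delta_24hr_pop": "delta24hr",
    "Vpl_pop": "Vpl",
    "Vts_pop": "Vts",
    "Vns_pop": "Vns",
    "Vrn_pop": "Vrn",
    "Qfr_ns_pop": "Qfr_ns",
    "Qfr_ts_pop": "Qfr_ts",
    "Qrn_pop": "Qrn",
    "ACE_total_pop": "ACEtotal",
    "Shcc_pop": "S0",
    "Phcc_pop": "P0",
    "Ang17hcc_pop": "Ang17_0",
    "AngIIIhcc_pop": "AngIII0",
    "AngIVhcc_pop": "AngIV0",
    "ka1_pop": "ka1",
    "ka_pop": "ka",
    "Cl_pop": "ClI",
    "ClP_pop": "ClP",
    "ClS_pop": "ClS",
    "ClAng17_pop": "ClAng17",
    "ClAngIII_pop": "ClAngIII",
    "ClAngIV_pop": "ClAngIV",
    "kd_pop": "kd",
    "k1_s_pop": "k1s",
    "k2_s_pop": "k2s",
    "k3_s_pop": "k3s",
    "kI_17_pop": "kI17",
    "kII_17_pop": "kII17",
    "kII_III_pop": "kII_III",
    "kIII_IV_pop": "kIII_IV",
    "PRA_pop": "PRA",
    "r_S_pop": "rS",
    "bAngI_1to10": "bAngI",
    "bAngII_1to8": "bAngII",
    "bAngIII_2to8": "bAngIII",
    "bAngIV_3to8": "bAngIV",
    "bAng_1to7": "bAng17",
    "bconcentration": "bBenazeprilat",
}

_FIELD_TO_KEY = {v: k for k, v in TABLE_KEY_TO_FIELD.items()}

# fields that must lie in (0, 1]; PRA handled separately (clock time)
_FRACTION_FIELDS = ("F0abs", "Fbio", "FACEfr")
_NONNEG_FIELDS = ("delta24hr",)
# residual-error SDs: non-negative
_ERROR_FIELDS = (
    "bAngI",
    "bAngII",
    "bAngIII",
    "bAngIV",
    "bAng17",
    "bBenazeprilat",
)


@dataclasses.dataclass(frozen=True)
class FixedEffects:
    """Typical-value parameter vector of one (virtual) dog.

    Values are stored exactly as printed in the population parameter table:
    volumes in L, flows and clearances in L/h, first-order rates in 1/h,
    baseline concentrations in pmol/L, the enzyme rate constants ``k1s``,
    ``k2s``, ``k3s`` in 1/s on the published "scaled" convention, and
    ``ACEtotal`` / ``rS`` on the model's internal micromolar amount scale.
    Conversion to a single consistent unit system (pmol, L, h) happens in
    :func:`raassim.model.derive_rates`.
    """

    F0abs: float
    Fbio: float
    FACEfr: float
    delta24hr: float
    Vpl: float
    Vts: float
    Vns: float
    Vrn: float
    Qfr_ns: float
    Qfr_ts: float
    Qrn: float
    ACEtotal: float
    S0: float
    P0: float
    Ang17_0: float
    AngIII0: float
    AngIV0: float
    ka1: float
    ka: float
    ClI: float
    ClP: float
    ClS: float
    ClAng17: float
    ClAngIII: float
    ClAngIV: float
    kd: float
    k1s: float
    k2s: float
    k3s: float
    kI17: float
    kII17: float
    kII_III: float
    kIII_IV: float
    PRA: float
    rS: float
    bAngI: float
    bAngII: float
    bAngIII: float
    bAngIV: float
    bAng17: float
    bBenazeprilat: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None or not isinstance(v, (int, float)):
                raise ConfigurationError(f"parameter {f.name!r} is missing or non-numeric")
            if v != v or v in (float("inf"), float("-inf")):
                raise ConfigurationError(f"parameter {f.name!r} is non-finite")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"fraction {name!r}={v} outside [0, 1]")
        for name in _NONNEG_FIELDS + _ERROR_FIELDS:
            if getattr(self, name) < 0.0:
                raise ConfigurationError(f"parameter {name!r} must be non-negative")
        if not 0.0 <= self.PRA < 24.0:
            raise ConfigurationError(f"PRA={self.PRA} outside the 24-h clock [0, 24)")
        for name in (
            "Vpl", "Vts", "Vns", "Vrn", "Qfr_ns", "Qfr_ts", "Qrn", "ACEtotal",
            "S0", "P0", "Ang17_0", "AngIII0", "AngIV0", "ka1", "ka", "ClI",
            "ClP", "ClS", "ClAng17", "ClAngIII", "ClAngIV", "kd", "k1s",
            "k2s", "k3s", "kI17", "kII17", "kII_III", "kIII_IV", "rS",
        ):
            if getattr(self, name) <= 0.0:
                raise ConfigurationError(f"parameter {name!r} must be strictly positive")

    def replace(self, **overrides: float) -> "FixedEffects":
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class IIVSpec:
    """Inter-individual-variability specification.

    ``omega`` maps each parameter (FixedEffects field name) to the SD of its
    normal random effect on the transformed scale; ``link`` maps it to the
    link function (``"lognormal"``, ``"logitnormal"`` or ``"none"``).
    Parameters with no estimated random effect carry ``omega == 0`` and
    ``link == "none"``; entries whose random effect was fixed to the small
    exploratory value (SD 0.030) keep that SD.  The random-effect covariance
    is diagonal: no correlations were estimated.
    """

    omega: dict[str, float]
    link: dict[str, str]

    def __post_init__(self) -> None:
        for name, w in self.omega.items():
            if w < 0:
                raise ConfigurationError(f"omega for {name!r} must be >= 0")
            lk = self.link.get(name, "none")
            if lk not in ("lognormal", "logitnormal", "none"):
                raise ConfigurationError(f"unknown link {lk!r} for {name!r}")

    def varying(self) -> list[str]:
        """Names of parameters with a non-zero random effect, in field order."""
        return [n for n, w in self.omega.items() if w > 0.0]


@dataclasses.dataclass(frozen=True)
class ModelConstants:
    """Fixed physical constants pinned in the defaults file."""

    mw_benazepril_hcl: float  # g/mol
    mw_benazeprilat: float  # g/mol
    amount_scale: float  # pmol per internal amount unit (umol)
    rate_scale: float  # per-hour units per published per-second unit


def default_parameter_path() -> Path:
    """Path of the packaged parameter defaults file."""
    return Path(resources.files("raassim").joinpath("data/parameters.json"))


def load_defaults(
    path: str | Path | None = None,
    overrides: dict[str, float] | None = None,
) -> tuple[FixedEffects, IIVSpec, ModelConstants]:
    """Load (fixed effects, IIV spec, constants) from a defaults file.

    Parameters
    ----------
    path:
        JSON parameter file; ``None`` loads the packaged defaults.
    overrides:
        Optional ``{field or table key: typical value}`` replacements applied
        to the fixed effects after loading (IIV SDs are unchanged).
    """
    path = Path(path) if path is not None else default_parameter_path()
    with open(path) as fh:
        raw = json.load(fh)

    records = raw["parameters"]
    missing = set(TABLE_KEY_TO_FIELD) - set(records)
    if missing:
        raise ConfigurationError(f"parameter file {path} is missing entries: {sorted(missing)}")

    values: dict[str, float] = {}
    omega: dict[str, float] = {}
    link: dict[str, str] = {}
    for key, field in TABLE_KEY_TO_FIELD.items():
        rec = records[key]
        try:
            values[field] = float(rec["value"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad value for {key!r} in {path}") from exc
        omega[field] = float(rec.get("iiv_sd", 0.0))
        link[field] = str(rec.get("link", "none"))

    if overrides:
        for key, val in overrides.items():
            field = TABLE_KEY_TO_FIELD.get(key, key)
            if field not in values:
                raise ConfigurationError(f"unknown parameter override {key!r}")
            values[field] = float(val)

    consts = raw.get("constants", {})

    def _const(name: str, fallback: float) -> float:
        rec = consts.get(name)
        return float(rec["value"]) if rec else fallback

    constants = ModelConstants(
        mw_benazepril_hcl=_const("MW_BENAZEPRIL_HCL", 460.96),
        mw_benazeprilat=_const("MW_BENAZEPRILAT", 396.44),
        amount_scale=_const("AMOUNT_SCALE", 1e6),
        rate_scale=_const("RATE_SCALE", 3600.0),
    )
    return FixedEffects(**values), IIVSpec(omega=omega, link=link), constants


def parameter_file_checksum(path: str | Path | None = None) -> str:
    """SHA-256 checksum of the parameter file (for run manifests)."""
    path = Path(path) if path is not None else default_parameter_path()
    return hashlib.sha256(path.read_bytes()).hexdigest()


def table_key(field: str) -> str:
    """The defaults-file (audit) key for a FixedEffects field."""
    return _FIELD_TO_KEY[field]
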